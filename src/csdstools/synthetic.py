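"""Seeded synthetic cohorts with recorded ground truth.

Every generator emulates the statistical structure of one data modality of a
chronic-social-defeat-stress experiment — behavioral test battery, rotarod
and reaching motor learning, longitudinal spine presence, microglia /
dendrite confocal fields, and a CSF protein-group intensity matrix — and
returns both the observable data and the planted ground truth, so every
downstream estimator can be tested for parameter recovery without any
external data.

Randomness: each generator draws from an independent stream derived from
``(config.seed, stage_tag)``; identical config and seed give bit-identical
outputs, and adding a stage never perturbs earlier ones.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiLineString
from skimage.draw import line as draw_line
from scipy.ndimage import binary_dilation
from skimage.morphology import disk

from .config import PHENOTYPES, ConfigError, SimulationConfig

__all__ = [
    "gen_behavior",
    "gen_rotarod",
    "gen_reaching",
    "gen_spine_timeline",
    "gen_microglia_image",
    "gen_coloc_image",
    "gen_proteome",
    "MicrogliaField",
    "ColocField",
]

CUTOFFS = (60.0, 4.0, 50.0)  # sucrose %, nestlet score, interaction s
VALUE_BOUNDS = ((0.0, 100.0), (0.0, 5.0), (0.0, np.inf))


def gen_behavior(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Behavioral test battery for control and stressed animals.

    Stressed animals come from a two-component mixture: a planted susceptible
    fraction whose test means lie ``effect`` beyond each pathological cutoff,
    and a healthy component shared with controls.  Values are truncated to
    their physical ranges (0-100 %, 0-5, >= 0 s) after noise addition.

    Returns the records table and a ground-truth table with the planted
    phenotype per animal.
    """
    rng = config.rng("behavior")
    bp = config.behavior
    n_sus = int(np.round(config.n_stressed * config.susceptible_fraction))
    planted = ["susceptible"] * n_sus + ["resilient"] * (config.n_stressed - n_sus)
    rows, truth = [], []
    pathological_means = [c - e for c, e in zip(CUTOFFS, bp.effect)]
    animal_iter = itertools.count(1)
    for group, n in (("control", config.n_control), ("stressed", config.n_stressed)):
        for i in range(n):
            aid = f"m{next(animal_iter):03d}"
            phen = planted[i] if group == "stressed" else "control"
            vals = []
            for j in range(3):
                if phen == "susceptible":
                    v = rng.normal(pathological_means[j], bp.susceptible_sd[j])
                else:
                    v = rng.normal(bp.healthy_mean[j], bp.healthy_sd[j])
                lo, hi = VALUE_BOUNDS[j]
                vals.append(float(np.clip(v, lo, hi)))
            rows.append(
                dict(animal_id=aid, group=group,
                     sucrose_preference_pct=vals[0], nestlet_score=vals[1],
                     interaction_time_s=vals[2]))
            truth.append(dict(animal_id=aid, planted_phenotype=phen))
    return pd.DataFrame(rows), pd.DataFrame(truth)


def gen_rotarod(
    config: SimulationConfig, labels: pd.DataFrame, n_trials: int = 15,
    cap_s: float = 90.0,
) -> pd.DataFrame:
    """Rotarod trial times: Hill curve per phenotype plus Gaussian noise,
    clipped to [0, cap].

    ``labels`` maps animal_id to planted_phenotype (ground truth of
    :func:`gen_behavior`).  Returns a long table (animal_id, trial, time_s).
    """
    from .motor import hill_curve

    rng = config.rng("rotarod")
    rows = []
    x = np.arange(1, n_trials + 1, dtype=float)
    for _, rec in labels.iterrows():
        phen = rec["planted_phenotype"]
        if phen not in config.rotarod:
            raise ConfigError(f"no rotarod parameters for phenotype {phen!r}")
        p = config.rotarod[phen]
        clean = hill_curve(x, p.t0, p.tmax, p.ls50, p.h)
        noisy = clean + (rng.normal(0.0, p.noise_sd, n_trials) if p.noise_sd > 0
                         else 0.0)
        times = np.clip(noisy, 0.0, cap_s)
        for t, v in zip(range(1, n_trials + 1), times):
            rows.append(dict(animal_id=rec["animal_id"], trial=t, time_s=float(v)))
    return pd.DataFrame(rows)


def gen_reaching(config: SimulationConfig, labels: pd.DataFrame,
                 n_pellets: int = 48) -> pd.DataFrame:
    """Skilled-reaching outcomes: 5 days x 48 Bernoulli pellets per animal."""
    rng = config.rng("reaching")
    rows = []
    for _, rec in labels.iterrows():
        phen = rec["planted_phenotype"]
        probs = config.reaching[phen]
        for day, q in enumerate(probs, start=1):
            outcomes = rng.random(n_pellets) < q
            for pellet, s in enumerate(outcomes, start=1):
                rows.append(dict(animal_id=rec["animal_id"], day=day,
                                 pellet=pellet, success=bool(s)))
    return pd.DataFrame(rows)


def gen_spine_timeline(
    config: SimulationConfig,
    labels: pd.DataFrame,
    taskborn_sessions: tuple[int, ...] = (5, 11),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Longitudinal spine presence as a discrete birth-death process.

    Per imaging interval each existing spine dies with the phenotype's loss
    probability and new spines are born at the gain rate (Poisson, per
    existing spine).  Spines first appearing at a session listed in
    ``taskborn_sessions`` (the sessions right after the motor tasks) instead
    survive their next interval with the planted task-born survival
    probability.  Reappearance never happens: a lost id stays absent.

    Returns the long-format presence table and a per-spine ground-truth table
    (birth/death sessions, task-born flag).
    """
    if len(config.session_days) == 0:
        raise ConfigError("session schedule must not be empty")
    rng = config.rng("spines")
    days = list(config.session_days)
    rows, truth = [], []
    spine_counter = itertools.count(1)
    for _, rec in labels.iterrows():
        phen = rec["planted_phenotype"]
        sp = config.spines[phen]
        for r in range(config.rois_per_animal):
            roi = f"{rec['animal_id']}_roi{r + 1}"
            length = float(rng.uniform(*config.dendrite_length_um))
            n0 = max(1, int(np.round(sp.initial_density_per_um * length)))
            # spine state bookkeeping: birth day, death day (None = alive)
            spines: dict[str, dict] = {}
            for _ in range(n0):
                sid = f"s{next(spine_counter):06d}"
                spines[sid] = dict(birth=days[0], death=None, taskborn=False)
            alive = set(spines)
            for prev_day, day in zip(days, days[1:]):
                survivors = set()
                for sid in sorted(alive):
                    born_last = spines[sid]["birth"] == prev_day
                    if born_last and prev_day in taskborn_sessions:
                        spines[sid]["taskborn"] = True
                        p_die = 1.0 - sp.taskborn_survival
                    else:
                        p_die = sp.loss_prob
                    if rng.random() < p_die:
                        spines[sid]["death"] = day
                    else:
                        survivors.add(sid)
                n_born = rng.poisson(sp.gain_rate * len(alive))
                for _ in range(n_born):
                    sid = f"s{next(spine_counter):06d}"
                    spines[sid] = dict(birth=day, death=None, taskborn=False)
                    survivors.add(sid)
                alive = survivors
            for sid, info in spines.items():
                spine_len = float(rng.uniform(0.5, 2.5))
                for day in days:
                    if day < info["birth"] or (info["death"] is not None and day >= info["death"]):
                        state = "absent"
                    else:
                        state = "present"
                    rows.append(dict(
                        roi_id=roi, animal_id=rec["animal_id"], spine_id=sid,
                        session_day=day, state=state,
                        length_um=spine_len,
                        dendrite_length_um=length,
                    ))
                truth.append(dict(
                    roi_id=roi, animal_id=rec["animal_id"], spine_id=sid,
                    birth_day=info["birth"], death_day=info["death"],
                    taskborn=info["taskborn"], planted_phenotype=phen,
                ))
    return pd.DataFrame(rows), pd.DataFrame(truth)


@dataclass(frozen=True)
class MicrogliaField:
    """One synthetic microglia channel: intensity image, per-cell masks and
    analytic ground truth."""

    image: np.ndarray
    cell_masks: list
    ground_truth: pd.DataFrame
    pixel_size_um: float


def _branch_polylines(rng, soma_rc, n_branches, length_range, bounds):
    """Random stick-figure branches from a soma: straight segments, some with
    one kink, confined to ``bounds`` (rmin, rmax, cmin, cmax).  Returns
    integer-endpoint polylines."""
    rmin, rmax, cmin, cmax = bounds
    polys = []
    # evenly spaced base angles with jitter: processes radiate from the soma
    # without running on top of each other, as in a ramified microglial cell
    spacing = 2 * np.pi / n_branches
    phase = rng.uniform(0, 2 * np.pi)
    for b in range(n_branches):
        angle = phase + b * spacing + rng.uniform(-0.25, 0.25) * spacing
        total = rng.integers(length_range[0], length_range[1] + 1)
        pts = [np.asarray(soma_rc, float)]
        n_seg = 1 + int(rng.random() < 0.5)
        remaining = float(total)
        for s in range(n_seg):
            seg_len = remaining if s == n_seg - 1 else remaining * rng.uniform(0.4, 0.7)
            remaining -= seg_len
            angle += rng.uniform(-0.3, 0.3) if s else 0.0
            nxt = pts[-1] + seg_len * np.array([np.sin(angle), np.cos(angle)])
            nxt = np.array([np.clip(nxt[0], rmin, rmax), np.clip(nxt[1], cmin, cmax)])
            pts.append(nxt)
        polys.append(np.rint(pts).astype(int))
    return polys


def _rasterize_polylines(polys, shape):
    mask = np.zeros(shape, bool)
    n_steps = 0.0
    for pts in polys:
        for (r0, c0), (r1, c1) in zip(pts, pts[1:]):
            rr, cc = draw_line(r0, c0, r1, c1)
            mask[rr, cc] = True
            dr, dc = abs(r1 - r0), abs(c1 - c0)
            n_steps += min(dr, dc) * np.sqrt(2.0) + abs(dr - dc)
    return mask, n_steps


def gen_microglia_image(config: SimulationConfig) -> MicrogliaField:
    """Rasterized stick-figure microglia on a noisy background.

    Cells are placed on non-overlapping tiles; each is a set of branches
    drawn as Bresenham polylines and dilated to a known width.  Ground truth
    per cell: analytic skeleton length (polyline step length), analytic
    convex-hull area (hull of the buffered polylines, shapely) and the exact
    rasterized pixel area.
    """
    ip = config.images
    rng = config.rng("microglia")
    size = ip.image_size_px
    n = ip.n_cells
    tiles = int(np.ceil(np.sqrt(n)))
    tile = size // tiles
    margin = ip.branch_length_px[1] + 3 * ip.branch_width_px + 4
    if tile < 2 * margin:
        raise ConfigError(
            f"image too small for {n} non-overlapping cells of this branch length")
    selem = disk(ip.branch_width_px)
    img = np.full((size, size), float(ip.background_level))
    masks, gt_rows = [], []
    order = rng.permutation(tiles * tiles)[:n]
    for ci, t in enumerate(order):
        tr, tc = divmod(int(t), tiles)
        soma = (tr * tile + tile // 2, tc * tile + tile // 2)
        nb = int(rng.integers(ip.n_branches[0], ip.n_branches[1] + 1))
        # keep the dilated cell strictly inside its tile
        pad = ip.branch_width_px + 2
        bounds = (tr * tile + pad, (tr + 1) * tile - pad - 1,
                  tc * tile + pad, (tc + 1) * tile - pad - 1)
        polys = _branch_polylines(rng, soma, nb, ip.branch_length_px, bounds)
        sk_mask, n_steps = _rasterize_polylines(polys, (size, size))
        cell = binary_dilation(sk_mask, selem)
        # analytic hull area via buffered polylines (pixel-center geometry)
        lines = MultiLineString([LineString(p[:, ::-1].astype(float)) for p in polys])
        hull_area = lines.buffer(ip.branch_width_px + 0.5).convex_hull.area
        masks.append(cell)
        gt_rows.append(dict(
            cell_id=ci,
            skeleton_length_um=n_steps * ip.pixel_size_um,
            hull_area_um2=hull_area * ip.pixel_size_um**2,
            pixel_area_um2=int(cell.sum()) * ip.pixel_size_um**2,
            n_branches=nb,
        ))
        img[cell] = ip.foreground_level
    union = np.zeros((size, size), np.int32)
    for m in masks:
        union += m
    if (union > 1).any():
        raise ConfigError("generated cells overlap; reduce branch length or cell count")
    img += rng.normal(0.0, ip.noise_sd, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return MicrogliaField(img, masks, pd.DataFrame(gt_rows), ip.pixel_size_um)


@dataclass(frozen=True)
class ColocField:
    """Two-channel dendrite (green) / microglia (red) binary field."""

    mask_green: np.ndarray
    mask_red: np.ndarray
    segment_rois: list
    ground_truth: pd.DataFrame
    pixel_size_um: float


def gen_coloc_image(config: SimulationConfig) -> ColocField:
    """Dendrite segments with a planted red-overlap fraction.

    Each green segment is a straight line of at least 30 um; exactly
    ``round(fraction * n_pixels)`` of its pixels are also set in the red
    channel, so the measured yellow/(yellow+green) ratio equals the planted
    fraction up to rounding, deterministically.  Additional red-only clutter
    avoids green pixels.
    """
    ip = config.images
    rng = config.rng("coloc")
    size = ip.image_size_px
    green = np.zeros((size, size), bool)
    red = np.zeros((size, size), bool)
    rois, gt = [], []
    min_len_px = int(np.ceil(30.0 / ip.pixel_size_um))
    for s in range(ip.n_segments):
        length = int(rng.integers(max(ip.segment_length_px[0], min_len_px),
                                  ip.segment_length_px[1] + 1))
        for _ in range(100):
            r0 = int(rng.integers(5, size - 5))
            c0 = int(rng.integers(5, size - 5))
            angle = rng.uniform(0, 2 * np.pi)
            r1 = int(np.clip(round(r0 + length * np.sin(angle)), 2, size - 3))
            c1 = int(np.clip(round(c0 + length * np.cos(angle)), 2, size - 3))
            if np.hypot(r1 - r0, c1 - c0) >= min_len_px:
                break
        else:
            raise ConfigError("could not place dendrite segment")
        rr, cc = draw_line(r0, c0, r1, c1)
        seg = np.zeros((size, size), bool)
        new = ~green[rr, cc]
        seg[rr[new], cc[new]] = True
        green |= seg
        px = np.argwhere(seg)
        n_yellow = int(round(ip.coloc_fraction * len(px)))
        chosen = px[rng.permutation(len(px))[:n_yellow]]
        red[chosen[:, 0], chosen[:, 1]] = True
        seg_len_um = np.hypot(r1 - r0, c1 - c0) * ip.pixel_size_um
        rois.append(seg)
        gt.append(dict(segment_id=s, n_pixels=int(len(px)), n_overlap=n_yellow,
                       planted_fraction=(n_yellow / len(px) if len(px) else np.nan),
                       length_um=seg_len_um))
    # red-only clutter (microglia processes) that never touches green
    for _ in range(ip.n_segments):
        r0 = int(rng.integers(5, size - 5)); c0 = int(rng.integers(5, size - 5))
        ang = rng.uniform(0, 2 * np.pi); ln = int(rng.integers(40, 90))
        r1 = int(np.clip(round(r0 + ln * np.sin(ang)), 2, size - 3))
        c1 = int(np.clip(round(c0 + ln * np.cos(ang)), 2, size - 3))
        rr, cc = draw_line(r0, c0, r1, c1)
        keep = ~green[rr, cc]
        red[rr[keep], cc[keep]] = True
    return ColocField(green, red, rois, pd.DataFrame(gt), ip.pixel_size_um)


def gen_proteome(config: SimulationConfig) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Protein-group x sample intensity matrix with spiked fold changes.

    Log-normal intensities: per-protein base level, per-sample loading
    offset, Gaussian measurement noise.  ``n_spiked`` proteins are shifted by
    ``spike_log2fc`` in the susceptible group and another ``n_spiked`` in the
    resilient group (half up, half down); entries go missing completely at
    random at the missing rate.

    Returns (raw intensity matrix, sample->group design, ground truth with
    the planted per-comparison log2 differences).
    """
    pp = config.proteome
    rng = config.rng("proteome")
    n = pp.n_proteins
    samples, design = [], {}
    for g, size in zip(("control", "resilient", "susceptible"), pp.group_sizes):
        for i in range(size):
            sid = f"{g[:3]}_{i + 1:02d}"
            samples.append(sid)
            design[sid] = g
    proteins = [f"P{i + 1:05d}" for i in range(n)]
    base = rng.normal(pp.base_mean_log2, pp.base_sd_log2, n)
    offsets = rng.normal(0.0, pp.sample_offset_sd_log2, len(samples))
    shift = pd.DataFrame(0.0, index=proteins, columns=["resilient", "susceptible"])
    idx = rng.permutation(n)[: 2 * pp.n_spiked]
    sus_idx, res_idx = idx[: pp.n_spiked], idx[pp.n_spiked:]
    for which, rows_ in (("susceptible", sus_idx), ("resilient", res_idx)):
        signs = np.where(np.arange(len(rows_)) % 2 == 0, 1.0, -1.0)
        shift.iloc[rows_, shift.columns.get_loc(which)] = signs * pp.spike_log2fc
    log2 = (
        base[:, None]
        + offsets[None, :]
        + rng.normal(0.0, pp.sample_sd_log2, (n, len(samples)))
    )
    for j, sid in enumerate(samples):
        g = design[sid]
        if g in shift.columns:
            log2[:, j] += shift[g].to_numpy()
    intens = np.power(2.0, log2)
    if pp.missing_rate > 0:
        intens[rng.random(intens.shape) < pp.missing_rate] = np.nan
    matrix = pd.DataFrame(intens, index=proteins, columns=samples)
    truth = pd.DataFrame(index=pd.Index(proteins, name="protein"))
    truth["delta_sus_ctrl"] = shift["susceptible"]
    truth["delta_res_ctrl"] = shift["resilient"]
    truth["delta_sus_res"] = shift["susceptible"] - shift["resilient"]
    truth["spiked"] = (shift != 0).any(axis=1).to_numpy()
    return matrix, pd.Series(design), truth
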