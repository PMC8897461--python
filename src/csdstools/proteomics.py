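"""CSF label-free proteomics regulation calling.

The workflow mirrors a Perseus-style analysis of a protein-group x sample
intensity matrix with three groups (control, resilient, susceptible):
valid-value filtering (at least two observations per group), optional
contaminant removal, log2 transform, per-sample median subtraction, group
averaging, two-sided Significance-A outlier detection on the per-protein
group-mean differences, Benjamini-Hochberg FDR adjustment, and regulation
calling at FDR < 0.05 with at least two-fold change.

Significance A estimates asymmetric spreads of the difference distribution
from its 15.87th / 84.13th percentiles (one-sigma quantiles of a Gaussian):
with m the median, sigma_right = P84.13 - m and sigma_left = m - P15.87, the
z-score of a difference d is (d - m)/sigma_right for d >= m and
(m - d)/sigma_left otherwise; the two-sided p-value is min(1, erfc(z/sqrt(2))).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "COMPARISONS",
    "ComparisonResult",
    "preprocess",
    "filter_min_valid",
    "filter_contaminants",
    "significance_A",
    "bh_adjust",
    "call_regulated",
    "run_all_comparisons",
    "enrichment_hypergeometric",
]

GROUPS = ("control", "resilient", "susceptible")

#: the three intergroup comparisons, as (numerator, denominator) of the ratio
COMPARISONS = {
    "sus/ctrl": ("susceptible", "control"),
    "res/ctrl": ("resilient", "control"),
    "sus/res": ("susceptible", "resilient"),
}

_P_LOW, _P_HIGH = 15.87, 84.13  # one-sigma Gaussian quantiles


def preprocess(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2-transform intensities and median-center every sample.

    Missing entries (NaN) propagate; after centering the observed median of
    every sample is exactly zero.  Non-positive intensities are rejected.
    """
    vals = matrix.to_numpy(dtype=float)
    if np.any(vals[np.isfinite(vals)] <= 0):
        raise ValueError("intensities must be positive where present")
    log2 = np.log2(vals)
    med = np.nanmedian(log2, axis=0)
    return pd.DataFrame(log2 - med, index=matrix.index, columns=matrix.columns)


def filter_min_valid(
    matrix: pd.DataFrame,
    design: Mapping[str, str] | pd.Series,
    min_valid: int = 2,
    scope: str = "all_groups",
) -> tuple[pd.DataFrame, dict]:
    """Drop proteins with too few observed values.

    ``scope='all_groups'`` (default) keeps a protein only when every group
    has at least ``min_valid`` observed values; ``scope='any_group'`` is the
    laxer reading requiring it in at least one group.  Returns the filtered
    matrix and before/after counts.
    """
    if scope not in ("all_groups", "any_group"):
        raise ValueError("scope must be 'all_groups' or 'any_group'")
    design = pd.Series(dict(design)) if not isinstance(design, pd.Series) else design
    missing = [s for s in matrix.columns if s not in design.index]
    if missing:
        raise ValueError(f"samples without group assignment: {missing}")
    observed = matrix.notna()
    per_group = observed.T.groupby(design.loc[matrix.columns]).sum().T
    ok = (per_group >= min_valid)
    keep = ok.all(axis=1) if scope == "all_groups" else ok.any(axis=1)
    out = matrix.loc[keep]
    return out, {"n_before": int(len(matrix)), "n_after": int(len(out)),
                 "n_removed": int(len(matrix) - len(out))}


def filter_contaminants(
    matrix: pd.DataFrame,
    contaminant_ids: Sequence[str] = (),
    flags: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Remove contaminant protein groups by explicit id list and/or flag column."""
    drop = set(contaminant_ids)
    if flags is not None:
        drop |= set(flags.index[flags.astype(bool)])
    keep = [p for p in matrix.index if p not in drop]
    out = matrix.loc[keep]
    return out, {"n_before": int(len(matrix)), "n_after": int(len(out)),
                 "n_removed": int(len(matrix) - len(out))}


def significance_A(deltas) -> np.ndarray:
    """Two-sided Significance-A outlier p-values for log2 differences.

    Spreads come from the 15.87/84.13 percentiles (linear interpolation) of
    the input distribution itself; at the median p = 1, at the 84.13th
    percentile the two-sided p is erfc(1/sqrt(2)) ~ 0.3173.
    """
    d = np.asarray(deltas, dtype=float)
    finite = d[np.isfinite(d)]
    if finite.size < 10:
        raise ValueError("need at least 10 finite differences")
    m = np.percentile(finite, 50)
    sigma_right = np.percentile(finite, _P_HIGH) - m
    sigma_left = m - np.percentile(finite, _P_LOW)
    if sigma_right <= 0 or sigma_left <= 0:
        raise ValueError("degenerate difference distribution (zero spread)")
    z = np.where(d >= m, (d - m) / sigma_right, (m - d) / sigma_left)
    p = np.minimum(1.0, special.erfc(z / np.sqrt(2.0)))
    p[~np.isfinite(d)] = np.nan
    return p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, stable ties).

    NaN entries are ignored for ranking and returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


@dataclass(frozen=True)
class ComparisonResult:
    comparison: str
    table: pd.DataFrame  # per protein: delta_log2, p_sigA, q_bh, regulated, direction
    fdr: float = 0.05
    min_abs_log2fc: float = 1.0

    @property
    def regulated_ids(self) -> list:
        return list(self.table.index[self.table["regulated"]])


def call_regulated(
    deltas: pd.Series,
    q_values: pd.Series,
    fdr: float = 0.05,
    min_abs_log2fc: float = 1.0,
    comparison: str = "",
) -> ComparisonResult:
    """Flag regulated proteins: q < FDR and at least two-fold change.

    The fold-change gate is inclusive (|log2 difference| >= 1 is two-fold);
    direction follows the sign of the difference.
    """
    if not deltas.index.equals(q_values.index):
        raise ValueError("deltas and q-values must be aligned")
    d = deltas.to_numpy(dtype=float)
    q = q_values.to_numpy(dtype=float)
    regulated = (q < fdr) & (np.abs(d) >= min_abs_log2fc)
    direction = np.where(d >= 0, "up", "down")
    table = pd.DataFrame(
        {
            "delta_log2": d,
            "q_bh": q,
            "regulated": regulated,
            "direction": direction,
        },
        index=deltas.index,
    )
    return ComparisonResult(comparison, table, fdr, min_abs_log2fc)


def run_all_comparisons(
    matrix: pd.DataFrame,
    design: Mapping[str, str] | pd.Series,
    min_valid: int = 2,
    scope: str = "all_groups",
    fdr: float = 0.05,
    min_abs_log2fc: float = 1.0,
    contaminant_ids: Sequence[str] = (),
) -> dict:
    """Full regulation-calling workflow over the three intergroup comparisons.

    Steps: valid-value filter, contaminant filter, log2 + median centering,
    per-group replicate averaging, per-comparison group-mean differences,
    Significance A, BH adjustment within comparison, and the two-fold/FDR
    gate.  Returns the per-comparison :class:`ComparisonResult` objects, the
    filter log, and an overlap summary across comparisons.
    """
    design = pd.Series(dict(design)) if not isinstance(design, pd.Series) else design
    counts = design.loc[matrix.columns].value_counts()
    for g in GROUPS:
        if counts.get(g, 0) < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")
    filtered, log_valid = filter_min_valid(matrix, design, min_valid, scope)
    filtered, log_contam = filter_contaminants(filtered, contaminant_ids)
    normed = preprocess(filtered)
    group_means = normed.T.groupby(design.loc[normed.columns]).mean().T
    results: dict[str, ComparisonResult] = {}
    for tag, (num, den) in COMPARISONS.items():
        delta = group_means[num] - group_means[den]
        p = significance_A(delta.to_numpy())
        q = bh_adjust(p)
        res = call_regulated(
            delta, pd.Series(q, index=delta.index), fdr, min_abs_log2fc, tag
        )
        res.table.insert(1, "p_sigA", p)
        results[tag] = res
    reg_sets = {tag: set(r.regulated_ids) for tag, r in results.items()}
    union = set().union(*reg_sets.values())
    summary = {
        "n_regulated_total": len(union),
        "n_regulated": {tag: len(s) for tag, s in reg_sets.items()},
        "pct_of_total": {
            tag: (round(100.0 * len(s) / len(union)) if union else 0)
            for tag, s in reg_sets.items()
        },
        "filter_valid_values": log_valid,
        "filter_contaminants": log_contam,
    }
    return {"comparisons": results, "summary": summary}


def enrichment_hypergeometric(
    regulated_ids: Sequence[str],
    annotations: pd.DataFrame,
    universe: Sequence[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per annotation term.

    ``annotations`` is a two-column table (term, id).  Terms are restricted
    to the universe; terms with no member in the universe are skipped.  BH
    adjustment is applied across the tested terms.
    """
    universe_set = set(universe)
    reg = set(regulated_ids)
    if not reg <= universe_set:
        raise ValueError("regulated set must be contained in the universe")
    M, n = len(universe_set), len(reg)
    rows = []
    for term, sub in annotations.groupby(annotations.columns[0]):
        members = set(sub[annotations.columns[1]]) & universe_set
        if not members:
            continue  # no overlap with universe; skipped
        K = len(members)
        k = len(members & reg)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if n else 1.0
        rows.append((term, K, k, p))
    out = pd.DataFrame(rows, columns=["term", "n_term", "n_overlap", "p"])
    if len(out):
        out["q_bh"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q_bh"] = []
    return out
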