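"""Behavioral phenotyping by symptom load.

Three post-stress tests feed the classification: sucrose preference
(anhedonia), nestlet shredding (self-care) and social avoidance.  A test is
pathological when its value falls below its cutoff (60 %, score 4, 50 s); a
stressed animal beyond cutoff in at least two of the three tests is
*susceptible*, otherwise *resilient*.  Control animals with more than one
pathological result are excluded from analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CutoffSet",
    "PhenotypeLabel",
    "MeasurementError",
    "ClassificationError",
    "compute_sucrose_preference",
    "classify_symptom_load",
    "classify_cohort",
    "cohort_phenotype_summary",
    "summarize_defeats",
    "SEVERITY_GRID",
]

SEVERITY_GRID = (1.0, 1.5, 2.0, 2.5, 3.0)

TEST_NAMES = ("sucrose_preference_pct", "nestlet_score", "interaction_time_s")


class MeasurementError(ValueError):
    """Physically impossible measurement (e.g. a bottle gaining weight)."""


class ClassificationError(ValueError):
    """Record cannot be classified (missing or invalid test value)."""


@dataclass(frozen=True)
class CutoffSet:
    """Pathological cutoffs; a value *below* the cutoff is pathological.

    The sucrose and nestlet cutoffs are strictly-below by definition; for the
    50 s interaction cutoff the convention is not fixed in the literature, so
    ``interaction_inclusive=True`` switches it to "at or below is
    pathological".
    """

    sucrose_pct: float = 60.0
    nestlet_score: float = 4.0
    interaction_s: float = 50.0
    interaction_inclusive: bool = False

    def __post_init__(self) -> None:
        for v in (self.sucrose_pct, self.nestlet_score, self.interaction_s):
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"cutoffs must be finite and positive, got {v}")


@dataclass(frozen=True)
class PhenotypeLabel:
    label: str  # control | resilient | susceptible | excluded_control
    pathological_flags: tuple[bool, bool, bool]
    symptom_load: int

    def __post_init__(self) -> None:
        if self.symptom_load != sum(self.pathological_flags):
            raise ValueError("symptom_load must equal the number of pathological flags")


def compute_sucrose_preference(
    water_g: Sequence[float], sucrose_g: Sequence[float]
) -> float:
    """Sucrose preference (%) from bottle weights at 0, 24 and 48 h.

    Bottles are weighed at the start, at the 24 h bottle switch and at 48 h.
    Per 24 h period the preference is ``100 * sucrose / (sucrose + water)``
    consumed mass; the test value is the mean of the two periods.

    Raises
    ------
    MeasurementError
        If any bottle gained weight over a period, or a period shows zero
        total consumption (preference undefined).
    """
    water = np.asarray(water_g, dtype=float)
    sucrose = np.asarray(sucrose_g, dtype=float)
    if water.shape != (3,) or sucrose.shape != (3,):
        raise ValueError("expected three weights (0, 24, 48 h) per bottle")
    prefs = []
    for i in (0, 1):
        dw = water[i] - water[i + 1]
        ds = sucrose[i] - sucrose[i + 1]
        if dw < 0 or ds < 0:
            raise MeasurementError(
                f"bottle weight increased during period {i + 1} "
                f"(water {dw:+.3f} g, sucrose {ds:+.3f} g consumed)"
            )
        total = dw + ds
        if total == 0:
            raise MeasurementError(f"zero total consumption in period {i + 1}")
        prefs.append(100.0 * ds / total)
    return float(np.mean(prefs))


def _flags(
    sucrose: float, nestlet: float, interaction: float, cutoffs: CutoffSet
) -> tuple[bool, bool, bool]:
    for name, v in zip(TEST_NAMES, (sucrose, nestlet, interaction)):
        if v is None or not math.isfinite(float(v)):
            raise ClassificationError(f"missing or non-finite {name}; no imputation")
    f_suc = sucrose < cutoffs.sucrose_pct
    f_nest = nestlet < cutoffs.nestlet_score
    if cutoffs.interaction_inclusive:
        f_int = interaction <= cutoffs.interaction_s
    else:
        f_int = interaction < cutoffs.interaction_s
    return (bool(f_suc), bool(f_nest), bool(f_int))


def classify_symptom_load(
    record, cutoffs: CutoffSet = CutoffSet()
) -> PhenotypeLabel:
    """Assign the stress-phenotype label of one animal.

    ``record`` is any mapping or object with ``group`` in {control, stressed}
    and the three test values.  Stressed animals with symptom load >= 2 are
    susceptible, otherwise resilient; controls with load >= 2 are excluded.
    """
    get = record.get if hasattr(record, "get") else lambda k: getattr(record, k)
    group = get("group")
    if group not in ("control", "stressed"):
        raise ClassificationError(f"unknown group {group!r}")
    flags = _flags(
        float(get("sucrose_preference_pct")),
        float(get("nestlet_score")),
        float(get("interaction_time_s")),
        cutoffs,
    )
    load = sum(flags)
    if group == "stressed":
        label = "susceptible" if load >= 2 else "resilient"
    else:
        label = "excluded_control" if load >= 2 else "control"
    return PhenotypeLabel(label, flags, load)


def classify_cohort(
    records: pd.DataFrame, cutoffs: CutoffSet = CutoffSet()
) -> pd.DataFrame:
    """Classify every animal in a behavior table.

    Returns a copy with pathological flags, symptom load and label columns;
    row order is preserved and irrelevant to the result.
    """
    out = records.copy()
    labels = [classify_symptom_load(row, cutoffs) for _, row in records.iterrows()]
    for i, name in enumerate(TEST_NAMES):
        out[f"pathological_{name.split('_')[0]}"] = [l.pathological_flags[i] for l in labels]
    out["symptom_load"] = [l.symptom_load for l in labels]
    out["label"] = [l.label for l in labels]
    return out


def cohort_phenotype_summary(labeled: pd.DataFrame) -> dict:
    """Counts and integer percentages per phenotype label, plus the
    group-by-pathological 2x2 contingency table.

    Percentages are within group: susceptible/resilient out of stressed
    animals, excluded out of controls.
    """
    counts = {lab: 0 for lab in ("control", "resilient", "susceptible", "excluded_control")}
    if len(labeled):
        counts.update(labeled["label"].value_counts().to_dict())
    n_stressed = int((labeled["group"] == "stressed").sum()) if len(labeled) else 0
    n_control = int((labeled["group"] == "control").sum()) if len(labeled) else 0

    def pct(k: int, n: int) -> int | None:
        return int(round(100.0 * k / n)) if n else None

    table = pd.DataFrame(
        0,
        index=pd.Index(["control", "stressed"], name="group"),
        columns=pd.Index([False, True], name="pathological"),
    )
    if len(labeled):
        patho = labeled["symptom_load"] >= 2
        for g in ("control", "stressed"):
            sel = labeled["group"] == g
            table.loc[g, True] = int((sel & patho).sum())
            table.loc[g, False] = int((sel & ~patho).sum())
    return {
        "counts": counts,
        "n_control": n_control,
        "n_stressed": n_stressed,
        "pct_susceptible": pct(counts["susceptible"], n_stressed),
        "pct_resilient": pct(counts["resilient"], n_stressed),
        "pct_excluded_control": pct(counts["excluded_control"], n_control),
        "contingency": table,
    }


def summarize_defeats(
    events: pd.DataFrame, animals: Iterable | None = None
) -> pd.DataFrame:
    """Per-animal attack count and mean severity over the defeat period.

    ``events`` has columns ``animal_id``, ``day`` (1-10) and ``severity`` on
    the 0.5-step grid from 1 (brief contact, no bite) to 3 (biting, pinning).
    When an ``animals`` roster is given, animals without any event are
    reported with count 0 and undefined (NaN) mean severity.
    """
    if len(events):
        sev = events["severity"].to_numpy(dtype=float)
        bad = ~np.isin(sev, SEVERITY_GRID)
        if bad.any():
            raise ValueError(
                f"severity values off the {SEVERITY_GRID} grid: {sorted(set(sev[bad]))}"
            )
        days = events["day"].to_numpy()
        if ((days < 1) | (days > 10)).any():
            raise ValueError("defeat days must be within 1..10")
        out = (events.groupby("animal_id")["severity"]
               .agg(n_attacks="size", mean_severity="mean").reset_index())
    else:
        out = pd.DataFrame(columns=["animal_id", "n_attacks", "mean_severity"])
    if animals is not None:
        missing = [a for a in animals if a not in set(out["animal_id"])]
        if missing:
            out = pd.concat(
                [out, pd.DataFrame(dict(animal_id=missing, n_attacks=0,
                                        mean_severity=np.nan))],
                ignore_index=True)
    out["n_attacks"] = out["n_attacks"].astype(int)
    return out
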