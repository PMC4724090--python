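"""Paired plan comparison and cohort-level statistics.

Each patient carries a reference plan ("AAA-like", the plan the treatment
was normalized on) and a recalculated plan ("AXB-like") evaluated on the
same structures and scheme.  Deltas are defined reference - recalculated,
so a positive delta means the reference plan reports the higher value.
Cohort summaries stratify by tumor location (peripheral vs central) and
report median plus (min, max) range, matching the usual presentation of
small SBRT cohorts.  Group differences use the Kruskal-Wallis rank test;
trend screens use Spearman rank correlation with a seeded permutation
p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .models import PlanEvaluation

__all__ = [
    "PatientRecord",
    "PairedComparison",
    "compare_pair",
    "cohort_summary",
    "kruskal_wallis",
    "delta_vs_covariate",
    "comparisons_frame",
]

LOCATIONS = ("peripheral", "central")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    tumor_location: str
    ptv_volume_cc: float
    reference: PlanEvaluation
    recalculated: PlanEvaluation

    def __post_init__(self) -> None:
        if self.tumor_location not in LOCATIONS:
            raise ValueError(f"tumor_location must be one of {LOCATIONS}")


@dataclass(frozen=True)
class PairedComparison:
    """Reference-minus-recalculated deltas for one patient's plan pair."""

    patient_id: str
    tumor_location: str
    ptv_volume_cc: float
    d_d95_gy: float
    d_mean_gy: float
    d_max_gy: float
    d_min_gy: float
    d_mld_gy: Optional[float]
    d_tcp: Dict[str, float] = field(default_factory=dict)
    d_ntcp: Dict[str, float] = field(default_factory=dict)


def compare_pair(record: PatientRecord, ptv_structure: str = "ptv") -> PairedComparison:
    """All per-metric deltas (reference - recalculated) for one patient."""
    ref, rec = record.reference, record.recalculated
    if set(ref.metrics) != set(rec.metrics):
        raise ValueError(
            f"patient {record.patient_id}: structure sets differ "
            f"({sorted(ref.metrics)} vs {sorted(rec.metrics)})"
        )
    if set(ref.tcp) != set(rec.tcp) or set(ref.ntcp) != set(rec.ntcp):
        raise ValueError(
            f"patient {record.patient_id}: plans evaluated under different "
            "parameter sets"
        )
    mr, mx = ref.metrics[ptv_structure], rec.metrics[ptv_structure]
    mld = None
    if "lung" in ref.metrics:
        mld = ref.metrics["lung"]["mean_gy"] - rec.metrics["lung"]["mean_gy"]
    return PairedComparison(
        patient_id=record.patient_id,
        tumor_location=record.tumor_location,
        ptv_volume_cc=record.ptv_volume_cc,
        d_d95_gy=mr["d95_gy"] - mx["d95_gy"],
        d_mean_gy=mr["mean_gy"] - mx["mean_gy"],
        d_max_gy=mr["max_gy"] - mx["max_gy"],
        d_min_gy=mr["min_gy"] - mx["min_gy"],
        d_mld_gy=mld,
        d_tcp={k: ref.tcp[k] - rec.tcp[k] for k in ref.tcp},
        d_ntcp={k: ref.ntcp[k] - rec.ntcp[k] for k in ref.ntcp},
    )


def comparisons_frame(comparisons: Iterable[PairedComparison]) -> pd.DataFrame:
    """Tidy long-format frame: one row per (patient, metric)."""
    rows = []
    for c in comparisons:
        base = {
            "patient_id": c.patient_id,
            "location": c.tumor_location,
            "ptv_cc": c.ptv_volume_cc,
        }
        rows.append({**base, "metric": "d_d95_gy", "value": c.d_d95_gy})
        rows.append({**base, "metric": "d_mean_gy", "value": c.d_mean_gy})
        rows.append({**base, "metric": "d_max_gy", "value": c.d_max_gy})
        rows.append({**base, "metric": "d_min_gy", "value": c.d_min_gy})
        if c.d_mld_gy is not None:
            rows.append({**base, "metric": "d_mld_gy", "value": c.d_mld_gy})
        for k, v in c.d_tcp.items():
            rows.append({**base, "metric": f"d_tcp:{k}", "value": v})
        for k, v in c.d_ntcp.items():
            rows.append({**base, "metric": f"d_ntcp:{k}", "value": v})
    return pd.DataFrame(rows)


def cohort_summary(comparisons: Sequence[PairedComparison]) -> pd.DataFrame:
    """Median and (min, max) range per metric, stratified by location.

    Empty location groups are omitted.  Returns a frame with columns
    ``location, metric, n, median, min, max``.
    """
    if not comparisons:
        raise ValueError("cohort_summary needs at least one comparison")
    df = comparisons_frame(comparisons)
    out = (
        df.groupby(["location", "metric"], sort=False)["value"]
        .agg(n="size", median="median", min="min", max="max")
        .reset_index()
    )
    return out


def _h_statistic(groups: Sequence[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H (0 when every pooled value ties)."""
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0  # fully tied: the tie correction degenerates; H is 0
    try:
        h, _ = stats.kruskal(*groups)
    except ValueError:
        return 0.0
    return float(h)


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    exact_threshold: int = 10,
) -> Tuple[float, float]:
    """Kruskal-Wallis H statistic and p-value across >= 2 groups.

    Uses the tie-corrected H with a chi-square (k-1 df) tail; when the
    pooled sample size is <= ``exact_threshold`` the p-value is computed
    exactly by enumerating every assignment of the pooled values to the
    group sizes.  All values identical gives (H=0, p=1) by convention.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("kruskal_wallis needs >= 2 nonempty groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h_obs = _h_statistic(arrays)
    n_total = pooled.size
    if n_total <= exact_threshold:
        return h_obs, _exact_p(arrays, pooled, h_obs)
    p = float(stats.chi2.sf(h_obs, df=len(arrays) - 1))
    return h_obs, p


def _exact_p(arrays: Sequence[np.ndarray], pooled: np.ndarray, h_obs: float) -> float:
    """Exact permutation p: enumerate assignments of pooled indices."""
    sizes = [a.size for a in arrays]
    idx_all = list(range(pooled.size))

    def h_of(partition: List[List[int]]) -> float:
        return _h_statistic([pooled[list(ix)] for ix in partition])

    count = total = 0

    def recurse(remaining: List[int], gi: int, acc: List[List[int]]) -> None:
        nonlocal count, total
        if gi == len(sizes) - 1:
            part = acc + [remaining]
            total += 1
            if h_of(part) >= h_obs - 1e-12:
                count += 1
            return
        for combo in combinations(remaining, sizes[gi]):
            rest = [i for i in remaining if i not in set(combo)]
            recurse(rest, gi + 1, acc + [list(combo)])

    recurse(idx_all, 0, [])
    return count / total


def delta_vs_covariate(
    comparisons: Sequence[PairedComparison],
    metric: str,
    covariate: str,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Spearman rank correlation between a delta metric and a covariate.

    ``metric`` is a column of :func:`comparisons_frame` (e.g. ``d_d95_gy``
    or ``d_tcp:martel_30mo``); ``covariate`` is one of ``d_d95_gy``,
    ``ptv_volume_cc`` or ``location`` (encoded peripheral=0, central=1).
    Returns the ordered pairs, rho and a two-sided permutation p-value
    (``n_permutations`` shuffles of the covariate, seeded).  A constant
    covariate yields ``rho=None`` flagged ``undefined``.
    """
    if len(comparisons) < 3:
        raise ValueError("delta_vs_covariate needs >= 3 records")
    df = comparisons_frame(comparisons)
    wide = df.pivot_table(index="patient_id", columns="metric", values="value")
    meta = df.drop_duplicates("patient_id").set_index("patient_id")
    y = wide[metric].to_numpy(dtype=float)
    if covariate == "ptv_volume_cc":
        x = meta.loc[wide.index, "ptv_cc"].to_numpy(dtype=float)
    elif covariate == "location":
        x = (meta.loc[wide.index, "location"] == "central").to_numpy(dtype=float)
    else:
        x = wide[covariate].to_numpy(dtype=float)
    order = np.argsort(x, kind="stable")
    pairs = list(zip(x[order].tolist(), y[order].tolist()))
    if np.all(x == x[0]):
        return {"pairs": pairs, "rho": None, "p_value": None, "undefined": True}
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        r = float(stats.spearmanr(rng.permutation(x), y).statistic)
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return {"pairs": pairs, "rho": rho, "p_value": p, "undefined": False}
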