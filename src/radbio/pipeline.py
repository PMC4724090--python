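"""End-to-end helpers: manifest/patients -> evaluations -> comparisons.

These are the functions the command-line interface and the reproduction
script are thin wrappers over; library users can call them directly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .cohort import PairedComparison, PatientRecord, compare_pair, kruskal_wallis
from .constraints import check_constraints
from .dvh import FractionationScheme
from .io import read_dvh_csv, read_manifest
from .models import PlanEvaluation, evaluate_plan
from .params import ParameterRegistry, load_registry
from .simulate import SyntheticPatient

__all__ = [
    "default_parameter_selection",
    "evaluate_patients",
    "evaluate_manifest",
    "compare_cohort",
    "summary_report_text",
]


def default_parameter_selection(
    registry: Optional[ParameterRegistry] = None,
    tcp_labels: Optional[Sequence[str]] = None,
    ntcp_labels: Optional[Sequence[str]] = None,
) -> Tuple[dict, dict]:
    """Resolve TCP/NTCP label selections against the registry.

    With no labels given, every bundled set is selected.
    """
    reg = registry or load_registry()
    tcp = (
        {lbl: reg.get(lbl) for lbl in tcp_labels}
        if tcp_labels is not None
        else dict(reg.tcp)
    )
    ntcp = (
        {lbl: reg.get(lbl) for lbl in ntcp_labels}
        if ntcp_labels is not None
        else reg.ntcp_labels()
    )
    return tcp, ntcp


def _record(
    patient_id: str,
    location: str,
    ptv_cc: float,
    ref_dvhs: dict,
    rec_dvhs: dict,
    scheme: FractionationScheme,
    tcp_sets: dict,
    ntcp_sets: dict,
) -> PatientRecord:
    ref = evaluate_plan(ref_dvhs, scheme, tcp_sets, ntcp_sets, plan_label="reference")
    rec = evaluate_plan(rec_dvhs, scheme, tcp_sets, ntcp_sets, plan_label="recalculated")
    return PatientRecord(patient_id, location, ptv_cc, ref, rec)


def evaluate_patients(
    patients: Sequence[SyntheticPatient],
    scheme: FractionationScheme,
    tcp_sets: dict,
    ntcp_sets: dict,
) -> List[PatientRecord]:
    """Evaluate in-memory synthetic patients into paired records."""
    return [
        _record(
            p.patient_id,
            p.tumor_location,
            p.ptv_volume_cc,
            p.reference_dvhs,
            p.recalculated_dvhs,
            scheme,
            tcp_sets,
            ntcp_sets,
        )
        for p in patients
    ]


def evaluate_manifest(
    manifest_path,
    scheme: FractionationScheme,
    tcp_sets: dict,
    ntcp_sets: dict,
) -> Tuple[List[PatientRecord], List[str]]:
    """Evaluate every plan pair listed in a cohort manifest.

    A patient whose DVH files fail to parse is skipped; the failure is
    collected (with the file named) and processing continues.
    """
    df = read_manifest(manifest_path)
    records: List[PatientRecord] = []
    failures: List[str] = []
    for row in df.itertuples(index=False):
        try:
            ref = read_dvh_csv(row.ref_dvh_path)
            rec = read_dvh_csv(row.recalc_dvh_path)
            records.append(
                _record(
                    str(row.patient_id),
                    row.location,
                    float(row.ptv_cc),
                    ref,
                    rec,
                    scheme,
                    tcp_sets,
                    ntcp_sets,
                )
            )
        except Exception as exc:  # keep going; report at the end
            failures.append(f"{row.patient_id}: {exc}")
    return records, failures


def compare_cohort(records: Sequence[PatientRecord]) -> List[PairedComparison]:
    return [compare_pair(r) for r in records]


def evaluations_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Tidy long-format frame of every evaluated quantity.

    One row per (patient, plan role, quantity); lossless for everything the
    comparison stage consumes, so saved evaluations can be re-loaded with
    :func:`records_from_evaluations` and re-compared bit-identically.
    """
    rows = []
    for r in records:
        for role, ev in (("reference", r.reference), ("recalculated", r.recalculated)):
            base = {
                "patient_id": r.patient_id,
                "location": r.tumor_location,
                "ptv_cc": r.ptv_volume_cc,
                "total_dose_gy": ev.scheme.total_dose_gy,
                "n_fractions": ev.scheme.n_fractions,
                "plan_role": role,
            }
            for sid, metrics in ev.metrics.items():
                for key, val in metrics.items():
                    rows.append(
                        {**base, "kind": "metric", "structure": sid, "key": key, "value": val}
                    )
            for label, val in ev.tcp.items():
                rows.append(
                    {**base, "kind": "tcp", "structure": "ptv", "key": label, "value": val}
                )
            for label, val in ev.ntcp.items():
                rows.append(
                    {**base, "kind": "ntcp", "structure": "", "key": label, "value": val}
                )
    return pd.DataFrame(rows)


def records_from_evaluations(df: pd.DataFrame) -> List[PatientRecord]:
    """Rebuild paired patient records from a saved evaluations frame."""
    records: List[PatientRecord] = []
    for pid, grp in df.groupby("patient_id", sort=False):
        evs: Dict[str, PlanEvaluation] = {}
        for role, sub in grp.groupby("plan_role", sort=False):
            scheme = FractionationScheme(
                float(sub["total_dose_gy"].iloc[0]), int(sub["n_fractions"].iloc[0])
            )
            metrics: Dict[str, dict] = {}
            for row in sub[sub["kind"] == "metric"].itertuples(index=False):
                metrics.setdefault(row.structure, {})[row.key] = float(row.value)
            tcp = {
                row.key: float(row.value)
                for row in sub[sub["kind"] == "tcp"].itertuples(index=False)
            }
            ntcp = {
                row.key: float(row.value)
                for row in sub[sub["kind"] == "ntcp"].itertuples(index=False)
            }
            evs[role] = PlanEvaluation(role, scheme, metrics, tcp, ntcp)
        if set(evs) != {"reference", "recalculated"}:
            continue  # single-plan patients cannot be compared
        records.append(
            PatientRecord(
                str(pid),
                grp["location"].iloc[0],
                float(grp["ptv_cc"].iloc[0]),
                evs["reference"],
                evs["recalculated"],
            )
        )
    return records


def constraints_frame(constraint_results: Dict[str, list]) -> pd.DataFrame:
    """Tidy frame of per-patient constraint verdicts (one row per rule)."""
    rows = []
    for pid in sorted(constraint_results):
        for res in constraint_results[pid]:
            rows.append(
                {
                    "patient_id": pid,
                    "rule": res.constraint.describe(),
                    "measured": res.measured,
                    "verdict": res.verdict,
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "rule", "measured", "verdict"])


def summary_report_text(
    records: Sequence[PatientRecord],
    comparisons: Sequence[PairedComparison],
    constraints_df: Optional[pd.DataFrame] = None,
) -> str:
    """Human-readable cohort report: per-location medians and ranges of the
    plan metrics, delta summaries with Kruskal-Wallis p-values between
    locations, and (when provided) per-patient constraint verdicts for the
    reference plans."""
    from .cohort import cohort_summary, comparisons_frame

    lines: List[str] = []
    lines.append("Cohort report")
    lines.append("=" * 60)
    lines.append(f"patients: {len(records)}")
    by_loc: Dict[str, int] = {}
    for r in records:
        by_loc[r.tumor_location] = by_loc.get(r.tumor_location, 0) + 1
    lines.append(
        "locations: "
        + ", ".join(f"{k}={v}" for k, v in sorted(by_loc.items(), reverse=True))
    )
    lines.append("")
    lines.append("PTV dose metrics, median (range) in Gy")
    lines.append("-" * 60)
    for role in ("reference", "recalculated"):
        for loc in ("peripheral", "central"):
            vals: Dict[str, List[float]] = {}
            for r in records:
                if r.tumor_location != loc:
                    continue
                ev: PlanEvaluation = getattr(
                    r, "reference" if role == "reference" else "recalculated"
                )
                for key in ("d95_gy", "mean_gy", "max_gy", "min_gy"):
                    vals.setdefault(key, []).append(ev.metrics["ptv"][key])
            if not vals:
                continue
            for key, xs in vals.items():
                s = pd.Series(xs)
                lines.append(
                    f"{role:13s} {loc:11s} PTV {key:8s} "
                    f"{s.median():6.1f} ({s.min():.1f}, {s.max():.1f})"
                )
    lines.append("")
    lines.append("Paired deltas (reference - recalculated), median (range)")
    lines.append("-" * 60)
    summ = cohort_summary(comparisons)
    frame = comparisons_frame(comparisons)
    for metric in summ["metric"].unique():
        sub = summ[summ["metric"] == metric]
        for row in sub.itertuples(index=False):
            lines.append(
                f"{metric:35s} {row.location:11s} "
                f"{row.median:8.4f} ({row.min:.4f}, {row.max:.4f})"
            )
        groups = [
            frame[(frame["metric"] == metric) & (frame["location"] == loc)][
                "value"
            ].to_numpy()
            for loc in ("peripheral", "central")
        ]
        if all(len(g) for g in groups):
            h, p = kruskal_wallis(groups)
            lines.append(f"{'':35s} peripheral-vs-central H={h:.3f} p={p:.3g}")
    if constraints_df is not None and len(constraints_df):
        lines.append("")
        lines.append("Normal-tissue constraints (reference plans)")
        lines.append("-" * 60)
        counts = constraints_df["verdict"].value_counts().to_dict()
        for row in constraints_df.itertuples(index=False):
            measured = "n/a" if pd.isna(row.measured) else f"{row.measured:.2f}"
            lines.append(
                f"{str(row.patient_id):8s} {row.rule:42s} "
                f"measured={measured:>8s}  {row.verdict}"
            )
        lines.append(
            f"totals: pass={counts.get('pass', 0)} fail={counts.get('fail', 0)} "
            f"not_evaluable={counts.get('not_evaluable', 0)}"
        )
    return "\n".join(lines) + "\n"
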