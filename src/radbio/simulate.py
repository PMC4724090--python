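"""Seeded generator of paired reference/recalculated DVH cohorts.

No planning data are distributed with lung-SBRT dosimetry studies, so
every pipeline stage is exercised against synthetic cohorts whose *metric*
structure matches the published ranges: a reference ("AAA-like") PTV DVH
normalized so D95% is exactly the 60 Gy prescription, a recalculated
("AXB-like") partner whose D95% is lower by a draw from the printed
per-location difference ranges, and exponential-tail OAR DVHs that satisfy
the normal-tissue constraints by construction.  DVH *shapes* (logistic
fall-off for the PTV, truncated exponential for OARs) are parametric
plumbing — nothing downstream depends on them beyond the metrics.

Reproducibility: one seed drives the whole cohort; each patient draws from
an independent substream spawned by patient counter, so records are stable
under reordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .dvh import (
    DoseVolumeHistogram,
    FractionationScheme,
    dose_at_volume,
    summary_metrics,
)
from .io import write_dvh_csv, write_manifest

__all__ = ["CohortSpec", "SyntheticPatient", "generate_ptv_pair",
           "generate_oar_dvh", "generate_cohort", "write_cohort"]

OARS = ("lung", "esophagus", "heart", "cord")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the published cohort: 28 patients (19 peripheral /
    9 central), 60 Gy in 5 fractions prescribed to D95% of the PTV,
    per-location D95% degradation ranges and PTV volume ranges as printed.
    The mean-lung-dose range is not printed anywhere and is an invented
    but clinically plausible default.
    """

    n_patients: int = 28
    fraction_peripheral: float = 19 / 28
    seed: int = 0
    scheme: FractionationScheme = field(
        default_factory=lambda: FractionationScheme(60.0, 5)
    )
    # reference-minus-recalculated D95% difference, Gy, per location
    d_d95_range: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"peripheral": (0.3, 6.5), "central": (0.6, 4.4)}
    )
    d_d95_median: Dict[str, float] = field(
        default_factory=lambda: {"peripheral": 1.7, "central": 1.0}
    )
    delta_distribution: str = "uniform"  # or "triangular" (mode at median)
    ptv_cc_range: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"peripheral": (15.3, 107.3), "central": (19.0, 144.9)}
    )
    ptv_dmax_range: Tuple[float, float] = (63.7, 73.2)
    mean_lung_dose_range: Tuple[float, float] = (3.0, 8.0)
    oar_dose_perturbation: float = 0.02  # recalculated OAR dose scale, +/- fraction
    bin_width_gy: float = 0.1

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0 <= self.fraction_peripheral <= 1:
            raise ValueError("fraction_peripheral must lie in [0, 1]")
        for rng_ in (*self.d_d95_range.values(), *self.ptv_cc_range.values(),
                     self.ptv_dmax_range, self.mean_lung_dose_range):
            if rng_[0] > rng_[1]:
                raise ValueError(f"range {rng_} is not ordered")
        if self.delta_distribution not in ("uniform", "triangular"):
            raise ValueError("delta_distribution must be uniform or triangular")


@dataclass(frozen=True)
class SyntheticPatient:
    patient_id: str
    tumor_location: str
    ptv_volume_cc: float
    reference_dvhs: Dict[str, DoseVolumeHistogram]
    recalculated_dvhs: Dict[str, DoseVolumeHistogram]


def _draw_delta(spec: CohortSpec, location: str, rng: np.random.Generator) -> float:
    lo, hi = spec.d_d95_range[location]
    if spec.delta_distribution == "triangular":
        return float(rng.triangular(lo, spec.d_d95_median[location], hi))
    return float(rng.uniform(lo, hi))


def generate_ptv_pair(
    spec: CohortSpec,
    location: str,
    rng: np.random.Generator,
    delta: Optional[float] = None,
) -> Tuple[DoseVolumeHistogram, DoseVolumeHistogram, float]:
    """One patient's (reference, recalculated) PTV DVH pair and the drawn
    D95% degradation (``delta`` overrides the draw; 0 gives an identical
    pair).

    The reference curve is a logistic fall-off whose dose axis is rescaled
    so D95% equals the prescription exactly (dose-linear interpolation
    makes the rescale exact, not approximate); its maximum dose is drawn
    within the published range.  The recalculated curve is the reference
    under a uniform monotone dose contraction that lowers D95% by the
    drawn delta while conserving volume mass.
    """
    presc = spec.scheme.total_dose_gy
    dmax = rng.uniform(*spec.ptv_dmax_range)
    # logistic steepness fixed by requiring 95% coverage at the
    # prescription and ~0.5% residual coverage at the drawn maximum dose
    k = (np.log(19.0) + np.log(199.0)) / (dmax - presc)
    mu = presc + np.log(19.0) / k
    # extend the grid until the logistic tail is below the zeroing cutoff,
    # so the cumulative curve closes at exactly 0 and volume mass is 1
    tail_cut = 2e-4
    grid_max = mu + np.log(1.0 / tail_cut) / k
    edges = np.arange(0.0, grid_max + spec.bin_width_gy, spec.bin_width_gy)
    cum = 1.0 / (1.0 + np.exp(k * (edges - mu)))
    cum[cum < 5e-4] = 0.0   # close the hot tail
    cum[cum > 1.0 - 5e-4] = 1.0  # flatten the cold head (realistic Dmin)
    cum[0] = 1.0
    cum = np.minimum.accumulate(cum)
    ref = DoseVolumeHistogram("ptv", edges, cum, "cumulative")
    # exact D95 normalization: dose metrics are linear under dose scaling
    ref = ref.with_scaled_doses(presc / dose_at_volume(ref, 0.95))
    if delta is None:
        delta = _draw_delta(spec, location, rng)
        while presc - delta <= 0:  # unreachable for the study ranges; kept safe
            delta = _draw_delta(spec, location, rng)
    elif presc - delta <= 0:
        raise ValueError("delta must leave a positive prescription dose")
    recalc = ref.with_scaled_doses((presc - delta) / presc)
    return ref, recalc, delta


# per-organ (mean-dose range Gy, dose cap Gy, volume-cc range); caps sit
# below the constraint ceilings so generated plans pass by construction
_OAR_SHAPES: Dict[str, Tuple[Tuple[float, float], float, Tuple[float, float]]] = {
    "lung": ((np.nan, np.nan), 55.0, (2500.0, 4000.0)),  # mean range from spec
    "esophagus": ((2.0, 6.0), 32.0, (30.0, 50.0)),
    "heart": ((2.0, 6.0), 36.0, (500.0, 800.0)),
    "cord": ((1.0, 5.0), 27.0, (30.0, 60.0)),
}


def generate_oar_dvh(
    organ: str,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> DoseVolumeHistogram:
    """One organ-at-risk cumulative DVH with an exponentially decaying tail.

    The curve is ``exp(-D/m)`` truncated smoothly at an organ-specific dose
    cap (kept below the constraint ceiling), then dose-rescaled so the mean
    dose equals the drawn target exactly.
    """
    if organ not in _OAR_SHAPES:
        raise ValueError(f"unknown organ {organ!r}; choose from {OARS}")
    mean_rng, cap, cc_rng = _OAR_SHAPES[organ]
    if organ == "lung":
        mean_rng = spec.mean_lung_dose_range
    target_mean = rng.uniform(*mean_rng)
    total_cc = rng.uniform(*cc_rng)
    edges = np.arange(0.0, cap + spec.bin_width_gy, spec.bin_width_gy)
    cum = (np.exp(-edges / target_mean) - np.exp(-cap / target_mean)) / (
        1.0 - np.exp(-cap / target_mean)
    )
    cum = np.clip(cum, 0.0, None)
    cum[0] = 1.0
    dvh = DoseVolumeHistogram(organ, edges, cum, "cumulative", total_volume_cc=total_cc)
    # rescale the dose axis so the realised mean hits the target exactly
    dvh = dvh.with_scaled_doses(target_mean / summary_metrics(dvh)["mean_gy"])
    return dvh


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def generate_cohort(spec: CohortSpec) -> List[SyntheticPatient]:
    """Generate the full paired cohort.

    Locations are assigned deterministically from ``fraction_peripheral``
    (first ``round(f*n)`` patients peripheral); all dose draws come from
    per-patient substreams of the cohort seed.
    """
    n_peripheral = round(spec.fraction_peripheral * spec.n_patients)
    patients: List[SyntheticPatient] = []
    for i in range(spec.n_patients):
        rng = _patient_rng(spec.seed, i)
        location = "peripheral" if i < n_peripheral else "central"
        ptv_cc = float(rng.uniform(*spec.ptv_cc_range[location]))
        ref_ptv, rec_ptv, _ = generate_ptv_pair(spec, location, rng)
        ref_ptv = replace(ref_ptv, total_volume_cc=ptv_cc)
        rec_ptv = replace(rec_ptv, total_volume_cc=ptv_cc)
        ref = {"ptv": ref_ptv}
        rec = {"ptv": rec_ptv}
        for organ in OARS:
            oar = generate_oar_dvh(organ, spec, rng)
            eps = rng.uniform(-spec.oar_dose_perturbation, spec.oar_dose_perturbation)
            ref[organ] = oar
            rec[organ] = oar.with_scaled_doses(1.0 + eps)
        patients.append(
            SyntheticPatient(f"p{i + 1:03d}", location, ptv_cc, ref, rec)
        )
    return patients


def write_cohort(patients: List[SyntheticPatient], out_dir, spec: Optional[CohortSpec] = None) -> Path:
    """Write per-plan DVH CSVs plus a manifest (and a spec echo) to ``out_dir``.

    Returns the manifest path; the manifest is consumable by
    :func:`radbio.io.read_manifest`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patients:
        ref_path = f"{p.patient_id}_ref.csv"
        rec_path = f"{p.patient_id}_recalc.csv"
        write_dvh_csv(out / ref_path, p.reference_dvhs)
        write_dvh_csv(out / rec_path, p.recalculated_dvhs)
        rows.append(
            {
                "patient_id": p.patient_id,
                "location": p.tumor_location,
                "ptv_cc": round(p.ptv_volume_cc, 3),
                "ref_dvh_path": ref_path,
                "recalc_dvh_path": rec_path,
            }
        )
    manifest = out / "manifest.csv"
    write_manifest(manifest, rows)
    if spec is not None:
        echo = {
            "n_patients": spec.n_patients,
            "fraction_peripheral": spec.fraction_peripheral,
            "seed": spec.seed,
            "total_dose_gy": spec.scheme.total_dose_gy,
            "n_fractions": spec.scheme.n_fractions,
            "delta_distribution": spec.delta_distribution,
        }
        (out / "cohort_spec.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))
    return manifest
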