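"""Radiobiological dose-response models.

This module implements the chain that turns a physical-dose DVH into
tumor-control and normal-tissue-complication probabilities:

1. **EQD2 correction** — every dose is mapped to its equivalent in 2-Gy
   fractions under the linear-quadratic model,
   ``EQD2 = D (1 + d/(a/b)) / (1 + 2/(a/b))``, with ``d`` the dose per
   fraction actually delivered to that voxel/bin.
2. **TCP** — Poisson-LQ (Källman) dose response
   ``P(D) = 2^(-exp(e * gamma * (1 - D/D50)))`` aggregated over the DVH by
   the voxel-independence product ``TCP = prod_i P(D_i)^{v_i}``.
3. **NTCP** — Lyman-Kutcher-Burman probit of the generalized equivalent
   uniform dose ``EUD = (sum_i v_i D_i^{1/n})^n``, or the relative-seriality
   model ``NTCP = [1 - prod_i (1 - P(D_i)^s)^{v_i}]^{1/s}``.

Probabilities are clipped to ``[1e-12, 1 - 1e-12]`` before logs and
products to avoid underflow; the clip is documented here rather than
silent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Iterable, List, Optional

import numpy as np
from scipy import special, stats

from .dvh import (
    DoseVolumeHistogram,
    DVHValidationError,
    FractionationScheme,
    summary_metrics,
    to_differential,
)
from .params import LKBParams, SerialityParams, TCPParams

__all__ = [
    "eqd2",
    "eqd2_correct_dvh",
    "poisson_response",
    "tcp_from_dvh",
    "eud",
    "lkb_ntcp",
    "seriality_ntcp",
    "PlanEvaluation",
    "evaluate_plan",
    "RESPONSE_FUNCTIONS",
]

_P_CLIP = 1e-12


def eqd2(total_dose_gy, dose_per_fraction_gy, alpha_beta_gy):
    """Equivalent dose in 2-Gy fractions of ``total_dose_gy`` delivered at
    ``dose_per_fraction_gy`` per fraction, for tissue ratio ``alpha_beta_gy``.

    Vectorised over ``total_dose_gy`` and ``dose_per_fraction_gy``.
    """
    ab = alpha_beta_gy
    if ab <= 0:
        raise ValueError("alpha_beta_gy must be positive")
    if np.any(np.asarray(dose_per_fraction_gy) < 0) or np.any(
        np.asarray(total_dose_gy) < 0
    ):
        raise ValueError("doses must be >= 0")
    out = np.asarray(total_dose_gy) * (1.0 + np.asarray(dose_per_fraction_gy) / ab) / (
        1.0 + 2.0 / ab
    )
    return float(out) if np.isscalar(total_dose_gy) else out


def eqd2_correct_dvh(
    dvh: DoseVolumeHistogram,
    scheme: FractionationScheme,
    alpha_beta_gy: float,
) -> DoseVolumeHistogram:
    """Fractionation-correct a differential DVH to the EQD2 scale.

    Each bin dose ``D`` is delivered evenly over all fractions, so its
    per-fraction dose is ``D / n_fractions``; the bin edges are remapped
    through the (monotone increasing) EQD2 transform and the fractional
    volumes are carried over unchanged, conserving volume exactly.  The
    output grid is non-uniform.
    """
    diff = to_differential(dvh)
    new_edges = eqd2(diff.dose_edges, diff.dose_edges / scheme.n_fractions, alpha_beta_gy)
    return replace(diff, dose_edges=np.asarray(new_edges, dtype=float))


def _kallman_response(dose_gy, d50_gy: float, gamma: float):
    z = np.exp(math.e * gamma * (1.0 - np.asarray(dose_gy, dtype=float) / d50_gy))
    return np.power(2.0, -z)


RESPONSE_FUNCTIONS: Dict[str, Callable] = {"kallman": _kallman_response}
"""Named Poisson-type dose-response forms; ``kallman`` is the default and
currently only entry, kept behind a registry so alternative closed forms
can be added without touching call sites."""


def poisson_response(eqd2_gy, params: TCPParams, form: str = "kallman"):
    """Poisson-LQ probability of local control at uniform dose ``eqd2_gy``.

    Satisfies ``P(D50) = 0.5`` exactly and has normalized slope ``gamma``
    at its steepest point.  Vectorised over dose.
    """
    if np.any(np.asarray(eqd2_gy) < 0):
        raise ValueError("dose must be >= 0")
    fn = RESPONSE_FUNCTIONS[form]
    out = fn(eqd2_gy, params.d50_eqd2_gy, params.gamma)
    return float(out) if np.isscalar(eqd2_gy) else out


def _normalised_diff(dvh: DoseVolumeHistogram) -> DoseVolumeHistogram:
    diff = to_differential(dvh)
    if abs(float(diff.volume.sum()) - 1.0) > 1e-6:
        raise DVHValidationError(
            f"DVH volumes for {dvh.structure_id!r} sum to "
            f"{float(diff.volume.sum()):.6f}, expected 1"
        )
    return diff


def tcp_from_dvh(
    dvh_eqd2: DoseVolumeHistogram,
    params: TCPParams,
    method: str = "product",
) -> float:
    """Tumor control probability of an EQD2-corrected DVH.

    ``method="product"`` (default) applies the voxel-independence Poisson
    aggregation ``prod_i P(D_i)^{v_i}``.  ``method="eud"`` evaluates the
    response at the arithmetic-mean EQD2 instead (a simple uniform-dose
    reduction, useful for cross-checks).
    """
    diff = _normalised_diff(dvh_eqd2)
    if method == "eud":
        return float(poisson_response(summary_metrics(diff)["mean_gy"], params))
    if method != "product":
        raise ValueError(f"unknown TCP aggregation method {method!r}")
    p = np.clip(
        _kallman_response(diff.bin_centers, params.d50_eqd2_gy, params.gamma),
        _P_CLIP,
        1.0 - _P_CLIP,
    )
    return float(np.exp(np.dot(diff.volume, np.log(p))))


def eud(dvh_eqd2: DoseVolumeHistogram, n_volume: float) -> float:
    """Generalized equivalent uniform dose ``(sum_i v_i D_i^{1/n})^n``.

    ``n = 1`` gives the mean dose (parallel organ); ``n -> 0`` approaches
    the maximum dose (serial organ).  Zero-dose bins contribute nothing.
    """
    if n_volume <= 0:
        raise ValueError("n_volume must be positive")
    diff = _normalised_diff(dvh_eqd2)
    d = diff.bin_centers
    mask = (diff.volume > 0) & (d > 0)
    if not np.any(mask):
        return 0.0
    # log-sum-exp keeps small n (serial organs) from overflowing d**(1/n)
    log_terms = np.log(diff.volume[mask]) + np.log(d[mask]) / n_volume
    return float(np.exp(n_volume * special.logsumexp(log_terms)))


def lkb_ntcp(eud_gy: float, params: LKBParams) -> float:
    """LKB complication probability: standard normal CDF of
    ``t = (EUD - D50) / (m * D50)``."""
    if eud_gy < 0:
        raise ValueError("EUD must be >= 0")
    t = (eud_gy - params.d50_gy) / (params.m_slope * params.d50_gy)
    return float(stats.norm.cdf(t))


def seriality_ntcp(dvh_eqd2: DoseVolumeHistogram, params: SerialityParams) -> float:
    """Relative-seriality complication probability.

    ``NTCP = [1 - prod_i (1 - P(D_i)^s)^{v_i}]^{1/s}`` with ``P`` the
    Poisson-LQ response of this organ's (D50, gamma).  ``s -> 0`` is a
    fully parallel organ, large ``s`` fully serial.
    """
    s = params.s_seriality
    diff = _normalised_diff(dvh_eqd2)
    p = np.clip(
        _kallman_response(diff.bin_centers, params.d50_gy, params.gamma),
        _P_CLIP,
        1.0 - _P_CLIP,
    )
    inner = np.clip(1.0 - np.power(p, s), _P_CLIP, 1.0)
    prod = np.exp(np.dot(diff.volume, np.log(inner)))
    return float(np.clip(1.0 - prod, 0.0, 1.0) ** (1.0 / s))


@dataclass(frozen=True)
class PlanEvaluation:
    """Per-structure dose metrics and TCP/NTCP values for one plan."""

    plan_label: str
    scheme: FractionationScheme
    metrics: Dict[str, dict]          # structure -> summary_metrics (physical Gy)
    tcp: Dict[str, float]             # tcp parameter label -> probability
    ntcp: Dict[str, float]            # ntcp parameter label -> probability
    warnings: List[str] = field(default_factory=list)


def evaluate_plan(
    dvhs: Dict[str, DoseVolumeHistogram],
    scheme: FractionationScheme,
    tcp_sets: Optional[Dict[str, TCPParams]] = None,
    ntcp_sets: Optional[Dict[str, object]] = None,
    plan_label: str = "plan",
    ptv_structure: str = "ptv",
    tcp_method: str = "product",
) -> PlanEvaluation:
    """Evaluate one plan's DVH set under the requested parameter bundles.

    The PTV DVH is mandatory; each NTCP set whose organ DVH is missing is
    skipped with a recorded warning.  Every NTCP set applies its own
    alpha/beta in the EQD2 step, so the same organ DVH may be corrected
    several times on different effective-dose scales.
    """
    if ptv_structure not in dvhs:
        raise DVHValidationError(f"plan has no PTV structure {ptv_structure!r}")
    tcp_sets = tcp_sets or {}
    ntcp_sets = ntcp_sets or {}
    notes: List[str] = []

    metrics = {sid: summary_metrics(d) for sid, d in dvhs.items()}

    tcp_out: Dict[str, float] = {}
    for label, tp in tcp_sets.items():
        ptv_eqd2 = eqd2_correct_dvh(dvhs[ptv_structure], scheme, tp.alpha_beta_gy)
        tcp_out[label] = tcp_from_dvh(ptv_eqd2, tp, method=tcp_method)

    ntcp_out: Dict[str, float] = {}
    for label, pars in ntcp_sets.items():
        organ = getattr(pars, "structure", "") or label.split("_")[0]
        if organ not in dvhs:
            msg = f"NTCP set {label!r}: structure {organ!r} missing, skipped"
            notes.append(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        organ_eqd2 = eqd2_correct_dvh(dvhs[organ], scheme, pars.alpha_beta_gy)
        if isinstance(pars, LKBParams):
            ntcp_out[label] = lkb_ntcp(eud(organ_eqd2, pars.n_volume), pars)
        elif isinstance(pars, SerialityParams):
            ntcp_out[label] = seriality_ntcp(organ_eqd2, pars)
        else:
            raise TypeError(f"unsupported NTCP parameter type {type(pars)!r}")

    return PlanEvaluation(plan_label, scheme, metrics, tcp_out, ntcp_out, notes)
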