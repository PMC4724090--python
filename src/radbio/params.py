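"""Model-parameter dataclasses and the bundled parameter registry.

Published TCP/NTCP parameter sets ship with the package as a versioned
YAML file and are addressed by dotted citation labels, e.g.
``tcp.martel_30mo`` or ``lkb.lung_lkb.seppenwoolde_ab1.3`` (the leading
family prefix may be omitted when the label is unambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional

import yaml

__all__ = [
    "TCPParams",
    "LKBParams",
    "SerialityParams",
    "ParameterRegistry",
    "load_registry",
]


@dataclass(frozen=True)
class TCPParams:
    """Poisson-LQ tumor dose-response parameters (EQD2 scale)."""

    d50_eqd2_gy: float
    gamma: float
    alpha_beta_gy: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.d50_eqd2_gy <= 0 or self.gamma <= 0 or self.alpha_beta_gy <= 0:
            raise ValueError("TCP parameters must all be positive")


@dataclass(frozen=True)
class LKBParams:
    """Lyman-Kutcher-Burman NTCP parameters with volume-effect exponent n."""

    d50_gy: float
    n_volume: float
    m_slope: float
    alpha_beta_gy: float
    structure: str = ""
    endpoint: str = ""

    def __post_init__(self) -> None:
        if self.d50_gy <= 0:
            raise ValueError("d50_gy must be positive")
        if not 0 < self.n_volume <= 1:
            raise ValueError("n_volume must lie in (0, 1]")
        if self.m_slope <= 0:
            raise ValueError("m_slope must be positive")
        if self.alpha_beta_gy <= 0:
            raise ValueError("alpha_beta_gy must be positive")


@dataclass(frozen=True)
class SerialityParams:
    """Relative-seriality Poisson NTCP parameters."""

    d50_gy: float
    gamma: float
    s_seriality: float
    alpha_beta_gy: float
    structure: str = ""
    endpoint: str = ""

    def __post_init__(self) -> None:
        for name in ("d50_gy", "gamma", "s_seriality", "alpha_beta_gy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ParameterRegistry:
    version: int
    tcp: Dict[str, TCPParams]
    lkb: Dict[str, LKBParams]
    seriality: Dict[str, SerialityParams]

    def get(self, label: str):
        """Resolve a dotted label, with or without its family prefix."""
        for family, table in (
            ("tcp", self.tcp),
            ("lkb", self.lkb),
            ("seriality", self.seriality),
        ):
            if label in table:
                return table[label]
            prefix = family + "."
            if label.startswith(prefix) and label[len(prefix):] in table:
                return table[label[len(prefix):]]
        raise KeyError(f"unknown parameter label {label!r}")

    def ntcp_labels(self) -> Dict[str, object]:
        """All NTCP sets (LKB + seriality) keyed by label."""
        out: Dict[str, object] = dict(self.lkb)
        out.update(self.seriality)
        return out


def _load_yaml(path: Optional[str]) -> dict:
    if path is None:
        ref = resources.files("radbio") / "data" / "parameters.yaml"
        return yaml.safe_load(ref.read_text())
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_registry(path: Optional[str] = None) -> ParameterRegistry:
    """Load the bundled registry, or a user-provided YAML of the same shape."""
    raw = _load_yaml(path)
    tcp = {k: TCPParams(**v) for k, v in raw.get("tcp", {}).items()}
    lkb = {k: LKBParams(**v) for k, v in raw.get("lkb", {}).items()}
    ser = {k: SerialityParams(**v) for k, v in raw.get("seriality", {}).items()}
    return ParameterRegistry(raw.get("version", 1), tcp, lkb, ser)
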