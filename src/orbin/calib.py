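"""Air-scale calibration and shot-noise precision diagnostics.

Working-standard deltas measured in an in-house reference frame are placed on
the international atmospheric-N2 (Air) scale through the exact composition of
ratio transforms,

    delta_s,Air = delta_s,std + delta_std,Air + delta_s,std * delta_std,Air / 1000,

where delta_std,Air is the EA-IRMS-certified value of the working standard.
The cross term is not an approximation: the expression is algebraically
identical to ((1 + d1/1000)(1 + d2/1000) - 1) * 1000.

The precision floor of a counting measurement is the shot-noise limit

    sigma_delta**2 = 2e6 * (1/N_M + 1/N_m)   [permil**2]

with N_M, N_m the collected major/minor isotopologue ions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class StandardAnchor:
    """EA-IRMS-characterized delta15N_Air of a working standard, in permil."""

    compound: str
    delta_air: float
    uncertainty: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_air <= -1000.0:
            raise ValueError("delta_air must exceed -1000 permil")


#: Built-in EA-IRMS anchors for the shipped working standards (permil vs Air).
BUILTIN_ANCHORS: dict[str, StandardAnchor] = {
    a.compound: a
    for a in (
        StandardAnchor("Glycine", 1.32, 0.02),
        StandardAnchor("L-alanine", 43.22, 0.02),
        StandardAnchor("D-alanine", -1.05, 0.03),
        StandardAnchor("L-valine", 62.0, 0.2),
        StandardAnchor("D-valine", 5.88, 0.01),
        StandardAnchor("beta-alanine", -14.1, 0.02),
        StandardAnchor("alpha-AIB", 8.97, 0.04),
    )
}


def to_air_scale(delta_sample_vs_standard: float, anchor: StandardAnchor | float) -> float:
    """Place a delta measured against a working standard on the Air scale."""
    d_std = anchor.delta_air if isinstance(anchor, StandardAnchor) else float(anchor)
    d = delta_sample_vs_standard
    return d + d_std + d * d_std / 1000.0


@dataclass(frozen=True)
class ShotNoiseEstimate:
    """Predicted permil precision floor from collected ion counts."""

    sigma_delta: float
    counts_major: float
    counts_minor: float
    total_ions: float

    def se_for(self, n_replicates: int) -> float:
        """Expected SE of the replicate-mean delta for n identical replicates."""
        if n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        return self.sigma_delta / math.sqrt(n_replicates)


def shot_noise_sigma(counts_major: float, counts_minor: float) -> ShotNoiseEstimate:
    """Shot-noise sigma_delta (permil) from major/minor ion counts."""
    if counts_major <= 0 or counts_minor <= 0:
        raise ValueError("both ion counts must be positive")
    sigma = math.sqrt(2.0e6 * (1.0 / counts_major + 1.0 / counts_minor))
    return ShotNoiseEstimate(
        sigma_delta=sigma,
        counts_major=counts_major,
        counts_minor=counts_minor,
        total_ions=counts_major + counts_minor,
    )


@dataclass(frozen=True)
class PrecisionBudget:
    """Minor/major ions required per acquisition to hit a target SE."""

    counts_minor: int
    counts_major: float
    target_se: float
    n_replicates: int


def precision_budget(
    target_se: float, ratio: float, n_replicates: int
) -> PrecisionBudget:
    """Smallest N_m with sqrt(2e6 (1 + R)/N_m)/sqrt(n) <= target SE.

    With N_M = N_m / R the shot-noise variance collapses to
    2e6 (1 + R)/N_m, so the bound inverts in closed form.
    """
    if target_se <= 0:
        raise ValueError("target_se must be positive")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    n_minor = math.ceil(2.0e6 * (1.0 + ratio) / (n_replicates * target_se**2))
    return PrecisionBudget(
        counts_minor=n_minor,
        counts_major=n_minor / ratio,
        target_se=target_se,
        n_replicates=n_replicates,
    )


def anchors_from_config(path: str | Path) -> dict[str, StandardAnchor]:
    """Load standard anchors from a YAML/JSON table.

    Entries need ``compound``, ``delta_air_permil`` and optionally
    ``uncertainty_permil``.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    anchors = {}
    for entry in data:
        anchor = StandardAnchor(
            compound=str(entry["compound"]),
            delta_air=float(entry["delta_air_permil"]),
            uncertainty=float(entry.get("uncertainty_permil", 0.0)),
        )
        anchors[anchor.compound] = anchor
    return anchors
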