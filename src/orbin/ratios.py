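"""Ratio integration, delta notation, and replicate statistics.

The 15N/14N ratio of an acquisition is formed by summing ion counts for each
isotopologue over the whole integration window and dividing the sums
(sum-then-divide), never by averaging per-scan ratios: per-scan ratios at low
minor-ion counts are noisy and biased, while the summed-count ratio is the
count-weighted estimator whose variance attains the shot-noise limit.

Deltas follow conventional permil notation,

    delta15N = (15R_sample / 15R_standard - 1) * 1000,

and replicate sets are summarized by their mean, sample standard deviation
(n-1 denominator) and standard error SE = S / sqrt(n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from .counts import (
    IntegrationWindow,
    IonCountSettings,
    extract_isotopologue,
    ions_from_intensity,
    select_window,
)
from .model_io import Acquisition, RunSequence


class DegenerateAcquisitionError(ValueError):
    """No major-isotopologue ions in the integration window."""


class BracketingError(ValueError):
    """A sample acquisition lacks a preceding or following standard."""


@dataclass(frozen=True)
class RatioResult:
    """Summed ion counts and the 15N/14N ratio of one acquisition."""

    counts_major: float  # N_M, summed 14N-isotopologue ions
    counts_minor: float  # N_m, summed 15N-isotopologue ions
    ratio: float  # 15R = N_m / N_M
    window: IntegrationWindow
    n_scans: int

    def __post_init__(self) -> None:
        if self.counts_major <= 0:
            raise DegenerateAcquisitionError("counts_major must be positive")
        if self.counts_minor < 0:
            raise ValueError("counts_minor must be >= 0")


@dataclass(frozen=True)
class DeltaResult:
    """Replicate-averaged delta for one compound, in permil."""

    delta_vs_standard: float
    replicate_deltas: tuple[float, ...]
    n: int
    sd: float | None  # None when n = 1 (flagged, not zero)
    se: float | None
    delta_air: float | None = None
    compound: str = ""
    counts_major: float | None = None
    counts_minor: float | None = None
    shot_noise_sigma: float | None = None


def integrate_ratio(
    acquisition: Acquisition,
    window: IntegrationWindow,
    settings: IonCountSettings | None = None,
) -> RatioResult:
    """Sum isotopologue ion counts over the window and form 15R.

    A scan where the minor (15N) peak is absent contributes zero minor ions;
    zero-observation scans are informative at low minor-isotopologue
    abundance and are never dropped.
    """
    settings = settings or IonCountSettings()
    frag = acquisition.fragment
    total_major = 0.0
    total_minor = 0.0
    n_scans = 0
    for scan in window.scans(acquisition):
        n_scans += 1
        base = extract_isotopologue(scan, frag.base_mass, settings.ppm_tolerance)
        minor = extract_isotopologue(scan, frag.mass_15N, settings.ppm_tolerance)
        if base is not None:
            total_major += ions_from_intensity(base, scan, settings, frag.charge)
        if minor is not None:
            total_minor += ions_from_intensity(minor, scan, settings, frag.charge)
    if total_major <= 0:
        raise DegenerateAcquisitionError(
            "no major-isotopologue ions collected inside the window"
        )
    return RatioResult(
        counts_major=total_major,
        counts_minor=total_minor,
        ratio=total_minor / total_major,
        window=window,
        n_scans=n_scans,
    )


def delta_vs_standard(r_sample: float, r_standard: float) -> float:
    """delta15N in permil of a sample ratio against a standard ratio."""
    if r_standard <= 0:
        raise ValueError("standard ratio must be positive")
    return (r_sample / r_standard - 1.0) * 1000.0


def average_replicates(deltas: Sequence[float]) -> DeltaResult:
    """Mean, sample sd (n-1) and SE = sd/sqrt(n) of replicate deltas.

    With a single replicate the spread is undefined: sd and se come back as
    None rather than zero.
    """
    deltas = tuple(float(d) for d in deltas)
    n = len(deltas)
    if n == 0:
        raise ValueError("at least one replicate delta required")
    mean = sum(deltas) / n
    if n == 1:
        return DeltaResult(
            delta_vs_standard=mean, replicate_deltas=deltas, n=1, sd=None, se=None
        )
    var = sum((d - mean) ** 2 for d in deltas) / (n - 1)
    sd = math.sqrt(var)
    return DeltaResult(
        delta_vs_standard=mean,
        replicate_deltas=deltas,
        n=n,
        sd=sd,
        se=sd / math.sqrt(n),
    )


def acquisition_ratio(
    acquisition: Acquisition,
    settings: IonCountSettings | None = None,
    tic_it_band: float | None = None,
    require_ratio_stability: bool = False,
) -> RatioResult:
    """Window selection followed by ratio integration, in one call."""
    window = select_window(
        acquisition,
        tic_it_band=tic_it_band,
        require_ratio_stability=require_ratio_stability,
        settings=settings,
    )
    return integrate_ratio(acquisition, window, settings)


def pair_and_reduce(
    sequence: RunSequence,
    scheme: str = "pooled_standard",
    settings: IonCountSettings | None = None,
    tic_it_band: float | None = None,
) -> dict[str, DeltaResult]:
    """Reduce a run sequence to one DeltaResult per sample compound.

    ``pooled_standard`` references every sample replicate to the mean ratio
    of all standard acquisitions of the compound; ``bracketing`` references
    each sample to the mean of its nearest preceding and following standard.
    Blank acquisitions are ignored here and reported separately by the CLI.
    """
    if scheme not in ("pooled_standard", "bracketing"):
        raise ValueError(f"unknown pairing scheme {scheme!r}")

    # per-compound, ordered lists of (position, role, RatioResult)
    by_compound: dict[str, list[tuple[int, str, RatioResult]]] = {}
    for pos, acq in enumerate(sequence):
        if acq.role == "blank":
            continue
        result = acquisition_ratio(acq, settings=settings, tic_it_band=tic_it_band)
        by_compound.setdefault(acq.fragment.name, []).append((pos, acq.role, result))

    reduced: dict[str, DeltaResult] = {}
    for compound, entries in by_compound.items():
        standards = [(p, r) for p, role, r in entries if role == "standard"]
        samples = [(p, r) for p, role, r in entries if role == "sample"]
        if not samples:
            continue
        if not standards:
            raise ValueError(f"{compound}: no standard acquisition in the sequence")
        deltas = []
        for pos, sample in samples:
            if scheme == "pooled_standard":
                r_std = sum(r.ratio for _, r in standards) / len(standards)
            else:
                before = [(p, r) for p, r in standards if p < pos]
                after = [(p, r) for p, r in standards if p > pos]
                if not before or not after:
                    raise BracketingError(
                        f"{compound}: sample at position {pos} lacks a "
                        f"{'preceding' if not before else 'following'} standard"
                    )
                r_std = (before[-1][1].ratio + after[0][1].ratio) / 2.0
            deltas.append(delta_vs_standard(sample.ratio, r_std))
        result = average_replicates(deltas)
        total_major = sum(r.counts_major for _, r in samples)
        total_minor = sum(r.counts_minor for _, r in samples)
        reduced[compound] = replace(
            result,
            compound=compound,
            counts_major=total_major,
            counts_minor=total_minor,
        )
    return reduced
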