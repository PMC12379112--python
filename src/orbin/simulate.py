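"""Synthetic GC-Orbitrap acquisitions with known isotopic ground truth.

The generator embodies the ion statistics that set the precision of an
Orbitrap isotope-ratio measurement:

* ions arrive as a Poisson process at a true 15N/14N ratio, thinned
  independently into major (14N) and minor (15N) isotopologue counts;
* AGC sets each scan's injection time to ``agc_target`` charges given the
  instantaneous flux, saturating at a hard ceiling (200 ms by default), so
  low flux pins IT at the ceiling and high flux shortens it;
* the elution profile is either a narrow Gaussian (direct elution, tens of
  seconds) or a slow near-exponential bleed from a sample loop (peak
  trapping, up to ten minutes), which is what multiplies the usable scan
  count;
* realized counts are written back as peak intensities by inverting the
  intensity-to-ion-count relation with a constant noise band, plus Gaussian
  mass jitter, so the full reduction pipeline can run on the output.

An optional constant background ion flux contributes to AGC regulation and
to the TIC but not to the analyte peaks: it stands for the non-analyte ion
population of the scan window, and is what keeps injection times below the
ceiling in low-concentration scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .chem import FragmentDef, get_fragment
from .counts import IonCountSettings
from .model_io import Acquisition, MassPeak, RunSequence, ScanRecord

#: Absolute 15N/14N ratio of atmospheric N2, the simulator's scale anchor.
#: The reduction pipeline never needs this number; the simulator needs one
#: to turn delta-vs-Air truths into absolute ratios.
AIR_15R = 0.0036765

#: Per-carbon 13C/12C abundance used to decorate scans with a 13C peak.
R13C_PER_CARBON = 0.011


class SimConfigError(ValueError):
    """A simulation configuration the instrument model cannot realize."""


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters for one simulated acquisition.

    ``total_analyte_ions`` is the expected number of analyte ions
    *collected* (major + minor, summed over all scans during their injection
    times) if the whole elution profile fell inside the acquisition; the
    realized expectation is scaled by the flux fraction actually inside
    ``duration_s``.  Times are seconds, injection times milliseconds.
    """

    fragment: FragmentDef
    true_delta_air: float = 0.0
    mode: str = "trapped"
    total_analyte_ions: float = 3.0e6
    scan_period_s: float = 0.4
    duration_s: float | None = None  # default: 600 (trapped) / 30 (direct)
    elution_center_s: float = 15.0  # direct mode
    elution_width_s: float = 4.0  # direct mode, Gaussian sigma
    release_start_s: float = 0.0  # trapped mode
    decay_constant_s: float | None = 2000.0  # trapped; None = constant bleed
    agc_target: float = 200_000.0
    max_it_ms: float = 200.0
    min_it_ms: float = 0.03  # instrument injection-time quantum
    background_flux: float = 1.25e6  # ions/s seen by AGC and TIC, not the peaks
    noise_units: float = 1000.0  # constant per-peak noise, arbitrary units
    resolution_setting: float = 60_000.0
    micro_scans: int = 1
    mass_jitter_ppm: float = 1.0
    include_13c: bool = True
    settings: IonCountSettings = field(default_factory=IonCountSettings)

    def __post_init__(self) -> None:
        if self.mode not in ("direct", "trapped"):
            raise SimConfigError(f"mode must be 'direct' or 'trapped', got {self.mode!r}")
        if self.total_analyte_ions <= 0:
            raise SimConfigError("total_analyte_ions must be positive")
        if self.scan_period_s <= 0:
            raise SimConfigError("scan_period_s must be positive")
        if self.max_it_ms > self.scan_period_s * 1e3:
            raise SimConfigError("max injection time cannot exceed the scan period")
        if self.duration_s is None:
            object.__setattr__(
                self, "duration_s", 600.0 if self.mode == "trapped" else 30.0
            )

    @property
    def n_scans(self) -> int:
        return int(round(self.duration_s / self.scan_period_s))


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth bookkeeping for one simulated acquisition."""

    true_ratio: float
    true_delta_air: float
    expected_flux: np.ndarray  # analyte ions/s at each scan midpoint
    expected_collected: float  # E[major + minor] over all scans
    realized_major: int
    realized_minor: int


def _profile(cfg: SimConfig, t: np.ndarray) -> tuple[np.ndarray, float]:
    """Normalized elution density p(t) at scan midpoints and the flux
    fraction inside the acquisition (both for unit total delivery)."""
    if cfg.mode == "direct":
        w = cfg.elution_width_s
        p = np.exp(-0.5 * ((t - cfg.elution_center_s) / w) ** 2) / (
            w * math.sqrt(2.0 * math.pi)
        )
    else:
        tau = cfg.decay_constant_s
        rel = t - cfg.release_start_s
        if tau is None:
            # constant bleed over the acquisition
            p = np.where(rel >= 0.0, 1.0 / cfg.duration_s, 0.0)
        else:
            p = np.where(rel >= 0.0, np.exp(-np.maximum(rel, 0.0) / tau) / tau, 0.0)
    inside = float(min(np.sum(p) * cfg.scan_period_s, 1.0))
    return p, inside


def _injection_times(
    lam_analyte: np.ndarray, cfg: SimConfig
) -> np.ndarray:
    """AGC-governed injection time (s) per scan, ceiling-capped."""
    z = cfg.fragment.charge
    charges_per_s = (lam_analyte + cfg.background_flux) * z
    max_it = cfg.max_it_ms * 1e-3
    with np.errstate(divide="ignore"):
        it = np.where(
            charges_per_s > 0.0, cfg.agc_target / charges_per_s, np.inf
        )
    return np.minimum(it, max_it)


def simulate_acquisition(
    cfg: SimConfig,
    rng: np.random.Generator | int | None = None,
    role: str = "sample",
    replicate_id: int = 0,
) -> tuple[Acquisition, SimTruth]:
    """Simulate one acquisition; deterministic for a fixed seed/generator."""
    rng = np.random.default_rng(rng)
    frag = cfg.fragment
    z = frag.charge
    n = cfg.n_scans
    if n < 1:
        raise SimConfigError("duration shorter than one scan period")
    t = (np.arange(n) + 0.5) * cfg.scan_period_s
    p, inside = _profile(cfg, t)
    target_collected = cfg.total_analyte_ions * inside
    if target_collected <= 0:
        raise SimConfigError("no elution flux falls inside the acquisition")

    # Solve the flux scale s so that the expected collected analyte ions,
    # E[sum_i s p_i IT_i(s)], equal the target.  AGC couples IT to the flux,
    # so the balance is solved numerically (it is monotone in s).
    active = p > 0.0
    capacity = float(np.count_nonzero(active)) * cfg.agc_target / z
    if target_collected >= capacity:
        raise SimConfigError(
            f"requested {target_collected:.3g} collected ions exceed the AGC "
            f"capacity {capacity:.3g} of {n} scans at target {cfg.agc_target:.3g}"
        )

    def collected(scale: float) -> float:
        lam = scale * p
        return float(np.sum(lam * _injection_times(lam, cfg)))

    s_hi = max(target_collected / (np.sum(p) * cfg.max_it_ms * 1e-3), 1.0)
    while collected(s_hi) < target_collected:
        s_hi *= 2.0
        if s_hi > 1e30:
            raise SimConfigError("cannot realize the requested ion total")
    scale = brentq(
        lambda s: collected(s) - target_collected, 1e-30, s_hi, xtol=1e-12, rtol=1e-12
    )

    lam = scale * p
    it = _injection_times(lam, cfg)
    if np.any(it[active] < cfg.min_it_ms * 1e-3):
        raise SimConfigError(
            "analyte flux so high that the injection time falls below the "
            f"instrument quantum ({cfg.min_it_ms} ms)"
        )

    true_ratio = AIR_15R * (1.0 + cfg.true_delta_air / 1000.0)
    mu = lam * it  # expected analyte ions per scan
    expect_major = mu / (1.0 + true_ratio)
    expect_minor = mu * true_ratio / (1.0 + true_ratio)
    major = rng.poisson(expect_major)
    minor = rng.poisson(expect_minor)
    r13 = R13C_PER_CARBON * frag.composition["C"]
    c13 = rng.poisson(expect_major * r13) if cfg.include_13c else np.zeros(n, int)
    bg_ions = rng.poisson(cfg.background_flux * it)

    # invert the ion-count relation: S = noise * N_io * (z/C_N) * (R/R_N)^a / mu^b
    st = cfg.settings
    to_signal = (
        cfg.noise_units
        * (z / st.noise_charges)
        * (cfg.resolution_setting / st.reference_resolution) ** st.resolution_exponent
        / cfg.micro_scans**st.microscan_exponent
    )

    targets = [frag.base_mass, frag.mass_15N, frag.mass_13C]
    labels = ["base", "15N", "13C"]
    counts = [major, minor, c13]
    jitter = rng.normal(0.0, cfg.mass_jitter_ppm * 1e-6, size=(n, 3))

    scans = []
    for i in range(n):
        peaks = []
        for j, (target, label) in enumerate(zip(targets, labels)):
            if label == "13C" and not cfg.include_13c:
                continue
            peaks.append(
                MassPeak(
                    mz=target * (1.0 + jitter[i, j]),
                    signal=float(counts[j][i]) * to_signal,
                    noise=cfg.noise_units,
                    assigned_isotopologue=label,
                )
            )
        tic = sum(pk.signal for pk in peaks) + float(bg_ions[i]) * to_signal
        scans.append(
            ScanRecord(
                scan_index=i + 1,
                retention_time=float(t[i]),
                peaks=tuple(peaks),
                injection_time=float(it[i]) * 1e3,
                tic=tic,
                resolution_setting=cfg.resolution_setting,
                micro_scans=cfg.micro_scans,
                agc_target=cfg.agc_target,
            )
        )

    acquisition = Acquisition(
        scans=tuple(scans),
        fragment=frag,
        role=role,
        replicate_id=replicate_id,
        mode=cfg.mode,
        max_injection_time=cfg.max_it_ms,
    )
    truth = SimTruth(
        true_ratio=true_ratio,
        true_delta_air=cfg.true_delta_air,
        expected_flux=lam,
        expected_collected=float(np.sum(mu)),
        realized_major=int(np.sum(major)),
        realized_minor=int(np.sum(minor)),
    )
    return acquisition, truth


def simulate_sequence(
    sample_cfg: SimConfig,
    standard_cfg: SimConfig,
    n_sample: int,
    n_standard: int,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[RunSequence, list[SimTruth]]:
    """Interleaved standard/sample run sequence with per-acquisition seeds.

    Standards lead the sequence and alternate with samples (with
    ``n_standard = n_sample + 1`` they bracket every sample); the standard's
    ion total is expected to be matched to the sample's, mirroring the
    identical-treatment principle.
    """
    if n_sample < 1 or n_standard < 1:
        raise ValueError("need at least one sample and one standard acquisition")
    roles: list[str] = []
    ns, nst = n_sample, n_standard
    while ns or nst:
        if nst:
            roles.append("standard")
            nst -= 1
        if ns:
            roles.append("sample")
            ns -= 1
    entropy = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = entropy.spawn(len(roles))
    acquisitions, truths = [], []
    counters = {"sample": 0, "standard": 0}
    for role, child in zip(roles, children):
        cfg = sample_cfg if role == "sample" else standard_cfg
        counters[role] += 1
        acq, truth = simulate_acquisition(
            cfg,
            rng=np.random.default_rng(child),
            role=role,
            replicate_id=counters[role],
        )
        acquisitions.append(acq)
        truths.append(truth)
    timestamps = tuple(
        i * (sample_cfg.duration_s + 60.0) for i in range(len(acquisitions))
    )
    return RunSequence(tuple(acquisitions), timestamps), truths


def inject_anomalies(
    acquisition: Acquisition,
    ceiling_scans: Sequence[int] = (),
    tic_spike_scans: Sequence[int] = (),
    spike_factor: float = 1.0,
) -> Acquisition:
    """Force listed scans to the IT ceiling and/or multiply their TIC x IT.

    Scan indices refer to ``scan_index`` values.  Everything else is left
    untouched; used to build fixtures for the window-selection filters.
    """
    known = {s.scan_index for s in acquisition.scans}
    for idx in list(ceiling_scans) + list(tic_spike_scans):
        if idx not in known:
            raise IndexError(f"scan_index {idx} not present in the acquisition")
    ceiling = set(ceiling_scans)
    spiked = set(tic_spike_scans)
    scans = []
    for scan in acquisition.scans:
        if scan.scan_index in ceiling:
            scan = replace(scan, injection_time=acquisition.max_injection_time)
        if scan.scan_index in spiked:
            scan = replace(scan, tic=scan.tic * spike_factor)
        scans.append(scan)
    return replace(acquisition, scans=tuple(scans))


def poisson_delta_replicates(
    expected_minor: float,
    ratio: float = AIR_15R,
    n_replicates: int = 200,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Replicate sample-vs-standard deltas (permil) from Poisson ion totals.

    Each replicate draws an intensity-matched sample *and* standard
    measurement at the same true ratio and expected counts, as a delta
    measurement does: both contribute counting noise, which is where the
    factor 2 in the shot-noise variance 2e6 (1/N_M + 1/N_m) comes from.
    Sums of per-scan Poisson counts are Poisson, so drawing acquisition
    totals directly is statistically identical to scan-by-scan simulation
    and is the cheap way to probe the law across decades of ion counts.
    """
    if expected_minor <= 0 or not 0.0 < ratio < 1.0:
        raise ValueError("expected_minor must be > 0 and ratio in (0, 1)")
    rng = np.random.default_rng(rng)
    draws = rng.poisson(
        [[expected_minor / ratio, expected_minor]] * 2, size=(n_replicates, 2, 2)
    )
    if np.any(draws == 0):
        raise ValueError("degenerate replicate with zero ions; raise expected_minor")
    r_sample = draws[:, 0, 1] / draws[:, 0, 0]
    r_standard = draws[:, 1, 1] / draws[:, 1, 0]
    return (r_sample / r_standard - 1.0) * 1000.0


def config_for_collected(cfg: SimConfig, collected_ions: float) -> SimConfig:
    """Rescale ``total_analyte_ions`` so the *collected* expectation equals
    ``collected_ions`` given the flux fraction inside the acquisition."""
    t = (np.arange(cfg.n_scans) + 0.5) * cfg.scan_period_s
    _, inside = _profile(cfg, t)
    if inside <= 0:
        raise SimConfigError("no elution flux falls inside the acquisition")
    return replace(cfg, total_analyte_ions=collected_ions / inside)


def default_scenario(
    compound: str = "Glycine",
    mode: str = "trapped",
    delta_air_sample: float = 50.0,
    delta_air_standard: float = 0.0,
    collected_ions: float = 3.0e6,
    **overrides,
) -> tuple[SimConfig, SimConfig]:
    """Matched sample/standard configs for a named built-in fragment."""
    fragment = get_fragment(compound)
    base = SimConfig(fragment=fragment, mode=mode, **overrides)
    sample = config_for_collected(
        replace(base, true_delta_air=delta_air_sample), collected_ions
    )
    standard = replace(sample, true_delta_air=delta_air_standard)
    return sample, standard
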