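"""Ion counting and AGC-stable window selection.

Orbitrap FTMS reports peak intensities, not ion numbers.  The shot-noise
statistics that set the precision floor of an isotope-ratio measurement act
on ions, so intensities are converted to ion counts with

    N_io = (S/N) * (C_N / z) * (R_N / R)**a * mu**b

where S/N is the reported signal-to-noise of the peak, C_N the number of
charges in the noise band at the reference resolution R_N, z the ion charge,
R the scan's resolution setting, and mu the micro-scan count.  The exponents
default to 1/2 (noise scales with the square root of transient length and of
averaged packets).

Only scans acquired under regulated AGC are usable for ratio work: scans
whose injection time sits at the instrument ceiling, or whose TIC x IT
product strays outside a band around the acquisition median, are excluded,
and the longest contiguous clean run forms the integration window.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Sequence

from .model_io import Acquisition, MassPeak, ScanRecord

IT_AT_CEILING = "IT_at_ceiling"
TICXIT_OUT_OF_BAND = "TICxIT_out_of_band"
RATIO_UNSTABLE = "ratio_unstable"


class EmptyWindowError(ValueError):
    """No scan passes the AGC-stability filters; discard the acquisition."""


@dataclass(frozen=True)
class IonCountSettings:
    """Constants of the intensity-to-ion-count conversion.

    ``noise_charges`` (C_N) is instrument-specific and determined empirically;
    the default of 4.4 charges at a reference resolution of 240 000 matches
    values reported for Q Exactive-class analyzers.
    """

    noise_charges: float = 4.4
    reference_resolution: float = 240_000.0
    resolution_exponent: float = 0.5
    microscan_exponent: float = 0.5
    ppm_tolerance: float = 5.0
    tic_it_band: float = 0.20

    def __post_init__(self) -> None:
        if self.noise_charges <= 0:
            raise ValueError("noise_charges must be positive")
        if self.reference_resolution <= 0:
            raise ValueError("reference_resolution must be positive")


def ions_from_intensity(
    peak: MassPeak,
    scan: ScanRecord,
    settings: IonCountSettings,
    charge: int = 1,
) -> float:
    """Number of ions behind one reported peak intensity."""
    if peak.noise <= 0:
        raise ValueError("peak noise must be positive to form S/N")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    sn = peak.signal / peak.noise
    return (
        sn
        * (settings.noise_charges / charge)
        * (settings.reference_resolution / scan.resolution_setting)
        ** settings.resolution_exponent
        * scan.micro_scans**settings.microscan_exponent
    )


def extract_isotopologue(
    scan: ScanRecord, target_mz: float, tolerance_ppm: float
) -> MassPeak | None:
    """Nearest peak within ``tolerance_ppm`` of ``target_mz``; None if absent.

    Ties in mass distance break toward the higher-signal peak.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    best: MassPeak | None = None
    best_ppm = float("inf")
    for peak in scan.peaks:
        ppm = abs(peak.mz - target_mz) / target_mz * 1e6
        if ppm > tolerance_ppm:
            continue
        if ppm < best_ppm or (ppm == best_ppm and peak.signal > best.signal):
            best = peak
            best_ppm = ppm
    return best


@dataclass(frozen=True)
class IntegrationWindow:
    """Contiguous AGC-stable scan range (inclusive) plus exclusion diagnostics."""

    start_scan: int
    end_scan: int
    excluded_scans: tuple[tuple[int, str], ...] = ()
    tic_it_reference: float = 0.0

    def __post_init__(self) -> None:
        if self.start_scan > self.end_scan:
            raise ValueError("window start must be <= end")

    def __contains__(self, scan_index: int) -> bool:
        return self.start_scan <= scan_index <= self.end_scan

    def scans(self, acquisition: Acquisition) -> list[ScanRecord]:
        return [s for s in acquisition.scans if s.scan_index in self]

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_scans)


def _running_ratio_flags(
    acquisition: Acquisition,
    candidates: Sequence[ScanRecord],
    settings: IonCountSettings,
) -> set[int]:
    """Scans where the cumulative 15N/14N ratio departs >3 sigma (shot noise
    from the counts accumulated so far) from the final cumulative ratio."""
    frag = acquisition.fragment
    majors, minors = [], []
    for scan in candidates:
        base = extract_isotopologue(scan, frag.base_mass, settings.ppm_tolerance)
        minor = extract_isotopologue(scan, frag.mass_15N, settings.ppm_tolerance)
        majors.append(
            ions_from_intensity(base, scan, settings, frag.charge) if base else 0.0
        )
        minors.append(
            ions_from_intensity(minor, scan, settings, frag.charge) if minor else 0.0
        )
    total_major = sum(majors)
    total_minor = sum(minors)
    if total_major <= 0 or total_minor <= 0:
        return set()
    final_ratio = total_minor / total_major
    flags: set[int] = set()
    cum_major = cum_minor = 0.0
    for scan, nm, nn in zip(candidates, majors, minors):
        cum_major += nm
        cum_minor += nn
        if cum_major <= 0 or cum_minor <= 0:
            continue
        running = cum_minor / cum_major
        sigma = final_ratio * (1.0 / cum_major + 1.0 / cum_minor) ** 0.5
        if abs(running - final_ratio) > 3.0 * sigma:
            flags.add(scan.scan_index)
    return flags


def select_window(
    acquisition: Acquisition,
    tic_it_band: float | None = None,
    require_ratio_stability: bool = False,
    settings: IonCountSettings | None = None,
) -> IntegrationWindow:
    """Select the longest contiguous run of AGC-stable scans.

    Filters, in order of precedence:

    1. injection time at (or above) the instrument ceiling;
    2. TIC x IT outside ``median * (1 +/- band)`` over the ceiling-passing scans;
    3. optionally, a running-ratio stability screen (off by default).

    Every excluded scan carries exactly one (primary) reason code.  Raises
    :class:`EmptyWindowError` when no scan survives — the acquisition should
    be discarded.
    """
    settings = settings or IonCountSettings()
    band = settings.tic_it_band if tic_it_band is None else tic_it_band
    if not acquisition.scans:
        raise EmptyWindowError("acquisition has no scans")

    excluded: dict[int, str] = {}
    passing_it = [
        s
        for s in acquisition.scans
        if s.injection_time < acquisition.max_injection_time
    ]
    for scan in acquisition.scans:
        if scan.injection_time >= acquisition.max_injection_time:
            excluded[scan.scan_index] = IT_AT_CEILING

    reference = 0.0
    candidates: list[ScanRecord] = []
    if passing_it:
        products = {s.scan_index: s.tic * s.injection_time for s in passing_it}
        reference = median(products.values())
        low, high = reference * (1.0 - band), reference * (1.0 + band)
        for scan in passing_it:
            if not low <= products[scan.scan_index] <= high:
                excluded[scan.scan_index] = TICXIT_OUT_OF_BAND
            else:
                candidates.append(scan)

    if require_ratio_stability and candidates:
        for idx in _running_ratio_flags(acquisition, candidates, settings):
            excluded[idx] = RATIO_UNSTABLE
        candidates = [s for s in candidates if s.scan_index not in excluded]

    if not candidates:
        raise EmptyWindowError(
            "no scan passes the AGC-stability filters; discard this acquisition"
        )

    # longest contiguous run of retained scans (contiguous in acquisition
    # order); earliest run wins ties
    retained = {s.scan_index for s in candidates}
    best_run: tuple[int, int] | None = None
    best_len = 0
    run_start = None
    run_len = 0
    for scan in acquisition.scans:
        if scan.scan_index in retained:
            if run_start is None:
                run_start = scan.scan_index
                run_len = 0
            run_len += 1
            if run_len > best_len:
                best_len = run_len
                best_run = (run_start, scan.scan_index)
        else:
            run_start = None
            run_len = 0

    assert best_run is not None
    ordered_exclusions = tuple(
        (s.scan_index, excluded[s.scan_index])
        for s in acquisition.scans
        if s.scan_index in excluded
    )
    return IntegrationWindow(
        start_scan=best_run[0],
        end_scan=best_run[1],
        excluded_scans=ordered_exclusions,
        tic_it_reference=reference,
    )
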