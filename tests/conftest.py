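"""Shared fixtures: hand-built scans/acquisitions with known ion counts."""

from __future__ import annotations

import numpy as np
import pytest

from orbin.chem import get_fragment
from orbin.counts import IonCountSettings
from orbin.model_io import Acquisition, MassPeak, ScanRecord

#: Settings under which one unit of S/N equals exactly one ion (z = 1,
#: R = R_N, C_N = 1, mu = 1) — lets tests state ion counts directly.
UNIT_SETTINGS = IonCountSettings(noise_charges=1.0, reference_resolution=60_000.0)


@pytest.fixture
def glycine():
    return get_fragment("Glycine")


@pytest.fixture
def unit_settings():
    return UNIT_SETTINGS


def make_scan(
    scan_index: int,
    peaks=(),
    it_ms: float = 50.0,
    tic: float = 100.0,
    resolution: float = 60_000.0,
    micro_scans: int = 1,
    agc: float = 200_000.0,
) -> ScanRecord:
    """A scan from (mz, signal, noise) triples with stable AGC metadata."""
    return ScanRecord(
        scan_index=scan_index,
        retention_time=scan_index * 0.4,
        peaks=tuple(MassPeak(mz=m, signal=s, noise=n) for m, s, n in peaks),
        injection_time=it_ms,
        tic=tic,
        resolution_setting=resolution,
        micro_scans=micro_scans,
        agc_target=agc,
    )


def acquisition_from_counts(fragment, counts, role="sample", replicate_id=0,
                            it_ms=50.0, tic=100.0) -> Acquisition:
    """An acquisition whose per-scan (major, minor) ion counts are exact
    under UNIT_SETTINGS (signal = count, noise = 1, R = R_N, C_N = 1)."""
    scans = []
    for i, (major, minor) in enumerate(counts, start=1):
        peaks = [(fragment.base_mass, float(major), 1.0)]
        if minor is not None:
            peaks.append((fragment.mass_15N, float(minor), 1.0))
        scans.append(make_scan(i, peaks, it_ms=it_ms, tic=tic))
    return Acquisition(
        scans=tuple(scans), fragment=fragment, role=role, replicate_id=replicate_id
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
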