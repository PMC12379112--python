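"""Domain containers for scans/acquisitions and the scan-table CSV dialect.

A scan table is a plain CSV with one row per detected mass peak; scan-level
instrument state (injection time, TIC, resolution, ...) is repeated on every
peak row of the scan.  The dialect is an open stand-in for vendor scan
exports, with units taken verbatim (injection time in ms, m/z in Da,
intensities in arbitrary instrument units).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .chem import FragmentDef

#: Mandatory scan-table columns, in write order.
SCAN_TABLE_COLUMNS = [
    "scan_index",
    "rt_s",
    "mz",
    "intensity",
    "noise",
    "it_ms",
    "tic",
    "resolution",
    "micro_scans",
    "agc_target",
]

ROLES = ("sample", "standard", "blank")
MODES = ("direct", "trapped")


class ScanTableError(ValueError):
    """A scan-table file violating the documented dialect."""


@dataclass(frozen=True)
class MassPeak:
    """One centroided mass peak: m/z, reported signal S, and its noise N."""

    mz: float
    signal: float
    noise: float
    assigned_isotopologue: str | None = None  # base | 15N | 13C | None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.signal < 0:
            raise ValueError(f"peak signal must be >= 0, got {self.signal}")
        if self.noise <= 0:
            raise ValueError(f"peak noise must be positive, got {self.noise}")


@dataclass(frozen=True)
class ScanRecord:
    """One Orbitrap scan: its peaks plus the instrument state that produced it."""

    scan_index: int
    retention_time: float  # s
    peaks: tuple[MassPeak, ...]
    injection_time: float  # ms
    tic: float
    resolution_setting: float  # at m/z 200
    micro_scans: int = 1
    agc_target: float = 200_000.0

    def __post_init__(self) -> None:
        if self.injection_time <= 0:
            raise ValueError("injection_time must be positive")
        if self.micro_scans < 1:
            raise ValueError("micro_scans must be >= 1")
        peaks = tuple(sorted(self.peaks, key=lambda p: p.mz))
        object.__setattr__(self, "peaks", peaks)


@dataclass(frozen=True)
class Acquisition:
    """An ordered scan sequence for one compound injection, with role metadata."""

    scans: tuple[ScanRecord, ...]
    fragment: FragmentDef
    role: str = "sample"
    replicate_id: int = 0
    mode: str = "trapped"
    max_injection_time: float = 200.0  # ms; AGC hard ceiling

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.max_injection_time <= 0:
            raise ValueError("max_injection_time must be positive")
        scans = tuple(self.scans)
        object.__setattr__(self, "scans", scans)
        indices = [s.scan_index for s in scans]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("scan_index must be strictly increasing")
        if scans:
            r0, agc0 = scans[0].resolution_setting, scans[0].agc_target
            for s in scans:
                if s.resolution_setting != r0 or s.agc_target != agc0:
                    raise ValueError(
                        "all scans in an acquisition must share resolution_setting "
                        "and agc_target"
                    )

    def __len__(self) -> int:
        return len(self.scans)


@dataclass(frozen=True)
class RunSequence:
    """Acquisitions in analysis order (standards interleaved with samples)."""

    acquisitions: tuple[Acquisition, ...]
    timestamps: tuple[float, ...] | None = None  # acquisition start times, s

    def __post_init__(self) -> None:
        acqs = tuple(self.acquisitions)
        object.__setattr__(self, "acquisitions", acqs)
        if self.timestamps is not None:
            ts = tuple(self.timestamps)
            if len(ts) != len(acqs):
                raise ValueError("one timestamp per acquisition required")
            object.__setattr__(self, "timestamps", ts)

    def __len__(self) -> int:
        return len(self.acquisitions)

    def __iter__(self):
        return iter(self.acquisitions)


def read_scan_table(
    path: str | Path,
    fragment: FragmentDef,
    role: str = "sample",
    replicate_id: int = 0,
    mode: str = "trapped",
    max_injection_time: float = 200.0,
) -> Acquisition:
    """Read one acquisition from a scan-table CSV.

    Raises :class:`ScanTableError` naming the missing column, the malformed
    line numbers, or the ordering violation.
    """
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in SCAN_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ScanTableError(f"{path.name}: missing mandatory column(s) {missing}")

    numeric = table[SCAN_TABLE_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        lines = [int(i) + 2 for i in numeric.index[bad][:20]]
        raise ScanTableError(f"{path.name}: malformed row(s) at line(s) {lines}")

    scans: list[ScanRecord] = []
    last_index = -math.inf
    # group by position, not value: a scan_index reappearing later in the
    # file is an ordering error, not a continuation of the earlier scan
    blocks = (numeric["scan_index"] != numeric["scan_index"].shift()).cumsum()
    for _, group in numeric.groupby(blocks, sort=False):
        scan_index = group["scan_index"].iloc[0]
        if scan_index <= last_index:
            raise ScanTableError(
                f"{path.name}: scan_index not strictly increasing at scan "
                f"{int(scan_index)}"
            )
        last_index = scan_index
        first = group.iloc[0]
        peaks = tuple(
            MassPeak(mz=row.mz, signal=row.intensity, noise=row.noise)
            for row in group.itertuples()
        )
        scans.append(
            ScanRecord(
                scan_index=int(scan_index),
                retention_time=float(first.rt_s),
                peaks=peaks,
                injection_time=float(first.it_ms),
                tic=float(first.tic),
                resolution_setting=float(first.resolution),
                micro_scans=int(first.micro_scans),
                agc_target=float(first.agc_target),
            )
        )
    return Acquisition(
        scans=tuple(scans),
        fragment=fragment,
        role=role,
        replicate_id=replicate_id,
        mode=mode,
        max_injection_time=max_injection_time,
    )


def write_scan_table(acquisition: Acquisition, path: str | Path) -> None:
    """Write an acquisition in the scan-table CSV dialect (lossless round-trip)."""
    rows = []
    for scan in acquisition.scans:
        for peak in scan.peaks:
            rows.append(
                {
                    "scan_index": scan.scan_index,
                    "rt_s": scan.retention_time,
                    "mz": peak.mz,
                    "intensity": peak.signal,
                    "noise": peak.noise,
                    "it_ms": scan.injection_time,
                    "tic": scan.tic,
                    "resolution": scan.resolution_setting,
                    "micro_scans": scan.micro_scans,
                    "agc_target": scan.agc_target,
                }
            )
    frame = pd.DataFrame(rows, columns=SCAN_TABLE_COLUMNS)
    # repr-round-trip float formatting keeps the read/write cycle lossless
    frame.to_csv(path, index=False, float_format="%.17g")


_RESULT_COLUMNS = [
    "compound",
    "n",
    "delta_vs_standard_permil",
    "sd_permil",
    "se_permil",
    "delta_air_permil",
    "counts_major",
    "counts_minor",
    "shot_noise_sigma_permil",
]


def write_results(results: Sequence, path: str | Path) -> None:
    """Write per-compound delta results as TSV plus a JSON twin.

    ``results`` are :class:`orbin.ratios.DeltaResult` objects (duck-typed so
    this module stays import-light).
    """
    if not results:
        raise ValueError("no results to write")
    path = Path(path)
    rows = []
    for r in results:
        rows.append(
            {
                "compound": getattr(r, "compound", ""),
                "n": r.n,
                "delta_vs_standard_permil": r.delta_vs_standard,
                "sd_permil": r.sd,
                "se_permil": r.se,
                "delta_air_permil": r.delta_air,
                "counts_major": getattr(r, "counts_major", None),
                "counts_minor": getattr(r, "counts_minor", None),
                "shot_noise_sigma_permil": getattr(r, "shot_noise_sigma", None),
            }
        )
    frame = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    twin = path.with_suffix(".json")
    twin.write_text(json.dumps(rows, indent=2, default=float) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back into a DataFrame."""
    return pd.read_csv(path, sep="\t")


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    compound: str
    role: str
    replicate: int = 0
    mode: str = "trapped"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"manifest role must be one of {ROLES}, got {self.role!r}")


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read a run-sequence manifest (YAML or JSON list of acquisitions)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if isinstance(data, dict):
        data = data.get("acquisitions", [])
    entries = []
    for item in data:
        entries.append(
            ManifestEntry(
                path=str(item["path"]),
                compound=str(item["compound"]),
                role=str(item["role"]),
                replicate=int(item.get("replicate", 0)),
                mode=str(item.get("mode", "trapped")),
            )
        )
    return entries
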