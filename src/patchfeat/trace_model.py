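"""Core trace containers, an on-disk bundle format, and recording-quality gating.

Unit conventions used throughout the package: membrane potential in mV,
current in pA, resistance in MΩ, time in seconds.  All unit conversions
happen at the I/O boundary; in-memory arrays are always in these units.

A *bundle* is a plain directory holding one ``manifest.json`` (cell metadata,
protocols, QC fields, simulator ground truth when present) plus one ``.npy``
array file per sweep, so a dataset is inspectable with nothing but a text
editor and numpy.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

__all__ = [
    "Sweep",
    "StepProtocol",
    "CellRecord",
    "QCResult",
    "FormatError",
    "TraceValidationError",
    "load_bundle",
    "save_bundle",
    "apply_inclusion_criteria",
    "baseline_level",
    "LEAK_LIMIT_PA",
    "RA_LIMIT_MOHM",
    "RA_DRIFT_LIMIT",
]

#: Inclusion gate constants: |leak| must stay below 100 pA at the −70 mV hold,
#: access resistance below 25 MΩ (strict for the excitability arm, ≤ for the
#: PSC arm) and Ra drift below 20% during PSC collection.
LEAK_LIMIT_PA = 100.0
RA_LIMIT_MOHM = 25.0
RA_DRIFT_LIMIT = 0.20

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"

#: Uniform-sampling tolerance on the time axis, in seconds.
_DT_TOL_S = 1e-9


class FormatError(Exception):
    """Malformed bundle metadata."""


class TraceValidationError(Exception):
    """A sweep violated a structural invariant (lengths, sampling, mode)."""


@dataclass
class Sweep:
    """One time-aligned recorded trace plus its command waveform.

    ``primary`` is membrane potential (mV) in current clamp or membrane
    current (pA) in voltage clamp; ``command`` is the injected current (pA)
    or command potential (mV) respectively.
    """

    time_s: np.ndarray
    primary: np.ndarray
    command: np.ndarray
    rate_hz: float
    mode: str = CURRENT_CLAMP
    label: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.primary = np.asarray(self.primary, dtype=float)
        self.command = np.asarray(self.command, dtype=float)
        n = len(self.time_s)
        if not (len(self.primary) == len(self.command) == n):
            raise TraceValidationError(
                f"sweep {self.label!r}: array length mismatch "
                f"(time={n}, primary={len(self.primary)}, command={len(self.command)})"
            )
        if not self.rate_hz > 0:
            raise TraceValidationError(f"sweep {self.label!r}: rate_hz must be > 0")
        if self.mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
            raise TraceValidationError(f"sweep {self.label!r}: unknown mode {self.mode!r}")
        if n >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise TraceValidationError(f"sweep {self.label!r}: time axis not increasing")
            if np.ptp(dt) > _DT_TOL_S:
                raise TraceValidationError(
                    f"sweep {self.label!r}: non-uniform sampling (ptp(dt)={np.ptp(dt):.3e} s)"
                )

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) if self.n_samples else 0.0

    def index_at(self, t: float) -> int:
        """Nearest sample index to time ``t`` (seconds)."""
        return int(round((t - float(self.time_s[0])) * self.rate_hz))


@dataclass
class StepProtocol:
    """A family of square current steps from a common baseline.

    ``baseline_mV`` is the pre-step target level (−70 mV for the step family,
    −60 mV for the AHP burst protocol, −70 mV hold for PSC collection).
    """

    baseline_mV: float
    step_onset_s: float
    step_offset_s: float
    amplitudes_pA: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes_pA = np.asarray(self.amplitudes_pA, dtype=float)
        if not self.step_onset_s < self.step_offset_s:
            raise TraceValidationError("step_onset_s must precede step_offset_s")
        if len(self.amplitudes_pA) >= 2:
            inc = np.diff(self.amplitudes_pA)
            if np.any(inc <= 0):
                raise TraceValidationError("step amplitudes must be strictly increasing")
            if np.ptp(inc) > 1e-9:
                raise TraceValidationError("step amplitude increment must be uniform")

    @property
    def step_duration_s(self) -> float:
        return self.step_offset_s - self.step_onset_s


@dataclass
class CellRecord:
    """All sweeps and QC metadata for one recorded (or simulated) cell."""

    cell_id: str
    genotype: str
    sweeps: Dict[str, List[Sweep]] = field(default_factory=dict)
    protocols: Dict[str, StepProtocol] = field(default_factory=dict)
    animal_id: str = ""
    leak_pA: float = 0.0
    ra_MOhm_start: float = 0.0
    ra_MOhm_end: Optional[float] = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genotype not in ("WT", "Tg"):
            raise TraceValidationError(
                f"cell {self.cell_id}: genotype must be WT or Tg, got {self.genotype!r}"
            )
        for v, name in ((self.leak_pA, "leak_pA"), (self.ra_MOhm_start, "ra_MOhm_start")):
            if not np.isfinite(v):
                raise TraceValidationError(f"cell {self.cell_id}: {name} not finite")
        if self.ra_MOhm_end is not None and not np.isfinite(self.ra_MOhm_end):
            raise TraceValidationError(f"cell {self.cell_id}: ra_MOhm_end not finite")


@dataclass
class QCResult:
    included: bool
    reasons: List[str]

    def __post_init__(self) -> None:
        if self.included != (len(self.reasons) == 0):
            raise ValueError("QCResult: included must be equivalent to empty reasons")


def apply_inclusion_criteria(
    record: CellRecord, excitability_qc: bool = True, psc_qc: bool = False
) -> QCResult:
    """Apply the recording-quality inclusion gate.

    Excitability arm: |leak| < 100 pA at the −70 mV hold and Ra < 25 MΩ
    (strict).  PSC arm: Ra ≤ 25 MΩ and Ra drift < 20% of the starting value
    during collection.  Each failed criterion contributes one entry to
    ``reasons`` ("leak", "ra", "ra_drift"), so a record failing k criteria
    yields exactly k reasons.
    """
    reasons: List[str] = []
    if not abs(record.leak_pA) < LEAK_LIMIT_PA:
        reasons.append("leak")
    ra0 = record.ra_MOhm_start
    ra_fail = False
    if excitability_qc and not ra0 < RA_LIMIT_MOHM:
        ra_fail = True
    if psc_qc and not ra0 <= RA_LIMIT_MOHM:
        ra_fail = True
    if ra_fail:
        reasons.append("ra")
    if psc_qc:
        if record.ra_MOhm_end is None:
            raise ValueError(
                f"cell {record.cell_id}: ra_MOhm_end required for PSC inclusion check"
            )
        drift = abs(record.ra_MOhm_end - ra0) / ra0
        if not drift < RA_DRIFT_LIMIT:
            reasons.append("ra_drift")
    return QCResult(included=not reasons, reasons=reasons)


def baseline_level(sweep: Sweep, window: Sequence[float]) -> float:
    """Mean of the primary signal over ``window = (t0, t1)`` seconds."""
    t0, t1 = float(window[0]), float(window[1])
    i0 = max(0, sweep.index_at(t0))
    i1 = min(sweep.n_samples, sweep.index_at(t1))
    if i1 <= i0:
        raise ValueError(f"empty baseline window ({t0}, {t1}) for sweep {sweep.label!r}")
    return float(np.mean(sweep.primary[i0:i1]))


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

_MANIFEST = "manifest.json"
_BUNDLE_VERSION = 1


def _protocol_to_json(p: StepProtocol) -> dict:
    d = asdict(p)
    d["amplitudes_pA"] = [float(a) for a in p.amplitudes_pA]
    return d


def _protocol_from_json(d: dict) -> StepProtocol:
    return StepProtocol(
        baseline_mV=d["baseline_mV"],
        step_onset_s=d["step_onset_s"],
        step_offset_s=d["step_offset_s"],
        amplitudes_pA=np.asarray(d["amplitudes_pA"], dtype=float),
    )


def save_bundle(records: Sequence[CellRecord], path) -> None:
    """Write records to a bundle directory (manifest.json + one .npy per sweep).

    Arrays are stored float64 so ``load_bundle`` reproduces them bit-exactly.
    An existing bundle at ``path`` is replaced.
    """
    root = Path(path)
    if root.exists():
        if not (root / _MANIFEST).exists() and any(root.iterdir()):
            raise FormatError(f"{root} exists and is not a bundle; refusing to overwrite")
        shutil.rmtree(root)
    arrays = root / "arrays"
    arrays.mkdir(parents=True)

    cells = []
    for rec in records:
        entry = {
            "cell_id": rec.cell_id,
            "animal_id": rec.animal_id,
            "genotype": rec.genotype,
            "leak_pA": rec.leak_pA,
            "ra_MOhm_start": rec.ra_MOhm_start,
            "ra_MOhm_end": rec.ra_MOhm_end,
            "ground_truth": rec.ground_truth,
            "protocols": {k: _protocol_to_json(v) for k, v in rec.protocols.items()},
            "sweeps": {},
        }
        for proto, sweeps in rec.sweeps.items():
            entry["sweeps"][proto] = []
            for i, sw in enumerate(sweeps):
                fname = f"{rec.cell_id}__{proto}__{i}.npy"
                np.save(arrays / fname, np.vstack([sw.time_s, sw.primary, sw.command]))
                entry["sweeps"][proto].append(
                    {"file": fname, "rate_hz": sw.rate_hz, "mode": sw.mode, "label": sw.label}
                )
        cells.append(entry)

    manifest = {"version": _BUNDLE_VERSION, "cells": cells}
    with open(root / _MANIFEST, "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_bundle(path) -> List[CellRecord]:
    """Read a bundle directory written by :func:`save_bundle`.

    Raises :class:`FormatError` for malformed metadata and
    :class:`TraceValidationError` (naming the offending sweep) when an array
    violates a sweep invariant.
    """
    root = Path(path)
    mpath = root / _MANIFEST
    if not mpath.exists():
        raise FormatError(f"no {_MANIFEST} found in {root}")
    try:
        with open(mpath) as fh:
            manifest = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"unreadable manifest in {root}: {exc}") from exc
    if manifest.get("version") != _BUNDLE_VERSION:
        raise FormatError(f"unsupported bundle version {manifest.get('version')!r}")

    records: List[CellRecord] = []
    for entry in manifest.get("cells", []):
        try:
            cell_id = entry["cell_id"]
            sweeps: Dict[str, List[Sweep]] = {}
            for proto, sweep_entries in entry["sweeps"].items():
                sweeps[proto] = []
                for se in sweep_entries:
                    arr = np.load(root / "arrays" / se["file"])
                    if arr.ndim != 2 or arr.shape[0] != 3:
                        raise TraceValidationError(
                            f"sweep {se['label'] or se['file']!r}: "
                            f"expected 3×n array, got shape {arr.shape}"
                        )
                    sweeps[proto].append(
                        Sweep(
                            time_s=arr[0],
                            primary=arr[1],
                            command=arr[2],
                            rate_hz=se["rate_hz"],
                            mode=se["mode"],
                            label=se.get("label", ""),
                        )
                    )
            records.append(
                CellRecord(
                    cell_id=cell_id,
                    animal_id=entry.get("animal_id", ""),
                    genotype=entry["genotype"],
                    sweeps=sweeps,
                    protocols={
                        k: _protocol_from_json(v) for k, v in entry.get("protocols", {}).items()
                    },
                    leak_pA=entry["leak_pA"],
                    ra_MOhm_start=entry["ra_MOhm_start"],
                    ra_MOhm_end=entry.get("ra_MOhm_end"),
                    ground_truth=entry.get("ground_truth", {}),
                )
            )
        except KeyError as exc:
            raise FormatError(f"manifest entry missing field {exc} in {root}") from exc
    return records
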