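"""Current-clamp feature extraction.

Implements the intrinsic-excitability measurements of the analysis this
package reproduces: resting membrane potential, input resistance from the
V–I slope of the −100…+50 pA steps, spike detection and rheobase, AP
threshold by the 5%-of-maximum-dV/dt rule, AP height and width at
half-maximum, the F–I curve, sag ratio and rebound voltages from
hyperpolarizing steps, and the medium/slow afterhyperpolarization measures.

Window lengths (100 ms baselines, 200 ms sag/rebound search, 10 ms blanking
after the last burst pulse) are configuration, not physiology: they must be
shorter than the step and longer than the membrane time constant, and every
one of them is an explicit keyword argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .trace_model import CURRENT_CLAMP, CellRecord, StepProtocol, Sweep, baseline_level
from .synthetic_data import AHP_LAST_PULSE_OFFSET_S

__all__ = [
    "StepMeasurement",
    "APFeatures",
    "FICurve",
    "AHPMeasure",
    "resting_membrane_potential",
    "input_resistance",
    "fit_vi_slope",
    "detect_spikes",
    "ap_threshold",
    "ap_height_and_width",
    "rheobase",
    "fi_curve",
    "measure_step_voltages",
    "sag_ratio",
    "cell_sag_ratio",
    "rebound_points",
    "pooled_rebound_slope",
    "ahp_measures",
    "extract_cell_features",
    "feature_table",
    "fi_table",
    "rebound_table",
]

#: Minimum steady-state deflection (mV) for a step to enter the sag-ratio
#: average; smaller deflections make the ratio numerically meaningless.
MIN_DEFLECTION_MV = 0.5


@dataclass
class StepMeasurement:
    """Voltages measured on one current step (see the sag/rebound scheme).

    ``V_SAG`` is extremum-minus-steady-state (≤ 0 on hyperpolarizing steps);
    ``V_rebound`` is the post-offset peak above the pre-step baseline.
    """

    V_h: float
    V_SS: float
    V_SAG: float
    V_rebound: float
    I_step: float


@dataclass
class APFeatures:
    t_peak: float
    V_peak: float
    V_threshold: float
    height: float  # mV, V_peak − V_threshold
    fwhm: float  # ms

    def __post_init__(self) -> None:
        if not (self.height > 0 and self.fwhm > 0):
            raise ValueError("AP height and FWHM must be positive")


@dataclass
class FICurve:
    steps_pA: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.steps_pA = np.asarray(self.steps_pA, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.steps_pA) != len(self.counts):
            raise ValueError("steps and counts must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")


@dataclass
class AHPMeasure:
    mAHP_mV: float
    sAHP_auc_mVs: float


def resting_membrane_potential(sweep: Sweep, window: Optional[Sequence[float]] = None) -> float:
    """Mean potential of a zero-holding-current sweep (default: full sweep)."""
    if sweep.mode != CURRENT_CLAMP:
        raise ValueError("RMP requires a current-clamp sweep")
    if np.any(sweep.command != 0):
        raise ValueError("RMP must be measured with zero holding current")
    if window is None:
        window = (float(sweep.time_s[0]), float(sweep.time_s[-1]) + 0.5 / sweep.rate_hz)
    return baseline_level(sweep, window)


# ---------------------------------------------------------------------------
# Spikes
# ---------------------------------------------------------------------------


def detect_spikes(
    sweep: Sweep,
    window: Optional[Sequence[float]] = None,
    height_mV: float = 0.0,
    min_separation_s: float = 1e-3,
) -> np.ndarray:
    """Peak times of suprathreshold excursions (peak > ``height_mV``).

    Peaks closer than ``min_separation_s`` are merged keeping the larger one.
    Returns an empty array when nothing crosses.
    """
    v = sweep.primary
    i0, i1 = 0, sweep.n_samples
    if window is not None:
        i0 = max(0, sweep.index_at(window[0]))
        i1 = min(sweep.n_samples, sweep.index_at(window[1]))
    distance = max(1, int(round(min_separation_s * sweep.rate_hz)))
    idx, _ = find_peaks(v[i0:i1], height=height_mV, distance=distance)
    return sweep.time_s[i0 + idx]


def ap_threshold(
    sweep: Sweep,
    t_peak: float,
    frac: float = 0.05,
    search_window_s: float = 0.010,
) -> float:
    """AP threshold by the dV/dt criterion.

    Within ``search_window_s`` before the peak, find the maximum of dV/dt,
    then walk backward to the last sample before the peak at which |dV/dt|
    has fallen to ``frac`` (5%) of that maximum; the membrane potential there
    is the threshold.  Ties at exactly the 5% level take the earliest sample.
    """
    i_peak = sweep.index_at(t_peak)
    w0 = max(1, i_peak - int(round(search_window_s * sweep.rate_hz)))
    if i_peak <= w0:
        raise ValueError("peak too close to sweep start for threshold search")
    dvdt = np.gradient(sweep.primary, 1.0 / sweep.rate_hz)
    i_maxd = w0 + int(np.argmax(dvdt[w0 : i_peak + 1]))
    level = frac * dvdt[i_maxd]
    j = i_maxd
    while j > w0 and dvdt[j] > level:
        j -= 1
    if dvdt[j] > level:
        raise ValueError("dV/dt never fell to the 5% level in the search window")
    while j - 1 >= w0 and dvdt[j - 1] == dvdt[j]:
        j -= 1
    return float(sweep.primary[j])


def ap_height_and_width(sweep: Sweep, t_peak: float, threshold: float) -> APFeatures:
    """Height (threshold → peak) and width at half-maximum height.

    Half-height crossing times are linearly interpolated between samples.
    """
    i_peak = sweep.index_at(t_peak)
    # refine the peak to the local maximum within ±1 ms
    r = int(round(1e-3 * sweep.rate_hz))
    lo = max(0, i_peak - r)
    i_peak = lo + int(np.argmax(sweep.primary[lo : i_peak + r + 1]))
    v = sweep.primary
    V_peak = float(v[i_peak])
    height = V_peak - threshold
    if height <= 0:
        raise ValueError("peak does not exceed threshold")
    half = threshold + height / 2.0

    def _cross(direction: int) -> float:
        j = i_peak
        while 0 < j < len(v) - 1:
            j += direction
            if v[j] < half:
                # interpolate between j and j-direction
                v1, v0 = v[j], v[j - direction]
                f = (v0 - half) / (v0 - v1)
                return float(sweep.time_s[j - direction] + direction * f / sweep.rate_hz)
        raise ValueError("half-maximum level not crossed on both sides of the peak")

    t_left = _cross(-1)
    t_right = _cross(+1)
    return APFeatures(
        t_peak=float(sweep.time_s[i_peak]),
        V_peak=V_peak,
        V_threshold=threshold,
        height=height,
        fwhm=(t_right - t_left) * 1e3,
    )


# ---------------------------------------------------------------------------
# Step-family measures
# ---------------------------------------------------------------------------


def _step_window(sweep: Sweep, protocol: StepProtocol) -> Tuple[int, int]:
    i_on = sweep.index_at(protocol.step_onset_s)
    i_off = sweep.index_at(protocol.step_offset_s)
    if not (0 < i_on < i_off <= sweep.n_samples):
        raise ValueError("step window lies outside the sweep")
    return i_on, i_off


def measure_step_voltages(
    sweep: Sweep,
    protocol: StepProtocol,
    pre_window_s: float = 0.100,
    ss_window_s: float = 0.100,
    sag_window_s: float = 0.200,
    rebound_window_s: float = 0.200,
) -> StepMeasurement:
    """Baseline, steady-state, sag and rebound voltages for one step sweep.

    V_h = mean over ``pre_window_s`` before onset; V_SS = mean over the last
    ``ss_window_s`` of the step; V_SAG = (extremum within the first
    ``sag_window_s`` of the step) − V_SS, taking the minimum for
    hyperpolarizing and the maximum for depolarizing steps; V_rebound =
    (maximum within ``rebound_window_s`` after offset) − V_h.
    """
    i_on, i_off = _step_window(sweep, protocol)
    rate = sweep.rate_hz
    n_pre = int(round(pre_window_s * rate))
    n_ss = int(round(ss_window_s * rate))
    n_sag = int(round(sag_window_s * rate))
    n_reb = int(round(rebound_window_s * rate))
    if i_on - n_pre < 0 or i_off + n_reb > sweep.n_samples or n_sag > i_off - i_on:
        raise ValueError("measurement windows exceed the sweep")
    v = sweep.primary
    V_h = float(np.mean(v[i_on - n_pre : i_on]))
    V_SS = float(np.mean(v[i_off - n_ss : i_off]))
    I_step = float(np.mean(sweep.command[i_on:i_off]))
    seg = v[i_on : i_on + n_sag]
    extremum = float(np.min(seg)) if I_step < 0 else float(np.max(seg))
    V_rebound = float(np.max(v[i_off : i_off + n_reb])) - V_h
    return StepMeasurement(V_h=V_h, V_SS=V_SS, V_SAG=extremum - V_SS,
                           V_rebound=V_rebound, I_step=I_step)


def fit_vi_slope(I_pA: np.ndarray, V_mV: np.ndarray) -> float:
    """Ordinary least-squares slope of V (mV) on I (pA), returned in MΩ."""
    I_pA = np.asarray(I_pA, dtype=float)
    V_mV = np.asarray(V_mV, dtype=float)
    slope_mV_per_pA = np.polyfit(I_pA, V_mV, 1)[0]
    return float(slope_mV_per_pA * 1e3)  # mV/pA = GΩ → MΩ


def input_resistance(
    record: CellRecord | Sequence[Sweep],
    protocol: Optional[StepProtocol] = None,
    fit_range_pA: Tuple[float, float] = (-100.0, 50.0),
) -> float:
    """Input resistance (MΩ) from the V–I slope of the −100…+50 pA steps.

    Steady-state voltages are regressed on step current; sweeps containing
    spikes within the step are excluded from the fit.  Raises when fewer
    than two usable points remain.
    """
    sweeps, protocol = _resolve_steps(record, protocol)
    I_list, V_list = [], []
    for sw in sweeps:
        m = measure_step_voltages(sw, protocol)
        if not fit_range_pA[0] - 1e-9 <= m.I_step <= fit_range_pA[1] + 1e-9:
            continue
        if len(detect_spikes(sw, (protocol.step_onset_s, protocol.step_offset_s))):
            continue
        I_list.append(m.I_step)
        V_list.append(m.V_SS)
    if len(I_list) < 2:
        raise ValueError("fewer than 2 usable (non-spiking) steps for the V–I fit")
    return fit_vi_slope(np.asarray(I_list), np.asarray(V_list))


def _resolve_steps(
    record: CellRecord | Sequence[Sweep], protocol: Optional[StepProtocol]
) -> Tuple[List[Sweep], StepProtocol]:
    if isinstance(record, CellRecord):
        sweeps = record.sweeps.get("steps", [])
        protocol = protocol or record.protocols.get("steps")
    else:
        sweeps = list(record)
    if protocol is None:
        raise ValueError("a StepProtocol is required")
    return list(sweeps), protocol


def rheobase(
    record: CellRecord | Sequence[Sweep], protocol: Optional[StepProtocol] = None
) -> float:
    """Smallest step current (pA) eliciting at least one spike; NaN if none."""
    sweeps, protocol = _resolve_steps(record, protocol)
    best = math.inf
    for sw in sweeps:
        I = float(np.mean(sw.command[sw.index_at(protocol.step_onset_s):
                                     sw.index_at(protocol.step_offset_s)]))
        if I <= 0 or I >= best:
            continue
        if len(detect_spikes(sw, (protocol.step_onset_s, protocol.step_offset_s))):
            best = I
    return best if math.isfinite(best) else float("nan")


def fi_curve(
    record: CellRecord | Sequence[Sweep], protocol: Optional[StepProtocol] = None
) -> FICurve:
    """Spike count per positive current step (the F–I relation)."""
    sweeps, protocol = _resolve_steps(record, protocol)
    steps, counts = [], []
    for sw in sweeps:
        I = float(np.mean(sw.command[sw.index_at(protocol.step_onset_s):
                                     sw.index_at(protocol.step_offset_s)]))
        if I <= 0:
            continue
        steps.append(I)
        counts.append(len(detect_spikes(sw, (protocol.step_onset_s, protocol.step_offset_s))))
    order = np.argsort(steps)
    return FICurve(np.asarray(steps)[order], np.asarray(counts)[order])


# ---------------------------------------------------------------------------
# Sag, rebound, AHP
# ---------------------------------------------------------------------------


def sag_ratio(m: StepMeasurement) -> float:
    """Sag ratio of one step: (V_SAG + (V_SS − V_h)) / (V_SS − V_h).

    Equals 1 when there is no sag and grows with the transient overshoot.
    Raises for deflections below ``MIN_DEFLECTION_MV``.
    """
    defl = m.V_SS - m.V_h
    if abs(defl) < MIN_DEFLECTION_MV:
        raise ValueError("steady-state deflection too small for a sag ratio")
    return (m.V_SAG + defl) / defl


def cell_sag_ratio(
    record: CellRecord | Sequence[Sweep],
    protocol: Optional[StepProtocol] = None,
    step_range_pA: Tuple[float, float] = (-100.0, -25.0),
) -> float:
    """Per-cell sag ratio: mean over the four hyperpolarizing steps.

    Steps whose deflection is below ``MIN_DEFLECTION_MV`` are skipped; NaN is
    returned when no usable step remains.
    """
    sweeps, protocol = _resolve_steps(record, protocol)
    ratios = []
    for sw in sweeps:
        m = measure_step_voltages(sw, protocol)
        if not step_range_pA[0] - 1e-9 <= m.I_step <= step_range_pA[1] + 1e-9:
            continue
        if abs(m.V_SS - m.V_h) < MIN_DEFLECTION_MV:
            continue
        ratios.append(sag_ratio(m))
    return float(np.mean(ratios)) if ratios else float("nan")


def rebound_points(
    records: Iterable[CellRecord],
    protocol: Optional[StepProtocol] = None,
    step_range_pA: Tuple[float, float] = (-100.0, -25.0),
) -> pd.DataFrame:
    """Long table of (V_SS, V_rebound) pairs, one row per cell × hyperpolarizing step."""
    rows = []
    for rec in records:
        sweeps, proto = _resolve_steps(rec, protocol)
        for sw in sweeps:
            m = measure_step_voltages(sw, proto)
            if not step_range_pA[0] - 1e-9 <= m.I_step <= step_range_pA[1] + 1e-9:
                continue
            rows.append(
                {
                    "cell_id": rec.cell_id,
                    "genotype": rec.genotype,
                    "V_ss_mV": m.V_SS,
                    "V_rebound_mV": m.V_rebound,
                }
            )
    return pd.DataFrame(rows, columns=["cell_id", "genotype", "V_ss_mV", "V_rebound_mV"])


def pooled_rebound_slope(points: pd.DataFrame) -> float:
    """OLS slope of V_rebound on V_SS pooled over all rows (mV/mV)."""
    return float(np.polyfit(points["V_ss_mV"], points["V_rebound_mV"], 1)[0])


def ahp_measures(
    sweep: Sweep,
    v_hold_mV: float = -60.0,
    last_pulse_offset_s: float = AHP_LAST_PULSE_OFFSET_S,
    blank_s: float = 0.010,
    mahp_end_s: float = 0.500,
    auc_window_s: Tuple[float, float] = (0.500, 2.000),
) -> AHPMeasure:
    """Medium-AHP trough and signed slow-AHP area after the burst.

    mAHP = min(V − V_hold) over [last pulse offset + ``blank_s``,
    ``mahp_end_s``]; sAHP AUC = trapezoidal integral of (V − V_hold) over
    ``auc_window_s`` — signed, so depolarizing excursions subtract.
    """
    if sweep.time_s[-1] + 1.0 / sweep.rate_hz < auc_window_s[1]:
        raise ValueError("sweep shorter than the 2 s AHP analysis window")
    rel = sweep.primary - v_hold_mV
    i0 = sweep.index_at(last_pulse_offset_s + blank_s)
    i1 = sweep.index_at(mahp_end_s)
    mahp = float(np.min(rel[i0:i1]))
    j0 = sweep.index_at(auc_window_s[0])
    j1 = min(sweep.n_samples - 1, sweep.index_at(auc_window_s[1]))
    auc = float(np.trapezoid(rel[j0 : j1 + 1], dx=1.0 / sweep.rate_hz))
    return AHPMeasure(mAHP_mV=mahp, sAHP_auc_mVs=auc)


# ---------------------------------------------------------------------------
# Per-cell extraction / tables
# ---------------------------------------------------------------------------


def extract_cell_features(record: CellRecord) -> dict:
    """All scalar features for one cell, NaN where a measure is unavailable."""
    out = {
        "cell_id": record.cell_id,
        "genotype": record.genotype,
        "rmp_mV": float("nan"),
        "rin_MOhm": float("nan"),
        "rheobase_pA": float("nan"),
        "vthresh_mV": float("nan"),
        "ap_height_mV": float("nan"),
        "ap_fwhm_ms": float("nan"),
        "sag_ratio": float("nan"),
        "mahp_mV": float("nan"),
        "sahp_auc_mVs": float("nan"),
    }
    if record.sweeps.get("rmp"):
        out["rmp_mV"] = resting_membrane_potential(record.sweeps["rmp"][0])
    if record.sweeps.get("steps"):
        proto = record.protocols["steps"]
        out["rin_MOhm"] = input_resistance(record)
        out["sag_ratio"] = cell_sag_ratio(record)
        rb = rheobase(record)
        out["rheobase_pA"] = rb
        if math.isfinite(rb):
            sw = next(
                s for s in record.sweeps["steps"]
                if abs(np.mean(s.command[s.index_at(proto.step_onset_s):
                                         s.index_at(proto.step_offset_s)]) - rb) < 1e-6
            )
            peaks = detect_spikes(sw, (proto.step_onset_s, proto.step_offset_s))
            thr = ap_threshold(sw, peaks[0])
            apf = ap_height_and_width(sw, peaks[0], thr)
            out.update(vthresh_mV=thr, ap_height_mV=apf.height, ap_fwhm_ms=apf.fwhm)
    if record.sweeps.get("ahp"):
        ahp = ahp_measures(record.sweeps["ahp"][0])
        out.update(mahp_mV=ahp.mAHP_mV, sahp_auc_mVs=ahp.sAHP_auc_mVs)
    return out


def feature_table(records: Iterable[CellRecord], qc_reasons: Optional[dict] = None) -> pd.DataFrame:
    """One row per cell: the CSV-exportable feature table."""
    rows = []
    for rec in records:
        row = extract_cell_features(rec)
        flags = (qc_reasons or {}).get(rec.cell_id, [])
        row["qc_flags"] = ";".join(flags)
        rows.append(row)
    return pd.DataFrame(rows)


def fi_table(records: Iterable[CellRecord]) -> pd.DataFrame:
    """Long F–I table: {cell_id, genotype, step_pA, n_spikes}."""
    rows = []
    for rec in records:
        fic = fi_curve(rec)
        for s, c in zip(fic.steps_pA, fic.counts):
            rows.append(
                {"cell_id": rec.cell_id, "genotype": rec.genotype,
                 "step_pA": float(s), "n_spikes": int(c)}
            )
    return pd.DataFrame(rows, columns=["cell_id", "genotype", "step_pA", "n_spikes"])


def rebound_table(records: Iterable[CellRecord]) -> pd.DataFrame:
    """Alias of :func:`rebound_points` over many cells (CSV export shape)."""
    return rebound_points(records)
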