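"""Seed-deterministic simulator of patch-clamp sweeps with exact ground truth.

The generator is phenomenological: every waveform is pieced together from
analytic kernels (exponential charging, raised-cosine bumps, spline-free
spike templates) so that the feature a downstream extractor measures —
steady-state deflection, sag extremum, rebound peak, AP threshold / height /
FWHM, AHP trough and signed area, PSC peak amplitude and timing — equals its
ground-truth parameter *by construction*, not merely in expectation.  This
is deliberate: the package's validation surface is parameter recovery, so
the simulator must make the true value unambiguous.  No conductance-based
(Hodgkin–Huxley) dynamics are modelled.

Protocols emulated (current/voltage values follow the acquisition they mimic):

* a 25 pA current-step family from a −70 mV baseline, −100 to +375 pA, with
  passive charging, Ih-style sag and rebound on hyperpolarizing steps, and
  pasted action potentials on suprathreshold depolarizing steps;
* a 4 × 2 nA / 2 ms burst protocol at −60 mV followed by a medium and a slow
  afterhyperpolarization;
* 300 s voltage-clamp traces at −70 mV with inward bi-exponential synaptic
  events on Gaussian noise;
* 8-bit histology images with an ROI mask and an exact suprathreshold pixel
  fraction.

Default sampling rate is 20 kHz, matching the acquisition emulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .trace_model import (
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
    CellRecord,
    StepProtocol,
    Sweep,
)

__all__ = [
    "PassiveParams",
    "SagParams",
    "SpikeParams",
    "AHPParams",
    "PSCParams",
    "GroupParams",
    "DEFAULT_RATE_HZ",
    "AHP_PULSE_STARTS_S",
    "AHP_LAST_PULSE_OFFSET_S",
    "default_step_protocol",
    "vi_step_protocol",
    "spike_template",
    "simulate_step_family",
    "simulate_rmp_sweep",
    "simulate_ahp_sweep",
    "simulate_psc_trace",
    "simulate_cohort",
    "iter_cohort",
    "simulate_plaque_image",
    "wt_group_params",
    "tg_group_params",
]

DEFAULT_RATE_HZ = 20_000.0

#: Burst-protocol pulse starts (s), 70 ms start-to-start; each pulse is 2 ms.
AHP_PULSE_STARTS_S = (0.010, 0.080, 0.150, 0.220)
AHP_PULSE_WIDTH_S = 0.002
AHP_LAST_PULSE_OFFSET_S = AHP_PULSE_STARTS_S[-1] + AHP_PULSE_WIDTH_S


# ---------------------------------------------------------------------------
# Parameter containers (ground truth)
# ---------------------------------------------------------------------------


@dataclass
class PassiveParams:
    """Passive membrane ground truth: R_in (MΩ), τ_m (ms), resting V (mV)."""

    R_in_MOhm: float = 176.3
    tau_m_ms: float = 22.0
    V_rest_mV: float = -69.3

    def __post_init__(self) -> None:
        if not (self.R_in_MOhm > 0 and self.tau_m_ms > 0):
            raise ValueError("R_in and tau_m must be positive")


@dataclass
class SagParams:
    """Ih-style sag/rebound ground truth.

    ``sag_ratio_true`` is the dimensionless ratio (≥ 1) the sag extractor
    should recover; ``rebound_slope_true``/``rebound_intercept_mV`` define the
    programmed rebound amplitude above baseline as a linear function of the
    absolute steady-state voltage, matching the rebound-regression analysis.
    """

    sag_ratio_true: float = 1.19
    tau_sag_ms: float = 45.0
    rebound_slope_true: float = -0.084
    rebound_intercept_mV: float = -5.3

    def __post_init__(self) -> None:
        if self.sag_ratio_true < 1:
            raise ValueError("sag_ratio_true must be >= 1")
        if self.tau_sag_ms <= 0:
            raise ValueError("tau_sag must be positive")


@dataclass
class SpikeParams:
    """Action-potential template and firing-rate ground truth.

    The F–I relation of a simulated cell is f = fi_gain · (I − I_theta) with
    I_theta the current whose steady state just reaches threshold; spikes are
    pasted templates, so threshold, peak and FWHM are exact by construction.
    ``adaptation_strength`` lengthens the k-th inter-spike interval by a
    factor (1 + adaptation_strength · k).
    """

    V_threshold_true: float = -43.78
    ap_peak: float = 37.2
    ap_fwhm_true: float = 1.99  # ms
    fi_gain: float = 0.15  # Hz/pA
    adaptation_strength: float = 0.1
    reset_depth_mV: float = 8.0

    def __post_init__(self) -> None:
        if not self.ap_peak > self.V_threshold_true:
            raise ValueError("ap_peak must exceed V_threshold_true")
        if not self.ap_fwhm_true > 0:
            raise ValueError("ap_fwhm_true must be positive")


@dataclass
class AHPParams:
    """Afterhyperpolarization ground truth.

    ``mAHP_amp_true`` (mV, ≤ 0) is the exact trough of the medium AHP;
    ``sAHP_auc_true`` (mV·s) is the exact signed area of the slow AHP over
    the 0.5–2.0 s analysis window.  The time constants set the widths of the
    two raised-cosine components (the slow component is normalised so its
    analytic integral equals the target area).
    """

    mAHP_amp_true: float = -3.2
    sAHP_auc_true: float = -0.57
    tau_m_ahp_ms: float = 40.0
    tau_s_ahp_ms: float = 250.0

    def __post_init__(self) -> None:
        if not (self.tau_m_ahp_ms > 0 and self.tau_s_ahp_ms > 0):
            raise ValueError("AHP time constants must be positive")


@dataclass
class PSCParams:
    """Spontaneous postsynaptic current ground truth.

    Events are inward (negative) bi-exponential deflections; ``amp_mean_pA``
    is the deflection magnitude at the event peak.  ``regular=True`` places
    events on a fixed grid at 1/rate_hz spacing; otherwise times are Poisson,
    thinned to a minimum separation of 3·τ_decay when ``well_separated``.
    """

    rate_hz: float = 4.3
    amp_mean_pA: float = 22.7
    amp_sd_pA: float = 6.0
    tau_rise_ms: float = 0.5
    tau_decay_ms: float = 5.0
    noise_sd_pA: float = 2.0
    regular: bool = False
    well_separated: bool = True
    holding_pA: float = 0.0

    def __post_init__(self) -> None:
        if not self.tau_rise_ms < self.tau_decay_ms:
            raise ValueError("tau_rise must be shorter than tau_decay")
        if self.amp_mean_pA <= 0:
            raise ValueError("amp_mean_pA is a deflection magnitude and must be > 0")


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------


def default_step_protocol(
    baseline_mV: float = -70.0,
    step_onset_s: float = 0.2,
    step_offset_s: float = 0.9,
    lo_pA: float = -100.0,
    hi_pA: float = 375.0,
    increment_pA: float = 25.0,
) -> StepProtocol:
    """The full excitability step family: −100 … +375 pA in 25 pA increments."""
    amps = np.arange(lo_pA, hi_pA + increment_pA / 2, increment_pA)
    return StepProtocol(baseline_mV, step_onset_s, step_offset_s, amps)


def vi_step_protocol(**kwargs) -> StepProtocol:
    """The seven-step −100 … +50 pA family used for the V–I (input resistance) fit."""
    return default_step_protocol(hi_pA=50.0, **kwargs)


# ---------------------------------------------------------------------------
# Spike template
# ---------------------------------------------------------------------------


def spike_template(sp: SpikeParams, rate_hz: float = DEFAULT_RATE_HZ) -> Tuple[np.ndarray, int]:
    """Analytic AP template sampled at ``rate_hz``.

    Rise (threshold → peak) and fall (peak → threshold) are half-cosine
    segments with durations t_r + t_f = 2·FWHM, so the width at half of the
    threshold-to-peak height is exactly ``ap_fwhm_true``; a short cosine tail
    then drops to the post-spike reset level.  The template begins exactly at
    threshold with zero initial dV/dt, keeping the subthreshold trajectory's
    slope far below 5% of the template's maximum dV/dt.

    Returns ``(values_mV, peak_index)``.
    """
    dt = 1.0 / rate_hz
    fwhm_s = sp.ap_fwhm_true * 1e-3
    t_r = min(0.6e-3, fwhm_s)
    t_f = 2.0 * fwhm_s - t_r
    t_tail = 1.0e-3
    theta, peak = sp.V_threshold_true, sp.ap_peak
    height = peak - theta
    n = int(round((t_r + t_f + t_tail) / dt)) + 1
    t = np.arange(n) * dt
    v = np.empty(n)
    m_rise = t <= t_r
    v[m_rise] = theta + height * 0.5 * (1.0 - np.cos(np.pi * t[m_rise] / t_r))
    m_fall = (t > t_r) & (t <= t_r + t_f)
    v[m_fall] = theta + height * 0.5 * (1.0 + np.cos(np.pi * (t[m_fall] - t_r) / t_f))
    m_tail = t > t_r + t_f
    v[m_tail] = theta - sp.reset_depth_mV * 0.5 * (
        1.0 - np.cos(np.pi * (t[m_tail] - t_r - t_f) / t_tail)
    )
    return v, int(round(t_r / dt))


# ---------------------------------------------------------------------------
# Current-clamp step family
# ---------------------------------------------------------------------------


def _charge_exact(a: float, b: float, tau: float, t_local: np.ndarray, T: float) -> np.ndarray:
    """Exponential charge from value ``a`` to *exactly* ``b`` over duration ``T``."""
    return a + (b - a) * (1.0 - np.exp(-t_local / tau)) / (1.0 - math.exp(-T / tau))


def _step_sweep(
    I_pA: float,
    passive: PassiveParams,
    sag: Optional[SagParams],
    spikes: Optional[SpikeParams],
    protocol: StepProtocol,
    rate_hz: float,
    duration_s: float,
    rng: np.random.Generator,
    noise_sd: float,
    rebound_noise_sd: float,
    label: str,
) -> Tuple[Sweep, dict]:
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    i_on = int(round(protocol.step_onset_s * rate_hz))
    i_off = int(round(protocol.step_offset_s * rate_hz))
    Vh = protocol.baseline_mV
    tau = passive.tau_m_ms * 1e-3
    dv = I_pA * passive.R_in_MOhm * 1e-3  # pA × MΩ → μV×1e3 = mV per 1e3; net: mV

    v = np.full(n, Vh)
    cmd = np.zeros(n)
    cmd[i_on:i_off] = I_pA
    tl = t[i_on:i_off] - t[i_on]
    info: dict = {"I_pA": I_pA, "spike_times_s": []}

    theta = spikes.V_threshold_true if spikes is not None else None

    if I_pA < 0 and sag is not None:
        s = sag.sag_ratio_true
        t_rise = 0.06  # s; sag extremum is placed here, inside the 200 ms search window
        tau_sag = sag.tau_sag_ms * 1e-3
        seg = np.empty_like(tl)
        m1 = tl <= t_rise
        seg[m1] = _charge_exact(Vh, Vh + s * dv, tau, tl[m1], t_rise)
        seg[~m1] = Vh + dv + (s - 1.0) * dv * np.exp(-(tl[~m1] - t_rise) / tau_sag)
        v[i_on:i_off] = seg
        v_end = seg[-1]

        reb = sag.rebound_intercept_mV + sag.rebound_slope_true * (Vh + dv)
        if rebound_noise_sd > 0:
            reb += rng.normal(0.0, rebound_noise_sd)
        info["rebound_target_mV"] = float(reb)
        tp = t[i_off:] - t[i_off]
        if reb > 0:
            t_rb, tau_rel = 0.05, 0.04
            post = np.empty_like(tp)
            m1 = tp <= t_rb
            post[m1] = _charge_exact(v_end, Vh + reb, tau, tp[m1], t_rb)
            post[~m1] = Vh + reb * np.exp(-(tp[~m1] - t_rb) / tau_rel)
            v[i_off:] = post
        else:
            v[i_off:] = Vh + (v_end - Vh) * np.exp(-tp / tau)
    else:
        Vinf = Vh + dv
        if spikes is not None and Vinf > theta:
            tmpl, pk = spike_template(spikes, rate_hz)
            frac = (theta - Vh) / dv
            t_first = -tau * math.log1p(-frac)
            I_theta = (theta - Vh) / passive.R_in_MOhm * 1e3  # pA
            f = spikes.fi_gain * (I_pA - I_theta)
            step_dur = protocol.step_duration_s
            times = [t_first]
            k = 1
            while True:
                nxt = times[-1] + (1.0 / f) * (1.0 + spikes.adaptation_strength * k)
                if nxt + len(tmpl) / rate_hz >= step_dur:
                    break
                times.append(nxt)
                k += 1
            out = np.empty_like(tl)
            j0, a = 0, Vh
            n_step = len(tl)
            for st in times:
                i_s = int(round(st * rate_hz))
                if i_s + len(tmpl) > n_step:
                    break
                if i_s > j0:
                    tt = (np.arange(j0, i_s) - j0) / rate_hz
                    out[j0:i_s] = np.minimum(Vinf + (a - Vinf) * np.exp(-tt / tau), theta)
                out[i_s : i_s + len(tmpl)] = tmpl
                info["spike_times_s"].append(float(t[i_on] + (i_s + pk) / rate_hz))
                j0 = i_s + len(tmpl)
                a = tmpl[-1]
            if j0 < n_step:
                tt = (np.arange(j0, n_step) - j0) / rate_hz
                out[j0:] = np.minimum(Vinf + (a - Vinf) * np.exp(-tt / tau), theta)
            v[i_on:i_off] = out
            v_end = out[-1]
        else:
            seg = Vh + dv * (1.0 - np.exp(-tl / tau))
            v[i_on:i_off] = seg
            v_end = seg[-1] if len(seg) else Vh
        v[i_off:] = Vh + (v_end - Vh) * np.exp(-(t[i_off:] - t[i_off]) / tau)

    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, n)
    sweep = Sweep(t, v, cmd, rate_hz, CURRENT_CLAMP, label=label)
    return sweep, info


def simulate_step_family(
    passive: PassiveParams,
    sag: Optional[SagParams] = None,
    spikes: Optional[SpikeParams] = None,
    protocol: Optional[StepProtocol] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    rate_hz: float = DEFAULT_RATE_HZ,
    duration_s: Optional[float] = None,
    rebound_noise_sd: float = 0.0,
    cell_id: str = "cell0",
    genotype: str = "WT",
    animal_id: str = "",
) -> CellRecord:
    """Simulate one cell's current-step family as a :class:`CellRecord`.

    Per step I: the steady deflection is I·R_in; hyperpolarizing steps get a
    sag whose extremum is exactly ``sag_ratio_true`` × the steady deflection
    and a post-offset rebound of exactly ``intercept + slope·V_SS`` mV above
    baseline; suprathreshold depolarizing steps get pasted AP templates whose
    first spike occurs where the passive trajectory crosses threshold.
    Ground truth (including per-step spike times) is stored on the record.
    """
    protocol = protocol or default_step_protocol()
    if len(protocol.amplitudes_pA) >= 2:
        inc = np.diff(protocol.amplitudes_pA)
        if np.ptp(inc) > 1e-9:
            raise ValueError("protocol amplitudes must lie on a uniform grid")
    duration_s = duration_s or protocol.step_offset_s + 0.5
    rng = np.random.default_rng(seed)
    sweeps: List[Sweep] = []
    step_info = []
    for I in protocol.amplitudes_pA:
        sw, info = _step_sweep(
            I, passive, sag, spikes, protocol, rate_hz, duration_s, rng, noise_sd,
            rebound_noise_sd, label=f"{cell_id}:step:{I:+.0f}pA",
        )
        sweeps.append(sw)
        step_info.append(info)

    gt: dict = {
        "R_in_MOhm": passive.R_in_MOhm,
        "V_rest_mV": passive.V_rest_mV,
        "tau_m_ms": passive.tau_m_ms,
        "steps": step_info,
    }
    if sag is not None:
        gt.update(
            sag_ratio=sag.sag_ratio_true,
            rebound_slope=sag.rebound_slope_true,
            rebound_intercept_mV=sag.rebound_intercept_mV,
        )
    if spikes is not None:
        I_theta = (spikes.V_threshold_true - protocol.baseline_mV) / passive.R_in_MOhm * 1e3
        grid = protocol.amplitudes_pA
        above = grid[grid > I_theta]
        gt.update(
            V_threshold_mV=spikes.V_threshold_true,
            ap_height_mV=spikes.ap_peak - spikes.V_threshold_true,
            ap_fwhm_ms=spikes.ap_fwhm_true,
            rheobase_pA=float(above[0]) if len(above) else None,
        )
    return CellRecord(
        cell_id=cell_id,
        animal_id=animal_id,
        genotype=genotype,
        sweeps={"steps": sweeps},
        protocols={"steps": protocol},
        ground_truth=gt,
    )


def simulate_rmp_sweep(
    passive: PassiveParams,
    duration_s: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    rate_hz: float = DEFAULT_RATE_HZ,
    label: str = "rmp",
) -> Sweep:
    """Zero-holding-current sweep sitting at the resting potential."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    v = np.full(n, passive.V_rest_mV)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, n)
    return Sweep(t, v, np.zeros(n), rate_hz, CURRENT_CLAMP, label=label)


# ---------------------------------------------------------------------------
# AHP burst protocol
# ---------------------------------------------------------------------------


def _raised_cosine(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Smooth bump on [t0, t1]: 0 at both ends, exactly 1 at the midpoint."""
    out = np.zeros_like(t)
    m = (t >= t0) & (t <= t1)
    out[m] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[m] - t0) / (t1 - t0)))
    return out


def simulate_ahp_sweep(
    ahp: AHPParams,
    seed: int = 0,
    noise_sd: float = 0.0,
    rate_hz: float = DEFAULT_RATE_HZ,
    v_hold_mV: float = -60.0,
    label: str = "ahp",
) -> Sweep:
    """2 s sweep at −60 mV: four 2 nA / 2 ms pulses then an m/sAHP waveform.

    The medium-AHP component is a raised-cosine trough centred at 0.35 s whose
    minimum equals ``mAHP_amp_true`` exactly (the centre falls on a sample);
    the slow component is a raised cosine supported inside [0.5, 2.0] s scaled
    so its analytic integral equals ``sAHP_auc_true`` exactly.
    """
    rng = np.random.default_rng(seed)
    n = int(round(2.0 * rate_hz)) + 1  # include t = 2.0 s
    t = np.arange(n) / rate_hz
    v = np.full(n, v_hold_mV)
    cmd = np.zeros(n)

    # Pulse artifacts: a generic pasted AP per pulse (shape is irrelevant to
    # the AHP measures; it just has to stay out of the analysis windows).
    artifact_sp = SpikeParams(
        V_threshold_true=v_hold_mV + 20.0, ap_peak=35.0, ap_fwhm_true=1.0,
        reset_depth_mV=2.0,
    )
    tmpl, _pk = spike_template(artifact_sp, rate_hz)
    for start in AHP_PULSE_STARTS_S:
        i0 = int(round(start * rate_hz))
        i1 = min(n, i0 + int(round(AHP_PULSE_WIDTH_S * rate_hz)))
        cmd[i0:i1] = 2000.0  # 2 nA in pA
        j1 = min(n, i0 + len(tmpl))
        v[i0:j1] = tmpl[: j1 - i0]

    # Medium AHP: trough inside the (last pulse offset + 10 ms, 500 ms) window.
    c = 0.35
    half = min(0.11, 3.0 * ahp.tau_m_ahp_ms * 1e-3)
    v += ahp.mAHP_amp_true * _raised_cosine(t, c - half, c + half)

    # Slow AHP: supported in [0.5, 0.5 + w]; integral of the bump is w/2.
    w = min(1.5, 6.0 * ahp.tau_s_ahp_ms * 1e-3)
    v += (ahp.sAHP_auc_true / (w / 2.0)) * _raised_cosine(t, 0.5, 0.5 + w)

    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, n)
    return Sweep(t, v, cmd, rate_hz, CURRENT_CLAMP, label=label)


# ---------------------------------------------------------------------------
# Voltage-clamp PSC traces
# ---------------------------------------------------------------------------


def _psc_kernel(tau_r_s: float, tau_d_s: float, rate_hz: float) -> Tuple[np.ndarray, float]:
    """Unit-peak bi-exponential kernel and its time-to-peak (s)."""
    t_peak = tau_r_s * tau_d_s / (tau_d_s - tau_r_s) * math.log(tau_d_s / tau_r_s)
    span = 8.0 * tau_d_s
    tk = np.arange(int(round(span * rate_hz))) / rate_hz
    k = np.exp(-tk / tau_d_s) - np.exp(-tk / tau_r_s)
    k /= math.exp(-t_peak / tau_d_s) - math.exp(-t_peak / tau_r_s)
    return k, t_peak


def simulate_psc_trace(
    psc: PSCParams,
    duration_s: float = 300.0,
    seed: int = 0,
    rate_hz: float = DEFAULT_RATE_HZ,
    label: str = "psc",
) -> Tuple[Sweep, pd.DataFrame]:
    """Voltage-clamp trace at −70 mV with inward PSC events.

    Returns the sweep together with the ground-truth event table
    (columns ``t_onset_s``, ``t_peak_s``, ``amp_pA``).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    tau_r = psc.tau_rise_ms * 1e-3
    tau_d = psc.tau_decay_ms * 1e-3
    kernel, t_peak = _psc_kernel(tau_r, tau_d, rate_hz)

    pad = 8.0 * tau_d
    if psc.rate_hz <= 0:
        starts = np.empty(0)
    elif psc.regular:
        starts = np.arange(0.5, duration_s - pad, 1.0 / psc.rate_hz)
    else:
        gaps = rng.exponential(1.0 / psc.rate_hz, size=int(psc.rate_hz * duration_s * 2) + 20)
        starts = 0.5 + np.cumsum(gaps)
        starts = starts[starts < duration_s - pad]
        if psc.well_separated and len(starts):
            min_sep = 3.0 * tau_d
            keep = [0]
            for i in range(1, len(starts)):
                if starts[i] - starts[keep[-1]] >= min_sep:
                    keep.append(i)
            starts = starts[keep]

    amps = np.maximum(rng.normal(psc.amp_mean_pA, psc.amp_sd_pA, len(starts)), 0.1)
    x = np.full(n, psc.holding_pA)
    if psc.noise_sd_pA > 0:
        x += rng.normal(0.0, psc.noise_sd_pA, n)
    for s, a in zip(starts, amps):
        i0 = int(round(s * rate_hz))
        L = min(len(kernel), n - i0)
        x[i0 : i0 + L] -= a * kernel[:L]

    truth = pd.DataFrame(
        {"t_onset_s": starts, "t_peak_s": starts + t_peak, "amp_pA": amps}
    )
    sweep = Sweep(t, x, np.full(n, -70.0), rate_hz, VOLTAGE_CLAMP, label=label)
    return sweep, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class GroupParams:
    """Per-genotype distributions from which cell parameters are drawn.

    Means default to the wild-type group means of the study emulated;
    between-cell SDs are reconstructed from the printed SEMs (SEM·√n with
    n ≈ 35 cells/group for current-clamp features, 32 for PSC features).
    """

    rin_mean_MOhm: float = 176.3
    rin_sd_MOhm: float = 54.0
    rmp_mean_mV: float = -69.3
    rmp_sd_mV: float = 7.1
    tau_m_ms: float = 22.0
    sag_mean: float = 1.19
    sag_sd: float = 0.12
    rebound_slope: float = -0.084
    rebound_intercept_mV: float = -5.3
    rebound_noise_sd_mV: float = 0.5
    vthresh_mean_mV: float = -43.78
    vthresh_sd_mV: float = 5.2
    ap_height_mean_mV: float = 80.99
    ap_height_sd_mV: float = 12.2
    ap_fwhm_mean_ms: float = 1.99
    ap_fwhm_sd_ms: float = 0.52
    fi_gain_hz_per_pA: float = 0.15
    adaptation_strength: float = 0.1
    mahp_mean_mV: float = -3.2
    mahp_sd_mV: float = 2.25
    sahp_mean_mVs: float = -0.57
    sahp_sd_mVs: float = 1.6
    psc_amp_mean_pA: float = 22.7
    psc_amp_sd_between_pA: float = 8.5
    psc_amp_sd_within_pA: float = 6.0
    psc_rate_mean_hz: float = 4.3
    psc_rate_sd_hz: float = 3.6
    leak_sd_pA: float = 30.0


def wt_group_params() -> GroupParams:
    """Wild-type group distribution (the defaults)."""
    return GroupParams()


def tg_group_params() -> GroupParams:
    """Transgenic (APP/PS1) group distribution: reported Tg means, SEM·√n SDs."""
    return GroupParams(
        rin_mean_MOhm=148.6, rin_sd_MOhm=53.0,
        rmp_mean_mV=-69.8, rmp_sd_mV=9.3,
        sag_mean=1.26, sag_sd=0.17,
        rebound_slope=-0.14, rebound_intercept_mV=-9.3,
        vthresh_mean_mV=-43.27, vthresh_sd_mV=6.8,
        ap_height_mean_mV=79.2, ap_height_sd_mV=13.2,
        ap_fwhm_mean_ms=2.07, ap_fwhm_sd_ms=0.49,
        mahp_mean_mV=-2.95, mahp_sd_mV=2.3,
        sahp_mean_mVs=-0.71, sahp_sd_mVs=2.3,
        psc_amp_mean_pA=21.1, psc_amp_sd_between_pA=6.2,
        psc_rate_mean_hz=3.8, psc_rate_sd_hz=2.4,
    )


def _draw_cell_params(gp: GroupParams, rng: np.random.Generator):
    """One cell's ground-truth parameters; hard floors keep draws physical."""
    passive = PassiveParams(
        R_in_MOhm=max(30.0, rng.normal(gp.rin_mean_MOhm, gp.rin_sd_MOhm)),
        tau_m_ms=gp.tau_m_ms,
        V_rest_mV=rng.normal(gp.rmp_mean_mV, gp.rmp_sd_mV),
    )
    sag = SagParams(
        sag_ratio_true=max(1.0, rng.normal(gp.sag_mean, gp.sag_sd)),
        rebound_slope_true=gp.rebound_slope,
        rebound_intercept_mV=gp.rebound_intercept_mV,
    )
    vth = min(-20.0, rng.normal(gp.vthresh_mean_mV, gp.vthresh_sd_mV))
    spikes = SpikeParams(
        V_threshold_true=vth,
        ap_peak=vth + max(40.0, rng.normal(gp.ap_height_mean_mV, gp.ap_height_sd_mV)),
        ap_fwhm_true=max(0.5, rng.normal(gp.ap_fwhm_mean_ms, gp.ap_fwhm_sd_ms)),
        fi_gain=gp.fi_gain_hz_per_pA,
        adaptation_strength=gp.adaptation_strength,
    )
    ahp = AHPParams(
        mAHP_amp_true=min(0.0, rng.normal(gp.mahp_mean_mV, gp.mahp_sd_mV)),
        sAHP_auc_true=rng.normal(gp.sahp_mean_mVs, gp.sahp_sd_mVs),
    )
    psc = PSCParams(
        rate_hz=max(0.2, rng.normal(gp.psc_rate_mean_hz, gp.psc_rate_sd_hz)),
        amp_mean_pA=max(12.0, rng.normal(gp.psc_amp_mean_pA, gp.psc_amp_sd_between_pA)),
        amp_sd_pA=gp.psc_amp_sd_within_pA,
    )
    return passive, sag, spikes, ahp, psc


def simulate_cohort(
    genotype_param_sets: Optional[Dict[str, GroupParams]] = None,
    n_cells_per_group: int = 35,
    seed: int = 0,
    rate_hz: float = DEFAULT_RATE_HZ,
    protocol: Optional[StepProtocol] = None,
    noise_sd_mV: float = 0.2,
    include_psc: bool = True,
    psc_duration_s: float = 300.0,
) -> List[CellRecord]:
    """Simulate a two-group cohort with per-cell ground truth stored on each record.

    Each cell gets an ``rmp`` sweep (no holding current), the full ``steps``
    family, an ``ahp`` burst sweep and (optionally) a ``psc`` voltage-clamp
    trace.  QC fields are drawn from distributions under which nearly all
    cells pass the inclusion gate.  Identical seeds give bit-identical cohorts.

    A full cell is tens of MB of sweeps; for large cohorts prefer
    :func:`iter_cohort`, which yields cells one at a time so a streaming
    consumer never holds the whole cohort in memory.
    """
    return list(
        iter_cohort(
            genotype_param_sets, n_cells_per_group, seed, rate_hz, protocol,
            noise_sd_mV, include_psc, psc_duration_s,
        )
    )


def iter_cohort(
    genotype_param_sets: Optional[Dict[str, GroupParams]] = None,
    n_cells_per_group: int = 35,
    seed: int = 0,
    rate_hz: float = DEFAULT_RATE_HZ,
    protocol: Optional[StepProtocol] = None,
    noise_sd_mV: float = 0.2,
    include_psc: bool = True,
    psc_duration_s: float = 300.0,
):
    """Generator form of :func:`simulate_cohort` (same seeds, same cells)."""
    if genotype_param_sets is None:
        genotype_param_sets = {"WT": wt_group_params(), "Tg": tg_group_params()}
    protocol = protocol or default_step_protocol()
    ss = np.random.SeedSequence(seed)
    for genotype in genotype_param_sets:
        gp = genotype_param_sets[genotype]
        children = ss.spawn(n_cells_per_group)
        for j in range(n_cells_per_group):
            crng = np.random.default_rng(children[j])
            passive, sag, spikes, ahp, psc = _draw_cell_params(gp, crng)
            sub = crng.integers(0, 2**31 - 1, size=4)
            cell_id = f"{genotype}_{j:03d}"
            rec = simulate_step_family(
                passive, sag, spikes, protocol,
                noise_sd=noise_sd_mV, seed=int(sub[0]), rate_hz=rate_hz,
                rebound_noise_sd=gp.rebound_noise_sd_mV,
                cell_id=cell_id, genotype=genotype,
                animal_id=f"{genotype}_animal_{j // 3:02d}",
            )
            rec.sweeps["rmp"] = [
                simulate_rmp_sweep(passive, 0.5, noise_sd_mV, int(sub[1]), rate_hz,
                                   label=f"{cell_id}:rmp")
            ]
            rec.sweeps["ahp"] = [
                simulate_ahp_sweep(ahp, int(sub[2]), noise_sd_mV, rate_hz,
                                   label=f"{cell_id}:ahp")
            ]
            rec.ground_truth.update(
                mAHP_mV=ahp.mAHP_amp_true, sAHP_auc_mVs=ahp.sAHP_auc_true,
            )
            if include_psc:
                sw, truth = simulate_psc_trace(
                    psc, psc_duration_s, int(sub[3]), rate_hz, label=f"{cell_id}:psc"
                )
                rec.sweeps["psc"] = [sw]
                rec.ground_truth.update(
                    psc_rate_hz=psc.rate_hz,
                    psc_amp_mean_pA=psc.amp_mean_pA,
                    psc_n_events=int(len(truth)),
                )
            rec.leak_pA = float(crng.normal(0.0, gp.leak_sd_pA))
            rec.ra_MOhm_start = float(crng.uniform(8.0, 22.0))
            rec.ra_MOhm_end = float(rec.ra_MOhm_start * crng.normal(1.0, 0.05))
            yield rec


# ---------------------------------------------------------------------------
# Histology images
# ---------------------------------------------------------------------------


def simulate_plaque_image(
    area_fraction: float,
    mask_shape: Tuple[int, int] = (1000, 1000),
    seed: int = 0,
    threshold: int = 100,
    margin: int = 20,
) -> Tuple[np.ndarray, np.ndarray]:
    """8-bit image + ROI mask with an *exact* suprathreshold pixel fraction.

    The ROI is a ``mask_shape`` rectangle inset by ``margin`` background
    pixels; exactly ``round(area_fraction · ROI pixels)`` ROI pixels are set
    strictly above ``threshold`` (pixel-count construction), the rest at or
    below it.  Bright pixels are also scattered *outside* the mask so that
    mask handling is exercised.
    """
    if not 0.0 <= area_fraction <= 1.0:
        raise ValueError("area_fraction must be in [0, 1]")
    h, w = mask_shape
    rng = np.random.default_rng(seed)
    H, W = h + 2 * margin, w + 2 * margin
    img = rng.integers(0, min(61, threshold + 1), size=(H, W)).astype(np.uint8)
    mask = np.zeros((H, W), dtype=bool)
    mask[margin : margin + h, margin : margin + w] = True

    n_roi = h * w
    n_sup = int(round(area_fraction * n_roi))
    if n_sup:
        flat = rng.choice(n_roi, size=n_sup, replace=False)
        rows = margin + flat // w
        cols = margin + flat % w
        img[rows, cols] = rng.integers(threshold + 1, 256, size=n_sup).astype(np.uint8)
    # bright clutter outside the ROI (must not affect the measured fraction)
    if margin > 0:
        n_out = max(1, (H * W - n_roi) // 100)
        out_idx = np.flatnonzero(~mask)
        pick = rng.choice(out_idx, size=min(n_out, len(out_idx)), replace=False)
        img.flat[pick] = 255
    return img, mask
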