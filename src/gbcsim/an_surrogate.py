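"""Acoustic stimulus synthesis and a surrogate auditory-nerve generator.

The surrogate replaces a full cochlear transduction model with a
phenomenological inhomogeneous point process: the stimulus envelope is
mapped through an expansive saturating nonlinearity to an instantaneous
firing rate with a spontaneous floor and an onset-adaptation term, and
spikes are drawn by Poisson thinning with an absolute dead time.  Fibres
lock to the stimulus *envelope* only (the 16 kHz default carrier is above
the phase-locking range), and the driven rate is calibrated
deterministically so that the steady-state effective rate matches a target
(200 Hz by default) at the reference level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "P_REF_PA",
    "StimulusSpec",
    "Stimulus",
    "ANParams",
    "make_stimulus",
    "an_spike_trains",
    "dead_time_rate",
]

P_REF_PA = 2e-5  # reference pressure for dB SPL


@dataclass
class StimulusSpec:
    """Parametric description of a tone, SAM tone, or click train."""

    kind: str = "tone"  # tone | SAM | click_train
    carrier_hz: float = 16000.0
    f_mod_hz: float = 100.0
    mod_depth: float = 1.0
    level_db_spl: float = 30.0
    duration_ms: float = 1000.0
    rise_fall_ms: float = 2.5
    delay_ms: float = 0.0
    sample_rate_hz: float = 100000.0
    click_width_us: float = 100.0
    click_rate_hz: float = 50.0

    def __post_init__(self) -> None:
        if self.kind not in ("tone", "SAM", "click_train"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "SAM" and not self.f_mod_hz < self.carrier_hz:
            raise ValueError("modulation frequency must be below the carrier")
        if self.duration_ms < 2 * self.rise_fall_ms:
            raise ValueError("duration must cover the rise and fall ramps")
        if not 0.0 <= self.mod_depth <= 1.0:
            raise ValueError("mod_depth must be in [0, 1]")


@dataclass
class Stimulus:
    """Synthesized pressure waveform and its analytic envelope (Pa)."""

    spec: StimulusSpec
    t_s: np.ndarray
    waveform_pa: np.ndarray
    envelope_pa: np.ndarray


def _ramp(t_s: np.ndarray, spec: StimulusSpec) -> np.ndarray:
    """Cosine-squared rise/fall envelope gate in [0, 1]."""
    rf = spec.rise_fall_ms * 1e-3
    t0 = spec.delay_ms * 1e-3
    dur = spec.duration_ms * 1e-3
    gate = np.zeros_like(t_s)
    inside = (t_s >= t0) & (t_s <= t0 + dur)
    tt = t_s[inside] - t0
    g = np.ones_like(tt)
    rising = tt < rf
    g[rising] = np.sin(0.5 * math.pi * tt[rising] / rf) ** 2
    falling = tt > dur - rf
    g[falling] = np.sin(0.5 * math.pi * (dur - tt[falling]) / rf) ** 2
    gate[inside] = g
    return gate


def make_stimulus(spec: StimulusSpec, total_ms: float | None = None) -> Stimulus:
    """Synthesize the waveform; steady-portion RMS = 20 uPa * 10^(level/20)."""
    fs = spec.sample_rate_hz
    total = (total_ms if total_ms is not None else spec.delay_ms + spec.duration_ms) * 1e-3
    n = int(round(total * fs)) + 1
    t = np.arange(n) / fs
    target_rms = P_REF_PA * 10.0 ** (spec.level_db_spl / 20.0)
    gate = _ramp(t, spec)
    if spec.kind in ("tone", "SAM"):
        carrier = np.sin(2 * math.pi * spec.carrier_hz * t)
        if spec.kind == "SAM":
            mod = 1.0 + spec.mod_depth * np.sin(2 * math.pi * spec.f_mod_hz * t)
            # steady RMS of (1 + d sin) * sin(c) is sqrt((1 + d^2/2)/2)
            amp = target_rms * math.sqrt(2.0) / math.sqrt(1.0 + spec.mod_depth**2 / 2.0)
        else:
            mod = np.ones_like(t)
            amp = target_rms * math.sqrt(2.0)
        wave = amp * gate * mod * carrier
        env = amp * gate * mod
    else:  # click train
        width = int(max(1, round(spec.click_width_us * 1e-6 * fs)))
        wave = np.zeros_like(t)
        t0 = spec.delay_ms * 1e-3
        t1 = t0 + spec.duration_ms * 1e-3
        peak = target_rms * math.sqrt(2.0)
        click_times = np.arange(t0, t1 - spec.click_width_us * 1e-6, 1.0 / spec.click_rate_hz)
        for ct in click_times:
            i0 = int(round(ct * fs))
            wave[i0: i0 + width] = peak
        env = wave.copy()
    return Stimulus(spec=spec, t_s=t, waveform_pa=wave, envelope_pa=np.abs(env))


@dataclass
class ANParams:
    """Surrogate auditory-nerve fibre parameters (high-spontaneous class)."""

    spont_rate_hz: float = 100.0
    target_driven_rate_hz: float = 200.0
    dead_time_ms: float = 0.7
    envelope_gain: float = 3.0  # expansive exponent; larger = sharper locking
    reference_level_db: float = 30.0
    adaptation_strength: float = 1.0  # onset rate = (1 + a) * steady rate
    adaptation_tau_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.spont_rate_hz < 0 or self.target_driven_rate_hz < 0:
            raise ValueError("rates must be non-negative")
        if self.dead_time_ms <= 0:
            raise ValueError("dead time must be positive")


def dead_time_rate(rate_hz: float, dead_time_s: float) -> float:
    """Effective rate of a Poisson process thinned by an absolute dead time."""
    return rate_hz / (1.0 + rate_hz * dead_time_s)


def _rate_profile(stim: Stimulus, params: ANParams, gain: float) -> np.ndarray:
    """Instantaneous driving rate lambda(t), Hz, before dead-time thinning.

    For tonal stimuli the fibre follows the envelope-driven rate alone
    while the stimulus gate is open (the driven synapse absorbs the
    spontaneous drive, which is what lets real fibres fall silent in SAM
    troughs and lock tightly); outside the gate, and for click trains at
    all times, the spontaneous rate floor applies additively.
    """
    spec = stim.spec
    ref_env = P_REF_PA * 10.0 ** (params.reference_level_db / 20.0) * math.sqrt(2.0)
    x = stim.envelope_pa / ref_env
    drive = gain * x**params.envelope_gain
    if params.adaptation_strength > 0:
        t0 = spec.delay_ms * 1e-3
        tau = params.adaptation_tau_ms * 1e-3
        adapt = 1.0 + params.adaptation_strength * np.exp(
            -np.maximum(stim.t_s - t0, 0.0) / tau
        )
        drive = drive * np.where(stim.t_s >= t0, adapt, 1.0)
    if spec.kind == "click_train":
        return params.spont_rate_hz + drive
    t0 = spec.delay_ms * 1e-3
    t1 = t0 + spec.duration_ms * 1e-3
    gate_open = (stim.t_s >= t0) & (stim.t_s <= t1) & (x > 1e-6)
    return np.where(gate_open, drive, params.spont_rate_hz + drive)


def _steady_window(spec: StimulusSpec) -> tuple[float, float]:
    t0 = spec.delay_ms * 1e-3
    return (t0 + 10 * spec.rise_fall_ms * 1e-3 + 0.05,
            t0 + spec.duration_ms * 1e-3 - spec.rise_fall_ms * 1e-3)


def calibrate_gain(stim: Stimulus, params: ANParams) -> float:
    """Gain such that the steady-state effective rate hits the target.

    Deterministic: solves mean_t[lambda(t)/(1 + lambda(t)*dead)] = target
    over the steady portion of the stimulus by bisection.
    """
    a, b = _steady_window(stim.spec)
    sel = (stim.t_s >= a) & (stim.t_s <= b)
    if not sel.any():
        sel = stim.envelope_pa > 0
    dead = params.dead_time_ms * 1e-3
    target = params.target_driven_rate_hz

    def eff(gain: float) -> float:
        lam = _rate_profile(stim, params, gain)[sel]
        return float(np.mean(lam / (1.0 + lam * dead)))

    lo, hi = 0.0, 10.0
    while eff(hi) < target and hi < 1e9:
        hi *= 4.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if eff(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def an_spike_trains(
    spec: StimulusSpec | Stimulus,
    params: ANParams | None = None,
    n_fibers: int = 1,
    n_trials: int = 1,
    seed: int = 0,
) -> list[list[np.ndarray]]:
    """Surrogate ANF spike trains: trains[trial][fiber] = times in seconds.

    Spikes follow an inhomogeneous Poisson process with intensity from the
    calibrated envelope-rate map, thinned by an absolute dead time.
    Fibres and trials are independent; identical seeds give identical
    collections.
    """
    params = params or ANParams()
    stim = spec if isinstance(spec, Stimulus) else make_stimulus(spec)
    if stim.envelope_pa.max() > 0:
        gain = calibrate_gain(stim, params)
    else:
        gain = 0.0
    lam = _rate_profile(stim, params, gain)
    lam_max = float(lam.max())
    duration = float(stim.t_s[-1])
    dead = params.dead_time_ms * 1e-3
    rng = np.random.default_rng(seed)
    out: list[list[np.ndarray]] = []
    for _trial in range(n_trials):
        trial_trains: list[np.ndarray] = []
        for _fiber in range(n_fibers):
            n_cand = rng.poisson(lam_max * duration)
            cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
            keep = rng.random(n_cand) < np.interp(cand, stim.t_s, lam) / lam_max
            cand = cand[keep]
            # absolute dead time, enforced sequentially
            times = []
            last = -np.inf
            for c in cand:
                if c - last >= dead:
                    times.append(c)
                    last = c
            trial_trains.append(np.array(times))
        out.append(trial_trains)
    return out
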