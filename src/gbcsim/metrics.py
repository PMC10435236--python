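"""Spike detection and temporal-coding statistics for spike trains.

All metrics are pure functions of event times plus explicit metadata.
Spike times are in seconds throughout this module; trains are lists of
sorted per-trial time arrays.

The suite covers: waveform spike detection (height + slope + width
criteria), vector strength with grouped SD, rate modulation transfer
functions, entrainment to the modulation period, shuffled autocorrelograms
with the Poisson-normalized correlation index, pre/post cross-correlograms,
per-input efficacy and participation, logistic efficacy-vs-ASA fits, and
first/second spike latency and ISI regularity summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SpikeDetectParams",
    "VSResult",
    "SACResult",
    "EfficacyResult",
    "LogisticFit",
    "FitError",
    "detect_spikes",
    "vector_strength",
    "rmtf",
    "entrainment",
    "sac",
    "cross_correlogram",
    "efficacy",
    "participation",
    "efficacy_participation",
    "fit_logistic",
    "fsl_ssl",
    "isi_cv",
]

Trains = Sequence[np.ndarray]


class FitError(RuntimeError):
    """A requested fit could not be performed on the given data."""


# -----------------------------------------------------------------------------
# Spike detection
# -----------------------------------------------------------------------------

@dataclass
class SpikeDetectParams:
    """Criteria separating action potentials from large EPSPs.

    Bushy-cell somatic spikes are small and variable, so a peak is only
    accepted when it is high enough, rises and falls steeply enough, and
    is narrow at half height.  Defaults are recorded in every result.
    """

    min_peak_mV: float = -20.0
    min_rise_slope_mV_ms: float = 20.0
    min_fall_slope_mV_ms: float = 10.0
    max_halfwidth_ms: float = 1.0
    refractory_ms: float = 0.7


def detect_spikes(
    t_ms: np.ndarray,
    v_mV: np.ndarray,
    params: SpikeDetectParams | None = None,
) -> np.ndarray:
    """Detect action potentials in a somatic voltage trace.

    Returns spike peak times in **seconds**, with sub-sample parabolic
    interpolation of the peak.  An empty result is valid.
    """
    p = params or SpikeDetectParams()
    t = np.asarray(t_ms, dtype=float)
    v = np.asarray(v_mV, dtype=float)
    if len(v) < 3:
        return np.empty(0)
    dt = t[1] - t[0]
    dvdt = np.gradient(v, dt)
    peaks = np.flatnonzero((v[1:-1] >= v[:-2]) & (v[1:-1] > v[2:])) + 1
    out: list[float] = []
    last = -np.inf
    for i in peaks:
        if v[i] < p.min_peak_mV:
            continue
        # look back/forward a couple of ms for slope extrema
        w = max(2, int(round(2.0 / dt)))
        lo = max(0, i - w)
        hi = min(len(v), i + w)
        if dvdt[lo:i + 1].max(initial=-np.inf) < p.min_rise_slope_mV_ms:
            continue
        if -dvdt[i:hi].min(initial=np.inf) < p.min_fall_slope_mV_ms:
            continue
        # half-width: width at half height above the local baseline
        base = v[lo:hi].min()
        half = base + 0.5 * (v[i] - base)
        j0 = i
        while j0 > lo and v[j0] > half:
            j0 -= 1
        j1 = i
        while j1 < hi - 1 and v[j1] > half:
            j1 += 1
        if (j1 - j0) * dt > p.max_halfwidth_ms:
            continue
        # sub-sample peak via parabola through (i-1, i, i+1)
        denom = v[i - 1] - 2 * v[i] + v[i + 1]
        frac = 0.5 * (v[i - 1] - v[i + 1]) / denom if denom != 0 else 0.0
        tpk = t[i] + np.clip(frac, -0.5, 0.5) * dt
        if tpk - last < p.refractory_ms:
            continue
        out.append(tpk)
        last = tpk
    return np.asarray(out) * 1e-3  # ms -> s


# -----------------------------------------------------------------------------
# Vector strength
# -----------------------------------------------------------------------------

@dataclass
class VSResult:
    vs: float
    mean_phase: float
    sd_vs: float
    n_spikes: int
    valid: bool
    n_groups: int = 0
    metadata: dict = field(default_factory=dict)


def vector_strength(
    trains: Trains,
    f_mod: float,
    window_s: tuple[float, float] | None = None,
    min_spikes: int = 50,
    group_size: int = 10,
) -> VSResult:
    """Vector strength of phase locking to f_mod, with grouped SD.

    VS = |sum exp(i 2 pi f t)| / N over spikes inside the analysis window,
    pooled over trials.  The SD is taken over disjoint groups of
    ``group_size`` consecutive trials (10 groups of 10 for the standard
    100-trial protocol; fewer trials re-derive the grouping proportionally,
    flagged in the metadata).  Results with fewer than ``min_spikes``
    spikes are marked invalid.
    """
    if f_mod <= 0:
        raise ValueError("f_mod must be positive")

    def circ(ts: np.ndarray) -> complex:
        ph = 2 * np.pi * f_mod * ts
        return complex(np.exp(1j * ph).sum())

    windowed = []
    for tr in trains:
        tr = np.asarray(tr, dtype=float)
        if window_s is not None:
            tr = tr[(tr >= window_s[0]) & (tr < window_s[1])]
        windowed.append(tr)
    n = int(sum(len(tr) for tr in windowed))
    if n == 0:
        return VSResult(0.0, 0.0, float("nan"), 0, False)
    z = sum((circ(tr) for tr in windowed), start=0j)
    vs = abs(z) / n
    phase = math.atan2(z.imag, z.real)

    n_trials = len(windowed)
    gs = group_size if n_trials >= group_size else max(1, n_trials)
    n_groups = n_trials // gs
    regrouped = n_trials != 100 or gs != 10
    group_vs = []
    for g in range(n_groups):
        chunk = windowed[g * gs: (g + 1) * gs]
        m = sum(len(c) for c in chunk)
        if m == 0:
            continue
        zg = sum((circ(c) for c in chunk), start=0j)
        group_vs.append(abs(zg) / m)
    sd = float(np.std(group_vs, ddof=1)) if len(group_vs) > 1 else float("nan")
    return VSResult(
        vs=float(vs),
        mean_phase=float(phase),
        sd_vs=sd,
        n_spikes=n,
        valid=n >= min_spikes,
        n_groups=len(group_vs),
        metadata={"regrouped": regrouped, "group_size": gs},
    )


# -----------------------------------------------------------------------------
# Rate MTF and entrainment
# -----------------------------------------------------------------------------

def _cycle_window(
    f_mod: float, onset_s: float, stim_end_s: float, analysis_start_s: float
) -> tuple[float, float]:
    """Whole-cycle analysis window from analysis_start to the last time with
    the starting phase before stimulus end."""
    if f_mod <= 0:
        raise ValueError("f_mod must be positive")
    start = analysis_start_s
    n_cycles = math.floor((stim_end_s - start) * f_mod)
    if n_cycles < 1:
        raise ValueError("analysis window is shorter than one modulation cycle")
    return start, start + n_cycles / f_mod


def rmtf(
    trains_by_fmod: dict[float, Trains],
    stim_onset_s: float = 0.0,
    stim_dur_s: float = 1.0,
    analysis_delay_s: float = 0.25,
) -> dict[float, float]:
    """Rate modulation transfer function: mean rate per f_mod.

    The rate window starts ``analysis_delay_s`` after stimulus onset and
    ends at the last whole modulation cycle before stimulus offset, so
    every frequency averages over complete cycles.
    """
    out: dict[float, float] = {}
    for f_mod, trains in trains_by_fmod.items():
        a, b = _cycle_window(
            f_mod, stim_onset_s, stim_onset_s + stim_dur_s, stim_onset_s + analysis_delay_s
        )
        counts = [np.count_nonzero((tr >= a) & (tr < b)) for tr in trains]
        out[f_mod] = float(np.mean(counts) / (b - a))
    return out


def entrainment(
    trains: Trains,
    f_mod: float,
    stim_onset_s: float = 0.0,
    stim_dur_s: float = 1.0,
    analysis_delay_s: float = 0.25,
) -> float:
    """Entrainment index: ISIs within [0.5/f, 1.5/f] per modulation cycle.

    The lower ISI bound is 0.5/f rather than 0 so that multiple spikes per
    cycle at low modulation frequencies are not counted as entrained
    intervals; the window is closed at both bounds.  Returns 0 when there
    are no ISIs.
    """
    a, b = _cycle_window(
        f_mod, stim_onset_s, stim_onset_s + stim_dur_s, stim_onset_s + analysis_delay_s
    )
    lo, hi = 0.5 / f_mod, 1.5 / f_mod
    n_isi = 0
    for tr in trains:
        tr = tr[(tr >= a) & (tr < b)]
        if len(tr) > 1:
            isis = np.diff(tr)
            n_isi += int(np.count_nonzero((isis >= lo) & (isis <= hi)))
    n_cycles = int(round((b - a) * f_mod)) * len(trains)
    return n_isi / n_cycles if n_cycles else 0.0


# -----------------------------------------------------------------------------
# Shuffled autocorrelogram
# -----------------------------------------------------------------------------

@dataclass
class SACResult:
    lags_ms: np.ndarray
    rate: np.ndarray  # normalized coincidence rate (Poisson -> 1)
    ci: float  # value at zero lag
    halfwidth_ms: float
    n_spikes: int
    valid: bool
    metadata: dict = field(default_factory=dict)


def sac(
    trains: Trains,
    binwidth_ms: float = 0.05,
    maxlag_ms: float = 5.0,
    window_s: tuple[float, float] | None = None,
    min_spikes: int = 100,
) -> SACResult:
    """Shuffled autocorrelogram across trials (Louage normalization).

    All spike-time differences between *distinct* trials are histogrammed
    and normalized by N(N-1) r^2 dt D (N trials, r mean rate, dt binwidth,
    D window duration), so a homogeneous Poisson process gives a flat SAC
    at 1.  CI is the zero-lag value; the halfwidth is the full width at
    half height of the central peak above the asymptote of 1, with linear
    interpolation between bins.
    """
    if len(trains) < 2:
        raise ValueError("SAC needs at least two trials")
    if window_s is None:
        tmax = max((tr[-1] for tr in trains if len(tr)), default=0.0)
        window_s = (0.0, tmax if tmax > 0 else 1.0)
    a, b = window_s
    D = b - a
    cut = [np.asarray(tr)[(np.asarray(tr) >= a) & (np.asarray(tr) < b)] for tr in trains]
    N = len(cut)
    n_total = sum(len(tr) for tr in cut)
    r = n_total / (N * D)
    maxlag = maxlag_ms * 1e-3
    bw = binwidth_ms * 1e-3
    nbins = 2 * int(round(maxlag / bw)) + 1
    edges = (np.arange(nbins + 1) - nbins / 2) * bw
    counts = np.zeros(nbins)
    for i in range(N):
        ti = cut[i]
        if not len(ti):
            continue
        for j in range(N):
            if i == j or not len(cut[j]):
                continue
            d = (cut[j][None, :] - ti[:, None]).ravel()
            d = d[np.abs(d) <= maxlag + 0.5 * bw]
            idx = np.clip(np.floor((d + edges[-1]) / bw).astype(int), 0, nbins - 1)
            np.add.at(counts, idx, 1)
    norm = N * (N - 1) * r**2 * bw * D
    rate = counts / norm if norm > 0 else counts
    centers = 0.5 * (edges[:-1] + edges[1:]) * 1e3
    mid = nbins // 2
    ci = float(rate[mid])

    halfwidth = float("nan")
    if ci > 1.0:
        half = 1.0 + 0.5 * (ci - 1.0)

        def cross(direction: int) -> float:
            k = mid
            while 0 < k < nbins - 1:
                nk = k + direction
                if rate[nk] < half <= rate[k]:
                    frac = (rate[k] - half) / (rate[k] - rate[nk])
                    return centers[k] + frac * (centers[nk] - centers[k])
                k = nk
            return centers[0] if direction < 0 else centers[-1]

        halfwidth = cross(+1) - cross(-1)
    return SACResult(
        lags_ms=centers,
        rate=rate,
        ci=ci,
        halfwidth_ms=float(halfwidth),
        n_spikes=n_total,
        valid=n_total >= min_spikes,
        metadata={"binwidth_ms": binwidth_ms, "window_s": window_s, "rate_hz": r},
    )


# -----------------------------------------------------------------------------
# Cross-correlogram
# -----------------------------------------------------------------------------

def cross_correlogram(
    pre_trains: Trains,
    post_trains: Trains,
    range_ms: float = 5.0,
    res_ms: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Rate of presynaptic spikes at lags <= 0 relative to postsynaptic spikes.

    Returns (lag centers in ms over [-range, 0], coincidence rate in Hz =
    counts per postsynaptic spike per second).  Trials are paired by index.
    """
    if len(pre_trains) != len(post_trains):
        raise ValueError("pre and post collections must share trial structure")
    nbins = int(round(range_ms / res_ms))
    edges = -np.arange(nbins + 1)[::-1] * res_ms * 1e-3
    counts = np.zeros(nbins)
    n_post = 0
    for pre, post in zip(pre_trains, post_trains):
        pre = np.asarray(pre)
        post = np.asarray(post)
        n_post += len(post)
        for tp in post:
            d = pre - tp
            d = d[(d >= edges[0]) & (d <= 0.0)]
            idx = np.minimum(np.floor((d - edges[0]) / (res_ms * 1e-3)).astype(int), nbins - 1)
            np.add.at(counts, idx, 1)
    centers = 0.5 * (edges[:-1] + edges[1:]) * 1e3
    rate = counts / (n_post * res_ms * 1e-3) if n_post else counts
    return centers, rate


# -----------------------------------------------------------------------------
# Efficacy / participation
# -----------------------------------------------------------------------------

@dataclass
class EfficacyResult:
    efficacy: np.ndarray | None  # per input, lone-input definition
    participation: np.ndarray  # per input, all-inputs condition
    attribution: np.ndarray  # per rank, exclusive attribution fractions
    window_ms: tuple[float, float]
    n_post: int


def efficacy(pre_trains: Trains, post_trains: Trains) -> float:
    """Postsynaptic APs per presynaptic AP (single active input)."""
    n_pre = sum(len(tr) for tr in pre_trains)
    if n_pre == 0:
        raise FitError("efficacy undefined: no presynaptic spikes")
    n_post = sum(len(tr) for tr in post_trains)
    return n_post / n_pre


def _fired_in_window(pre: np.ndarray, t_post: float, window_s: tuple[float, float]) -> bool:
    lo, hi = t_post + window_s[0], t_post + window_s[1]
    i = np.searchsorted(pre, lo, side="left")
    return bool(i < len(pre) and pre[i] <= hi)


def participation(
    inputs_trains: Sequence[Trains],
    post_trains: Trains,
    window_ms: tuple[float, float] = (-2.7, -0.5),
) -> np.ndarray:
    """Fraction of postsynaptic spikes preceded in-window by each input."""
    w = (window_ms[0] * 1e-3, window_ms[1] * 1e-3)
    n_inputs = len(inputs_trains)
    hits = np.zeros(n_inputs)
    n_post = 0
    for trial, post in enumerate(post_trains):
        n_post += len(post)
        for k in range(n_inputs):
            pre = np.asarray(inputs_trains[k][trial])
            for tp in post:
                if _fired_in_window(pre, tp, w):
                    hits[k] += 1
    return hits / n_post if n_post else hits


def efficacy_participation(
    inputs_trains: Sequence[Trains],
    post_trains: Trains,
    window_ms: tuple[float, float] = (-2.7, -0.5),
    lone_input_posts: Sequence[Trains] | None = None,
) -> EfficacyResult:
    """Participation and exclusive rank attribution (inputs ordered by size).

    ``inputs_trains[k]`` is the k-th largest input's trains (one array per
    trial) in the all-inputs condition.  Exclusive attribution credits a
    postsynaptic spike to rank k when input k fired in the integration
    window and no larger input did (ties therefore go to the larger
    input).  If ``lone_input_posts`` is given (postsynaptic trains from
    runs with only that input active), per-input efficacies are computed
    from them.
    """
    w = (window_ms[0] * 1e-3, window_ms[1] * 1e-3)
    n_inputs = len(inputs_trains)
    attribution = np.zeros(n_inputs)
    n_post = 0
    for trial, post in enumerate(post_trains):
        pres = [np.asarray(inputs_trains[k][trial]) for k in range(n_inputs)]
        n_post += len(post)
        for tp in post:
            for k in range(n_inputs):
                if _fired_in_window(pres[k], tp, w):
                    attribution[k] += 1
                    break
    part = participation(inputs_trains, post_trains, window_ms)
    eff = None
    if lone_input_posts is not None:
        eff = np.array(
            [
                efficacy(inputs_trains[k], lone_input_posts[k])
                for k in range(n_inputs)
            ]
        )
    return EfficacyResult(
        efficacy=eff,
        participation=part,
        attribution=attribution / n_post if n_post else attribution,
        window_ms=window_ms,
        n_post=n_post,
    )


# -----------------------------------------------------------------------------
# Logistic efficacy fit
# -----------------------------------------------------------------------------

@dataclass
class LogisticFit:
    emax: float
    a50_um2: float
    k_um2: float
    cov: np.ndarray


def fit_logistic(asa_um2: np.ndarray, eff: np.ndarray) -> LogisticFit:
    """Least-squares fit of eff = Emax / (1 + exp(-(ASA - A50)/k))."""
    from scipy.optimize import curve_fit

    asa = np.asarray(asa_um2, dtype=float)
    eff = np.asarray(eff, dtype=float)
    if len(asa) < 4:
        raise FitError("need at least 4 points for a logistic fit")
    if np.allclose(eff, 0.0) or np.ptp(eff) < 1e-12:
        raise FitError("degenerate efficacy data (no growth to fit)")

    def logistic(a, emax, a50, k):
        return emax / (1.0 + np.exp(-(a - a50) / k))

    p0 = (max(eff.max(), 1e-3), float(np.median(asa)), max(np.ptp(asa) / 10.0, 1.0))
    try:
        popt, pcov = curve_fit(
            logistic, asa, eff, p0=p0,
            bounds=([1e-6, 0.0, 1e-6], [1.0, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"logistic fit failed: {exc}") from exc
    return LogisticFit(emax=float(popt[0]), a50_um2=float(popt[1]),
                       k_um2=float(popt[2]), cov=pcov)


# -----------------------------------------------------------------------------
# Latencies and regularity
# -----------------------------------------------------------------------------

def fsl_ssl(trains: Trains, onset_s: float) -> dict:
    """First- and second-spike latency distributions after stimulus onset."""
    fsl, ssl = [], []
    empty = 0
    for tr in trains:
        tr = np.asarray(tr)
        after = tr[tr >= onset_s]
        if len(after) == 0:
            empty += 1
            continue
        fsl.append(after[0] - onset_s)
        if len(after) > 1:
            ssl.append(after[1] - onset_s)
    return {
        "fsl_s": np.asarray(fsl),
        "ssl_s": np.asarray(ssl),
        "n_empty_trials": empty,
    }


def write_events_csv(path, trains: Trains, source: int = 0) -> None:
    """Serialize trains as an event table (trial, source, time_s)."""
    import pandas as pd

    rows = [
        (trial, source, t)
        for trial, tr in enumerate(trains)
        for t in np.asarray(tr)
    ]
    pd.DataFrame(rows, columns=["trial", "source", "time_s"]).to_csv(path, index=False)


def read_events_csv(path, source: int | None = None) -> list[np.ndarray]:
    import pandas as pd

    df = pd.read_csv(path)
    if source is not None:
        df = df[df["source"] == source]
    n_trials = int(df["trial"].max()) + 1 if len(df) else 0
    return [
        np.sort(df.loc[df["trial"] == k, "time_s"].to_numpy())
        for k in range(n_trials)
    ]


def isi_cv(trains: Trains, window_s: tuple[float, float] | None = None) -> float:
    """Coefficient of variation of interspike intervals (pooled over trials)."""
    isis = []
    for tr in trains:
        tr = np.asarray(tr)
        if window_s is not None:
            tr = tr[(tr >= window_s[0]) & (tr < window_s[1])]
        if len(tr) > 1:
            isis.append(np.diff(tr))
    if not isis:
        return float("nan")
    allisi = np.concatenate(isis)
    return float(allisi.std(ddof=1) / allisi.mean())
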