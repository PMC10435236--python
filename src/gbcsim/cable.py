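"""Branched-cable integrator: discretization, current clamp, voltage clamp.

The compartmental model is a tree of iso-potential segments produced from a
tagged morphology by the d-lambda rule.  Integration is implicit (backward
Euler by default, trapezoid/Crank-Nicolson optionally) with gating
variables advanced by the exponential (Rush-Larsen) update at the current
voltage, and the resulting linear tree system solved exactly per step with
a Hines-ordered elimination.

Internal unit system: mV, ms, nF, uS, nA (so I = g*V and C*dV/dt = I are
consistent without conversion factors).  Geometry is carried in um/um^2,
Ra in Ohm*cm, cm in uF/cm^2, and converted once at build time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from gbcsim import membrane
from gbcsim.morphology import Morphology, Tag

__all__ = [
    "CompartmentalModel",
    "ClampProtocol",
    "Recording",
    "SynapticDrive",
    "discretize",
    "run_current_clamp",
    "run_voltage_clamp",
    "measure_passive",
    "IntegrationError",
]

AREA_UM2_TO_US = 1e-5  # (mS/cm^2)*(um^2) -> uS
AREA_UM2_TO_NF = 1e-5  # (uF/cm^2)*(um^2) -> nF


class IntegrationError(RuntimeError):
    """Numerical blow-up during integration."""


def _lambda_f_um(d_um: float, f_hz: float, ra_ohm_cm: float, cm_uf_cm2: float) -> float:
    """AC length constant at frequency f, in micrometres."""
    d_cm = d_um * 1e-4
    lam_cm = 0.5 * math.sqrt(d_cm / (math.pi * f_hz * ra_ohm_cm * cm_uf_cm2 * 1e-6))
    return lam_cm * 1e4


def _split_section(sec, nseg: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment (area um^2, axial resistance MOhm) for equal arc-length
    segments, partitioning the section's frustum area exactly."""
    pts = sec.points
    d = np.diff(pts[:, :3], axis=0)
    seg_len = np.sqrt((d**2).sum(axis=1))
    mask = seg_len > 0
    seg_len = seg_len[mask]
    r0 = pts[:-1, 3][mask]
    r1 = pts[1:, 3][mask]
    s_knots = np.concatenate([[0.0], np.cumsum(seg_len)])
    L = s_knots[-1]
    bounds = np.linspace(0.0, L, nseg + 1)
    # merge knots and boundaries, then accumulate per sub-piece
    s_all = np.unique(np.concatenate([s_knots, bounds]))
    r_all = np.interp(s_all, s_knots, np.concatenate([[r0[0]], r1]))
    piece_idx = np.minimum(
        np.searchsorted(bounds, 0.5 * (s_all[:-1] + s_all[1:]), side="right") - 1,
        nseg - 1,
    )
    ds = np.diff(s_all)
    ra_piece = np.where(ds > 0, ds / np.maximum(r_all[:-1] * r_all[1:], 1e-30), 0.0)
    slant = np.sqrt(ds**2 + np.diff(r_all) ** 2)
    area_piece = np.pi * (r_all[:-1] + r_all[1:]) * slant
    areas = np.zeros(nseg)
    np.add.at(areas, piece_idx, area_piece)
    ra = np.zeros(nseg)
    np.add.at(ra, piece_idx, ra_piece)
    return areas, ra  # ra in um/um^2 units; scaled by caller


@dataclass
class CompartmentalModel:
    """Discretized segments with areas, tags, densities and axial coupling."""

    morphology: Morphology
    parent: np.ndarray  # parent segment index, -1 for root
    g_axial: np.ndarray  # uS coupling each segment to its parent (0 at root)
    area: np.ndarray  # um^2
    seg_tag: list
    seg_section: np.ndarray  # section id per segment
    cm: float  # uF/cm^2
    Ra: float  # Ohm*cm
    density: dict = field(default_factory=dict)  # channel -> mS/cm^2 array
    decorated: bool = False

    # integration state
    V: np.ndarray | None = None
    gates: dict | None = None

    def __post_init__(self) -> None:
        n = len(self.area)
        if not self.density:
            self.density = {c: np.zeros(n) for c in membrane.CHANNELS}
        if n > 1 and not np.all(self.parent[1:] < np.arange(1, n)):
            raise ValueError("segments must be ordered with parents before children")
        self.c_nF = self.area * self.cm * AREA_UM2_TO_NF

    # -- addressing -----------------------------------------------------------
    @property
    def n_segments(self) -> int:
        return len(self.area)

    def segments_with_tag(self, tag: Tag) -> np.ndarray:
        return np.flatnonzero(np.array([t is tag for t in self.seg_tag]))

    @property
    def soma_index(self) -> int:
        idx = self.segments_with_tag(Tag.SOMA)
        if len(idx) == 0:
            raise ValueError("model has no soma segment")
        return int(idx[len(idx) // 2])  # middle soma segment

    def tag_area(self, tags) -> float:
        tagset = set(tags)
        return float(sum(a for a, t in zip(self.area, self.seg_tag) if t in tagset))

    def total_conductance_nS(self, channel: str, tags=None) -> float:
        """Sum of maximal conductance over segments, in nS."""
        dens = self.density[channel]
        if tags is None:
            sel = np.ones(self.n_segments, dtype=bool)
        else:
            tagset = set(tags)
            sel = np.array([t in tagset for t in self.seg_tag])
        return float((dens[sel] * self.area[sel]).sum() * AREA_UM2_TO_US * 1e3)

    def scale_density(self, channel: str, factor: float) -> None:
        self.density[channel] = self.density[channel] * factor

    def copy(self) -> "CompartmentalModel":
        m = CompartmentalModel(
            morphology=self.morphology,
            parent=self.parent.copy(),
            g_axial=self.g_axial.copy(),
            area=self.area.copy(),
            seg_tag=list(self.seg_tag),
            seg_section=self.seg_section.copy(),
            cm=self.cm,
            Ra=self.Ra,
            density={c: d.copy() for c, d in self.density.items()},
            decorated=self.decorated,
        )
        return m

    # -- state ------------------------------------------------------------------
    def init_state(self, V0: float = -65.0) -> None:
        n = self.n_segments
        self.V = np.full(n, float(V0))
        self.gates = {}
        for ch in membrane.CHANNELS:
            for gate, (inf, _tau) in membrane.channel_rates(ch, V0).items():
                self.gates[(ch, gate)] = np.full(n, float(inf))


@dataclass
class ClampProtocol:
    """Piecewise-constant command waveform for current or voltage clamp.

    steps is a sequence of (duration_ms, value) pairs; values are nA in
    current mode, mV in voltage mode.  dt_us defaults to the standard 25 us
    (current clamp) / 5 us (voltage clamp) time steps.
    """

    mode: str  # "current" | "voltage"
    steps: Sequence[tuple[float, float]]
    dt_us: float | None = None
    Rs_MOhm: float = 1.0
    initial_V: float = -65.0
    settle_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.mode not in ("current", "voltage"):
            raise ValueError("mode must be 'current' or 'voltage'")
        if self.dt_us is None:
            self.dt_us = 25.0 if self.mode == "current" else 5.0
        if self.dt_us <= 0 or self.Rs_MOhm < 0:
            raise ValueError("dt must be > 0 and Rs >= 0")

    @property
    def duration_ms(self) -> float:
        return float(sum(d for d, _ in self.steps))

    def command(self) -> tuple[np.ndarray, np.ndarray]:
        """(time_ms, value) arrays sampled on the integration grid."""
        dt = self.dt_us * 1e-3
        n = int(round(self.duration_ms / dt)) + 1
        t = np.arange(n) * dt
        v = np.empty(n)
        edges = np.concatenate([[0.0], np.cumsum([d for d, _ in self.steps])])
        vals = np.array([val for _, val in self.steps])
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(vals) - 1)
        v[:] = vals[idx]
        return t, v


@dataclass
class Recording:
    """Time series recorded during a protocol."""

    t: np.ndarray  # ms
    V: np.ndarray  # mV at the recorded site
    I: np.ndarray | None = None  # nA clamp current (voltage mode)
    metadata: dict = field(default_factory=dict)

    @property
    def dt_ms(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_frame(self):
        import pandas as pd

        data = {"t_ms": self.t, "V_mV": self.V}
        if self.I is not None:
            data["I_nA"] = self.I
        return pd.DataFrame(data)


@dataclass
class SynapticDrive:
    """Time-varying synaptic conductance applied to one segment.

    g_trace must be sampled on the protocol's integration grid (uS).  The
    rectification function maps V (mV) -> multiplicative factor in (0, 1].
    """

    target: int
    g_trace: np.ndarray
    e_rev: float = 0.0
    rectify: Callable[[np.ndarray], np.ndarray] | None = None


def discretize(
    m: Morphology,
    f: float = 1000.0,
    d_lambda: float = 0.1,
    Ra: float = 150.0,
    cm: float = 0.9,
) -> CompartmentalModel:
    """Build a compartmental model using the d-lambda rule at frequency f.

    Per section, the segment count is the smallest odd integer >=
    L/(d_lambda*lambda_f) with lambda_f evaluated at the section's mean
    diameter; segment areas partition the section frustum area exactly.
    """
    if Ra <= 0 or cm <= 0 or f <= 0 or d_lambda <= 0:
        raise ValueError("electrical constants must be positive")
    parent_idx: list[int] = []
    g_axial: list[float] = []
    areas: list[float] = []
    tags: list[Tag] = []
    sec_ids: list[int] = []
    last_seg_of_sec: dict[int, int] = {}
    half_r_end: dict[int, float] = {}  # MOhm from last segment centre to section end

    ordered = []
    queue = [m.root]
    while queue:
        s = queue.pop(0)
        ordered.append(s)
        queue.extend(sorted(m.children(s.id), key=lambda c: c.id))

    for sec in ordered:
        lam = _lambda_f_um(sec.mean_diameter, f, Ra, cm)
        nseg = max(1, math.ceil(sec.length / (d_lambda * lam)))
        if nseg % 2 == 0:
            nseg += 1
        seg_area, seg_ra = _split_section(sec, nseg)
        # axial resistance in MOhm: Ra/(pi) * sum(ds/(r1*r2)), lengths um
        seg_r_MOhm = Ra / math.pi * seg_ra * 1e-2
        base = len(areas)
        for j in range(nseg):
            if j == 0:
                if sec.parent_id is None:
                    parent_idx.append(-1)
                    g_axial.append(0.0)
                else:
                    pseg = last_seg_of_sec[sec.parent_id]
                    r = half_r_end[sec.parent_id] + 0.5 * seg_r_MOhm[0]
                    parent_idx.append(pseg)
                    g_axial.append(1.0 / r if r > 0 else 0.0)
            else:
                r = 0.5 * seg_r_MOhm[j - 1] + 0.5 * seg_r_MOhm[j]
                parent_idx.append(base + j - 1)
                g_axial.append(1.0 / r if r > 0 else 0.0)
            areas.append(seg_area[j])
            tags.append(sec.tag)
            sec_ids.append(sec.id)
        last_seg_of_sec[sec.id] = base + nseg - 1
        half_r_end[sec.id] = 0.5 * seg_r_MOhm[-1]

    return CompartmentalModel(
        morphology=m,
        parent=np.array(parent_idx, dtype=int),
        g_axial=np.array(g_axial),
        area=np.array(areas),
        seg_tag=tags,
        seg_section=np.array(sec_ids, dtype=int),
        cm=cm,
        Ra=Ra,
    )


# -----------------------------------------------------------------------------
# Core stepping
# -----------------------------------------------------------------------------

def _active_channels(model: CompartmentalModel) -> list[str]:
    return [
        ch
        for ch in membrane.CHANNELS
        if ch != "Leak" and np.any(model.density[ch] > 0)
    ]


def _hines_solve_py(parent, diag, off, rhs):
    """Exact solve of the symmetric tree system (Hines elimination).

    Relies on the construction invariant parent[i] < i, so a single
    reverse sweep eliminates every child into its parent.
    """
    n = len(diag)
    for i in range(n - 1, 0, -1):
        m = off[i] / diag[i]
        p = parent[i]
        diag[p] -= m * off[i]
        rhs[p] -= m * rhs[i]
    v = np.empty_like(rhs)
    v[0] = rhs[0] / diag[0]
    for i in range(1, n):
        v[i] = (rhs[i] - off[i] * v[parent[i]]) / diag[i]
    return v


try:  # numba gives a large speed-up for the per-step tree solve
    from numba import njit as _njit

    _hines_solve = _njit(cache=False)(_hines_solve_py)
    _hines_solve(np.array([-1, 0]), np.ones(2), np.zeros(2), np.ones(2))
except Exception:  # pragma: no cover - numba is normally available
    _hines_solve = _hines_solve_py


def _simulate(
    model: CompartmentalModel,
    dt_ms: float,
    n_steps: int,
    inj_site: int | None = None,
    inj_nA: np.ndarray | None = None,
    clamp_site: int | None = None,
    clamp_mV: np.ndarray | None = None,
    g_series_uS: float = 0.0,
    synapses: Sequence[SynapticDrive] | None = None,
    record_site: int = 0,
    method: str = "be",
    record_all: bool = False,
):
    """Advance the model n_steps and record V at record_site (and clamp I).

    method 'be' is backward Euler; 'cn' the trapezoid rule on the linear
    (conductance) part with gates updated by Rush-Larsen each step.
    """
    if model.V is None:
        raise RuntimeError("call init_state first")
    theta = 1.0 if method == "be" else 0.5
    V = model.V
    n = model.n_segments
    c_dt = model.c_nF / dt_ms
    g_seg = {
        ch: model.density[ch] * model.area * AREA_UM2_TO_US
        for ch in membrane.CHANNELS
    }
    e_leak = membrane.REVERSALS_MV["Leak"]
    active = _active_channels(model)
    erev = {ch: membrane.reversal_for(ch) for ch in active}
    gates = model.gates
    parent = model.parent
    g_ax = model.g_axial
    child_idx = np.flatnonzero(parent >= 0)
    par_of_child = parent[child_idx]

    rec_V = np.empty(n_steps + 1)
    rec_I = np.empty(n_steps + 1) if clamp_site is not None else None
    all_V = np.empty((n_steps + 1, n)) if record_all else None
    rec_V[0] = V[record_site]
    if rec_I is not None:
        rec_I[0] = g_series_uS * (clamp_mV[0] - V[clamp_site])
    if all_V is not None:
        all_V[0] = V

    # precompute exponential-update factors cache on a voltage grid
    for step in range(1, n_steps + 1):
        # 1) gates via Rush-Larsen at current V
        for ch in active:
            rates = membrane.channel_rates(ch, V)
            for gate, (inf, tau) in rates.items():
                x = gates[(ch, gate)]
                gates[(ch, gate)] = inf + (x - inf) * np.exp(-dt_ms / tau)

        # 2) assemble per-segment total conductance and driving terms
        g_tot = g_seg["Leak"].copy()
        ge_tot = g_seg["Leak"] * e_leak
        for ch in active:
            po = membrane.open_probability(
                ch, {g: gates[(ch, g)] for g, _ in membrane.GATES[ch]}
            )
            gch = g_seg[ch] * po
            g_tot += gch
            ge_tot += gch * erev[ch]
        if synapses:
            for syn in synapses:
                g = syn.g_trace[step] if step < len(syn.g_trace) else 0.0
                if syn.rectify is not None:
                    g = g * float(syn.rectify(V[syn.target]))
                g_tot[syn.target] += g
                ge_tot[syn.target] += g * syn.e_rev

        # theta method on C dV/dt = -g_tot V + ge_tot + axial(V)
        #                           + g_s (vcmd - V) + I_inj
        # with source terms (ge_tot, vcmd, I_inj) held constant over the step.
        diag = c_dt + theta * g_tot
        diag[child_idx] += theta * g_ax[child_idx]
        np.add.at(diag, par_of_child, theta * g_ax[child_idx])
        off = -theta * g_ax  # off-diagonal coupling to parent

        rhs = c_dt * V + ge_tot
        if inj_site is not None and inj_nA is not None:
            rhs[inj_site] += inj_nA[step] if step < len(inj_nA) else inj_nA[-1]
        vcmd = None
        if clamp_site is not None:
            vcmd = clamp_mV[step] if step < len(clamp_mV) else clamp_mV[-1]
            diag[clamp_site] += theta * g_series_uS
            rhs[clamp_site] += g_series_uS * vcmd
        if theta != 1.0:
            # explicit fraction of the V-dependent part, evaluated at V0
            ax_flow = g_ax[child_idx] * (V[par_of_child] - V[child_idx])
            expl = -(1.0 - theta) * g_tot * V
            np.add.at(expl, child_idx, (1.0 - theta) * ax_flow)
            np.add.at(expl, par_of_child, -(1.0 - theta) * ax_flow)
            if clamp_site is not None:
                expl[clamp_site] -= (1.0 - theta) * g_series_uS * V[clamp_site]
            rhs += expl

        V = _hines_solve(parent, diag, off.copy(), rhs)
        if not np.all(np.abs(V) < 200.0):
            raise IntegrationError(
                f"voltage blow-up at step {step} (t={step*dt_ms:.3f} ms): "
                f"|V|max={np.abs(V).max():.1f} mV"
            )
        rec_V[step] = V[record_site]
        if rec_I is not None:
            vcmd = clamp_mV[step] if step < len(clamp_mV) else clamp_mV[-1]
            rec_I[step] = g_series_uS * (vcmd - V[clamp_site])
        if all_V is not None:
            all_V[step] = V

    model.V = V
    model.gates = gates
    t = np.arange(n_steps + 1) * dt_ms
    return t, rec_V, rec_I, all_V


def _settle(
    model: CompartmentalModel,
    dt_ms: float,
    settle_ms: float,
    V0: float,
    clamp_site: int | None = None,
    g_series_uS: float = 0.0,
) -> None:
    """Relax to steady state before a protocol (clamped at V0 if requested)."""
    model.init_state(V0)
    if settle_ms > 0:
        # settle with a coarser step: only slow relaxation matters here
        dt_settle = max(dt_ms, 0.025)
        n = max(1, int(round(settle_ms / dt_settle)))
        if clamp_site is not None:
            _simulate(
                model,
                dt_settle,
                n,
                clamp_site=clamp_site,
                clamp_mV=np.full(2, V0),
                g_series_uS=g_series_uS,
            )
        else:
            _simulate(model, dt_settle, n)


def run_current_clamp(
    model: CompartmentalModel,
    protocol: ClampProtocol,
    site: int | None = None,
    synapses: Sequence[SynapticDrive] | None = None,
    method: str = "be",
    record_all: bool = False,
) -> Recording:
    """Inject the protocol's current waveform at a segment and record V."""
    if protocol.mode != "current":
        raise ValueError("protocol mode must be 'current'")
    if site is None:
        site = model.soma_index
    dt = protocol.dt_us * 1e-3
    _settle(model, dt, protocol.settle_ms, protocol.initial_V)
    _t, cmd = protocol.command()
    t, v, _i, all_V = _simulate(
        model,
        dt,
        len(cmd) - 1,
        inj_site=site,
        inj_nA=cmd,
        record_site=site,
        synapses=synapses,
        method=method,
        record_all=record_all,
    )
    meta = {"protocol": "current_clamp", "dt_us": protocol.dt_us, "site": site}
    if record_all:
        meta["all_V"] = all_V
    return Recording(t=t, V=v, metadata=meta)


def run_voltage_clamp(
    model: CompartmentalModel,
    protocol: ClampProtocol,
    site: int | None = None,
    method: str = "cn",
) -> Recording:
    """Clamp a segment through series resistance Rs and record pipette current.

    The pipette node is in series with Rs, so the membrane voltage deviates
    from the command whenever current flows and Rs > 0.  The trapezoid rule
    is the default integrator here because the clamp charging transient can
    be comparable to the time step.
    """
    if protocol.mode != "voltage":
        raise ValueError("protocol mode must be 'voltage'")
    if site is None:
        site = model.soma_index
    dt = protocol.dt_us * 1e-3
    if protocol.Rs_MOhm > 0:
        g_s = 1.0 / protocol.Rs_MOhm
    else:
        # ideal clamp: a huge series conductance is only stable with the
        # L-stable first-order method, not with the trapezoid rule
        g_s = 1e6
        method = "be"
    _settle(
        model, dt, protocol.settle_ms, protocol.initial_V,
        clamp_site=site, g_series_uS=g_s,
    )
    _t, cmd = protocol.command()
    t, v, i, _ = _simulate(
        model,
        dt,
        len(cmd) - 1,
        clamp_site=site,
        clamp_mV=cmd,
        g_series_uS=g_s,
        record_site=site,
        method=method,
    )
    return Recording(
        t=t,
        V=v,
        I=i,
        metadata={
            "protocol": "voltage_clamp",
            "dt_us": protocol.dt_us,
            "Rs_MOhm": protocol.Rs_MOhm,
            "site": site,
        },
    )


# -----------------------------------------------------------------------------
# Passive characterization
# -----------------------------------------------------------------------------

def measure_passive(
    model: CompartmentalModel,
    probe_nA: float = -0.1,
    iv_currents: np.ndarray | None = None,
    pulse_ms: float = 100.0,
    settle_ms: float = 200.0,
    dt_us: float = 25.0,
) -> dict:
    """Input resistance, membrane time constant and an IV family.

    Rin is the steady-state slope for a small hyperpolarizing step; tau is
    a mono-exponential fit to that step's onset; the IV family reports peak
    (spike-excluded, signed extremum toward the step polarity) and the mean
    of the last 10 ms.
    """
    from scipy.optimize import curve_fit

    work = model.copy()
    proto = ClampProtocol(
        "current",
        [(20.0, 0.0), (pulse_ms, probe_nA), (20.0, 0.0)],
        dt_us=dt_us,
        settle_ms=settle_ms,
    )
    rec = run_current_clamp(work, proto)
    t, v = rec.t, rec.V
    i0 = np.searchsorted(t, 20.0)
    i1 = np.searchsorted(t, 20.0 + pulse_ms)
    vrest = v[i0 - 1]
    vss = v[i1 - int(10.0 / rec.dt_ms): i1].mean()
    rin = (vss - vrest) / probe_nA  # mV/nA = MOhm

    # mono-exponential fit of onset
    tt = t[i0:i1] - t[i0]
    seg = v[i0:i1]

    def expdec(x, a, tau):
        return vss + a * np.exp(-x / tau)

    try:
        (a, tau), _ = curve_fit(
            expdec, tt, seg, p0=(vrest - vss, 2.0), maxfev=5000
        )
        tau = float(abs(tau))
        fit_ok = True
    except RuntimeError:
        tau, fit_ok = float("nan"), False

    iv = None
    if iv_currents is not None:
        peaks, steadies = [], []
        for amp in iv_currents:
            w = model.copy()
            p = ClampProtocol(
                "current",
                [(20.0, 0.0), (pulse_ms, float(amp)), (20.0, 0.0)],
                dt_us=dt_us,
                settle_ms=settle_ms,
            )
            r = run_current_clamp(w, p)
            j0 = np.searchsorted(r.t, 20.0)
            j1 = np.searchsorted(r.t, 20.0 + pulse_ms)
            vwin = r.V[j0:j1]
            base = r.V[j0 - 1]
            # peak excluding spikes: clip depolarizations above -20 mV
            vclip = np.minimum(vwin, -20.0) if amp > 0 else vwin
            peak = vclip.max() if amp > 0 else vclip.min()
            peaks.append(peak - base)
            steadies.append(vwin[-int(10.0 / r.dt_ms):].mean() - base)
        iv = {
            "I_nA": np.asarray(iv_currents, dtype=float),
            "peak_mV": np.array(peaks),
            "steady_mV": np.array(steadies),
        }
    return {"Rin_MOhm": float(rin), "tau_ms": tau, "tau_fit_ok": fit_ok, "IV": iv}
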