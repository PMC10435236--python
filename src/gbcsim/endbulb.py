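"""ASA-weighted stochastic multisite endbulb synapses.

An endbulb of Held contains many independent release sites; the site count
is the apposed surface area (ASA) times the average synapse density
(0.7686 synapses/um^2).  Each presynaptic spike triggers an independent
Bernoulli release decision per site with fixed probability Pr, so the
release count per spike is Binomial(n_sites, Pr) and the mean synaptic
weight is linear in ASA.  Each release event contributes a biexponential
conductance transient (the simplified stand-in for cleft diffusion plus
receptor kinetics); the AMPA current rectifies at depolarized potentials
(polyamine block), and an optional NMDA component carries a sigmoidal
voltage-dependent block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SYNAPSE_DENSITY_PER_UM2",
    "ConductanceKernel",
    "EndbulbInput",
    "n_sites",
    "release_events",
    "biexp_kernel",
    "conductance_trace",
    "ampa_rectification",
    "nmda_block",
]

#: average synapse density on endbulb contacts (synapses per um^2 of ASA)
SYNAPSE_DENSITY_PER_UM2 = 0.7686

#: default per-site release probability (fixed over time; no depletion)
DEFAULT_PR = 0.3


def n_sites(asa_um2: float, density_per_um2: float = SYNAPSE_DENSITY_PER_UM2) -> int:
    """Number of independent release sites for a terminal of given ASA."""
    if asa_um2 < 0:
        raise ValueError("ASA must be non-negative")
    return int(round(asa_um2 * density_per_um2))


@dataclass
class ConductanceKernel:
    """Biexponential conductance transient for one release event.

    gmax_nS is the peak conductance contributed per site per release.  The
    rectification parameters shape the voltage dependence of the AMPA
    conductance: rect(V) = floor + (1-floor)/(1+exp((V-v_half)/k)), which
    is 1 at hyperpolarized V and decays toward ``floor`` with
    depolarization.
    """

    tau_rise_ms: float = 0.1
    tau_decay_ms: float = 0.3
    gmax_nS: float = 0.7
    e_rev_mV: float = 0.0
    rect_floor: float = 0.2
    rect_vhalf_mV: float = -20.0
    rect_k_mV: float = 20.0
    nmda_fraction: float = 0.1
    nmda_tau_rise_ms: float = 2.0
    nmda_tau_decay_ms: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise_ms < self.tau_decay_ms:
            raise ValueError("need 0 < tau_rise < tau_decay")

    @property
    def peak_time_ms(self) -> float:
        tr, td = self.tau_rise_ms, self.tau_decay_ms
        return tr * td / (td - tr) * math.log(td / tr)

    @property
    def norm(self) -> float:
        """Normalization so the biexponential difference peaks at 1."""
        tp = self.peak_time_ms
        return 1.0 / (math.exp(-tp / self.tau_decay_ms) - math.exp(-tp / self.tau_rise_ms))


@dataclass
class EndbulbInput:
    """One auditory-nerve terminal onto the model cell."""

    input_id: int
    asa_um2: float
    pr: float = DEFAULT_PR
    kernel: ConductanceKernel = field(default_factory=ConductanceKernel)
    target: int | None = None  # segment index; None = soma
    density_per_um2: float = SYNAPSE_DENSITY_PER_UM2

    def __post_init__(self) -> None:
        if not 0.0 <= self.pr <= 1.0:
            raise ValueError("Pr must be in [0, 1]")

    @property
    def n_sites(self) -> int:
        return n_sites(self.asa_um2, self.density_per_um2)


def release_events(
    presyn_times: np.ndarray,
    n_sites: int,
    pr: float,
    rng: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stochastic release: (event_times, site_indices).

    For every presynaptic spike each site independently draws a uniform
    number and releases when it falls below Pr; release latency jitter is
    not modelled, so events coincide with the presynaptic spike time.
    """
    if not 0.0 <= pr <= 1.0:
        raise ValueError("Pr must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    presyn_times = np.asarray(presyn_times, dtype=float)
    if len(presyn_times) == 0 or n_sites == 0 or pr == 0.0:
        return np.empty(0), np.empty(0, dtype=int)
    u = rng.random((len(presyn_times), n_sites))
    spike_idx, site_idx = np.nonzero(u < pr)
    return presyn_times[spike_idx], site_idx


def biexp_kernel(t_ms: np.ndarray, kernel: ConductanceKernel) -> np.ndarray:
    """Normalized biexponential evaluated at times >= 0 (peak = gmax)."""
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = (
        kernel.gmax_nS
        * kernel.norm
        * (np.exp(-t[pos] / kernel.tau_decay_ms) - np.exp(-t[pos] / kernel.tau_rise_ms))
    )
    return out


def conductance_trace(
    event_times_ms: np.ndarray,
    kernel: ConductanceKernel,
    t_ms: np.ndarray,
    nmda: bool = False,
) -> np.ndarray:
    """Superpose per-event kernels on a uniform time grid (nS).

    Linear summation of independent events; the kernel is truncated at
    25 decay time constants (relative amplitude < 2e-11).
    """
    t = np.asarray(t_ms, dtype=float)
    ev = np.sort(np.asarray(event_times_ms, dtype=float))
    g = np.zeros_like(t)
    if len(ev) == 0 or len(t) < 2:
        return g
    dt = t[1] - t[0]
    if nmda:
        k = ConductanceKernel(
            tau_rise_ms=kernel.nmda_tau_rise_ms,
            tau_decay_ms=kernel.nmda_tau_decay_ms,
            gmax_nS=kernel.gmax_nS * kernel.nmda_fraction,
        )
    else:
        k = kernel
    support = int(math.ceil(25.0 * k.tau_decay_ms / dt))
    idx0 = np.searchsorted(t, ev)  # first grid point at/after the event
    for e, i0 in zip(ev, idx0):
        if i0 >= len(t):
            continue
        offs = t[i0: i0 + support + 1] - e
        g[i0: i0 + len(offs)] += biexp_kernel(offs, k)
    return g


def ampa_rectification(V_mV, kernel: ConductanceKernel):
    """Voltage-dependent conductance scaling from polyamine channel block."""
    V = np.asarray(V_mV, dtype=float)
    f = kernel.rect_floor
    return f + (1.0 - f) / (1.0 + np.exp((V - kernel.rect_vhalf_mV) / kernel.rect_k_mV))


def nmda_block(V_mV, v_half: float = -15.0, k: float = 13.0):
    """Sigmoidal relief of the NMDA Mg2+ block with depolarization."""
    V = np.asarray(V_mV, dtype=float)
    return 1.0 / (1.0 + np.exp(-(V - v_half) / k))


def profile_to_csv(inputs: list[EndbulbInput], path) -> None:
    """Write an endbulb profile as CSV (input_id, asa_um2, Pr, target)."""
    import pandas as pd

    pd.DataFrame(
        {
            "input_id": [e.input_id for e in inputs],
            "asa_um2": [e.asa_um2 for e in inputs],
            "pr": [e.pr for e in inputs],
            "target": [e.target if e.target is not None else -1 for e in inputs],
        }
    ).to_csv(path, index=False)


def profile_from_csv(path) -> list[EndbulbInput]:
    import pandas as pd

    df = pd.read_csv(path)
    return [
        EndbulbInput(
            input_id=int(r.input_id),
            asa_um2=float(r.asa_um2),
            pr=float(r.pr),
            target=None if int(r.target) < 0 else int(r.target),
        )
        for r in df.itertuples()
    ]


def synaptic_current(
    g_nS: np.ndarray,
    V_mV: np.ndarray,
    kernel: ConductanceKernel,
) -> np.ndarray:
    """Instantaneous AMPA current (nA): g * rect(V) * (V - E_rev)."""
    return g_nS * 1e-3 * ampa_rectification(V_mV, kernel) * (V_mV - kernel.e_rev_mV)
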