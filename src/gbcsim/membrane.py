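"""Ion-channel kinetics and compartment decoration for bushy-cell models.

Kinetics are the standard ventral-cochlear-nucleus Hodgkin-Huxley
formulations derived from acutely isolated bushy neurons: a fast transient
Na+ current, high- and low-threshold K+ currents (KHT, KLT) and the
hyperpolarization-activated cation current (IH), with rate constants
measured at 22 degC and scaled to the 37 degC simulation temperature by
Q10 factors.

Decoration assigns maximal conductance densities per morphological tag:
somatic densities derive from whole-cell conductances measured in vitro,
axonal compartments use fixed ratios relative to the soma, and dendrites
follow one of three bracketing schemes (passive / half-active / active).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

from gbcsim.morphology import AXON_TAGS, DENDRITE_TAGS, Tag

__all__ = [
    "CHANNELS",
    "GATES",
    "ChannelSet",
    "DecorationScheme",
    "channel_rates",
    "gating_exponents",
    "steady_state_current",
    "decorate",
    "area_from_capacitance",
    "capacitance_from_area",
    "density_from_total",
    "total_from_density",
]

CHANNELS = ("Na", "KHT", "KLT", "IH", "Leak")

#: gating variables per channel and their exponents in the open probability
GATES: Mapping[str, tuple[tuple[str, int], ...]] = {
    "Na": (("m", 3), ("h", 1)),
    "KHT": (("n", 2), ("p", 1)),  # open prob = 0.85 n^2 + 0.15 p
    "KLT": (("w", 4), ("z", 1)),
    "IH": (("r", 1),),
    "Leak": (),
}

#: gates whose steady state increases with depolarization
ACTIVATION_GATES = frozenset({"m", "n", "p", "w", "r_inv"}) - {"r_inv"}

T_REF = 22.0  # degC, temperature of the source kinetic measurements
Q10_RATES = 3.0
Q10_COND = 2.0

#: Leak reversal is set below EK (chloride/pump-dominated leak) so that the
#: fully decorated reference cell rests near -62 mV despite the standing
#: IH depolarization; see the methods note.
REVERSALS_MV = {"Na": 55.0, "K": -70.0, "IH": -43.0, "Leak": -80.0}


def _q10_tau(T: float, q10: float = Q10_RATES) -> float:
    """Divide time constants by this factor when warming from T_REF to T."""
    return q10 ** ((T - T_REF) / 10.0)


def channel_rates(
    channel: str, V: float | np.ndarray, T: float = 37.0
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Steady states and time constants (ms) for each gate of a channel.

    Returns {gate: (inf, tau)} with V in mV.  Time constants are scaled
    from the 22 degC measurement temperature by Q10 = 3.
    """
    V = np.asarray(V, dtype=float)
    k = _q10_tau(T)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if channel == "Na":
        minf = 1.0 / (1.0 + np.exp(-(V + 38.0) / 7.0))
        hinf = 1.0 / (1.0 + np.exp((V + 65.0) / 6.0))
        taum = 10.0 / (5.0 * np.exp((V + 60.0) / 18.0) + 36.0 * np.exp(-(V + 60.0) / 25.0)) + 0.04
        tauh = 100.0 / (7.0 * np.exp((V + 60.0) / 11.0) + 10.0 * np.exp(-(V + 60.0) / 25.0)) + 0.6
        out = {"m": (minf, taum / k), "h": (hinf, tauh / k)}
    elif channel == "KHT":
        ninf = (1.0 / (1.0 + np.exp(-(V + 15.0) / 5.0))) ** 0.5
        pinf = 1.0 / (1.0 + np.exp(-(V + 23.0) / 6.0))
        taun = 100.0 / (11.0 * np.exp((V + 60.0) / 24.0) + 21.0 * np.exp(-(V + 60.0) / 23.0)) + 0.7
        taup = 100.0 / (4.0 * np.exp((V + 60.0) / 32.0) + 5.0 * np.exp(-(V + 60.0) / 22.0)) + 5.0
        out = {"n": (ninf, taun / k), "p": (pinf, taup / k)}
    elif channel == "KLT":
        winf = (1.0 / (1.0 + np.exp(-(V + 48.0) / 6.0))) ** 0.25
        zinf = 0.5 + 0.5 / (1.0 + np.exp((V + 71.0) / 10.0))
        tauw = 100.0 / (6.0 * np.exp((V + 60.0) / 6.0) + 16.0 * np.exp(-(V + 60.0) / 45.0)) + 1.5
        tauz = 1000.0 / (np.exp((V + 60.0) / 20.0) + np.exp(-(V + 60.0) / 8.0)) + 50.0
        out = {"w": (winf, tauw / k), "z": (zinf, tauz / k)}
    elif channel == "IH":
        rinf = 1.0 / (1.0 + np.exp((V + 76.0) / 7.0))
        taur = 1e5 / (237.0 * np.exp((V + 60.0) / 12.0) + 17.0 * np.exp(-(V + 60.0) / 14.0)) + 25.0
        out = {"r": (rinf, taur / k)}
    elif channel == "Leak":
        out = {}
    else:
        raise KeyError(f"unknown channel {channel!r}")
    return out


def gating_exponents(channel: str) -> tuple[tuple[str, int], ...]:
    return GATES[channel]


def open_probability(channel: str, gates: Mapping[str, np.ndarray]) -> np.ndarray:
    """Open probability from gate values (KHT mixes two gate populations)."""
    if channel == "Na":
        return gates["m"] ** 3 * gates["h"]
    if channel == "KHT":
        return 0.85 * gates["n"] ** 2 + 0.15 * gates["p"]
    if channel == "KLT":
        return gates["w"] ** 4 * gates["z"]
    if channel == "IH":
        return gates["r"]
    if channel == "Leak":
        return np.asarray(1.0)
    raise KeyError(channel)


def steady_state_current(
    channel: str, gbar_nS: float, V: float, T: float = 37.0
) -> float:
    """Steady-state current (nA) of a channel at clamped voltage V."""
    rates = channel_rates(channel, V, T)
    gates = {g: inf for g, (inf, _tau) in rates.items()}
    erev = REVERSALS_MV["K" if channel in ("KHT", "KLT") else channel]
    po = float(open_probability(channel, gates))
    return gbar_nS * 1e-3 * po * (V - erev)  # nS*mV = pA -> *1e-3 nA


def reversal_for(channel: str) -> float:
    return REVERSALS_MV["K" if channel in ("KHT", "KLT") else channel]


# -----------------------------------------------------------------------------
# Decoration
# -----------------------------------------------------------------------------

def _load_tables() -> dict:
    with resources.files("gbcsim.data").joinpath("decoration.json").open() as fh:
        return json.load(fh)


_TABLES = _load_tables()


@dataclass
class ChannelSet:
    """Maximal conductance densities (mS/cm^2) and reversal potentials."""

    densities: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in CHANNELS}
    )
    reversals: dict[str, float] = field(default_factory=lambda: dict(REVERSALS_MV))
    temperature: float = 37.0


@dataclass
class DecorationScheme:
    """Base somatic conductances plus axonal ratios and a dendrite mode.

    Base values are the whole-cell conductances of the reference somatic
    model (nS, at 37 degC); axon ratios and dendrite modes mirror the
    shipped decoration tables.
    """

    dendrite_mode: str = "half_active"
    somatic_base_nS: dict[str, float] = field(
        default_factory=lambda: dict(_TABLES["somatic_base_nS"])
    )
    somatic_leak_mS_cm2: float = _TABLES["somatic_leak_mS_cm2"]
    axon_ratios: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _TABLES["axon_ratios"].items()}
    )
    dendrite_modes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in _TABLES["dendrite_modes"].items()
        }
    )
    #: hook for Na inter-channel cooperativity; None = independent gating
    na_cooperativity: None = None

    def __post_init__(self) -> None:
        if self.dendrite_mode not in self.dendrite_modes:
            raise ValueError(f"unknown dendrite mode {self.dendrite_mode!r}")


def area_from_capacitance(c_pF: float, cm_uF_cm2: float = 0.9) -> float:
    """Membrane area (um^2) equivalent to a capacitance at specific cm."""
    return c_pF / cm_uF_cm2 * 100.0  # pF/(uF/cm^2) = 1e-6 cm^2 = 100 um^2


def capacitance_from_area(area_um2: float, cm_uF_cm2: float = 0.9) -> float:
    """Capacitance (pF) of a membrane area at specific cm."""
    return area_um2 * cm_uF_cm2 / 100.0


def density_from_total(g_nS: float, area_um2: float) -> float:
    """Convert a whole-cell conductance over an area to mS/cm^2."""
    return g_nS / area_um2 * 100.0


def total_from_density(density_mS_cm2: float, area_um2: float) -> float:
    """Convert a density (mS/cm^2) over an area (um^2) to nS."""
    return density_mS_cm2 * area_um2 / 100.0


_TAG_KEYS = {
    Tag.MYELINATED_AXON: "myelinated",
    Tag.AIS: "AIS",
    Tag.AXON_HILLOCK: "hillock",
}


def decorate(model, scheme: DecorationScheme, soma_area: float):
    """Assign per-segment channel densities according to a decoration scheme.

    ``soma_area`` is the reference membrane area (um^2) over which the base
    whole-cell conductances are spread; the standard choice is the
    capacitance-equivalent area of the in vitro reference measurement.
    Somatic density (mS/cm^2) = base nS / soma_area; axonal tags multiply
    the somatic density by their tabulated ratios; dendritic tags share the
    selected mode's relative densities, with leak set absolutely.
    Returns the model (mutated in place).
    """
    if soma_area <= 0:
        raise ValueError("soma_area must be positive")
    somatic = {
        ch: density_from_total(g, soma_area)
        for ch, g in scheme.somatic_base_nS.items()
    }
    somatic["Leak"] = scheme.somatic_leak_mS_cm2
    mode = scheme.dendrite_modes[scheme.dendrite_mode]

    for i, tag in enumerate(model.seg_tag):
        if tag is Tag.SOMA:
            dens = dict(somatic)
        elif tag in AXON_TAGS:
            ratios = scheme.axon_ratios[_TAG_KEYS[tag]]
            dens = {ch: somatic[ch] * ratios[ch] for ch in CHANNELS}
        elif tag in DENDRITE_TAGS:
            dens = {ch: somatic[ch] * mode[ch] for ch in ("Na", "KHT", "KLT", "IH")}
            dens["Leak"] = mode["Leak"]  # absolute, mS/cm^2
        else:
            raise ValueError(f"segment {i} carries unknown tag {tag}")
        for ch in CHANNELS:
            model.density[ch][i] = dens[ch]
    model.decorated = True
    return model
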