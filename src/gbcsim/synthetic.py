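"""Seeded generators for toy cells, endbulb profiles, phantoms and trains.

These generators reproduce the *statistical structure* the analysis code
assumes for globular bushy cells: somatic areas near 1352 um^2 (SD 168.1),
dendrite/soma area ratios near 2.76, a 2.3 um axon hillock, an AIS in the
14.2-21.4 um range, 5-12 convergent endbulbs per cell with apposed surface
areas (ASA) above 35 um^2, and spike trains with known phase structure for
oracle tests of the timing metrics.  Everything is deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from gbcsim.morphology import Morphology, Section, Tag

__all__ = [
    "CellTemplate",
    "EndbulbProfile",
    "sample_template",
    "make_toy_cell",
    "make_standard_axon",
    "make_endbulb_profile",
    "make_voxel_phantom",
    "make_control_trains",
]

#: fraction of total dendritic membrane per compartment class
DENDRITE_AREA_FRACTIONS = {
    "proximal_dendrite": 0.04,
    "hub": 0.10,
    "swelling": 0.28,
    "shaft": 0.58,
}


@dataclass
class CellTemplate:
    """Target geometry for a toy globular bushy cell."""

    soma_area: float = 1352.0  # um^2
    dendrite_ratio: float = 2.76  # dendrite area / soma area
    hillock_length: float = 2.3  # um
    ais_length: float = 16.8  # um, population mean; range 14.2-21.4
    ais_radius: float = 0.75  # um
    hillock_taper: tuple[float, float] = (1.5, 0.85)  # um radii, soma -> AIS
    myelinated_length: float = 30.0  # um
    myelinated_radius: float = 1.35  # um
    n_branches: int = 6  # branches leaving the primary hub (2-14)
    swellings_per_branch: int = 3
    proximal_length: float = 10.0  # um
    hub_length: float = 6.0  # um
    shaft_length: float = 60.0  # um per branch

    @property
    def dendrite_area(self) -> float:
        return self.soma_area * self.dendrite_ratio


@dataclass
class EndbulbProfile:
    """Convergent endbulb ASAs for one cell, sorted descending."""

    mode: str  # "coincidence" | "mixed"
    asas: np.ndarray  # um^2

    def __post_init__(self) -> None:
        self.asas = np.sort(np.asarray(self.asas, dtype=float))[::-1]

    @property
    def n_inputs(self) -> int:
        return len(self.asas)


def sample_template(seed: int | np.random.Generator = 0) -> CellTemplate:
    """Draw one cell template from the population statistics."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    soma = float(np.clip(rng.normal(1352.0, 168.1), 600.0, None))
    ratio = float(np.clip(rng.normal(2.76, 0.24), 1.5, None))
    hillock = float(np.clip(rng.normal(2.3, 0.9), 0.5, None))
    ais = float(rng.uniform(14.2, 21.4))
    nb = int(rng.integers(2, 15))
    return CellTemplate(
        soma_area=soma,
        dendrite_ratio=ratio,
        hillock_length=hillock,
        ais_length=ais,
        n_branches=nb,
    )


def _cyl(sid, parent, tag, p0, direction, length, radius) -> Section:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    p1 = np.asarray(p0, dtype=float) + d * length
    pts = np.array([[*p0, radius], [*p1, radius]])
    return Section(id=sid, parent_id=parent, tag=tag, points=pts)


def make_toy_cell(
    template: CellTemplate | None = None, seed: int = 0, cell_id: str = "toy"
) -> Morphology:
    """Construct a tagged toy morphology matching the template's areas.

    The soma is a cylinder of equal length and diameter (area pi*d^2, the
    same as the equivalent sphere).  One proximal dendrite leads to a
    primary hub from which ``n_branches`` shafts radiate, each interrupted
    by swelling sections; radii are solved analytically so that the
    per-tag areas hit the template's partition exactly.  The axon is a
    tapered hillock, a thin AIS, and a myelinated section.  Geometry is
    deterministic; ``seed`` only perturbs branch directions.
    """
    t = template or CellTemplate()
    rng = np.random.default_rng(seed)
    secs: list[Section] = []
    sid = 0

    # soma: cylinder with L = d, lateral area pi*d^2 = soma_area
    d_soma = math.sqrt(t.soma_area / math.pi)
    r_soma = d_soma / 2.0
    soma = _cyl(sid, None, Tag.SOMA, (0.0, 0.0, 0.0), (1, 0, 0), d_soma, r_soma)
    secs.append(soma)
    soma_id = sid
    sid += 1

    # axon: hillock (tapered) -> AIS -> myelinated, leaving -x end of soma
    r0, r1 = t.hillock_taper
    hp0 = np.array([0.0, 0.0, 0.0])
    hp1 = hp0 + np.array([-t.hillock_length, 0.0, 0.0])
    hillock = Section(
        id=sid,
        parent_id=soma_id,
        tag=Tag.AXON_HILLOCK,
        points=np.array([[*hp0, r0], [*hp1, r1]]),
    )
    secs.append(hillock)
    hillock_id = sid
    sid += 1
    ais = _cyl(sid, hillock_id, Tag.AIS, hp1, (-1, 0, 0), t.ais_length, t.ais_radius)
    secs.append(ais)
    ais_id = sid
    sid += 1
    my0 = hp1 + np.array([-t.ais_length, 0.0, 0.0])
    secs.append(
        _cyl(sid, ais_id, Tag.MYELINATED_AXON, my0, (-1, 0, 0),
             t.myelinated_length, t.myelinated_radius)
    )
    sid += 1

    # dendrites from the +x end of the soma
    A_dend = t.dendrite_area
    A_pd = A_dend * DENDRITE_AREA_FRACTIONS["proximal_dendrite"]
    A_hub = A_dend * DENDRITE_AREA_FRACTIONS["hub"]
    A_sw = A_dend * DENDRITE_AREA_FRACTIONS["swelling"]
    A_sh = A_dend * DENDRITE_AREA_FRACTIONS["shaft"]

    base = np.array([d_soma, 0.0, 0.0])
    r_pd = A_pd / (2.0 * math.pi * t.proximal_length)
    pd = _cyl(sid, soma_id, Tag.PROXIMAL_DENDRITE, base, (1, 0, 0),
              t.proximal_length, r_pd)
    secs.append(pd)
    pd_id = sid
    sid += 1

    hub_base = base + np.array([t.proximal_length, 0.0, 0.0])
    r_hub = A_hub / (2.0 * math.pi * t.hub_length)
    hub = _cyl(sid, pd_id, Tag.HUB, hub_base, (1, 0, 0), t.hub_length, r_hub)
    secs.append(hub)
    hub_id = sid
    sid += 1

    nb = t.n_branches
    if not 2 <= nb <= 14:
        raise ValueError("hub branch count must be in [2, 14]")
    A_sh_branch = A_sh / nb
    A_sw_each = A_sw / (nb * t.swellings_per_branch)
    d_sw = math.sqrt(A_sw_each / math.pi)  # swelling: cylinder with L = d
    branch_base = hub_base + np.array([t.hub_length, 0.0, 0.0])
    n_shaft_pieces = t.swellings_per_branch + 1
    piece_len = t.shaft_length / n_shaft_pieces
    r_shaft = A_sh_branch / (2.0 * math.pi * t.shaft_length)
    for b in range(nb):
        ang = 2.0 * math.pi * b / nb + rng.uniform(-0.1, 0.1)
        direction = np.array([1.0, 0.6 * math.cos(ang), 0.6 * math.sin(ang)])
        parent = hub_id
        p0 = branch_base.copy()
        for piece in range(n_shaft_pieces):
            sh = _cyl(sid, parent, Tag.DISTAL_DENDRITE, p0, direction,
                      piece_len, r_shaft)
            secs.append(sh)
            parent = sid
            sid += 1
            p0 = sh.points[-1, :3].copy()
            if piece < t.swellings_per_branch:
                sw = _cyl(sid, parent, Tag.SWELLING, p0, direction, d_sw, d_sw / 2.0)
                secs.append(sw)
                parent = sid
                sid += 1
                p0 = sw.points[-1, :3].copy()

    return Morphology(secs, cell_id=cell_id)


def make_standard_axon(
    hillock_length: float = 2.3,
    ais_length: float = 16.8,
    ais_radius: float = 0.75,
    hillock_taper: tuple[float, float] = (1.5, 0.85),
    myelinated_length: float = 30.0,
    myelinated_radius: float = 1.35,
) -> Morphology:
    """Population-average axon fragment (hillock + AIS + myelinated)."""
    r0, r1 = hillock_taper
    h = Section(
        id=0,
        parent_id=None,
        tag=Tag.AXON_HILLOCK,
        points=np.array([[0.0, 0.0, 0.0, r0], [-hillock_length, 0.0, 0.0, r1]]),
    )
    a = _cyl(1, 0, Tag.AIS, (-hillock_length, 0, 0), (-1, 0, 0), ais_length, ais_radius)
    m = _cyl(
        2, 1, Tag.MYELINATED_AXON,
        (-hillock_length - ais_length, 0, 0), (-1, 0, 0),
        myelinated_length, myelinated_radius,
    )
    return Morphology([h, a, m], cell_id="standard_axon")


# -----------------------------------------------------------------------------
# Endbulb profiles
# -----------------------------------------------------------------------------

def make_endbulb_profile(
    mode: str = "coincidence",
    n_inputs: int | None = None,
    seed: int = 0,
    asa_min: float = 35.0,
    mixed_threshold: float = 180.0,
    lognorm_mu: float = math.log(80.0),
    lognorm_sigma: float = 0.55,
) -> EndbulbProfile:
    """Draw one cell's convergent endbulb ASA profile.

    ASAs follow a right-skewed log-normal truncated below at 35 um^2 (the
    size threshold separating endbulbs from small boutons).  In coincidence
    mode every input stays below 180 um^2; in mixed mode the largest input
    is forced to at least 180 um^2.
    """
    if mode not in ("coincidence", "mixed"):
        raise ValueError("mode must be 'coincidence' or 'mixed'")
    rng = np.random.default_rng(seed)
    if n_inputs is None:
        n_inputs = int(rng.integers(5, 13))
    if not 5 <= n_inputs <= 12:
        raise ValueError("endbulb count must be in [5, 12]")

    def draw(n, lo, hi):
        out = []
        while len(out) < n:
            x = rng.lognormal(lognorm_mu, lognorm_sigma, size=4 * n)
            x = x[(x >= lo) & (x < hi)]
            out.extend(x.tolist())
        return np.array(out[:n])

    if mode == "coincidence":
        asas = draw(n_inputs, asa_min, mixed_threshold)
    else:
        rest = draw(n_inputs - 1, asa_min, mixed_threshold)
        largest = float(rng.uniform(mixed_threshold, 270.0))
        asas = np.concatenate([[largest], rest])
    return EndbulbProfile(mode=mode, asas=asas)


# -----------------------------------------------------------------------------
# Voxel phantoms
# -----------------------------------------------------------------------------

def make_voxel_phantom(
    kind: str,
    spacing_nm: tuple[float, float, float] = (11.0, 11.0, 60.0),
    face_um: float = 5.5,
    gap_um: float = 1.0,
    sphere_radius_um: float = 4.0,
    penetration_um: float = 2.0,
):
    """Build (terminal_volume, soma_volume, analytic_asa_um2) test phantoms.

    kinds:
      ``abutting_cuboids`` -- terminal cuboid sitting on a soma slab,
        sharing a flat square face of side ``face_um`` (contact normal
        along z); analytic area = face_um**2.
      ``separated``        -- same, but lifted by ``gap_um`` (analytic 0).
      ``sphere_on_plane``  -- spherical terminal sunk ``penetration_um``
        into a soma slab; analytic area is the submerged spherical cap,
        2*pi*R*p.  Steep caps (p near R/2) are measured accurately; very
        shallow caps are inflated by the z-staircase of the anisotropic
        grid, a documented limitation of the mesh/2 estimator.
    """
    from gbcsim.asa_voxel import LabelVolume

    sx, sy, sz = (s * 1e-3 for s in spacing_nm)  # um per voxel
    if kind in ("abutting_cuboids", "separated"):
        nxy = int(round(face_um / sx))
        pad = 16  # > dilation reach (6 voxels), with margin
        lift = int(round(gap_um / sz)) if kind == "separated" else 0
        nz_soma = 8
        nz_term = 6
        shape = (nxy + 2 * pad, nxy + 2 * pad, nz_soma + nz_term + lift + 12)
        term = np.zeros(shape, dtype=np.uint8)
        soma = np.zeros(shape, dtype=np.uint8)
        soma[:, :, :nz_soma] = 1
        z0 = nz_soma + lift
        term[pad: pad + nxy, pad: pad + nxy, z0: z0 + nz_term] = 1
        analytic = 0.0 if kind == "separated" else (nxy * sx) * (nxy * sy)
    elif kind == "sphere_on_plane":
        R = sphere_radius_um
        p = penetration_um
        r_contact = math.sqrt(max(R * R - (R - p) ** 2, 0.0))
        half_xy = r_contact + 1.5
        nx = int(round(2 * half_xy / sx))
        ny = int(round(2 * half_xy / sy))
        nz_soma = int(round(1.2 / sz)) + 4
        z_above = 1.2  # um of sphere kept above the plane (cropped phantom)
        nz = nz_soma + int(round(z_above / sz)) + 4
        shape = (nx, ny, nz)
        term = np.zeros(shape, dtype=np.uint8)
        soma = np.zeros(shape, dtype=np.uint8)
        soma[:, :, :nz_soma] = 1
        # sphere centre sits R - p above the slab surface
        cx, cy = nx // 2, ny // 2
        cz_um = nz_soma * sz + (R - p)
        xs = (np.arange(nx) - cx)[:, None, None] * sx
        ys = (np.arange(ny) - cy)[None, :, None] * sy
        zs = (np.arange(nz)[None, None, :] * sz) - cz_um
        inside = xs**2 + ys**2 + zs**2 <= R * R
        term[inside] = 1
        analytic = 2.0 * math.pi * R * p
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    va = LabelVolume(term, spacing_nm=spacing_nm)
    vb = LabelVolume(soma, spacing_nm=spacing_nm)
    return va, vb, float(analytic)


# -----------------------------------------------------------------------------
# Control spike trains
# -----------------------------------------------------------------------------

def make_control_trains(
    kind: str,
    duration_s: float = 1.0,
    n_trials: int = 10,
    rate_hz: float = 100.0,
    f_mod: float = 100.0,
    kappa: float = 2.0,
    dead_time_s: float = 0.7e-3,
    phase: float = 0.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Spike-train collections with known statistical structure.

    kinds: ``poisson`` (homogeneous), ``periodic`` (one spike per cycle of
    f_mod at fixed phase), ``von_mises`` (one spike per cycle with phase
    jitter of concentration kappa), ``dead_time_poisson`` (homogeneous with
    an absolute refractory period).  Returns a list of sorted spike-time
    arrays (seconds), one per trial.
    """
    rng = np.random.default_rng(seed)
    trains: list[np.ndarray] = []
    for _ in range(n_trials):
        if kind == "poisson":
            n = rng.poisson(rate_hz * duration_s)
            t = np.sort(rng.uniform(0.0, duration_s, size=n))
        elif kind == "periodic":
            period = 1.0 / f_mod
            t = np.arange(phase / (2 * np.pi) * period, duration_s, period)
        elif kind == "von_mises":
            period = 1.0 / f_mod
            cycles = np.arange(0.0, duration_s, period)
            ph = rng.vonmises(phase, kappa, size=len(cycles))  # [-pi, pi)
            t = np.sort(cycles + (ph + np.pi) / (2 * np.pi) * period)
            t = t[(t >= 0) & (t < duration_s)]
        elif kind == "dead_time_poisson":
            # thinning-free sequential generation with absolute dead time
            t_list = []
            now = 0.0
            while True:
                now += rng.exponential(1.0 / rate_hz)
                if t_list:
                    now = max(now, t_list[-1] + dead_time_s)
                if now >= duration_s:
                    break
                t_list.append(now)
            t = np.array(t_list)
        else:
            raise ValueError(f"unknown control train kind {kind!r}")
        trains.append(t)
    return trains
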