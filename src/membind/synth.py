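"""Seeded synthetic membrane-association trajectories with planted ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, at desk scale and with no force-field realism:

* a flat symmetric bilayer whose lipid species follow a stated composition
  (largest-remainder apportionment of mole fractions), with slow lateral
  lipid diffusion and periodic wrapping;
* a rigid-body protein (one bead per residue, plus designated backbone beads
  for the three orientation reference residues) that first diffuses freely in
  3D and then associates stably with one leaflet, driven by a Gaussian-well
  attraction of its binding-patch beads to the nearer leaflet surface;
* an emergent preferred orientation, because the attraction is strongest when
  the flat binding patch lies parallel to the membrane plane;
* planted local enrichment of chosen lipid types around chosen residues,
  implemented by swapping lateral lipid sites at the moment of first stable
  binding (type assignment in space, never biased forces), so that slow lipid
  diffusion preserves the enrichment over the bound portion of the run.

Everything is deterministic given the seed; replicate seeds are spawned from
the master seed with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (
    Frame,
    GeometryError,
    ParameterError,
    SelectionError,
    StabilityError,
    Topology,
    Trajectory,
    concat_topologies,
    min_image,
    LIPID_TYPE_ORDER,
    save_trajectory,
)

__all__ = [
    "MembraneSpec",
    "SyntheticParams",
    "SyntheticTruth",
    "EnrichmentSite",
    "PAPER_COMPOSITION",
    "apportion_lipids",
    "build_membrane",
    "build_protein",
    "planted_truth",
    "simulate_binding",
    "local_lipid_fraction",
    "save_replicates",
]

#: Mole fractions of the model plasma-membrane mixture used throughout:
#: 40% POPE, 25% CHOL, 15% POPS, 10% POPC, 7% POP2 (PIP2), 3% POP3 (PIP3).
PAPER_COMPOSITION = {
    "POPE": 0.40, "CHOL": 0.25, "POPS": 0.15,
    "POPC": 0.10, "POP2": 0.07, "POP3": 0.03,
}

# Bead templates per lipid type: (name, dx, dy, dz, subset), with dz measured
# from the bilayer centre toward the surface at +h/2.  Phospholipids put the
# headgroup at the surface and two tail beads inward; the phosphoinositides
# carry a laterally extended three-bead headgroup (the inositol-phosphate
# group is much bulkier than a PE/PC/PS headgroup); CHOL is a single
# mid-leaflet bead.
_TAIL_BEADS = (("T1", 0.0, 0.0, -0.7, "tail"), ("T2", 0.0, 0.0, -1.4, "tail"))
_PI_HEAD = (("HD", 0.0, 0.0, 0.0, "headgroup"),
            ("P4", 0.25, 0.14, 0.05, "headgroup"),
            ("P5", -0.25, 0.14, 0.05, "headgroup"),
            ("P1", 0.0, -0.28, 0.05, "headgroup"))
_BEAD_TEMPLATES = {
    "CHOL": (("ROH", 0.0, 0.0, -1.0, "whole"),),
    "POP2": _PI_HEAD + _TAIL_BEADS,
    "POP3": _PI_HEAD + _TAIL_BEADS,
}
_DEFAULT_PHOSPHO = (("HD", 0.0, 0.0, 0.0, "headgroup"),) + _TAIL_BEADS


def _beads_for(lipid_type: str):
    return _BEAD_TEMPLATES.get(lipid_type, _DEFAULT_PHOSPHO)


@dataclass(frozen=True)
class MembraneSpec:
    """Bilayer composition and geometry."""

    fractions: dict = field(default_factory=lambda: dict(PAPER_COMPOSITION))
    half_thickness: float = 2.0      # nm, bilayer centre to headgroup surface
    area_per_lipid: float = 0.40     # nm^2 per lipid per leaflet
    d_lipid: float = 5e-5            # lateral lipid diffusion constant, nm^2/ns

    def validate(self) -> None:
        vals = np.array(list(self.fractions.values()), dtype=float)
        if np.any(vals < 0):
            raise ParameterError("lipid mole fractions must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ParameterError(f"lipid mole fractions sum to {vals.sum()}, not 1")
        if self.half_thickness <= 0:
            raise ParameterError("half_thickness must be positive")


@dataclass(frozen=True)
class EnrichmentSite:
    """Planted local enrichment: ``lipid_type`` around ``residue`` within ``radius``."""

    residue: int
    lipid_type: str = "POP2"
    radius: float = 1.25     # nm
    gamma: float = 13.0      # local / global mole-fraction enrichment factor

    def validate(self) -> None:
        if self.gamma < 1:
            raise ParameterError("enrichment factor gamma must be >= 1")
        if self.radius <= 0:
            raise ParameterError("enrichment radius must be positive")


@dataclass
class SyntheticParams:
    """All knobs of one synthetic membrane-association experiment.

    The defaults define the reference study conditions of the generator:
    eight replicates of 1200 ns in a 20 x 20 x 26 nm box with 1000 lipids per
    leaflet of the standard composition, strong patch binding (6 kT per patch
    bead, 0.7 nm capture width) and diffusion constants typical of a ~100 kDa
    protein in water, with membrane-drag scaling once the patch engages.
    """

    seed: int = 0
    n_replicates: int = 8
    duration: float = 1200.0         # ns
    dt: float = 0.05                 # ns, integrator step
    save_every: int = 20             # steps between recorded frames (1 ns)
    box: tuple = (20.0, 20.0, 26.0)  # nm
    membrane: MembraneSpec = field(default_factory=MembraneSpec)
    n_lipids_per_leaflet: int = 1000
    # protein geometry (generated ellipsoid)
    n_residues: int = 60
    semi_axes: tuple = (3.8, 3.8, 1.5)
    patch_residues: tuple = ()       # default: the flat bottom disc (set by build)
    # dynamics
    epsilon: float = 6.0             # kT per patch bead, Gaussian-well depth
    sigma: float = 0.7               # nm, capture range (well width)
    d_trans: float = 0.05            # nm^2/ns, free translational diffusion
    d_rot: float = 0.05              # rad^2/ns, free rotational diffusion
    bound_mobility_scale: float = 0.001  # translational drag once stably bound
    bound_rotation_scale: float = 0.0004  # rotational drag once stably bound
    wall_k: float = 50.0             # kT/nm^2, soft repulsion inside the slab
    start_height: float = 6.0        # nm, initial protein COM above bilayer centre
    enrichment: tuple = ()           # tuple[EnrichmentSite]

    def validate(self) -> None:
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.duration < self.dt:
            raise ParameterError("duration must be at least one step")
        self.membrane.validate()
        for site in self.enrichment:
            site.validate()

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class SyntheticTruth:
    """Planted parameters used as ground truth in recovery tests."""

    theta_star: float                       # degrees, in [0, 180]
    patch_residues: tuple
    enrichment: tuple                       # tuple[EnrichmentSite]
    bound_fraction: float | None = None     # filled in by simulate_binding

    def to_dict(self) -> dict:
        return {
            "theta_star": self.theta_star,
            "patch_residues": list(self.patch_residues),
            "enrichment": [asdict(e) for e in self.enrichment],
            "bound_fraction": self.bound_fraction,
        }


# ---------------------------------------------------------------------------
# Membrane construction
# ---------------------------------------------------------------------------

def apportion_lipids(fractions: dict, n: int) -> dict:
    """Integer per-type lipid counts by largest-remainder apportionment.

    Ties in the fractional remainders are broken by the fixed type order
    POPE, CHOL, POPS, POPC, POP2, POP3 (then alphabetically for any other
    type), making the apportionment fully deterministic.
    """
    vals = np.array(list(fractions.values()), dtype=float)
    if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
        raise ParameterError("fractions must be non-negative and sum to 1")

    def order_key(t: str) -> tuple:
        try:
            return (0, LIPID_TYPE_ORDER.index(t))
        except ValueError:
            return (1, t)

    types = sorted(fractions, key=order_key)
    quotas = {t: fractions[t] * n for t in types}
    counts = {t: int(math.floor(quotas[t])) for t in types}
    short = n - sum(counts.values())
    by_remainder = sorted(types, key=lambda t: (-(quotas[t] - counts[t]),
                                                order_key(t)))
    for t in by_remainder[:short]:
        counts[t] += 1
    return counts


def _membrane_layout(spec: MembraneSpec, n_per_leaflet: int, box_xy: tuple,
                     rng: np.random.Generator):
    """Lateral site grid and per-molecule type assignment for ONE leaflet.

    Both leaflets use identical sites and types (mirror symmetry about z=0).
    Returns (types: (M,) str array, sites: (M,2) xy in the centred box).
    """
    lx, ly = float(box_xy[0]), float(box_xy[1])
    if n_per_leaflet * spec.area_per_lipid > lx * ly + 1e-9:
        raise GeometryError(
            f"{n_per_leaflet} lipids at {spec.area_per_lipid} nm^2 each do not "
            f"fit a {lx} x {ly} nm leaflet")
    counts = apportion_lipids(spec.fractions, n_per_leaflet)
    if n_per_leaflet < sum(1 for c in counts.values() if c > 0):
        raise ParameterError("fewer lipids than lipid types")

    nx = int(math.ceil(math.sqrt(n_per_leaflet * lx / ly)))
    ny = int(math.ceil(n_per_leaflet / nx))
    xs = (np.arange(nx) + 0.5) * lx / nx - lx / 2
    ys = (np.arange(ny) + 0.5) * ly / ny - ly / 2
    grid = np.array([(x, y) for y in ys for x in xs])[:n_per_leaflet]

    def order_key(t):
        try:
            return (0, LIPID_TYPE_ORDER.index(t))
        except ValueError:
            return (1, t)

    types = np.concatenate([np.repeat(t, counts[t])
                            for t in sorted(counts, key=order_key)])
    types = types[rng.permutation(n_per_leaflet)]
    return types, grid


def _membrane_topology(types_one_leaflet: np.ndarray, mol_id_offset: int = 0) -> Topology:
    """Topology of both leaflets given one leaflet's per-molecule types."""
    names, resids, resnames, mol_ids, subsets, ltypes = [], [], [], [], [], []
    mol = mol_id_offset
    for leaflet in (1, -1):
        for t in types_one_leaflet:
            for bead, _dx, _dy, _dz, subset in _beads_for(t):
                names.append(bead)
                resids.append(mol + 1)
                resnames.append(t)
                mol_ids.append(mol)
                subsets.append(subset)
                ltypes.append(t)
            mol += 1
    n = len(names)
    return Topology(
        names=np.array(names, dtype=object),
        resids=np.array(resids),
        resnames=np.array(resnames, dtype=object),
        mol_ids=np.array(mol_ids),
        mol_kinds=np.array(["lipid"] * n, dtype=object),
        lipid_types=np.array(ltypes, dtype=object),
        subsets=np.array(subsets, dtype=object),
        backbone=np.zeros(n, dtype=bool),
    )


def _lipid_positions(types: np.ndarray, sites_top: np.ndarray,
                     sites_bottom: np.ndarray, half_thickness: float) -> np.ndarray:
    """Bead positions of both leaflets from per-leaflet lateral sites."""
    rows = []
    for leaflet, sites in ((1, sites_top), (-1, sites_bottom)):
        for t, (x, y) in zip(types, sites):
            for _bead, dx, dy, dz, _subset in _beads_for(t):
                rows.append((x + dx, y + dy, leaflet * (half_thickness + dz)))
    return np.array(rows)


def build_membrane(spec: MembraneSpec, n_lipids_per_leaflet: int,
                   box_xy: tuple = (20.0, 20.0), box_z: float = 26.0,
                   rng: np.random.Generator | int | None = 0):
    """Construct a symmetric flat bilayer: two mirrored leaflets about z = 0.

    Per-type counts follow :func:`apportion_lipids`; both leaflets carry
    identical counts on identical lateral sites (so reflecting z maps one
    leaflet exactly onto the other).  ``rng`` shuffles the lateral assignment
    of types (default: a fixed seed, so the builder is deterministic).

    Returns ``(topology, frame)``.
    """
    spec.validate()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    types, sites = _membrane_layout(spec, n_lipids_per_leaflet, box_xy, rng)
    top = _membrane_topology(types)
    pos = _lipid_positions(types, sites, sites, spec.half_thickness)
    frame = Frame(time=0.0, box=np.array([box_xy[0], box_xy[1], box_z]),
                  positions=pos)
    frame.validate(top)
    return top, frame


# ---------------------------------------------------------------------------
# Protein construction
# ---------------------------------------------------------------------------

N_PATCH_CENTER = 1
N_PATCH_INNER = 5    # the default planted ring
N_PATCH_OUTER = 5
PATCH_INNER_RADIUS = 2.2
PATCH_OUTER_RADIUS = 3.6
PATCH_OUTER_OFFSET = 36.0  # degrees; keeps outer beads far from planted discs


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


def build_protein(params: SyntheticParams):
    """Rigid-body protein geometry in the body frame.

    Layout: a flat circular binding patch (centre bead, inner ring of 5,
    outer ring of 6, all at body z = -c) on the underside of an ellipsoid of
    semi-axes ``params.semi_axes``; the remaining residues sit on the upper
    ellipsoid surface; the last three residues are the orientation reference
    residues, a horizontal triangle ordered so that the cross-product plane
    normal points along body +z.  Reference residues carry an ``SC`` bead and
    a designated ``BB`` backbone bead (offset uniformly along body +z, which
    leaves the plane normal unchanged); all other residues are single ``SC``
    beads.

    Returns ``(topology, body_coords, patch_resids, reference_resids)``.
    """
    a, b, c = params.semi_axes
    n_patch = N_PATCH_CENTER + N_PATCH_INNER + N_PATCH_OUTER
    n_body = params.n_residues - n_patch - 3
    if n_body < 0:
        raise ParameterError("n_residues too small for the patch + reference layout")

    coords: list[tuple] = [(0.0, 0.0, -c)]
    for k in range(N_PATCH_INNER):
        ang = 2 * np.pi * k / N_PATCH_INNER
        coords.append((PATCH_INNER_RADIUS * np.cos(ang),
                       PATCH_INNER_RADIUS * np.sin(ang), -c))
    for k in range(N_PATCH_OUTER):
        ang = 2 * np.pi * k / N_PATCH_OUTER + math.radians(PATCH_OUTER_OFFSET)
        coords.append((PATCH_OUTER_RADIUS * np.cos(ang),
                       PATCH_OUTER_RADIUS * np.sin(ang), -c))

    # upper-body beads on the ellipsoid surface (z_unit > -0.3 keeps them
    # clear of the flat patch)
    unit = _fibonacci_sphere(3 * n_body)
    unit = unit[unit[:, 2] > -0.3][:n_body]
    coords.extend((a * u[0], b * u[1], c * u[2]) for u in unit)

    # reference triangle, horizontal at body z = +c/2, normal = +z
    r_ref = 1.5
    for ang in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
        coords.append((r_ref * np.cos(ang), r_ref * np.sin(ang), c / 2))

    body = np.array(coords)
    n_res = len(body)
    resids = np.arange(1, n_res + 1)
    patch_resids = tuple(int(r) for r in resids[:n_patch])
    ref_resids = tuple(int(r) for r in resids[-3:])

    names, p_resids, resnames, backbone, rows = [], [], [], [], []
    for i, r in enumerate(resids):
        names.append("SC"); p_resids.append(int(r)); resnames.append("GLY")
        backbone.append(False); rows.append(body[i])
        if int(r) in ref_resids:
            names.append("BB"); p_resids.append(int(r)); resnames.append("GLY")
            backbone.append(True); rows.append(body[i] + np.array([0, 0, 0.05]))
    body_particles = np.array(rows)
    n = len(names)
    top = Topology(
        names=np.array(names, dtype=object),
        resids=np.array(p_resids),
        resnames=np.array(resnames, dtype=object),
        mol_ids=np.zeros(n, dtype=np.int64),
        mol_kinds=np.array(["protein"] * n, dtype=object),
        lipid_types=np.array([""] * n, dtype=object),
        subsets=np.array([""] * n, dtype=object),
        backbone=np.array(backbone),
        reference_residues=ref_resids,
    )
    return top, body_particles, patch_resids, ref_resids


def default_enrichment(n_sites: int = 5, lipid_type: str = "POP2",
                       radius: float = 1.25, gamma: float = 13.0) -> tuple:
    """Enrichment sites on the inner patch ring (residues 2..6 by layout)."""
    if n_sites > N_PATCH_INNER:
        raise ParameterError(f"at most {N_PATCH_INNER} inner-ring sites available")
    return tuple(EnrichmentSite(residue=2 + k, lipid_type=lipid_type,
                                radius=radius, gamma=gamma)
                 for k in range(n_sites))


# ---------------------------------------------------------------------------
# Planted truth
# ---------------------------------------------------------------------------

def planted_truth(params: SyntheticParams, grid_points: int = 4000) -> SyntheticTruth:
    """Theoretical bound orientation from patch geometry alone (no simulation).

    Brute-force grid search over rotations: the bound-state score of a
    rotation depends only on which body direction ``u`` maps to the outward
    membrane normal, so the search runs over ``grid_points`` directions on the
    unit sphere.  For each ``u`` the protein is rested on the surface (lowest
    bead touching) and the score is the mean height of the patch beads above
    the surface; the minimiser is the theoretical bound orientation, and
    theta* is the angle between the reference-plane normal and ``u``.
    """
    params.validate()
    top, body, patch_resids, ref_resids = build_protein(params)
    patch = set(params.patch_residues or patch_resids)
    patch_idx = np.array([i for i, r in enumerate(top.resids) if int(r) in patch])
    if len(patch_idx) == 0:
        raise ParameterError("patch_residues select no particles")

    bb_idx = [np.flatnonzero((top.resids == r) & top.backbone)[0] for r in ref_resids]
    p1, p2, p3 = body[bb_idx[0]], body[bb_idx[1]], body[bb_idx[2]]
    normal = np.cross(p2 - p1, p3 - p1)
    normal = normal / np.linalg.norm(normal)

    dirs = _fibonacci_sphere(grid_points)
    heights = body @ dirs.T                       # (N, M) bead height along u
    score = (heights[patch_idx].mean(axis=0) - heights.min(axis=0))
    u = dirs[int(np.argmin(score))]
    theta = math.degrees(math.acos(float(np.clip(normal @ u, -1.0, 1.0))))
    return SyntheticTruth(theta_star=theta,
                          patch_residues=tuple(sorted(patch)),
                          enrichment=tuple(params.enrichment))


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> Rotation:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q))


def _patch_forces(z_beads: np.ndarray, patch_mask: np.ndarray, h2: float,
                  eps: float, sigma: float, wall_k: float, lz: float):
    """Per-bead z forces: patch Gaussian well toward the nearer leaflet
    surface plus a soft repulsive wall inside the slab.  Returns (fz, engaged,
    seated) where engagement is 'any patch bead within 3 sigma of a surface'
    and seated is 'mean patch |dz| < sigma'."""
    z = z_beads - lz * np.round(z_beads / lz)     # min image about the bilayer
    sign = np.where(z >= 0, 1.0, -1.0)
    dz = z - sign * h2
    fz = np.zeros_like(z)
    if eps > 0:
        g = np.exp(-dz[patch_mask] ** 2 / (2 * sigma ** 2))
        fz[patch_mask] += -eps * dz[patch_mask] / sigma ** 2 * g
    inside = np.abs(z) < h2
    fz[inside] += wall_k * (h2 - np.abs(z[inside])) * sign[inside]
    pdz = np.abs(dz[patch_mask])
    return fz, bool(np.any(pdz < 3 * sigma)), bool(pdz.mean() < sigma)


def _plant_enrichment(sites: tuple, planted_xy: dict, lip_xy: np.ndarray,
                      lip_types: np.ndarray, lip_leaflet: np.ndarray,
                      leaflet: int, box_xy: np.ndarray,
                      rng: np.random.Generator) -> None:
    """Swap lateral lipid sites (in place) so that, around each planted
    residue, the local mole fraction of its lipid type reaches
    min(gamma * global, 0.9).  Swapping positions conserves the composition
    exactly and involves no forces.

    Allocation is round-robin, one swap per site per pass, so a finite donor
    pool (only ~7% of the leaflet is POP2) is shared evenly between sites
    rather than exhausted by whichever site happens to be planted first.
    Takers are filled nearest-first, so the contact-reach core of each disc
    is enriched with certainty, not just in expectation.
    """
    in_leaf = lip_leaflet == leaflet
    max_r = max(s.radius for s in sites)
    site_xy = np.array([planted_xy[s.residue] for s in sites])

    def site_state(site):
        center = planted_xy[site.residue]
        d = np.linalg.norm(min_image(lip_xy - center, box_xy), axis=1)
        local = in_leaf & (d <= site.radius)
        n_local = int(local.sum())
        f_global = (lip_types == site.lipid_type).mean()
        target = int(round(min(site.gamma * f_global, 0.9) * n_local))
        have = int((local & (lip_types == site.lipid_type)).sum())
        return d, local, target - have

    progress = True
    while progress:
        progress = False
        for site in sites:
            d, local, deficit = site_state(site)
            if deficit <= 0:
                continue
            d_all = np.linalg.norm(
                min_image(lip_xy[:, None, :] - site_xy[None, :, :],
                          box_xy), axis=2).min(axis=1)
            donors = np.flatnonzero(in_leaf & (lip_types == site.lipid_type)
                                    & (d_all > max_r + 0.5))
            takers = np.flatnonzero(local & (lip_types != site.lipid_type))
            if len(donors) == 0 or len(takers) == 0:
                continue
            donor = int(rng.choice(donors))
            taker = int(takers[np.argmin(d[takers])])
            lip_xy[[donor, taker]] = lip_xy[[taker, donor]]
            progress = True


def simulate_binding(params: SyntheticParams):
    """Run the synthetic experiment; returns ``(trajectories, truth)``.

    The protein evolves by overdamped translational and rotational Langevin
    steps (kT = 1); lipid molecules perform lateral Brownian motion with
    periodic wrapping.  Deterministic given ``params.seed``: replicates use
    seeds spawned from the master seed, the noise stream per step has a fixed
    layout, and enrichment swaps draw from the same per-replicate stream.
    A displacement larger than half the box in one step raises
    :class:`StabilityError` advising a smaller dt.
    """
    params.validate()
    lx, ly, lz = params.box
    box_xy = np.array([lx, ly])
    h2 = params.membrane.half_thickness

    master = np.random.SeedSequence(params.seed)
    layout_rng = np.random.default_rng(master.spawn(1)[0])
    types, sites0 = _membrane_layout(params.membrane, params.n_lipids_per_leaflet,
                                     (lx, ly), layout_rng)
    mem_top = _membrane_topology(types)
    prot_top, body, patch_resids, ref_resids = build_protein(params)
    patch = tuple(params.patch_residues or patch_resids)
    truth = planted_truth(params)
    topology = concat_topologies(prot_top, mem_top, reference_residues=ref_resids)
    topology.validate()

    patch_mask = np.isin(prot_top.resids, patch)
    n_prot = prot_top.n_particles
    n_lip = len(types)                           # per leaflet
    lip_types2 = np.concatenate([types, types])  # both leaflets
    lip_leaflet = np.concatenate([np.ones(n_lip, int), -np.ones(n_lip, int)])
    planted_res_idx = {s.residue: np.flatnonzero(prot_top.resids == s.residue)[0]
                       for s in params.enrichment}

    n_steps = params.n_steps
    dt = params.dt
    rep_seeds = master.spawn(params.n_replicates)
    trajectories = []
    n_bound = 0

    for rep, seq in enumerate(rep_seeds):
        rng = np.random.default_rng(seq)
        com = np.array([0.0, 0.0, params.start_height])
        rot = _random_rotation(rng)
        lip_xy = np.concatenate([sites0, sites0]).astype(float)
        latched = False

        n_frames = n_steps // params.save_every
        positions = np.empty((n_frames, topology.n_particles, 3))
        times = np.empty(n_frames)
        f = 0
        lip_noise_scale = math.sqrt(2 * params.membrane.d_lipid * dt)

        for step in range(n_steps):
            beads = com + body @ rot.as_matrix().T
            fz, engaged, seated = _patch_forces(
                beads[:, 2], patch_mask, h2, params.epsilon, params.sigma,
                params.wall_k, lz)

            if not latched and seated and params.epsilon > 0:
                latched = True
                if params.enrichment:
                    planted_xy = {r: beads[i, :2]
                                  for r, i in planted_res_idx.items()}
                    leaflet = 1 if com[2] - lz * round(com[2] / lz) >= 0 else -1
                    _plant_enrichment(params.enrichment, planted_xy, lip_xy,
                                      lip_types2, lip_leaflet, leaflet,
                                      box_xy, rng)

            # membrane drag once stably bound; free diffusion while docking
            d_t = params.d_trans * (params.bound_mobility_scale if latched else 1.0)
            d_r = params.d_rot * (params.bound_rotation_scale if latched else 1.0)

            force = np.array([0.0, 0.0, fz.sum()])
            lever = beads - com
            torque = np.cross(lever, np.column_stack(
                [np.zeros_like(fz), np.zeros_like(fz), fz])).sum(axis=0)

            noise = rng.normal(size=6)
            dcom = d_t * force * dt + math.sqrt(2 * d_t * dt) * noise[:3]
            drot = d_r * torque * dt + math.sqrt(2 * d_r * dt) * noise[3:]
            lip_step = lip_noise_scale * rng.normal(size=(2 * n_lip, 2))

            if (np.max(np.abs(dcom)) > min(lx, ly, lz) / 2
                    or np.max(np.abs(lip_step)) > min(lx, ly) / 2):
                raise StabilityError(
                    "divergent step (displacement > box/2); reduce dt")

            com = com + dcom
            com -= np.array([lx, ly, lz]) * np.round(com / np.array([lx, ly, lz]))
            rot = Rotation.from_rotvec(drot) * rot
            lip_xy += lip_step
            lip_xy -= box_xy * np.round(lip_xy / box_xy)

            if (step + 1) % params.save_every == 0:
                beads = com + body @ rot.as_matrix().T
                lpos = _lipid_positions(types, lip_xy[:n_lip], lip_xy[n_lip:], h2)
                positions[f, :n_prot] = beads
                positions[f, n_prot:] = lpos
                times[f] = (step + 1) * dt
                f += 1

        traj = Trajectory(
            topology=topology, times=times,
            boxes=np.tile(np.array([lx, ly, lz]), (n_frames, 1)),
            positions=positions, replicate_id=rep,
            provenance={"generator": "membind.synth", "seed": int(params.seed),
                        "replicate": rep, "latched": latched},
        )
        traj.validate()
        trajectories.append(traj)
        n_bound += int(latched)

    truth.bound_fraction = n_bound / params.n_replicates
    return trajectories, truth


# ---------------------------------------------------------------------------
# Measurement helpers and persistence
# ---------------------------------------------------------------------------

def local_lipid_fraction(traj: Trajectory, residue: int, lipid_type: str,
                         radius: float, frames: np.ndarray | None = None) -> float:
    """Time-averaged local mole fraction of ``lipid_type`` among same-leaflet
    lipid molecules whose lateral (min-image) distance from ``residue`` is at
    most ``radius``.  Used to check the planted-enrichment contract."""
    top = traj.topology
    res_idx = top.residue_particles(residue)
    if len(res_idx) == 0:
        raise SelectionError(f"residue {residue} not in topology")
    res_idx = int(res_idx[0])
    lip = top.lipid_mask
    mol_ids = top.mol_ids[lip]
    mols, first = np.unique(mol_ids, return_index=True)
    mol_type = top.lipid_types[lip][first]
    lip_particle_rows = np.flatnonzero(lip)
    # one representative particle per molecule (first bead)
    rep_rows = lip_particle_rows[first]

    if frames is None:
        frames = np.arange(traj.n_frames)
    fracs = []
    for i in frames:
        box = traj.boxes[i]
        ppos = traj.positions[i, res_idx]
        mpos = traj.positions[i, rep_rows]
        same_leaflet = np.sign(mpos[:, 2]) == np.sign(
            ppos[2] - box[2] * round(ppos[2] / box[2]) or 1.0)
        d = np.linalg.norm(min_image(mpos[:, :2] - ppos[:2], box[:2]), axis=1)
        near = same_leaflet & (d <= radius)
        if near.sum() == 0:
            continue
        fracs.append((mol_type[near] == lipid_type).mean())
    return float(np.mean(fracs)) if fracs else 0.0


def save_replicates(trajectories, truth: SyntheticTruth, outdir: str | Path) -> None:
    """Write each replicate as GRO + XTC plus a JSON truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for traj in trajectories:
        stem = f"replicate_{traj.replicate_id:02d}"
        save_trajectory(traj, outdir / f"{stem}.gro", outdir / f"{stem}.xtc")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
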