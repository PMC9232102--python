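"""Orientation-angle and distance analysis with periodic-boundary corrections.

The orientation of the protein relative to the bilayer is the angle θ between
the normal of a plane through the backbone particles of three reference
residues (416, 1011 and 1194 by default) and the membrane-normal z axis; the
protein-membrane separation is the z component of the COM difference.  Under
periodic boundaries the protein may bind the far leaflet by travelling
through the z boundary, in which case the raw separation is negative and the
raw angle is reflected; the correction applied frame-wise whenever
zdist_uncorrected < 0 is

    θ = 180° − θ_uncorrected,      zdist = −zdist_uncorrected,

after which θ and zdist describe the protein-leaflet geometry independently
of which leaflet was bound.  The cross-product point order is fixed and the
normal is never absolute-valued, so θ spans the full [0°, 180°] — the
correction would be meaningless on a half-range angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    EmptyInputError,
    GeometryError,
    GroupSpec,
    ParameterError,
    SelectionError,
    Trajectory,
    select_group,
)

__all__ = [
    "BoundSelection",
    "StateDensity2D",
    "DensityProfile",
    "plane_normal_angle",
    "com_z_separation",
    "apply_pbc_correction",
    "orientation_series",
    "state_density_2d",
    "select_bound_replicates",
    "z_density_profile",
]

ORIENTATION_COLUMNS = ("time", "theta_uncorrected", "zdist_uncorrected",
                       "theta", "zdist")


def plane_normal_angle(p1, p2, p3, axis=(0.0, 0.0, 1.0)) -> float:
    """Angle (degrees, in [0, 180]) between the plane through p1,p2,p3 and ``axis``.

    Computed as arccos(n̂·axis) with n = (p2-p1) x (p3-p1); invariant to rigid
    translation of the three points.  Collinear points raise
    :class:`GeometryError`.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    n = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        raise GeometryError("reference points are collinear (degenerate plane)")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    c = float(np.clip(n @ axis / norm, -1.0, 1.0))
    return math.degrees(math.acos(c))


def com_z_separation(frame, protein: GroupSpec | np.ndarray,
                     membrane: GroupSpec | np.ndarray,
                     weights: np.ndarray | None = None,
                     wrap: bool = True) -> float:
    """Signed z distance COM(protein) − COM(membrane), positive when the
    protein sits above the membrane centre of mass.

    ``weights`` are optional per-particle masses (per group, concatenated
    protein-then-membrane); uniform weights otherwise.  With ``wrap`` the
    difference is folded by the box z length into (−Lz/2, Lz/2], mirroring the
    convention of analysing a protein centred in the periodic box.
    """
    p_idx = protein.indices if isinstance(protein, GroupSpec) else np.asarray(protein)
    m_idx = membrane.indices if isinstance(membrane, GroupSpec) else np.asarray(membrane)
    if len(p_idx) == 0 or len(m_idx) == 0:
        raise SelectionError("empty group in COM separation")
    if weights is None:
        wp = wm = None
    else:
        wp, wm = weights[:len(p_idx)], weights[len(p_idx):]
    zp = np.average(frame.positions[p_idx, 2], weights=wp)
    zm = np.average(frame.positions[m_idx, 2], weights=wm)
    d = float(zp - zm)
    if wrap and np.isfinite(frame.box[2]):
        lz = frame.box[2]
        d -= lz * round(d / lz)
    return d


def apply_pbc_correction(theta_uncorrected: float,
                         zdist_uncorrected: float) -> tuple[float, float]:
    """Fold a raw (θ, zdist) pair onto the bound-leaflet convention.

    When the raw separation is negative (protein below the bilayer centre,
    i.e. bound to the far leaflet through the boundary) return
    (180° − θ, −zdist); otherwise the identity.  Output zdist is always ≥ 0,
    so re-applying the correction to corrected records is the identity.
    """
    if not 0.0 <= theta_uncorrected <= 180.0:
        raise ParameterError(
            f"theta_uncorrected={theta_uncorrected} outside [0, 180]")
    if zdist_uncorrected < 0:
        return 180.0 - theta_uncorrected, -zdist_uncorrected
    return theta_uncorrected, zdist_uncorrected


def orientation_series(traj: Trajectory,
                       reference_residues: tuple[int, int, int] | None = None,
                       ) -> pd.DataFrame:
    """Per-frame orientation records for one trajectory.

    Returns a DataFrame with columns ``time, theta_uncorrected,
    zdist_uncorrected, theta, zdist``; the PBC correction is applied
    frame-wise.  Reference residues default to the topology's triple and must
    each resolve to a designated backbone particle.
    """
    top = traj.topology
    refs = tuple(reference_residues or top.reference_residues)
    try:
        bb = [top.backbone_particle(r) for r in refs]
    except ConfigurationError as exc:
        raise ConfigurationError(
            f"orientation reference residues {refs} unavailable: {exc}") from exc
    prot = select_group(top, "protein")
    memb = select_group(top, "membrane")

    rows = np.empty((traj.n_frames, 5))
    for i in range(traj.n_frames):
        frame = traj.frame(i)
        th_u = plane_normal_angle(frame.positions[bb[0]],
                                  frame.positions[bb[1]],
                                  frame.positions[bb[2]])
        zd_u = com_z_separation(frame, prot, memb)
        th, zd = apply_pbc_correction(th_u, zd_u)
        rows[i] = (frame.time, th_u, zd_u, th, zd)
    return pd.DataFrame(rows, columns=list(ORIENTATION_COLUMNS))


@dataclass
class StateDensity2D:
    """2D histogram of (zdist, θ) over all ingested frames."""

    zdist_edges: np.ndarray
    theta_edges: np.ndarray
    counts: np.ndarray          # (n_zbins, n_thetabins), in-range frames
    density: np.ndarray         # counts normalised to sum to 1
    n_frames: int               # total frames ingested
    n_overflow: int             # frames outside the binned range

    def to_frame(self) -> pd.DataFrame:
        zc = 0.5 * (self.zdist_edges[:-1] + self.zdist_edges[1:])
        tc = 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])
        zz, tt = np.meshgrid(zc, tc, indexing="ij")
        return pd.DataFrame({"zdist": zz.ravel(), "theta": tt.ravel(),
                             "count": self.counts.ravel().astype(int),
                             "density": self.density.ravel()})


def state_density_2d(series, zdist_edges: np.ndarray | None = None,
                     theta_edges: np.ndarray | None = None,
                     zdist_bin: float = 0.1, theta_bin: float = 2.0,
                     ) -> StateDensity2D:
    """Distance-orientation density of states pooled over replicates.

    ``series`` is one orientation DataFrame or an iterable of them (one per
    replicate); corrected (θ, zdist) values are histogrammed.  Default bins
    are 0.1 nm x 2°, covering the observed range; frames outside explicit
    user-provided edges are counted in ``n_overflow`` and reported, never
    silently dropped from the frame total.
    """
    if isinstance(series, pd.DataFrame):
        series = [series]
    series = list(series)
    if not series or sum(len(s) for s in series) == 0:
        raise EmptyInputError("no orientation records to histogram")
    zd = np.concatenate([np.asarray(s["zdist"]) for s in series])
    th = np.concatenate([np.asarray(s["theta"]) for s in series])

    if zdist_edges is None:
        hi = max(zdist_bin, float(np.ceil(zd.max() / zdist_bin)) * zdist_bin)
        zdist_edges = np.arange(0.0, hi + zdist_bin / 2, zdist_bin)
    if theta_edges is None:
        theta_edges = np.arange(0.0, 180.0 + theta_bin / 2, theta_bin)
    zdist_edges = np.asarray(zdist_edges, dtype=float)
    theta_edges = np.asarray(theta_edges, dtype=float)

    in_range = ((zd >= zdist_edges[0]) & (zd <= zdist_edges[-1])
                & (th >= theta_edges[0]) & (th <= theta_edges[-1]))
    counts, _, _ = np.histogram2d(zd[in_range], th[in_range],
                                  bins=[zdist_edges, theta_edges])
    total_in = counts.sum()
    density = counts / total_in if total_in > 0 else counts
    return StateDensity2D(zdist_edges=zdist_edges, theta_edges=theta_edges,
                          counts=counts, density=density,
                          n_frames=len(zd),
                          n_overflow=int(len(zd) - in_range.sum()))


@dataclass(frozen=True)
class BoundSelection:
    """Criteria deciding which replicates reached the preferred bound state.

    A replicate qualifies iff its final-frame corrected θ lies in the closed
    ``theta_window`` (default [6°, 12°]) and its final-frame zdist is
    strictly below ``max_zdist`` (default 4.5 nm) — closed window, strict
    distance, matching the printed inequality forms.  ``endpoint`` may be set
    to ``"window_mean"`` to average over the trailing ``window_ns`` instead of
    reading the literal final frame.
    """

    theta_window: tuple = (6.0, 12.0)
    max_zdist: float = 4.5
    window_ns: float = 500.0
    endpoint: str = "final"

    def __post_init__(self) -> None:
        lo, hi = self.theta_window
        if lo > hi:
            raise ParameterError("theta window bounds out of order")
        if self.max_zdist <= 0:
            raise ParameterError("max zdist must be positive")


def select_bound_replicates(series_by_replicate: dict,
                            selection: BoundSelection = BoundSelection(),
                            ) -> list:
    """Replicate ids whose endpoint satisfies the bound-state criteria."""
    chosen = []
    for rep, s in series_by_replicate.items():
        if len(s) == 0:
            raise EmptyInputError(f"replicate {rep} has an empty series")
        if selection.endpoint == "window_mean":
            tail = s[s["time"] >= s["time"].iloc[-1] - selection.window_ns]
            theta, zdist = float(tail["theta"].mean()), float(tail["zdist"].mean())
        else:
            theta = float(s["theta"].iloc[-1])
            zdist = float(s["zdist"].iloc[-1])
        lo, hi = selection.theta_window
        if lo <= theta <= hi and zdist < selection.max_zdist:
            chosen.append(rep)
    return sorted(chosen)


@dataclass
class DensityProfile:
    """Per-group number density along z relative to the membrane COM."""

    centers: np.ndarray
    densities: dict                # group name -> (nbins,) nm^-3
    bin_width: float
    n_frames: int
    symmetrized: bool
    empty: bool = False
    area: float = float("nan")     # mean lateral box area, nm^2

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"z": self.centers})
        for name, rho in self.densities.items():
            out[name] = rho
        return out


def z_density_profile(trajectories, groups,
                      window_ns: float = 500.0, bin_width: float = 0.1,
                      symmetrize: bool = True) -> DensityProfile:
    """Symmetrised number-density profiles of particle groups along z.

    For every frame inside the final ``window_ns`` of each qualifying
    trajectory, each group's particle z coordinates are taken relative to
    that frame's membrane (all-lipid) centre of mass, folded by the box into
    (−Lz/2, Lz/2], and histogrammed; densities are number densities
    (particles nm⁻³) averaged over frames and, when requested, symmetrised as
    ρ_sym(z) = (ρ(z) + ρ(−z)) / 2 on bins paired exactly about z = 0.

    An empty trajectory list returns an explicit empty-result profile
    (``empty=True``) rather than failing silently.
    """
    trajectories = list(trajectories)
    if not trajectories:
        return DensityProfile(centers=np.array([]), densities={},
                              bin_width=bin_width, n_frames=0,
                              symmetrized=symmetrize, empty=True)
    top = trajectories[0].topology
    resolved = [g if isinstance(g, GroupSpec) else select_group(top, g)
                for g in groups]
    memb = select_group(top, "membrane")

    lz = float(trajectories[0].boxes[0][2])
    nhalf = int(np.ceil(lz / 2 / bin_width))
    edges = np.arange(-nhalf, nhalf + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = {g.name: np.zeros(len(centers)) for g in resolved}
    n_frames = 0
    areas = []
    for traj in trajectories:
        mask = traj.window_mask(window_ns)
        for i in np.flatnonzero(mask):
            frame = traj.frame(i)
            z_mem = float(np.mean(frame.positions[memb.indices, 2]))
            areas.append(frame.box[0] * frame.box[1])
            for g in resolved:
                rel = frame.positions[g.indices, 2] - z_mem
                rel -= frame.box[2] * np.round(rel / frame.box[2])
                h, _ = np.histogram(rel, bins=edges)
                counts[g.name] += h
            n_frames += 1
    if n_frames == 0:
        return DensityProfile(centers=centers, densities={},
                              bin_width=bin_width, n_frames=0,
                              symmetrized=symmetrize, empty=True)
    area = float(np.mean(areas))
    densities = {}
    for name, c in counts.items():
        rho = c / (n_frames * area * bin_width)
        if symmetrize:
            rho = 0.5 * (rho + rho[::-1])
        densities[name] = rho
    return DensityProfile(centers=centers, densities=densities,
                          bin_width=bin_width, n_frames=n_frames,
                          symmetrized=symmetrize, area=area)
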