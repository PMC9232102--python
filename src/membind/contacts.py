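"""Molecule-level protein-lipid contact fingerprints, hotspots, convergence.

A contact is counted at molecule level: a lipid molecule contributes at most
one contact to a given (residue, lipid group) cell per frame, no matter how
many of its particles fall within the cutoff (0.55 nm by default, closed:
distance ≤ cutoff counts, compared on squared distances so the boundary case
is exact).  The lipid groups are the phospholipid headgroups per type plus
whole-molecule CHOL; the protein side uses every particle of each residue.
Distances obey the minimum-image convention in x, y and z (scipy cKDTree with
a periodic box does the neighbour search; correctness is pinned to an
all-pairs brute-force oracle in the tests).

Normalisation follows the per-group max convention: within each lipid group,
every residue's total is divided by the group's largest total, so the residue
with the most contacts has the normalised value 1.  Residues whose normalised
contact with the PIP2 (POP2) headgroup group exceeds 0.8 are called hotspots.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import (
    Frame,
    ParameterError,
    SelectionError,
    Topology,
    Trajectory,
)

__all__ = [
    "lipid_group_names",
    "frame_contacts",
    "accumulate_contacts",
    "pool_tables",
    "normalize_contacts",
    "hotspot_residues",
    "convergence_curve",
]

#: Canonical column order of the contact tables.
GROUP_ORDER = ("POPC headgroup", "POPE headgroup", "POPS headgroup",
               "POP2 headgroup", "POP3 headgroup", "CHOL")


def _group_of(lipid_type: str) -> str:
    return "CHOL" if lipid_type == "CHOL" else f"{lipid_type} headgroup"


def lipid_group_names(topology: Topology) -> list:
    """Contact-table columns for the lipid types present, in canonical order."""
    present = {_group_of(t) for t in np.unique(
        topology.lipid_types[topology.lipid_mask])}
    ordered = [g for g in GROUP_ORDER if g in present]
    ordered += sorted(present - set(GROUP_ORDER))
    return ordered


def _lipid_subset_rows(topology: Topology):
    """Particle rows tested for contacts (headgroups; CHOL whole), with their
    molecule ids and group labels."""
    lip = topology.lipid_mask
    tested = lip & ((topology.subsets == "headgroup") | (topology.subsets == "whole"))
    rows = np.flatnonzero(tested)
    groups = np.array([_group_of(t) for t in topology.lipid_types[rows]],
                      dtype=object)
    return rows, topology.mol_ids[rows], groups


def frame_contacts(frame: Frame, topology: Topology,
                   cutoff: float = 0.55) -> pd.DataFrame:
    """Per-(residue, lipid group) molecule-level contact counts for one frame."""
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    box = np.asarray(frame.box, dtype=float)
    if not np.all(box > 0) or not np.all(np.isfinite(box)):
        raise ParameterError("frame has no valid periodic box")

    resids = topology.protein_resids()
    groups = lipid_group_names(topology)
    table = pd.DataFrame(0, index=pd.Index(resids, name="residue"),
                         columns=groups, dtype=np.int64)

    prot_rows = np.flatnonzero(topology.protein_mask)
    lip_rows, lip_mols, lip_groups = _lipid_subset_rows(topology)
    if len(prot_rows) == 0 or len(lip_rows) == 0:
        return table

    ppos = np.mod(frame.positions[prot_rows], box)
    lpos = np.mod(frame.positions[lip_rows], box)
    # np.mod can round a tiny negative onto the upper box face exactly
    ppos[ppos >= box] = 0.0
    lpos[lpos >= box] = 0.0

    ptree = cKDTree(ppos, boxsize=box)
    ltree = cKDTree(lpos, boxsize=box)
    neighbours = ptree.query_ball_tree(ltree, r=cutoff)

    cutoff2 = cutoff * cutoff
    seen: set = set()
    for pi, ls in enumerate(neighbours):
        if not ls:
            continue
        resid = int(topology.resids[prot_rows[pi]])
        # re-check on squared distances so the closed-boundary convention is
        # exactly the oracle's
        d = lpos[ls] - ppos[pi]
        d -= box * np.round(d / box)
        ok = np.einsum("ij,ij->i", d, d) <= cutoff2
        for li, good in zip(ls, ok):
            if good:
                seen.add((resid, str(lip_groups[li]), int(lip_mols[li])))
    for resid, group, _mol in seen:
        table.at[resid, group] += 1
    table.attrs = {"frames": 1, "cutoff": cutoff}
    return table


def accumulate_contacts(traj: Trajectory, window_ns: float = 1000.0,
                        cutoff: float = 0.55) -> pd.DataFrame:
    """Contact totals over all frames within the final ``window_ns``.

    If the trajectory is shorter than the window the whole trajectory is used
    and the table metadata flags ``full_trajectory``.
    """
    span = float(traj.times[-1] - traj.times[0])
    mask = traj.window_mask(window_ns)
    full = span < window_ns
    total = None
    for i in np.flatnonzero(mask):
        t = frame_contacts(traj.frame(i), traj.topology, cutoff=cutoff)
        total = t if total is None else total.add(t, fill_value=0)
    if total is None:
        raise ParameterError("window selects zero frames")
    total = total.astype(np.int64)
    total.attrs = {
        "frames": int(mask.sum()),
        "window_requested_ns": window_ns,
        "window_used_ns": window_ns if not full else span,
        "full_trajectory": bool(full),
        "cutoff": cutoff,
        "replicate_id": traj.replicate_id,
    }
    return total


def pool_tables(tables) -> pd.DataFrame:
    """Element-wise sum of contact tables (pooling frames or replicates)."""
    tables = list(tables)
    if not tables:
        raise ParameterError("no tables to pool")
    total = tables[0].copy()
    for t in tables[1:]:
        total = total.add(t, fill_value=0)
    total = total.astype(np.int64)
    total.attrs = {"frames": sum(t.attrs.get("frames", 0) for t in tables),
                   "cutoff": tables[0].attrs.get("cutoff")}
    return total


def normalize_contacts(table: pd.DataFrame) -> pd.DataFrame:
    """Per-lipid-group max-normalised fingerprint.

    Within each group every residue's total is divided by the group maximum;
    groups with zero total contacts come out all-zero and are listed in
    ``attrs["zero_groups"]`` (no division error).  ``attrs["argmax"]`` records
    the top residue per group.
    """
    norm = table.astype(float).copy()
    argmax: dict = {}
    zero_groups = []
    for g in table.columns:
        m = table[g].max()
        if m > 0:
            norm[g] = table[g] / m
            argmax[g] = int(table[g].idxmax())
        else:
            norm[g] = 0.0
            zero_groups.append(g)
    norm.attrs = dict(table.attrs)
    norm.attrs["argmax"] = argmax
    norm.attrs["zero_groups"] = zero_groups
    return norm


def hotspot_residues(norm: pd.DataFrame, group: str = "POP2 headgroup",
                     threshold: float = 0.8) -> list:
    """Residues whose normalised contact with ``group`` is strictly above
    ``threshold``, sorted by descending value."""
    if group not in norm.columns:
        raise SelectionError(f"unknown lipid group '{group}'")
    col = norm[group]
    hot = col[col > threshold].sort_values(ascending=False)
    return [int(r) for r in hot.index]


def convergence_curve(tables_by_replicate, group: str = "POP2 headgroup",
                      subset_sizes=None, n_draws: int = 20,
                      seed: int = 0) -> pd.DataFrame:
    """Replicate-subset convergence of the normalised contact profile.

    For each subset size k, ``n_draws`` pairs of disjoint k-replicate subsets
    are drawn; each subset's contact tables are pooled, normalised, and the
    Pearson correlation of the paired ``group`` profiles is recorded.
    Deterministic given ``seed``.  Requires max(k) ≤ floor(n_replicates / 2).
    """
    tables = list(tables_by_replicate)
    n = len(tables)
    if n < 2:
        raise ParameterError("convergence analysis needs at least 2 replicates")
    if subset_sizes is None:
        subset_sizes = list(range(1, n // 2 + 1))
    subset_sizes = list(subset_sizes)
    if max(subset_sizes) > n // 2:
        raise ParameterError(
            f"subset size {max(subset_sizes)} exceeds floor(n/2) = {n // 2}")
    if group not in tables[0].columns:
        raise SelectionError(f"unknown lipid group '{group}'")

    rng = np.random.default_rng(seed)
    rows = []
    for k in subset_sizes:
        rs = []
        for _ in range(n_draws):
            perm = rng.permutation(n)
            a = normalize_contacts(pool_tables([tables[i] for i in perm[:k]]))
            b = normalize_contacts(pool_tables([tables[i] for i in perm[k:2 * k]]))
            rs.append(_pearson(a[group].to_numpy(), b[group].to_numpy()))
        rows.append((k, float(np.mean(rs)), float(np.std(rs, ddof=0)), n_draws))
    out = pd.DataFrame(rows, columns=["k", "mean_correlation",
                                      "sd_correlation", "n_draws"])
    out.attrs = {"group": group, "seed": seed}
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return 1.0 if np.allclose(x, y) else 0.0
    return float(np.corrcoef(x, y)[0, 1])
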