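"""Shared fixtures: the reference synthetic runs and small hand-built systems."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from membind import contacts as ct
from membind.core import Frame, Topology, Trajectory
from membind.synth import (
    SyntheticParams,
    default_enrichment,
    simulate_binding,
)

RECOVERY_SEED = 1
PLANTED_RESIDUES = (2, 3, 4, 5, 6)


@pytest.fixture(scope="session")
def recovery_run():
    """The reference strong-binding experiment: 8 replicates with 5 planted
    PIP2-enrichment residues, under the generator's default conditions."""
    params = SyntheticParams(seed=RECOVERY_SEED, enrichment=default_enrichment())
    trajs, truth = simulate_binding(params)
    tables = [ct.accumulate_contacts(t) for t in trajs]
    return {"params": params, "trajs": trajs, "truth": truth, "tables": tables}


@pytest.fixture(scope="session")
def variant_run():
    """The neutralised-sites analogue: identical conditions and seed but the
    planted enrichment removed (the alanine-substitution counterpart)."""
    params = SyntheticParams(seed=RECOVERY_SEED)
    trajs, truth = simulate_binding(params)
    tables = [ct.accumulate_contacts(t) for t in trajs]
    return {"params": params, "trajs": trajs, "truth": truth, "tables": tables}


def make_topology(particles, reference_residues=(1, 2, 3)):
    """Build a Topology from rows of
    (name, resid, resname, mol_id, kind, lipid_type, subset, backbone)."""
    cols = list(zip(*particles))
    return Topology(
        names=np.array(cols[0], dtype=object),
        resids=np.array(cols[1]),
        resnames=np.array(cols[2], dtype=object),
        mol_ids=np.array(cols[3]),
        mol_kinds=np.array(cols[4], dtype=object),
        lipid_types=np.array(cols[5], dtype=object),
        subsets=np.array(cols[6], dtype=object),
        backbone=np.array(cols[7], dtype=bool),
        reference_residues=reference_residues,
    )


@pytest.fixture
def toy_system():
    """A minimal protein + membrane system with hand-computable geometry.

    Protein: three reference residues (BB beads) forming a horizontal
    triangle at z = 5, plus one extra residue bead; membrane: two POPE
    molecules mirrored about z = 0 plus one CHOL per leaflet, so the membrane
    COM z is exactly zero.
    """
    particles = [
        ("BB", 1, "GLY", 0, "protein", "", "", True),
        ("BB", 2, "GLY", 0, "protein", "", "", True),
        ("BB", 3, "GLY", 0, "protein", "", "", True),
        ("SC", 4, "LEU", 0, "protein", "", "", False),
    ]
    for mol, leaf in ((1, 1), (2, -1)):
        particles += [
            ("HD", 100 + mol, "POPE", mol, "lipid", "POPE", "headgroup", False),
            ("T1", 100 + mol, "POPE", mol, "lipid", "POPE", "tail", False),
            ("T2", 100 + mol, "POPE", mol, "lipid", "POPE", "tail", False),
        ]
    particles += [
        ("ROH", 103, "CHOL", 3, "lipid", "CHOL", "whole", False),
        ("ROH", 104, "CHOL", 4, "lipid", "CHOL", "whole", False),
    ]
    top = make_topology(particles)

    def positions(theta_deg=0.0, com_z=5.0):
        """Triangle tilted by theta about x, centred at (0, 0, com_z)."""
        th = np.radians(theta_deg)
        rot = np.array([[1, 0, 0],
                        [0, np.cos(th), -np.sin(th)],
                        [0, np.sin(th), np.cos(th)]])
        tri = np.array([[1.0, 0, 0], [-0.5, 0.866025403784, 0],
                        [-0.5, -0.866025403784, 0]]) @ rot.T
        tri += np.array([0, 0, com_z])
        extra = np.array([[0.0, 0.0, com_z + 1.0]])
        lipids = np.array([
            [3.0, 3.0, 2.0], [3.0, 3.0, 1.3], [3.0, 3.0, 0.6],     # POPE up
            [3.0, 3.0, -2.0], [3.0, 3.0, -1.3], [3.0, 3.0, -0.6],  # POPE down
            [5.0, 5.0, 1.0], [5.0, 5.0, -1.0],                     # CHOL
        ])
        return np.vstack([tri, extra, lipids])

    return top, positions


def make_trajectory(top, frames, box=(10.0, 10.0, 26.0), times=None, rep=0):
    frames = np.asarray(frames, dtype=float)
    if times is None:
        times = np.arange(1, len(frames) + 1, dtype=float)
    traj = Trajectory(topology=top, times=np.asarray(times, dtype=float),
                      boxes=np.tile(np.asarray(box, dtype=float),
                                    (len(frames), 1)),
                      positions=frames, replicate_id=rep)
    traj.validate()
    return traj


def random_contact_system(rng, n_lipids=200, n_res=30, box=(8.0, 8.0, 8.0)):
    """A random (unphysical) frame for contact-counting oracle checks.

    Lipid types are sampled over all six species; positions are uniform over
    three box images so minimum-image wrapping is exercised.
    """
    types = rng.choice(["POPE", "CHOL", "POPS", "POPC", "POP2", "POP3"],
                       size=n_lipids)
    particles = []
    for r in range(1, n_res + 1):
        particles.append(("BB", r, "GLY", 0, "protein", "", "", True))
        particles.append(("SC", r, "GLY", 0, "protein", "", "", False))
    for i, t in enumerate(types):
        mol = i + 1
        if t == "CHOL":
            particles.append(("ROH", 1000 + mol, t, mol, "lipid", t, "whole", False))
        else:
            particles.append(("HD", 1000 + mol, t, mol, "lipid", t, "headgroup", False))
            particles.append(("T1", 1000 + mol, t, mol, "lipid", t, "tail", False))
            particles.append(("T2", 1000 + mol, t, mol, "lipid", t, "tail", False))
    top = make_topology(particles)
    box = np.asarray(box, dtype=float)
    pos = rng.uniform(-box, 2 * box, size=(top.n_particles, 3))
    return top, Frame(time=0.0, box=box, positions=pos)


def brute_force_contacts(frame, top, cutoff=0.55):
    """All-pairs molecule-level contact oracle with explicit minimum image.

    Independent of the cell-list implementation: nested loops over residues
    and lipid molecules, squared-distance comparison (closed cutoff).
    """
    resids = top.protein_resids()
    groups = ct.lipid_group_names(top)
    table = pd.DataFrame(0, index=pd.Index(resids, name="residue"),
                         columns=groups, dtype=np.int64)
    box = np.asarray(frame.box, dtype=float)
    c2 = cutoff * cutoff

    lip = top.lipid_mask
    tested = lip & ((top.subsets == "headgroup") | (top.subsets == "whole"))
    mol_rows = {}
    for i in np.flatnonzero(tested):
        mol_rows.setdefault(int(top.mol_ids[i]), []).append(i)

    for resid in resids:
        ppos = frame.positions[top.residue_particles(int(resid))]
        for mol, rows in mol_rows.items():
            lt = str(top.lipid_types[rows[0]])
            group = "CHOL" if lt == "CHOL" else f"{lt} headgroup"
            hit = False
            for row in rows:
                d = ppos - frame.positions[row]
                d -= box * np.round(d / box)
                if np.any(np.einsum("ij,ij->i", d, d) <= c2):
                    hit = True
                    break
            if hit:
                table.at[resid, group] += 1
    return table
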