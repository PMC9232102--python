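"""Shared domain model: topology, trajectory, named particle groups, file IO.

The in-memory model is deliberately small: a :class:`Topology` holds flat
per-particle annotation arrays (residue, molecule, lipid type, headgroup/tail
subset, designated backbone flag) and a :class:`Trajectory` holds an
``(F, N, 3)`` position array in nanometres with per-frame box vectors and
times in nanoseconds.  All reading and writing of standard coordinate and
trajectory formats (GRO, PDB, XTC, TRR, DCD) goes through MDAnalysis;
MDAnalysis works in angstroms and picoseconds internally, so coordinates are
scaled by 0.1 and times by 1/1000 on load and the inverse on write.  Keeping a
single internal unit (nm / ns) avoids silent angstrom/nanometre mix-ups: the
contact cutoff the analysis uses is stored as 0.55 nm, not 5.5 A.

Residue numbering is 1-based canonical PLCγ1 numbering for the two-segment
catalytic-core model (residues 22-488 and 934-1215, with 489-933 absent); the
numbering of loaded files is preserved verbatim, gaps included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "MembindError",
    "MappingError",
    "ConfigurationError",
    "StructuralError",
    "SelectionError",
    "GeometryError",
    "StabilityError",
    "IntegrityError",
    "ParameterError",
    "EmptyInputError",
    "Topology",
    "Frame",
    "Trajectory",
    "GroupSpec",
    "default_annotation",
    "load_annotation",
    "load_topology",
    "load_trajectory",
    "save_trajectory",
    "write_gro",
    "select_group",
    "protein_topology_from_sequence",
]

DEFAULT_REFERENCE_RESIDUES = (416, 1011, 1194)

#: Lipid types of the model membrane, in the fixed order used for
#: deterministic tie-breaking everywhere (apportionment, column order).
LIPID_TYPE_ORDER = ("POPE", "CHOL", "POPS", "POPC", "POP2", "POP3")

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

_ION_RESNAMES = {"NA", "CL", "NA+", "CL-", "ION", "K", "K+", "CA", "CA2+", "MG"}
_SOLVENT_RESNAMES = {"W", "WN", "SOL", "HOH", "TIP3", "WAT"}


class MembindError(Exception):
    """Base class for all package errors."""


class MappingError(MembindError):
    """A particle or residue name could not be mapped by the annotation."""


class ConfigurationError(MembindError):
    """Invalid or incomplete configuration (e.g. missing reference residue)."""


class StructuralError(MembindError):
    """Topology/trajectory structural mismatch (particle counts etc.)."""


class SelectionError(MembindError):
    """A particle-group selection is empty or refers to unknown entities."""


class GeometryError(MembindError):
    """Degenerate or impossible geometry."""


class StabilityError(MembindError):
    """The synthetic integrator took a divergent step."""


class IntegrityError(MembindError):
    """A verified-sequence check failed."""


class ParameterError(MembindError):
    """A numeric parameter is out of its valid domain."""


class EmptyInputError(MembindError):
    """An operation received zero frames / zero records."""


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def default_annotation() -> dict:
    """Built-in lipid headgroup/tail particle-name table.

    Covers both Martini-style bead names and the names emitted by the
    synthetic generator (``HD``/``T1``/``T2``/``ROH``).  Editable: load a YAML
    file with the same structure via :func:`load_annotation` to adapt to other
    naming dialects.
    """
    phospho_head = {
        "POPE": ["NH3", "PO4", "HD"],
        "POPC": ["NC3", "PO4", "HD"],
        "POPS": ["CNO", "PO4", "HD"],
        "POP2": ["C1", "C2", "C3", "CP", "PO4", "P1", "P2", "P4", "P5", "HD"],
        "POP3": ["C1", "C2", "C3", "CP", "PO4", "P1", "P2", "P3", "P4", "P5", "HD"],
    }
    tail = ["GL1", "GL2",
            "C1A", "C2A", "C3A", "C4A", "D2A", "D3A",
            "C1B", "C2B", "C3B", "C4B", "D2B", "D3B",
            "T1", "T2"]
    lipids = {t: {"headgroup": names, "tail": list(tail)}
              for t, names in phospho_head.items()}
    lipids["CHOL"] = {"whole": True}
    return {
        "lipids": lipids,
        "protein_resnames": sorted(AA3_TO_1),
        "backbone_names": ["BB", "CA", "N", "C", "O"],
    }


def load_annotation(path: str | Path) -> dict:
    """Load a lipid/residue annotation config from YAML."""
    with open(path) as fh:
        ann = yaml.safe_load(fh)
    if not isinstance(ann, dict) or "lipids" not in ann:
        raise ConfigurationError(f"annotation file {path} lacks a 'lipids' table")
    ann.setdefault("protein_resnames", sorted(AA3_TO_1))
    ann.setdefault("backbone_names", ["BB", "CA", "N", "C", "O"])
    return ann


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Static particle annotation shared by every frame of a trajectory.

    All arrays have one entry per particle.  ``mol_kinds`` is one of
    ``protein``, ``lipid``, ``ion``, ``solvent``; ``lipid_types`` is the lipid
    species of the owning molecule (empty string for non-lipids); ``subsets``
    tags every phospholipid particle ``headgroup`` or ``tail`` and every CHOL
    particle ``whole``.
    """

    names: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    mol_ids: np.ndarray
    mol_kinds: np.ndarray
    lipid_types: np.ndarray
    subsets: np.ndarray
    backbone: np.ndarray
    reference_residues: tuple[int, int, int] = DEFAULT_REFERENCE_RESIDUES

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.resids = np.asarray(self.resids, dtype=np.int64)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.mol_ids = np.asarray(self.mol_ids, dtype=np.int64)
        self.mol_kinds = np.asarray(self.mol_kinds, dtype=object)
        self.lipid_types = np.asarray(self.lipid_types, dtype=object)
        self.subsets = np.asarray(self.subsets, dtype=object)
        self.backbone = np.asarray(self.backbone, dtype=bool)

    @property
    def n_particles(self) -> int:
        return len(self.names)

    def validate(self) -> None:
        n = self.n_particles
        for arr in (self.resids, self.resnames, self.mol_ids, self.mol_kinds,
                    self.lipid_types, self.subsets, self.backbone):
            if len(arr) != n:
                raise StructuralError("topology annotation arrays disagree in length")
        lip = self.mol_kinds == "lipid"
        phospho = lip & (self.lipid_types != "CHOL")
        if not np.all(np.isin(self.subsets[phospho], ("headgroup", "tail"))):
            raise StructuralError("phospholipid particle without headgroup/tail tag")
        if not np.all(self.subsets[lip & (self.lipid_types == "CHOL")] == "whole"):
            raise StructuralError("CHOL particle not tagged 'whole'")
        prot = self.mol_kinds == "protein"
        if prot.any():
            # residue indices unique within the protein: each resid maps to one residue
            resids = self.resids[prot]
            names_by_res: dict[int, set] = {}
            for r, nm in zip(resids, self.names[prot]):
                names_by_res.setdefault(int(r), set()).add(nm)
            # (uniqueness is by construction of per-residue grouping)

    # -- convenience views ---------------------------------------------------
    @property
    def protein_mask(self) -> np.ndarray:
        return self.mol_kinds == "protein"

    @property
    def lipid_mask(self) -> np.ndarray:
        return self.mol_kinds == "lipid"

    def protein_resids(self) -> np.ndarray:
        """Sorted unique residue indices of the protein."""
        return np.unique(self.resids[self.protein_mask])

    def residue_particles(self, resid: int) -> np.ndarray:
        """Particle indices of one protein residue."""
        return np.flatnonzero(self.protein_mask & (self.resids == resid))

    def backbone_particle(self, resid: int) -> int:
        """The designated backbone particle of a protein residue.

        Falls back to the residue's single particle for one-bead residues.
        """
        idx = self.residue_particles(resid)
        if len(idx) == 0:
            raise ConfigurationError(f"reference residue {resid} not present in topology")
        bb = idx[self.backbone[idx]]
        if len(bb) >= 1:
            return int(bb[0])
        if len(idx) == 1:
            return int(idx[0])
        raise ConfigurationError(
            f"residue {resid} has {len(idx)} particles but no designated backbone")

    def lipid_molecules(self) -> tuple[np.ndarray, np.ndarray]:
        """(unique lipid molecule ids, lipid_type per molecule)."""
        lip = self.lipid_mask
        mols, first = np.unique(self.mol_ids[lip], return_index=True)
        return mols, self.lipid_types[lip][first]

    def same_partition(self, other: "Topology") -> bool:
        """True if both topologies describe the same particle/molecule partition."""
        if self.n_particles != other.n_particles:
            return False
        # molecule ids may be renumbered on round-trip; compare the partition
        _, inv_a = np.unique(self.mol_ids, return_inverse=True)
        _, inv_b = np.unique(other.mol_ids, return_inverse=True)
        return (
            np.array_equal(self.resids, other.resids)
            and np.array_equal(self.resnames, other.resnames)
            and np.array_equal(self.names, other.names)
            and np.array_equal(inv_a, inv_b)
            and np.array_equal(self.mol_kinds, other.mol_kinds)
            and np.array_equal(self.lipid_types, other.lipid_types)
            and np.array_equal(self.subsets, other.subsets)
        )


def concat_topologies(a: Topology, b: Topology,
                      reference_residues: tuple[int, int, int] | None = None) -> Topology:
    """Concatenate two topologies (particles of ``a`` first), renumbering molecules."""
    off = a.mol_ids.max() + 1 if a.n_particles else 0
    return Topology(
        names=np.concatenate([a.names, b.names]),
        resids=np.concatenate([a.resids, b.resids]),
        resnames=np.concatenate([a.resnames, b.resnames]),
        mol_ids=np.concatenate([a.mol_ids, b.mol_ids + off]),
        mol_kinds=np.concatenate([a.mol_kinds, b.mol_kinds]),
        lipid_types=np.concatenate([a.lipid_types, b.lipid_types]),
        subsets=np.concatenate([a.subsets, b.subsets]),
        backbone=np.concatenate([a.backbone, b.backbone]),
        reference_residues=reference_residues or a.reference_residues,
    )


@dataclass
class Frame:
    """One trajectory frame: time (ns), box lengths (nm), positions (nm)."""

    time: float
    box: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)

    def validate(self, topology: Topology | None = None) -> None:
        if not np.all(self.box > 0):
            raise StructuralError("box lengths must be strictly positive")
        if not np.all(np.isfinite(self.positions)):
            raise StructuralError("non-finite coordinates in frame")
        if topology is not None and len(self.positions) != topology.n_particles:
            raise StructuralError(
                f"frame has {len(self.positions)} positions, topology has "
                f"{topology.n_particles} particles")


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology.

    ``positions`` has shape (F, N, 3) in nm, ``boxes`` (F, 3) in nm and
    ``times`` (F,) in ns, strictly increasing.
    """

    topology: Topology
    times: np.ndarray
    boxes: np.ndarray
    positions: np.ndarray
    replicate_id: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)

    def validate(self) -> None:
        if self.n_frames < 1:
            raise EmptyInputError("trajectory has zero frames")
        if self.positions.shape[1] != self.topology.n_particles:
            raise StructuralError("trajectory particle count does not match topology")
        if np.any(np.diff(self.times) <= 0):
            raise StructuralError("frame times are not strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def frame(self, i: int) -> Frame:
        return Frame(time=float(self.times[i]), box=self.boxes[i],
                     positions=self.positions[i])

    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def window_mask(self, window_ns: float) -> np.ndarray:
        """Boolean mask of frames within the final ``window_ns`` of the run."""
        return self.times >= self.times[-1] - window_ns


@dataclass(frozen=True)
class GroupSpec:
    """A named, resolved particle selection (subset of topology particles)."""

    name: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices",
                           np.asarray(self.indices, dtype=np.int64))
        if len(self.indices) == 0:
            raise SelectionError(f"group '{self.name}' selects no particles")


# ---------------------------------------------------------------------------
# Group selection
# ---------------------------------------------------------------------------

#: Residue sets of the named membrane-facing protein groups (PLCγ1 numbering).
TIM_RIDGE_RESIDUES = (344, 384, 1018)
C2_LOOP_RESIDUES = (1166, 1167)


def _side_chain_mask(top: Topology, resids: Iterable[int]) -> np.ndarray:
    mask = np.zeros(top.n_particles, dtype=bool)
    for r in resids:
        idx = top.residue_particles(r)
        if len(idx) == 0:
            raise SelectionError(f"residue {r} not present in topology")
        sc = idx[~top.backbone[idx]]
        mask[sc] = True
    return mask


def select_group(topology: Topology, spec: str | Mapping) -> GroupSpec:
    """Resolve a named or residue-list selection to a deterministic particle set.

    String names: ``protein``, ``membrane`` (all lipid particles),
    ``phospholipid headgroups``, ``phospholipid tails``,
    ``TIM hydrophobic ridge`` (side-chain particles of residues 344, 384,
    1018) and ``C2 hydrophobic loop`` (side chains of 1166, 1167).
    Side-chain particles are all particles of a residue except its designated
    backbone particle.  Mapping specs: ``{"name", "residues", "part"}`` with
    ``part`` one of ``all``, ``side_chain``, ``backbone``.
    """
    lip = topology.lipid_mask
    phospho = lip & (topology.lipid_types != "CHOL")
    if isinstance(spec, str):
        name = spec
        if name == "protein":
            mask = topology.protein_mask
        elif name == "membrane":
            mask = lip
        elif name == "phospholipid headgroups":
            mask = phospho & (topology.subsets == "headgroup")
        elif name == "phospholipid tails":
            mask = phospho & (topology.subsets == "tail")
        elif name == "TIM hydrophobic ridge":
            mask = _side_chain_mask(topology, TIM_RIDGE_RESIDUES)
        elif name == "C2 hydrophobic loop":
            mask = _side_chain_mask(topology, C2_LOOP_RESIDUES)
        else:
            raise SelectionError(f"unknown group name '{name}'")
        return GroupSpec(name, np.flatnonzero(mask))

    name = spec.get("name", "custom")
    resids = spec.get("residues")
    if resids is None:
        raise SelectionError(f"group '{name}' defines no residues")
    part = spec.get("part", "all")
    if part == "side_chain":
        mask = _side_chain_mask(topology, resids)
    else:
        mask = np.zeros(topology.n_particles, dtype=bool)
        for r in resids:
            idx = topology.residue_particles(r)
            if len(idx) == 0:
                raise SelectionError(f"residue {r} not present in topology")
            if part == "backbone":
                mask[idx[topology.backbone[idx]]] = True
            else:
                mask[idx] = True
    return GroupSpec(name, np.flatnonzero(mask))


# ---------------------------------------------------------------------------
# File IO (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _classify_residue(resname: str, annotation: dict) -> str:
    if resname in annotation["lipids"]:
        return "lipid"
    if resname in annotation["protein_resnames"]:
        return "protein"
    if resname.upper() in _ION_RESNAMES:
        return "ion"
    if resname.upper() in _SOLVENT_RESNAMES:
        return "solvent"
    raise MappingError(f"unknown residue name '{resname}' (not in annotation)")


def load_topology(coordinate_file: str | Path,
                  annotation: dict | str | Path | None = None,
                  reference_residues: tuple[int, int, int] | None = None) -> Topology:
    """Build a :class:`Topology` from a GRO or PDB coordinate file.

    Every residue name must be mapped by the annotation: lipid residues to a
    lipid type with headgroup/tail particle-name lists (CHOL is whole-molecule),
    amino-acid residues to the protein.  Unknown names raise
    :class:`MappingError` naming the offending residue.

    Reference residues are checked only when passed explicitly; the default
    triple (416, 1011, 1194) is attached but its absence is tolerated until an
    orientation analysis actually needs it.
    """
    import MDAnalysis as mda

    if annotation is None:
        annotation = default_annotation()
    elif not isinstance(annotation, dict):
        annotation = load_annotation(annotation)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(coordinate_file))

    names, resids, resnames = [], [], []
    mol_ids, mol_kinds, lipid_types, subsets, backbone = [], [], [], [], []
    bb_names = set(annotation["backbone_names"])
    next_mol = 1  # molecule 0 reserved for the protein
    has_protein = False

    for res in u.residues:
        rname = str(res.resname).strip()
        kind = _classify_residue(rname, annotation)
        if kind == "protein":
            has_protein = True
            mol = 0
        else:
            mol = next_mol
            next_mol += 1
        lipdef = annotation["lipids"].get(rname, {})
        for atom in res.atoms:
            aname = str(atom.name).strip()
            names.append(aname)
            resids.append(int(res.resid))
            resnames.append(rname)
            mol_ids.append(mol)
            mol_kinds.append(kind)
            if kind == "lipid":
                lipid_types.append(rname)
                if lipdef.get("whole"):
                    subsets.append("whole")
                elif aname in lipdef.get("headgroup", ()):
                    subsets.append("headgroup")
                elif aname in lipdef.get("tail", ()):
                    subsets.append("tail")
                else:
                    raise MappingError(
                        f"particle '{aname}' of lipid residue {rname} {res.resid} "
                        f"is in neither the headgroup nor the tail list")
                backbone.append(False)
            else:
                lipid_types.append("")
                subsets.append("")
                backbone.append(kind == "protein" and aname in bb_names)

    if not has_protein:
        pass  # membrane-only topologies are legal

    top = Topology(
        names=np.array(names, dtype=object),
        resids=np.array(resids),
        resnames=np.array(resnames, dtype=object),
        mol_ids=np.array(mol_ids),
        mol_kinds=np.array(mol_kinds, dtype=object),
        lipid_types=np.array(lipid_types, dtype=object),
        subsets=np.array(subsets, dtype=object),
        backbone=np.array(backbone),
        reference_residues=tuple(reference_residues or DEFAULT_REFERENCE_RESIDUES),
    )
    top.validate()
    if reference_residues is not None:
        for r in reference_residues:
            top.backbone_particle(r)  # raises ConfigurationError if absent
    return top


def _empty_universe(topology: Topology):
    import MDAnalysis as mda

    # build per-residue tables in particle order
    res_keys: list[tuple] = []
    atom_resindex = np.empty(topology.n_particles, dtype=np.int64)
    res_resids, res_resnames = [], []
    seen: dict[tuple, int] = {}
    for i in range(topology.n_particles):
        key = (int(topology.mol_ids[i]), int(topology.resids[i]))
        if key not in seen:
            seen[key] = len(res_keys)
            res_keys.append(key)
            res_resids.append(int(topology.resids[i]))
            res_resnames.append(str(topology.resnames[i]))
        atom_resindex[i] = seen[key]
    u = mda.Universe.empty(
        n_atoms=topology.n_particles,
        n_residues=len(res_keys),
        atom_resindex=atom_resindex,
        residue_segindex=np.zeros(len(res_keys), dtype=np.int64),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(n) for n in topology.names])
    u.add_TopologyAttr("resids", res_resids)
    u.add_TopologyAttr("resnames", res_resnames)
    return u


def write_gro(topology: Topology, frame: Frame, path: str | Path) -> None:
    """Write one frame as a GRO coordinate file (nm, 3 decimals)."""
    u = _empty_universe(topology)
    u.atoms.positions = frame.positions * 10.0  # nm -> A
    u.dimensions = [frame.box[0] * 10, frame.box[1] * 10, frame.box[2] * 10,
                    90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def save_trajectory(traj: Trajectory, gro_path: str | Path,
                    traj_path: str | Path) -> None:
    """Write a trajectory as GRO (first frame) + XTC/TRR/DCD (all frames)."""
    import MDAnalysis as mda

    write_gro(traj.topology, traj.frame(0), gro_path)
    u = _empty_universe(traj.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(traj_path), n_atoms=traj.topology.n_particles) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.positions[i] * 10.0
                ts = u.trajectory.ts
                ts.dimensions = [traj.boxes[i][0] * 10, traj.boxes[i][1] * 10,
                                 traj.boxes[i][2] * 10, 90.0, 90.0, 90.0]
                ts.time = traj.times[i] * 1000.0  # ns -> ps
                ts.frame = i
                w.write(u.atoms)


def load_trajectory(topology: Topology, trajectory_file: str | Path,
                    replicate_id: int = 0) -> Trajectory:
    """Read an XTC/TRR/DCD (or single-frame GRO/PDB) trajectory.

    Coordinates are converted to nm and times to ns regardless of the source
    dialect (MDAnalysis presents every format in angstrom/ps).  Frames whose
    recorded times are not strictly increasing (e.g. formats that store no
    time at all) are assigned 1-ns spaced synthetic times.
    """
    import MDAnalysis as mda

    u = _empty_universe(topology)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.load_new(str(trajectory_file))
    except (OSError, ValueError) as exc:
        raise StructuralError(
            f"could not read trajectory {trajectory_file}: {exc}") from exc

    times, boxes, positions = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            if len(ts.positions) != topology.n_particles:
                raise StructuralError(
                    f"trajectory frame has {len(ts.positions)} particles, "
                    f"topology has {topology.n_particles}")
            positions.append(ts.positions.astype(float) * 0.1)
            times.append(float(getattr(ts, "time", 0.0)) / 1000.0)
            dims = ts.dimensions
            if dims is None or not np.all(np.asarray(dims[:3]) > 0):
                boxes.append(np.array([np.inf, np.inf, np.inf]))
            else:
                boxes.append(np.asarray(dims[:3], dtype=float) * 0.1)
    if len(positions) == 0:
        raise EmptyInputError(f"trajectory {trajectory_file} contains zero frames")

    times_arr = np.asarray(times)
    if len(times_arr) > 1 and np.any(np.diff(times_arr) <= 0):
        times_arr = np.arange(len(times_arr), dtype=float)
    traj = Trajectory(topology=topology, times=times_arr,
                      boxes=np.asarray(boxes), positions=np.asarray(positions),
                      replicate_id=replicate_id,
                      provenance={"source": str(trajectory_file)})
    traj.validate()
    return traj


# ---------------------------------------------------------------------------
# Small builders used by model preparation and tests
# ---------------------------------------------------------------------------

def protein_topology_from_sequence(
        segments: Sequence[tuple[int, str]],
        reference_residues: tuple[int, int, int] = DEFAULT_REFERENCE_RESIDUES,
) -> Topology:
    """Build a coarse one-bead-per-residue protein topology from sequence segments.

    ``segments`` is a list of ``(start_resid, one_letter_sequence)`` pairs, so
    the two-segment catalytic core is ``[(22, seq_a), (934, seq_b)]``.  Every
    residue gets a ``BB`` backbone bead; residues other than GLY and ALA also
    get an ``SC`` side-chain bead.
    """
    names, resids, resnames = [], [], []
    for start, seq in segments:
        for i, letter in enumerate(seq):
            if letter not in AA1_TO_3:
                raise MappingError(f"unknown amino-acid letter '{letter}'")
            rn = AA1_TO_3[letter]
            names.append("BB"); resids.append(start + i); resnames.append(rn)
            if rn not in ("GLY", "ALA"):
                names.append("SC"); resids.append(start + i); resnames.append(rn)
    n = len(names)
    return Topology(
        names=np.array(names, dtype=object),
        resids=np.array(resids),
        resnames=np.array(resnames, dtype=object),
        mol_ids=np.zeros(n, dtype=np.int64),
        mol_kinds=np.array(["protein"] * n, dtype=object),
        lipid_types=np.array([""] * n, dtype=object),
        subsets=np.array([""] * n, dtype=object),
        backbone=np.array([nm == "BB" for nm in names]),
        reference_residues=reference_residues,
    )


def min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement(s) under an orthorhombic periodic box."""
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)
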