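"""Model-preparation bookkeeping: variants, loop excision, restraints, counts.

Covers the arithmetic around preparing the two-segment catalytic-core model
for simulation: alanine-substitution variant specs (core P: nPH residues 41,
42, 45; core E: those plus 166, 175, 195, 204 and 990), excision of the two
TIM-barrel/sPH linker loops with formal-charge and counter-ion bookkeeping,
the four active-site harmonic distance restraints for the PIP2 headgroup, and
the membrane composition apportionment (shared with the synthetic builder).

The formal-charge model is the standard coarse-grained side-chain convention
at pH 7: Lys/Arg +1, Asp/Glu −1, His neutral, all else 0, with neutral
termini for internally excised segments.  Under this convention excising the
two linker loops removes a net charge of −2, i.e. two sodium counter-ions
leave with them — which functions as a consistency check on the convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    AA3_TO_1,
    IntegrityError,
    MappingError,
    ParameterError,
    Topology,
)
from .synth import MembraneSpec, apportion_lipids

__all__ = [
    "CORE_P_POSITIONS",
    "CORE_E_POSITIONS",
    "CORE_MODEL_RANGES",
    "VariantSpec",
    "LoopExcision",
    "Restraint",
    "RestraintSpec",
    "formal_charge",
    "excise_loops",
    "apply_variant",
    "make_restraints",
    "serialize_restraints",
    "parse_restraints",
    "membrane_counts",
]

CORE_P_POSITIONS = (41, 42, 45)
CORE_E_POSITIONS = (41, 42, 45, 166, 175, 195, 204, 990)
#: Residue ranges of the two-segment catalytic-core model.
CORE_MODEL_RANGES = ((22, 488), (934, 1215))

_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}

#: Atomistic backbone names kept on substitution to alanine (plus CB).
_AT_BACKBONE = {"N", "CA", "C", "O"}


def formal_charge(sequence: str) -> int:
    """Net formal side-chain charge of a one-letter sequence.

    K/R → +1, D/E → −1, H → 0, everything else 0; termini neutral (the
    sequences handled here are internal excisions).  Additive over
    concatenation by construction.
    """
    total = 0
    for letter in sequence:
        if letter not in AA3_TO_1.values():
            raise MappingError(f"unknown amino-acid letter '{letter}'")
        total += _CHARGE.get(letter, 0)
    return total


@dataclass(frozen=True)
class VariantSpec:
    """A set of alanine substitutions, e.g. the core P / core E presets."""

    name: str
    substitutions: tuple  # positions mutated to ALA

    def __post_init__(self) -> None:
        if len(set(self.substitutions)) != len(self.substitutions):
            raise ParameterError("duplicate substitution positions")

    @classmethod
    def core_p(cls) -> "VariantSpec":
        return cls("core_P", CORE_P_POSITIONS)

    @classmethod
    def core_e(cls) -> "VariantSpec":
        return cls("core_E", CORE_E_POSITIONS)


@dataclass(frozen=True)
class LoopExcision:
    """The two linker loops removed before substrate-access simulations."""

    ranges: tuple = ((471, 488), (934, 947))
    expected_sequences: tuple = ("AYEEVPTSVMYSENDISN", "DARLTEGKMMERRK")

    def __post_init__(self) -> None:
        for (lo, hi), seq in zip(self.ranges, self.expected_sequences):
            if hi - lo + 1 != len(seq):
                raise IntegrityError(
                    f"range {lo}-{hi} covers {hi - lo + 1} residues but the "
                    f"expected sequence has {len(seq)}")

    @property
    def net_charge_removed(self) -> int:
        return sum(formal_charge(s) for s in self.expected_sequences)

    @property
    def n_cations_to_remove(self) -> int:
        """Counter-cations that leave with the excised charge (0 if net ≥ 0)."""
        return max(0, -self.net_charge_removed)


def _topology_sequence(top: Topology, lo: int, hi: int) -> str:
    letters = []
    for r in range(lo, hi + 1):
        idx = top.residue_particles(r)
        if len(idx) == 0:
            raise IntegrityError(f"residue {r} absent from topology")
        rn = str(top.resnames[idx[0]])
        if rn not in AA3_TO_1:
            raise MappingError(f"residue {r} has non-amino-acid name '{rn}'")
        letters.append(AA3_TO_1[rn])
    return "".join(letters)


def excise_loops(topology: Topology,
                 excision: LoopExcision = LoopExcision()) -> tuple:
    """Remove the excision ranges; return (reduced topology, cations to remove).

    The topology sequence over each range is verified against the expected
    sequence (an :class:`IntegrityError` names the first mismatching
    position); residue numbering of the remainder is preserved, gaps
    included.  A net-positive excision emits a warning (anion bookkeeping is
    out of scope) and removes zero cations.
    """
    drop = np.zeros(topology.n_particles, dtype=bool)
    for (lo, hi), expected in zip(excision.ranges, excision.expected_sequences):
        found = _topology_sequence(topology, lo, hi)
        for off, (a, b) in enumerate(zip(found, expected)):
            if a != b:
                raise IntegrityError(
                    f"sequence mismatch at residue {lo + off}: "
                    f"topology has {a}, expected {b}")
        for r in range(lo, hi + 1):
            drop[topology.residue_particles(r)] = True

    keep = ~drop
    reduced = Topology(
        names=topology.names[keep],
        resids=topology.resids[keep],
        resnames=topology.resnames[keep],
        mol_ids=topology.mol_ids[keep],
        mol_kinds=topology.mol_kinds[keep],
        lipid_types=topology.lipid_types[keep],
        subsets=topology.subsets[keep],
        backbone=topology.backbone[keep],
        reference_residues=topology.reference_residues,
    )
    net = excision.net_charge_removed
    if net > 0:
        warnings.warn(
            f"excised segments carry net charge +{net}; anion bookkeeping is "
            "out of scope, removing 0 cations", stacklevel=2)
    return reduced, excision.n_cations_to_remove


def _in_model_range(pos: int) -> bool:
    return any(lo <= pos <= hi for lo, hi in CORE_MODEL_RANGES)


def apply_variant(topology: Topology, spec: VariantSpec) -> tuple:
    """Apply alanine substitutions; return (mutated topology, n_substituted).

    Residue names become ALA and side-chain particles beyond the alanine
    representation are removed (coarse-grained residues keep the backbone
    bead; atomistic residues keep N, CA, C, O and CB).  Positions outside the
    model range raise; positions already ALA warn and are skipped from the
    substitution count.
    """
    resnames = topology.resnames.copy()
    drop = np.zeros(topology.n_particles, dtype=bool)
    n_sub = 0
    for pos in spec.substitutions:
        if not _in_model_range(pos):
            raise ParameterError(
                f"substitution position {pos} outside the model residue "
                f"ranges {CORE_MODEL_RANGES}")
        idx = topology.residue_particles(pos)
        if len(idx) == 0:
            raise ParameterError(f"substitution position {pos} not in topology")
        if str(topology.resnames[idx[0]]) == "ALA":
            warnings.warn(f"residue {pos} is already ALA", stacklevel=2)
            continue
        resnames[idx] = "ALA"
        keep_names = _AT_BACKBONE | {"CB"} if any(
            str(topology.names[i]) in _AT_BACKBONE for i in idx) else set()
        for i in idx:
            nm = str(topology.names[i])
            if keep_names:
                if nm not in keep_names:
                    drop[i] = True
            elif not topology.backbone[i]:
                drop[i] = True
        n_sub += 1

    keep = ~drop
    mutated = Topology(
        names=topology.names[keep],
        resids=topology.resids[keep],
        resnames=resnames[keep],
        mol_ids=topology.mol_ids[keep],
        mol_kinds=topology.mol_kinds[keep],
        lipid_types=topology.lipid_types[keep],
        subsets=topology.subsets[keep],
        backbone=topology.backbone[keep],
        reference_residues=topology.reference_residues,
    )
    return mutated, n_sub


@dataclass(frozen=True)
class Restraint:
    """One harmonic distance restraint between a lipid atom and a protein atom."""

    lipid_atom: str
    residue: int
    protein_atom: str
    distance: float         # nm
    force_constant: float   # kJ mol^-1 nm^-2

    def __post_init__(self) -> None:
        if self.distance <= 0 or self.force_constant <= 0:
            raise ParameterError("restraint distance and force constant must be > 0")


#: The four canonical PIP2-headgroup / active-site pairs, in printed order:
#: P1-HIS380:NE2, P1-HIS335:NE2, P4-LYS462:NZ, O3-ARG988:CZ.
CANONICAL_RESTRAINT_PAIRS = (
    ("P1", 380, "NE2"),
    ("P1", 335, "NE2"),
    ("P4", 462, "NZ"),
    ("O3", 988, "CZ"),
)


@dataclass
class RestraintSpec:
    restraints: list
    default_pairs: bool = True


def make_restraints(distances=None, force_constant: float = 1000.0,
                    extra_pairs=()) -> RestraintSpec:
    """Build the active-site restraint specification.

    ``distances``: one target distance (nm) for all four canonical pairs or a
    sequence of four; the default 0.35 nm is a documented placeholder — the
    reference target distances belong in user configuration.  ``extra_pairs``
    appends user restraints ``(lipid_atom, residue, protein_atom, distance)``
    and clears the default flag.
    """
    if distances is None:
        distances = 0.35
    if np.isscalar(distances):
        distances = [float(distances)] * len(CANONICAL_RESTRAINT_PAIRS)
    if len(distances) != len(CANONICAL_RESTRAINT_PAIRS):
        raise ParameterError("need one distance per canonical pair")
    restraints = [
        Restraint(la, res, pa, float(d), force_constant)
        for (la, res, pa), d in zip(CANONICAL_RESTRAINT_PAIRS, distances)
    ]
    default = True
    for la, res, pa, d in extra_pairs:
        restraints.append(Restraint(la, int(res), pa, float(d), force_constant))
        default = False
    return RestraintSpec(restraints=restraints, default_pairs=default)


def serialize_restraints(spec: RestraintSpec) -> str:
    """Plain-text restraint table: pair, distance (nm), force constant."""
    lines = ["# lipid_atom\tresidue\tprotein_atom\tdistance_nm\tk_kJ_mol_nm2"]
    for r in spec.restraints:
        lines.append(f"{r.lipid_atom}\t{r.residue}\t{r.protein_atom}\t"
                     f"{r.distance:.6g}\t{r.force_constant:.6g}")
    return "\n".join(lines) + "\n"


def parse_restraints(text: str) -> RestraintSpec:
    restraints = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        la, res, pa, d, k = line.split("\t")
        restraints.append(Restraint(la, int(res), pa, float(d), float(k)))
    canonical = [(r.lipid_atom, r.residue, r.protein_atom)
                 for r in restraints[:len(CANONICAL_RESTRAINT_PAIRS)]]
    default = (len(restraints) == len(CANONICAL_RESTRAINT_PAIRS)
               and tuple(canonical) == CANONICAL_RESTRAINT_PAIRS)
    return RestraintSpec(restraints=restraints, default_pairs=default)


def membrane_counts(spec: MembraneSpec | dict, n: int) -> dict:
    """Per-type lipid counts for ``n`` lipids per leaflet.

    Standalone view of the apportionment contract of the membrane builder
    (largest remainder, fixed-order tie-break).
    """
    fractions = spec.fractions if isinstance(spec, MembraneSpec) else spec
    return apportion_lipids(fractions, n)
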