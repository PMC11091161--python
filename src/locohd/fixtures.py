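"""Synthetic inputs for tests and demos: toy clouds, minimal PDB files,
perturbed ensembles and two-state trajectories.

Every generator is a pure function of its arguments (seed included), so
repeated generation is byte-identical.  Side chains are placeholders
with correct atom names at crude geometry — sufficient because the
metric consumes only typed points and distances; do not mistake these
for physical models.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from locohd.errors import ConfigurationError, DomainError
from locohd.primitives import PrimitiveAtom, PrimitiveCloud
from locohd.structure_io import AtomRecord, ResidueKey, Structure, write_pdb

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

SIDECHAIN_ATOMS = {
    "ALA": ["CB"],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "CYS": ["CB", "SG"],
    "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "GLY": [],
    "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "MET": ["CB", "CG", "SD", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["CB", "CG", "CD"],
    "SER": ["CB", "OG"],
    "THR": ["CB", "OG1", "CG2"],
    "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "VAL": ["CB", "CG1", "CG2"],
}

BACKBONE_OFFSETS = {
    "N": np.array([-1.20, 0.85, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.25, 0.70, 0.0]),
    "O": np.array([1.40, 1.92, 0.25]),
}


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic input; seed is mandatory."""

    kind: str  # cloud | pdb | ensemble | trajectory
    seed: int
    parameters: dict = field(default_factory=dict)


def _source_key(label: str, number: int) -> ResidueKey:
    return ResidueKey(chain_id="A", residue_number=number, residue_name=label)


def worked_example_cloud(hetero_tag: bool = True) -> PrimitiveCloud:
    """The canned toy cloud over type set {A, B, C}.

    Four primitives on a line: two of type A from residue X (one being
    the 0 Å anchor), one B at 3 Å from residue Y, one B at 5 Å from
    residue Z.
    """
    x = _source_key("X", 1)
    y = _source_key("Y", 2) if hetero_tag else x
    z = _source_key("Z", 3) if hetero_tag else x
    atoms = [
        PrimitiveAtom("A", (0.0, 0.0, 0.0), x),
        PrimitiveAtom("A", (1.0, 0.0, 0.0), x),
        PrimitiveAtom("B", (3.0, 0.0, 0.0), y),
        PrimitiveAtom("B", (5.0, 0.0, 0.0), z),
    ]
    return PrimitiveCloud(atoms=atoms, scheme="toy", type_set=("A", "B", "C"), provenance="worked-example")


def make_cloud(spec: FixtureSpec) -> PrimitiveCloud:
    """Build a toy primitive cloud from a spec.

    Parameters: either ``triples`` (list of (ptype, xyz, source-label))
    or ``n_atoms``/``box``/``type_set`` for random placement.
    """
    if spec.kind != "cloud":
        raise ConfigurationError(f"expected a cloud spec, got kind {spec.kind!r}")
    params = spec.parameters
    type_set = tuple(params.get("type_set", ("A", "B", "C")))
    if "triples" in params:
        atoms = []
        for i, (ptype, xyz, label) in enumerate(params["triples"]):
            if ptype not in type_set:
                raise ConfigurationError(f"ptype {ptype!r} not in type set {type_set}")
            atoms.append(PrimitiveAtom(ptype, tuple(float(v) for v in xyz), _source_key(label, i + 1)))
        if not atoms:
            raise ConfigurationError("cloud fixture needs at least one atom")
        return PrimitiveCloud(atoms=atoms, scheme="toy", type_set=type_set, provenance="triples")
    n_atoms = int(params.get("n_atoms", 0))
    if n_atoms < 1:
        raise ConfigurationError("cloud fixture needs at least one atom")
    box = float(params.get("box", 10.0))
    rng = np.random.default_rng(spec.seed)
    coords = rng.uniform(0.0, box, size=(n_atoms, 3))
    types = rng.choice(len(type_set), size=n_atoms)
    atoms = [
        PrimitiveAtom(type_set[int(t)], tuple(float(v) for v in c), _source_key("R", i + 1))
        for i, (t, c) in enumerate(zip(types, coords))
    ]
    return PrimitiveCloud(atoms=atoms, scheme="toy", type_set=type_set, provenance=f"random-{spec.seed}")


def _sidechain_offset(k: int) -> np.ndarray:
    # zigzag away from CA: distinct positions, roughly bonded spacing
    return np.array(
        [0.45 * (k % 2), -0.8 * ((k % 3) - 1), 1.25 * (k + 1)],
    )


def make_structure(sequence: str, geometry: str = "extended", chain_id: str = "A") -> Structure:
    """Idealized-backbone Structure for a one-letter sequence.

    ``extended`` places residues 3.8 Å apart on a line with side chains
    alternating above/below; ``helix-like`` winds the backbone on a
    coarse helix.  Atom names are canonical so typing-scheme coverage is
    fully exercised.
    """
    if not sequence:
        raise DomainError("sequence must be non-empty")
    residues: dict[ResidueKey, list[AtomRecord]] = {}
    for i, letter in enumerate(sequence):
        if letter not in ONE_TO_THREE:
            raise DomainError(f"invalid residue letter {letter!r} at position {i + 1}")
        resname = ONE_TO_THREE[letter]
        if geometry == "extended":
            origin = np.array([3.8 * i, 0.0, 0.0])
            flip = 1.0 if i % 2 == 0 else -1.0
        elif geometry == "helix-like":
            angle = np.deg2rad(100.0 * i)
            origin = np.array([2.3 * np.cos(angle), 2.3 * np.sin(angle), 1.5 * i])
            flip = 1.0
        else:
            raise DomainError(f"unknown geometry {geometry!r}")
        atoms = []
        for name, off in BACKBONE_OFFSETS.items():
            atoms.append(
                AtomRecord(atom_name=name, element=name[0], coords=tuple(origin + off))
            )
        for k, name in enumerate(SIDECHAIN_ATOMS[resname]):
            off = _sidechain_offset(k) * np.array([1.0, 1.0, flip])
            atoms.append(AtomRecord(atom_name=name, element=name[0], coords=tuple(origin + off)))
        key = ResidueKey(chain_id=chain_id, residue_number=i + 1, residue_name=resname)
        residues[key] = atoms
    return Structure(model_id=0, residues=residues)


def make_pdb(sequence: str, path: str | Path, geometry: str = "extended", seed: int = 0) -> Path:
    """Write a minimal standard-conforming PDB for a sequence; returns the path."""
    structure = make_structure(sequence, geometry=geometry)
    path = Path(path)
    write_pdb(structure, path)
    return path


def _perturb(structure: Structure, rng: np.random.Generator, sigma: float) -> Structure:
    out: dict[ResidueKey, list[AtomRecord]] = {}
    for key, atoms in structure.residues.items():
        out[key] = [
            dataclasses.replace(
                a, coords=tuple(np.asarray(a.coords) + rng.normal(0.0, sigma, 3))
            )
            if sigma > 0
            else a
            for a in atoms
        ]
    return Structure(model_id=structure.model_id, residues=out)


def _shift_residues(
    structure: Structure, keys: set[ResidueKey], shift: np.ndarray, sidechain_only: bool = False
) -> Structure:
    backbone = set(BACKBONE_OFFSETS)
    out: dict[ResidueKey, list[AtomRecord]] = {}
    for key, atoms in structure.residues.items():
        if key in keys:
            out[key] = [
                a
                if sidechain_only and a.atom_name in backbone
                else dataclasses.replace(a, coords=tuple(np.asarray(a.coords) + shift))
                for a in atoms
            ]
        else:
            out[key] = list(atoms)
    return Structure(model_id=structure.model_id, residues=out)


def make_ensemble(
    base: Structure,
    n_structures: int,
    noise_sigma: float = 0.3,
    n_clusters: int = 1,
    cluster_shift: float = 0.0,
    seed: int = 0,
) -> tuple[list[Structure], np.ndarray]:
    """Noise-perturbed copies of ``base``, optionally split into planted clusters.

    Cluster c rigidly shifts the C-terminal half of the chain by
    c·cluster_shift along +y before noise is added.  Returns the members
    and their planted cluster labels.
    """
    if n_structures < 2:
        raise DomainError("an ensemble needs at least 2 members")
    if n_clusters < 1 or n_clusters > n_structures:
        raise DomainError("cluster count must be in [1, n_structures]")
    rng = np.random.default_rng(seed)
    keys = list(base.residues)
    tail = set(keys[len(keys) // 2:])
    members = []
    labels = np.array([m * n_clusters // n_structures for m in range(n_structures)])
    for m, label in enumerate(labels):
        s = base
        if label > 0 and cluster_shift != 0.0:
            s = _shift_residues(base, tail, np.array([0.0, label * cluster_shift, 0.0]))
        s = _perturb(s, rng, noise_sigma)
        members.append(Structure(model_id=m, residues=s.residues))
    return members, labels


def make_trajectory(
    base: Structure,
    n_frames: int,
    switch_frame: int,
    switch_residue: ResidueKey,
    displacement: float = 4.0,
    noise_sigma: float = 0.1,
    seed: int = 0,
) -> list[Structure]:
    """Two-state trajectory: from ``switch_frame`` on, the switch residue's
    side chain is displaced, giving nearby anchors a bimodal score series."""
    if not 0 <= switch_frame <= n_frames:
        raise DomainError(f"switch frame {switch_frame} outside [0, {n_frames}]")
    if switch_residue not in base.residues:
        raise DomainError(f"unknown residue {switch_residue}")
    rng = np.random.default_rng(seed)
    shift = np.array([displacement, 0.0, 0.0])
    frames = []
    for t in range(n_frames):
        s = base
        if t >= switch_frame and displacement != 0.0:
            s = _shift_residues(base, {switch_residue}, shift, sidechain_only=True)
        s = _perturb(s, rng, noise_sigma)
        frames.append(Structure(model_id=t, residues=s.residues))
    return frames
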