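"""Reading, standardizing and aligning protein structures.

Downstream modules expect a clean heavy-atom representation of canonical
amino-acid residues with well-defined residue identities.  Parsing is
delegated to Biopython; this module owns the standardization policy
(hydrogen/hetero/altloc handling), chain pairing by sequence alignment,
and pruning two structures to a common atom inventory.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.PDB.MMCIFParser import MMCIFParser
from Bio.PDB.PDBParser import PDBParser

from locohd.errors import ConfigurationError, EmptyStructureError, PairingError, ParseError

CANONICAL_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class ResidueKey:
    """Identity of a residue as deposited (chain, number, insertion code, name)."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""
    residue_name: str = ""

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        icode = self.insertion_code or ""
        return f"{self.chain_id}/{self.residue_name}{self.residue_number}{icode}"


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: stripped PDB name, element, coordinates (Å), altloc, occupancy."""

    atom_name: str
    element: str
    coords: tuple[float, float, float]
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Structure:
    """One model: an ordered map from ResidueKey to its atom list."""

    model_id: int
    residues: dict[ResidueKey, list[AtomRecord]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.residues)

    def atom_count(self) -> int:
        return sum(len(a) for a in self.residues.values())

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for key in self.residues:
            seen.setdefault(key.chain_id, None)
        return list(seen)

    def chain_residues(self, chain_id: str) -> list[ResidueKey]:
        return [k for k in self.residues if k.chain_id == chain_id]

    def copy(self) -> "Structure":
        return Structure(self.model_id, {k: list(v) for k, v in self.residues.items()})


@dataclass
class ChainMapping:
    """Residue-level correspondence between a reference and a model structure."""

    pairs: list[tuple[ResidueKey, ResidueKey]]

    def __post_init__(self) -> None:
        refs = [p[0] for p in self.pairs]
        mods = [p[1] for p in self.pairs]
        if len(set(refs)) != len(refs) or len(set(mods)) != len(mods):
            raise ValueError("chain mapping must be injective in both directions")
        for ref, mod in self.pairs:
            if ref.residue_name != mod.residue_name:
                raise ValueError(f"paired residues differ in type: {ref} vs {mod}")


@dataclass(frozen=True)
class StandardizePolicy:
    """What `standardize` removes.

    drop_zero_occupancy approximates the removal of disordered elements
    from reference structures; exact parity with any particular external
    preprocessing pipeline is not guaranteed.
    """

    remove_hydrogens: bool = True
    remove_hetero: bool = True
    remove_non_canonical: bool = True
    drop_zero_occupancy: bool = False


def read_structure(path: str | Path, fmt: str = "auto") -> list[Structure]:
    """Read a PDB or mmCIF file into a list of Structure, one per model.

    Multi-model files yield the frame/conformer list in file order.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if fmt == "pdb":
        parser = PDBParser(QUIET=True, PERMISSIVE=True)
    elif fmt == "mmcif":
        parser = MMCIFParser(QUIET=True)
    else:
        raise ConfigurationError(f"unknown structure format: {fmt!r}")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Biopython raises assorted exception types
        raise ParseError(f"failed to parse {path}: {exc}") from exc

    structures = [_convert_model(model, i) for i, model in enumerate(bio_structure)]
    if not structures or all(len(s) == 0 for s in structures):
        raise ParseError(f"no atoms found in {path}")
    return structures


def _convert_model(model, index: int) -> Structure:
    residues: dict[ResidueKey, list[AtomRecord]] = {}
    for chain in model:
        for residue in chain:
            hetflag, resnum, icode = residue.id
            key = ResidueKey(
                chain_id=chain.id,
                residue_number=resnum,
                insertion_code=icode.strip(),
                residue_name=residue.get_resname().strip(),
            )
            records = []
            for atom in residue.get_unpacked_list():
                occ = atom.get_occupancy()
                records.append(
                    AtomRecord(
                        atom_name=atom.get_name().strip(),
                        element=(atom.element or "").strip().upper(),
                        coords=tuple(float(x) for x in atom.get_coord()),
                        altloc=atom.get_altloc().strip(),
                        occupancy=1.0 if occ is None else min(max(float(occ), 0.0), 1.0),
                    )
                )
            if records:
                residues[key] = records
    return Structure(model_id=index, residues=residues)


def standardize(structure: Structure, policy: StandardizePolicy | None = None) -> Structure:
    """Return a new Structure restricted to heavy atoms of canonical residues.

    Hydrogens, waters, hetero and non-canonical residues are removed; for
    alternate locations the highest-occupancy conformer is kept, ties
    broken by lexicographically first altloc id.
    """
    policy = policy or StandardizePolicy()
    out: dict[ResidueKey, list[AtomRecord]] = {}
    for key, atoms in structure.residues.items():
        if key.residue_name == "HOH" or key.residue_name == "WAT":
            continue
        if policy.remove_non_canonical and key.residue_name not in CANONICAL_RESIDUES:
            continue
        kept: dict[str, AtomRecord] = {}
        for atom in atoms:
            if policy.remove_hydrogens and atom.element in {"H", "D"}:
                continue
            if policy.drop_zero_occupancy and atom.occupancy == 0.0:
                continue
            prev = kept.get(atom.atom_name)
            if prev is None:
                kept[atom.atom_name] = atom
            elif atom.occupancy > prev.occupancy or (
                atom.occupancy == prev.occupancy and atom.altloc < prev.altloc
            ):
                # higher occupancy wins; ties go to the first altloc id
                kept[atom.atom_name] = atom
        if kept:
            out[key] = [dataclasses.replace(a, altloc="") for a in kept.values()]
    if not out:
        raise EmptyStructureError(
            f"structure (model {structure.model_id}) has no canonical residues after standardization"
        )
    return Structure(model_id=structure.model_id, residues=out)


def chain_sequence(structure: Structure, chain_id: str) -> str:
    return "".join(
        THREE_TO_ONE.get(key.residue_name, "X") for key in structure.chain_residues(chain_id)
    )


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def pair_chains(
    reference: Structure, model: Structure, min_identity: float = 0.3
) -> ChainMapping:
    """Pair chains of two structures by global sequence alignment.

    Every reference chain is aligned against every model chain
    (match +1 / mismatch -1 / gap -2); chains are assigned greedily by
    descending alignment score, and aligned identical residues become
    mapping pairs.
    """
    aligner = _make_aligner()
    ref_chains = reference.chains()
    mod_chains = model.chains()
    scored: list[tuple[float, str, str]] = []
    alignments: dict[tuple[str, str], object] = {}
    for rc in ref_chains:
        for mc in mod_chains:
            ref_seq = chain_sequence(reference, rc)
            mod_seq = chain_sequence(model, mc)
            if not ref_seq or not mod_seq:
                continue
            aln = aligner.align(ref_seq, mod_seq)[0]
            scored.append((float(aln.score), rc, mc))
            alignments[(rc, mc)] = aln
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))

    used_ref: set[str] = set()
    used_mod: set[str] = set()
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    for score, rc, mc in scored:
        if rc in used_ref or mc in used_mod:
            continue
        aln = alignments[(rc, mc)]
        ref_keys = reference.chain_residues(rc)
        mod_keys = model.chain_residues(mc)
        chain_pairs = []
        matches = 0
        aligned = 0
        for (r0, r1), (m0, m1) in zip(*aln.aligned):
            for ri, mi in zip(range(r0, r1), range(m0, m1)):
                aligned += 1
                if ref_keys[ri].residue_name == mod_keys[mi].residue_name:
                    matches += 1
                    chain_pairs.append((ref_keys[ri], mod_keys[mi]))
        identity = matches / max(len(ref_keys), len(mod_keys))
        if identity < min_identity:
            continue
        used_ref.add(rc)
        used_mod.add(mc)
        pairs.extend(chain_pairs)

    if not pairs:
        raise PairingError(
            f"no chain pair exceeds the minimum identity of {min_identity:.2f}"
        )
    return ChainMapping(pairs=pairs)


def prune_to_common(
    reference: Structure, model: Structure, mapping: ChainMapping
) -> tuple[Structure, Structure]:
    """Restrict both structures to mapped residues and shared atom names.

    The outputs have identical residue and atom inventories in
    corresponding order, which is what positional anchor pairing needs.
    """
    ref_out: dict[ResidueKey, list[AtomRecord]] = {}
    mod_out: dict[ResidueKey, list[AtomRecord]] = {}
    for ref_key, mod_key in mapping.pairs:
        ref_atoms = {a.atom_name: a for a in reference.residues.get(ref_key, [])}
        mod_atoms = {a.atom_name: a for a in model.residues.get(mod_key, [])}
        common = [name for name in ref_atoms if name in mod_atoms]
        if not common:
            continue
        ref_out[ref_key] = [ref_atoms[n] for n in common]
        mod_out[mod_key] = [mod_atoms[n] for n in common]
    if not ref_out:
        raise EmptyStructureError("no common atoms remain after pruning")
    return (
        Structure(model_id=reference.model_id, residues=ref_out),
        Structure(model_id=model.model_id, residues=mod_out),
    )


def write_pdb(structures: Structure | Iterable[Structure], path: str | Path) -> None:
    """Write one or more models as a (multi-model) PDB file.

    Used for fixtures and debugging; coordinates are written with the
    standard %8.3f precision.
    """
    if isinstance(structures, Structure):
        structures = [structures]
    structures = list(structures)
    multi = len(structures) > 1
    lines: list[str] = []
    for structure in structures:
        if multi:
            lines.append(f"MODEL     {structure.model_id + 1:>4d}")
        serial = 1
        last_chain = None
        for key, atoms in structure.residues.items():
            last_chain = key.chain_id
            for atom in atoms:
                name = atom.atom_name
                # PDB atom-name column rules: 1-char elements start in col 14
                padded = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:>5d} {padded}{atom.altloc or ' '}"
                    f"{key.residue_name:>3s} {key.chain_id}{key.residue_number:>4d}"
                    f"{key.insertion_code or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        if last_chain is not None:
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def iter_residue_arrays(structure: Structure) -> Iterator[tuple[ResidueKey, np.ndarray]]:
    """Yield (ResidueKey, (n_atoms, 3) coordinate array) per residue."""
    for key, atoms in structure.residues.items():
        yield key, np.array([a.coords for a in atoms], dtype=float)
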