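"""Primitive typing schemes: map structures to typed point clouds.

Four schemes are shipped: ``FA`` (one primitive per heavy atom), ``CG``
(one site per chemical group), and their ``+Cent`` variants which add a
virtual primitive at the geometric center of every residue's heavy
atoms.  Rule tables live in packaged plain-text files (``data/*.txt``)
and can be overridden with a user-supplied file of the same format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from locohd.errors import ConfigurationError, DomainError
from locohd.structure_io import ResidueKey, Structure

logger = logging.getLogger(__name__)

CENT_TYPE = "Cent"

_SCHEME_FILES = {
    "FA": ("fa_rules.txt", False),
    "FA+Cent": ("fa_rules.txt", True),
    "CG": ("cg_rules.txt", False),
    "CG+Cent": ("cg_rules.txt", True),
}


class TypingError(DomainError):
    """An atom has no covering rule under a strict (full-atom) scheme."""


@dataclass(frozen=True)
class TypingRule:
    residue_name: str  # "*" matches every canonical residue
    atom_names: tuple[str, ...]
    ptype: str
    mode: str  # "atom": one site per atom; "group": one centroid site

    def __post_init__(self) -> None:
        if self.mode not in ("atom", "group"):
            raise ConfigurationError(f"unknown rule mode {self.mode!r}")


@dataclass
class TypingScheme:
    """A named, inspectable rule table."""

    name: str
    type_set: tuple[str, ...]
    rules: list[TypingRule]
    strict: bool = False
    cterm_rule: TypingRule | None = None
    with_cent: bool = False

    def rules_for(self, residue_name: str) -> list[TypingRule]:
        return [r for r in self.rules if r.residue_name in ("*", residue_name)]


@dataclass(frozen=True)
class PrimitiveAtom:
    """A typed point with the identity of its source residue."""

    ptype: str
    coords: tuple[float, float, float]
    source: ResidueKey

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise ValueError("non-finite primitive atom coordinates")


@dataclass
class PrimitiveCloud:
    atoms: list[PrimitiveAtom]
    scheme: str
    type_set: tuple[str, ...] = ()
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


def parse_rule_file(text: str, name: str) -> TypingScheme:
    """Parse the plain-text rule table format (see ``data/fa_rules.txt``)."""
    type_set: tuple[str, ...] = ()
    strict = False
    cterm: TypingRule | None = None
    rules: list[TypingRule] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "@types":
            type_set = tuple(parts[1].split(","))
        elif parts[0] == "@strict":
            strict = True
        elif parts[0] == "@cterm":
            if len(parts) != 4:
                raise ConfigurationError(f"line {lineno}: @cterm needs atoms, ptype, mode")
            cterm = TypingRule("*", tuple(parts[1].split(",")), parts[2], parts[3])
        elif len(parts) == 4:
            rules.append(TypingRule(parts[0], tuple(parts[1].split(",")), parts[2], parts[3]))
        else:
            raise ConfigurationError(f"line {lineno}: malformed rule {raw!r}")
    if not type_set:
        raise ConfigurationError("rule table declares no @types line")
    for rule in rules + ([cterm] if cterm else []):
        if rule.ptype not in type_set:
            raise ConfigurationError(
                f"rule type {rule.ptype!r} not in declared type set {type_set}"
            )
    return TypingScheme(name=name, type_set=type_set, rules=rules, strict=strict, cterm_rule=cterm)


def list_scheme(scheme_name: str, scheme_file: str | Path | None = None) -> TypingScheme:
    """Return the full declarative scheme for one of FA, CG, FA+Cent, CG+Cent.

    With ``scheme_file``, the packaged table is replaced by the user's;
    the ``+Cent`` suffix of ``scheme_name`` still controls centroid sites.
    """
    if scheme_name not in _SCHEME_FILES:
        raise ConfigurationError(
            f"unknown scheme {scheme_name!r}; expected one of {sorted(_SCHEME_FILES)}"
        )
    filename, with_cent = _SCHEME_FILES[scheme_name]
    if scheme_file is not None:
        text = Path(scheme_file).read_text()
    else:
        text = resources.files("locohd.data").joinpath(filename).read_text()
    scheme = parse_rule_file(text, scheme_name)
    scheme.with_cent = with_cent
    if with_cent:
        scheme.type_set = scheme.type_set + (CENT_TYPE,)
    return scheme


def apply_scheme(
    structure: Structure,
    scheme: str | TypingScheme,
    scheme_file: str | Path | None = None,
    provenance: str = "",
) -> PrimitiveCloud:
    """Map a standardized structure to its primitive atom cloud.

    Emission order is deterministic: file residue order, then rule order
    within each residue, with the Cent site (if any) last.
    """
    if isinstance(scheme, str):
        scheme = list_scheme(scheme, scheme_file)
    atoms_out: list[PrimitiveAtom] = []
    for key, atom_list in structure.residues.items():
        by_name = {a.atom_name: a for a in atom_list}
        has_oxt = scheme.cterm_rule is not None and any(
            n in by_name for n in scheme.cterm_rule.atom_names
        ) and "OXT" in by_name
        reserved: set[str] = set(scheme.cterm_rule.atom_names) if has_oxt else set()
        covered: set[str] = set()

        def emit(rule: TypingRule, names: tuple[str, ...]) -> None:
            present = [n for n in names if n in by_name]
            if not present:
                return
            covered.update(present)
            if rule.mode == "atom":
                for n in present:
                    atoms_out.append(PrimitiveAtom(rule.ptype, by_name[n].coords, key))
            else:
                if len(present) < len(names):
                    logger.debug(
                        "group %s of %s incomplete (%d/%d atoms present)",
                        rule.ptype, key, len(present), len(names),
                    )
                center = np.mean([by_name[n].coords for n in present], axis=0)
                atoms_out.append(PrimitiveAtom(rule.ptype, tuple(float(x) for x in center), key))

        for rule in scheme.rules_for(key.residue_name):
            names = tuple(n for n in rule.atom_names if n not in reserved)
            emit(rule, names)
        if has_oxt:
            emit(scheme.cterm_rule, scheme.cterm_rule.atom_names)
        if scheme.strict:
            missing = sorted(set(by_name) - covered)
            if missing:
                raise TypingError(
                    f"scheme {scheme.name} has no rule for atom(s) {missing} of {key}"
                )
        if scheme.with_cent:
            center = np.mean([a.coords for a in atom_list], axis=0)
            atoms_out.append(PrimitiveAtom(CENT_TYPE, tuple(float(x) for x in center), key))
    return PrimitiveCloud(
        atoms=atoms_out,
        scheme=scheme.name,
        type_set=scheme.type_set,
        provenance=provenance or f"model-{structure.model_id}",
    )
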