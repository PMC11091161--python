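"""The local composition Hellinger distance itself.

An anchor's *environment* is its distance-sorted list of typed
neighbors.  At any radius ``r`` the environment induces a composition
vector (fraction of each primitive type among atoms within ``r``); the
score for an anchor pair is the average Hellinger distance between the
two composition profiles, weighted by a probability density over the
radius.  Because compositions only change at neighbor distances, the
integral collapses to an exact finite sum over breakpoint intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from locohd.errors import DomainError
from locohd.primitives import CENT_TYPE, PrimitiveCloud


@dataclass(frozen=True)
class UniformWeight:
    """Uniform probability density on (lower, upper) Å, exposed via its CDF."""

    lower: float = 3.0
    upper: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower < self.upper:
            raise DomainError(f"invalid weight bounds ({self.lower}, {self.upper})")

    def cumulative(self, r: float) -> float:
        """W(r); clamps to [0, 1] outside the support.  W(inf) = 1."""
        if r <= self.lower:
            return 0.0
        if r >= self.upper:
            return 1.0
        return (r - self.lower) / (self.upper - self.lower)

    def density(self, r: float) -> float:
        return 1.0 / (self.upper - self.lower) if self.lower < r < self.upper else 0.0


@dataclass(frozen=True)
class ComparisonSettings:
    """Settings shared by every comparison in a run.

    Defaults: uniform weight on 3-10 Å, hetero-residue contacts only,
    truncation at the weight's upper bound (atoms beyond it cannot
    affect the score).
    """

    scheme_name: str = "FA"
    weight: UniformWeight = field(default_factory=UniformWeight)
    hetero_only: bool = True
    truncation_radius: float | None = None

    def __post_init__(self) -> None:
        trunc = self.truncation_radius
        if trunc is not None and trunc < self.weight.upper:
            raise DomainError(
                f"truncation radius {trunc} below the weight upper bound {self.weight.upper}"
            )

    @property
    def effective_truncation(self) -> float:
        return self.weight.upper if self.truncation_radius is None else self.truncation_radius


@dataclass
class Environment:
    """An anchor plus its (distance, primitive type) neighbor list.

    The anchor itself is always the first entry at 0 Å; distances are
    sorted ascending.
    """

    anchor_ptype: str
    neighbors: list[tuple[float, str]]
    type_set: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.neighbors or self.neighbors[0] != (0.0, self.anchor_ptype):
            raise DomainError("environment must start with its anchor at 0 Å")
        dists = [d for d, _ in self.neighbors]
        if any(d < 0 for d in dists) or any(a > b for a, b in zip(dists, dists[1:])):
            raise DomainError("neighbor distances must be non-negative and sorted")
        unknown = {t for _, t in self.neighbors} - set(self.type_set)
        if unknown:
            raise DomainError(f"neighbor types {unknown} not in type set {self.type_set}")

    @property
    def distances(self) -> np.ndarray:
        return np.array([d for d, _ in self.neighbors], dtype=float)


def build_environment(
    cloud: PrimitiveCloud, anchor_index: int, settings: ComparisonSettings
) -> Environment:
    """Collect the typed neighborhood of one anchor atom.

    Atoms beyond the truncation radius are dropped; with
    ``hetero_only`` atoms sharing the anchor's source residue are
    dropped too (the anchor itself is exempt).  Ties in distance keep
    cloud order, which makes outputs byte-stable.
    """
    if not 0 <= anchor_index < len(cloud.atoms):
        raise DomainError(f"anchor index {anchor_index} out of range")
    anchor = cloud.atoms[anchor_index]
    coords = cloud.coords_array()
    dists = np.linalg.norm(coords - np.asarray(anchor.coords), axis=1)
    trunc = settings.effective_truncation
    entries: list[tuple[float, str]] = [(0.0, anchor.ptype)]
    order = np.argsort(dists[np.arange(len(dists)) != anchor_index], kind="stable")
    others = [i for i in range(len(cloud.atoms)) if i != anchor_index]
    for j in order:
        i = others[j]
        d = float(dists[i])
        if d > trunc:
            continue
        atom = cloud.atoms[i]
        if settings.hetero_only and atom.source == anchor.source:
            continue
        entries.append((d, atom.ptype))
    return Environment(anchor_ptype=anchor.ptype, neighbors=entries, type_set=cloud.type_set)


def ddec(env: Environment, r: float) -> np.ndarray:
    """Composition vector at radius ``r``: per-type fraction of atoms within ``r``.

    ``r = 0`` is valid (the anchor alone); the result always sums to 1
    because the anchor guarantees at least one atom at every radius.
    """
    if r < 0:
        raise DomainError(f"radius must be non-negative, got {r}")
    index = {t: i for i, t in enumerate(env.type_set)}
    counts = np.zeros(len(env.type_set), dtype=float)
    for d, t in env.neighbors:
        if d <= r:
            counts[index[t]] += 1
    return counts / counts.sum()


def hellinger(p: np.ndarray, q: np.ndarray) -> float:
    """Hellinger distance between two composition vectors: sqrt(½ Σ (√p−√q)²)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise DomainError(f"composition vectors differ in dimension: {p.shape} vs {q.shape}")
    return float(np.sqrt(0.5 * np.sum((np.sqrt(p) - np.sqrt(q)) ** 2)))


def _counts_matrix(env: Environment, breakpoints: np.ndarray) -> np.ndarray:
    """Cumulative per-type counts at each breakpoint (atoms with d <= breakpoint)."""
    index = {t: i for i, t in enumerate(env.type_set)}
    n_types = len(env.type_set)
    dists = env.distances
    type_ids = np.array([index[t] for _, t in env.neighbors])
    counts = np.zeros((len(breakpoints), n_types), dtype=float)
    for k, r in enumerate(breakpoints):
        inside = type_ids[dists <= r]
        if inside.size:
            counts[k] = np.bincount(inside, minlength=n_types)
    return counts


def locohd_pair(envA: Environment, envB: Environment, weight: UniformWeight) -> float:
    """Exact piecewise evaluation of the weighted Hellinger integral.

    Breakpoints are the merged neighbor distances of both environments;
    on each open interval both compositions are constant (counting atoms
    at distance <= the interval's lower edge), and the final interval to
    infinity carries weight 1 − W(last breakpoint).
    """
    if envA.type_set != envB.type_set:
        raise DomainError(
            f"environments use different type sets: {envA.type_set} vs {envB.type_set}"
        )
    breaks = np.unique(np.concatenate([envA.distances, envB.distances]))
    countsA = _counts_matrix(envA, breaks)
    countsB = _counts_matrix(envB, breaks)
    compsA = countsA / countsA.sum(axis=1, keepdims=True)
    compsB = countsB / countsB.sum(axis=1, keepdims=True)
    h = np.sqrt(0.5 * np.sum((np.sqrt(compsA) - np.sqrt(compsB)) ** 2, axis=1))
    w = np.array([weight.cumulative(r) for r in breaks] + [1.0])
    return float(np.sum(h * np.diff(w)))


def compare_clouds(
    cloudA: PrimitiveCloud,
    cloudB: PrimitiveCloud,
    anchor_pairs: list[tuple[int, int]],
    settings: ComparisonSettings,
) -> list[float]:
    """Score a list of (indexA, indexB) anchor pairs; order is preserved."""
    if cloudA.scheme != cloudB.scheme:
        raise DomainError(f"scheme mismatch: {cloudA.scheme} vs {cloudB.scheme}")
    scores = []
    for ia, ib in anchor_pairs:
        envA = build_environment(cloudA, ia, settings)
        envB = build_environment(cloudB, ib, settings)
        scores.append(locohd_pair(envA, envB, settings.weight))
    return scores


def default_anchor_pairs(
    cloudA: PrimitiveCloud, cloudB: PrimitiveCloud, mode: str = "all_primitive"
) -> list[tuple[int, int]]:
    """Standard anchor pairings.

    ``all_primitive`` pairs positionally and requires identical
    inventories (same protein / pruned pair); ``centroid`` pairs the
    Cent site of corresponding residues and requires a +Cent scheme.
    """
    if cloudA.scheme != cloudB.scheme:
        raise DomainError(f"scheme mismatch: {cloudA.scheme} vs {cloudB.scheme}")
    if mode == "all_primitive":
        if len(cloudA) != len(cloudB) or any(
            a.ptype != b.ptype for a, b in zip(cloudA.atoms, cloudB.atoms)
        ):
            raise DomainError(
                "clouds differ in primitive inventory; run prune_to_common on the "
                "structures before all-primitive anchor pairing"
            )
        return [(i, i) for i in range(len(cloudA))]
    if mode == "centroid":
        idxA = [i for i, a in enumerate(cloudA.atoms) if a.ptype == CENT_TYPE]
        idxB = [i for i, a in enumerate(cloudB.atoms) if a.ptype == CENT_TYPE]
        if not idxA or not idxB:
            raise DomainError(
                f"centroid anchors require a +Cent scheme (got {cloudA.scheme})"
            )
        if len(idxA) != len(idxB):
            raise DomainError(
                f"residue counts differ ({len(idxA)} vs {len(idxB)}); "
                "supply an explicit residue correspondence"
            )
        return list(zip(idxA, idxB))
    raise DomainError(f"unknown anchor mode {mode!r}")
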