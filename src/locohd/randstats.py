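"""Random residue-pair score distributions and their statistics.

Structures are shuffled, consumed in successive disjoint pairs, and
within each structure pair every residue of the smaller structure is
randomly paired (without replacement) with a residue of the larger one.
Scoring the pairs with centroid anchors yields an empirical score
distribution, which is summarized per residue-type pair and modeled
with a Beta distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from locohd.core import ComparisonSettings, build_environment, locohd_pair
from locohd.errors import DomainError
from locohd.primitives import CENT_TYPE, apply_scheme
from locohd.structure_io import ResidueKey, Structure

#: one-sided 95% standard-normal quantile used for the CI half-width rule
Z_95 = 1.6449

AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)


@dataclass(frozen=True)
class LabeledScoreSample:
    score: float
    type_pair: tuple[str, str]  # lexicographically ordered
    provenance: tuple[str, str]

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.type_pair != tuple(sorted(self.type_pair)):
            raise ValueError("type_pair must be order-normalized")


@dataclass(frozen=True)
class BetaFit:
    alpha: float
    beta_param: float
    ks_statistic: float
    ks_pvalue: float


@dataclass(frozen=True)
class DescriptorRow:
    type_pair: tuple[str, str]
    n: int
    mean: float
    median: float
    stdev: float | None
    ci_halfwidth: float | None
    minimum: float
    maximum: float


def random_pairs(
    structures: list[Structure], rng_seed: int
) -> list[tuple[tuple[int, ResidueKey], tuple[int, ResidueKey]]]:
    """Draw uncorrelated residue pairs from a structure list.

    Returns ((structure index, ResidueKey), (structure index,
    ResidueKey)) tuples; with an odd structure count the last shuffled
    structure is unused.
    """
    if len(structures) < 2:
        raise DomainError("random pairing needs at least 2 structures")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(structures))
    pairs = []
    for k in range(0, len(order) - 1, 2):
        i, j = int(order[k]), int(order[k + 1])
        res_i = list(structures[i].residues)
        res_j = list(structures[j].residues)
        if len(res_i) > len(res_j):
            i, j, res_i, res_j = j, i, res_j, res_i
        chosen = rng.choice(len(res_j), size=len(res_i), replace=False)
        for a, b in zip(res_i, chosen):
            pairs.append(((i, a), (j, res_j[int(b)])))
    return pairs


def score_pairs(
    structures: list[Structure],
    pairs: list[tuple[tuple[int, ResidueKey], tuple[int, ResidueKey]]],
    settings: ComparisonSettings | None = None,
) -> list[LabeledScoreSample]:
    """Score residue pairs through their Cent anchors.

    Cross-residue-type comparison requires the residue centroid
    primitive atoms as anchors, so only +Cent schemes are accepted.
    """
    settings = settings or ComparisonSettings(scheme_name="FA+Cent")
    if not settings.scheme_name.endswith("+Cent"):
        raise DomainError(
            "random residue pairing requires a +Cent scheme: only residue "
            "centroid primitive atoms can anchor comparisons between "
            "arbitrary residue types"
        )
    needed = sorted({i for pair in pairs for i, _ in pair})
    clouds = {
        i: apply_scheme(structures[i], settings.scheme_name, provenance=str(i)) for i in needed
    }
    cent_index: dict[int, dict[ResidueKey, int]] = {}
    for i, cloud in clouds.items():
        cent_index[i] = {
            a.source: idx for idx, a in enumerate(cloud.atoms) if a.ptype == CENT_TYPE
        }
    env_cache: dict[tuple[int, ResidueKey], object] = {}

    def env_for(i: int, key: ResidueKey):
        tag = (i, key)
        if tag not in env_cache:
            env_cache[tag] = build_environment(clouds[i], cent_index[i][key], settings)
        return env_cache[tag]

    samples = []
    for (i, key_a), (j, key_b) in pairs:
        score = locohd_pair(env_for(i, key_a), env_for(j, key_b), settings.weight)
        type_pair = tuple(sorted((key_a.residue_name, key_b.residue_name)))
        samples.append(
            LabeledScoreSample(
                score=score,
                type_pair=type_pair,
                provenance=(f"{i}:{key_a}", f"{j}:{key_b}"),
            )
        )
    return samples


def fit_beta(samples: np.ndarray, eps: float = 1e-9) -> BetaFit:
    """Maximum-likelihood Beta fit on (0, 1) plus a one-sample KS test.

    Values at exactly 0 or 1 are clipped inward by ``eps``.  The KS
    p-value uses the asymptotic distribution without a refitting
    correction.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise DomainError("beta fit needs at least 10 samples")
    if np.any((x < 0) | (x > 1)):
        raise DomainError("samples must lie in [0, 1]")
    x = np.clip(x, eps, 1.0 - eps)
    alpha, beta_param, _, _ = stats.beta.fit(x, floc=0.0, fscale=1.0)
    ks = stats.kstest(x, stats.beta(alpha, beta_param).cdf)
    return BetaFit(
        alpha=float(alpha),
        beta_param=float(beta_param),
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )


def ci_halfwidth(stdev: float, n: int) -> float:
    """Half-width of the reported confidence interval: z·s/√n with z = 1.6449."""
    return Z_95 * stdev / np.sqrt(n)


def descriptor_table(samples: list[LabeledScoreSample]) -> list[DescriptorRow]:
    """Per-type-pair summary rows (n, mean, median, stdev, CI, min, max).

    Rows are sorted by ascending mean; stdev (divisor n−1) and the CI
    are reported missing for single-sample groups.
    """
    groups: dict[tuple[str, str], list[float]] = {}
    for s in samples:
        groups.setdefault(s.type_pair, []).append(s.score)
    rows = []
    for pair, values in groups.items():
        v = np.array(values, dtype=float)
        n = v.size
        stdev = float(np.std(v, ddof=1)) if n > 1 else None
        rows.append(
            DescriptorRow(
                type_pair=pair,
                n=n,
                mean=float(v.mean()),
                median=float(np.median(v)),
                stdev=stdev,
                ci_halfwidth=ci_halfwidth(stdev, n) if stdev is not None else None,
                minimum=float(v.min()),
                maximum=float(v.max()),
            )
        )
    rows.sort(key=lambda r: (r.mean, r.type_pair))
    return rows


def mean_matrix(samples: list[LabeledScoreSample]) -> np.ndarray:
    """20×20 symmetric matrix of per-type-pair mean scores (NaN where unseen).

    Rows/columns follow ``AMINO_ACIDS`` order.
    """
    index = {name: i for i, name in enumerate(AMINO_ACIDS)}
    sums = np.zeros((20, 20))
    counts = np.zeros((20, 20))
    for s in samples:
        a, b = s.type_pair
        ia, ib = index[a], index[b]
        sums[ia, ib] += s.score
        counts[ia, ib] += 1
        if ia != ib:
            sums[ib, ia] += s.score
            counts[ib, ia] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
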