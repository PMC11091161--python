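"""Application pipelines built on the core metric.

Three families: ensemble distance matrices (with SVD-superposition RMSD
for comparison and complete-linkage clustering), reference-vs-model
scoring with optional external per-residue score columns, and
trajectory time series screened with Sarle's bimodality coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from locohd.core import ComparisonSettings, build_environment, compare_clouds, default_anchor_pairs, locohd_pair
from locohd.errors import DomainError
from locohd.primitives import PrimitiveCloud, apply_scheme
from locohd.structure_io import ResidueKey, Structure

#: Bimodality of the uniform distribution; values above it suggest bimodality.
BIMODALITY_REFERENCE = 5.0 / 9.0


@dataclass
class ScoreMatrix:
    """Symmetric zero-diagonal N×N structure-structure distance matrix."""

    values: np.ndarray
    labels: list[str]
    metric: str  # "locohd" or "rmsd"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DomainError("score matrix must be square")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise DomainError("score matrix must be symmetric with a zero diagonal")
        self.values = v

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


@dataclass
class AnchorSeries:
    anchor_id: str
    times: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.times.shape != self.scores.shape:
            raise DomainError("times and scores must have equal length")


@dataclass(frozen=True)
class BimodalityResult:
    beta: float
    skewness: float
    kurtosis: float


def _clouds_for(structures: list[Structure], settings: ComparisonSettings) -> list[PrimitiveCloud]:
    clouds = [apply_scheme(s, settings.scheme_name, provenance=str(i)) for i, s in enumerate(structures)]
    first = clouds[0]
    for c in clouds[1:]:
        if len(c) != len(first) or any(a.ptype != b.ptype for a, b in zip(c.atoms, first.atoms)):
            raise DomainError(
                "ensemble members differ in primitive inventory; standardize and "
                "prune the structures to a common atom set first"
            )
    return clouds


def ensemble_matrices(
    structures: list[Structure], settings: ComparisonSettings
) -> tuple[list[ScoreMatrix], ScoreMatrix, np.ndarray]:
    """All-against-all comparison of an ensemble, anchor by anchor.

    For M anchors and N structures this performs M·N·(N−1)/2 pair
    scores.  Returns (per-anchor matrices, the per-pair mean matrix,
    per-anchor mean scores over all pairs).
    """
    if len(structures) < 2:
        raise DomainError("an ensemble needs at least two structures")
    clouds = _clouds_for(structures, settings)
    n = len(clouds)
    m = len(clouds[0])
    labels = [c.provenance for c in clouds]
    # cache environments: M x N builds instead of M x N x (N-1) rebuilds
    envs = [[build_environment(c, a, settings) for c in clouds] for a in range(m)]
    per_anchor = np.zeros((m, n, n), dtype=float)
    for a in range(m):
        for i in range(n):
            for j in range(i + 1, n):
                s = locohd_pair(envs[a][i], envs[a][j], settings.weight)
                per_anchor[a, i, j] = per_anchor[a, j, i] = s
    matrices = [ScoreMatrix(per_anchor[a], labels, "locohd") for a in range(m)]
    mean_matrix = ScoreMatrix(per_anchor.mean(axis=0), labels, "locohd")
    iu = np.triu_indices(n, k=1)
    per_anchor_means = per_anchor[:, iu[0], iu[1]].mean(axis=1)
    return matrices, mean_matrix, per_anchor_means


def kabsch_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """RMSD after optimal rigid superposition (SVD, reflections disallowed)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise DomainError(f"coordinate sets must share shape (n, 3); got {X.shape} vs {Y.shape}")
    if X.shape[0] < 3:
        raise DomainError("at least 3 points are required for superposition")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    U, _, Vt = np.linalg.svd(Xc.T @ Yc)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    diff = Xc - Yc @ R.T
    return float(np.sqrt((diff**2).sum() / X.shape[0]))


def rmsd_matrix(structures: list[Structure], scheme_name: str) -> ScoreMatrix:
    """Pairwise superposition RMSD over the scheme's primitive-atom coordinates."""
    settings = ComparisonSettings(scheme_name=scheme_name)
    clouds = _clouds_for(structures, settings)
    coords = [c.coords_array() for c in clouds]
    n = len(coords)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = kabsch_rmsd(coords[i], coords[j])
    return ScoreMatrix(values, [c.provenance for c in clouds], "rmsd")


def complete_linkage(
    matrix: ScoreMatrix, threshold: float | None = None, k: int | None = None
) -> np.ndarray:
    """Agglomerative complete-linkage clustering of a distance matrix.

    Cut either at a distance threshold or at a fixed cluster count.
    Labels are renumbered 0..n_clusters-1 in order of first appearance.
    """
    if (threshold is None) == (k is None):
        raise DomainError("specify exactly one of threshold or k")
    n = matrix.values.shape[0]
    if k is not None and not 1 <= k <= n:
        raise DomainError(f"cluster count {k} outside [1, {n}]")
    Z = linkage(squareform(matrix.values, checks=False), method="complete")
    if threshold is not None:
        raw = fcluster(Z, t=threshold, criterion="distance")
    else:
        raw = fcluster(Z, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        labels[i] = remap.setdefault(int(r), len(remap))
    return labels


def spearman(x: np.ndarray, y: np.ndarray) -> float | None:
    """Spearman rank correlation (midranks for ties); None when undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("inputs must be 1-d arrays of equal length")
    if x.size < 3:
        raise DomainError("at least 3 observations are required")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    rho = spearmanr(x, y).statistic
    return None if np.isnan(rho) else float(rho)


@dataclass
class ResidueScoreRow:
    key: ResidueKey
    locohd: float
    external: float | None = None


@dataclass
class ModelPairResult:
    rows: list[ResidueScoreRow]
    prm_locohd: float
    prm_external: float | None
    spearman_rho: float | None
    unjoined: int = 0


def score_model_pair(
    reference: Structure,
    model: Structure,
    settings: ComparisonSettings | None = None,
    external_scores: dict[ResidueKey, float] | None = None,
) -> ModelPairResult:
    """Per-residue centroid-anchored comparison of a model against a reference.

    Inputs must already be chain-paired and pruned to a common
    inventory.  Externally computed per-residue scores (e.g. lDDT) are
    joined by reference ResidueKey; residues without a score are kept
    for the LoCoHD column but excluded from the correlation.
    """
    settings = settings or ComparisonSettings(scheme_name="FA+Cent")
    cloud_ref = apply_scheme(reference, settings.scheme_name, provenance="reference")
    cloud_mod = apply_scheme(model, settings.scheme_name, provenance="model")
    pairs = default_anchor_pairs(cloud_ref, cloud_mod, mode="centroid")
    scores = compare_clouds(cloud_ref, cloud_mod, pairs, settings)
    ref_keys = [cloud_ref.atoms[ia].source for ia, _ in pairs]

    rows = []
    unjoined = 0
    for key, s in zip(ref_keys, scores):
        ext = None
        if external_scores is not None:
            ext = external_scores.get(key)
            if ext is None:
                unjoined += 1
        rows.append(ResidueScoreRow(key=key, locohd=s, external=ext))
    prm = float(np.median([r.locohd for r in rows]))
    joined = [(r.locohd, r.external) for r in rows if r.external is not None]
    prm_ext = float(np.median([e for _, e in joined])) if joined else None
    rho = None
    if len(joined) >= 3:
        rho = spearman(np.array([l for l, _ in joined]), np.array([e for _, e in joined]))
    return ModelPairResult(rows=rows, prm_locohd=prm, prm_external=prm_ext, spearman_rho=rho, unjoined=unjoined)


def trajectory_series(
    frames: list[Structure],
    reference_index: int = 0,
    settings: ComparisonSettings | None = None,
    stride: int = 1,
    anchor_mode: str = "centroid",
) -> list[AnchorSeries]:
    """Per-anchor LoCoHD of each strided frame against a reference frame."""
    settings = settings or ComparisonSettings(scheme_name="CG+Cent")
    if not 0 <= reference_index < len(frames):
        raise DomainError(f"reference index {reference_index} out of range")
    if stride < 1:
        raise DomainError("stride must be >= 1")
    clouds = _clouds_for(frames, settings)
    ref_cloud = clouds[reference_index]
    pairs = default_anchor_pairs(ref_cloud, ref_cloud, mode=anchor_mode)
    anchor_idx = [ia for ia, _ in pairs]
    if anchor_mode == "centroid":
        ids = [str(ref_cloud.atoms[i].source) for i in anchor_idx]
    else:
        ids = [f"{ref_cloud.atoms[i].source}:{ref_cloud.atoms[i].ptype}:{i}" for i in anchor_idx]
    frame_ids = list(range(0, len(frames), stride))
    ref_envs = [build_environment(ref_cloud, i, settings) for i in anchor_idx]
    series = np.zeros((len(anchor_idx), len(frame_ids)), dtype=float)
    for t, fi in enumerate(frame_ids):
        for a, i in enumerate(anchor_idx):
            env = build_environment(clouds[fi], i, settings)
            series[a, t] = locohd_pair(ref_envs[a], env, settings.weight)
    times = np.array(frame_ids, dtype=float)
    return [AnchorSeries(anchor_id=ids[a], times=times, scores=series[a]) for a in range(len(ids))]


def bimodality(samples: np.ndarray) -> BimodalityResult:
    """Sarle's bimodality coefficient β = (γ² + 1) / κ.

    γ and κ are the moment-based sample skewness and non-excess
    kurtosis with divisor-n central moments; this convention makes the
    uniform distribution land at 5/9 ≈ 0.555.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 4:
        raise DomainError("bimodality needs at least 4 samples")
    centered = x - x.mean()
    m2 = np.mean(centered**2)
    if m2 == 0:
        raise DomainError("bimodality is undefined for a constant sample")
    gamma = np.mean(centered**3) / m2**1.5
    kappa = np.mean(centered**4) / m2**2
    return BimodalityResult(beta=float((gamma**2 + 1) / kappa), skewness=float(gamma), kurtosis=float(kappa))


def rank_bimodal(series_list: list[AnchorSeries]) -> list[tuple[str, float]]:
    """Rank anchors by descending bimodality coefficient (ties by anchor id)."""
    ranked = [(s.anchor_id, bimodality(s.scores).beta) for s in series_list]
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return ranked
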