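"""Epitope binning from pairwise cross-competition ELISA matrices.

The competition matrix holds one detection OD per ordered antibody pair:
entry (i, j) is the signal with antibody *i* captured on the plate first and
antibody *j* pre-complexed with the antigen.  Low signal means *j* blocked
the epitope that *i* needs — the two antibodies compete.  Rows (competition
profiles of the first-captured antibody) are clustered with Ward's
minimum-variance method; the number of epitope groups is chosen at the
largest relative gap between successive merge heights, and the grouping is
cross-checked by PCA and by clustering the transposed matrix.

Ward's method is implemented directly through the Lance–Williams recurrence
so that merge order and the tie-break (smallest original leaf index) are
fully specified; heights follow the convention
``h(i, j) = sqrt(2 * ni * nj / (ni + nj)) * ||ci - cj||`` which for two
singletons reduces to the Euclidean distance between the profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score


@dataclass
class CompetitionMatrix:
    """Ordered square matrix of first-antibody x second-antibody signals."""

    antibody_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.antibody_ids)
        if self.values.shape != (n, n):
            raise ValueError("competition matrix must be square and match the id list")
        if len(set(self.antibody_ids)) != n:
            raise ValueError("antibody ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("competition matrix must be finite")

    @property
    def n(self) -> int:
        return len(self.antibody_ids)


@dataclass
class Dendrogram:
    """Agglomerative merge history (scipy linkage convention for ids).

    Leaves are 0..n-1; the cluster created at step *s* has id ``n + s``.
    ``merges`` rows are (left, right, height, size).
    """

    n_leaves: int
    merges: list[tuple[int, int, float, int]]
    method: str = "ward"

    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def to_scipy_linkage(self) -> np.ndarray:
        return np.array(
            [[left, right, height, size] for left, right, height, size in self.merges],
            dtype=float,
        )

    def cut(self, k: int) -> np.ndarray:
        """Labels (0..k-1) obtained by undoing the last k-1 merges."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError("k out of range")
        parent = list(range(self.n_leaves + len(self.merges)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for step, (left, right, _, _) in enumerate(self.merges[: self.n_leaves - k]):
            new = self.n_leaves + step
            parent[find(left)] = new
            parent[find(right)] = new
        roots = {find(i) for i in range(self.n_leaves)}
        relabel = {r: i for i, r in enumerate(sorted(roots))}
        return np.array([relabel[find(i)] for i in range(self.n_leaves)])


@dataclass
class EpitopeGroups:
    """Selected grouping with diagnostics."""

    k: int
    labels: np.ndarray
    antibody_ids: list[str]
    cut_height: float
    separation: float | None = None
    asymmetric_pairs: list[tuple[str, str]] = field(default_factory=list)


def normalize_matrix(
    matrix: CompetitionMatrix, control_column: str | None = None
) -> CompetitionMatrix:
    """Scale each row to [0, 1] by its no-competition reference signal.

    By default the reference is the row maximum (the least-competed pair);
    an explicit no-competition control column can be named instead.  Rows
    with zero range cannot be normalized and raise.
    """
    values = matrix.values
    if control_column is not None:
        ref = values[:, matrix.antibody_ids.index(control_column)]
    else:
        ref = values.max(axis=1)
    span = values.max(axis=1) - values.min(axis=1)
    if np.any(span <= 0) or np.any(ref <= 0):
        bad = [matrix.antibody_ids[i] for i in np.where((span <= 0) | (ref <= 0))[0]]
        raise ValueError(f"zero-range rows cannot be normalized: {bad}")
    return CompetitionMatrix(
        antibody_ids=list(matrix.antibody_ids), values=values / ref[:, None]
    )


def _ward_merge_height(d2: float) -> float:
    return float(np.sqrt(d2))


def ward_cluster(profiles: np.ndarray | CompetitionMatrix) -> Dendrogram:
    """Agglomerate row profiles with Ward's minimum-variance criterion.

    Uses the Lance–Williams update on squared Euclidean distances; the pair
    with the smallest merge cost merges first, ties broken by the smallest
    original leaf index contained in either cluster.
    """
    if isinstance(profiles, CompetitionMatrix):
        x = profiles.values
    else:
        x = np.asarray(profiles, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two row profiles")
    if not np.all(np.isfinite(x)):
        raise ValueError("profiles must be finite")

    n = x.shape[0]
    # squared Euclidean distances; for singletons the Ward merge cost
    # sqrt(2 * (1*1/2) * ||xi - xj||^2) equals the plain distance
    diff = x[:, None, :] - x[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)

    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    min_leaf: dict[int, int] = {i: i for i in range(n)}
    dist: dict[frozenset, float] = {
        frozenset((i, j)): d2[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float, int]] = []

    for step in range(n - 1):
        best_pair = None
        best_key = None
        for pair, val in dist.items():
            i, j = sorted(pair, key=lambda c: min_leaf[c])
            key = (val, min_leaf[i], min_leaf[j])
            if best_key is None or key < best_key:
                best_key = key
                best_pair = (i, j)
        i, j = best_pair
        new = n + step
        ni, nj = active[i], active[j]
        d_ij = dist.pop(frozenset((i, j)))
        merges.append((i, j, _ward_merge_height(d_ij), ni + nj))

        for k in list(active):
            if k in (i, j):
                continue
            nk = active[k]
            d_ik = dist.pop(frozenset((i, k)))
            d_jk = dist.pop(frozenset((j, k)))
            # Lance-Williams update for Ward on squared distances
            dist[frozenset((new, k))] = (
                (ni + nk) * d_ik + (nj + nk) * d_jk - nk * d_ij
            ) / (ni + nj + nk)

        del active[i], active[j]
        active[new] = ni + nj
        min_leaf[new] = min(min_leaf[i], min_leaf[j])

    return Dendrogram(n_leaves=n, merges=merges)


def select_k(
    dendrogram: Dendrogram,
    k_override: int | None = None,
    min_k: int = 1,
    max_k: int | None = None,
) -> tuple[int, float]:
    """Choose the number of clusters at the largest relative height gap.

    Automates manual dendrogram inspection: the cut goes where the relative
    jump ``(h[m+1] - h[m]) / h[m]`` between successive merge heights is
    largest, giving ``k = n_leaves - m_cut`` clusters.  When all gaps vanish
    (e.g. all heights equal) no cut is dominant and k = 1.  A manual
    override is accepted and returns the corresponding cut height.
    """
    n = dendrogram.n_leaves
    heights = dendrogram.heights()
    if k_override is not None:
        if not 1 <= k_override <= n:
            raise ValueError("k_override out of range")
        idx = n - k_override
        cut = float(heights[idx]) if idx < len(heights) else float(heights[-1])
        return k_override, cut
    if max_k is None:
        max_k = n
    eps = max(heights.max(), 1.0) * 1e-12
    best_k, best_gap = 1, 0.0
    for m in range(len(heights) - 1):  # gap between merge m and m+1 (0-based)
        k = n - (m + 1)
        if not min_k <= k <= max_k:
            continue
        gap = (heights[m + 1] - heights[m]) / max(heights[m], eps)
        if gap >= best_gap and gap > 0:
            best_gap, best_k = gap, k
    if best_gap <= 0:
        return 1, float(heights[-1])
    cut = float(heights[len(heights) - best_k + 1]) if best_k > 1 else float(heights[-1])
    return best_k, cut


def pca_confirm(
    profiles: np.ndarray | CompetitionMatrix,
    labels: np.ndarray | None = None,
    n_components: int = 3,
):
    """Project row profiles on their first principal components.

    Returns ``(coordinates, explained_variance_ratio, separation)`` where
    separation is the mean between-group centroid distance divided by the
    mean within-group spread (None without labels).  Degenerate inputs give
    fewer components with a warning.
    """
    x = profiles.values if isinstance(profiles, CompetitionMatrix) else np.asarray(profiles)
    if x.shape[0] < 4:
        raise ValueError("need at least 4 profiles for PCA confirmation")
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    ncomp = min(n_components, x.shape[0] - 1, x.shape[1], max(rank, 1))
    if ncomp < n_components:
        warnings.warn(
            f"rank-deficient profiles: returning {ncomp} components", RuntimeWarning
        )
    pca = PCA(n_components=ncomp)
    coords = pca.fit_transform(x)

    separation = None
    if labels is not None:
        labels = np.asarray(labels)
        centroids = {g: coords[labels == g].mean(axis=0) for g in np.unique(labels)}
        within = [
            np.linalg.norm(coords[i] - centroids[labels[i]]) for i in range(len(labels))
        ]
        cents = list(centroids.values())
        between = [
            np.linalg.norm(a - b) for i, a in enumerate(cents) for b in cents[i + 1 :]
        ]
        mean_within = float(np.mean(within))
        mean_between = float(np.mean(between)) if between else 0.0
        separation = mean_between / max(mean_within, 1e-12)
    return coords, pca.explained_variance_ratio_, separation


def transpose_check(matrix: CompetitionMatrix, k: int | None = None) -> float:
    """Agreement (adjusted Rand index) between row- and column-clusterings.

    Rows are the primary binning axis; re-running the same Ward analysis on
    the transposed matrix should give nearly the same partition when the
    competition pattern is close to symmetric.
    """
    rows = ward_cluster(matrix.values)
    cols = ward_cluster(matrix.values.T)
    if k is None:
        k, _ = select_k(rows)
    return float(adjusted_rand_score(rows.cut(k), cols.cut(k)))


def detect_asymmetry(
    matrix: CompetitionMatrix, margin: float = 0.3
) -> list[tuple[str, str]]:
    """Flag ordered pairs whose two orientations disagree by more than *margin*.

    The returned pair (i, j) is oriented so that competition shows with *i*
    captured first (low signal at (i, j)) but not in the reverse direction —
    the signature of an asymmetric binder whose blocking depends on which
    antibody saw the antigen first.
    """
    v = matrix.values
    pairs: list[tuple[str, str]] = []
    for i in range(matrix.n):
        for j in range(i + 1, matrix.n):
            if abs(v[i, j] - v[j, i]) > margin:
                if v[i, j] < v[j, i]:
                    pairs.append((matrix.antibody_ids[i], matrix.antibody_ids[j]))
                else:
                    pairs.append((matrix.antibody_ids[j], matrix.antibody_ids[i]))
    return pairs


def bin_epitopes(
    matrix: CompetitionMatrix,
    k_override: int | None = None,
    asymmetry_margin: float = 0.3,
    normalize: bool = True,
) -> EpitopeGroups:
    """Full binning pass: normalize, Ward-cluster, cut, confirm, flag."""
    norm = normalize_matrix(matrix) if normalize else matrix
    dendrogram = ward_cluster(norm)
    k, cut = select_k(dendrogram, k_override=k_override)
    labels = dendrogram.cut(k)
    separation = None
    if norm.n >= 4 and k > 1:
        _, _, separation = pca_confirm(norm, labels)
    return EpitopeGroups(
        k=k,
        labels=labels,
        antibody_ids=list(norm.antibody_ids),
        cut_height=cut,
        separation=separation,
        asymmetric_pairs=detect_asymmetry(norm, margin=asymmetry_margin),
    )
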