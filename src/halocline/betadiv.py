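"""Beta diversity: Bray-Curtis distances, PCoA, PERMANOVA, UPGMA tree.

PCoA follows the Gower double-centering construction; negative eigenvalues
(possible because Bray-Curtis is non-Euclidean) are reported raw but the
proportion explained is normalized over the positive eigenvalues only.
PERMANOVA uses Anderson's pseudo-F on squared distances with the +1
permutation p-value rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .tables import CountTable, RelativeAbundanceTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "bray_curtis",
    "pcoa",
    "permanova",
    "upgma",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances between samples, zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if np.isnan(v).any():
            raise ValueError("NaN in distance matrix")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class OrdinationResult:
    coordinates: np.ndarray          # samples x axes
    eigenvalues: np.ndarray          # all eigenvalues, descending (may be < 0)
    proportion_explained: np.ndarray  # per retained (positive) axis
    sample_ids: list[str]


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int


def bray_curtis(table: CountTable | RelativeAbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between samples."""
    if isinstance(table, RelativeAbundanceTable):
        data = table.proportions
    else:
        totals = table.sample_totals()
        if (totals == 0).any():
            j = int(np.argmax(totals == 0))
            raise ValueError(f"sample {table.sample_ids[j]!r} has zero total")
        data = table.counts
    if data.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(np.asarray(data, dtype=float).T, metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), d)


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis of a distance matrix.

    Eigendecomposition of the double-centered matrix -0.5 J D^2 J; coordinates
    are eigenvectors scaled by sqrt(eigenvalue) for positive eigenvalues.
    """
    d = dm.values
    n = dm.n
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    vals, vecs = eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > np.max([1e-12, 1e-10 * abs(vals[0])]) if n else vals > 0
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    total_pos = vals[pos].sum()
    prop = vals[pos] / total_pos if total_pos > 0 else np.zeros(0)
    return OrdinationResult(coords, vals, prop, list(dm.sample_ids))


def _group_sums(d2: np.ndarray, labels: np.ndarray):
    """Within-group sum of squared distances / group size, summed over groups."""
    ss_w = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_w += sub.sum() / (2 * len(idx))
    return ss_w


def permanova(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA (Anderson's pseudo-F).

    ``p = (1 + #{permuted F >= observed F}) / (n_perm + 1)``; labels are
    permuted freely (no strata) with a seeded generator.
    """
    labels = np.asarray([str(g) for g in groups])
    if len(labels) != dm.n:
        raise ValueError("group labels length must match number of samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA requires at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    rng = np.random.default_rng(seed)
    n, g = dm.n, len(uniq)
    d2 = dm.values**2
    ss_t = d2.sum() / (2 * n)

    def pseudo_f(lab):
        ss_w = _group_sums(d2, lab)
        ss_a = ss_t - ss_w
        return (ss_a / (g - 1)) / (ss_w / (n - g)), ss_a

    f_obs, ss_a = pseudo_f(labels)
    count = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        f_p, _ = pseudo_f(lab)
        if f_p >= f_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermanovaResult(float(f_obs), float(ss_a / ss_t), float(p), n_perm)


def upgma(dm: DistanceMatrix) -> str:
    """Average-linkage (UPGMA) tree as a newick string with branch lengths.

    Ultrametric: every leaf sits at distance (merge height)/2 from the root.
    Ties in the minimum pairwise distance break by the lexicographically
    smallest (sorted) pair of cluster labels.
    """
    if dm.n < 2:
        raise ValueError("UPGMA requires at least 2 samples")
    # cluster state: label (min leaf id, for tie-breaks), size, height, newick
    clusters = {
        i: {"label": sid, "size": 1, "height": 0.0, "nwk": sid}
        for i, sid in enumerate(dm.sample_ids)
    }
    dist = {
        (i, j): dm.values[i, j]
        for i in range(dm.n)
        for j in range(i + 1, dm.n)
    }
    next_id = dm.n
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                tuple(sorted((clusters[kv[0][0]]["label"], clusters[kv[0][1]]["label"]))),
            ),
        )
        (a, b), d_ab = best
        ca, cb = clusters.pop(a), clusters.pop(b)
        h = d_ab / 2.0
        nwk = (
            f"({ca['nwk']}:{h - ca['height']:.10g},"
            f"{cb['nwk']}:{h - cb['height']:.10g})"
        )
        new = {
            "label": min(ca["label"], cb["label"]),
            "size": ca["size"] + cb["size"],
            "height": h,
            "nwk": nwk,
        }
        # average linkage update
        for k in list(clusters):
            d_ak = dist.pop((min(a, k), max(a, k)))
            d_bk = dist.pop((min(b, k), max(b, k)))
            dist[(min(next_id, k), max(next_id, k))] = (
                ca["size"] * d_ak + cb["size"] * d_bk
            ) / new["size"]
        del dist[(a, b)]
        clusters[next_id] = new
        next_id += 1
    root = next(iter(clusters.values()))
    return root["nwk"] + ";"
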