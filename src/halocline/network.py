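"""Ensemble co-occurrence network inference (CoNet-style).

Association between taxon pairs is scored by four measures — Pearson and
Spearman correlation, Bray-Curtis similarity (1 - dissimilarity) and
symmetrized Kullback-Leibler divergence — each tested against a permutation
null that shuffles every taxon's values across samples independently and
then re-closes the columns to sum one.  The renormalization keeps the
compositional structure inside the null and so absorbs the spurious
negative correlations that closure induces.  Surviving candidates are
vetted by bootstrap (the edge is dropped when the null expectation lies
inside the bootstrap interval of the score), the per-method p-values are
merged with Brown's correlated-chi-square extension of Fisher's method, and
the merged p-values pass a Benjamini-Hochberg step-up at the target FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import chi2, rankdata
from statsmodels.stats.multitest import multipletests

from .tables import CountTable, RelativeAbundanceTable, to_relative, top_n_taxa

logger = logging.getLogger("halocline")

METHODS = ("pearson", "spearman", "bray_curtis", "kl")

__all__ = [
    "NetworkConfig",
    "EnsembleNetwork",
    "edge_scores",
    "permutation_null",
    "bootstrap_restore",
    "brown_merge",
    "bh_fdr",
    "build_network",
    "topology",
]


@dataclass
class NetworkConfig:
    methods: tuple[str, ...] = METHODS
    n_perm: int = 1000
    n_boot: int = 100
    q: float = 0.05
    top_n: int = 100
    renormalize: bool = True
    boot_min_frac: float = 0.5  # fraction of methods whose bootstrap must exclude null
    seed: int = 0


@dataclass
class EnsembleNetwork:
    graph: nx.Graph
    edges: pd.DataFrame          # accepted edges with scores, merged p, q, sign
    candidates: pd.DataFrame     # all scored pairs (diagnostics)
    config: NetworkConfig = field(default_factory=NetworkConfig)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


# ---------------------------------------------------------------------------
# vectorized scoring


def _row_profiles(x: np.ndarray) -> np.ndarray:
    """Row-normalize taxon profiles with a per-row pseudocount of half the
    smallest nonzero entry (KL needs strictly positive profiles)."""
    x = x.astype(float).copy()
    for i in range(x.shape[0]):
        nz = x[i][x[i] > 0]
        eps = nz.min() / 2 if nz.size else 1.0
        x[i] = x[i] + eps
    return x / x.sum(axis=1, keepdims=True)


def _condensed_corr(x: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    iu = np.triu_indices(x.shape[0], k=1)
    return c[iu]


def _score_matrix(x: np.ndarray, methods) -> dict[str, np.ndarray]:
    """Condensed (upper-triangle) pairwise scores for each method."""
    out = {}
    if "pearson" in methods:
        out["pearson"] = _condensed_corr(x)
    if "spearman" in methods:
        ranks = rankdata(x, axis=1)
        out["spearman"] = _condensed_corr(ranks)
    if "bray_curtis" in methods:
        with np.errstate(invalid="ignore"):
            out["bray_curtis"] = 1.0 - pdist(x, metric="braycurtis")
    if "kl" in methods:
        q = _row_profiles(x)
        lq = np.log(q)
        s = (q * lq).sum(axis=1)
        cross = q @ lq.T
        iu = np.triu_indices(x.shape[0], k=1)
        out["kl"] = (s[iu[0]] + s[iu[1]] - cross[iu] - cross.T[iu])
    return out


def edge_scores(
    table: RelativeAbundanceTable, methods=METHODS
) -> pd.DataFrame:
    """All pairwise association scores.

    Pairs involving a constant taxon have undefined correlation; they are
    flagged (``valid = False``) and excluded downstream.
    """
    x = table.proportions
    if x.shape[1] < 4:
        raise ValueError("need at least 4 samples to score associations")
    scores = _score_matrix(x, methods)
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    taxa = np.asarray(table.taxon_ids)
    df = pd.DataFrame({"taxon_a": taxa[iu[0]], "taxon_b": taxa[iu[1]]})
    for m in methods:
        df[m] = scores[m]
    const = x.std(axis=1) == 0
    bad = const[iu[0]] | const[iu[1]]
    df["valid"] = ~bad
    if bad.any():
        logger.info("edge_scores: %d pair(s) involve constant taxa; flagged", bad.sum())
    return df


# ---------------------------------------------------------------------------
# permutation null


def _permuted(x: np.ndarray, rng: np.random.Generator, renormalize: bool) -> np.ndarray:
    idx = np.argsort(rng.random(x.shape), axis=1)
    xp = np.take_along_axis(x, idx, axis=1)
    if renormalize:
        colsum = xp.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        xp = xp / colsum
    return xp


def _null_scores(
    x: np.ndarray, methods, n_perm: int, rng: np.random.Generator, renormalize: bool
) -> dict[str, np.ndarray]:
    """Null score matrices, shape (n_perm, n_pairs) per method."""
    out = {m: [] for m in methods}
    for _ in range(n_perm):
        s = _score_matrix(_permuted(x, rng, renormalize), methods)
        for m in methods:
            out[m].append(s[m])
    return {m: np.asarray(v) for m, v in out.items()}


def _two_sided_p(obs: np.ndarray, null: np.ndarray) -> np.ndarray:
    """(1 + #{|null - mean| >= |obs - mean|}) / (n_perm + 1), columnwise."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(null, axis=0)
    dev_obs = np.abs(obs - mu)
    dev_null = np.abs(null - mu)
    count = np.nansum(dev_null >= dev_obs[None, :] - 1e-15, axis=0)
    return (1.0 + count) / (null.shape[0] + 1.0)


def permutation_null(
    table: RelativeAbundanceTable,
    pair: tuple[str, str],
    method: str,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    renormalize: bool = True,
):
    """Null score sample and two-sided permutation p for one taxon pair.

    Each permutation shuffles the taxa's values across samples independently;
    with ``renormalize`` the whole table is shuffled row-wise and columns are
    re-closed to sum 1 before scoring, keeping compositional effects in the
    null.
    """
    if n_perm < 10:
        raise ValueError("n_perm < 10 is uninformative")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse p-value", RuntimeWarning, stacklevel=2)
    a, b = pair
    ia, ib = table.taxon_ids.index(a), table.taxon_ids.index(b)
    x = table.proportions
    rng = np.random.default_rng(seed)
    obs = _score_matrix(x[[ia, ib]], (method,))[method][0]
    null = np.empty(n_perm)
    for r in range(n_perm):
        xp = _permuted(x, rng, renormalize)
        null[r] = _score_matrix(xp[[ia, ib]], (method,))[method][0]
    p = float(_two_sided_p(np.array([obs]), null[:, None])[0])
    return null, p


# ---------------------------------------------------------------------------
# bootstrap restoration


def _boot_scores(
    x: np.ndarray, methods, n_boot: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    out = {m: [] for m in methods}
    mcols = x.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, mcols, size=mcols)
        s = _score_matrix(x[:, cols], methods)
        for m in methods:
            out[m].append(s[m])
    return {m: np.asarray(v) for m, v in out.items()}


def bootstrap_restore(
    table: RelativeAbundanceTable,
    pair: tuple[str, str],
    method: str,
    n_boot: int = 100,
    seed: int | np.random.Generator = 0,
    null_mean: float | None = None,
    n_perm: int = 200,
):
    """95% bootstrap percentile interval of a pair's score and keep/drop.

    Samples are resampled with replacement; replicates where a taxon becomes
    constant (undefined correlation) are skipped and counted.  The edge is
    dropped when the permutation-null expectation lies inside the interval.
    """
    if n_boot < 10:
        raise ValueError("n_boot too small")
    a, b = pair
    ia, ib = table.taxon_ids.index(a), table.taxon_ids.index(b)
    x = table.proportions[[ia, ib]]
    rng = np.random.default_rng(seed)
    boots = _boot_scores(x, (method,), n_boot, rng)[method][:, 0]
    skipped = int(np.isnan(boots).sum())
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    if null_mean is None:
        null, _ = permutation_null(table, pair, method, n_perm=n_perm, seed=rng)
        null_mean = float(np.nanmean(null))
    keep = not (lo <= null_mean <= hi)
    return {
        "interval": (float(lo), float(hi)),
        "null_mean": float(null_mean),
        "keep": bool(keep),
        "skipped_replicates": skipped,
    }


# ---------------------------------------------------------------------------
# p-value combination


def brown_merge(pvals: dict[str, float], null_score_matrix: dict[str, np.ndarray]) -> float:
    """Brown's correlated Fisher merge of per-method p-values for one pair.

    The Fisher statistic T = -2 sum ln p is referred to a scaled chi-square
    c * chi2(f); scale and df derive from the empirical covariance of
    -2 ln p across the shared permutation replicates.
    """
    methods = list(pvals)
    if len(methods) < 2:
        raise ValueError("Brown merge needs at least 2 methods")
    reps = {m: np.asarray(null_score_matrix[m], dtype=float) for m in methods}
    n_rep = len(next(iter(reps.values())))
    if n_rep < 30:
        raise ValueError("need at least 30 permutation replicates for the covariance")
    logp = {m: _null_log_p_matrix(reps[m][:, None]) for m in methods}
    t_obs = float(sum(-2.0 * np.log(pvals[m]) for m in methods))
    return float(_brown_merge_vec(np.array([t_obs]), logp, methods)[0])


def bh_fdr(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up: (accepted mask, adjusted q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adj


# ---------------------------------------------------------------------------
# full pipeline


def build_network(
    table: CountTable | RelativeAbundanceTable,
    config: NetworkConfig | None = None,
) -> EnsembleNetwork:
    """Run the full ensemble pipeline on a (genus-level, top-N) table.

    Stages: pairwise scores; per-method permutation p with compositional
    renormalization; bootstrap restoration (an edge needs the null mean
    outside the bootstrap interval for at least ``boot_min_frac`` of the
    methods); Brown merge; BH at ``q``; sign assignment from the mean of the
    Pearson and Spearman scores, with sign-inconsistent correlation pairs
    discarded.
    """
    cfg = config or NetworkConfig()
    if isinstance(table, CountTable):
        if len(table.taxon_ids) > cfg.top_n:
            table = top_n_taxa(table, cfg.top_n)
        ra = to_relative(table)
    else:
        ra = table
    if len(ra.sample_ids) < 5:
        raise ValueError("need at least 5 samples for stable association scores")
    rng = np.random.default_rng(cfg.seed)
    methods = tuple(cfg.methods)
    x = ra.proportions
    cand = edge_scores(ra, methods)
    valid = cand["valid"].to_numpy()

    null = _null_scores(x, methods, cfg.n_perm, rng, cfg.renormalize)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        null_mean = {m: np.nanmean(null[m], axis=0) for m in methods}
    for m in methods:
        cand[f"p_{m}"] = _two_sided_p(cand[m].to_numpy(), null[m])

    # bootstrap restoration: per method, does the interval exclude the null mean?
    boots = _boot_scores(x, methods, cfg.n_boot, rng)
    support = np.zeros(len(cand), dtype=int)
    n_meth = 0
    for m in methods:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo = np.nanpercentile(boots[m], 2.5, axis=0)
            hi = np.nanpercentile(boots[m], 97.5, axis=0)
        excl = ~((lo <= null_mean[m]) & (null_mean[m] <= hi))
        cand[f"boot_keep_{m}"] = excl
        support += excl.astype(int)
        n_meth += 1
    cand["boot_support"] = support / n_meth
    restored = valid & (cand["boot_support"].to_numpy() >= cfg.boot_min_frac)

    # Brown merge across methods, vectorized over pairs
    logp = {m: _null_log_p_matrix(null[m]) for m in methods}
    t_obs = np.zeros(len(cand))
    for m in methods:
        t_obs += -2.0 * np.log(cand[f"p_{m}"].to_numpy())
    merged = _brown_merge_vec(t_obs, logp, methods)
    cand["p_merged"] = merged

    cand["q"] = np.nan
    cand["accepted"] = False
    if restored.any():
        rej, adj = bh_fdr(merged[restored], q=cfg.q)
        cand.loc[restored, "q"] = adj
        cand.loc[restored, "accepted"] = rej

    # signs
    sign = _edge_signs(cand, null_mean, methods)
    cand["sign"] = sign
    cand.loc[cand["sign"] == "inconsistent", "accepted"] = False

    edges = cand[cand["accepted"]].reset_index(drop=True)
    g = nx.Graph()
    g.add_nodes_from(ra.taxon_ids)
    for _, row in edges.iterrows():
        g.add_edge(row["taxon_a"], row["taxon_b"], sign=row["sign"], q=row["q"])
    return EnsembleNetwork(graph=g, edges=edges, candidates=cand, config=cfg)


def _null_log_p_matrix(null: np.ndarray) -> np.ndarray:
    """-2 ln empirical p of every null replicate, per pair (columns)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(null, axis=0)
    dev = np.abs(null - mu)
    dev = np.where(np.isnan(dev), -np.inf, dev)
    r = rankdata(-dev, method="max", axis=0)
    return -2.0 * np.log(r / (null.shape[0] + 1.0))


def _brown_merge_vec(t_obs: np.ndarray, logp: dict[str, np.ndarray], methods) -> np.ndarray:
    k = len(methods)
    mean_t = 2.0 * k
    cov_sum = np.zeros(t_obs.shape)
    for i in range(k):
        li = logp[methods[i]]
        mi = li.mean(axis=0)
        for j in range(i + 1, k):
            lj = logp[methods[j]]
            cov_sum += (li * lj).mean(axis=0) - mi * lj.mean(axis=0)
    var_t = np.maximum(4.0 * k + 2.0 * cov_sum, 1e-9)
    c = var_t / (2.0 * mean_t)
    f = 2.0 * mean_t**2 / var_t
    return np.clip(chi2.sf(t_obs / c, f), np.finfo(float).tiny, 1.0)


def _edge_signs(cand: pd.DataFrame, null_mean, methods) -> np.ndarray:
    n = len(cand)
    sign = np.full(n, "positive", dtype=object)
    has_corr = [m for m in ("pearson", "spearman") if m in methods]
    if has_corr:
        corr = cand[has_corr].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_corr = np.nanmean(corr, axis=1)
        sign = np.where(mean_corr >= 0, "positive", "negative").astype(object)
        if len(has_corr) == 2:
            signs = np.sign(corr)
            inconsistent = (signs[:, 0] * signs[:, 1]) < 0
            sign[inconsistent] = "inconsistent"
    elif "bray_curtis" in methods:
        sim = cand["bray_curtis"].to_numpy()
        sign = np.where(sim > null_mean["bray_curtis"], "positive", "negative").astype(object)
    elif "kl" in methods:
        div = cand["kl"].to_numpy()
        sign = np.where(div < null_mean["kl"], "positive", "negative").astype(object)
    return sign


def topology(net: EnsembleNetwork | nx.Graph) -> dict:
    """Table-style topology summary of an (ensemble) network.

    Mean degree is 2E/N; density follows the NetworkAnalyzer convention
    E/(N(N-1)); the clustering coefficient is the mean local clustering; the
    diameter is taken on the largest connected component.
    """
    g = net.graph if isinstance(net, EnsembleNetwork) else net
    n, e = g.number_of_nodes(), g.number_of_edges()
    out = {
        "nodes": n,
        "edges": e,
        "average_number_of_neighbors": 2 * e / n if n else 0.0,
        "network_density": e / (n * (n - 1)) if n > 1 else 0.0,
        "cluster_coefficient": nx.average_clustering(g) if n else 0.0,
    }
    if e > 0:
        comp = max(nx.connected_components(g), key=len)
        out["network_diameter"] = nx.diameter(g.subgraph(comp))
    else:
        out["network_diameter"] = 0
    signs = [d.get("sign") for _, _, d in g.edges(data=True)]
    pos = sum(1 for s in signs if s == "positive")
    neg = sum(1 for s in signs if s == "negative")
    tot = pos + neg
    out["positive_pct"] = 100.0 * pos / tot if tot else 0.0
    out["negative_pct"] = 100.0 * neg / tot if tot else 0.0
    return out
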