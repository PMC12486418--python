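"""Normalized stochasticity ratio (NST) and Levins niche breadth.

The NST compares observed pairwise community dissimilarity with its
expectation under a taxon-shuffling null model that preserves each sample's
richness and total while drawing taxon identities by regional occurrence
frequency and abundances by regional mean relative abundance.  Pairs whose
observed (dis)similarity sits at the null expectation score NST = 1 (purely
stochastic); pairs far more similar or more different than the null score
toward 0 (selection).  Group NST above 50% reads as stochastic-dominated
assembly, below 50% as deterministic-dominated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .betadiv import DistanceMatrix
from .tables import CountTable

logger = logging.getLogger("halocline")

__all__ = [
    "NSTResult",
    "NicheBreadthResult",
    "null_communities",
    "null_distance_mean",
    "stochasticity_ratio",
    "nst",
    "niche_breadth",
]


@dataclass
class NSTResult:
    group: str
    pairwise: pd.DataFrame       # sample_i, sample_j, st, nst
    nst: float                   # mean NST over within-group pairs
    classification: str          # stochastic- or deterministic-dominated
    settings: dict = field(default_factory=dict)


@dataclass
class NicheBreadthResult:
    breadth: pd.Series      # per-taxon B_j in [1, N]
    bcom: pd.Series         # per-sample community mean breadth
    n_communities: int


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    if total == 0:
        return np.zeros_like(weights, dtype=np.int64)
    q = weights / weights.sum() * total
    base = np.floor(q).astype(np.int64)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(q - base), kind="stable")
        base[order[:short]] += 1
    return base


def _null_counts(
    counts: np.ndarray, freq: np.ndarray, mean_ra: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One null draw: per sample keep richness & total, shuffle identities."""
    s, m = counts.shape
    richness = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    out = np.zeros((s, m), dtype=np.int64)
    # Gumbel top-k gives weighted sampling without replacement per sample
    with np.errstate(divide="ignore"):
        logf = np.log(freq)
    keys = logf[None, :] + rng.gumbel(size=(m, s))
    for j in range(m):
        r = int(richness[j])
        if r == 0:
            continue
        chosen = np.argpartition(-keys[j], r - 1)[:r]
        w = mean_ra[chosen]
        if w.sum() == 0:
            w = np.ones(r)
        # guarantee each chosen taxon at least one read, then apportion the rest
        out[chosen, j] = 1 + _largest_remainder(w, int(totals[j]) - r)
    return out


def null_communities(
    table: CountTable, n_draws: int, seed: int | np.random.Generator
):
    """Yield ``n_draws`` null count tables (fixed richness & totals per sample,
    taxa drawn by regional occurrence frequency, abundances proportional to
    regional mean relative abundance with largest-remainder rounding)."""
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    freq = (table.counts > 0).mean(axis=1)
    totals = table.sample_totals()
    mean_ra = (table.counts / totals).mean(axis=1)
    for _ in range(n_draws):
        yield CountTable(
            list(table.taxon_ids),
            list(table.sample_ids),
            _null_counts(table.counts, freq, mean_ra, rng),
        )


def _distances(counts: np.ndarray, metric: str) -> np.ndarray:
    x = counts.T.astype(float)
    if metric == "bray-curtis":
        return pdist(x, metric="braycurtis")
    if metric == "jaccard":
        return pdist(x > 0, metric="jaccard")
    raise ValueError(f"unknown metric {metric!r}; use 'bray-curtis' or 'jaccard'")


def null_distance_mean(
    table: CountTable, metric: str, n_draws: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Mean pairwise distance (condensed) over null draws."""
    freq = (table.counts > 0).mean(axis=1)
    totals = table.sample_totals()
    mean_ra = (table.counts / totals).mean(axis=1)
    rng = np.random.default_rng(seed)
    acc = None
    for _ in range(n_draws):
        d = _distances(_null_counts(table.counts, freq, mean_ra, rng), metric)
        acc = d if acc is None else acc + d
    return acc / n_draws


def stochasticity_ratio(
    dm_obs: DistanceMatrix, null_dms
) -> pd.DataFrame:
    """Per-pair selection strength (st) and stochasticity (nst = 1 - st).

    With observed similarity C = 1 - D and null means C-bar / D-bar: a pair
    more similar than null scores st = (C - C̄)/(1 - C̄); a pair more
    different scores st = (D - D̄)/(1 - D̄); nst is 1 - st capped to [0, 1].
    """
    null_dms = list(null_dms)
    if not null_dms:
        raise ValueError("need at least one null distance matrix")
    for nd in null_dms:
        if nd.sample_ids != dm_obs.sample_ids:
            raise ValueError("null distance matrix sample ids mismatch observed")
    d_obs = dm_obs.condensed()
    d_null = np.mean([nd.condensed() for nd in null_dms], axis=0)
    return _pairwise_nst(dm_obs.sample_ids, d_obs, d_null)


def _pairwise_nst(sample_ids, d_obs: np.ndarray, d_null: np.ndarray) -> pd.DataFrame:
    c_obs, c_null = 1.0 - d_obs, 1.0 - d_null
    st = np.empty_like(d_obs)
    more_similar = c_obs >= c_null
    with np.errstate(divide="ignore", invalid="ignore"):
        st_sim = np.where(c_null < 1, (c_obs - c_null) / (1.0 - c_null), 0.0)
        st_dis = np.where(d_null < 1, (d_obs - d_null) / (1.0 - d_null), 0.0)
    st = np.where(more_similar, st_sim, st_dis)
    nst_pair = np.clip(1.0 - st, 0.0, 1.0)
    ii, jj = np.triu_indices(len(sample_ids), k=1)
    return pd.DataFrame(
        {
            "sample_i": np.asarray(sample_ids)[ii],
            "sample_j": np.asarray(sample_ids)[jj],
            "d_obs": d_obs,
            "d_null_mean": d_null,
            "st": st,
            "nst": nst_pair,
        }
    )


def nst(
    table: CountTable,
    groups,
    metric: str = "bray-curtis",
    n_draws: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict[str, NSTResult]:
    """Group-level normalized stochasticity ratio.

    The null model is built from the whole table (the regional pool); NST per
    group is the mean pairwise value over within-group pairs.  Groups with
    fewer than 3 samples are skipped with a warning.
    """
    labels = np.asarray([str(g) for g in groups])
    if len(labels) != len(table.sample_ids):
        raise ValueError("group labels length must match samples")
    d_obs = _distances(table.counts, metric)
    d_null = null_distance_mean(table, metric, n_draws, seed)
    pairs = _pairwise_nst(table.sample_ids, d_obs, d_null)
    lab = {s: g for s, g in zip(table.sample_ids, labels)}
    pairs["group_i"] = pairs["sample_i"].map(lab)
    pairs["group_j"] = pairs["sample_j"].map(lab)
    settings = {"model": "PF (proportional, fixed richness)", "draws": n_draws,
                "metric": metric}
    out: dict[str, NSTResult] = {}
    for g in pd.unique(labels):
        if (labels == g).sum() < 3:
            logger.warning("nst: group %r has < 3 samples; skipped", g)
            continue
        sub = pairs[(pairs["group_i"] == g) & (pairs["group_j"] == g)]
        val = float(sub["nst"].mean())
        out[str(g)] = NSTResult(
            group=str(g),
            pairwise=sub.drop(columns=["group_i", "group_j"]).reset_index(drop=True),
            nst=val,
            classification=(
                "stochastic-dominated" if val > 0.5 else "deterministic-dominated"
            ),
            settings=dict(settings),
        )
    return out


def niche_breadth(table: CountTable) -> NicheBreadthResult:
    """Levins niche breadth B_j = 1 / sum_i P_ij^2 and community means.

    P_ij is the share of taxon j's total abundance found in community
    (sample) i, so B_j ranges from 1 (single site) to N (perfectly even over
    the N samples).  Bcom per sample is the unweighted mean of B_j over taxa
    present in that sample.  Zero-total taxa are excluded.
    """
    if len(table.sample_ids) < 1:
        raise ValueError("need at least one sample")
    totals = table.taxon_totals()
    present = totals > 0
    counts = table.counts[present]
    pij = counts / counts.sum(axis=1, keepdims=True)
    b = 1.0 / (pij**2).sum(axis=1)
    taxa = pd.Index(np.asarray(table.taxon_ids)[present], name="taxon_id")
    breadth = pd.Series(b, index=taxa, name="B")
    bcom = {}
    for j, sid in enumerate(table.sample_ids):
        mask = counts[:, j] > 0
        bcom[sid] = float(b[mask].mean()) if mask.any() else float("nan")
    return NicheBreadthResult(
        breadth=breadth,
        bcom=pd.Series(bcom, name="Bcom"),
        n_communities=len(table.sample_ids),
    )
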