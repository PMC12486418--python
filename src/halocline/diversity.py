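"""Alpha-diversity estimators and rarefaction curves.

The metric set mirrors the standard amplicon workflow: Shannon entropy,
Simpson dominance (sum of squared proportions, so higher = less diverse),
bias-corrected Chao1, classical ACE with a rare/abundant cutoff of 10,
Good's coverage, and observed richness.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .tables import CountTable, rarefy

__all__ = [
    "shannon",
    "simpson_dominance",
    "chao1",
    "ace",
    "goods_coverage",
    "observed_richness",
    "alpha_diversity",
    "rarefaction_curve",
]


def _positive(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or c.sum() <= 0:
        raise ValueError("diversity metrics require at least one positive count")
    if (c < 0).any():
        raise ValueError("negative counts")
    return c[c > 0]


def shannon(counts, base: float = np.e) -> float:
    """Shannon entropy -sum p_i log_base(p_i) over positive entries."""
    if base <= 1:
        raise ValueError("log base must exceed 1")
    c = _positive(counts)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum() / np.log(base))


def simpson_dominance(counts) -> float:
    """Simpson dominance sum p_i^2 (1/S for a uniform community of S taxa)."""
    c = _positive(counts)
    p = c / c.sum()
    return float((p**2).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1))."""
    c = _positive(counts)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return float(len(c) + f1 * (f1 - 1) / (2 * (f2 + 1)))


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator (classical form).

    Taxa with count <= ``rare_cutoff`` form the rare class.  When every rare
    individual is a singleton the coverage estimate C_ace is zero and the
    estimator is undefined; the bias-corrected Chao1 is returned instead with
    a warning.
    """
    c = _positive(counts)
    rare = c[c <= rare_cutoff]
    s_abund = int((c > rare_cutoff).sum())
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = rare.sum()
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        warnings.warn(
            "ACE undefined: every rare individual is a singleton; "
            "falling back to bias-corrected Chao1",
            RuntimeWarning,
            stacklevel=2,
        )
        return chao1(counts)
    ks = np.arange(1, rare_cutoff + 1)
    fk = np.array([(rare == k).sum() for k in ks])
    if n_rare > 1:
        gamma2 = max(
            s_rare * (ks * (ks - 1) * fk).sum() / (c_ace * n_rare * (n_rare - 1)) - 1,
            0.0,
        )
    else:
        gamma2 = 0.0
    return float(s_abund + s_rare / c_ace + f1 / c_ace * gamma2)


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N: fraction of reads from already-seen taxa."""
    c = _positive(counts)
    return float(1.0 - (c == 1).sum() / c.sum())


def observed_richness(counts) -> int:
    return int(len(_positive(counts)))


def alpha_diversity(
    table: CountTable, base: float = np.e, rare_cutoff: int = 10
) -> pd.DataFrame:
    """All six metrics for every sample; one row per sample."""
    rows = {}
    for j, sid in enumerate(table.sample_ids):
        c = table.counts[:, j]
        rows[sid] = {
            "observed_richness": observed_richness(c),
            "shannon": shannon(c, base=base),
            "simpson_dominance": simpson_dominance(c),
            "chao1": chao1(c),
            "ace": ace(c, rare_cutoff=rare_cutoff),
            "goods_coverage": goods_coverage(c),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def rarefaction_curve(
    table: CountTable,
    depths,
    replicates: int = 10,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Mean observed richness and Shannon per sample at each subsampling depth.

    Depths exceeding a sample's total are skipped for that sample.  Returns a
    long-format frame (sample, depth, observed_richness, shannon), each value
    the mean over ``replicates`` random subsamples.
    """
    depths = list(depths)
    if not depths:
        raise ValueError("depth list must be non-empty")
    if sorted(depths) != depths:
        raise ValueError("depths must be increasing")
    rng = np.random.default_rng(seed)
    records = []
    totals = table.sample_totals()
    for depth in depths:
        eligible = [
            (j, sid) for j, sid in enumerate(table.sample_ids) if totals[j] >= depth
        ]
        if not eligible:
            continue
        sub = CountTable(
            list(table.taxon_ids),
            [sid for _, sid in eligible],
            table.counts[:, [j for j, _ in eligible]],
        )
        rich = np.zeros(len(eligible))
        shan = np.zeros(len(eligible))
        for _ in range(replicates):
            r = rarefy(sub, depth, rng)
            for k in range(len(eligible)):
                c = r.counts[:, k]
                rich[k] += observed_richness(c)
                shan[k] += shannon(c)
        for k, (_, sid) in enumerate(eligible):
            records.append(
                {
                    "sample_id": sid,
                    "depth": depth,
                    "observed_richness": rich[k] / replicates,
                    "shannon": shan[k] / replicates,
                }
            )
    return pd.DataFrame.from_records(records)
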