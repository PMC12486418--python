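"""Synthetic community generators for the 4-pond salinity-gradient design.

Three generative regimes cover the assumptions of the downstream analyses:

* **neutral** — every sample assembles by drift plus immigration from one
  shared log-normal metacommunity.  Sample proportions are Dirichlet with
  concentration N*m*p (N reads, migration rate m, metacommunity proportions
  p), whose beta marginals are exactly the stationary distribution the
  neutral-model fit assumes, so migration-rate recovery is a meaningful
  round-trip.
* **filtered** — each taxon carries a salinity optimum; a Gaussian niche
  filter exp(-(salinity - optimum)^2 / (2 sigma^2)) reweights the
  metacommunity before multinomial sampling.  Small sigma = strong
  environmental selection.
* **correlated** — a latent Gaussian copula plants target correlations
  between chosen taxon pairs before closure to proportions, for network
  benchmarking.

Defaults echo the study scale: 4 ponds at salinities 31/39/47/55 PSU,
6 samples per pond, 500 taxa, 30,000 reads per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tables import CountTable, SampleMetadata

__all__ = [
    "SyntheticSpec",
    "simulate_neutral",
    "simulate_filtered",
    "simulate_correlated",
    "simulate_gradient_dataset",
]


@dataclass
class SyntheticSpec:
    """Parameters of the generative models."""

    S: int = 500                      # number of taxa
    n_samples: int = 6                # samples per group
    depth: int = 30_000               # reads per sample
    lognormal_sigma: float = 2.0      # metacommunity log-abundance spread
    m: float = 0.1                    # migration rate (0, 1]
    filter_sigma: float = 3.0         # niche width along salinity (PSU)
    group_salinities: tuple[float, ...] = (31.0, 39.0, 47.0, 55.0)
    filter_max_weight: float = 0.9    # strongest mixing weight on the gradient
    diversity_decline: bool = True    # shrink niche width along the gradient
    planted_edges: tuple[tuple[int, int, float], ...] = ()  # (i, j, rho)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S <= 0 or self.n_samples <= 0 or self.depth <= 0:
            raise ValueError("S, n_samples and depth must be positive")
        if not 0 < self.m <= 1:
            raise ValueError("migration rate m must lie in (0, 1]")
        if self.filter_sigma <= 0:
            raise ValueError("filter_sigma must be positive")

    @property
    def n_total(self) -> int:
        return self.n_samples * len(self.group_salinities)

    def to_dict(self) -> dict:
        return asdict(self)


def _metacommunity(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    logab = rng.normal(0.0, spec.lognormal_sigma, size=spec.S)
    p = np.exp(logab)
    return p / p.sum()


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _group_metadata(spec: SyntheticSpec, sample_ids) -> SampleMetadata:
    groups, sal = [], []
    letters = [chr(ord("A") + g) for g in range(len(spec.group_salinities))]
    for g, s in enumerate(spec.group_salinities):
        groups += [letters[g]] * spec.n_samples
        sal += [s] * spec.n_samples
    return SampleMetadata(
        pd.DataFrame({"group": groups, "salinity": sal}, index=list(sample_ids))
    )


def simulate_neutral(
    spec: SyntheticSpec, n_samples: int | None = None, rng=None
) -> CountTable:
    """Neutral assembly: Dirichlet(N*m*p) sample proportions, multinomial counts."""
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    n = spec.n_total if n_samples is None else n_samples
    p = _metacommunity(spec, rng)
    conc = spec.depth * spec.m * p
    counts = np.empty((spec.S, n), dtype=np.int64)
    for j in range(n):
        props = rng.dirichlet(conc)
        counts[:, j] = rng.multinomial(spec.depth, props)
    return CountTable(_ids("OTU", spec.S), _ids("S", n), counts)


def _filter_weights(
    p: np.ndarray,
    optima: np.ndarray,
    salinity: float,
    sigma: float,
    strength: float = 1.0,
) -> np.ndarray:
    """Niche-filtered metacommunity weights.

    ``strength`` tempers the Gaussian filter (0 = no filtering, 1 = full);
    tempering mixes neutral and filtered regimes geometrically, which keeps
    the community a proper Dirichlet-multinomial draw around one composition
    instead of an overdispersed sum of two.
    """
    w = p * np.exp(-strength * (salinity - optima) ** 2 / (2.0 * sigma**2))
    s = w.sum()
    if s <= 0:
        w = p.copy()
        s = w.sum()
    return w / s


def _draw_optima(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    # pad the optimum range by half the salinity span on each side so the
    # gradient's end groups are not artificially depauperate (edge effect)
    lo, hi = min(spec.group_salinities), max(spec.group_salinities)
    pad = (hi - lo) / 2.0
    return rng.uniform(lo - pad, hi + pad, size=spec.S)


def simulate_filtered(spec: SyntheticSpec, filter_sigmas=None, rng=None):
    """Environmental filtering: Gaussian niche filter along the salinity axis.

    Returns the count table and group metadata.  Within a group all samples
    share the group salinity, so small ``filter_sigma`` makes groups
    internally homogeneous and mutually distinct.  ``filter_sigmas`` can give
    each group its own niche width (e.g. shrinking along the gradient).
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    p = _metacommunity(spec, rng)
    optima = _draw_optima(spec, rng)
    if filter_sigmas is None:
        filter_sigmas = [spec.filter_sigma] * len(spec.group_salinities)
    counts = np.empty((spec.S, spec.n_total), dtype=np.int64)
    j = 0
    for sal, sigma in zip(spec.group_salinities, filter_sigmas):
        w = _filter_weights(p, optima, sal, sigma)
        for _ in range(spec.n_samples):
            counts[:, j] = rng.multinomial(spec.depth, w)
            j += 1
    table = CountTable(_ids("OTU", spec.S), _ids("S", spec.n_total), counts)
    return table, _group_metadata(spec, table.sample_ids)


def simulate_correlated(
    spec: SyntheticSpec, n_samples: int | None = None, rng=None
) -> CountTable:
    """Latent Gaussian copula with planted pairwise correlations.

    Non-planted taxa are independent in the latent layer; log-normal
    abundances are closed to proportions, then multinomial counts.  Raises
    on a non-positive-definite requested correlation structure.
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    n = spec.n_total if n_samples is None else n_samples
    corr = np.eye(spec.S)
    for i, j, rho in spec.planted_edges:
        if i == j:
            raise ValueError("planted edge endpoints must be distinct taxa")
        corr[i, j] = corr[j, i] = rho
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError("planted correlation structure is not positive definite")
    mu = rng.normal(0.0, spec.lognormal_sigma, size=spec.S)  # base log-abundances
    z = rng.standard_normal(size=(n, spec.S)) @ chol.T
    ab = np.exp(mu[None, :] + 1.0 * z)  # unit latent scale on top of the base
    props = ab / ab.sum(axis=1, keepdims=True)
    counts = np.empty((spec.S, n), dtype=np.int64)
    for j in range(n):
        counts[:, j] = rng.multinomial(spec.depth, props[j])
    return CountTable(_ids("OTU", spec.S), _ids("S", n), counts)


def simulate_gradient_dataset(spec: SyntheticSpec, rng=None):
    """4-group design mixing neutral and filtered assembly along the gradient.

    Group g's metacommunity is the neutral pool tempered by its salinity
    filter raised to the mixing weight w_g (geometric neutral/filtered mix),
    with w rising linearly from 0 (first group, purely neutral) to
    ``filter_max_weight`` (last group, strongly filtered); samples then
    assemble neutrally (Dirichlet-multinomial) around that group pool.
    With ``diversity_decline`` the niche width also shrinks along the
    gradient, so richness and Shannon diversity fall with salinity.
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    p = _metacommunity(spec, rng)
    optima = _draw_optima(spec, rng)
    n_groups = len(spec.group_salinities)
    weights = np.linspace(0.0, spec.filter_max_weight, n_groups)
    counts = np.empty((spec.S, spec.n_total), dtype=np.int64)
    j = 0
    for g, sal in enumerate(spec.group_salinities):
        sigma = spec.filter_sigma * (0.7**g if spec.diversity_decline else 1.0)
        pool = _filter_weights(p, optima, sal, sigma, strength=weights[g])
        conc = spec.depth * spec.m * pool
        for _ in range(spec.n_samples):
            props = rng.dirichlet(conc)
            counts[:, j] = rng.multinomial(spec.depth, props)
            j += 1
    table = CountTable(_ids("OTU", spec.S), _ids("S", spec.n_total), counts)
    return table, _group_metadata(spec, table.sample_ids)
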