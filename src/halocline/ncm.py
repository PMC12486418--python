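"""Sloan neutral community model (NCM) fitting.

The model treats each local community as assembled by drift plus immigration
from a shared metacommunity.  At stationarity a taxon with metacommunity
relative abundance ``p`` has local relative abundance distributed
Beta(Nm*p, Nm*(1-p)), where N is the local community size (reads per
sample) and m the migration rate.  The probability of detecting the taxon
(local abundance above the detection limit d = 1/N) is therefore

    f(p) = 1 - I_d(Nm*p, Nm*(1-p))

with I the regularized incomplete beta function.  Nm is the single free
parameter, estimated by nonlinear least squares of observed occurrence
frequencies against f(p); R^2 of that fit measures how far the community is
from neutral expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import betainc
from statsmodels.stats.proportion import proportion_confint

from .tables import CountTable

__all__ = ["NCMFit", "occurrence_abundance", "ncm_predicted_frequency", "fit_ncm"]


@dataclass
class NCMFit:
    Nm: float          # N * m, the single fitted parameter
    m: float           # migration rate Nm / N
    N: float           # mean per-sample read total
    d: float           # detection limit (default ln2/N, see fit_ncm)
    r_squared: float
    curve: pd.DataFrame      # per-taxon p, f_obs, f_pred, lower95, upper95
    partition: pd.Series     # taxon -> {"above", "within", "below"}

    @property
    def partition_counts(self) -> dict[str, int]:
        return self.partition.value_counts().to_dict()


def occurrence_abundance(table: CountTable) -> pd.DataFrame:
    """Per-taxon mean relative abundance p and occurrence frequency f.

    Taxa observed in zero samples are excluded.
    """
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    totals = table.sample_totals()
    if (totals == 0).any():
        raise ValueError("zero-total sample")
    ra = table.counts / totals
    present = table.taxon_totals() > 0
    df = pd.DataFrame(
        {
            "p": ra.mean(axis=1)[present],
            "f": (table.counts > 0).mean(axis=1)[present],
        },
        index=pd.Index(np.asarray(table.taxon_ids)[present], name="taxon_id"),
    )
    return df


def ncm_predicted_frequency(p, Nm: float, d: float):
    """Neutral prediction of occurrence frequency at mean abundance ``p``.

    ``1 - I_d(Nm*p, Nm*(1-p))`` — the beta survival probability beyond the
    detection limit.  Accepts scalars or arrays in (0, 1).
    """
    p = np.asarray(p, dtype=float)
    if Nm <= 0:
        raise ValueError("Nm must be positive")
    if not 0 < d < 1:
        raise ValueError("detection limit d must lie in (0, 1)")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly in (0, 1)")
    out = 1.0 - betainc(Nm * p, Nm * (1.0 - p), d)
    return float(out) if out.ndim == 0 else out


def _fit_nm(p: np.ndarray, f: np.ndarray, d: float, N: float) -> tuple[float, float]:
    """Least-squares Nm over log(Nm) in [log 1e-2 N, log 1e3 N].

    Bounded scalar minimization with three bracket restarts across the
    search range (guards against the occasional flat/multimodal SSE
    profile).  Returns (Nm, SSE).
    """

    def sse(log_nm: float) -> float:
        pred = 1.0 - betainc(np.exp(log_nm) * p, np.exp(log_nm) * (1 - p), d)
        return float(((f - pred) ** 2).sum())

    lo, hi = np.log(1e-2 * N), np.log(1e3 * N)
    best = None
    edges = np.linspace(lo, hi, 4)
    for a, b in zip(edges[:-1], edges[1:]):
        res = minimize_scalar(
            sse, bounds=(a, b), method="bounded", options={"xatol": 1e-10}
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"NCM optimizer failed to converge: {best}")
    return float(np.exp(best.x)), float(best.fun)


def fit_ncm(
    table: CountTable,
    conf_level: float = 0.95,
    detection_limit: float | None = None,
) -> NCMFit:
    """Fit Nm by least squares of occurrence frequency on mean abundance.

    The default detection limit is d = ln(2)/N with N the mean per-sample
    total: under multinomial sampling at depth N a taxon of true relative
    abundance q is detected with probability 1 - (1-q)^N, a smooth kernel
    whose median sits at q = ln(2)/N, so this d makes the model's hard
    threshold the unbiased equivalent of the real detection process (pass
    ``detection_limit=1/N`` for the conventional hard-threshold choice).
    The confidence band is a Wilson binomial interval around each predicted
    frequency with the number of samples as trial count; taxa are
    partitioned into above/within/below the band.
    """
    oa = occurrence_abundance(table)
    if len(oa) < 5:
        raise ValueError("need at least 5 observed taxa to fit")
    n_samples = len(table.sample_ids)
    N = float(table.sample_totals().mean())
    d = np.log(2.0) / N if detection_limit is None else float(detection_limit)
    p = np.clip(oa["p"].to_numpy(), 1e-12, 1 - 1e-12)
    f = oa["f"].to_numpy()
    nm, best_sse = _fit_nm(p, f, d, N)
    pred = ncm_predicted_frequency(p, nm, d)
    sst = float(((f - f.mean()) ** 2).sum())
    r2 = 1.0 - best_sse / sst if sst > 0 else float("nan")
    lower, upper = proportion_confint(
        pred * n_samples, n_samples, alpha=1 - conf_level, method="wilson"
    )
    part = np.where(f > upper, "above", np.where(f < lower, "below", "within"))
    curve = pd.DataFrame(
        {"p": oa["p"], "f_obs": f, "f_pred": pred, "lower95": lower, "upper95": upper},
        index=oa.index,
    )
    return NCMFit(
        Nm=nm,
        m=nm / N,
        N=N,
        d=d,
        r_squared=float(r2),
        curve=curve,
        partition=pd.Series(part, index=oa.index, name="partition"),
    )
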