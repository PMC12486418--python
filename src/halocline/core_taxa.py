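"""Core-microbiome detection.

A taxon is "core" when it occurs in at least ``occurrence_min`` of the
samples AND its mean per-sample relative abundance is at least
``mean_ra_min`` (both comparisons inclusive).  The mean relative abundance
is the unweighted mean of per-sample proportions, not pooled counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import CountTable, SampleMetadata, to_relative

__all__ = ["CoreSet", "find_core", "shared_core", "core_fraction", "core_by_group"]


@dataclass
class CoreSet:
    group: str
    members: pd.DataFrame  # index taxon_id; columns occurrence, mean_relative_abundance
    core_fraction_of_reads: float

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.members.index)


def find_core(
    table: CountTable,
    occurrence_min: float = 0.8,
    mean_ra_min: float = 0.001,
    group: str = "all",
) -> CoreSet:
    """Taxa occurring in >= ``occurrence_min`` of samples at mean relative
    abundance >= ``mean_ra_min``."""
    for name, v in (("occurrence_min", occurrence_min), ("mean_ra_min", mean_ra_min)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if len(table.sample_ids) < 1:
        raise ValueError("need at least one sample")
    ra = to_relative(table).proportions
    occurrence = (table.counts > 0).mean(axis=1)
    mean_ra = ra.mean(axis=1)
    mask = (occurrence >= occurrence_min) & (mean_ra >= mean_ra_min)
    members = pd.DataFrame(
        {
            "occurrence": occurrence[mask],
            "mean_relative_abundance": mean_ra[mask],
        },
        index=pd.Index(np.asarray(table.taxon_ids)[mask], name="taxon_id"),
    )
    frac = core_fraction_ids(table, list(members.index))
    return CoreSet(group, members, frac)


def shared_core(coresets) -> set[str]:
    """Intersection of member taxa across core sets."""
    coresets = list(coresets)
    if len(coresets) < 2:
        raise ValueError("shared_core requires at least 2 core sets")
    ids = set(coresets[0].taxon_ids)
    for cs in coresets[1:]:
        ids &= set(cs.taxon_ids)
    return ids


def core_fraction_ids(table: CountTable, taxon_ids) -> float:
    unknown = set(taxon_ids) - set(table.taxon_ids)
    if unknown:
        raise ValueError(f"unknown taxon ids: {sorted(unknown)}")
    grand = table.counts.sum()
    if not taxon_ids:
        return 0.0
    pos = {t: i for i, t in enumerate(table.taxon_ids)}
    idx = [pos[t] for t in taxon_ids]
    return float(table.counts[idx].sum() / grand)


def core_fraction(table: CountTable, core: CoreSet) -> float:
    """Fraction of all reads carried by the core taxa."""
    return core_fraction_ids(table, core.taxon_ids)


def core_by_group(
    table: CountTable,
    meta: SampleMetadata,
    occurrence_min: float = 0.8,
    mean_ra_min: float = 0.001,
) -> dict[str, CoreSet]:
    """Group-wise core sets (occurrence evaluated within each group)."""
    labels = meta.groups_for(table.sample_ids)
    out = {}
    for g in pd.unique(labels):
        sub = table.select_samples(
            [s for s, lab in zip(table.sample_ids, labels) if lab == g]
        )
        out[str(g)] = find_core(sub, occurrence_min, mean_ra_min, group=str(g))
    return out
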