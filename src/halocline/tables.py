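"""Count tables, taxonomy and metadata: the entry stage of the pipeline.

Everything downstream consumes a :class:`CountTable` (taxa x samples integer
matrix) or its :class:`RelativeAbundanceTable` counterpart.  Readers accept
tab-separated text (taxa as rows by default, transposable) and the BIOM 1.0
JSON dialect.  Rarefaction subsamples reads without replacement
(multivariate hypergeometric) to a common depth, dropping samples that fall
short of it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("halocline")

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

__all__ = [
    "CountTable",
    "RelativeAbundanceTable",
    "TaxonomyTable",
    "SampleMetadata",
    "read_count_table",
    "read_biom_table",
    "write_count_table",
    "read_taxonomy",
    "read_metadata",
    "rarefy",
    "to_relative",
    "aggregate_taxonomy",
    "top_n_taxa",
]


class TableError(ValueError):
    """Structural or parse problem in an input table."""


def _check_unique(ids, kind: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise TableError(f"duplicate {kind} id {i!r}")
        seen.add(i)
    return ids


@dataclass
class CountTable:
    """Integer taxon x sample abundance matrix.

    Parameters
    ----------
    taxon_ids, sample_ids
        Ordered, duplicate-free identifiers.
    counts
        Non-negative integer matrix with shape ``(len(taxon_ids),
        len(sample_ids))``.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = _check_unique(self.taxon_ids, "taxon")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise TableError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise TableError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        counts = counts.astype(np.int64, copy=False)
        if counts.size and counts.min() < 0:
            r, c = np.argwhere(counts < 0)[0]
            raise TableError(
                f"negative count for taxon {self.taxon_ids[r]!r} in sample "
                f"{self.sample_ids[c]!r}"
            )
        self.counts = counts

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def taxon_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, sample_ids) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(list(self.taxon_ids), list(sample_ids), self.counts[:, idx])

    def select_taxa(self, taxon_ids) -> "CountTable":
        pos = {t: i for i, t in enumerate(self.taxon_ids)}
        try:
            idx = [pos[t] for t in taxon_ids]
        except KeyError as e:
            raise TableError(f"unknown taxon id {e.args[0]!r}") from None
        return CountTable(list(taxon_ids), list(self.sample_ids), self.counts[idx])


@dataclass
class RelativeAbundanceTable:
    """Column-closed proportions; each sample column sums to 1 (tol 1e-9)."""

    taxon_ids: list[str]
    sample_ids: list[str]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = _check_unique(self.taxon_ids, "taxon")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise TableError("proportions shape does not match id lists")
        if p.size:
            if p.min() < 0 or p.max() > 1:
                raise TableError("proportions must lie in [0, 1]")
            colsums = p.sum(axis=0)
            bad = np.abs(colsums - 1.0) > 1e-9
            if bad.any():
                j = int(np.argmax(bad))
                raise TableError(
                    f"sample {self.sample_ids[j]!r} proportions sum to {colsums[j]!r}"
                )
        self.proportions = p

    @property
    def shape(self) -> tuple[int, int]:
        return self.proportions.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions, index=self.taxon_ids, columns=self.sample_ids
        )


@dataclass
class TaxonomyTable:
    """taxon_id -> ranked lineage (domain ... genus).

    Missing ranks are stored with a sentinel prefix (``norank_<parent>``),
    mirroring SILVA-style placeholder labels.
    """

    lineages: dict[str, tuple[str, ...]]
    ranks: tuple[str, ...] = RANKS

    def __post_init__(self) -> None:
        n = len(self.ranks)
        fixed = {}
        for tid, lin in self.lineages.items():
            lin = tuple(lin)
            if len(lin) > n:
                raise TableError(f"lineage for {tid!r} longer than rank list")
            fixed[str(tid)] = lin
        self.lineages = fixed

    def label(self, taxon_id: str, rank: str) -> str:
        """Rank label for a taxon; pooled sentinel when the rank is missing."""
        if rank not in self.ranks:
            raise ValueError(f"unknown rank {rank!r}; expected one of {self.ranks}")
        if taxon_id not in self.lineages:
            raise TableError(f"taxon {taxon_id!r} missing from taxonomy")
        lin = self.lineages[taxon_id]
        i = self.ranks.index(rank)
        if i < len(lin) and lin[i]:
            return lin[i]
        parent = "root"
        for j in range(min(i, len(lin)) - 1, -1, -1):
            if lin[j]:
                parent = lin[j]
                break
        return f"norank_{parent}"


@dataclass
class SampleMetadata:
    """Per-sample group label, salinity (PSU) and optional covariates."""

    table: pd.DataFrame  # index = sample_id; columns include group, salinity

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise TableError("metadata requires a 'group' column")
        if self.table.index.has_duplicates:
            raise TableError("duplicate sample ids in metadata")
        if (self.table["group"].astype(str).str.len() == 0).any():
            raise TableError("empty group label in metadata")

    def groups_for(self, sample_ids) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise TableError(f"samples missing from metadata: {missing}")
        return self.table.loc[list(sample_ids), "group"].to_numpy()

    def salinity_for(self, sample_ids) -> np.ndarray:
        return self.table.loc[list(sample_ids), "salinity"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(
    path, *, transposed: bool = False, relative: bool = False
) -> CountTable | RelativeAbundanceTable:
    """Read a tab-separated count table (rows = taxa, columns = samples).

    ``transposed=True`` accepts the samples-as-rows layout.  ``relative=True``
    reads proportions into a :class:`RelativeAbundanceTable` instead of
    requiring integers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transposed:
        df = df.T
    taxa = _check_unique(df.index, "taxon")
    samples = _check_unique(df.columns, "sample")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for t in taxa:
            for s in df.columns:
                try:
                    float(df.loc[t, s])
                except ValueError:
                    raise TableError(
                        f"non-numeric cell for taxon {t!r}, sample {s!r}: "
                        f"{df.loc[t, s]!r}"
                    ) from None
        raise
    if relative:
        return RelativeAbundanceTable(taxa, samples, values)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise TableError(f"empty cell for taxon {taxa[r]!r}, sample {samples[c]!r}")
    neg = values < 0
    if neg.any():
        r, c = np.argwhere(neg)[0]
        raise TableError(
            f"negative count for taxon {taxa[r]!r} in sample {samples[c]!r}"
        )
    if not np.allclose(values, np.round(values)):
        r, c = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise TableError(
            f"non-integer count for taxon {taxa[r]!r} in sample {samples[c]!r}"
        )
    return CountTable(taxa, samples, values.astype(np.int64))


def write_count_table(table: CountTable | RelativeAbundanceTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="taxon_id")


def read_biom_table(path) -> CountTable:
    """Read a BIOM 1.0 (JSON dialect) OTU table."""
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    counts = np.zeros(shape, dtype=np.int64)
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            counts[int(r), int(c)] = int(v)
    else:
        counts[:] = np.asarray(doc["data"], dtype=np.int64)
    return CountTable(taxa, samples, counts)


def read_taxonomy(path, *, ranks: tuple[str, ...] = RANKS) -> TaxonomyTable:
    """Read tab-separated taxonomy: taxon_id then one column per rank."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    lineages = {str(t): tuple(row) for t, row in zip(df.index, df.to_numpy())}
    return TaxonomyTable(lineages, ranks=ranks)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [c.lower() for c in df.columns]
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# transformations


def rarefy(table: CountTable, depth: int, seed: int | np.random.Generator) -> CountTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples whose total falls below ``depth`` are dropped (and logged);
    the draw is multivariate hypergeometric, so a sample whose total equals
    ``depth`` is returned unchanged.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.info(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, ", ".join(dropped),
        )
    if not keep.any():
        raise ValueError(f"all samples fall below rarefaction depth {depth}")
    cols = []
    for j in np.flatnonzero(keep):
        col = table.counts[:, j]
        if totals[j] == depth:
            cols.append(col.copy())
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
    out = np.column_stack(cols)
    samples = [s for s, k in zip(table.sample_ids, keep) if k]
    return CountTable(list(table.taxon_ids), samples, out)


def to_relative(table: CountTable) -> RelativeAbundanceTable:
    """Column-close counts to proportions; errors on a zero-total sample."""
    totals = table.sample_totals()
    if (totals == 0).any():
        j = int(np.argmax(totals == 0))
        raise ValueError(f"sample {table.sample_ids[j]!r} has zero total count")
    return RelativeAbundanceTable(
        list(table.taxon_ids), list(table.sample_ids), table.counts / totals
    )


def aggregate_taxonomy(table: CountTable, tax: TaxonomyTable, rank: str) -> CountTable:
    """Sum rows sharing the same label at ``rank``.

    Lineages lacking the rank pool under ``norank_<parent>`` labels.  First
    appearance decides output row order; the grand total is conserved.
    """
    labels = [tax.label(t, rank) for t in table.taxon_ids]
    order: list[str] = []
    pos: dict[str, int] = {}
    for lab in labels:
        if lab not in pos:
            pos[lab] = len(order)
            order.append(lab)
    out = np.zeros((len(order), len(table.sample_ids)), dtype=np.int64)
    for lab, row in zip(labels, table.counts):
        out[pos[lab]] += row
    return CountTable(order, list(table.sample_ids), out)


def top_n_taxa(table: CountTable, n: int) -> CountTable:
    """Keep the ``n`` taxa with the largest total counts.

    Original row order is preserved among the retained taxa; ties at the
    cutoff break by ascending lexicographic taxon id.
    """
    if n <= 0:
        raise ValueError(f"n must be >= 1, got {n}")
    if n >= len(table.taxon_ids):
        return table
    totals = table.taxon_totals()
    # sort by (descending total, ascending id) to rank; then restore file order
    ranked = sorted(range(len(totals)), key=lambda i: (-totals[i], table.taxon_ids[i]))
    keep = sorted(ranked[:n])
    return CountTable(
        [table.taxon_ids[i] for i in keep],
        list(table.sample_ids),
        table.counts[keep],
    )
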