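"""Core data model and I/O for sample-by-taxon count tables.

The central object is :class:`AbundanceTable`, an integer count matrix of
samples (rows) by taxa (columns, typically amplicon sequence variants or
genera), joined to a :class:`TaxonomyTable` (rank labels per taxon) and a
:class:`SampleMetadata` table (subject, anatomical site, season, age, sex,
grade).  All downstream stages — alpha/beta diversity, community state
clustering and transition analysis — consume these three objects.

All files are plain TSV: counts are wide (first column ``sample_id``),
taxonomy has one row per taxon with the four rank columns, metadata has one
row per sample.  Writers emit the same dialects the readers accept, so
``read_tables(write_tables(x)) == x`` bit-exact for integer counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("commstate")
if not logger.handlers:  # default to stderr at WARNING unless app configures
    logging.basicConfig(format="%(levelname)s %(name)s: %(message)s")

#: Fixed taxonomic ranks, coarsest to finest.
RANKS = ("phylum", "order", "family", "genus")
#: Anatomical sites sampled in the cohort design.
SITES = ("oral", "nasopharyngeal")
#: School-year seasons in temporal order (southern hemisphere campaign).
SEASONS = ("autumn", "winter", "spring")
SEXES = ("female", "male")

#: Label that pools taxa lacking an assignment at the aggregation rank.
UNASSIGNED = "Unassigned"
#: Label that pools low-abundance taxa in :func:`top_taxa`.
OTHER = "Other"

_ROW_SUM_TOL = 1e-9


class DataError(ValueError):
    """Raised for malformed input tables (bad counts, enums, duplicates)."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dup = s[s.duplicated()].unique().tolist()
        raise DataError(f"duplicate {what} identifier(s): {dup}")


@dataclass
class AbundanceTable:
    """Sample x taxon integer count matrix.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are samples, columns taxa, values non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        _check_unique(self.counts.index, "sample")
        _check_unique(self.counts.columns, "taxon")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.round(values)):
                raise DataError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            i, j = np.argwhere(values < 0)[0]
            raise DataError(
                f"negative count at sample {self.counts.index[i]!r}, "
                f"taxon {self.counts.columns[j]!r}"
            )
        self.counts.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        return AbundanceTable(self.counts.loc[list(sample_ids)].copy())


@dataclass
class RelativeAbundanceTable:
    """Sample x taxon fractional matrix; every row sums to 1."""

    fractions: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.fractions.index, "sample")
        _check_unique(self.fractions.columns, "taxon")
        values = self.fractions.to_numpy(dtype=float)
        if values.size:
            if values.min() < -_ROW_SUM_TOL or values.max() > 1 + _ROW_SUM_TOL:
                raise DataError("relative abundances must lie in [0, 1]")
            bad = np.abs(values.sum(axis=1) - 1.0) > _ROW_SUM_TOL
            if bad.any():
                raise DataError(
                    f"rows do not sum to 1: {list(self.fractions.index[bad])[:5]}"
                )
        self.fractions.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.fractions.columns)

    def subset(self, sample_ids: Iterable[str]) -> "RelativeAbundanceTable":
        return RelativeAbundanceTable(self.fractions.loc[list(sample_ids)].copy())


@dataclass
class TaxonomyTable:
    """Taxon -> rank-label mapping for the fixed rank set.

    Empty strings / NaN mark unassigned ranks.
    """

    ranks: pd.DataFrame  # index taxon_id, columns RANKS

    def __post_init__(self) -> None:
        _check_unique(self.ranks.index, "taxon")
        missing = [r for r in RANKS if r not in self.ranks.columns]
        if missing:
            raise DataError(f"taxonomy table lacks rank column(s): {missing}")
        self.ranks = self.ranks[list(RANKS)].copy()
        self.ranks.index.name = "taxon_id"
        # normalize unassigned markers to empty string
        self.ranks = self.ranks.fillna("").astype(str)

    def label_for(self, taxon_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise DataError(f"unknown rank {rank!r}; expected one of {RANKS}")
        if taxon_id not in self.ranks.index:
            return ""
        return str(self.ranks.at[taxon_id, rank])


_ENUMS = {"site": SITES, "season": SEASONS, "sex": SEXES}


@dataclass
class SampleMetadata:
    """Per-sample subject/site/season/age/sex/grade records.

    One sample per (subject, site, season); seasons are ordered
    autumn < winter < spring.
    """

    table: pd.DataFrame  # index sample_id

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        required = ["subject_id", "site", "season", "age", "sex", "grade"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise DataError(f"metadata lacks column(s): {missing}")
        self.table = self.table[required].copy()
        for col, allowed in _ENUMS.items():
            bad = ~self.table[col].isin(allowed)
            if bad.any():
                row = self.table.index[bad][0]
                raise DataError(
                    f"metadata row {row!r}: invalid {col} "
                    f"{self.table.loc[row, col]!r}; expected one of {allowed}"
                )
        key = self.table[["subject_id", "site", "season"]]
        dup = key.duplicated()
        if dup.any():
            row = self.table.index[dup][0]
            raise DataError(
                f"metadata row {row!r}: duplicate (subject, site, season) "
                f"{tuple(key.loc[row])}"
            )
        self.table["age"] = self.table["age"].astype(int)
        self.table.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def stratum(self, site: str, season: str) -> list[str]:
        """Sample ids belonging to one (site, season) stratum."""
        t = self.table
        return list(t.index[(t["site"] == site) & (t["season"] == season)])

    def subject_of(self) -> pd.Series:
        return self.table["subject_id"]

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)].copy())


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_tables(
    counts_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
) -> tuple[AbundanceTable, TaxonomyTable, SampleMetadata]:
    """Read and join the counts / taxonomy / metadata TSV trio.

    Count rows lacking metadata are dropped with a logged warning; samples
    with an all-zero count row are likewise dropped.  Malformed input
    (duplicate ids, negative or non-integer counts, enum violations) raises
    :class:`DataError`.
    """
    counts_df = pd.read_csv(counts_path, sep="\t", index_col=0, dtype={0: str})
    counts_df.index = counts_df.index.astype(str)
    try:
        table = AbundanceTable(counts_df)
    except DataError as e:
        raise DataError(f"{counts_path}: {e}") from None

    tax_df = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype=str)
    tax_df.index = tax_df.index.astype(str)
    taxonomy = TaxonomyTable(tax_df)

    meta_df = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    meta_df.index = meta_df.index.astype(str)
    metadata = SampleMetadata(meta_df)

    missing = [s for s in table.sample_ids if s not in metadata.table.index]
    if missing:
        logger.warning(
            "dropping %d count row(s) without metadata: %s",
            len(missing), missing[:10],
        )
        table = AbundanceTable(table.counts.drop(index=missing))
    zero = table.counts.index[table.row_totals() == 0].tolist()
    if zero:
        logger.warning("dropping %d all-zero sample row(s): %s", len(zero), zero[:10])
        table = AbundanceTable(table.counts.drop(index=zero))
    metadata = metadata.subset(table.sample_ids)
    return table, taxonomy, metadata


def write_tables(
    table: AbundanceTable,
    taxonomy: TaxonomyTable,
    metadata: SampleMetadata,
    out_dir: str | Path,
    prefix: str = "",
) -> dict[str, Path]:
    """Write the three tables as TSVs under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / f"{prefix}counts.tsv",
        "taxonomy": out / f"{prefix}taxonomy.tsv",
        "metadata": out / f"{prefix}metadata.tsv",
    }
    table.counts.to_csv(paths["counts"], sep="\t")
    taxonomy.ranks.to_csv(paths["taxonomy"], sep="\t")
    metadata.table.to_csv(paths["metadata"], sep="\t")
    return paths


# ---------------------------------------------------------------------------
# Aggregation / normalization
# ---------------------------------------------------------------------------

def aggregate_by_rank(
    table: AbundanceTable, taxonomy: TaxonomyTable, rank: str
) -> AbundanceTable:
    """Sum counts of taxa sharing the same label at ``rank``.

    Taxa without an assignment at that rank (or absent from the taxonomy
    table entirely) are pooled under :data:`UNASSIGNED`.  Per-sample totals
    are conserved exactly.  Output column order follows first appearance in
    the input.
    """
    if rank not in RANKS:
        raise DataError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = []
    for taxon in table.taxon_ids:
        lab = taxonomy.label_for(taxon, rank)
        labels.append(lab if lab else UNASSIGNED)
    grouped = table.counts.T.groupby(pd.Index(labels, name=rank), sort=False).sum().T
    return AbundanceTable(grouped)


def to_relative(table: AbundanceTable) -> RelativeAbundanceTable:
    """Divide each sample row by its total count."""
    totals = table.row_totals()
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise DataError(f"all-zero sample row(s): {zero}")
    frac = table.counts.div(totals, axis=0)
    return RelativeAbundanceTable(frac)


def top_taxa(rel: RelativeAbundanceTable, n: int) -> RelativeAbundanceTable:
    """Keep the ``n`` taxa of highest mean relative abundance, pool the rest.

    The pooled mass goes into an :data:`OTHER` column so rows still sum to 1.
    If ``n`` is at least the number of taxa the table is returned unchanged
    apart from an all-zero "Other" column.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    means = rel.fractions.mean(axis=0)
    # deterministic ranking: by descending mean, ties by column order
    order = sorted(range(len(means)), key=lambda i: (-means.iloc[i], i))
    keep_idx = sorted(order[:n])
    keep = [rel.fractions.columns[i] for i in keep_idx]
    kept = rel.fractions[keep].copy()
    other = 1.0 - kept.sum(axis=1)
    kept[OTHER] = other.clip(lower=0.0)
    return RelativeAbundanceTable(kept)


def rarefy(table: AbundanceTable, depth: int, seed: int | None = None) -> AbundanceTable:
    """Subsample each row without replacement to an even ``depth``.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    Optional pre-processing before alpha diversity; off by default in the
    pipeline.
    """
    if depth < 1:
        raise DataError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    keep_rows = []
    out = []
    for sid, row in table.counts.iterrows():
        total = int(row.sum())
        if total < depth:
            logger.warning("rarefy: dropping %r (depth %d < %d)", sid, total, depth)
            continue
        drawn = rng.multivariate_hypergeometric(row.to_numpy(), depth)
        keep_rows.append(sid)
        out.append(drawn)
    return AbundanceTable(
        pd.DataFrame(out, index=keep_rows, columns=table.taxon_ids, dtype=np.int64)
    )


def filter_taxa(
    table: AbundanceTable,
    min_count: int = 0,
    min_prevalence: float = 0.0,
) -> AbundanceTable:
    """Optional taxon filter: total count and presence-fraction floors.

    No filtering is applied by default anywhere in the pipeline; when used,
    the dropped taxa are logged.
    """
    keep = pd.Series(True, index=table.counts.columns)
    if min_count > 0:
        keep &= table.counts.sum(axis=0) >= min_count
    if min_prevalence > 0:
        keep &= (table.counts > 0).mean(axis=0) >= min_prevalence
    dropped = keep.index[~keep].tolist()
    if dropped:
        logger.info("filter_taxa: dropping %d taxa: %s", len(dropped), dropped[:10])
    return AbundanceTable(table.counts.loc[:, keep].copy())
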