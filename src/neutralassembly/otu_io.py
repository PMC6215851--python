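"""OTU count-table I/O and species-abundance distributions.

A community sample is one row of an OTU table: integer read counts over
taxa.  For the community-level (Etienne) machinery each sample is reduced
to its species-abundance distribution (SAD) ``D = (n_1, ..., n_S)`` — the
multiset of positive counts, conventionally sorted in descending order —
together with the total reads ``J = sum(n_i)``, the richness ``S`` and the
abundance-multiplicity map ``phi[j]`` = number of taxa with abundance j.

Tables are tab-separated UTF-8 text with a header row of taxon identifiers
and a first column of sample identifiers (samples as rows by default; most
public OTU tables are transposed, so the readers take an orientation flag).
Group metadata is a two-column TSV ``sample_id<TAB>group``.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OTUTable",
    "GroupMap",
    "CommunitySAD",
    "OTUTableError",
    "EmptyCommunityError",
    "read_otu_table",
    "read_sparse_otu_table",
    "write_otu_table",
    "read_group_map",
    "write_group_map",
    "sample_to_sad",
    "write_results_table",
    "TABLE1_COLUMNS",
    "TABLE2_COLUMNS",
]

#: Column set of the community-scale test report (the pipeline's table1.tsv).
TABLE1_COLUMNS = ["ID", "J", "S", "theta", "m", "logL0", "logL1", "q", "p"]

#: Column set of the species-scale design summary (the pipeline's table2.tsv).
TABLE2_COLUMNS = [
    "source",
    "destination",
    "N",
    "m",
    "R2",
    "total",
    "pct_neutral",
    "pct_non_neutral",
]


class OTUTableError(ValueError):
    """A count table violates the format contract (negative / non-integer
    cells, duplicate identifiers, shape mismatches)."""


class EmptyCommunityError(ValueError):
    """A sample contains no reads, so it has no species-abundance
    distribution."""


@dataclass
class OTUTable:
    """Validated integer count matrix, samples x taxa.

    Parameters
    ----------
    counts
        Non-negative integer matrix of shape ``(n_samples, n_taxa)``.
    sample_ids, taxon_ids
        Unique string identifiers matching the matrix dimensions.
    """

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise OTUTableError("counts must be a 2-D matrix (samples x taxa)")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                bad = np.argwhere(~np.isfinite(counts) | (counts != np.floor(counts)))
                r, c = bad[0]
                raise OTUTableError(
                    f"non-integer count at sample {self.sample_ids[r]!r}, "
                    f"taxon {self.taxon_ids[c]!r}: {counts[r, c]!r}"
                )
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            r, c = np.argwhere(counts < 0)[0]
            raise OTUTableError(
                f"negative count at sample {self.sample_ids[r]!r}, "
                f"taxon {self.taxon_ids[c]!r}: {counts[r, c]}"
            )
        self.counts = counts.astype(np.int64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        if len(self.sample_ids) != counts.shape[0]:
            raise OTUTableError("sample_ids length does not match matrix rows")
        if len(self.taxon_ids) != counts.shape[1]:
            raise OTUTableError("taxon_ids length does not match matrix columns")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise OTUTableError("duplicate sample identifiers")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise OTUTableError("duplicate taxon identifiers")
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._taxon_index = {t: i for i, t in enumerate(self.taxon_ids)}

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def sample_counts(self, sample_id: str) -> np.ndarray:
        try:
            return self.counts[self._sample_index[sample_id]]
        except KeyError:
            raise KeyError(f"unknown sample identifier {sample_id!r}") from None

    def sample_indices(self, sample_ids) -> np.ndarray:
        return np.array([self._sample_index[s] for s in sample_ids], dtype=np.intp)

    def depths(self) -> np.ndarray:
        """Total reads per sample, in table order."""
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OTUTable":
        return cls(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OTUTable)
            and self.sample_ids == other.sample_ids
            and self.taxon_ids == other.taxon_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class GroupMap:
    """Assignment of sample identifiers to group labels (e.g. lean/obese)."""

    mapping: dict

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}

    @property
    def labels(self) -> list[str]:
        seen: dict = {}
        for g in self.mapping.values():
            seen.setdefault(g, None)
        return list(seen)

    def samples(self, label: str) -> list[str]:
        out = [s for s, g in self.mapping.items() if g == label]
        if not out:
            raise KeyError(f"unknown group label {label!r}")
        return out

    def validate_against(self, table: OTUTable) -> None:
        missing = [s for s in self.mapping if s not in table._sample_index]
        if missing:
            raise OTUTableError(
                f"group map references samples absent from the OTU table: {missing[:5]}"
            )

    def __getitem__(self, sample_id: str) -> str:
        return self.mapping[sample_id]

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class CommunitySAD:
    """Species-abundance distribution of one community sample.

    ``abundances`` holds the positive per-species counts sorted descending;
    ``J``, ``S`` and ``phi`` are derived and kept consistent by construction.
    """

    abundances: np.ndarray
    sample_id: str | None = None

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundances)
        if ab.ndim != 1 or ab.size == 0:
            raise EmptyCommunityError("a SAD needs at least one species")
        if np.any(ab != np.floor(ab)) or np.any(ab < 1):
            raise ValueError("abundances must be positive integers")
        self.abundances = np.sort(ab.astype(np.int64))[::-1]

    @property
    def J(self) -> int:
        """Total individuals (reads) in the sample."""
        return int(self.abundances.sum())

    @property
    def S(self) -> int:
        """Number of species present."""
        return int(self.abundances.size)

    @property
    def phi(self) -> dict:
        """Map abundance value j -> number of species with abundance j."""
        return dict(collections.Counter(self.abundances.tolist()))

    @classmethod
    def from_counts(cls, counts, sample_id: str | None = None) -> "CommunitySAD":
        """Build a SAD from a (possibly zero-padded) count vector."""
        counts = np.asarray(counts)
        positive = counts[counts > 0]
        if positive.size == 0:
            raise EmptyCommunityError(
                f"sample {sample_id!r} has no positive counts" if sample_id else "all counts are zero"
            )
        return cls(positive, sample_id=sample_id)


def read_otu_table(path, samples_as_rows: bool = True) -> OTUTable:
    """Read a tab-separated OTU count table.

    ``samples_as_rows=False`` transposes the file (taxa as rows), the layout
    of most public OTU tables.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not samples_as_rows:
        df = df.T
    values = df.to_numpy()
    if values.dtype == object:
        raise OTUTableError(f"{path}: table contains non-numeric cells")
    return OTUTable(values, [str(i) for i in df.index], [str(c) for c in df.columns])


def read_sparse_otu_table(path, samples_as_rows: bool = True) -> OTUTable:
    """Read a sparse triplet text export: ``sample<TAB>taxon<TAB>count`` rows
    with a header line (biom-style TSV export of the nonzero cells)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] != 3:
        raise OTUTableError(f"{path}: expected 3 columns (sample, taxon, count)")
    df.columns = ["sample", "taxon", "count"]
    if not samples_as_rows:
        df = df.rename(columns={"sample": "taxon", "taxon": "sample"})
    wide = df.pivot_table(
        index="sample", columns="taxon", values="count", fill_value=0, aggfunc="sum"
    )
    return OTUTable.from_dataframe(wide)


def write_otu_table(table: OTUTable, path) -> None:
    """Write a table in the samples-as-rows TSV layout read back by
    :func:`read_otu_table`."""
    table.to_dataframe().to_csv(path, sep="\t")


def read_group_map(path, table: OTUTable | None = None) -> GroupMap:
    """Read a two-column TSV (sample_id, group); optionally validate the
    sample identifiers against an OTU table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise OTUTableError(f"{path}: expected two columns (sample_id, group)")
    gm = GroupMap(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))
    if table is not None:
        gm.validate_against(table)
    return gm


def write_group_map(groups: GroupMap, path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups.mapping), "group": list(groups.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def sample_to_sad(table: OTUTable, sample_id: str) -> CommunitySAD:
    """Reduce one sample of an OTU table to its SAD (zero-count taxa
    dropped, abundances sorted descending)."""
    return CommunitySAD.from_counts(table.sample_counts(sample_id), sample_id=sample_id)


def write_results_table(records, path, columns=None, float_format: str = "%.6g") -> None:
    """Write a results table (list of dicts or DataFrame) as TSV.

    With an empty record list and explicit ``columns`` a header-only file is
    produced, so downstream schema expectations still hold.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records), columns=columns)
    if columns is not None:
        df = df.reindex(columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
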