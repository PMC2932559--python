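"""Data model and I/O for OTU count tables, taxonomy tables, and representative sequences.

The canonical in-memory container is :class:`CountTable`, an OTU-by-sample
matrix of non-negative integer read counts (rows = OTUs, columns = samples).
Two on-disk dialects are supported:

* ``tsv`` — plain tab-separated, first column ``otu_id``, one header column
  per sample.
* ``mothur`` — the mothur "shared" file layout (``label``, ``Group``,
  ``numOtus``, then one column per OTU; one row per sample).  Transposed into
  the canonical orientation on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CountTable",
    "TaxonomyTable",
    "read_count_table",
    "write_count_table",
    "read_taxonomy",
    "read_rep_seqs",
    "write_rep_seqs",
    "collapse_to_phylum",
    "merge_tables",
]


class CountTableError(ValueError):
    """Raised when a count table violates its invariants or fails to parse."""


class CountTable:
    """OTU-by-sample abundance matrix with validated invariants.

    Parameters
    ----------
    df : pandas.DataFrame
        Integer counts, index = OTU ids, columns = sample ids.
    drop_empty : bool
        Silently drop all-zero OTU rows instead of raising.
    """

    def __init__(self, df: pd.DataFrame, drop_empty: bool = False):
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate OTU ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate sample ids: {dups}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise CountTableError("counts must be integers")
        if values.size and (values < 0).any():
            raise CountTableError("counts must be non-negative")
        df = df.astype(np.int64)
        empty = df.sum(axis=1) == 0
        if empty.any():
            if drop_empty:
                df = df.loc[~empty]
            else:
                raise CountTableError(
                    f"all-zero OTU rows: {df.index[empty].tolist()[:10]}"
                )
        self.df = df

    # -- basic accessors -------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def column(self, sample: str) -> pd.Series:
        if sample not in self.df.columns:
            raise KeyError(f"unknown sample id: {sample!r}")
        return self.df[sample]

    def sample_total(self, sample: str) -> int:
        return int(self.column(sample).sum())

    def totals(self) -> pd.Series:
        """Per-sample read totals (column sums)."""
        return self.df.sum(axis=0)

    def presence(self) -> pd.DataFrame:
        """Boolean OTU-by-sample presence matrix (count > 0)."""
        return self.df > 0

    def richness(self, sample: str) -> int:
        return int((self.column(sample) > 0).sum())

    def subset_samples(self, samples: Sequence[str]) -> "CountTable":
        missing = [s for s in samples if s not in self.df.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return CountTable(self.df[list(samples)].copy(), drop_empty=True)

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"CountTable({self.shape[0]} OTUs x {self.shape[1]} samples)"

    @classmethod
    def from_dict(cls, counts: Mapping[str, Mapping[str, int]]) -> "CountTable":
        """Build from {sample_id: {otu_id: count}}."""
        df = pd.DataFrame(counts).fillna(0)
        return cls(df)


# -- count table I/O -----------------------------------------------------

def read_count_table(path: str | Path, dialect: str = "tsv") -> CountTable:
    """Read a count table in the ``tsv`` or ``mothur`` (shared) dialect."""
    path = Path(path)
    if dialect == "tsv":
        return _read_plain_tsv(path)
    if dialect == "mothur":
        return _read_mothur_shared(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _parse_count(token: str, path: Path, lineno: int) -> int:
    try:
        value = int(token)
    except ValueError:
        raise CountTableError(
            f"{path}:{lineno}: non-integer count {token!r}"
        ) from None
    if value < 0:
        raise CountTableError(f"{path}:{lineno}: negative count {token!r}")
    return value


def _read_plain_tsv(path: Path) -> CountTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise CountTableError(f"{path}:1: expected otu_id + sample columns")
        samples = header[1:]
        otus: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise CountTableError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            otus.append(fields[0])
            rows.append([_parse_count(t, path, lineno) for t in fields[1:]])
    df = pd.DataFrame(rows, index=otus, columns=samples, dtype=np.int64)
    return CountTable(df)


def _read_mothur_shared(path: Path) -> CountTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["label", "Group", "numOtus"]:
            raise CountTableError(
                f"{path}:1: not a mothur shared header (label/Group/numOtus)"
            )
        otu_ids = header[3:]
        samples: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise CountTableError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            n_otus = _parse_count(fields[2], path, lineno)
            if n_otus != len(otu_ids):
                raise CountTableError(
                    f"{path}:{lineno}: numOtus={n_otus} but header lists {len(otu_ids)} OTUs"
                )
            samples.append(fields[1])
            rows.append([_parse_count(t, path, lineno) for t in fields[3:]])
    # sample-rows on disk -> OTU-rows in memory
    df = pd.DataFrame(rows, index=samples, columns=otu_ids, dtype=np.int64).T
    return CountTable(df, drop_empty=True)


def write_count_table(table: CountTable, path: str | Path, dialect: str = "tsv",
                      label: str = "0.03") -> None:
    path = Path(path)
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("otu_id\t" + "\t".join(table.sample_ids) + "\n")
            for otu, row in table.df.iterrows():
                fh.write(otu + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    elif dialect == "mothur":
        with open(path, "w") as fh:
            fh.write("label\tGroup\tnumOtus\t" + "\t".join(table.otu_ids) + "\n")
            for sample in table.sample_ids:
                col = table.df[sample]
                fh.write(
                    f"{label}\t{sample}\t{len(table.otu_ids)}\t"
                    + "\t".join(str(int(v)) for v in col) + "\n"
                )
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


# -- taxonomy ------------------------------------------------------------

UNCLASSIFIED = "unclassified"


@dataclass
class TaxonomyTable:
    """Per-OTU lineage and percent identity to the nearest reference.

    An OTU whose best reference identity falls below ``phylum_threshold``
    (conservative default 85%) is binned as "unclassified" at the phylum
    rank regardless of its lineage string.
    """

    lineages: dict[str, list[str]]
    percent_identity: dict[str, float]
    phylum_threshold: float = 85.0

    def phylum(self, otu_id: str) -> str:
        if otu_id not in self.lineages:
            raise KeyError(f"OTU missing from taxonomy: {otu_id!r}")
        if self.percent_identity.get(otu_id, 0.0) < self.phylum_threshold:
            return UNCLASSIFIED
        lineage = self.lineages[otu_id]
        return lineage[1] if len(lineage) > 1 else UNCLASSIFIED

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages


def read_taxonomy(path: str | Path, phylum_threshold: float = 85.0) -> TaxonomyTable:
    """Read a TSV with columns otu_id, lineage (semicolon ranks), percent_identity."""
    lineages: dict[str, list[str]] = {}
    identity: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("otu_id\t"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise CountTableError(f"{path}:{lineno}: expected 3 fields")
            otu, lineage, pid = fields
            lineages[otu] = [r.strip() for r in lineage.split(";") if r.strip()]
            identity[otu] = float(pid)
    return TaxonomyTable(lineages, identity, phylum_threshold)


def collapse_to_phylum(table: CountTable, tax: TaxonomyTable) -> CountTable:
    """Pool OTU rows into phylum rows; column totals are preserved."""
    missing = [o for o in table.otu_ids if o not in tax]
    if missing:
        raise CountTableError(f"OTUs missing from taxonomy: {missing[:10]}")
    phyla = pd.Series({o: tax.phylum(o) for o in table.otu_ids})
    collapsed = table.df.groupby(phyla).sum()
    collapsed = collapsed.sort_index()
    return CountTable(collapsed)


# -- merge / representative sequences ------------------------------------

def merge_tables(tables: Iterable[CountTable]) -> CountTable:
    """Union of samples; counts summed for OTU ids shared across inputs."""
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to merge")
    seen: set[str] = set()
    for t in tables:
        clash = seen & set(t.sample_ids)
        if clash:
            raise CountTableError(f"sample id collision on merge: {sorted(clash)}")
        seen.update(t.sample_ids)
    merged = pd.concat([t.df for t in tables], axis=1).fillna(0).astype(np.int64)
    return CountTable(merged)


def read_rep_seqs(path: str | Path) -> dict[str, str]:
    """Read representative sequences (FASTA) into {otu_id: sequence}."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise CountTableError(f"duplicate sequence id: {rec.id}")
        seq = str(rec.seq).upper()
        if not seq:
            raise CountTableError(f"empty sequence for {rec.id}")
        seqs[rec.id] = seq
    return seqs


def write_rep_seqs(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
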