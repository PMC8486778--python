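"""Readers, writers and shared coordinate conventions.

All genomic coordinates in this package are 0-based, half-open
(``start`` inclusive, ``end`` exclusive), matching BED and the 10x
``fragments.tsv`` dialect.  The length of any interval is ``end - start``.

Supported formats: 10x-style fragment TSV (optionally gzipped), BED3/BED4,
FASTA (via :mod:`pyfaidx`), chrom.sizes, bedGraph GC tracks, TSV matrices
with row/column headers, and MatrixMarket-style triplets for expression.
"""

from __future__ import annotations

import gzip
import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default aliases mapping Ensembl-style names onto UCSC-style ones
DEFAULT_CHROM_ALIASES = {str(i): f"chr{i}" for i in list(range(1, 23))} | {
    "X": "chrX",
    "Y": "chrY",
    "MT": "chrM",
    "M": "chrM",
}


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: start >= end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced accessible-DNA fragment tagged with its cell barcode.

    ``count`` is the duplicate count reported by the fragment file
    (column 5 of the 10x dialect).
    """

    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid fragment {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.count < 1:
            raise ValueError(f"fragment duplicate count must be >= 1, got {self.count}")


class GenomeModel:
    """Ordered chromosomes with lengths and optional sequence access."""

    def __init__(
        self,
        lengths: Mapping[str, int],
        sequences: Mapping[str, str] | None = None,
    ) -> None:
        if len(set(lengths)) != len(list(lengths)):
            raise ValueError("duplicate chromosome names")
        for name, n in lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {n}")
        self.lengths: dict[str, int] = dict(lengths)
        self.sequences = sequences

    @property
    def names(self) -> list[str]:
        return list(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __len__(self) -> int:
        return len(self.lengths)

    def sequence(self, region: Region) -> str:
        if self.sequences is None:
            raise ValueError("genome model carries no sequence")
        seq = self.sequences[region.chrom]
        # pyfaidx FastaRecord supports slicing; str() normalizes either backend
        return str(seq[region.start : region.end])

    def validate_region(self, region: Region) -> None:
        if region.chrom not in self.lengths:
            raise KeyError(f"unknown chromosome {region.chrom!r}")
        if region.end > self.lengths[region.chrom]:
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} exceeds "
                f"chromosome length {self.lengths[region.chrom]}"
            )


def normalize_chrom(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Map a chromosome name through an alias table ("1" -> "chr1" by default)."""
    table = DEFAULT_CHROM_ALIASES if aliases is None else aliases
    return table.get(name, name)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_fragments(
    path: str | Path,
    genome: GenomeModel | None = None,
    *,
    on_unknown_chrom: str = "fail",
    aliases: Mapping[str, str] | None = None,
) -> Iterator[FragmentRecord]:
    """Stream fragment records from a 10x-style fragments TSV.

    Lines starting with ``#`` are comments.  Exactly five columns are used
    (chrom, start, end, barcode, count); extra columns are ignored with a
    warning on first sight.  ``on_unknown_chrom`` is ``"fail"`` or ``"skip"``
    (skipped lines are logged with their line number).
    """
    if on_unknown_chrom not in ("fail", "skip"):
        raise ValueError("on_unknown_chrom must be 'fail' or 'skip'")
    warned_extra = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise ValueError(f"line {lineno}: expected >=5 tab-separated fields")
            if len(parts) > 5 and not warned_extra:
                warnings.warn(
                    f"{path}: more than 5 columns; extras ignored (line {lineno})"
                )
                warned_extra = True
            chrom = normalize_chrom(parts[0], aliases)
            try:
                start, end, count = int(parts[1]), int(parts[2]), int(parts[4])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer field: {exc}") from None
            if genome is not None and chrom not in genome:
                if on_unknown_chrom == "skip":
                    logger.warning("line %d: unknown chromosome %r skipped", lineno, chrom)
                    continue
                raise ValueError(f"line {lineno}: unknown chromosome {chrom!r}")
            try:
                yield FragmentRecord(chrom, start, end, parts[3], count)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None


def read_fragments_frame(path: str | Path, genome: GenomeModel | None = None, **kw) -> pd.DataFrame:
    """Read a whole fragments file into the columnar form the pipeline uses."""
    recs = list(read_fragments(path, genome, **kw))
    return fragments_to_frame(recs)


def fragments_to_frame(records: Iterable[FragmentRecord]) -> pd.DataFrame:
    records = list(records)
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "start": np.asarray([r.start for r in records], dtype=np.int64),
            "end": np.asarray([r.end for r in records], dtype=np.int64),
            "barcode": [r.barcode for r in records],
            "count": np.asarray([r.count for r in records], dtype=np.int64),
        }
    )


def write_fragments(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a fragments DataFrame as a (optionally gzipped) 5-column TSV."""
    cols = ["chrom", "start", "end", "barcode", "count"]
    frame[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, aliases: Mapping[str, str] | None = None) -> list[Region]:
    """Read BED3/BED4 regions, returned sorted by (chrom, start).

    Identical duplicates are kept; deduplication is the caller's choice.
    """
    regions: list[Region] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected >=3 BED fields")
            name = parts[3] if len(parts) > 3 else None
            try:
                regions.append(
                    Region(normalize_chrom(parts[0], aliases), int(parts[1]), int(parts[2]), name)
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return regions


def write_bed(regions: Sequence[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fields = [r.chrom, str(r.start), str(r.end)]
            if r.name is not None:
                fields.append(r.name)
            fh.write("\t".join(fields) + "\n")


def read_chrom_sizes(path: str | Path, aliases: Mapping[str, str] | None = None) -> GenomeModel:
    lengths: dict[str, int] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, size = line.split("\t")[:2]
            lengths[normalize_chrom(name, aliases)] = int(size)
    return GenomeModel(lengths)


def read_fasta_genome(path: str | Path) -> GenomeModel:
    """Load a genome (lengths + lazy sequence) from an indexed FASTA."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    lengths = {name: len(fa[name]) for name in fa.keys()}
    return GenomeModel(lengths, sequences=fa)


def read_gc_bedgraph(path: str | Path, aliases: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a per-interval GC-fraction track (chrom, start, end, gc)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "gc"],
        dtype={"start": np.int64, "end": np.int64, "gc": float},
    )
    df["chrom"] = [normalize_chrom(c, aliases) for c in df["chrom"]]
    if ((df["gc"] < 0) | (df["gc"] > 1)).any():
        raise ValueError("GC fractions must lie in [0, 1]")
    return df


# ---------------------------------------------------------------------------
# profile tables (entities x windows)

def window_labels(windows: pd.DataFrame) -> list[str]:
    return [f"{c}:{s}-{e}" for c, s, e in zip(windows["chrom"], windows["start"], windows["end"])]


def write_profile_table(profiles: pd.DataFrame, path: str | Path) -> None:
    """Write an entities-by-windows table; columns are ``chrom:start-end``.

    Missing values are written as ``NA``.  Round-trip through
    :func:`read_profile_table` is lossless at full float precision.
    """
    profiles.to_csv(path, sep="\t", index_label="entity", na_rep="NA", float_format="%.17g")


def read_profile_table(path: str | Path, expected_columns: Sequence[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="entity", na_values=["NA"]).astype(float)
    if expected_columns is not None and list(df.columns) != list(expected_columns):
        raise ValueError("profile table windows do not match the expected window set")
    return df


# ---------------------------------------------------------------------------
# expression matrices

def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix contract: unique ids, non-negative values."""
    if matrix.index.duplicated().any():
        raise ValueError("duplicate gene identifiers")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate sample identifiers")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    return matrix


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes-by-samples TSV with row and column headers."""
    return validate_expression(pd.read_csv(path, sep="\t", index_col=0))


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    validate_expression(matrix).to_csv(path, sep="\t", index_label="gene")


def read_expression_triplets(path: str | Path) -> pd.DataFrame:
    """Read a sparse (gene, sample, value) triplet TSV into a dense matrix."""
    trip = pd.read_csv(path, sep="\t", header=None, names=["gene", "sample", "value"])
    mat = trip.pivot_table(index="gene", columns="sample", values="value", fill_value=0.0)
    mat.columns.name = None
    mat.index.name = None
    return validate_expression(mat)
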