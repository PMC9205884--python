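"""Core domain containers: genes, 5'-end tracks, count matrices, designs.

Coordinate convention: all internal coordinates are 1-based, fully closed
and strand-explicit. For a gene, ``start`` is always the first nucleotide
of the initiation codon *in transcription direction* (the leftmost
coordinate on the + strand, the rightmost on the - strand) and ``end`` is
the last coding nucleotide in transcription direction. bedGraph (0-based,
half-open) is converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Tuple

import pandas as pd

STRANDS = ("+", "-")

#: (contig, strand, 1-based position) -> raw read count
TrackKey = Tuple[str, str, int]


class ValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-normalized initiation-codon coordinates."""

    gene_id: str
    contig: str
    strand: str
    start: int   # first nt of initiation codon, transcription direction
    end: int     # last coding nt, transcription direction
    is_ercc: bool = False

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if min(self.start, self.end) < 1:
            raise ValidationError(f"{self.gene_id}: coordinates must be >= 1")
        if self.strand == "+" and self.start > self.end:
            raise ValidationError(f"{self.gene_id}: + strand requires start <= end")
        if self.strand == "-" and self.start < self.end:
            raise ValidationError(f"{self.gene_id}: - strand requires start >= end")

    @property
    def left(self) -> int:
        return min(self.start, self.end)

    @property
    def right(self) -> int:
        return max(self.start, self.end)

    @property
    def length(self) -> int:
        return self.right - self.left + 1


class GeneSet:
    """An ordered collection of :class:`GeneModel` with unique ids."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: Dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            self._genes[g.gene_id] = g

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def chromosomal(self) -> "GeneSet":
        return GeneSet(g for g in self if not g.is_ercc)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(gene_id=g.gene_id, contig=g.contig, strand=g.strand,
                 start=g.start, end=g.end, is_ercc=g.is_ercc)
            for g in self
        ]
        return pd.DataFrame(rows, columns=["gene_id", "contig", "strand", "start", "end", "is_ercc"])


@dataclass
class FivePrimeTrack:
    """Sparse per-(contig, strand, position) 5'-end read counts for one replicate."""

    sample_id: str
    counts: Dict[TrackKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, c in self.counts.items():
            self._check(key, c)
        # drop explicit zeros so sparsity is canonical
        self.counts = {k: c for k, c in self.counts.items() if c > 0}

    @staticmethod
    def _check(key: TrackKey, count: int) -> None:
        contig, strand, pos = key
        if strand not in STRANDS:
            raise ValidationError(f"bad strand {strand!r} at {contig}:{pos}")
        if pos < 1:
            raise ValidationError(f"position must be >= 1: {contig}:{strand}:{pos}")
        if count < 0:
            raise ValidationError(f"negative count {count} at {contig}:{strand}:{pos}")

    def add(self, contig: str, strand: str, pos: int, count: int) -> None:
        key = (contig, strand, pos)
        self._check(key, count)
        if key in self.counts:
            raise ValidationError(
                f"duplicate entry for {contig}:{strand}:{pos} in {self.sample_id}"
            )
        if count > 0:
            self.counts[key] = count

    def get(self, contig: str, strand: str, pos: int) -> int:
        return self.counts.get((contig, strand, pos), 0)

    def total(self) -> int:
        return sum(self.counts.values())

    def positions(self, contig: str, strand: str) -> list[int]:
        return sorted(p for (c, s, p) in self.counts if c == contig and s == strand)

    def contig_strands(self) -> list[tuple[str, str]]:
        return sorted({(c, s) for (c, s, _p) in self.counts})


@dataclass
class SampleDesign:
    """Replicate -> condition mapping with a designated no-sigma control."""

    condition_of: Dict[str, str]
    control: str

    def __post_init__(self) -> None:
        if self.control not in set(self.condition_of.values()):
            raise ValidationError(
                f"control condition {self.control!r} absent from design "
                f"(conditions: {sorted(set(self.condition_of.values()))})"
            )

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.condition_of.values()))

    def replicates(self, condition: str) -> list[str]:
        return sorted(s for s, c in self.condition_of.items() if c == condition)

    def require_replicated(self, *conditions: str) -> None:
        """Statistical operations need >= 2 replicates per condition."""
        for cond in conditions:
            n = len(self.replicates(cond))
            if n < 2:
                raise ValidationError(
                    f"condition {cond!r} has {n} replicate(s); >= 2 required"
                )


def validate_count_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene x sample fragment-count matrix (integer, complete, unique ids)."""
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups}")
    if df.isna().any().any():
        raise ValidationError("count matrix contains missing cells")
    try:
        as_int = df.astype("int64")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"count matrix contains non-integer cells: {exc}") from exc
    if not (as_int.to_numpy() == df.to_numpy()).all():
        raise ValidationError("count matrix contains non-integer cells")
    if (as_int.to_numpy() < 0).any():
        raise ValidationError("count matrix contains negative counts")
    return as_int
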