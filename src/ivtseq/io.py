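"""Readers and writers for the standard formats the pipeline touches.

GFF3 parsing goes through :mod:`gffutils`, FASTA through Biopython, and
GraphML through networkx. bedGraph (the only 0-based surface) and SIF are
simple enough to read and write directly; conversion to the internal
1-based fully-closed convention happens here and nowhere else.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    FivePrimeTrack,
    GeneModel,
    GeneSet,
    SampleDesign,
    ValidationError,
    validate_count_matrix,
)

# ---------------------------------------------------------------------------
# annotation


def read_gene_annotation(path: str | Path, ercc_prefix: str = "ERCC-") -> GeneSet:
    """Read gene/CDS features from a GFF3 file into a :class:`GeneSet`.

    Coordinates are strand-normalized so ``start`` is the first nucleotide
    of the initiation codon in transcription direction. Features whose id
    starts with ``ercc_prefix`` are flagged as spike-in controls.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise ValidationError(f"malformed GFF3 {path}: {exc}") from exc

    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS"):
            continue
        gene_id = (
            feat.attributes.get("ID", [None])[0]
            or feat.attributes.get("locus_tag", [None])[0]
            or feat.id
        )
        if gene_id in seen:
            raise ValidationError(f"duplicate gene_id {gene_id!r} in {path}")
        seen.add(gene_id)
        if feat.strand not in ("+", "-"):
            raise ValidationError(f"{gene_id}: missing strand in {path}")
        left, right = int(feat.start), int(feat.end)
        if feat.strand == "+":
            start, end = left, right
        else:
            start, end = right, left
        genes.append(
            GeneModel(
                gene_id=gene_id,
                contig=feat.seqid,
                strand=feat.strand,
                start=start,
                end=end,
                is_ercc=gene_id.startswith(ercc_prefix),
            )
        )
    return GeneSet(genes)


def write_gene_annotation(genes: GeneSet, path: str | Path, source: str = "ivtseq") -> None:
    """Write a GeneSet as GFF3 (gene features, left/right coordinates)."""
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id}"
        lines.append(
            "\t".join(
                [g.contig, source, "gene", str(g.left), str(g.right),
                 ".", g.strand, ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# genome sequence


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA genome into {contig: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(contigs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# 5'-end tracks


def read_five_prime_track(
    path: str | Path,
    sample_id: str | None = None,
    fmt: str = "auto",
    strand: str | None = None,
) -> FivePrimeTrack:
    """Read a per-position 5'-end count track.

    Two dialects are supported:

    * ``tsv`` — 4 columns (contig, strand, 1-based position, count),
      strand-explicit.
    * ``bedgraph`` — standard 0-based half-open intervals; strandless, so
      the caller must pass ``strand``. Each interval is expanded to
      per-base 1-based positions with the interval's value.

    Duplicate entries for one position are an error (no silent summation).
    """
    path = Path(path)
    sample_id = sample_id or path.stem
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith(("#", "track", "browser"))
    ]
    if fmt == "auto":
        fmt = "tsv"
        if lines:
            fields = lines[0].split("\t")
            if len(fields) == 4 and fields[1] not in ("+", "-"):
                fmt = "bedgraph"
    track = FivePrimeTrack(sample_id=sample_id)
    for lineno, ln in enumerate(lines, 1):
        fields = ln.split("\t")
        if len(fields) != 4:
            raise ValidationError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        if fmt == "tsv":
            contig, strd, pos_s, count_s = fields
            _add_checked(track, path, lineno, contig, strd, int(pos_s), count_s)
        else:
            if strand is None:
                raise ValidationError(
                    f"{path}: bedGraph input is strandless; pass strand='+' or '-'"
                )
            contig, start0_s, end0_s, count_s = fields
            start0, end0 = int(start0_s), int(end0_s)
            if end0 <= start0:
                raise ValidationError(f"{path}:{lineno}: empty/inverted interval")
            for pos in range(start0 + 1, end0 + 1):  # 0-based half-open -> 1-based closed
                _add_checked(track, path, lineno, contig, strand, pos, count_s)
    return track


def _add_checked(
    track: FivePrimeTrack, path: Path, lineno: int,
    contig: str, strand: str, pos: int, count_s: str | int,
) -> None:
    try:
        count = int(count_s)
    except ValueError as exc:
        raise ValidationError(f"{path}:{lineno}: non-integer count {count_s!r}") from exc
    try:
        track.add(contig, strand, pos, count)
    except ValidationError as exc:
        raise ValidationError(f"{path}:{lineno}: {exc}") from exc


def write_five_prime_track(track: FivePrimeTrack, path: str | Path) -> None:
    """Write a track in the strand-explicit 4-column TSV dialect (sorted)."""
    rows = sorted(track.counts.items())
    with open(path, "w") as fh:
        for (contig, strand, pos), count in rows:
            fh.write(f"{contig}\t{strand}\t{pos}\t{count}\n")


# ---------------------------------------------------------------------------
# count matrix and design


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample TSV (header = sample ids, first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    try:
        return validate_count_matrix(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_count_matrix(df: pd.DataFrame, path: str | Path) -> None:
    out = df.sort_index()
    out.index.name = out.index.name or "gene_id"
    out.to_csv(path, sep="\t")


def read_sample_design(path: str | Path) -> SampleDesign:
    """Read a design TSV: columns sample_id, condition, is_control (0/1)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "condition", "is_control"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: design needs columns {sorted(required)}")
    controls = sorted(set(df.loc[df.is_control.astype(int) == 1, "condition"]))
    if len(controls) != 1:
        raise ValidationError(
            f"{path}: exactly one control condition required, found {controls}"
        )
    return SampleDesign(
        condition_of=dict(zip(df.sample_id, df.condition)), control=controls[0]
    )


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    rows = [
        dict(sample_id=s, condition=c, is_control=int(c == design.control))
        for s, c in sorted(design.condition_of.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result tables and networks


def write_results(table: pd.DataFrame, path: str | Path, sort_by: list[str] | None = None,
                  manifest_id: str | None = None) -> None:
    """Write a result table as TSV with deterministic row ordering."""
    out = table.copy()
    keys = sort_by or list(out.columns)
    if keys:
        out = out.sort_values(keys, kind="mergesort")
    with open(path, "w") as fh:
        if manifest_id:
            fh.write(f"# manifest: {manifest_id}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_network(graph: nx.DiGraph, sif_path: str | Path | None = None,
                  graphml_path: str | Path | None = None) -> None:
    """Export a regulatory network as SIF and/or GraphML (edges sorted)."""
    if sif_path is not None:
        lines = []
        for u, v, data in sorted(graph.edges(data=True)):
            interaction = data.get("interaction", "regulates")
            lines.append(f"{u}\t{interaction}\t{v}")
        Path(sif_path).write_text("\n".join(lines) + ("\n" if lines else ""))
    if graphml_path is not None:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(graph.nodes(data=True)))
        for u, v, data in sorted(graph.edges(data=True)):
            clean = {k: (",".join(sorted(v_)) if isinstance(v_, (set, frozenset)) else v_)
                     for k, v_ in data.items()}
            g.add_edge(u, v, **clean)
        nx.write_graphml(g, str(graphml_path))


def read_sif(path: str | Path) -> list[tuple[str, str, str]]:
    edges = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) != 3:
            raise ValidationError(f"{path}: SIF rows need 3 columns, got {len(fields)}")
        edges.append((fields[0], fields[1], fields[2]))
    return edges
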