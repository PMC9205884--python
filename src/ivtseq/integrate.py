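"""Integration of overexpression calls with sigma-dependent TSSs.

A gene is a *direct* target of a sigma factor when it is significantly
overexpressed and a sigma-dependent TSS lies within ``upstream_window_nt``
(default 300, inclusive) upstream of its initiation codon on the same
contig and strand; distance 0 (a leaderless transcript starting at the
initiation codon) qualifies. Because polycistronic operons place several
genes under one promoter, an overexpressed gene with no qualifying TSS of
its own becomes an *operon* target when its initiation codon lies within
``operon_gap_nt`` (default 50, inclusive) downstream of the 3' end of an
existing target on the same strand; the extension iterates to a fixed
point so whole operons are recovered. Overlapping downstream genes (gap
< 0) qualify, provided they start downstream of the upstream target's
initiation codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .models import GeneModel, GeneSet
from .tss import TSSCall


@dataclass
class TargetAssignment:
    sigma_id: str
    gene_id: str
    evidence: str                      # "direct" or "operon"
    tss_ids: list[str] = field(default_factory=list)
    distance: int | None = None        # TSS -> initiation codon, direct only
    via_gene: str | None = None        # upstream target, operon only


def _tss_distance(gene: GeneModel, call: TSSCall) -> int | None:
    """Nucleotides from the TSS to the initiation codon in transcription
    direction; None if contig/strand differ."""
    if call.contig != gene.contig or call.strand != gene.strand:
        return None
    return gene.start - call.position if gene.strand == "+" else call.position - gene.start


def assign_direct_targets(
    sigma_id: str,
    upregulated: Iterable[str],
    dependent_tss: Sequence[TSSCall],
    genes: GeneSet,
    upstream_window_nt: int = 300,
) -> list[TargetAssignment]:
    targets = []
    for gene_id in sorted(upregulated):
        gene = genes[gene_id]
        support = []
        best = None
        for call in dependent_tss:
            if not call.sigma_dependent:
                continue
            d = _tss_distance(gene, call)
            if d is not None and 0 <= d <= upstream_window_nt:
                support.append(f"{call.contig}:{call.strand}:{call.position}")
                best = d if best is None else min(best, d)
        if support:
            targets.append(
                TargetAssignment(sigma_id, gene_id, "direct", sorted(support), best)
            )
    return targets


def _operon_gap(upstream: GeneModel, candidate: GeneModel) -> int | None:
    """Gap from the 3' end of ``upstream`` to ``candidate``'s initiation
    codon, in transcription direction; None when the pair cannot extend an
    operon (different contig/strand, or candidate not downstream)."""
    if (candidate.contig, candidate.strand) != (upstream.contig, upstream.strand):
        return None
    if upstream.strand == "+":
        if candidate.start <= upstream.start:
            return None
        return candidate.start - upstream.end - 1
    if candidate.start >= upstream.start:
        return None
    return upstream.end - candidate.start - 1


def extend_operons(
    targets: Sequence[TargetAssignment],
    upregulated: Iterable[str],
    genes: GeneSet,
    operon_gap_nt: int = 50,
) -> list[TargetAssignment]:
    """Close the target set under the downstream-operon rule (fixed point).

    Output is independent of gene iteration order: candidates are scanned
    in sorted order and passes repeat until no gene is added.
    """
    result = list(targets)
    assigned = {t.gene_id for t in result}
    pool = sorted(set(upregulated) - assigned)
    if not result:
        return result
    sigma_id = result[0].sigma_id
    changed = True
    while changed:
        changed = False
        for gene_id in list(pool):
            cand = genes[gene_id]
            links = []
            for t in result:
                gap = _operon_gap(genes[t.gene_id], cand)
                if gap is not None and gap <= operon_gap_nt:
                    links.append(t.gene_id)
            if links:
                result.append(
                    TargetAssignment(
                        sigma_id, gene_id, "operon", via_gene=sorted(links)[0]
                    )
                )
                pool.remove(gene_id)
                changed = True
    return result


def targets_to_frame(targets: Sequence[TargetAssignment]) -> pd.DataFrame:
    rows = [
        dict(
            sigma_id=t.sigma_id,
            gene_id=t.gene_id,
            evidence=t.evidence,
            tss_ids=";".join(t.tss_ids),
            distance=t.distance if t.distance is not None else "",
            via_gene=t.via_gene or "",
        )
        for t in sorted(targets, key=lambda t: (t.sigma_id, t.gene_id))
    ]
    return pd.DataFrame(
        rows, columns=["sigma_id", "gene_id", "evidence", "tss_ids", "distance", "via_gene"]
    )


def summarize_regulon(targets: Sequence[TargetAssignment]) -> pd.DataFrame:
    """Per-sigma counts of direct, operon and total targets."""
    df = targets_to_frame(targets)
    if df.empty:
        return pd.DataFrame(columns=["sigma_id", "n_direct", "n_operon", "n_total"])
    counts = (
        df.groupby(["sigma_id", "evidence"]).size().unstack(fill_value=0)
        .reindex(columns=["direct", "operon"], fill_value=0)
    )
    out = pd.DataFrame(
        dict(
            sigma_id=counts.index,
            n_direct=counts["direct"].to_numpy(),
            n_operon=counts["operon"].to_numpy(),
        )
    )
    out["n_total"] = out["n_direct"] + out["n_operon"]
    return out.sort_values("sigma_id").reset_index(drop=True)
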