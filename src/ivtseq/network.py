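"""Sigma-factor regulatory networks and crosstalk matrices.

The directed network joins sigma -> target-gene edges from this assay
with optional literature/prior edges, tracking provenance per edge.
Crosstalk between sigma factors is summarized two ways: the number of
shared regulon genes per pair, and the number of TSSs shared per pair
(one-to-one matching on the same contig and strand within a positional
tolerance, +/-2 nt by default).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .integrate import TargetAssignment
from .tss import TSSCall

PROVENANCE_ASSAY = "ivt"
PROVENANCE_PRIOR = "prior"


def build_network(
    target_tables: Mapping[str, Sequence[TargetAssignment]],
    prior_edges: Sequence[tuple[str, str]] = (),
) -> nx.DiGraph:
    """Union of assay-derived and prior sigma -> gene edges, deduplicated.

    Edge attribute ``provenance`` is a set drawn from {"ivt", "prior"};
    node attribute ``kind`` is "sigma" or "gene" ("sigma" wins for
    sigma factors that are themselves targets).
    """
    g = nx.DiGraph()
    for sigma_id, targets in target_tables.items():
        g.add_node(sigma_id, kind="sigma")
        for t in targets:
            if not g.has_node(t.gene_id):
                g.add_node(t.gene_id, kind="gene")
            _add_edge(g, sigma_id, t.gene_id, PROVENANCE_ASSAY)
    for sigma_id, gene_id in prior_edges:
        g.add_node(sigma_id, kind="sigma")
        if not g.has_node(gene_id):
            g.add_node(gene_id, kind="gene")
        _add_edge(g, sigma_id, gene_id, PROVENANCE_PRIOR)
    return g


def _add_edge(g: nx.DiGraph, u: str, v: str, provenance: str) -> None:
    if g.has_edge(u, v):
        g.edges[u, v]["provenance"].add(provenance)
    else:
        g.add_edge(u, v, provenance={provenance}, interaction="regulates")


def regulon(g: nx.DiGraph, sigma_id: str) -> set[str]:
    return set(g.successors(sigma_id))


def shared_regulon_matrix(
    g: nx.DiGraph, sigma_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Symmetric sigma x sigma matrix of shared regulon genes; the
    diagonal holds regulon sizes."""
    if sigma_ids is None:
        sigma_ids = sorted(
            n for n, d in g.nodes(data=True) if d.get("kind") == "sigma"
        )
    regs = {s: regulon(g, s) for s in sigma_ids}
    data = [
        [len(regs[a] & regs[b]) for b in sigma_ids] for a in sigma_ids
    ]
    return pd.DataFrame(data, index=list(sigma_ids), columns=list(sigma_ids))


def count_shared_tss(
    tss_a: Sequence[TSSCall], tss_b: Sequence[TSSCall], tolerance_nt: int
) -> int:
    """One-to-one greedy nearest matching of two TSS sets within tolerance.

    Positions are processed in ascending order per contig/strand; each TSS
    of one set consumes at most one TSS of the other, so dense TSSs are
    never double counted. Symmetric in its arguments.
    """
    a_by, b_by = {}, {}
    for calls, by in ((tss_a, a_by), (tss_b, b_by)):
        for c in calls:
            by.setdefault((c.contig, c.strand), []).append(c.position)
    shared = 0
    for key in sorted(set(a_by) & set(b_by)):
        a = sorted(a_by[key])
        b = sorted(b_by[key])
        i = j = 0
        while i < len(a) and j < len(b):
            d = a[i] - b[j]
            if abs(d) <= tolerance_nt:
                shared += 1
                i += 1
                j += 1
            elif d < 0:
                i += 1
            else:
                j += 1
    return shared


def shared_tss_matrix(
    tss_by_sigma: Mapping[str, Sequence[TSSCall]], tolerance_nt: int = 2
) -> pd.DataFrame:
    """Symmetric sigma x sigma matrix of tolerantly shared TSSs."""
    sigma_ids = sorted(tss_by_sigma)
    dep = {
        s: [c for c in tss_by_sigma[s] if c.sigma_dependent]
        for s in sigma_ids
    }
    data = [
        [count_shared_tss(dep[a], dep[b], tolerance_nt) for b in sigma_ids]
        for a in sigma_ids
    ]
    return pd.DataFrame(data, index=sigma_ids, columns=sigma_ids)
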