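"""Synthetic in vitro transcription studies with known ground truth.

The generator emulates the statistical structure of a cell-free
transcription assay read out by 5'-end sequencing and whole-transcriptome
counting:

* a random genome with non-overlapping genes on both strands, including
  operon blocks (same-strand neighbours separated by short gaps);
* restriction-digested template DNA, so the no-sigma control shows
  elevated, strand-symmetric 5'-end background at every recognition-site
  position (core enzyme initiating from fragment ends) on top of sparse
  random background;
* sigma samples that add negative-binomial read pile-ups at planted TSSs
  (+/-1 nt jitter), each TSS lying within the upstream window of its
  target gene's initiation codon;
* 92 synthetic spike-in contigs with log-spaced true abundances spanning
  a 150-fold range (1-150 attomole scale), whose first-nucleotide counts
  scale with a per-sample recovery efficiency — the handle for the
  spike-in normalization; and
* a fragment-count matrix where planted regulon genes carry a fold-change
  in the sigma condition and spike-in rows follow efficiency only.

Everything is deterministic under the integer seed (PCG64 streams spawned
per stage), and every planted feature is recorded in a serializable
:class:`SimulationTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import FivePrimeTrack, GeneModel, GeneSet, SampleDesign

#: EcoRI, HindIII, BamHI, XhoI recognition sites (all palindromic)
RESTRICTION_MOTIFS = ("GAATTC", "AAGCTT", "GGATCC", "CTCGAG")

N_ERCC = 92
ERCC_CONTIG_LENGTH = 300
ERCC_ABUNDANCE_RANGE = (1.0, 150.0)  # attomole scale, log-spaced

CHROM = "chrom"


@dataclass
class PlantedTSS:
    contig: str
    strand: str
    position: int
    gene_id: str
    mean_count: float


@dataclass
class SimulationTruth:
    """Ground truth of one simulated study."""

    seed: int
    planted_tss: list[PlantedTSS]
    regulon: dict[str, float]                 # gene_id -> fold change
    direct_genes: list[str]
    operon_pairs: list[tuple[str, str]]       # (direct upstream, extended downstream)
    fragment_ends: list[int]
    ercc_abundance: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        d = dict(
            seed=self.seed,
            planted_tss=[vars(t) for t in self.planted_tss],
            regulon=self.regulon,
            direct_genes=self.direct_genes,
            operon_pairs=[list(p) for p in self.operon_pairs],
            fragment_ends=self.fragment_ends,
            ercc_abundance=self.ercc_abundance,
        )
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            seed=d["seed"],
            planted_tss=[PlantedTSS(**t) for t in d["planted_tss"]],
            regulon=d["regulon"],
            direct_genes=d["direct_genes"],
            operon_pairs=[tuple(p) for p in d["operon_pairs"]],
            fragment_ends=d["fragment_ends"],
            ercc_abundance=d["ercc_abundance"],
        )


@dataclass
class SimulatedStudy:
    """A complete synthetic input set plus its truth."""

    genome: dict[str, str]
    genes: GeneSet
    truth: SimulationTruth
    sigma_tracks: list[FivePrimeTrack]
    control_tracks: list[FivePrimeTrack]
    count_matrix: pd.DataFrame
    design: SampleDesign
    efficiencies: dict[str, float] = field(default_factory=dict)

    @property
    def ercc_ids(self) -> list[str]:
        return sorted(self.truth.ercc_abundance)


def _nb(rng: np.random.Generator, mean, dispersion: float, size=None) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (var = mu + a mu^2)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


# ---------------------------------------------------------------------------
# genome


def simulate_genome(
    n_genes: int,
    contig_length: int = 80_000,
    seed: int = 0,
    n_operon_pairs: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], GeneSet, list[tuple[str, str]]]:
    """Random genome with non-overlapping genes on both strands.

    ``n_operon_pairs`` of the genes are laid out as same-strand pairs
    separated by a 15-45 nt gap (operon blocks); all other intergenic
    gaps are 500-800 nt so each gene keeps a clear upstream window.
    Returns (contigs, genes, operon_pairs) where each pair is
    (transcription-upstream gene, downstream gene).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
    if 2 * n_operon_pairs > n_genes:
        raise ValueError("n_operon_pairs needs 2 genes each")
    n_blocks = n_genes - n_operon_pairs
    # first n_operon_pairs blocks hold 2 genes; order shuffled
    block_sizes = [2] * n_operon_pairs + [1] * (n_blocks - n_operon_pairs)
    rng.shuffle(block_sizes)

    genes: list[GeneModel] = []
    operon_pairs: list[tuple[str, str]] = []
    cursor = 0  # rightmost occupied coordinate
    idx = 0
    for size in block_sizes:
        strand = "+" if rng.random() < 0.5 else "-"
        left = cursor + int(rng.integers(500, 801))
        block: list[GeneModel] = []
        for k in range(size):
            length = int(rng.integers(300, 901))
            right = left + length - 1
            gene_id = f"gene{idx:04d}"
            idx += 1
            if strand == "+":
                block.append(GeneModel(gene_id, CHROM, "+", left, right))
            else:
                block.append(GeneModel(gene_id, CHROM, "-", right, left))
            cursor = right
            left = right + 1 + int(rng.integers(15, 46))
        genes.extend(block)
        if size == 2:
            if strand == "+":
                operon_pairs.append((block[0].gene_id, block[1].gene_id))
            else:
                # transcription runs right-to-left: rightmost gene is upstream
                operon_pairs.append((block[1].gene_id, block[0].gene_id))
    if cursor + 500 > contig_length:
        raise ValueError(
            f"contig_length {contig_length} too short for {n_genes} genes "
            f"(need >= {cursor + 500})"
        )
    contigs = {CHROM: _random_seq(rng, contig_length)}
    return contigs, GeneSet(genes), operon_pairs


def simulate_ercc_contigs(
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, float]]:
    """92 synthetic spike-in contigs with log-spaced true abundances."""
    lo, hi = ERCC_ABUNDANCE_RANGE
    abundances = np.logspace(np.log10(lo), np.log10(hi), N_ERCC)
    contigs, abundance = {}, {}
    for i, ab in enumerate(abundances, start=1):
        name = f"ERCC-{i:05d}"
        contigs[name] = _random_seq(rng, ERCC_CONTIG_LENGTH)
        abundance[name] = float(ab)
    return contigs, abundance


def simulate_fragment_ends(
    genome: Mapping[str, str],
    recognition_motifs: Sequence[str] = RESTRICTION_MOTIFS,
    contig: str = CHROM,
) -> list[int]:
    """1-based start positions of every recognition-site occurrence.

    Both strands are scanned; the default motifs are palindromic so the
    two scans coincide, but reverse-complement occurrences of asymmetric
    motifs are mapped back to forward coordinates.
    """
    comp = str.maketrans("ACGT", "TGCA")
    seq = genome[contig]
    hits: set[int] = set()
    for motif in recognition_motifs:
        for m in (motif.upper(), motif.upper().translate(comp)[::-1]):
            start = seq.find(m)
            while start != -1:
                hits.add(start + 1)
                start = seq.find(m, start + 1)
    return sorted(hits)


# ---------------------------------------------------------------------------
# 5'-end tracks


def simulate_five_prime_tracks(
    truth: SimulationTruth,
    genome: Mapping[str, str],
    efficiencies: Mapping[str, float],
    design: SampleDesign,
    sigma_condition: str,
    background_rate: float = 2e-4,
    background_mean: float = 3.0,
    end_boost: float = 30.0,
    nb_dispersion: float = 0.1,
    ercc_read_scale: float = 20.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[list[FivePrimeTrack], list[FivePrimeTrack]]:
    """Simulate 5'-end tracks for the sigma and no-sigma conditions.

    The background position set (density ``background_rate`` per strand
    per nt) and the fragment-end set are fixed by the template DNA and
    shared by all samples; counts are NB-resampled per replicate. Planted
    TSS pile-ups (mean from truth, +/-1 nt jitter per replicate) appear
    only in the sigma condition. Every expected count in a library —
    genomic background, fragment ends, TSSs and spike-ins alike — scales
    with the sample's recovery efficiency, which is exactly the shared
    factor the spike-in normalization is meant to cancel; spike-in
    first-nucleotide means are abundance x efficiency x
    ``ercc_read_scale``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
    chrom_len = len(genome[CHROM])
    n_bg = int(round(background_rate * chrom_len))
    bg_positions = {
        strand: sorted(rng.choice(chrom_len, size=n_bg, replace=False) + 1)
        for strand in "+-"
    }

    def make_track(sample_id: str, with_tss: bool) -> FivePrimeTrack:
        track = FivePrimeTrack(sample_id=sample_id)
        eff = efficiencies[sample_id]
        pending: dict[tuple[str, str, int], int] = {}

        def deposit(contig: str, strand: str, pos: int, count: int) -> None:
            if count > 0:
                key = (contig, strand, pos)
                pending[key] = pending.get(key, 0) + int(count)

        for strand in "+-":
            for pos in bg_positions[strand]:
                deposit(CHROM, strand, int(pos),
                        _nb(rng, background_mean * eff, nb_dispersion))
        for pos in truth.fragment_ends:
            for strand in "+-":  # end initiation is not strand-specific
                deposit(CHROM, strand, pos, _nb(rng, end_boost * eff, nb_dispersion))
        if with_tss:
            for tss in truth.planted_tss:
                jitter = int(rng.choice([-1, 0, 1], p=[0.15, 0.7, 0.15]))
                deposit(
                    tss.contig, tss.strand, tss.position + jitter,
                    _nb(rng, tss.mean_count * eff, nb_dispersion),
                )
        for ercc_id, abundance in sorted(truth.ercc_abundance.items()):
            mean = abundance * eff * ercc_read_scale
            deposit(ercc_id, "+", 1, _nb(rng, mean, nb_dispersion))
        for (contig, strand, pos), count in sorted(pending.items()):
            track.add(contig, strand, pos, count)
        return track

    sigma_tracks = [
        make_track(s, with_tss=True) for s in design.replicates(sigma_condition)
    ]
    control_tracks = [
        make_track(s, with_tss=False) for s in design.replicates(design.control)
    ]
    return sigma_tracks, control_tracks


# ---------------------------------------------------------------------------
# count matrix


def simulate_count_matrix(
    truth: SimulationTruth,
    genes: GeneSet,
    efficiencies: Mapping[str, float],
    design: SampleDesign,
    sigma_condition: str,
    base_means: Mapping[str, float] | None = None,
    default_base_mean: float = 100.0,
    nb_dispersion: float = 0.05,
    ercc_frag_scale: float = 10.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """NB fragment counts per gene and sample, spike-in rows included.

    Planted regulon genes carry mean x fold-change in the sigma
    condition. Every row's expected count scales with the sample's
    recovery efficiency (the library-wide factor the spike-in size
    factors remove); spike-in rows depend on abundance and efficiency
    only, never on condition.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
    samples = design.replicates(sigma_condition) + design.replicates(design.control)
    rows = {}
    for g in genes.chromosomal():
        base = (base_means or {}).get(g.gene_id, default_base_mean)
        fc = truth.regulon.get(g.gene_id, 1.0)
        counts = []
        for s in samples:
            mean = base * (fc if design.condition_of[s] == sigma_condition else 1.0)
            counts.append(int(_nb(rng, mean * efficiencies[s], nb_dispersion)))
        rows[g.gene_id] = counts
    for ercc_id, abundance in sorted(truth.ercc_abundance.items()):
        rows[ercc_id] = [
            int(_nb(rng, abundance * efficiencies[s] * ercc_frag_scale, nb_dispersion))
            for s in samples
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples).astype("int64")


# ---------------------------------------------------------------------------
# whole study


def simulate_study(
    seed: int = 0,
    n_genes: int = 60,
    contig_length: int = 80_000,
    n_tss: int = 20,
    n_direct_genes: int = 12,
    n_operon_pairs: int = 3,
    fold_change: float = 4.0,
    tss_mean_range: tuple[float, float] = (50.0, 200.0),
    n_replicates: int = 2,
    sigma_id: str = "sigA",
    **track_kwargs,
) -> SimulatedStudy:
    """Generate a complete study: genome, truth, tracks, counts, design.

    The default operating point plants 20 TSSs over 12 direct-target
    genes (the busiest promoters carry two TSSs >= 120 nt apart), a
    15-gene regulon (12 direct + 3 operon-extended) at 4-fold, and 2
    replicates per condition — the minimum the dependence criteria
    support.
    """
    if n_direct_genes < n_operon_pairs:
        raise ValueError("need at least one direct gene per operon pair")
    if not n_direct_genes <= n_tss <= 2 * n_direct_genes:
        raise ValueError("n_tss must be in [n_direct_genes, 2*n_direct_genes]")
    ss = np.random.SeedSequence(seed)
    r_genome, r_truth, r_tracks, r_counts = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    contigs, genes, operon_pairs = simulate_genome(
        n_genes, contig_length, n_operon_pairs=n_operon_pairs, rng=r_genome
    )
    ercc_contigs, ercc_abundance = simulate_ercc_contigs(r_genome)
    genome = {**contigs, **ercc_contigs}

    # choose direct-target genes: every operon-upstream gene, then singles
    operon_upstream = [up for up, _dn in operon_pairs]
    operon_downstream = [dn for _up, dn in operon_pairs]
    singles = [
        g.gene_id for g in genes
        if g.gene_id not in set(operon_upstream) | set(operon_downstream)
    ]
    extra = r_truth.choice(
        len(singles), size=n_direct_genes - len(operon_upstream), replace=False
    )
    direct_genes = sorted(operon_upstream + [singles[i] for i in sorted(extra)])

    planted: list[PlantedTSS] = []
    lo_mean, hi_mean = tss_mean_range
    second_tss = set(direct_genes[: n_tss - n_direct_genes])
    for gene_id in direct_genes:
        gene = genes[gene_id]
        offsets = [int(r_truth.integers(10, 81))]
        if gene_id in second_tss:
            offsets.append(int(r_truth.integers(200, 291)))
        for d in offsets:
            pos = gene.start - d if gene.strand == "+" else gene.start + d
            planted.append(
                PlantedTSS(
                    CHROM, gene.strand, pos, gene_id,
                    float(r_truth.uniform(lo_mean, hi_mean)),
                )
            )
    regulon = {g: fold_change for g in direct_genes + operon_downstream}

    truth = SimulationTruth(
        seed=seed,
        planted_tss=planted,
        regulon=regulon,
        direct_genes=direct_genes,
        operon_pairs=operon_pairs,
        fragment_ends=simulate_fragment_ends(genome),
        ercc_abundance=ercc_abundance,
    )

    condition_of = {}
    for i in range(1, n_replicates + 1):
        condition_of[f"{sigma_id}_{i}"] = sigma_id
        condition_of[f"nosigma_{i}"] = "no_sigma"
    design = SampleDesign(condition_of=condition_of, control="no_sigma")
    efficiencies = {
        s: float(r_truth.uniform(0.5, 1.0)) for s in sorted(condition_of)
    }

    sigma_tracks, control_tracks = simulate_five_prime_tracks(
        truth, genome, efficiencies, design, sigma_id, rng=r_tracks, **track_kwargs
    )
    count_matrix = simulate_count_matrix(
        truth, genes, efficiencies, design, sigma_id, rng=r_counts
    )
    # spike-in contigs are genes too, so DE/annotation can flag them
    all_genes = GeneSet(
        list(genes)
        + [
            GeneModel(e, e, "+", 1, ERCC_CONTIG_LENGTH, is_ercc=True)
            for e in sorted(ercc_abundance)
        ]
    )
    return SimulatedStudy(
        genome=genome,
        genes=all_genes,
        truth=truth,
        sigma_tracks=sigma_tracks,
        control_tracks=control_tracks,
        count_matrix=count_matrix,
        design=design,
        efficiencies=efficiencies,
    )
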