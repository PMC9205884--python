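# ivtseq

Sigma-factor regulon mapping from in vitro transcription sequencing.

Bacterial sigma factors give RNA polymerase its promoter specificity: the
core enzyme alone initiates non-specifically (notably at the ends of DNA
fragments), while the holoenzyme reconstituted with one sigma factor
transcribes that factor's promoters. Running cell-free transcription
reactions on restriction-digested genomic DNA — one reaction per sigma
factor plus a no-sigma control, with ERCC spike-in RNAs added as
normalization anchors — and reading the products out by 5′-end sequencing
and whole-transcriptome counting therefore maps a sigma factor's regulon
directly and biochemically. `ivtseq` implements the downstream
computational workflow for microbial transcription researchers: it starts
from per-position 5′-end count tracks and a per-gene fragment-count
matrix (read trimming, alignment and counting are upstream, external
steps) and produces sigma-dependent TSSs, overexpressed genes, regulons
with operon structure, promoter windows for motif discovery, and
crosstalk networks.

## Method

**TSS calling.** For each contig and strand, positions with 5′-end signal
in the sigma-sample replicates are clustered by single linkage with gap
≤ 100 bp. Each cluster is split into maximal runs whose population SD of
positions is < 10; within a run the position with the largest pooled read
count is the TSS and its count is the run's summed count per replicate
(reads are conserved).

**Spike-in normalization.** ERCC transcripts with ≥ 10 first-nucleotide
reads in every replicate are controls. For control transcript *t* and
sample *s* with first-nucleotide count *c(t,s)*, the factor is

    f(s) = mean_t [ c(t,s) / max_s' c(t,s') ]  ∈ (0, 1]

and normalized counts are raw counts / *f(s)*. TSSs with a normalized
count < 4 in any sigma replicate are dropped.

**Dependence.** A TSS is sigma-dependent iff (i) every sigma replicate
exceeds every no-sigma replicate, and (ii) the 2nd-lowest sigma replicate
is ≥ 4 × the largest no-sigma replicate (normalized counts throughout).

**Overexpression.** Fragment counts are normalized by ERCC-restricted
median-of-ratios size factors; each gene gets a negative-binomial Wald
test of the sigma-vs-control mean ratio (moment dispersion damped toward
the across-gene mean, floor 0.01; pseudocount 0.5). Genes with fold
change ≥ 2 and Benjamini–Hochberg adjusted p < 0.01 are called
upregulated; spike-in rows are excluded from testing.

**Targets.** An upregulated gene with a dependent TSS within 300 bp
upstream of its initiation codon (same strand, distance 0 allowed —
leaderless) is a direct target; an upregulated gene starting within
50 bp downstream of a target's 3′ end on the same strand joins the
regulon as an operon target, iterated to a fixed point. Regulons feed a
sigma → gene network and pairwise shared-regulon / shared-TSS (± 2 nt)
crosstalk matrices.

A seeded synthetic-data generator (`ivtseq.simulate`) produces complete
studies — genome, annotation, restriction-site background, planted TSSs
and regulons, spike-ins with log-spaced 1–150 attomole-scale abundances —
with serialized ground truth, so the whole pipeline is testable without
any sequencing data.

## Worked example

```python
from ivtseq.config import PipelineConfig
from ivtseq.diffexpr import run_diffexpr
from ivtseq.integrate import assign_direct_targets, extend_operons, summarize_regulon
from ivtseq.simulate import simulate_study
from ivtseq.spikein import (compute_normalization_factors, compute_size_factors,
                            first_nt_counts, select_control_transcripts)
from ivtseq.tss import call_tss_table

cfg = PipelineConfig(rng_seed=1)
study = simulate_study(seed=cfg.rng_seed)

tracks = study.sigma_tracks + study.control_tracks
controls = select_control_transcripts(tracks, study.ercc_ids,
                                      cfg.min_ercc_first_nt_reads)
factors = compute_normalization_factors(first_nt_counts(tracks, controls))
print("normalization factors:", {s: round(f, 3) for s, f in factors.items()})

calls = call_tss_table(study.sigma_tracks, study.control_tracks, factors, cfg,
                       contigs=["chrom"])
dependent = [c for c in calls if c.sigma_dependent]
print(f"TSS calls: {len(calls)}, sigma-dependent: {len(dependent)}")

sf = compute_size_factors(
    study.count_matrix.loc[study.count_matrix.index.isin(study.ercc_ids)])
de = run_diffexpr(study.count_matrix, sf, study.design, study.ercc_ids,
                  cfg.fc_threshold, cfg.padj_threshold, "sigA")
up = de.index[de.upregulated].tolist()
print(f"genes tested: {int(de.p_value.notna().sum())}, upregulated: {len(up)}")

targets = assign_direct_targets("sigA", up, dependent, study.genes,
                                cfg.upstream_window_nt)
targets = extend_operons(targets, up, study.genes, cfg.operon_gap_nt)
print(summarize_regulon(targets).to_string(index=False))
```

prints

```
normalization factors: {'sigA_1': 0.566, 'sigA_2': 0.906, 'nosigma_1': 0.488, 'nosigma_2': 0.77}
TSS calls: 211, sigma-dependent: 21
genes tested: 60, upregulated: 15
sigma_id  n_direct  n_operon  n_total
    sigA        12         3       15
```

The factors say each library recovered 49–91 % of the best library's
spike-in signal; of 211 raw 5′-end clusters (mostly restriction-fragment
ends the core enzyme fires from), 21 pass the dependence criteria. All
15 planted regulon genes — 12 with their own promoters, 3 reached
through operons — are recovered with no false positives.

The same run is available from a shell:

```
ivtseq --seed 1 simulate --out-dir run/sim
ivtseq call-tss --tracks-dir run/sim/tracks --design run/sim/design.tsv \
    --annotation run/sim/annotation.gff3 --out-dir run/tss
ivtseq de --counts run/sim/counts.tsv --design run/sim/design.tsv \
    --annotation run/sim/annotation.gff3 --out-dir run/de
ivtseq integrate --tss run/tss/tss_calls.tsv --de run/de/diffexpr.tsv \
    --annotation run/sim/annotation.gff3 --sigma-id sigA --out-dir run/targets
```

or in one step: `ivtseq --seed 1 all --out-dir run`.

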