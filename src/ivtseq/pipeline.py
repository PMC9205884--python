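"""File-level pipeline stages shared by the command-line interface.

Each stage reads standard-format inputs, runs the corresponding library
module and writes TSV outputs plus a run manifest. Stages are pure
functions of their inputs and configuration, so rerunning a stage on
identical inputs reproduces identical tables; ``run_all`` is literally
the composition of the stage functions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__, io, motifs, network, spikein, tss
from .config import PipelineConfig
from .diffexpr import run_diffexpr
from .integrate import (
    assign_direct_targets,
    extend_operons,
    summarize_regulon,
    targets_to_frame,
)
from .models import SampleDesign, ValidationError
from .simulate import simulate_study
from .tss import TSSCall

log = logging.getLogger("ivtseq")


# ---------------------------------------------------------------------------
# manifest


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    out_dir: Path, stage: str, config: PipelineConfig, inputs: Sequence[Path]
) -> str:
    """Write <stage>.manifest.json; returns the deterministic manifest id.

    The id hashes the config snapshot and input checksums only — the
    timestamp is provenance, recorded in the manifest but excluded from
    the id so reruns on identical inputs give identical table headers.
    """
    checksums = {str(p): file_checksum(p) for p in sorted(map(Path, inputs))}
    payload = json.dumps(
        dict(stage=stage, config=config.to_dict(), inputs=checksums), sort_keys=True
    )
    manifest_id = hashlib.sha256(payload.encode()).hexdigest()[:12]
    manifest = dict(
        manifest_id=manifest_id,
        stage=stage,
        version=__version__,
        config=config.to_dict(),
        inputs=checksums,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{stage}.manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest_id


def _sigma_condition(design: SampleDesign) -> str:
    conditions = [c for c in design.conditions if c != design.control]
    if len(conditions) != 1:
        raise ValidationError(
            f"expected one sigma condition vs the control, found {conditions}"
        )
    return conditions[0]


def _log_config(config: PipelineConfig) -> None:
    for key, value in config.to_dict().items():
        log.info("config %s = %s", key, value)


# ---------------------------------------------------------------------------
# stages


def run_simulate(out_dir: str | Path, config: PipelineConfig, **sim_kwargs) -> Path:
    """Write a complete synthetic study under ``out_dir``."""
    out = Path(out_dir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    study = simulate_study(seed=config.rng_seed, **sim_kwargs)
    io.write_genome(study.genome, out / "genome.fasta")
    io.write_gene_annotation(study.genes, out / "annotation.gff3")
    for track in study.sigma_tracks + study.control_tracks:
        io.write_five_prime_track(track, out / "tracks" / f"{track.sample_id}.tsv")
    io.write_count_matrix(study.count_matrix, out / "counts.tsv")
    io.write_sample_design(study.design, out / "design.tsv")
    study.truth.to_json(out / "truth.json")
    config.to_file(out / "config.used.yaml")
    write_manifest(out, "simulate", config, [])
    log.info(
        "simulated %d genes, %d planted TSSs, %d-gene regulon",
        len(study.genes.chromosomal()),
        len(study.truth.planted_tss),
        len(study.truth.regulon),
    )
    return out


def run_call_tss(
    tracks_dir: str | Path,
    design_path: str | Path,
    annotation_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig,
) -> pd.DataFrame:
    """TSS calling stage: factors, clustering, filtering, dependence."""
    _log_config(config)
    out = Path(out_dir)
    design = io.read_sample_design(design_path)
    sigma_condition = _sigma_condition(design)
    design.require_replicated(sigma_condition, design.control)
    genes = io.read_gene_annotation(annotation_path)
    ercc_ids = sorted(g.gene_id for g in genes if g.is_ercc)
    chrom_contigs = sorted({g.contig for g in genes.chromosomal()})

    track_paths = {
        s: Path(tracks_dir) / f"{s}.tsv" for s in sorted(design.condition_of)
    }
    missing = [str(p) for p in track_paths.values() if not p.exists()]
    if missing:
        raise ValidationError(f"missing track files: {missing}")
    tracks = {s: io.read_five_prime_track(p, sample_id=s) for s, p in track_paths.items()}
    sigma_tracks = [tracks[s] for s in design.replicates(sigma_condition)]
    control_tracks = [tracks[s] for s in design.replicates(design.control)]

    controls = spikein.select_control_transcripts(
        sigma_tracks + control_tracks, ercc_ids, config.min_ercc_first_nt_reads
    )
    log.info("using %d spike-in control transcripts", len(controls))
    factors = spikein.compute_normalization_factors(
        spikein.first_nt_counts(sigma_tracks + control_tracks, controls)
    )
    calls = tss.call_tss_table(
        sigma_tracks, control_tracks, factors, config, contigs=chrom_contigs
    )
    n_dep = sum(c.sigma_dependent for c in calls)
    log.info("%d TSS calls, %d sigma-dependent", len(calls), n_dep)

    manifest_id = write_manifest(
        out, "call_tss", config,
        [design_path, annotation_path, *track_paths.values()],
    )
    io.write_results(
        spikein.factors_table(factors, len(controls)),
        out / "normalization_factors.tsv", manifest_id=manifest_id,
    )
    frame = tss.calls_to_frame(calls)
    io.write_results(
        frame, out / "tss_calls.tsv",
        sort_by=["contig", "strand", "position"], manifest_id=manifest_id,
    )
    (out / "dependent_tss.bed").write_text(tss.dependent_calls_to_bed(calls))
    return frame


def run_de(
    counts_path: str | Path,
    design_path: str | Path,
    annotation_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Differential-transcription stage: size factors, NB test, BH, flags."""
    _log_config(config)
    out = Path(out_dir)
    design = io.read_sample_design(design_path)
    sigma_condition = _sigma_condition(design)
    design.require_replicated(sigma_condition, design.control)
    counts = io.read_count_matrix(counts_path)
    genes = io.read_gene_annotation(annotation_path)
    ercc_ids = sorted(g.gene_id for g in genes if g.is_ercc)
    size_factors = spikein.compute_size_factors(
        counts.loc[counts.index.isin(ercc_ids)]
    )
    res = run_diffexpr(
        counts, size_factors, design, ercc_ids,
        config.fc_threshold, config.padj_threshold, sigma_condition,
    )
    log.info("%d genes tested, %d upregulated", res.p_value.notna().sum(),
             int(res.upregulated.sum()))
    manifest_id = write_manifest(
        out, "de", config, [counts_path, design_path, annotation_path]
    )
    io.write_results(
        res.reset_index(), out / "diffexpr.tsv",
        sort_by=["gene_id"], manifest_id=manifest_id,
    )
    sf_frame = pd.DataFrame(
        sorted(size_factors.items()), columns=["sample_id", "size_factor"]
    )
    io.write_results(sf_frame, out / "size_factors.tsv", manifest_id=manifest_id)
    return res


def calls_from_frame(frame: pd.DataFrame) -> list[TSSCall]:
    """Rehydrate minimal TSS calls (position + verdicts) from a TSV table."""
    calls = []
    for row in frame.itertuples():
        calls.append(
            TSSCall(
                contig=row.contig, strand=row.strand, position=int(row.position),
                members=[int(row.position)], raw_sigma={}, raw_control={},
                passes_min_count=bool(row.passes_min_count),
                sigma_dependent=bool(row.sigma_dependent),
            )
        )
    return calls


def run_integrate(
    tss_path: str | Path,
    de_path: str | Path,
    annotation_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig,
    sigma_id: str,
) -> pd.DataFrame:
    """Integration stage: direct targets, operon closure, regulon summary."""
    _log_config(config)
    out = Path(out_dir)
    genes = io.read_gene_annotation(annotation_path)
    calls = calls_from_frame(io.read_results(tss_path))
    de = io.read_results(de_path)
    upregulated = de.loc[de.upregulated.astype(bool), "gene_id"].tolist()
    dependent = [c for c in calls if c.sigma_dependent]
    targets = assign_direct_targets(
        sigma_id, upregulated, dependent, genes, config.upstream_window_nt
    )
    targets = extend_operons(targets, upregulated, genes, config.operon_gap_nt)
    log.info("%s: %d targets (%d direct)", sigma_id, len(targets),
             sum(t.evidence == "direct" for t in targets))
    manifest_id = write_manifest(
        out, "integrate", config, [tss_path, de_path, annotation_path]
    )
    frame = targets_to_frame(targets)
    io.write_results(
        frame, out / "targets.tsv", sort_by=["sigma_id", "gene_id"],
        manifest_id=manifest_id,
    )
    io.write_results(
        summarize_regulon(targets), out / "regulon_summary.tsv",
        manifest_id=manifest_id,
    )
    return frame


def run_motif_windows(
    tss_path: str | Path,
    genome_path: str | Path,
    out_path: str | Path,
    config: PipelineConfig,
) -> int:
    calls = calls_from_frame(io.read_results(tss_path))
    genome = io.read_genome(genome_path)
    records = motifs.extract_promoter_windows(
        [c for c in calls if c.sigma_dependent], genome, config.promoter_window_nt
    )
    motifs.write_windows_fasta(records, out_path)
    log.info("wrote %d promoter windows", len(records))
    return len(records)


def run_filter_motifs(
    motifs_path: str | Path, out_path: str | Path, config: PipelineConfig
) -> pd.DataFrame:
    path = Path(motifs_path)
    records = (
        motifs.read_motifs_meme_xml(path)
        if path.suffix.lower() == ".xml"
        else motifs.read_motifs_tsv(path)
    )
    retained, consensus = motifs.filter_motifs(
        records, config.motif_min_width, config.motif_max_width,
        config.motif_min_sites, config.motif_max_evalue,
    )
    frame = motifs.motifs_to_frame(retained)
    frame["is_consensus"] = (
        frame.motif_id == (consensus.motif_id if consensus else None)
    )
    io.write_results(frame, out_path, sort_by=["e_value", "motif_id"])
    log.info("retained %d/%d motifs", len(retained), len(records))
    return frame


def run_network(
    target_paths: Sequence[str | Path],
    out_dir: str | Path,
    config: PipelineConfig,
    tss_paths: dict[str, str | Path] | None = None,
    prior_path: str | Path | None = None,
) -> None:
    """Network stage: sigma->gene graph plus crosstalk matrices."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, list] = {}
    for path in target_paths:
        df = io.read_results(path)
        for row in df.itertuples():
            from .integrate import TargetAssignment

            tables.setdefault(row.sigma_id, []).append(
                TargetAssignment(row.sigma_id, row.gene_id, row.evidence)
            )
    prior = []
    if prior_path is not None:
        pdf = io.read_results(prior_path)
        prior = list(zip(pdf.sigma_id, pdf.gene_id))
    g = network.build_network(tables, prior)
    io.write_network(g, out / "network.sif", out / "network.graphml")
    shared = network.shared_regulon_matrix(g)
    shared.to_csv(out / "shared_regulons.tsv", sep="\t")
    if tss_paths:
        tss_by_sigma = {
            sigma: calls_from_frame(io.read_results(p))
            for sigma, p in tss_paths.items()
        }
        mat = network.shared_tss_matrix(tss_by_sigma, config.shared_tss_tolerance_nt)
        mat.to_csv(out / "shared_tss.tsv", sep="\t")
    log.info("network: %d nodes, %d edges", g.number_of_nodes(), g.number_of_edges())


def run_all(out_dir: str | Path, config: PipelineConfig, **sim_kwargs) -> Path:
    """Simulate a study and run every downstream stage on its files."""
    out = Path(out_dir)
    sim = out / "sim"
    run_simulate(sim, config, **sim_kwargs)
    design = io.read_sample_design(sim / "design.tsv")
    sigma_id = _sigma_condition(design)
    run_call_tss(sim / "tracks", sim / "design.tsv", sim / "annotation.gff3",
                 out / "tss", config)
    run_de(sim / "counts.tsv", sim / "design.tsv", sim / "annotation.gff3",
           out / "de", config)
    run_integrate(out / "tss" / "tss_calls.tsv", out / "de" / "diffexpr.tsv",
                  sim / "annotation.gff3", out / "targets", config, sigma_id)
    run_motif_windows(out / "tss" / "tss_calls.tsv", sim / "genome.fasta",
                      out / "promoter_windows.fasta", config)
    run_network([out / "targets" / "targets.tsv"], out / "network", config,
                tss_paths={sigma_id: out / "tss" / "tss_calls.tsv"})
    return out
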