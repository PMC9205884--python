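"""TSS calling from 5'-end read-count tracks.

Pipeline per contig and strand, driven by the sigma-sample replicates:

1. pool the positions with any sigma-replicate signal and cluster them by
   single-linkage with gap <= ``cluster_window_nt`` (inclusive);
2. split each cluster into maximal greedy runs whose population standard
   deviation of positions stays below ``subcluster_sd``;
3. call one TSS per subcluster at the member with the largest pooled read
   count (ties go to the most upstream member in transcription
   direction), carrying the sum of member counts per replicate;
4. drop calls whose spike-in-normalized count falls below
   ``min_norm_count`` in at least one sigma replicate;
5. mark a surviving call sigma-dependent when every sigma replicate
   exceeds every no-sigma control replicate and the second-lowest sigma
   replicate is at least ``dependence_ratio`` times the largest control
   replicate.

Control replicate counts are looked up at the same member positions, so a
dependent call certifies signal the core enzyme alone does not produce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .config import PipelineConfig
from .models import FivePrimeTrack, ValidationError


@dataclass
class TSSCluster:
    contig: str
    strand: str
    members: list[int]  # sorted ascending

    def __post_init__(self) -> None:
        self.members = sorted(self.members)


@dataclass
class TSSCall:
    contig: str
    strand: str
    position: int
    members: list[int]
    raw_sigma: dict[str, int]       # replicate -> summed member counts
    raw_control: dict[str, int]
    norm_sigma: dict[str, float] = field(default_factory=dict)
    norm_control: dict[str, float] = field(default_factory=dict)
    passes_min_count: bool = False
    sigma_dependent: bool = False

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.contig, self.strand, self.position)


def cluster_positions(
    positions: Sequence[int], window: int, contig: str = "", strand: str = "+"
) -> list[TSSCluster]:
    """Single-linkage gap clustering: consecutive gaps <= window join."""
    pos = sorted(positions)
    if not pos:
        return []
    clusters: list[list[int]] = [[pos[0]]]
    for p in pos[1:]:
        if p - clusters[-1][-1] <= window:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return [TSSCluster(contig, strand, c) for c in clusters]


def _population_sd(values: Sequence[int]) -> float:
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / n)


def subcluster(cluster: TSSCluster, sd_threshold: float) -> list[list[int]]:
    """Greedy partition of a cluster into runs with positional SD < threshold.

    The scan proceeds in transcription direction (ascending coordinates on
    the + strand, descending on the -), extending the current run while
    its population SD stays below the threshold. Because a rejected
    extension can become admissible once the next run has grown (the SD
    of a union is not monotone in its members), adjacent runs whose union
    still satisfies the threshold are then merged until a fixed point, so
    the returned partition is maximal. Singletons (SD 0) always qualify.
    Returned runs are in ascending coordinate order.
    """
    if not cluster.members:
        raise ValidationError("cannot subcluster an empty cluster")
    ordered = cluster.members if cluster.strand == "+" else cluster.members[::-1]
    runs: list[list[int]] = [[ordered[0]]]
    for p in ordered[1:]:
        if _population_sd(runs[-1] + [p]) < sd_threshold:
            runs[-1].append(p)
        else:
            runs.append([p])
    merged = True
    while merged:
        merged = False
        i = 0
        while i + 1 < len(runs):
            if _population_sd(runs[i] + runs[i + 1]) < sd_threshold:
                runs[i: i + 2] = [runs[i] + runs[i + 1]]
                merged = True
            else:
                i += 1
    return [sorted(r) for r in runs]


def call_tss(
    members: Sequence[int],
    contig: str,
    strand: str,
    sigma_tracks: Sequence[FivePrimeTrack],
    control_tracks: Sequence[FivePrimeTrack] = (),
) -> TSSCall:
    """Call the TSS of one subcluster.

    The TSS position is the member with the largest read count summed
    across the sigma replicates; per-replicate call counts are the sums
    over all members (count conservation). A tie on the pooled count goes
    to the most upstream member in transcription direction.
    """
    if not members:
        raise ValidationError("cannot call a TSS from an empty subcluster")
    members = sorted(members)
    pooled = {
        p: sum(t.get(contig, strand, p) for t in sigma_tracks) for p in members
    }
    best = max(pooled.values())
    candidates = [p for p in members if pooled[p] == best]
    position = min(candidates) if strand == "+" else max(candidates)
    raw_sigma = {
        t.sample_id: sum(t.get(contig, strand, p) for p in members)
        for t in sigma_tracks
    }
    raw_control = {
        t.sample_id: sum(t.get(contig, strand, p) for p in members)
        for t in control_tracks
    }
    return TSSCall(contig, strand, position, list(members), raw_sigma, raw_control)


def filter_min_count(
    calls: Sequence[TSSCall],
    factors: Mapping[str, float],
    min_norm_count: float,
) -> list[TSSCall]:
    """Set ``passes_min_count``: a call fails if its normalized count is
    below the floor in at least one sigma replicate."""
    for call in calls:
        call.norm_sigma = {
            s: c / factors[s] for s, c in call.raw_sigma.items()
        }
        call.norm_control = {
            s: c / factors[s] for s, c in call.raw_control.items()
        }
        call.passes_min_count = all(
            v >= min_norm_count for v in call.norm_sigma.values()
        )
    return list(calls)


def determine_dependence(
    sigma_norm: Sequence[float],
    control_norm: Sequence[float],
    ratio: float,
) -> bool:
    """Sigma-factor dependence of one TSS from normalized replicate counts.

    (i) every sigma replicate exceeds every control replicate, and
    (ii) the second-lowest sigma replicate is >= ratio x the largest
    control replicate. Needs >= 2 sigma replicates for (ii).
    """
    if len(sigma_norm) < 2:
        raise ValidationError(
            "dependence criterion (ii) needs >= 2 sigma replicates, "
            f"got {len(sigma_norm)}"
        )
    ctrl_max = max(control_norm) if control_norm else 0.0
    every_above = min(sigma_norm) > ctrl_max
    second_lowest = sorted(sigma_norm)[1]
    return every_above and second_lowest >= ratio * ctrl_max


def call_tss_table(
    sigma_tracks: Sequence[FivePrimeTrack],
    control_tracks: Sequence[FivePrimeTrack],
    factors: Mapping[str, float],
    config: PipelineConfig,
    contigs: Sequence[str] | None = None,
) -> list[TSSCall]:
    """Run the full TSS-calling cascade over every contig/strand.

    ``contigs``, when given, restricts calling (e.g. to exclude spike-in
    contigs). Positions are defined by the sigma replicates; control
    counts are looked up at the same positions.
    """
    if len(sigma_tracks) < 2:
        raise ValidationError("TSS calling needs >= 2 sigma replicates")
    keys = sorted({cs for t in sigma_tracks for cs in t.contig_strands()})
    if contigs is not None:
        allowed = set(contigs)
        keys = [(c, s) for c, s in keys if c in allowed]
    calls: list[TSSCall] = []
    for contig, strand in keys:
        positions = sorted({
            p for t in sigma_tracks for (c, s, p) in t.counts
            if c == contig and s == strand
        })
        for cluster in cluster_positions(positions, config.cluster_window_nt, contig, strand):
            for members in subcluster(cluster, config.subcluster_sd):
                calls.append(
                    call_tss(members, contig, strand, sigma_tracks, control_tracks)
                )
    filter_min_count(calls, factors, config.min_norm_count)
    for call in calls:
        if call.passes_min_count:
            call.sigma_dependent = determine_dependence(
                list(call.norm_sigma.values()),
                list(call.norm_control.values()),
                config.dependence_ratio,
            )
    return calls


def calls_to_frame(calls: Sequence[TSSCall]) -> pd.DataFrame:
    """Flatten TSS calls into a tidy table (one row per call)."""
    rows = []
    for call in sorted(calls, key=lambda c: c.key):
        row: dict[str, object] = dict(
            contig=call.contig, strand=call.strand, position=call.position,
            n_members=len(call.members),
        )
        for s, v in sorted(call.raw_sigma.items()):
            row[f"raw_{s}"] = v
        for s, v in sorted(call.raw_control.items()):
            row[f"raw_{s}"] = v
        for s, v in sorted(call.norm_sigma.items()):
            row[f"norm_{s}"] = v
        for s, v in sorted(call.norm_control.items()):
            row[f"norm_{s}"] = v
        row["passes_min_count"] = call.passes_min_count
        row["sigma_dependent"] = call.sigma_dependent
        rows.append(row)
    return pd.DataFrame(rows)


def dependent_calls_to_bed(calls: Sequence[TSSCall]) -> str:
    """BED6 text of sigma-dependent TSSs (0-based half-open at the boundary)."""
    lines = []
    for call in sorted(calls, key=lambda c: c.key):
        if not call.sigma_dependent:
            continue
        score = int(round(sum(call.norm_sigma.values())))
        name = f"{call.contig}:{call.strand}:{call.position}"
        lines.append(
            f"{call.contig}\t{call.position - 1}\t{call.position}\t{name}\t{score}\t{call.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
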