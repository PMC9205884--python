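"""Promoter-window extraction and motif-record filtering.

Motif discovery itself is external; this module prepares its input (the
window of sequence ending at each sigma-dependent TSS, long enough to
carry the -35 element, spacer and -10 element) and filters its output by
width, site support and E value, selecting the smallest-E survivor as the
consensus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from lxml import etree

from .models import ValidationError
from .tss import TSSCall

#: annotation tier for high-confidence consensus reporting
HIGH_CONFIDENCE_EVALUE = 1e-8


@dataclass
class MotifRecord:
    motif_id: str
    width: int
    n_sites: int
    e_value: float
    pwm: np.ndarray | None = None  # 4 x width, columns sum to 1

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValidationError(f"{self.motif_id}: width must be >= 1")
        if self.e_value <= 0:
            raise ValidationError(f"{self.motif_id}: E value must be positive")
        if self.pwm is not None:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.shape != (4, self.width):
                raise ValidationError(
                    f"{self.motif_id}: PWM shape {self.pwm.shape} != (4, {self.width})"
                )
            if not np.allclose(self.pwm.sum(axis=0), 1.0, atol=1e-6):
                raise ValidationError(f"{self.motif_id}: PWM columns must sum to 1")

    @property
    def high_confidence(self) -> bool:
        return self.e_value < HIGH_CONFIDENCE_EVALUE


def extract_promoter_windows(
    dependent_tss: Sequence[TSSCall],
    genome: Mapping[str, str],
    window_nt: int = 50,
) -> list[tuple[str, str]]:
    """(id, sequence) promoter windows ending at each dependent TSS.

    The window covers the ``window_nt`` positions ending at the TSS in
    transcription direction; minus-strand windows are reverse
    complemented. TSSs too close to a contig edge are skipped with a
    warning. Ids are ``contig:strand:position``.
    """
    records = []
    for call in sorted(dependent_tss, key=lambda c: c.key):
        if not call.sigma_dependent:
            continue
        seq = genome.get(call.contig)
        if seq is None:
            raise ValidationError(f"contig {call.contig!r} absent from genome")
        name = f"{call.contig}:{call.strand}:{call.position}"
        if call.strand == "+":
            lo, hi = call.position - window_nt + 1, call.position
        else:
            lo, hi = call.position, call.position + window_nt - 1
        if lo < 1 or hi > len(seq):
            warnings.warn(
                f"TSS {name} within {window_nt} nt of contig edge; window skipped"
            )
            continue
        window = seq[lo - 1: hi]
        if call.strand == "-":
            window = str(Seq(window).reverse_complement())
        records.append((name, window))
    return records


def write_windows_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def filter_motifs(
    records: Sequence[MotifRecord],
    min_width: int = 22,
    max_width: int = 35,
    min_sites: int = 10,
    max_evalue: float = 1e-5,
) -> tuple[list[MotifRecord], MotifRecord | None]:
    """Retain motifs by width, site support and E value; pick the consensus.

    A record survives when min_width <= width <= max_width, n_sites >=
    min_sites and e_value < max_evalue (strict). The consensus is the
    retained record with the smallest E value (None if nothing survives).
    """
    retained = [
        r for r in records
        if min_width <= r.width <= max_width
        and r.n_sites >= min_sites
        and r.e_value < max_evalue
    ]
    consensus = min(retained, key=lambda r: (r.e_value, r.motif_id), default=None)
    return retained, consensus


def read_motifs_tsv(path: str | Path) -> list[MotifRecord]:
    """Minimal motif table: columns motif_id, width, n_sites, e_value."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"motif_id", "width", "n_sites", "e_value"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: motif TSV needs columns {sorted(required)}")
    return [
        MotifRecord(str(r.motif_id), int(r.width), int(r.n_sites), float(r.e_value))
        for r in df.itertuples()
    ]


def read_motifs_meme_xml(path: str | Path) -> list[MotifRecord]:
    """Parse motif records (with PWMs) from MEME XML output."""
    tree = etree.parse(str(path))
    records = []
    for motif in tree.findall(".//motifs/motif"):
        width = int(motif.get("width"))
        probs = []
        for ar in motif.findall(".//probabilities/alphabet_matrix/alphabet_array"):
            col = {v.get("letter_id"): float(v.text) for v in ar.findall("value")}
            probs.append([col.get(b, 0.0) for b in "ACGT"])
        pwm = np.array(probs).T if probs else None
        records.append(
            MotifRecord(
                motif_id=motif.get("id") or motif.get("name"),
                width=width,
                n_sites=int(motif.get("sites")),
                e_value=float(motif.get("e_value")),
                pwm=pwm,
            )
        )
    return records


def motifs_to_frame(records: Sequence[MotifRecord]) -> pd.DataFrame:
    rows = [
        dict(
            motif_id=r.motif_id, width=r.width, n_sites=r.n_sites,
            e_value=r.e_value, high_confidence=r.high_confidence,
        )
        for r in sorted(records, key=lambda r: (r.e_value, r.motif_id))
    ]
    return pd.DataFrame(
        rows, columns=["motif_id", "width", "n_sites", "e_value", "high_confidence"]
    )
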