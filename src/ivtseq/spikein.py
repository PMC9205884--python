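"""ERCC spike-in anchored normalization.

Two distinct normalizations share the spike-in anchor:

* 5'-end tracks — per-sample *normalization factors* in (0, 1]: for each
  qualifying control transcript the first-nucleotide read count is divided
  by its maximum across samples, and the factor is the mean of those
  relative counts. Normalized counts are raw counts divided by the
  sample's own factor, so they are always >= raw.
* fragment-count matrices — per-sample *size factors* from a
  median-of-ratios computed on the ERCC rows only, rescaled to geometric
  mean 1. Normalized counts are raw counts divided by the size factor.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import FivePrimeTrack, ValidationError

#: position of the first transcribed nucleotide on a spike-in contig
ERCC_FIRST_NT = 1


def first_nt_counts(
    tracks: Sequence[FivePrimeTrack], ercc_ids: Iterable[str]
) -> pd.DataFrame:
    """ERCC transcript x sample matrix of first-nucleotide read counts."""
    ids = list(ercc_ids)
    data = {
        t.sample_id: [t.get(e, "+", ERCC_FIRST_NT) for e in ids] for t in tracks
    }
    return pd.DataFrame(data, index=ids)


def select_control_transcripts(
    tracks: Sequence[FivePrimeTrack],
    ercc_ids: Iterable[str],
    min_first_nt_reads: int = 10,
) -> list[str]:
    """Spike-in transcripts with >= ``min_first_nt_reads`` first-nt reads in
    every replicate of every sample under comparison."""
    counts = first_nt_counts(tracks, ercc_ids)
    selected = counts.index[(counts >= min_first_nt_reads).all(axis=1)].tolist()
    if not selected:
        raise ValidationError(
            "no spike-in transcript reaches "
            f"{min_first_nt_reads} first-nucleotide reads in all replicates; "
            "normalization impossible — lower min_ercc_first_nt_reads or check inputs"
        )
    return selected


def compute_normalization_factors(first_nt: pd.DataFrame) -> dict[str, float]:
    """Per-sample factors = mean over control transcripts of count / row max.

    Each factor lies in (0, 1]; a factor of 1 requires the sample to be
    maximal for every control transcript.
    """
    if first_nt.empty:
        raise ValidationError("no control transcripts provided")
    mat = first_nt.to_numpy(dtype=float)
    row_max = mat.max(axis=1)
    if (row_max <= 0).any():
        bad = first_nt.index[row_max <= 0].tolist()
        raise ValidationError(f"control transcripts with zero max count: {bad}")
    relative = mat / row_max[:, None]
    factors = relative.mean(axis=0)
    return dict(zip(first_nt.columns, factors.tolist()))


def normalize_counts(raw: float, factor: float) -> float:
    """Raw 5'-end count divided by the sample's normalization factor."""
    if not 0 < factor <= 1:
        raise ValidationError(f"normalization factor must be in (0, 1], got {factor}")
    return raw / factor


def compute_size_factors(ercc_counts: pd.DataFrame) -> dict[str, float]:
    """ERCC-restricted median-of-ratios size factors, geometric mean 1.

    ``ercc_counts`` is the count matrix restricted to spike-in rows. Rows
    containing a zero contribute no ratio (their geometric mean is zero);
    at least two usable rows are required.
    """
    mat = ercc_counts.to_numpy(dtype=float)
    usable = (mat > 0).all(axis=1)
    if usable.sum() < 2:
        raise ValidationError(
            f"need >= 2 all-positive ERCC rows for size factors, have {int(usable.sum())}"
        )
    mat = mat[usable]
    log_geo = np.log(mat).mean(axis=1)
    ratios = np.log(mat) - log_geo[:, None]
    log_sf = np.median(ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # rescale to geometric mean 1
    return dict(zip(ercc_counts.columns, np.exp(log_sf).tolist()))


def factors_table(
    factors: Mapping[str, float], n_control_transcripts: int
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(sample_id=s, factor=f, n_control_transcripts=n_control_transcripts)
            for s, f in sorted(factors.items())
        ]
    )
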