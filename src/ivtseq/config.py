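"""Pipeline configuration.

Every threshold of the workflow lives in one validated record so that a run
is fully described by a flat key-value config file plus the input paths.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any


@dataclass
class PipelineConfig:
    """All tunable thresholds of the sigma-factor regulon pipeline.

    Defaults are the workflow's published operating point: 100 bp 5'-end
    clustering, subcluster positional SD < 10, normalized-count floor of 4,
    4x dependence ratio, >=10 first-nucleotide reads for ERCC controls,
    fold change >= 2 and BH-adjusted p < 0.01 for overexpression, 300 bp
    upstream TSS window, 50 bp operon gap, and 22-35 nt / >=10 sites /
    E < 1e-5 motif retention.
    """

    cluster_window_nt: int = 100
    subcluster_sd: float = 10.0
    min_norm_count: float = 4.0
    dependence_ratio: float = 4.0
    min_ercc_first_nt_reads: int = 10
    fc_threshold: float = 2.0
    padj_threshold: float = 0.01
    upstream_window_nt: int = 300
    operon_gap_nt: int = 50
    motif_min_width: int = 22
    motif_max_width: int = 35
    motif_min_sites: int = 10
    motif_max_evalue: float = 1e-5
    promoter_window_nt: int = 50
    shared_tss_tolerance_nt: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "cluster_window_nt", "subcluster_sd", "min_norm_count",
            "dependence_ratio", "min_ercc_first_nt_reads", "fc_threshold",
            "padj_threshold", "upstream_window_nt", "operon_gap_nt",
            "motif_min_width", "motif_max_width", "motif_min_sites",
            "motif_max_evalue", "promoter_window_nt",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.shared_tss_tolerance_nt < 0:
            raise ValueError("shared_tss_tolerance_nt must be >= 0")
        if self.motif_min_width > self.motif_max_width:
            raise ValueError(
                f"motif_min_width ({self.motif_min_width}) > "
                f"motif_max_width ({self.motif_max_width})"
            )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                coerced[f.name] = _coerce(f.type, d[f.name])
        return cls(**coerced)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat ``key: value`` (YAML-subset) config file."""
        d: dict[str, Any] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
            key, value = line.split(":", 1)
            d[key.strip()] = value.strip()
        return cls.from_dict(d)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k}: {v}" for k, v in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")


def _coerce(typ: Any, value: Any) -> Any:
    if isinstance(value, str):
        target = typ if isinstance(typ, type) else (int if "int" in str(typ) else float)
        return target(value)
    return value
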