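"""Screen configuration: thresholds, window geometry, and null settings."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["ScreenConfig"]


@dataclass(frozen=True)
class ScreenConfig:
    """All tunable screen parameters with their defaults.

    ``iteration_evalues`` records the homology-search E-value schedule
    (two stringent iterations then one permissive) as metadata for external
    search adapters; the in-package pipeline consumes alignments directly.
    """

    mode: str = "unflanked"  # or "flanked"
    alpha: float = 0.05  # per-pair E-value significance threshold
    rescue_threshold: float = 1e-4  # single-pair rescue E-value
    min_sig: int = 3  # criterion (i): total significant pairs
    min_same_stem: int = 2  # criterion (ii): significant pairs in one stem
    window: int = 1000  # IGR window size (nt)
    overlap: int = 500  # window overlap (nt)
    min_igr: int = 100  # minimum IGR length screened (nt)
    utr_cap: int = 2000  # UTR truncated to this many nt nearest the CDS
    cds_cap: int = 1000  # flanking CDS truncated to this many nt
    n_null: int = 20  # shuffled alignments pooled for the null
    s_min: int = 2  # per-column substitutions needed for power
    bulge_tol: int = 0  # stem continuation tolerance (unpaired nt)
    w_cov: float = 10.0  # fold bonus for a significant pair
    min_loop: int = 3  # minimum hairpin loop length
    max_codon_like: int = 3  # codon filter: flag when exceeded
    min_noncoding_nt: int = 50  # flanked mode: residues required per row
    seed: int = 42
    iteration_evalues: tuple = (1e-10, 1e-10, 1e-5)

    def __post_init__(self):
        object.__setattr__(self, "iteration_evalues", tuple(self.iteration_evalues))
        if self.mode not in {"flanked", "unflanked"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if len(self.iteration_evalues) < 1:
            raise ValueError("iteration_evalues must be non-empty")
        for name in ("window", "overlap", "min_igr", "utr_cap", "cds_cap",
                     "n_null", "min_sig", "min_same_stem"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.overlap >= self.window:
            raise ValueError("overlap must be smaller than window")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["iteration_evalues"] = list(self.iteration_evalues)
        return d

    @property
    def digest(self) -> str:
        """Stable short hash of the configuration, for provenance blocks."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls().to_dict())
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def updated(self, **kwargs) -> "ScreenConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})
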