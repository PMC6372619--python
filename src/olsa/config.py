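"""Run configuration: every tunable knob of the pipeline, with defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .preprocess import DEFAULT_NIQR_CONSTANT

__all__ = ["OLSAConfig"]


@dataclass
class OLSAConfig:
    """Knobs for preprocessing, decomposition, signatures, and enrichment.

    Attributes
    ----------
    cum_threshold : float
        Cumulative contribution governing component retention (0.8 for
        dense compound screens; 0.9 suits small sample sets).
    grubbs_alpha : float
        One-sided significance level of the iterative mirror-set outlier
        gate.
    niqr_constant : float
        IQR scaling in the robust z-score (0.7413 makes the NIQR consistent
        with a normal standard deviation).
    keep_controls : bool
        Whether control columns are z-scored and retained in D.
    fraction : float
        Top-gene fraction per factor fed to enrichment (0.01 = top 1%).
    signature_cutoff : float
        Cumulative squared-loading mass a factor signature must carry.
    alpha : float
        BH-adjusted significance level for enrichment.
    """

    cum_threshold: float = 0.8
    grubbs_alpha: float = 0.05
    niqr_constant: float = DEFAULT_NIQR_CONSTANT
    keep_controls: bool = False
    varimax_tol: float = 1e-8
    varimax_max_iter: int = 1000
    fraction: float = 0.01
    signature_cutoff: float = 0.9
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.cum_threshold <= 1:
            raise ValueError("cum_threshold must be in (0, 1]")
        if not 0 < self.grubbs_alpha < 1:
            raise ValueError("grubbs_alpha must be in (0, 1)")
        if self.niqr_constant <= 0:
            raise ValueError("niqr_constant must be positive")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if not 0 < self.signature_cutoff < 1:
            raise ValueError("signature_cutoff must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.varimax_tol <= 0 or self.varimax_max_iter < 0:
            raise ValueError("invalid varimax convergence settings")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "OLSAConfig":
        """Load from a YAML mapping; keyword overrides win over the file."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
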