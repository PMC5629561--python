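"""Analysis configuration shared by the scan, classify and network steps."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .exceptions import ValidationError


@dataclass
class AnalysisConfig:
    """Tunable parameters of the modulator-inference pipeline.

    min_samples_gene
        A TF or target is eligible only if its expression row has at least
        this many non-missing samples (default 400, matching a cohort of
        ~480 tumors).
    min_samples_triplet
        Minimum retained samples to fit the 4-parameter model (default 30).
    outlier_sd
        Per-gene outlier border in standard deviations around the mean
        (default 3.0), applied on the raw expression scale.
    psi_clamp_low / psi_clamp_high
        Boundary replacements for PSI values of exactly 0 / 1 so the
        logistic-style transform stays finite (defaults 0.01 / 0.99).
    sig_mode / alpha / pvalue_threshold
        "fdr": significant iff BH-adjusted q3 < alpha (default 0.05).
        "pvalue": significant iff raw p3 < pvalue_threshold (default 0.01).
    per_tf_fdr
        Apply BH within each TF's triplets instead of over the whole scan.
    exclude_self_pairs / exclude_self_modulation
        Optionally drop TF->TF self-pairs, and triplets whose event's host
        gene equals the TF or the target.
    psi_fraction / alpha_corr
        Size of the low/high PSI strata (default bottom and top 30%) and
        the two-sided significance level for calling a stratum's TF-target
        correlation '+' or '-' (default 0.05).
    min_pct
        Strict percentage threshold for keeping a TF-modulator edge in the
        bipartite network (default 30).
    """

    min_samples_gene: int = 400
    min_samples_triplet: int = 30
    outlier_sd: float = 3.0
    psi_clamp_low: float = 0.01
    psi_clamp_high: float = 0.99
    sig_mode: str = "fdr"
    alpha: float = 0.05
    pvalue_threshold: float = 0.01
    per_tf_fdr: bool = False
    exclude_self_pairs: bool = False
    exclude_self_modulation: bool = False
    psi_fraction: float = 0.30
    alpha_corr: float = 0.05
    min_pct: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.psi_clamp_low < self.psi_clamp_high < 1:
            raise ValidationError("psi_clamp bounds must satisfy 0 < low < high < 1")
        if self.sig_mode not in ("fdr", "pvalue"):
            raise ValidationError(f"sig_mode must be 'fdr' or 'pvalue', got {self.sig_mode!r}")
        if not 0 < self.psi_fraction <= 0.5:
            raise ValidationError("psi_fraction must be in (0, 0.5]")
        for name in ("alpha", "alpha_corr", "pvalue_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.outlier_sd <= 0:
            raise ValidationError("outlier_sd must be positive")
        if self.min_samples_triplet < 5:
            raise ValidationError("min_samples_triplet must be >= 5 to leave residual df")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def replace(self, **kw) -> "AnalysisConfig":
        return dataclasses.replace(self, **kw)
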