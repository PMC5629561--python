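"""Synthetic expression/PSI datasets with known modulation structure.

The generator works on the model's transformed scale: TF expression is
drawn Gaussian, exon inclusion Beta, and each target's transformed
expression follows

    y' = b0 + b1 * x_tf' + b2 * x_m' + b3 * x_tf' * x_m' + Normal(0, noise_sd)

where x_m' is the clamped-and-transformed PSI of the target's single
"driver" event.  Triplets pairing the target with any other event are
therefore true nulls (b3 = 0).  Expression is back-transformed to the raw
scale as 2**x - 1 (floored at 0) so the pipeline's log2(x + 1) inverts it
exactly; PSI stays on its natural [0, 1] scale and the pipeline's
clamp + transform is part of what is exercised.  Ground-truth b
coefficients are defined on the transformed scale used in fitting.

All randomness flows from a single integer seed through one
numpy Generator in documented order (TF expression, PSI, then per-target
coefficients and noise), so identical configs give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, PsiMatrix, TFTargetMap, TripletVectors
from .exceptions import ValidationError
from .preprocess import clamp_psi, transform_psi

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "TransitionTriplet",
    "TRANSITION_KINDS",
    "simulate_dataset",
    "simulate_triplet_vectors",
    "simulate_transition_triplet",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate a tumor RNA-seq cohort of 480 samples with log2-scale
    expression around 8 +/- 2, symmetric Beta(2, 2) exon inclusion, unit
    Gaussian noise on the transformed scale, and 10% of triplets carrying
    an interaction effect of 1.0.
    """

    n_samples: int = 480
    n_tfs: int = 5
    n_targets_per_tf: int = 20
    n_events: int = 4
    frac_modulated: float = 0.10
    beta3_effect: float = 1.0
    beta0: float = 2.0
    beta1_range: Tuple[float, float] = (0.5, 1.5)
    beta2_range: Tuple[float, float] = (-0.5, 0.5)
    noise_sd: float = 1.0
    psi_alpha: float = 2.0
    psi_beta: float = 2.0
    expr_mean_log: float = 8.0
    expr_sd_log: float = 2.0
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_modulated", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_samples < 10:
            raise ValidationError(f"n_samples must be >= 10, got {self.n_samples}")
        for name in ("n_tfs", "n_targets_per_tf", "n_events"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("noise_sd", "psi_alpha", "psi_beta", "expr_sd_log"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("beta1_range", "beta2_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name} must be (low, high) with low <= high")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """True coefficients per generated triplet.

    ``table`` has one row per (tf, target, event) with columns
    driver (the event whose inclusion actually enters the target's model),
    modulated, beta0..beta3.  b1/b2 are recorded on driver rows only; every
    non-driver row is a true null (b3 = 0).  ``transition`` is filled only
    by the transition-triplet generator.
    """

    table: pd.DataFrame

    def true_beta3(self) -> pd.Series:
        return self.table.set_index(["tf", "target", "event"])["beta3"]


def _back_transform(x: np.ndarray) -> np.ndarray:
    return np.maximum(np.exp2(x) - 1.0, 0.0)


def simulate_dataset(
    cfg: Optional[SimulationConfig] = None,
) -> Tuple[ExpressionMatrix, PsiMatrix, TFTargetMap, GroundTruth]:
    """Generate a full cohort: expression, PSI, TF-target pairs, truth."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    samples = [f"S{i:04d}" for i in range(1, cfg.n_samples + 1)]
    tfs = [f"TF{i:03d}" for i in range(1, cfg.n_tfs + 1)]
    events = [f"E{i:03d}" for i in range(1, cfg.n_events + 1)]
    event_gene = {e: f"MOD{i:03d}" for i, e in enumerate(events, start=1)}

    # 1. TF transformed expression: gene-specific mean and sd
    tf_mean = rng.normal(cfg.expr_mean_log, 1.0, size=cfg.n_tfs)
    tf_sd = rng.uniform(0.5 * cfg.expr_sd_log, 1.5 * cfg.expr_sd_log,
                        size=cfg.n_tfs)
    x_tf = tf_mean[:, None] + tf_sd[:, None] * rng.standard_normal(
        (cfg.n_tfs, cfg.n_samples))

    # 2. PSI per event
    psi_vals = rng.beta(cfg.psi_alpha, cfg.psi_beta,
                        size=(cfg.n_events, cfg.n_samples))
    x_m = transform_psi(clamp_psi(psi_vals))

    # 3. targets: each belongs to one TF and is driven by one event
    pairs = set()
    truth_rows = []
    target_rows = []
    target_ids = []
    t_idx = 0
    for i, tf in enumerate(tfs):
        for _ in range(cfg.n_targets_per_tf):
            t_idx += 1
            target = f"G{t_idx:05d}"
            target_ids.append(target)
            pairs.add((tf, target))
            driver = int(rng.integers(cfg.n_events))
            b1 = float(rng.uniform(*cfg.beta1_range))
            b2 = float(rng.uniform(*cfg.beta2_range))
            modulated = bool(rng.random() < cfg.frac_modulated)
            b3 = cfg.beta3_effect if modulated else 0.0
            noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_samples)
            y = (cfg.beta0 + b1 * x_tf[i] + b2 * x_m[driver]
                 + b3 * x_tf[i] * x_m[driver] + noise)
            target_rows.append(y)
            for j, e in enumerate(events):
                is_driver = j == driver
                truth_rows.append({
                    "tf": tf, "target": target, "event": e,
                    "driver": is_driver, "modulated": modulated and is_driver,
                    "beta0": cfg.beta0 if is_driver else np.nan,
                    "beta1": b1 if is_driver else np.nan,
                    "beta2": b2 if is_driver else np.nan,
                    "beta3": b3 if is_driver else 0.0,
                    "transition": "",
                })

    expr_vals = _back_transform(np.vstack([x_tf, np.array(target_rows)]))
    expr_df = pd.DataFrame(expr_vals, index=tfs + target_ids, columns=samples)
    psi_df = pd.DataFrame(psi_vals, index=events, columns=samples)

    # 4. missingness, expression then PSI
    if cfg.missing_rate > 0:
        expr_df = expr_df.mask(
            rng.random(expr_df.shape) < cfg.missing_rate)
        psi_df = psi_df.mask(
            rng.random(psi_df.shape) < cfg.missing_rate)

    truth = GroundTruth(pd.DataFrame(
        truth_rows,
        columns=["tf", "target", "event", "driver", "modulated",
                 "beta0", "beta1", "beta2", "beta3", "transition"]))
    return (ExpressionMatrix(expr_df), PsiMatrix(psi_df, event_gene=event_gene),
            TFTargetMap(pairs), truth)


def simulate_triplet_vectors(
    n: int,
    beta: Tuple[float, float, float, float],
    noise_sd: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    psi_alpha: float = 2.0,
    psi_beta: float = 2.0,
    expr_mean_log: float = 8.0,
    expr_sd_log: float = 2.0,
) -> TripletVectors:
    """One triplet's analysis-ready vectors drawn directly from the model.

    Bypasses the matrix plumbing (no missingness, no outlier filter) for
    fast statistical experiments on the regression itself: x_tf' Gaussian,
    PSI Beta then clamped + transformed, y' from the model equation.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    x_tf = rng.normal(expr_mean_log, expr_sd_log, size=n)
    psi_raw = rng.beta(psi_alpha, psi_beta, size=n)
    x_m = transform_psi(clamp_psi(psi_raw))
    b0, b1, b2, b3 = beta
    y = b0 + b1 * x_tf + b2 * x_m + b3 * x_tf * x_m + rng.normal(
        0.0, noise_sd, size=n)
    ids = [f"S{i:04d}" for i in range(1, n + 1)]
    return TripletVectors(sample_ids=ids, x_tf=x_tf, y_target=y, x_m=x_m,
                          psi_raw=psi_raw, n=n)


# canonical transition labels: low-PSI state -> high-PSI state
TRANSITION_KINDS = (
    "ns->+", "ns->-", "+->ns", "-->ns", "+->+", "-->-", "+->-", "-->+",
)

_CATEGORY = {
    "ns->+": "Active", "ns->-": "Active", "+->ns": "Active", "-->ns": "Active",
    "+->+": "Repress", "-->-": "Repress",
    "+->-": "Inverts", "-->+": "Inverts",
}


def normalize_kind(kind: str) -> str:
    """Map label variants ("Non-sig → +", "- -> -") onto the canonical form."""
    s = kind.replace("−", "-").replace("→", "->").replace("’", "")
    s = s.replace("Non-sig", "ns").replace("non-sig", "ns").replace("NS", "ns")
    s = "".join(ch for ch in s if not ch.isspace()).replace("'", "")
    left, _, right = s.partition("->")
    if left in ("+", "-", "ns") and right in ("+", "-", "ns"):
        canon = f"{left}->{right}"
        if canon == "ns->ns":
            raise ValidationError("'ns->ns' is Uncalled; no transition to plant")
        return canon
    raise ValidationError(f"unrecognized transition label {kind!r}")


@dataclass
class TransitionTriplet:
    """A single synthetic triplet with a planted correlation transition."""

    tv: TripletVectors
    kind: str
    category: str
    r_low: float
    r_high: float

    @property
    def psi_raw(self) -> pd.Series:
        return pd.Series(self.tv.psi_raw, index=self.tv.sample_ids)


def simulate_transition_triplet(
    kind: str,
    n: int = 400,
    effect: float = 0.8,
    seed: int = 0,
    expr_mean_log: float = 8.0,
    expr_sd_log: float = 2.0,
    r_low: Optional[float] = None,
    r_high: Optional[float] = None,
) -> TransitionTriplet:
    """Plant a low-PSI -> high-PSI correlation-state transition.

    The first half of the samples gets inclusion uniform in (0.02, 0.45)
    and TF-target correlation ``r_low``; the second half inclusion in
    (0.55, 0.98) and correlation ``r_high``.  Defaults derive the r values
    from the label: 'ns' is 0, '+'/'-' is +/-effect, except that same-sign
    ("Repress") transitions use a halved magnitude on the high side so the
    correlation is reduced, not unchanged.
    """
    kind = normalize_kind(kind)
    low_s, _, high_s = kind.partition("->")

    def default_r(state: str, other: str, side: str) -> float:
        if state == "ns":
            return 0.0
        mag = effect
        if state == other and side == "high":
            mag = effect / 2.0  # reduced same-sign correlation
        return mag if state == "+" else -mag

    rl = default_r(low_s, high_s, "low") if r_low is None else r_low
    rh = default_r(high_s, low_s, "high") if r_high is None else r_high

    rng = np.random.default_rng(seed)
    n_low = n // 2
    n_high = n - n_low
    psi_raw = np.concatenate([
        rng.uniform(0.02, 0.45, size=n_low),
        rng.uniform(0.55, 0.98, size=n_high),
    ])
    z = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    r_vec = np.concatenate([np.full(n_low, rl), np.full(n_high, rh)])
    zy = r_vec * z + np.sqrt(1.0 - r_vec ** 2) * eps
    x_tf = expr_mean_log + expr_sd_log * z
    y = expr_mean_log + expr_sd_log * zy
    ids = [f"S{i:04d}" for i in range(1, n + 1)]
    tv = TripletVectors(
        sample_ids=ids, x_tf=x_tf, y_target=y,
        x_m=transform_psi(clamp_psi(psi_raw)), psi_raw=psi_raw, n=n)
    return TransitionTriplet(tv=tv, kind=kind, category=_CATEGORY[kind],
                             r_low=rl, r_high=rh)
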