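"""Classical inverse-variance meta-analysis of individual studies.

Fixed-effects pooling, Cochran's Q heterogeneity statistic, the
DerSimonian-Laird moment estimator of the between-study variance tau^2,
random-effects pooling, and Wald confidence intervals.

Model: each study i reports an estimate theta_i ~ N(theta + u, sigma_i^2)
where u = 0 under the fixed-effects model and u ~ N(0, tau^2) under the
random-effects model.  Fixed-effects weights are w_i = 1/sigma_i^2;
random-effects weights are w_i* = 1/(sigma_i^2 + tau^2).  Q always uses the
fixed-effects weights.  A negative moment estimate of tau^2 is truncated
at zero.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import conversions
from .types import EffectEstimate, MetaSummary, StudyTable

__all__ = [
    "fixed_effects_pool",
    "q_statistic",
    "dl_tau2",
    "random_effects_pool",
    "confidence_interval",
    "meta_analyze",
]


def _as_arrays(
    estimates: Sequence[float], variances: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    theta = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if theta.size == 0:
        raise ValueError("at least one study is required")
    if theta.shape != var.shape:
        raise ValueError(
            f"estimates and variances differ in length ({theta.size} vs {var.size})"
        )
    if np.any(var <= 0):
        raise ValueError("all variances must be positive")
    return theta, var


def fixed_effects_pool(
    estimates: Sequence[float], variances: Sequence[float]
) -> tuple[float, float]:
    """Inverse-variance weighted mean and its variance.

    Returns (sum w_i theta_i / sum w_i, 1 / sum w_i) with w_i = 1/var_i.
    """
    theta, var = _as_arrays(estimates, variances)
    w = 1.0 / var
    sw = w.sum()
    return float(w @ theta / sw), float(1.0 / sw)


def q_statistic(
    estimates: Sequence[float], variances: Sequence[float]
) -> float:
    """Cochran's Q = sum w theta^2 - (sum w theta)^2 / sum w, w = 1/var.

    The weighted sum of squared deviations from the fixed-effects pooled
    value; never tau-adjusted.  Clamped at zero against roundoff.
    """
    theta, var = _as_arrays(estimates, variances)
    w = 1.0 / var
    q = float(w @ theta**2 - (w @ theta) ** 2 / w.sum())
    return max(0.0, q)


def dl_tau2(estimates: Sequence[float], variances: Sequence[float]) -> float:
    """DerSimonian-Laird moment estimate of the between-study variance.

    tau^2 = max{0, (Q - (k - 1)) / (sum w - sum w^2 / sum w)} with
    fixed-effects weights w = 1/var.  Requires at least two studies (the
    denominator degenerates at k = 1).
    """
    theta, var = _as_arrays(estimates, variances)
    if theta.size < 2:
        raise ValueError("tau^2 estimation requires at least 2 studies")
    w = 1.0 / var
    q = q_statistic(estimates, variances)
    denom = w.sum() - (w @ w) / w.sum()
    if denom <= 0:
        # equal weights make sum w - sum w^2/sum w > 0 for k >= 2; this
        # can only vanish through pathological cancellation
        return 0.0
    return max(0.0, (q - (theta.size - 1)) / denom)


def random_effects_pool(
    estimates: Sequence[float],
    variances: Sequence[float],
    tau2: float,
) -> tuple[float, float]:
    """Inverse-variance pool with weights 1/(var_i + tau^2).

    With tau2 = 0 this reduces exactly to :func:`fixed_effects_pool`.
    """
    if tau2 < 0:
        raise ValueError(f"tau2 must be nonnegative, got {tau2}")
    theta, var = _as_arrays(estimates, variances)
    w = 1.0 / (var + tau2)
    sw = w.sum()
    return float(w @ theta / sw), float(1.0 / sw)


def confidence_interval(
    estimate: float, variance: float, z_mult: float = conversions.DEFAULT_Z_MULT
) -> tuple[float, float]:
    """Symmetric Wald interval: estimate -/+ z_mult * sqrt(variance)."""
    if variance <= 0:
        raise ValueError(f"variance must be positive, got {variance}")
    half = z_mult * float(np.sqrt(variance))
    return estimate - half, estimate + half


def meta_analyze(
    table: StudyTable,
    meta_id: str | None = None,
    model: str = "fixed",
    z_mult: float = conversions.DEFAULT_Z_MULT,
    r_scale: str = "native",
) -> MetaSummary:
    """Meta-analyze one group of a study table.

    Parameters
    ----------
    table
        Study records; odds ratios are log-transformed and CI-only records
        get Wald-derived variances on ingestion.
    meta_id
        Which group to analyze; None pools every record in the table
        (which must then share one effect type).
    model
        ``fixed`` or ``random`` (DerSimonian-Laird tau^2, estimated from
        this group alone).
    r_scale
        How correlations are pooled: ``native`` averages the r values
        themselves with their reported variances (the convention of the
        worked examples this package reproduces); ``fisher_z`` pools on
        the variance-stabilized z scale and back-transforms the estimate,
        reporting the summary as a ``fisher_z``-scale MetaSummary.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"model must be 'fixed' or 'random', got {model!r}")
    if r_scale not in ("native", "fisher_z"):
        raise ValueError(f"r_scale must be 'native' or 'fisher_z', got {r_scale!r}")
    group = table if meta_id is None else table.subset(meta_id)
    std = conversions.standardize_table(group, z_mult)
    if len(std) == 0:
        raise ValueError(
            f"group {meta_id!r} has no informative records (variance or CI required)"
        )
    types = {rec.effect_type for rec in std}
    if len(types) > 1:
        raise ValueError(
            f"group {meta_id!r} mixes effect types {sorted(types)}; convert "
            "records to a common scale first (see metasynth.conversions)"
        )
    effect_type = types.pop()
    records: list[EffectEstimate] = list(std)

    if effect_type == "r" and r_scale == "fisher_z":
        estimates = [conversions.r_to_fisher_z(r.estimate) for r in records]
        variances = [
            conversions.variance_transform(
                r.variance, "r", "fisher_z", at_value=r.estimate
            )
            for r in records
        ]
        effect_type = "fisher_z"
    else:
        estimates = [r.estimate for r in records]
        variances = [r.variance for r in records]

    if model == "fixed" or len(records) < 2:
        tau2 = 0.0
        est, var = fixed_effects_pool(estimates, variances)
    else:
        tau2 = dl_tau2(estimates, variances)
        est, var = random_effects_pool(estimates, variances, tau2)

    lo, hi = confidence_interval(est, var, z_mult)
    label = meta_id if meta_id is not None else (
        records[0].meta_id if len(table.meta_ids()) == 1 else "pooled"
    )
    return MetaSummary(
        meta_id=label,
        effect_type=effect_type,
        estimate=est,
        variance=var,
        tau2=tau2,
        n_studies=len(records),
        model=model,
        ci_lower=lo,
        ci_upper=hi,
    )
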