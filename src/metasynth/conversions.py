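"""Effect-size conversions among correlation, Fisher z, log odds ratio and
standardized mean difference (SMD) scales.

Meta-analyses of the same question frequently publish on different scales:
continuous outcomes as SMDs, dichotomized outcomes as odds ratios, and
associations as Pearson correlations.  Before such summaries can be pooled
they must be moved onto one scale; the SMD is the common target here.  The
log odds ratio converts linearly — the logistic distribution differs from
the standard normal mainly in the tails, so ln(OR)/1.81 approximates an SMD
(1.81 being the conventional rounding of pi/sqrt(3)).  The correlation
travels through Fisher's z, whose relationship to the SMD,
m = e^z - e^(-z), is linearized as m ≈ 2z so that pooling stays a linear
operation.  Sampling variances move with their estimates by the delta
method.

Confidence intervals stand in for unreported variances: a symmetric
level-C Wald interval of width (UL - LL) implies a variance of
(UL - LL)^2 / (2 z_C)^2, with z_C = 1.96 at the conventional 95% level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace

from scipy.stats import norm

from .types import EffectDomainError, EffectEstimate, InvalidIntervalError, StudyTable

__all__ = [
    "DEFAULT_Z_MULT",
    "DEFAULT_SCALE_CONST",
    "z_multiplier",
    "variance_from_ci",
    "r_to_fisher_z",
    "fisher_z_to_r",
    "fisher_z_to_smd",
    "r_to_smd",
    "log_or_to_smd",
    "smd_to_log_or",
    "variance_transform",
    "standardize_record",
    "standardize_table",
    "to_smd",
]

logger = logging.getLogger(__name__)

#: Conventional normal quantile for a 95% Wald interval.  Kept at the
#: two-decimal value used throughout applied meta-analysis rather than the
#: exact quantile 1.95996..., so that desk calculations reproduce published
#: worked examples digit for digit.
DEFAULT_Z_MULT = 1.96

#: Logistic-to-normal scale constant: ln(OR)/1.81 approximates an SMD.
#: The exact ratio of standard deviations is pi/sqrt(3) = 1.8138...; the
#: two-decimal rounding is the value used in practice.
DEFAULT_SCALE_CONST = 1.81


def z_multiplier(level: float) -> float:
    """Two-sided normal quantile for a given confidence level.

    Returns the conventional 1.96 for the default 0.95 level; other levels
    use the exact normal quantile.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if level == 0.95:
        return DEFAULT_Z_MULT
    return float(norm.ppf(0.5 + level / 2.0))


def variance_from_ci(lower: float, upper: float, z_mult: float = DEFAULT_Z_MULT) -> float:
    """Sampling variance implied by a symmetric Wald confidence interval.

    var = (upper - lower)^2 / (2 * z_mult)^2.
    """
    if not upper > lower:
        raise InvalidIntervalError(
            f"upper limit {upper} must exceed lower limit {lower}"
        )
    if z_mult <= 0:
        raise ValueError(f"z_mult must be positive, got {z_mult}")
    half = (upper - lower) / (2.0 * z_mult)
    return half * half


def r_to_fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform z = atanh(r)."""
    if not -1.0 < r < 1.0:
        raise EffectDomainError(f"correlation must lie in (-1, 1), got {r}")
    return 0.5 * math.log((1.0 + r) / (1.0 - r))


def fisher_z_to_r(z: float) -> float:
    """Inverse Fisher transform r = tanh(z)."""
    return math.tanh(z)


def fisher_z_to_smd(z: float, mode: str = "linear") -> float:
    """Map a Fisher z-score to the SMD scale.

    The exact relationship is m = e^z - e^(-z) (= 2 sinh z); its first-order
    expansion m ≈ 2z preserves linearity under pooling and is the default.
    """
    if mode == "linear":
        return 2.0 * z
    if mode == "exact":
        return math.exp(z) - math.exp(-z)
    raise ValueError(f"mode must be 'linear' or 'exact', got {mode!r}")


def r_to_smd(r: float) -> float:
    """Direct correlation-to-SMD conversion m = 2r / sqrt(1 - r^2)."""
    if not -1.0 < r < 1.0:
        raise EffectDomainError(f"correlation must lie in (-1, 1), got {r}")
    return 2.0 * r / math.sqrt(1.0 - r * r)


def log_or_to_smd(log_or: float, scale_const: float = DEFAULT_SCALE_CONST) -> float:
    """Logistic-scale conversion m = ln(OR) / scale_const."""
    if scale_const <= 0:
        raise ValueError(f"scale_const must be positive, got {scale_const}")
    return log_or / scale_const


def smd_to_log_or(smd: float, scale_const: float = DEFAULT_SCALE_CONST) -> float:
    """Inverse of :func:`log_or_to_smd`."""
    if scale_const <= 0:
        raise ValueError(f"scale_const must be positive, got {scale_const}")
    return smd * scale_const


def _transform_factor(
    from_type: str, to_type: str, at_value: float | None, scale_const: float
) -> float:
    """Squared derivative of the conversion map, for delta-method variances."""
    if from_type == "r" and to_type == "fisher_z":
        _need_value(at_value, "r -> fisher_z")
        d = 1.0 / (1.0 - at_value * at_value)
        return d * d
    if from_type == "fisher_z" and to_type == "r":
        _need_value(at_value, "fisher_z -> r")
        r = math.tanh(at_value)
        d = 1.0 - r * r
        return d * d
    if from_type == "fisher_z" and to_type == "smd":
        return 4.0
    if from_type == "smd" and to_type == "fisher_z":
        return 0.25
    if from_type == "log_or" and to_type == "smd":
        return 1.0 / (scale_const * scale_const)
    if from_type == "smd" and to_type == "log_or":
        return scale_const * scale_const
    if from_type == "r" and to_type == "smd":
        _need_value(at_value, "r -> smd")
        d = 2.0 / (1.0 - at_value * at_value) ** 1.5
        return d * d
    raise NotImplementedError(
        f"no variance transform implemented for {from_type!r} -> {to_type!r}"
    )


def _need_value(at_value: float | None, pair: str) -> None:
    if at_value is None:
        raise ValueError(f"variance transform {pair} requires at_value")


def variance_transform(
    variance: float,
    from_type: str,
    to_type: str,
    at_value: float | None = None,
    scale_const: float = DEFAULT_SCALE_CONST,
) -> float:
    """Delta-method variance on the target scale.

    ``at_value`` is the point estimate on the *source* scale; it is required
    for the curved maps (those involving the correlation) and ignored for
    the linear ones.
    """
    if variance < 0:
        raise ValueError(f"variance must be nonnegative, got {variance}")
    if from_type == to_type:
        return variance
    if at_value is not None and from_type == "r" and not -1.0 < at_value < 1.0:
        raise EffectDomainError(f"correlation must lie in (-1, 1), got {at_value}")
    return variance * _transform_factor(from_type, to_type, at_value, scale_const)


def standardize_record(
    record: EffectEstimate, z_mult: float = DEFAULT_Z_MULT
) -> EffectEstimate | None:
    """Resolve a record to internal form: log-scale ORs, explicit variance.

    Odds-ratio records are log-transformed (limits included) on ingestion.
    A missing variance is derived from the confidence interval; records
    carrying neither variance nor interval are uninformative and are
    dropped with a warning (returning None).
    """
    rec = record
    if rec.effect_type == "or":
        rec = replace(
            rec,
            effect_type="log_or",
            estimate=math.log(rec.estimate),
            ci_lower=None if rec.ci_lower is None else math.log(rec.ci_lower),
            ci_upper=None if rec.ci_upper is None else math.log(rec.ci_upper),
        )
    if rec.variance is None or rec.variance == 0:
        if not rec.has_ci:
            logger.warning(
                "study %r (meta %r) reports neither a variance nor a confidence "
                "interval and is excluded from the synthesis",
                record.study_id,
                record.meta_id,
            )
            return None
        rec = replace(rec, variance=variance_from_ci(rec.ci_lower, rec.ci_upper, z_mult))
    return rec


def standardize_table(table: StudyTable, z_mult: float = DEFAULT_Z_MULT) -> StudyTable:
    """Apply :func:`standardize_record` across a table, dropping uninformative rows."""
    out = []
    for rec in table:
        std = standardize_record(rec, z_mult)
        if std is not None:
            out.append(std)
    return StudyTable(out)


def to_smd(
    record: EffectEstimate,
    scale_const: float = DEFAULT_SCALE_CONST,
    z_mult: float = DEFAULT_Z_MULT,
) -> EffectEstimate:
    """Convert a study record to the SMD scale with its delta-method variance.

    Correlations travel through Fisher's z with the linearized map m = 2z,
    so the implied variance is 4 var(z) = 4 var(r) / (1 - r^2)^2.
    """
    rec = standardize_record(record, z_mult)
    if rec is None:
        raise ValueError(
            f"study {record.study_id!r} carries no variance or interval; "
            "it cannot be converted for synthesis"
        )
    if rec.effect_type == "smd":
        return replace(rec, ci_lower=None, ci_upper=None)
    if rec.effect_type == "log_or":
        return replace(
            rec,
            effect_type="smd",
            estimate=log_or_to_smd(rec.estimate, scale_const),
            variance=variance_transform(
                rec.variance, "log_or", "smd", scale_const=scale_const
            ),
            ci_lower=None,
            ci_upper=None,
        )
    if rec.effect_type == "fisher_z":
        return replace(
            rec,
            effect_type="smd",
            estimate=fisher_z_to_smd(rec.estimate),
            variance=variance_transform(rec.variance, "fisher_z", "smd"),
            ci_lower=None,
            ci_upper=None,
        )
    # correlation: z = atanh(r), m = 2z, var = 4 var(z)
    z = r_to_fisher_z(rec.estimate)
    var_z = variance_transform(rec.variance, "r", "fisher_z", at_value=rec.estimate)
    return replace(
        rec,
        effect_type="smd",
        estimate=fisher_z_to_smd(z),
        variance=variance_transform(var_z, "fisher_z", "smd"),
        ci_lower=None,
        ci_upper=None,
    )
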