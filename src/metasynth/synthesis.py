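"""Synthesis of already-summarized meta-analyses.

When several meta-analyses address one question, their published summary
estimates can themselves be combined by inverse-variance weighting — an
umbrella-review analogue of ordinary pooling.  Under a fixed-effects model
this two-step synthesis is algebraically identical to re-pooling every
primary study; under a random-effects model the two paths differ only
through which studies inform the tau^2 estimate.

When the meta-analyses report different effect-size types, each summary is
moved to the standardized-mean-difference (SMD) scale before weighting:
log odds ratios divide by 1.81, correlations travel through Fisher's z.
The combined numerator follows the published closed form, in which the
correlation term enters with coefficient 1/2 on ln((1+r)/(1-r)); a
delta-consistent variant with coefficient 1/4 (weight times converted
value) is available, see :func:`synthesize_mixed`.

Finally, meta-analyses being synthesized often share primary studies.
Treating their summaries as independent then understates the combined
variance; :func:`overlap_corrected_variance` applies the exact inflation
factor computable from the shared studies' weights.
"""

from __future__ import annotations

import math
from typing import Sequence

from . import conversions, core
from .types import (
    EffectDomainError,
    MetaSummary,
    OverlapSpec,
    StudyTable,
    SynthesisResult,
)

__all__ = [
    "synthesize_same_type",
    "synthesize_mixed",
    "synthesize_or_summaries",
    "pooled_individual_mixed",
    "two_step_equivalence_gap",
    "overlap_corrected_variance",
    "apply_overlap",
]


def _resolve_summary_variance(s: MetaSummary, z_mult: float) -> float:
    """Summary variance, Wald-derived from the CI when not reported."""
    if s.variance is not None:
        return s.variance
    if s.has_ci:
        lo, up = s.ci_lower, s.ci_upper
        if s.effect_type == "or":
            lo, up = math.log(lo), math.log(up)
        return conversions.variance_from_ci(lo, up, conversions.z_multiplier(s.ci_level))
    raise ValueError(
        f"meta {s.meta_id!r} reports neither a variance nor a confidence "
        "interval and must be excluded from the synthesis"
    )


def _result(
    estimate: float,
    variance: float,
    scale: str,
    weights: list[tuple[str, float]],
    z_mult: float,
) -> SynthesisResult:
    lo, hi = core.confidence_interval(estimate, variance, z_mult)
    return SynthesisResult(
        estimate=estimate,
        variance=variance,
        ci_lower=lo,
        ci_upper=hi,
        scale=scale,
        weights=weights,
    )


def synthesize_same_type(
    summaries: Sequence[MetaSummary],
    z_mult: float = conversions.DEFAULT_Z_MULT,
) -> SynthesisResult:
    """Inverse-variance combination of same-scale meta-analysis summaries.

    estimate = sum w_j theta_j / sum w_j and variance = 1 / sum w_j with
    w_j = 1 / var(theta_j).  Applies identically to fixed- and
    random-effects summaries; the summary variances are taken as given.
    """
    if not summaries:
        raise ValueError("at least one summary is required")
    types = {s.effect_type for s in summaries}
    if len(types) > 1:
        raise ValueError(
            f"summaries mix effect types {sorted(types)}; use synthesize_mixed "
            "to combine different scales"
        )
    scale = types.pop()
    if scale == "or":
        return synthesize_or_summaries(list(summaries), z_mult)
    num = 0.0
    den = 0.0
    weights: list[tuple[str, float]] = []
    for s in summaries:
        w = 1.0 / _resolve_summary_variance(s, z_mult)
        num += w * s.estimate
        den += w
        weights.append((s.meta_id, w))
    return _result(num / den, 1.0 / den, scale, weights, z_mult)


def synthesize_mixed(
    summaries: Sequence[MetaSummary],
    numerator_mode: str = "as_printed",
    z_mult: float = conversions.DEFAULT_Z_MULT,
    scale_const: float = conversions.DEFAULT_SCALE_CONST,
) -> SynthesisResult:
    """Combine mixed-type meta-analysis summaries on the SMD scale.

    Each summary contributes in its originally reported metric:

    - SMD summaries with weight w_m = 1/var(m), term w_m * m;
    - odds-ratio summaries (reported as log-OR, or as OR with CI, which is
      log-transformed first) with weight w_OR = 1/var(ln OR), numerator
      term ``scale_const`` * w_OR * ln(OR), denominator term
      ``scale_const``^2 * w_OR;
    - correlation summaries with weight w_r = (1-r^2)^2/var(r), numerator
      term c * w_r * ln((1+r)/(1-r)), denominator term w_r/4.

    The coefficient c is 1/2 in ``as_printed`` mode — the closed form as
    conventionally written, which reproduces the published worked example —
    and 1/4 in ``delta_consistent`` mode, where each term is exactly
    (weight on the SMD scale) x (converted estimate 2z).  The combined
    variance is 1/denominator in both modes.
    """
    if not summaries:
        raise ValueError("at least one summary is required")
    if numerator_mode not in ("as_printed", "delta_consistent"):
        raise ValueError(
            f"numerator_mode must be 'as_printed' or 'delta_consistent', "
            f"got {numerator_mode!r}"
        )
    c_r = 0.5 if numerator_mode == "as_printed" else 0.25
    num = 0.0
    den = 0.0
    weights: list[tuple[str, float]] = []
    for s in summaries:
        var = _resolve_summary_variance(s, z_mult)
        if s.effect_type == "smd":
            w = 1.0 / var
            num += w * s.estimate
            den += w
            eff_w = w
        elif s.effect_type in ("log_or", "or"):
            log_or = math.log(s.estimate) if s.effect_type == "or" else s.estimate
            w = 1.0 / var
            num += scale_const * w * log_or
            eff_w = scale_const * scale_const * w
            den += eff_w
        elif s.effect_type == "r":
            r = s.estimate
            if not -1.0 < r < 1.0:
                raise EffectDomainError(
                    f"meta {s.meta_id!r}: correlation must lie in (-1, 1)"
                )
            w = (1.0 - r * r) ** 2 / var
            num += c_r * w * math.log((1.0 + r) / (1.0 - r))
            eff_w = 0.25 * w
            den += eff_w
        elif s.effect_type == "fisher_z":
            # a z-scale summary converts linearly: m = 2z, var(m) = 4 var(z)
            w = 0.25 / var
            num += w * 2.0 * s.estimate
            den += w
            eff_w = w
        else:  # pragma: no cover - types are validated upstream
            raise ValueError(f"unsupported effect type {s.effect_type!r}")
        weights.append((s.meta_id, eff_w))
    return _result(num / den, 1.0 / den, "smd", weights, z_mult)


def synthesize_or_summaries(
    or_summaries: Sequence[MetaSummary | tuple[float, float, float]],
    z_mult: float = conversions.DEFAULT_Z_MULT,
) -> SynthesisResult:
    """Pool meta-analytic odds ratios on the natural-log scale.

    Accepts (OR, ci_lower, ci_upper) triples or ``or``-type summaries.
    Estimates and limits are log-transformed, variances derived from the
    log-scale intervals, and the inverse-variance pool is reported on the
    log-OR scale; ``result.or_estimate`` / ``result.or_ci`` give the
    back-transformed odds ratio and interval.
    """
    if not or_summaries:
        raise ValueError("at least one odds-ratio summary is required")
    ests: list[float] = []
    vars_: list[float] = []
    ids: list[str] = []
    for i, s in enumerate(or_summaries):
        if isinstance(s, MetaSummary):
            if s.effect_type != "or":
                raise ValueError(
                    f"meta {s.meta_id!r}: expected effect_type 'or', got {s.effect_type!r}"
                )
            or_hat, lo, up, label = s.estimate, s.ci_lower, s.ci_upper, s.meta_id
            if s.variance is not None:
                ests.append(math.log(or_hat))
                vars_.append(s.variance)
                ids.append(label)
                continue
        else:
            or_hat, lo, up = s
            label = f"meta_{i + 1}"
        if or_hat <= 0 or lo is None or up is None or lo <= 0 or up <= 0:
            raise EffectDomainError(
                f"{label}: odds ratio and CI limits must all be positive"
            )
        ests.append(math.log(or_hat))
        vars_.append(conversions.variance_from_ci(math.log(lo), math.log(up), z_mult))
        ids.append(label)
    est, var = core.fixed_effects_pool(ests, vars_)
    weights = [(mid, 1.0 / v) for mid, v in zip(ids, vars_)]
    return _result(est, var, "log_or", weights, z_mult)


def pooled_individual_mixed(
    table: StudyTable,
    model: str = "random",
    z_mult: float = conversions.DEFAULT_Z_MULT,
    scale_const: float = conversions.DEFAULT_SCALE_CONST,
) -> SynthesisResult:
    """One-stage pool of mixed-type primary studies on the SMD scale.

    Every record is converted (log-OR / 1.81; correlation to 2 * Fisher z;
    SMD unchanged) with matching delta-method variances; under the random-
    effects model a single tau^2 is then estimated from all converted
    studies and the pool uses weights 1/(var + tau^2).
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"model must be 'fixed' or 'random', got {model!r}")
    converted = []
    for rec in table:
        try:
            converted.append(conversions.to_smd(rec, scale_const, z_mult))
        except (ValueError, NotImplementedError) as exc:
            raise ValueError(
                f"study {rec.study_id!r} cannot be converted to the SMD scale: {exc}"
            ) from exc
    if not converted:
        raise ValueError("no convertible records in table")
    estimates = [r.estimate for r in converted]
    variances = [r.variance for r in converted]
    if model == "fixed" or len(converted) < 2:
        tau2 = 0.0
    else:
        tau2 = core.dl_tau2(estimates, variances)
    est, var = core.random_effects_pool(estimates, variances, tau2)
    weights = [
        (r.study_id, 1.0 / (v + tau2)) for r, v in zip(converted, variances)
    ]
    return _result(est, var, "smd", weights, z_mult)


def two_step_equivalence_gap(
    table: StudyTable,
    model: str = "fixed",
    z_mult: float = conversions.DEFAULT_Z_MULT,
) -> tuple[SynthesisResult, SynthesisResult, float]:
    """Compare pooling all studies at once against the two-step synthesis.

    The pooled path meta-analyzes every record in one pass (tau^2, if any,
    estimated from the full study set); the two-step path summarizes each
    meta-analysis separately (per-group tau^2) and combines the summaries
    by inverse-variance weighting.  Under the fixed-effects model the two
    are algebraically identical; under random effects they differ only
    through the tau^2 estimates.  Returns (pooled, two_step, |gap|).
    """
    if len(table.meta_ids()) < 2:
        raise ValueError("equivalence comparison requires at least 2 meta-analyses")
    pooled_summary = core.meta_analyze(table.relabel("pooled"), model=model, z_mult=z_mult)
    pooled = _result(
        pooled_summary.estimate,
        pooled_summary.variance,
        pooled_summary.effect_type,
        [("pooled", 1.0 / pooled_summary.variance)],
        z_mult,
    )
    summaries = [
        core.meta_analyze(table, mid, model=model, z_mult=z_mult)
        for mid in table.meta_ids()
    ]
    two_step = synthesize_same_type(summaries, z_mult)
    return pooled, two_step, abs(pooled.estimate - two_step.estimate)


def overlap_corrected_variance(
    naive_variance: float, spec: OverlapSpec
) -> tuple[float, float]:
    """Inflate a naive combined variance for shared primary studies.

    Returns (naive_variance * IF, IF) where IF is computed exactly from the
    shared studies' weights when available, or taken from the spec's
    explicit value otherwise.  With no overlap IF = 1; with J meta-analyses
    of identical study sets IF = J.
    """
    if naive_variance <= 0:
        raise ValueError(f"naive_variance must be positive, got {naive_variance}")
    inflation = spec.compute_inflation_factor()
    return naive_variance * inflation, inflation


def apply_overlap(
    result: SynthesisResult,
    spec: OverlapSpec,
    z_mult: float = conversions.DEFAULT_Z_MULT,
) -> SynthesisResult:
    """A copy of a synthesis result with the overlap-corrected variance.

    The point estimate is unchanged (overlap biases only the variance);
    the confidence interval is rebuilt from the corrected variance, and
    the naive variance is retained for reporting.
    """
    corrected, inflation = overlap_corrected_variance(result.variance, spec)
    lo, hi = core.confidence_interval(result.estimate, corrected, z_mult)
    return SynthesisResult(
        estimate=result.estimate,
        variance=corrected,
        ci_lower=lo,
        ci_upper=hi,
        scale=result.scale,
        weights=list(result.weights),
        inflation_factor=inflation,
        naive_variance=result.variance,
    )
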