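"""Synthetic study tables from the two-level normal model.

Data are generated from the hierarchy underlying random-effects
meta-analysis: each study's true effect is theta_ij = theta + u_ij with
per-study random effects u_ij ~ N(0, tau^2) — the structure the
DerSimonian-Laird estimator targets — observed with noise
eps_ij ~ N(0, sigma_ij^2), the within-study variances drawn uniformly
from a configurable range.
Mixed-type tables place the truth on the SMD scale and push it through the
inverse conversions (times 1.81 for log odds ratios; Fisher back-transform
for correlations), so that forward conversion recovers the generating
scale and the mixed-type estimators are exercised end to end.

All output is reproducible: one master seed, with per-replicate streams
derived deterministically by replicate index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import conversions, core, synthesis
from .types import EffectEstimate, StudyTable

__all__ = ["SimulationConfig", "generate_study_table", "recovery_experiment"]


@dataclass
class SimulationConfig:
    """Parameters of the generating model.

    Parameters
    ----------
    n_meta
        Number of meta-analyses J.
    studies_per_meta
        Studies per meta-analysis: one integer for all groups or a
        sequence of length ``n_meta``.
    theta
        Grand mean effect on the SMD scale.
    tau
        Between-study standard deviation of the true effects (the random
        effect is drawn per study).
    within_variance_range
        (low, high) bounds for the uniformly drawn within-study variances
        sigma_ij^2 on the SMD scale.  The default [0.005, 0.05] spans the
        precision typical of small-to-moderate behavioural studies.
    effect_type_mix
        Proportions over {smd, log_or, r} governing each study's reported
        scale; must sum to 1.
    overlap_count
        Number p of studies duplicated across all meta-analyses (the first
        p studies of the first group), for exercising the overlap
        correction.
    seed
        Master seed; identical configs produce bit-identical tables.
    """

    n_meta: int = 2
    studies_per_meta: int | Sequence[int] = 10
    theta: float = 0.3
    tau: float = 0.15
    within_variance_range: tuple[float, float] = (0.005, 0.05)
    effect_type_mix: Mapping[str, float] = field(
        default_factory=lambda: {"smd": 1.0}
    )
    overlap_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_meta < 1:
            raise ValueError(f"n_meta must be positive, got {self.n_meta}")
        if isinstance(self.studies_per_meta, int):
            self.studies_per_meta = [self.studies_per_meta] * self.n_meta
        else:
            self.studies_per_meta = list(self.studies_per_meta)
        if len(self.studies_per_meta) != self.n_meta:
            raise ValueError(
                f"studies_per_meta has length {len(self.studies_per_meta)}, "
                f"expected n_meta = {self.n_meta}"
            )
        if any(k < 1 for k in self.studies_per_meta):
            raise ValueError("every meta-analysis needs at least one study")
        if self.tau < 0:
            raise ValueError(f"tau must be nonnegative, got {self.tau}")
        lo, hi = self.within_variance_range
        if not 0 < lo <= hi:
            raise ValueError(
                f"within_variance_range must satisfy 0 < low <= high, got ({lo}, {hi})"
            )
        mix = dict(self.effect_type_mix)
        unknown = set(mix) - {"smd", "log_or", "r"}
        if unknown:
            raise ValueError(f"effect_type_mix has unsupported types {sorted(unknown)}")
        total = sum(mix.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"effect_type_mix proportions must sum to 1, got {total}")
        if any(p < 0 for p in mix.values()):
            raise ValueError("effect_type_mix proportions must be nonnegative")
        self.effect_type_mix = mix
        if self.overlap_count < 0:
            raise ValueError("overlap_count must be nonnegative")
        if self.overlap_count > min(self.studies_per_meta):
            raise ValueError(
                "overlap_count cannot exceed the smallest meta-analysis size"
            )


def _observe(
    effect_type: str, true_smd: float, sigma2: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw one study's observed (estimate, variance) on its reporting scale.

    The SMD-scale observation is m_obs = true + eps, eps ~ N(0, sigma2).
    Log-OR studies report 1.81 * m_obs with variance 1.81^2 sigma2, so that
    dividing by 1.81 recovers the SMD model exactly.  Correlation studies
    observe on the Fisher-z scale (z_obs ~ N(true/2, sigma2/4)), report
    r = tanh(z_obs) with the delta-method variance, keeping |r| < 1 by
    construction; converting back through 2 * atanh(r) recovers z-scale
    noise with SMD-scale variance sigma2.
    """
    if effect_type == "smd":
        return true_smd + rng.normal(0.0, math.sqrt(sigma2)), sigma2
    if effect_type == "log_or":
        c = conversions.DEFAULT_SCALE_CONST
        m_obs = true_smd + rng.normal(0.0, math.sqrt(sigma2))
        return c * m_obs, c * c * sigma2
    # correlation via Fisher z
    z_obs = true_smd / 2.0 + rng.normal(0.0, math.sqrt(sigma2) / 2.0)
    r = math.tanh(z_obs)
    var_r = conversions.variance_transform(sigma2 / 4.0, "fisher_z", "r", at_value=z_obs)
    return r, var_r


def generate_study_table(config: SimulationConfig) -> StudyTable:
    """Draw one study table from the configured two-level model."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.within_variance_range
    types = sorted(config.effect_type_mix)
    probs = [config.effect_type_mix[t] for t in types]
    records: list[EffectEstimate] = []
    shared: list[EffectEstimate] = []
    for j in range(config.n_meta):
        meta_id = f"meta_{j + 1}"
        k_j = config.studies_per_meta[j]
        start = 0
        if j > 0 and config.overlap_count > 0:
            # the first p studies of meta_1 recur in every meta-analysis
            for rec in shared:
                records.append(
                    EffectEstimate(
                        study_id=rec.study_id,
                        meta_id=meta_id,
                        effect_type=rec.effect_type,
                        estimate=rec.estimate,
                        variance=rec.variance,
                    )
                )
            start = config.overlap_count
        for i in range(start, k_j):
            sigma2 = rng.uniform(lo, hi)
            effect_type = str(rng.choice(types, p=probs))
            u_ij = rng.normal(0.0, config.tau) if config.tau > 0 else 0.0
            est, var = _observe(effect_type, config.theta + u_ij, sigma2, rng)
            rec = EffectEstimate(
                study_id=f"study_{j + 1}_{i + 1}",
                meta_id=meta_id,
                effect_type=effect_type,
                estimate=est,
                variance=var,
            )
            records.append(rec)
            if j == 0 and i < config.overlap_count:
                shared.append(rec)
    return StudyTable(records)


def _replicate_config(config: SimulationConfig, rep: int) -> SimulationConfig:
    cfg = SimulationConfig(
        n_meta=config.n_meta,
        studies_per_meta=list(config.studies_per_meta),
        theta=config.theta,
        tau=config.tau,
        within_variance_range=config.within_variance_range,
        effect_type_mix=dict(config.effect_type_mix),
        overlap_count=config.overlap_count,
        seed=int(np.random.SeedSequence([config.seed, rep]).generate_state(1)[0] % (2**31)),
    )
    return cfg


def recovery_experiment(config: SimulationConfig, n_reps: int) -> dict:
    """Monte-Carlo check of the estimators against the generating truth.

    For each replicate the table is pooled under the random-effects model
    (SMD scale; mixed-type records converted first) and, when the table has
    at least two meta-analyses, the fixed-effects two-step gap is recorded.
    Returns a report dict with bias, RMSE and Wald-CI coverage for the
    grand mean, bias/RMSE for tau^2, and the maximum fixed-effects
    equivalence gap observed.
    """
    if n_reps < 2:
        raise ValueError(f"n_reps must be at least 2, got {n_reps}")
    theta_hats = np.empty(n_reps)
    tau2_hats = np.empty(n_reps)
    covered = np.zeros(n_reps, dtype=bool)
    max_fem_gap = 0.0
    for rep in range(n_reps):
        table = generate_study_table(_replicate_config(config, rep))
        res = synthesis.pooled_individual_mixed(table, model="random")
        theta_hats[rep] = res.estimate
        converted = [conversions.to_smd(r) for r in table]
        tau2_hats[rep] = core.dl_tau2(
            [r.estimate for r in converted], [r.variance for r in converted]
        )
        covered[rep] = res.ci_lower <= config.theta <= res.ci_upper
        if config.n_meta >= 2 and len(set(r.effect_type for r in table)) == 1:
            _, _, gap = synthesis.two_step_equivalence_gap(table, model="fixed")
            max_fem_gap = max(max_fem_gap, gap)
    tau2_true = config.tau**2
    return {
        "n_reps": n_reps,
        "theta_true": config.theta,
        "tau2_true": tau2_true,
        "theta_bias": float(theta_hats.mean() - config.theta),
        "theta_rmse": float(np.sqrt(((theta_hats - config.theta) ** 2).mean())),
        "theta_mc_se": float(theta_hats.std(ddof=1) / math.sqrt(n_reps)),
        "tau2_bias": float(tau2_hats.mean() - tau2_true),
        "tau2_rmse": float(np.sqrt(((tau2_hats - tau2_true) ** 2).mean())),
        "ci_coverage": float(covered.mean()),
        "max_fem_two_step_gap": float(max_fem_gap),
    }
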