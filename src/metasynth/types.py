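"""Core data structures for meta-analysis synthesis.

The objects here mirror the three levels at which evidence is handled:
individual studies (:class:`EffectEstimate`, grouped into a
:class:`StudyTable`), meta-analytic summaries (:class:`MetaSummary`), and
combinations of meta-analyses (:class:`SynthesisResult`).  An
:class:`OverlapSpec` describes primary studies shared among the synthesized
meta-analyses, for which the naive combined variance must be inflated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "EFFECT_TYPES",
    "EffectEstimate",
    "MetaSummary",
    "StudyTable",
    "SynthesisResult",
    "OverlapSpec",
    "InvalidIntervalError",
    "EffectDomainError",
]

#: Recognised effect-size scales.  ``or`` is an ingestion-only tag: odds
#: ratios are log-transformed on entry and carried as ``log_or`` internally.
EFFECT_TYPES = ("smd", "log_or", "or", "r", "fisher_z")


class InvalidIntervalError(ValueError):
    """A confidence interval whose lower limit is not below its upper limit."""


class EffectDomainError(ValueError):
    """An estimate outside the domain of its declared effect scale."""


def _check_effect_type(effect_type: str) -> None:
    if effect_type not in EFFECT_TYPES:
        raise ValueError(
            f"unknown effect_type {effect_type!r}; expected one of {EFFECT_TYPES}"
        )


@dataclass
class EffectEstimate:
    """A single study's effect estimate on a declared scale.

    Parameters
    ----------
    study_id, meta_id
        Labels for the study and the meta-analysis it belongs to.
    effect_type
        One of ``smd``, ``log_or``, ``or``, ``r``, ``fisher_z``.
    estimate
        Point estimate on the declared scale.
    variance
        Sampling variance on the same scale (squared units).  May be omitted
        when a confidence interval is given instead; records carrying
        neither are uninformative and are excluded from any synthesis.
    ci_lower, ci_upper, ci_level
        Optional confidence limits and their level (default 0.95).
    """

    study_id: str
    meta_id: str
    effect_type: str
    estimate: float
    variance: float | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        _check_effect_type(self.effect_type)
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.variance is not None and self.variance < 0:
            raise ValueError(
                f"study {self.study_id!r}: variance must be nonnegative, got {self.variance}"
            )
        if self.effect_type == "r" and not -1.0 < self.estimate < 1.0:
            raise EffectDomainError(
                f"study {self.study_id!r}: correlation must lie in (-1, 1), got {self.estimate}"
            )
        if self.effect_type == "or" and self.estimate <= 0:
            raise EffectDomainError(
                f"study {self.study_id!r}: odds ratio must be positive, got {self.estimate}"
            )
        if self.ci_lower is not None and self.ci_upper is not None:
            if not self.ci_lower < self.ci_upper:
                raise InvalidIntervalError(
                    f"study {self.study_id!r}: ci_lower {self.ci_lower} must be "
                    f"below ci_upper {self.ci_upper}"
                )
            if self.effect_type == "or" and self.ci_lower <= 0:
                raise EffectDomainError(
                    f"study {self.study_id!r}: odds-ratio CI limits must be positive"
                )

    @property
    def has_ci(self) -> bool:
        return self.ci_lower is not None and self.ci_upper is not None

    @property
    def informative(self) -> bool:
        """Whether the record carries enough information to be weighted."""
        return (self.variance is not None and self.variance > 0) or self.has_ci


@dataclass
class StudyTable:
    """Ordered collection of study records, grouped by meta-analysis label."""

    records: list[EffectEstimate] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EffectEstimate]:
        return iter(self.records)

    def meta_ids(self) -> list[str]:
        """Meta-analysis labels in order of first appearance."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.meta_id, None)
        return list(seen)

    def groups(self) -> dict[str, list[EffectEstimate]]:
        out: dict[str, list[EffectEstimate]] = {}
        for rec in self.records:
            out.setdefault(rec.meta_id, []).append(rec)
        return out

    def subset(self, meta_id: str) -> "StudyTable":
        recs = [r for r in self.records if r.meta_id == meta_id]
        if not recs:
            raise KeyError(f"no records with meta_id {meta_id!r}")
        return StudyTable(recs)

    def relabel(self, meta_id: str) -> "StudyTable":
        """A copy of the table with every record assigned to one group."""
        return StudyTable([replace(r, meta_id=meta_id) for r in self.records])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "study_id": [r.study_id for r in self.records],
                "meta_id": [r.meta_id for r in self.records],
                "effect_type": [r.effect_type for r in self.records],
                "estimate": [r.estimate for r in self.records],
                "ci_lower": [r.ci_lower for r in self.records],
                "ci_upper": [r.ci_upper for r in self.records],
                "variance": [r.variance for r in self.records],
                "ci_level": [r.ci_level for r in self.records],
            }
        )

    @classmethod
    def from_records(cls, records: Iterable[EffectEstimate]) -> "StudyTable":
        return cls(list(records))


@dataclass
class MetaSummary:
    """The published summary of one meta-analysis.

    ``tau2`` is the between-study variance used inside the meta-analysis
    (0 under a fixed-effects model); ``variance`` is the sampling variance
    of the pooled estimate, i.e. one over the sum of the study weights.
    """

    meta_id: str
    effect_type: str
    estimate: float
    variance: float | None = None
    tau2: float = 0.0
    n_studies: int = 1
    model: str = "fixed"
    ci_lower: float | None = None
    ci_upper: float | None = None
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        _check_effect_type(self.effect_type)
        if self.model not in ("fixed", "random"):
            raise ValueError(f"model must be 'fixed' or 'random', got {self.model!r}")
        if self.tau2 < 0:
            raise ValueError(f"tau2 must be nonnegative, got {self.tau2}")
        if self.n_studies < 1:
            raise ValueError(f"n_studies must be positive, got {self.n_studies}")
        if self.variance is not None and self.variance <= 0:
            raise ValueError(
                f"meta {self.meta_id!r}: summary variance must be positive, got {self.variance}"
            )
        if self.effect_type == "r" and not -1.0 < self.estimate < 1.0:
            raise EffectDomainError(
                f"meta {self.meta_id!r}: pooled correlation must lie in (-1, 1)"
            )
        if self.effect_type == "or":
            if self.estimate <= 0:
                raise EffectDomainError(
                    f"meta {self.meta_id!r}: odds ratio must be positive"
                )
            if self.ci_lower is not None and self.ci_lower <= 0:
                raise EffectDomainError(
                    f"meta {self.meta_id!r}: odds-ratio CI limits must be positive"
                )
        if (
            self.ci_lower is not None
            and self.ci_upper is not None
            and not self.ci_lower < self.ci_upper
        ):
            raise InvalidIntervalError(
                f"meta {self.meta_id!r}: ci_lower must be below ci_upper"
            )

    @property
    def has_ci(self) -> bool:
        return self.ci_lower is not None and self.ci_upper is not None


@dataclass
class SynthesisResult:
    """A combined estimate across meta-analyses.

    ``weights`` records, per input meta-analysis, its effective weight on
    the synthesis scale, so that without overlap correction
    ``variance == 1 / sum(weights)``; with correction
    ``variance == inflation_factor / sum(weights)`` and the uncorrected
    value is kept in ``naive_variance``.
    """

    estimate: float
    variance: float
    ci_lower: float
    ci_upper: float
    scale: str
    weights: list[tuple[str, float]] = field(default_factory=list)
    inflation_factor: float = 1.0
    naive_variance: float | None = None

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError(f"variance must be positive, got {self.variance}")
        if self.inflation_factor < 1.0:
            raise ValueError(
                f"inflation factor must be >= 1, got {self.inflation_factor}"
            )

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)

    # Odds-ratio reporting: a log-scale synthesis is conventionally
    # published back on the OR scale.
    @property
    def or_estimate(self) -> float:
        if self.scale != "log_or":
            raise ValueError("or_estimate is defined only for log_or-scale results")
        return math.exp(self.estimate)

    @property
    def or_ci(self) -> tuple[float, float]:
        if self.scale != "log_or":
            raise ValueError("or_ci is defined only for log_or-scale results")
        return math.exp(self.ci_lower), math.exp(self.ci_upper)


@dataclass
class OverlapSpec:
    """Primary studies shared by all of J synthesized meta-analyses.

    Exactly one of ``overlap_weights`` (the fixed-effects weights of the p
    studies common to every meta-analysis, from which the inflation factor
    is computed exactly) or ``inflation_factor`` (an explicit value supplied
    by the investigator when per-study weights cannot be retrieved) must be
    given.  ``nonoverlap_weight_sum`` is the summed weight of all remaining,
    non-shared studies across the J meta-analyses.
    """

    n_meta: int
    overlap_weights: Sequence[float] | None = None
    nonoverlap_weight_sum: float = 0.0
    inflation_factor: float | None = None

    def __post_init__(self) -> None:
        if self.n_meta < 1:
            raise ValueError(f"n_meta must be a positive integer, got {self.n_meta}")
        if self.nonoverlap_weight_sum < 0:
            raise ValueError("nonoverlap_weight_sum must be nonnegative")
        explicit = self.inflation_factor is not None
        weighted = self.overlap_weights is not None
        if explicit == weighted:
            raise ValueError(
                "provide exactly one of overlap_weights or an explicit inflation_factor"
            )
        if explicit and self.inflation_factor < 1.0:
            raise ValueError(
                f"explicit inflation factor must be >= 1, got {self.inflation_factor}"
            )
        if weighted and any(w <= 0 for w in self.overlap_weights):
            raise ValueError("overlap_weights must all be positive")

    @property
    def p(self) -> int:
        """Number of studies shared by all meta-analyses."""
        return 0 if self.overlap_weights is None else len(self.overlap_weights)

    def compute_inflation_factor(self) -> float:
        """Variance inflation factor for the naive combined variance.

        With J meta-analyses sharing p studies of total weight S_p and
        non-shared weight S_rest, IF = (J^2 S_p + S_rest) / (J S_p + S_rest).
        IF = 1 when nothing overlaps (p = 0) or there is a single
        meta-analysis; with complete overlap of identical meta-analyses it
        equals J.
        """
        if self.inflation_factor is not None:
            return float(self.inflation_factor)
        s_p = float(sum(self.overlap_weights))
        s_rest = float(self.nonoverlap_weight_sum)
        if self.p == 0 or self.n_meta == 1:
            return 1.0
        j = self.n_meta
        denom = j * s_p + s_rest
        if denom <= 0:
            raise ValueError("overlap specification has zero total weight")
        return (j * j * s_p + s_rest) / denom
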