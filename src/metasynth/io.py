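"""CSV/JSON readers and writers for study tables, summaries and results.

Study CSV schema (header required, extra columns ignored)::

    study_id,meta_id,effect_type,estimate,ci_lower,ci_upper,variance,ci_level

Summary CSV schema::

    meta_id,effect_type,estimate,ci_lower,ci_upper,variance,n_studies

Numbers are parsed with a dot decimal separator regardless of locale
(pandas' default).  Rows lacking both a variance and a confidence interval
carry no weight information; they are logged and dropped, not errored.
When both are present the explicit variance wins, and a disagreement of
more than 10% with the CI-derived value triggers a warning.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import conversions
from .types import EffectEstimate, MetaSummary, StudyTable, SynthesisResult

__all__ = [
    "read_study_table",
    "read_summaries",
    "write_summary",
    "write_result",
    "read_result",
]

logger = logging.getLogger(__name__)

_STUDY_COLUMNS = ("study_id", "meta_id", "effect_type", "estimate")
_SUMMARY_COLUMNS = ("meta_id", "effect_type", "estimate")


def _opt_float(row, key) -> float | None:
    if key not in row or pd.isna(row[key]):
        return None
    return float(row[key])


def _check_variance_ci_agreement(rec: EffectEstimate, line: int, path) -> None:
    if rec.variance is None or not rec.has_ci:
        return
    lo, up = rec.ci_lower, rec.ci_upper
    if rec.effect_type == "or":
        lo, up = math.log(lo), math.log(up)
    implied = conversions.variance_from_ci(lo, up, conversions.z_multiplier(rec.ci_level))
    if implied > 0 and abs(rec.variance - implied) / implied > 0.10:
        logger.warning(
            "%s line %d: reported variance %g differs from the CI-implied "
            "value %g by more than 10%%; using the reported variance",
            path,
            line,
            rec.variance,
            implied,
        )


def read_study_table(path: str | Path) -> StudyTable:
    """Read and validate a study-level CSV into a :class:`StudyTable`."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            rec = EffectEstimate(
                study_id=str(row["study_id"]),
                meta_id=str(row["meta_id"]),
                effect_type=str(row["effect_type"]).strip(),
                estimate=float(row["estimate"]),
                variance=_opt_float(row, "variance"),
                ci_lower=_opt_float(row, "ci_lower"),
                ci_upper=_opt_float(row, "ci_upper"),
                ci_level=_opt_float(row, "ci_level") or 0.95,
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {line}: {exc}") from exc
        if not rec.informative:
            logger.warning(
                "%s line %d: study %r has neither variance nor CI; dropped",
                path,
                line,
                rec.study_id,
            )
            continue
        _check_variance_ci_agreement(rec, line, path)
        records.append(rec)
    return StudyTable(records)


def read_summaries(path: str | Path) -> list[MetaSummary]:
    """Read a summary-level CSV into a list of :class:`MetaSummary`."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    out = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            summ = MetaSummary(
                meta_id=str(row["meta_id"]),
                effect_type=str(row["effect_type"]).strip(),
                estimate=float(row["estimate"]),
                variance=_opt_float(row, "variance"),
                tau2=_opt_float(row, "tau2") or 0.0,
                n_studies=int(row["n_studies"]) if "n_studies" in row and not pd.isna(row["n_studies"]) else 1,
                model=str(row["model"]) if "model" in row and not pd.isna(row["model"]) else "fixed",
                ci_lower=_opt_float(row, "ci_lower"),
                ci_upper=_opt_float(row, "ci_upper"),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {line}: {exc}") from exc
        if summ.variance is None and not summ.has_ci:
            logger.warning(
                "%s line %d: meta-analysis %r has neither variance nor CI; dropped",
                path,
                line,
                summ.meta_id,
            )
            continue
        out.append(summ)
    return out


def write_summary(summary: MetaSummary, path: str | Path, format: str = "csv") -> None:
    """Write one meta-analysis summary as a single-row CSV or a JSON object."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(asdict(summary), indent=2) + "\n")
    elif format == "csv":
        pd.DataFrame([asdict(summary)]).to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"format must be 'json' or 'csv', got {format!r}")


def _result_payload(result: SynthesisResult) -> dict:
    payload = {
        "estimate": result.estimate,
        "variance": result.variance,
        "ci_lower": result.ci_lower,
        "ci_upper": result.ci_upper,
        "scale": result.scale,
        "weights": {mid: w for mid, w in result.weights},
        "inflation_factor": result.inflation_factor,
        "naive_variance": result.naive_variance,
    }
    if result.scale == "log_or":
        lo, hi = result.or_ci
        payload["or_estimate"] = result.or_estimate
        payload["or_ci_lower"] = lo
        payload["or_ci_upper"] = hi
    return payload


def write_result(result: SynthesisResult, path: str | Path, format: str = "json") -> None:
    """Write a synthesis result as JSON (full fidelity) or a one-row CSV."""
    path = Path(path)
    payload = _result_payload(result)
    if format == "json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "csv":
        flat = dict(payload)
        flat["weights"] = ";".join(f"{m}={w:.17g}" for m, w in result.weights)
        pd.DataFrame([flat]).to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"format must be 'json' or 'csv', got {format!r}")


def read_result(path: str | Path) -> SynthesisResult:
    """Read a JSON synthesis result back into a :class:`SynthesisResult`."""
    payload = json.loads(Path(path).read_text())
    return SynthesisResult(
        estimate=payload["estimate"],
        variance=payload["variance"],
        ci_lower=payload["ci_lower"],
        ci_upper=payload["ci_upper"],
        scale=payload["scale"],
        weights=[(m, w) for m, w in payload["weights"].items()],
        inflation_factor=payload.get("inflation_factor", 1.0),
        naive_variance=payload.get("naive_variance"),
    )
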