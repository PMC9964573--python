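"""Residual analysis and Bland-Altman agreement for V̇O2 predictions.

Residuals are defined as predicted − measured, so a negative bias means
the model underpredicts.  The 95% limits of agreement follow the
two-standard-deviations convention (bias ± 2·SD of the residuals, sample
SD with n − 1); the report also carries the RMSE of the residuals.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import ValidationError

__all__ = ["AgreementReport", "EvaluationReport", "bland_altman", "report", "write_report"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class AgreementReport:
    """Bias, residual SD, 95% limits of agreement and RMSE (mL/min/kg)."""

    n: int
    bias: float
    residual_sd: float
    loa95: float
    rmse: float


def bland_altman(measured: Sequence[float], predicted: Sequence[float]) -> AgreementReport:
    """Agreement statistics between measured and predicted values.

    bias = mean(predicted − measured); residual SD uses the n−1
    denominator; loa95 = 2 × SD; rmse = sqrt(mean residual²).
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.ndim != 1:
        raise ValidationError("measured and predicted must be 1-d and equally long")
    if m.size < 2:
        raise ValidationError("agreement statistics need at least 2 pairs")
    resid = p - m
    sd = float(np.std(resid, ddof=1))
    return AgreementReport(
        n=int(m.size),
        bias=float(resid.mean()),
        residual_sd=sd,
        loa95=2.0 * sd,
        rmse=float(np.sqrt(np.mean(resid**2))),
    )


@dataclass
class EvaluationReport:
    """Pooled and per-subject agreement plus raw scatter/residual data."""

    pooled: AgreementReport
    per_subject: dict[int, AgreementReport]
    scatter: pd.DataFrame  # columns: subject_id, mean, difference
    residuals: pd.DataFrame  # columns: subject_id, time_s (optional), residual


def report(
    measured: Sequence[float],
    predicted: Sequence[float],
    subject_ids: Sequence[int] | None = None,
    times: Sequence[float] | None = None,
) -> EvaluationReport:
    """Pooled + per-subject Bland-Altman and plot-ready scatter data.

    Scatter rows are (pairwise mean, difference) per prediction, the
    quantities plotted on a Bland-Altman diagram; residuals are returned as
    a time series when ``times`` is given.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    sid = (
        np.zeros(m.size, dtype=int)
        if subject_ids is None
        else np.asarray(subject_ids, dtype=int)
    )
    if sid.shape != m.shape:
        raise ValidationError("subject_ids must match the number of pairs")
    pooled = bland_altman(m, p)
    per_subject = {
        int(s): bland_altman(m[sid == s], p[sid == s]) for s in np.unique(sid)
    }
    scatter = pd.DataFrame(
        {"subject_id": sid, "mean": (m + p) / 2.0, "difference": p - m}
    )
    residuals = pd.DataFrame({"subject_id": sid, "residual": p - m})
    if times is not None:
        residuals.insert(1, "time_s", np.asarray(times, dtype=float))
    return EvaluationReport(
        pooled=pooled, per_subject=per_subject, scatter=scatter, residuals=residuals
    )


def write_report(rep: EvaluationReport, out_dir: str | Path) -> dict[str, Path]:
    """Machine-readable JSON + CSV outputs (statistics and plot data)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "pooled": dataclasses.asdict(rep.pooled),
        "per_subject": {
            str(k): dataclasses.asdict(v) for k, v in rep.per_subject.items()
        },
    }
    files = {}
    p = out / "agreement.json"
    p.write_text(json.dumps(payload, indent=2))
    files["agreement.json"] = p
    for name, frame in (("bland_altman_scatter.csv", rep.scatter),
                        ("residuals.csv", rep.residuals)):
        fp = out / name
        frame.to_csv(fp, index=False, float_format="%.6f")
        files[name] = fp
    return files
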