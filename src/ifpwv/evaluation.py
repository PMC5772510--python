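"""Agreement statistics, cohort filters, and error propagation.

Predicted PWV is compared with the sequentially measured value through
Bland-Altman style agreement: bias (mean difference), SD of the
differences, 95% limits of agreement (bias +/- 1.96 SD), RMSE, and the
Pearson correlation.  Device-validation style reporting additionally
filters the cohort per the Artery Society guideline (BMI <= 30, PWV <
15 m/s) and breaks agreement down by measured-PWV tertile.

Because the sequential measurement is itself an imperfect surrogate of
the simultaneous reference method, the predicted-vs-reference error is
obtained by propagating two independent error components in quadrature:

    std(pred - ref)  = sqrt( std(pred - meas)^2 + std(ref - meas)^2 )
    E(pred - ref)    = E(pred - meas) - E(ref - meas)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AgreementStats",
    "ErrorPropagation",
    "agreement",
    "propagate_error",
    "artery_society_filter",
    "tertile_report",
]

#: normal 95% two-sided multiplier for the limits of agreement
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman agreement between predicted and measured PWV (m/s)."""

    n: int
    bias: float
    sd: float
    loa_half_width: float
    rmse: float
    pearson_r: float
    r_defined: bool = True
    computable: bool = True

    @property
    def loa(self) -> tuple[float, float]:
        return (self.bias - self.loa_half_width, self.bias + self.loa_half_width)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "bias": self.bias,
            "sd": self.sd,
            "loa_half_width": self.loa_half_width,
            "rmse": self.rmse,
            "pearson_r": self.pearson_r if self.r_defined else None,
            "computable": self.computable,
        }


_NOT_COMPUTABLE = AgreementStats(
    n=0, bias=math.nan, sd=math.nan, loa_half_width=math.nan,
    rmse=math.nan, pearson_r=math.nan, r_defined=False, computable=False,
)


@dataclass(frozen=True)
class ErrorPropagation:
    """Predicted-vs-reference error from two independent components (m/s)."""

    std_pm: float
    std_rm: float
    bias_pm: float
    bias_rm: float
    std_pr: float
    bias_pr: float


def agreement(pred: np.ndarray, meas: np.ndarray) -> AgreementStats:
    """Agreement statistics for paired predictions and measurements.

    ``sd`` uses the n-1 denominator; the Pearson correlation is flagged
    undefined (``r_defined=False``) when either input is constant.
    """
    p = np.asarray(pred, dtype=float)
    m = np.asarray(meas, dtype=float)
    if p.shape != m.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {m.shape}")
    if p.ndim != 1 or len(p) < 3:
        raise ValueError("need 1-d inputs of length >= 3")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(m))):
        raise ValueError("non-finite values in inputs")
    d = p - m
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    rmse = float(np.sqrt(np.mean(d**2)))
    r_defined = p.std() > 0 and m.std() > 0
    r = float(np.corrcoef(p, m)[0, 1]) if r_defined else math.nan
    return AgreementStats(
        n=len(d),
        bias=bias,
        sd=sd,
        loa_half_width=LOA_MULTIPLIER * sd,
        rmse=rmse,
        pearson_r=r,
        r_defined=bool(r_defined),
    )


def propagate_error(
    std_pm: float, std_rm: float, bias_pm: float = 0.0, bias_rm: float = 0.0
) -> ErrorPropagation:
    """Closed-form propagation of independent error components.

    Parameters use the p=predicted, m=sequential-measured, r=reference
    naming: ``std_pm = std(pred - meas)``, ``std_rm = std(ref - meas)``,
    ``bias_pm = E(pred - meas)``, ``bias_rm = E(ref - meas)``.
    """
    if std_pm < 0 or std_rm < 0:
        raise ValueError("standard deviations must be non-negative")
    return ErrorPropagation(
        std_pm=std_pm,
        std_rm=std_rm,
        bias_pm=bias_pm,
        bias_rm=bias_rm,
        std_pr=math.hypot(std_pm, std_rm),
        bias_pr=bias_pm - bias_rm,
    )


def artery_society_filter(
    records: pd.DataFrame,
    bmi_col: str = "BMI",
    pwv_col: str = "PWV_measured",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Device-validation cohort filter: keep BMI <= 30 and PWV < 15 m/s.

    High-BMI subjects are excluded because the body-surface path-length
    measurement is unreliable; extreme PWV because measurement error
    grows there.  Records with missing BMI are excluded with reason
    ``"missing"``.  Returns the kept rows and removal counts by reason.
    The filter is idempotent.
    """
    counts = {"bmi": 0, "pwv": 0, "missing": 0}
    if len(records) == 0:
        return records, counts
    for col in (bmi_col, pwv_col):
        if col not in records.columns:
            raise ValueError(f"records lack a {col!r} column")
    bmi = records[bmi_col].to_numpy(dtype=float)
    pwv = records[pwv_col].to_numpy(dtype=float)
    missing = ~np.isfinite(bmi)
    high_bmi = ~missing & (bmi > 30.0)
    high_pwv = ~missing & ~high_bmi & (pwv >= 15.0)
    keep = ~(missing | high_bmi | (pwv >= 15.0))
    counts["missing"] = int(missing.sum())
    counts["bmi"] = int(high_bmi.sum())
    counts["pwv"] = int(high_pwv.sum())
    return records.loc[keep], counts


def tertile_report(
    pred: np.ndarray,
    meas: np.ndarray,
    cutpoints: tuple[float, float] = (6.5, 7.9),
) -> dict[str, AgreementStats]:
    """Agreement broken down by measured-PWV group.

    Groups follow the convention low = PWV <= c1, mid = (c1, c2),
    high = PWV >= c2 with default cutpoints (6.5, 7.9) m/s.  A group
    with fewer than 3 pairs is flagged not computable.
    """
    c1, c2 = cutpoints
    if not c1 < c2:
        raise ValueError("cutpoints must be ascending")
    p = np.asarray(pred, dtype=float)
    m = np.asarray(meas, dtype=float)
    if p.shape != m.shape:
        raise ValueError("length mismatch")
    masks = {
        "low": m <= c1,
        "mid": (m > c1) & (m < c2),
        "high": m >= c2,
    }
    out: dict[str, AgreementStats] = {}
    for name, mask in masks.items():
        out[name] = agreement(p[mask], m[mask]) if mask.sum() >= 3 else _NOT_COMPUTABLE
    return out
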