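"""Feature engineering and best-subset selection for the PWV model.

From each fitted cycle the full candidate set ``V0`` combines

* the raw intrinsic frequencies ``omega1``, ``omega2`` (rad/s),
* their period-normalized variants: ``omega_bar1 = w1*T0``,
  ``omega_bar2 = w2*(T-T0)``, ``omega1c = w1*sqrt(T0)``,
  ``omega2c = w2*T^2``, ``omega1n = w1*T``, ``omega2n = w2*T``,
* timing terms ``T``, ``1/T0`` (inverse systole), ``1/(T-T0)``
  (inverse diastole),
* shape factors: notch height fraction ``rho``, mean-level fraction
  ``Cr``, systolic/diastolic envelope energy ratio ``Er``, and the mean
  carotid shape factor ``MCSF = (mean - min)/(max - min)``,
* clinical covariates: AIx, SSN, RWAT, Age, Ps, Pd.

The production model uses the 12-feature subset ``V`` (``V_NAMES``),
found by best-subset multilinear regression; :func:`best_subset_select`
reproduces that machinery (exhaustive search scored by an extended BIC
up to 15 candidates, branch-and-bound above).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intrinsic_frequency import IFResult
from .preprocess import CardiacCycle

__all__ = [
    "ClinicalRecord",
    "V0_NAMES",
    "V_NAMES",
    "derive_frequency_features",
    "derive_shape_features",
    "assemble_v0",
    "best_subset_select",
]

logger = logging.getLogger(__name__)

#: the full candidate feature set, in canonical column order
V0_NAMES: tuple[str, ...] = (
    "omega1", "omega2", "omega_bar1", "omega_bar2",
    "omega1c", "omega2c", "omega1n", "omega2n",
    "rho", "Er", "Cr", "T", "inv_diastole", "inv_systole",
    "MCSF", "AIx", "SSN", "RWAT", "Age", "Ps", "Pd",
)

#: the selected production subset V, in canonical column order
V_NAMES: tuple[str, ...] = (
    "omega_bar2", "omega1c", "omega1n", "rho", "Er", "MCSF",
    "AIx", "SSN", "RWAT", "Age", "Ps", "Pd",
)


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-subject clinical covariates.

    ``MCSF`` may be supplied externally (it is also computable from the
    waveform; an external value takes precedence).  ``PWV_measured`` is
    the sequential-method carotid-femoral PWV when available.
    """

    Age: float
    Ps: float
    Pd: float
    SSN: float
    AIx: float | None = None
    RWAT: float | None = None
    MCSF: float | None = None
    BMI: float | None = None
    PWV_measured: float | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not self.Age > 0:
            raise ValueError(f"Age must be positive, got {self.Age}")
        if not self.Ps > self.Pd > 0:
            raise ValueError(
                f"need systolic > diastolic > 0, got Ps={self.Ps}, Pd={self.Pd}"
            )
        if not self.SSN > 0:
            raise ValueError(f"SSN length must be positive, got {self.SSN}")


def derive_frequency_features(ifres: IFResult) -> dict[str, float]:
    """Frequency and timing features from one fitted cycle."""
    T0, T = ifres.T0, ifres.T
    if T0 <= 0.0 or T0 >= T:
        raise ValueError(f"need 0 < T0 < T for timing features, got T0={T0}, T={T}")
    w1, w2 = ifres.omega1, ifres.omega2
    return {
        "omega1": w1,
        "omega2": w2,
        "omega_bar1": w1 * T0,
        "omega_bar2": w2 * (T - T0),
        "omega1c": w1 * math.sqrt(T0),
        "omega2c": w2 * T**2,
        "omega1n": w1 * T,
        "omega2n": w2 * T,
        "T": T,
        "inv_systole": 1.0 / T0,
        "inv_diastole": 1.0 / (T - T0),
    }


def derive_shape_features(cycle: CardiacCycle, ifres: IFResult) -> dict[str, float]:
    """Shape factors of one cycle: rho, Cr, Er, MCSF.

    All four are invariant under affine rescaling of the waveform
    (``rho``/``Cr``/``MCSF`` are range fractions; ``Er`` is an envelope
    amplitude ratio whose numerator and denominator scale jointly).
    """
    s = np.asarray(cycle.samples, dtype=float)
    s_min, s_max = float(s.min()), float(s.max())
    if s_max <= s_min:
        raise ValueError("flat cycle: shape factors undefined")
    amp2 = math.hypot(ifres.a2, ifres.b2)
    if amp2 == 0.0:
        raise ValueError("diastolic envelope is zero: Er undefined")
    rng = s_max - s_min
    i_notch = min(int(round(ifres.T0 * cycle.fs)), len(s) - 1)
    rho = (float(s[i_notch]) - s_min) / rng
    cr = (ifres.p_bar - s_min) / rng
    mcsf = (float(s.mean()) - s_min) / rng
    return {
        "rho": float(np.clip(rho, 0.0, 1.0)),
        "Cr": float(np.clip(cr, 0.0, 1.0)),
        "Er": math.hypot(ifres.a1, ifres.b1) / amp2,
        "MCSF": mcsf,
    }


def assemble_v0(
    items: Iterable[tuple[Mapping[str, float], Mapping[str, float], ClinicalRecord]],
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Join per-subject frequency features, shape features, and covariates.

    Parameters
    ----------
    items
        One ``(frequency_features, shape_features, clinical)`` triple per
        subject.

    Returns
    -------
    (table, exclusions)
        ``table`` has one complete row per retained subject with the 21
        ``V0_NAMES`` columns (plus ``subject_id`` and, when available,
        ``BMI`` and ``PWV_measured``).  Subjects missing any component
        are excluded complete-case style and listed in ``exclusions`` as
        ``(subject_id, reason)``.  An externally supplied MCSF overrides
        the waveform-computed value (logged).
    """
    rows: list[dict] = []
    exclusions: list[tuple[str, str]] = []
    for i, (freq, shape, clin) in enumerate(items):
        sid = clin.subject_id or f"row{i}"
        row: dict[str, float] = {}
        row.update(freq)
        row.update(shape)
        if clin.MCSF is not None:
            if "MCSF" in row:
                logger.info(
                    "subject %s: externally supplied MCSF %.4f overrides "
                    "computed %.4f", sid, clin.MCSF, row["MCSF"],
                )
            row["MCSF"] = clin.MCSF
        for name in ("AIx", "SSN", "RWAT", "Age", "Ps", "Pd"):
            row[name] = getattr(clin, name)
        missing = [
            n for n in V0_NAMES
            if row.get(n) is None or not np.isfinite(row.get(n, np.nan))
        ]
        if missing:
            exclusions.append((sid, f"missing {', '.join(missing)}"))
            continue
        out = {"subject_id": sid}
        out.update({n: float(row[n]) for n in V0_NAMES})
        if clin.BMI is not None:
            out["BMI"] = clin.BMI
        if clin.PWV_measured is not None:
            out["PWV_measured"] = clin.PWV_measured
        rows.append(out)
    cols = ["subject_id", *V0_NAMES]
    table = pd.DataFrame(rows)
    if len(table):
        extras = [c for c in ("BMI", "PWV_measured") if c in table.columns]
        table = table[cols + extras]
    else:
        table = pd.DataFrame(columns=cols)
    return table, exclusions


def _rss(Xc: np.ndarray, yc: np.ndarray, subset: tuple[int, ...]) -> float:
    """Residual sum of squares of OLS on centered data for one subset."""
    Xs = Xc[:, subset]
    beta, _, _, _ = np.linalg.lstsq(Xs, yc, rcond=None)
    r = yc - Xs @ beta
    return float(r @ r)


def _ic_score(
    rss: float, n: int, p: int, k: int, gamma: float, scale: float
) -> float:
    """(Extended) BIC of an OLS subset: gamma=0 is plain BIC.

    The extended term ``2*gamma*log C(p, k)`` (Chen & Chen 2008)
    penalizes the size of the search space and controls the
    spurious-inclusion rate of exhaustive subset search; gamma=1 gives
    the strongest standard control and is the default for
    exact-support selection.

    ``rss`` is floored at a small fraction of the response's total sum
    of squares ``scale``: below that level a fit is numerically exact,
    and comparing raw log-RSS values of machine-epsilon residuals would
    let floating-point noise, not the penalty, pick the subset.
    """
    rss = max(rss, 1e-12 * scale, 1e-300)
    score = n * math.log(rss / n) + (k + 2) * math.log(n)
    if gamma:
        score += 2.0 * gamma * math.log(math.comb(p, k))
    return score


def _best_rss_of_size(
    Xc: np.ndarray, yc: np.ndarray, k: int
) -> tuple[float, tuple[int, ...]]:
    """Minimum-RSS subset of size ``k`` by branch-and-bound.

    Uses RSS monotonicity (adding a variable never increases RSS): a
    node's lower bound is the RSS of the subset plus *all* remaining
    candidates; nodes that cannot beat the incumbent are pruned.
    """
    p = Xc.shape[1]
    best = (math.inf, tuple(range(k)))

    def recurse(chosen: tuple[int, ...], start: int) -> None:
        nonlocal best
        if len(chosen) == k:
            rss = _rss(Xc, yc, chosen)
            if rss < best[0]:
                best = (rss, chosen)
            return
        remaining = p - start
        if len(chosen) + remaining < k:
            return
        bound = _rss(Xc, yc, chosen + tuple(range(start, p)))
        if bound >= best[0]:
            return
        for j in range(start, p):
            recurse(chosen + (j,), j + 1)

    recurse((), 0)
    return best


def best_subset_select(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float] | np.ndarray,
    criterion: str = "ebic",
    max_exhaustive: int = 15,
) -> list[str]:
    """Best-subset multilinear regression, scored by an information criterion.

    ``criterion`` is ``"ebic"`` (extended BIC, gamma=1; default — plain
    BIC's spurious-inclusion rate over an exhaustive search is too high
    for reliable exact-support recovery) or ``"bic"``.

    All non-empty subsets are searched exhaustively when the number of
    candidates is at most ``max_exhaustive``; above that, a
    branch-and-bound pass finds the minimum-RSS subset of each size and
    the criterion arbitrates across sizes (exact, since the criterion
    depends on a subset only through its size and RSS).  Subsets are
    enumerated smallest-size first and in lexicographic index order with
    strict improvement, so among collinear duplicates the lowest-index
    member wins.

    Returns the selected feature names in column order.
    """
    if criterion not in ("bic", "ebic"):
        raise ValueError(f"unsupported criterion {criterion!r}")
    gamma = 1.0 if criterion == "ebic" else 0.0
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X_arr = X.to_numpy(dtype=float)
    else:
        X_arr = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(X_arr.shape[1])]
    y_arr = np.asarray(y, dtype=float)
    n, p = X_arr.shape
    if n <= p:
        raise ValueError(f"need more rows than candidates, got n={n}, p={p}")
    if not (np.all(np.isfinite(X_arr)) and np.all(np.isfinite(y_arr))):
        raise ValueError("non-finite values in design or response")
    # center to absorb the intercept
    Xc = X_arr - X_arr.mean(axis=0)
    yc = y_arr - y_arr.mean()
    yty = float(yc @ yc)

    best_score = math.inf
    best_subset: tuple[int, ...] = ()
    if p <= max_exhaustive:
        for k in range(1, p + 1):
            for subset in itertools.combinations(range(p), k):
                score = _ic_score(_rss(Xc, yc, subset), n, p, k, gamma, yty)
                if score < best_score:
                    best_score, best_subset = score, subset
    else:
        for k in range(1, p + 1):
            rss, subset = _best_rss_of_size(Xc, yc, k)
            score = _ic_score(rss, n, p, k, gamma, yty)
            if score < best_score:
                best_score, best_subset = score, subset
    return [names[j] for j in best_subset]
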