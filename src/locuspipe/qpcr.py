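"""qPCR measurement engine.

Standard-curve absolute quantification, comparative-Ct (2^-ddCt) relative
expression, mean-centred dCt, Spearman rank correlation and copy-number
genotyping.  All downstream pipeline stages (locus read-through, 3C,
enrichment) quantify through the functions here.

Conventions
-----------
* Ct is linear in log10(template quantity): ct = intercept + slope * log10(q),
  with slope < 0.  A perfectly doubling reaction has slope -1/log10(2)
  (about -3.3219 cycles per decade).
* Amplification efficiency E is a fraction: the per-cycle amplification
  factor is 1 + E, so E = 10**(-1/slope) - 1 and E = 1 means perfect doubling.
* Missing Ct values (undetermined / censored wells) are carried as NaN and
  propagate with a machine-readable reason rather than being silently dropped.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "RelativeExpression",
    "SpearmanResult",
    "fit_standard_curve",
    "invert_quantity",
    "aggregate_replicates",
    "ddct_fold_change",
    "center_delta_ct",
    "spearman",
    "copy_number_ratio",
    "combine_control_folds",
    "efficiency_from_slope",
]

#: reason codes attached to propagated missing values
REASON_CENSORED = "censored"
REASON_MISSING_INPUT = "missing_input"
REASON_ZERO_DENOMINATOR = "zero_denominator"


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency E (fraction) from a standard-curve slope.

    E = 10**(-1/slope) - 1; slope must be negative.
    """
    if slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


@dataclass(frozen=True)
class StandardCurve:
    """Fitted Ct-vs-log10(quantity) calibration line.

    Attributes
    ----------
    slope : cycles per log10(pg), negative.
    intercept : Ct at 1 pg.
    efficiency : fractional amplification efficiency, 10**(-1/slope) - 1.
    r2 : coefficient of determination of the fit.
    """

    slope: float
    intercept: float
    efficiency: float
    r2: float

    def predict_ct(self, quantity_pg: float) -> float:
        """Forward prediction: Ct expected for a template quantity in pg."""
        if quantity_pg <= 0:
            raise ValueError("quantity must be positive")
        return self.intercept + self.slope * math.log10(quantity_pg)

    def invert(self, ct: float) -> float:
        """Quantity in pg for an observed Ct (NaN propagates as NaN)."""
        if ct is None or (isinstance(ct, float) and math.isnan(ct)):
            return float("nan")
        return 10.0 ** ((ct - self.intercept) / self.slope)


@dataclass(frozen=True)
class RelativeExpression:
    """2^-ddCt fold change for one sample; NaN fold carries a reason code."""

    sample: str
    fold_change: float
    log2_fold: float
    reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return math.isnan(self.fold_change)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    pvalue: float
    n: int
    reason: str | None = None


def fit_standard_curve(points: Iterable[tuple[float, float]]) -> StandardCurve:
    """Least-squares fit of Ct on log10(quantity_pg) over a dilution series.

    Parameters
    ----------
    points : iterable of (quantity_pg, ct) pairs; requires at least three
        distinct positive quantities.  Pairs with missing Ct are dropped.
    """
    pts = [(q, c) for q, c in points if not (c is None or math.isnan(c))]
    if any(q <= 0 for q, _ in pts):
        raise ValueError("dilution quantities must be positive")
    if len({q for q, _ in pts}) < 3:
        raise ValueError("standard curve needs >= 3 distinct quantities")
    logq = np.log10([q for q, _ in pts])
    ct = np.array([c for _, c in pts], dtype=float)
    res = stats.linregress(logq, ct)
    if res.slope >= 0:
        raise ValueError(
            f"standard curve has non-negative slope {res.slope:.3g}; "
            "Ct must decrease with template quantity"
        )
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=efficiency_from_slope(float(res.slope)),
        r2=float(res.rvalue) ** 2,
    )


def invert_quantity(ct: float, curve: StandardCurve) -> float:
    """Absolute quantity (pg) from a Ct via the calibration line.

    A missing / censored Ct yields NaN (flagged, not an error): undetermined
    wells stay undetermined.
    """
    return curve.invert(ct)


def aggregate_replicates(
    plate: pd.DataFrame,
    by: Sequence[str] = ("assay", "sample"),
) -> pd.DataFrame:
    """Collapse technical replicates: arithmetic mean of uncensored Ct wells.

    `plate` needs columns `by` + ['ct']; censored wells are NaN.  Groups with
    no uncensored well get ct NaN and n_wells 0.  Returns columns
    by + ['ct', 'ct_sd', 'n_wells'].
    """
    grouped = plate.groupby(list(by), sort=True)["ct"]
    out = grouped.agg(ct="mean", ct_sd="std", n_wells="count").reset_index()
    out["ct_sd"] = out["ct_sd"].fillna(0.0)
    return out


def ddct_fold_change(
    target_treated: float,
    ref_treated: float,
    target_control: float,
    ref_control: float,
    sample: str = "",
) -> RelativeExpression:
    """Comparative-Ct relative expression 2^-ddCt.

    ddCt = (target_treated - ref_treated) - (target_control - ref_control);
    fold = 2**-ddCt.  Any missing Ct propagates NaN with a reason code.
    """
    cts = (target_treated, ref_treated, target_control, ref_control)
    if any(c is None or math.isnan(c) for c in cts):
        return RelativeExpression(sample, float("nan"), float("nan"),
                                  reason=REASON_MISSING_INPUT)
    ddct = (target_treated - ref_treated) - (target_control - ref_control)
    fold = 2.0 ** (-ddct)
    return RelativeExpression(sample, fold, math.log2(fold))


def center_delta_ct(delta_cts: Sequence[float]) -> np.ndarray:
    """Mean-centre per-sample dCt values (so the output averages to zero)."""
    arr = np.asarray(delta_cts, dtype=float)
    if arr.size < 2:
        raise ValueError("centring needs at least two dCt values")
    return arr - arr.mean()


def _exact_spearman_pvalue(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for small n (enumerates all n! orders)."""
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]                          # (n!, n)
    zx = rx - rx.mean()
    zy = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((zx ** 2).sum() * (zy ** 2).sum(axis=1))
    rhos = (zy @ zx) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    Pairs with a missing member are dropped pairwise; at least three complete
    pairs are required.  p-value: exact permutation enumeration for n < 10,
    the usual t approximation for n >= 10.  Zero rank variance on either side
    gives an undefined (NaN) rho, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("spearman needs >= 3 complete pairs")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return SpearmanResult(float("nan"), float("nan"), n,
                              reason="zero_rank_variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n < 10:
        p = _exact_spearman_pvalue(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho, float(p), n)


def copy_number_ratio(
    ct_region: float,
    ct_reference: float,
    calibrator_delta_ct: float,
) -> float:
    """Relative DNA copy number by 2^-ddCt against a parental calibrator.

    ddCt = (ct_region - ct_reference) - calibrator dCt.  One extra cycle in
    the region assay relative to the calibrator halves the copy number
    (e.g. two of four alleles deleted -> 0.5).
    """
    if calibrator_delta_ct is None or math.isnan(calibrator_delta_ct):
        raise ValueError("calibrator dCt is required")
    for name, c in (("ct_region", ct_region), ("ct_reference", ct_reference)):
        if c is None or math.isnan(c):
            raise ValueError(f"{name} is missing")
    ddct = (ct_region - ct_reference) - calibrator_delta_ct
    return 2.0 ** (-ddct)


def combine_control_folds(folds: Sequence[float]) -> float:
    """Combine fold changes normalised to several loading controls.

    Geometric mean of the per-control-normalised folds (all must be > 0).
    """
    arr = np.asarray(folds, dtype=float)
    if arr.size == 0:
        raise ValueError("no folds to combine")
    if np.any(arr <= 0):
        raise ValueError("fold changes must be positive")
    return float(np.exp(np.mean(np.log(arr))))
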