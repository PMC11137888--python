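"""Standard-curve efficiency fitting and relative quantification.

A qPCR standard curve regresses Ct on log10 template concentration;
for a reaction that multiplies template by a factor E each cycle the
line has slope ``-1/log10(E)``, so the amplification factor is
recovered as ``E = 10**(-1/slope)`` and percent efficiency as
``(E - 1) * 100`` (100% = perfect doubling, slope -3.32193).

Target expression is reported with the ddCt scheme: per-sample relative
quantities for the target and for the chosen reference genes (their
per-sample geometric mean is the normalization factor NF), the ratio
target/NF, and fold changes relative to a calibrator sample set whose
aggregate fold is 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import CtMatrix
from .errors import (
    InputValidationError,
    InsufficientDataError,
    InvalidCurveError,
    ParameterError,
)
from .genorm import to_relative_quantities

__all__ = [
    "EfficiencyFit",
    "DdCtResult",
    "fit_standard_curve",
    "normalization_factor",
    "relative_expression",
]


@dataclass(frozen=True)
class EfficiencyFit:
    """OLS standard-curve fit: Ct = slope * log10(conc) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float    # (10**(-1/slope) - 1) * 100
    amplification_factor: float  # 10**(-1/slope)
    n_points: int


def fit_standard_curve(
    log10_concentrations: Sequence[float], ct_values: Sequence[float]
) -> EfficiencyFit:
    """Fit a dilution series and derive amplification efficiency.

    Requires >= 3 points and a negative slope (more template -> earlier
    crossing); a non-negative slope means the series is not a valid
    dilution curve.
    """
    x = np.asarray(log10_concentrations, dtype=float)
    y = np.asarray(ct_values, dtype=float)
    if x.shape != y.shape:
        raise InputValidationError("concentration and Ct arrays differ in length")
    if x.size < 3:
        raise InsufficientDataError(
            f"standard curve needs >= 3 dilution points, got {x.size}"
        )
    fit = sps.linregress(x, y)
    if fit.slope >= 0:
        raise InvalidCurveError(
            f"standard-curve slope must be negative, got {fit.slope:.4g}"
        )
    factor = 10.0 ** (-1.0 / fit.slope)
    return EfficiencyFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency_percent=(factor - 1.0) * 100.0,
        amplification_factor=factor,
        n_points=int(x.size),
    )


def normalization_factor(
    ct: CtMatrix,
    reference_genes: Sequence[str],
    efficiencies: float | Mapping[str, float] = 2.0,
) -> pd.Series:
    """Per-sample NF: geometric mean of the reference genes' quantities.

    With a single reference gene the NF is simply that gene's relative
    quantity row.
    """
    if not reference_genes:
        raise InputValidationError("need at least one reference gene")
    missing = [g for g in reference_genes if g not in ct.data.index]
    if missing:
        raise InputValidationError(f"reference gene(s) not in matrix: {missing}")
    sub = ct.subset_genes(list(reference_genes))
    q = to_relative_quantities(sub, efficiencies)
    nf = np.exp(np.log(q.values).mean(axis=0))
    return pd.Series(nf, index=q.data.columns, name="nf")


@dataclass(frozen=True)
class DdCtResult:
    """Per-sample normalized target expression and calibrated fold changes."""

    target_quantity: pd.Series
    nf: pd.Series
    ratio: pd.Series        # target_quantity / nf
    fold_change: pd.Series  # ratio / calibrator aggregate
    calibrator_samples: list[str]
    calibrator_aggregation: str  # "arithmetic" or "geometric"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target_q": self.target_quantity,
                "nf": self.nf,
                "ratio": self.ratio,
                "fold_change": self.fold_change,
            }
        )


def relative_expression(
    target_ct: pd.Series,
    nf: pd.Series,
    calibrator: Sequence[str],
    target_efficiency: float = 2.0,
    aggregation: str = "arithmetic",
) -> DdCtResult:
    """Fold change of a target gene versus a calibrator condition.

    ``target_ct`` is the target gene's Ct row over the same samples as
    ``nf``.  The target quantity uses the same within-subset minimum-Ct
    anchoring as the reference genes; anchoring constants cancel in the
    fold change.  The calibrator aggregate (arithmetic mean of ratios by
    default, geometric optional) is scaled to fold 1.
    """
    if target_efficiency <= 1:
        raise ParameterError("target amplification factor must be > 1")
    if aggregation not in ("arithmetic", "geometric"):
        raise ParameterError(f"unknown aggregation {aggregation!r}")
    if not list(calibrator):
        raise InputValidationError("calibrator sample set is empty")
    samples = list(nf.index)
    if list(target_ct.index) != samples:
        target_ct = target_ct.reindex(samples)
        if target_ct.isna().any():
            missing = target_ct.index[target_ct.isna()].tolist()
            raise InputValidationError(f"target Ct missing for samples: {missing}")
    absent = [s for s in calibrator if s not in samples]
    if absent:
        raise InputValidationError(f"calibrator sample(s) not present: {absent}")

    ct_arr = target_ct.to_numpy(dtype=float)
    target_q = pd.Series(
        target_efficiency ** (ct_arr.min() - ct_arr), index=nf.index,
        name="target_q",
    )
    ratio = target_q / nf
    cal = ratio.loc[list(calibrator)]
    baseline = float(cal.mean()) if aggregation == "arithmetic" \
        else float(np.exp(np.log(cal).mean()))
    fold = ratio / baseline
    return DdCtResult(
        target_quantity=target_q,
        nf=nf,
        ratio=ratio.rename("ratio"),
        fold_change=fold.rename("fold_change"),
        calibrator_samples=list(calibrator),
        calibrator_aggregation=aggregation,
    )
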