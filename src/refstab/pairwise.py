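"""Delta Ct comparative stability and BestKeeper descriptive statistics.

The Delta Ct method scores a gene by the average spread of its pairwise
Ct differences: for genes i and k, the per-sample difference
``dCt_j = Ct_ij - Ct_kj`` is constant when the two genes co-vary
perfectly, so the SD of that difference over samples measures how much
the pair disagrees.  A gene's stability value is the arithmetic mean of
its pair SDs against every other gene; lower = more stable.  Because
only differences enter, any per-sample loading shift common to all
genes cancels exactly.

BestKeeper instead works on raw Ct: per-gene descriptive statistics
(mean, min, max, SD, CV) plus the BestKeeper index — the per-sample
geometric mean Ct over all candidates — against which each gene is
correlated (Pearson).  Its SD is sensitive to per-sample loading shifts
by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import CtMatrix, StabilityResult, rank_ascending
from .errors import InsufficientDataError, ParameterError

__all__ = ["delta_ct_stability", "bestkeeper_stats", "BestKeeperDetail",
           "pairwise_sd_matrix"]


def pairwise_sd_matrix(values: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Symmetric matrix of SD over samples of row_i - row_k differences."""
    n = values.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        diff = values[i] - values[i + 1:]
        sd = diff.std(axis=1, ddof=ddof)
        out[i, i + 1:] = sd
        out[i + 1:, i] = sd
    return out


def delta_ct_stability(ct: CtMatrix) -> StabilityResult:
    """Mean pairwise Delta Ct SD per gene, ranked ascending.

    Returns a :class:`StabilityResult` whose ``detail`` is the full
    symmetric pair-SD matrix (genes x genes, zero diagonal).
    """
    if ct.n_genes < 2:
        raise InsufficientDataError("Delta Ct needs >= 2 genes")
    if ct.n_samples < 2:
        raise InsufficientDataError("Delta Ct needs >= 2 samples")
    pair_sd = pairwise_sd_matrix(ct.values)
    mean_sd = pair_sd.sum(axis=1) / (ct.n_genes - 1)
    values = pd.Series(mean_sd, index=ct.data.index, name="mean_sd")
    detail = pd.DataFrame(pair_sd, index=ct.data.index, columns=ct.data.index)
    return StabilityResult("delta_ct", values, rank_ascending(values), detail)


@dataclass(frozen=True)
class BestKeeperDetail:
    """Per-gene descriptives, the per-sample index, and index correlations."""

    descriptives: pd.DataFrame   # mean, min, max, dispersion, cv_percent per gene
    index: pd.Series             # per-sample geometric mean Ct
    correlations: pd.DataFrame   # pearson_r, p_value per gene (NaN if undefined)


def bestkeeper_stats(ct: CtMatrix, deviation: str = "sd") -> StabilityResult:
    """BestKeeper-style descriptive stability of raw Ct values.

    Parameters
    ----------
    deviation : {"sd", "mad"}
        Per-gene dispersion: sample standard deviation (n-1) or the mean
        absolute deviation from the arithmetic mean, as the original
        BestKeeper spreadsheet reports.

    Genes are ranked ascending by dispersion.  A zero-variance gene has
    no defined correlation with the index; its r and p are reported as
    missing with a warning rather than raising.
    """
    if deviation not in ("sd", "mad"):
        raise ParameterError(f"deviation must be 'sd' or 'mad', got {deviation!r}")
    if ct.n_samples < 2:
        raise InsufficientDataError("BestKeeper needs >= 2 samples")
    values = ct.values
    mean = values.mean(axis=1)
    if deviation == "sd":
        disp = values.std(axis=1, ddof=1)
    else:
        disp = np.abs(values - mean[:, None]).mean(axis=1)
    cv = 100.0 * disp / mean
    index = np.exp(np.log(values).mean(axis=0))  # geometric mean Ct per sample

    r = np.full(ct.n_genes, np.nan)
    p = np.full(ct.n_genes, np.nan)
    index_varies = index.std() > 0
    for i, gene in enumerate(ct.gene_ids):
        if values[i].std() == 0 or not index_varies:
            warnings.warn(
                f"BestKeeper correlation undefined for constant gene/index "
                f"({gene}); reported as missing",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        r[i], p[i] = sps.pearsonr(values[i], index)

    genes = ct.data.index
    descriptives = pd.DataFrame(
        {
            "mean_ct": mean,
            "min_ct": values.min(axis=1),
            "max_ct": values.max(axis=1),
            "dispersion": disp,
            "cv_percent": cv,
        },
        index=genes,
    )
    detail = BestKeeperDetail(
        descriptives=descriptives,
        index=pd.Series(index, index=ct.data.columns, name="bestkeeper_index"),
        correlations=pd.DataFrame({"pearson_r": r, "p_value": p}, index=genes),
    )
    series = pd.Series(disp, index=genes, name="dispersion")
    return StabilityResult("bestkeeper", series, rank_ascending(series), detail)
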