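"""Transcriptome-based candidate reference-gene screening.

Candidates are pre-screened from RNA-seq expression (FPKM) before any
qPCR work: a good candidate is expressed highly enough to be measurable
(mean FPKM, MF) and varies little across samples (coefficient of
variation, CV = SD/MF, reported in percent).  The default thresholds
MF >= 10 and CV <= 20% follow common practice for transcriptome-guided
reference-gene discovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import FpkmMatrix
from .errors import InsufficientDataError, ParameterError

__all__ = ["GeneStats", "ScreenConfig", "compute_gene_stats", "screen_candidates",
           "stats_to_frame"]


@dataclass(frozen=True)
class GeneStats:
    """Per-gene screening statistics over the FPKM matrix columns."""

    gene_id: str
    mf: float   # mean FPKM
    sd: float   # standard deviation of FPKM (n-1 denominator by default)
    cv: float   # percent, 100 * sd / mf


@dataclass(frozen=True)
class ScreenConfig:
    """Inclusive screening thresholds: keep genes with mf >= min_mf, cv <= max_cv."""

    min_mf: float = 10.0
    max_cv: float = 20.0
    allow_list: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.min_mf <= 0 or self.max_cv <= 0:
            raise ParameterError("min_mf and max_cv must be positive")


def compute_gene_stats(fpkm: FpkmMatrix, ddof: int = 1) -> list[GeneStats]:
    """Mean FPKM, SD and percent CV for every gene.

    SD uses the n-1 denominator by default (the sample SD); ``ddof=0``
    gives the population SD for sensitivity checks.  A gene with zero
    mean has CV defined as 0 (its SD is necessarily 0 for non-negative
    data).
    """
    if fpkm.values.shape[1] < 2:
        raise InsufficientDataError(
            "need >= 2 samples to compute an SD; got "
            f"{fpkm.values.shape[1]}"
        )
    values = fpkm.values
    mf = values.mean(axis=1)
    sd = values.std(axis=1, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mf > 0, 100.0 * sd / mf, 0.0)
    return [
        GeneStats(gene_id=g, mf=float(m), sd=float(s), cv=float(c))
        for g, m, s, c in zip(fpkm.gene_ids, mf, sd, cv)
    ]


def screen_candidates(
    stats: Sequence[GeneStats], config: ScreenConfig | None = None
) -> list[GeneStats]:
    """Filter to candidates with mf >= min_mf and cv <= max_cv.

    Result is sorted ascending by CV (most stable first), ties broken by
    gene id.  An optional allow-list restricts candidates to ids with
    credible annotation, a property not derivable from expression alone.
    """
    if not stats:
        raise InsufficientDataError("no gene statistics supplied")
    config = config or ScreenConfig()
    kept = [
        s for s in stats
        if s.mf >= config.min_mf and s.cv <= config.max_cv
        and (config.allow_list is None or s.gene_id in config.allow_list)
    ]
    return sorted(kept, key=lambda s: (s.cv, s.gene_id))


def stats_to_frame(stats: Iterable[GeneStats]) -> pd.DataFrame:
    """Tabulate GeneStats with the conventional column names."""
    return pd.DataFrame(
        [(s.gene_id, s.mf, s.sd, s.cv) for s in stats],
        columns=["gene_id", "mean_fpkm", "sd", "cv_percent"],
    )
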