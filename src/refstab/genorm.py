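"""geNorm expression-stability measure M and the pairwise-variation rule.

Ct values are first converted to relative quantities
``Q_ij = E_i ** (minCt_i - Ct_ij)`` with E the gene's amplification
factor (2.0 for a perfectly doubling reaction) and minCt the gene's
minimum Ct within the analyzed sample subset, so every gene's most
abundant sample has Q = 1 and Q in (0, 1].

For genes j and k the pairwise variation ``V_jk`` is the SD over
samples of ``log2(Q_j / Q_k)``; the stability measure of gene j is
``M_j = mean over k != j of V_jk``.  Two perfectly co-regulated genes
have a constant log ratio and hence V = 0.  Ranking is by iterative
exclusion: drop the gene with the largest M, recompute on the rest,
until two genes remain — those two are jointly most stable.

The number of reference genes worth using is decided from
normalization factors: ``NF_n`` is the per-sample geometric mean of the
n top-ranked genes' quantities, and ``V(n/n+1)`` the SD over samples of
``log2(NF_n / NF_{n+1})``.  The smallest n with V below 0.15 is the
customary optimum; adding a further gene past that point no longer
changes the normalization factor appreciably.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CtMatrix, StabilityResult
from .errors import InsufficientDataError, ParameterError

__all__ = [
    "RelativeQuantityMatrix",
    "GenormResult",
    "to_relative_quantities",
    "genorm_m",
    "genorm_rank",
    "genorm_v_series",
    "optimal_rg_count",
    "genorm_stability",
    "UNDETERMINED",
]

UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class RelativeQuantityMatrix:
    """Per-gene relative quantities in (0, 1]; each row's maximum is 1."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if (values <= 0).any() or not np.isfinite(values).all():
            raise ParameterError("relative quantities must be finite and > 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass(frozen=True)
class GenormResult:
    """Full geNorm output for one sample subset."""

    m_values: pd.Series          # per gene: M in the round it left the analysis
    ranking: list[str]           # most stable first; first two jointly rank 1-2
    exclusion_trace: pd.DataFrame  # rounds x genes M table (NaN once excluded)
    v_series: dict[int, float]   # n -> V(n/n+1), n = 2..G-1
    optimal_n: int | str         # smallest n with V < threshold, or "undetermined"
    v_threshold: float = 0.15


def _normalize_efficiencies(
    gene_ids: Sequence[str], efficiencies: float | Mapping[str, float]
) -> np.ndarray:
    if isinstance(efficiencies, Mapping):
        eff = np.array([float(efficiencies.get(g, 2.0)) for g in gene_ids])
    else:
        eff = np.full(len(gene_ids), float(efficiencies))
    if (eff <= 1).any():
        bad = [g for g, e in zip(gene_ids, eff) if e <= 1]
        raise ParameterError(
            f"amplification factor must be > 1 (2.0 = perfect doubling); bad: {bad}"
        )
    return eff


def to_relative_quantities(
    ct: CtMatrix, efficiencies: float | Mapping[str, float] = 2.0
) -> RelativeQuantityMatrix:
    """Transform Ct to relative quantities Q = E**(minCt - Ct), per gene.

    The minimum is taken per gene within the matrix passed in, so subset
    analyses are self-contained.  ``efficiencies`` is a single
    amplification factor or a gene -> factor mapping (genes absent from
    the mapping default to 2.0).
    """
    eff = _normalize_efficiencies(ct.gene_ids, efficiencies)
    values = ct.values
    exponent = values.min(axis=1, keepdims=True) - values
    q = eff[:, None] ** exponent
    return RelativeQuantityMatrix(
        pd.DataFrame(q, index=ct.data.index, columns=ct.data.columns)
    )


def _pairwise_v(logq: np.ndarray) -> np.ndarray:
    """Symmetric matrix of SD over samples of log2 Q ratios."""
    n = logq.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        sd = (logq[i] - logq[i + 1:]).std(axis=1, ddof=1)
        out[i, i + 1:] = sd
        out[i + 1:, i] = sd
    return out


def genorm_m(q: RelativeQuantityMatrix) -> pd.Series:
    """Stability measure M per gene: mean pairwise log2-ratio SD."""
    if len(q.gene_ids) < 2:
        raise InsufficientDataError("geNorm needs >= 2 genes")
    if len(q.sample_ids) < 2:
        raise InsufficientDataError("geNorm needs >= 2 samples")
    v = _pairwise_v(np.log2(q.values))
    m = v.sum(axis=1) / (len(q.gene_ids) - 1)
    return pd.Series(m, index=q.data.index, name="m_value")


def genorm_rank(q: RelativeQuantityMatrix, v_threshold: float = 0.15) -> GenormResult:
    """Iterative-exclusion geNorm ranking plus V series and optimal n.

    Each round removes the gene with the largest M (ties: the
    lexicographically larger gene id is removed; the choice is visible
    in the exclusion trace).  The two survivors are jointly most stable
    and are listed in lexicographic order.
    """
    gene_ids = list(q.gene_ids)
    if len(gene_ids) < 3:
        raise InsufficientDataError("geNorm ranking needs >= 3 genes")
    remaining = list(gene_ids)
    sub = q.data
    trace_rows: list[pd.Series] = []
    m_at_exclusion: dict[str, float] = {}
    excluded: list[str] = []
    while len(remaining) > 2:
        m = genorm_m(RelativeQuantityMatrix(sub.loc[remaining]))
        trace_rows.append(m.reindex(gene_ids))
        worst_m = m.max()
        # lexicographically larger id among the tied-at-max genes goes
        ties = sorted(m.index[m == worst_m])
        victim = ties[-1]
        m_at_exclusion[victim] = float(m[victim])
        excluded.append(victim)
        remaining.remove(victim)
    final_m = genorm_m(RelativeQuantityMatrix(sub.loc[remaining]))
    trace_rows.append(final_m.reindex(gene_ids))
    final_pair = sorted(remaining)
    for g in final_pair:
        m_at_exclusion[g] = float(final_m[g])
    ranking = final_pair + excluded[::-1]
    trace = pd.DataFrame(trace_rows)
    trace.index = pd.RangeIndex(1, len(trace_rows) + 1, name="round")
    m_values = pd.Series(
        {g: m_at_exclusion[g] for g in gene_ids}, name="m_value"
    ).reindex(gene_ids)
    v_series = genorm_v_series(q, ranking)
    result = GenormResult(
        m_values=m_values,
        ranking=ranking,
        exclusion_trace=trace,
        v_series=v_series,
        optimal_n=optimal_rg_count(v_series, v_threshold),
        v_threshold=v_threshold,
    )
    return result


def genorm_v_series(
    q: RelativeQuantityMatrix, ranking: Sequence[str]
) -> dict[int, float]:
    """Pairwise variation V(n/n+1) between consecutive normalization factors.

    ``NF_n`` is the per-sample geometric mean of the n top-ranked genes'
    quantities; V(n/n+1) is the SD over samples of ``log2(NF_n/NF_{n+1})``
    for n = 2 .. G-1.
    """
    genes = list(ranking)
    if len(genes) < 3:
        raise InsufficientDataError("V series needs >= 3 ranked genes")
    logq = np.log2(q.data.loc[genes].to_numpy(dtype=float))
    out: dict[int, float] = {}
    for n in range(2, len(genes)):
        log_nf_n = logq[:n].mean(axis=0)
        log_nf_n1 = logq[: n + 1].mean(axis=0)
        out[n] = float((log_nf_n - log_nf_n1).std(ddof=1))
    return out


def optimal_rg_count(
    v_series: Mapping[int, float], threshold: float = 0.15
) -> int | str:
    """Smallest n with V(n/n+1) < threshold; 'undetermined' if none qualifies.

    An undetermined result is a recommendation to use all candidate
    genes (or to re-examine the panel), not a failure.
    """
    if not v_series:
        raise InsufficientDataError("empty V series")
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    for n in sorted(v_series):
        if v_series[n] < threshold:
            return n
    return UNDETERMINED


def genorm_stability(
    q: RelativeQuantityMatrix,
    v_threshold: float = 0.15,
    tied_pair: bool = True,
) -> StabilityResult:
    """geNorm as a StabilityResult for rank aggregation.

    The exclusion-order ranking is converted to integer ranks.  With
    ``tied_pair`` (default, mirrors geNorm-classic output) the final
    pair enters as ranks (1, 1) and the next gene as 3; otherwise ranks
    are sequential (1, 2, 3, ...).
    """
    result = genorm_rank(q, v_threshold=v_threshold)
    ranks: dict[str, int] = {}
    for pos, gene in enumerate(result.ranking, start=1):
        if tied_pair and pos <= 2:
            ranks[gene] = 1
        else:
            ranks[gene] = pos
    gene_order = list(q.gene_ids)
    values = result.m_values.reindex(gene_order)
    rank_series = pd.Series({g: ranks[g] for g in gene_order}, dtype=int)
    return StabilityResult("genorm", values, rank_series, result)
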