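"""Comprehensive rank aggregation across stability methods.

Each method contributes an integer rank per gene (1 = most stable);
the comprehensive score is the geometric mean of a gene's ranks across
methods (the aggregation popularized by the RefFinder tool), and the
final ordering is ascending in that geomean.  Methods are weighted
equally; within-method ties carry the shared minimum rank into the
geomean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import StabilityResult, rank_ascending
from .errors import InputValidationError, InsufficientDataError
from .genorm import UNDETERMINED

__all__ = ["ComprehensiveRanking", "comprehensive_rank", "recommend_rgs"]


@dataclass(frozen=True)
class ComprehensiveRanking:
    """Per-gene method ranks, geomean and final rank (1 = most stable)."""

    table: pd.DataFrame          # columns rank_<method>..., geomean, final_rank
    methods_included: list[str]

    @property
    def ordered_genes(self) -> list[str]:
        """Genes from most to least stable (geomean, then gene id)."""
        order = self.table.assign(_gene=self.table.index).sort_values(
            ["geomean", "_gene"], kind="stable"
        )
        return list(order.index)


def comprehensive_rank(results: Sequence[StabilityResult]) -> ComprehensiveRanking:
    """Aggregate >= 2 StabilityResults by geometric mean of ranks.

    All results must cover the identical gene set; a mismatch raises an
    alignment error naming the offending genes.  Final ranks are
    ascending in geomean with ties sharing the minimum rank; the listed
    gene order breaks exact geomean ties lexicographically.
    """
    if len(results) < 2:
        raise InsufficientDataError("comprehensive ranking needs >= 2 methods")
    methods = [r.method for r in results]
    if len(set(methods)) != len(methods):
        raise InputValidationError(f"duplicate method labels: {methods}")
    base = set(results[0].gene_ids)
    for r in results[1:]:
        diff = base.symmetric_difference(r.gene_ids)
        if diff:
            raise InputValidationError(
                f"gene sets differ between {results[0].method} and "
                f"{r.method}: {sorted(diff)}"
            )
    genes = sorted(base)
    rank_cols = {
        f"rank_{r.method}": r.ranks.reindex(genes).astype(int) for r in results
    }
    table = pd.DataFrame(rank_cols, index=pd.Index(genes, name="gene"))
    log_ranks = np.log(table.to_numpy(dtype=float))
    table["geomean"] = np.exp(log_ranks.mean(axis=1))
    table["final_rank"] = rank_ascending(table["geomean"])
    table = table.assign(_gene=table.index).sort_values(
        ["geomean", "_gene"], kind="stable"
    ).drop(columns="_gene")
    return ComprehensiveRanking(table=table, methods_included=methods)


def recommend_rgs(
    ranking: ComprehensiveRanking, optimal_n: int | str
) -> list[str]:
    """Top ``optimal_n`` genes of the comprehensive ranking.

    When the optimal count is undetermined (no pairwise variation below
    the cutoff) the full ranking is returned with a warning: the caller
    should treat all candidates as needed.
    """
    genes = ranking.ordered_genes
    if optimal_n == UNDETERMINED:
        import warnings

        warnings.warn(
            "optimal reference-gene count undetermined; returning the "
            "full ranking",
            UserWarning,
            stacklevel=2,
        )
        return genes
    n = int(optimal_n)
    if n < 1 or n > len(genes):
        raise InputValidationError(
            f"optimal_n {n} outside 1..{len(genes)}"
        )
    return genes[:n]
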