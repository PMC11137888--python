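"""Model/Results front end for reference-gene selection.

``ReferenceGeneStability`` wraps a Ct matrix (plus optional grouping
and per-gene amplification factors); ``fit()`` runs the requested
stability methods and returns a ``StabilitySelectionResults`` holding
per-method values and ranks, the comprehensive (geometric-mean-of-
ranks) ordering, the geNorm pairwise-variation series with the optimal
reference-gene count, and a text ``summary()``.

Example
-------
>>> from refstab.simulate import preset_config, generate_ct_dataset
>>> from refstab.model import ReferenceGeneStability
>>> ct, design, truth = generate_ct_dataset(preset_config("corm_growth", seed=7))
>>> res = ReferenceGeneStability(ct).fit()
>>> res.recommended      # doctest: +SKIP
['GAPDH', 'UBQ10']
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .core import CtMatrix, GroupDesign, StabilityResult, ct_quality_check
from .errors import InputValidationError
from .genorm import GenormResult, genorm_stability, to_relative_quantities
from .normfinder import normfinder_stability
from .pairwise import bestkeeper_stats, delta_ct_stability
from .ranking import ComprehensiveRanking, comprehensive_rank, recommend_rgs

ALL_METHODS = ("delta_ct", "bestkeeper", "genorm", "normfinder")

__all__ = ["ReferenceGeneStability", "StabilitySelectionResults", "ALL_METHODS"]


class ReferenceGeneStability:
    """Stability model over a Ct matrix.

    Parameters
    ----------
    ct : CtMatrix or DataFrame
        Genes x samples Ct values; a plain DataFrame is validated into
        a :class:`CtMatrix`.
    groups : mapping sample -> group, optional
        Needed for NormFinder; overrides labels carried by the matrix.
    efficiencies : float or mapping gene -> amplification factor
        Used in the relative-quantity transform for geNorm (default
        2.0, perfect doubling).
    """

    def __init__(
        self,
        ct: CtMatrix | pd.DataFrame,
        groups: Mapping[str, str] | None = None,
        efficiencies: float | Mapping[str, float] = 2.0,
    ) -> None:
        if isinstance(ct, pd.DataFrame):
            ct = CtMatrix(ct, groups)
        elif groups is not None:
            ct = CtMatrix(ct.data, groups)
        self.ct = ct
        self.efficiencies = efficiencies

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        groups: Mapping[str, str] | None = None,
        **kwargs,
    ) -> "ReferenceGeneStability":
        return cls(CtMatrix(data, groups), **kwargs)

    def fit(
        self,
        methods: Sequence[str] = ALL_METHODS,
        v_threshold: float = 0.15,
        bestkeeper_deviation: str = "sd",
        genorm_tied_pair: bool = True,
    ) -> "StabilitySelectionResults":
        """Run the stability methods and aggregate their rankings."""
        unknown = [m for m in methods if m not in ALL_METHODS]
        if unknown:
            raise InputValidationError(
                f"unknown method(s) {unknown}; choose from {ALL_METHODS}"
            )
        per_method: dict[str, StabilityResult] = {}
        q = None
        if "delta_ct" in methods:
            per_method["delta_ct"] = delta_ct_stability(self.ct)
        if "bestkeeper" in methods:
            per_method["bestkeeper"] = bestkeeper_stats(
                self.ct, deviation=bestkeeper_deviation
            )
        if "genorm" in methods:
            q = to_relative_quantities(self.ct, self.efficiencies)
            per_method["genorm"] = genorm_stability(
                q, v_threshold=v_threshold, tied_pair=genorm_tied_pair
            )
        if "normfinder" in methods:
            per_method["normfinder"] = normfinder_stability(self.ct)

        comprehensive = None
        if len(per_method) >= 2:
            comprehensive = comprehensive_rank(list(per_method.values()))
        return StabilitySelectionResults(
            model=self,
            per_method=per_method,
            comprehensive=comprehensive,
            qc=ct_quality_check(self.ct),
        )


class StabilitySelectionResults:
    """Fitted stability analysis: per-method results plus aggregation."""

    def __init__(self, model, per_method, comprehensive, qc):
        self.model = model
        self.per_method = per_method
        self.comprehensive: ComprehensiveRanking | None = comprehensive
        self.qc = qc

    @property
    def genorm(self) -> GenormResult | None:
        res = self.per_method.get("genorm")
        return res.detail if res is not None else None

    @property
    def optimal_n(self):
        g = self.genorm
        return g.optimal_n if g is not None else None

    @property
    def v_series(self) -> dict[int, float] | None:
        g = self.genorm
        return g.v_series if g is not None else None

    @property
    def recommended(self) -> list[str] | None:
        """The optimal-n top genes of the comprehensive ranking."""
        if self.comprehensive is None or self.optimal_n is None:
            return None
        return recommend_rgs(self.comprehensive, self.optimal_n)

    def stability_values(self) -> pd.DataFrame:
        """Genes x methods table of stability values (method units)."""
        return pd.DataFrame(
            {m: r.values for m, r in self.per_method.items()}
        )

    def ranks(self) -> pd.DataFrame:
        """Genes x methods table of integer ranks (1 = most stable)."""
        return pd.DataFrame({m: r.ranks for m, r in self.per_method.items()})

    def summary(self) -> str:
        """Human-readable report of values, ranks, V series and QC flags."""
        lines = ["Reference-gene stability analysis",
                 "=" * 50,
                 f"genes: {self.model.ct.n_genes}   "
                 f"samples: {self.model.ct.n_samples}   "
                 f"methods: {', '.join(self.per_method)}"]
        flagged = self.qc.flags[self.qc.flags != "ok"]
        if len(flagged):
            lines.append(
                "QC flags (mean Ct outside 15-30): "
                + ", ".join(f"{g}={f}" for g, f in flagged.items())
            )
        values = self.stability_values().round(4)
        ranks = self.ranks()
        table = pd.concat(
            {"value": values, "rank": ranks}, axis=1
        ).swaplevel(axis=1).sort_index(axis=1, level=0)
        if self.comprehensive is not None:
            lines += ["", "Comprehensive ranking (geometric mean of ranks):",
                      self.comprehensive.table.round(4).to_string()]
        lines += ["", "Per-method results:", table.to_string()]
        if self.v_series is not None:
            v_text = "  ".join(
                f"V{n}/{n + 1}={v:.4f}" for n, v in sorted(self.v_series.items())
            )
            lines += ["", f"geNorm pairwise variation: {v_text}",
                      f"optimal reference-gene count: {self.optimal_n}"]
        if self.recommended is not None:
            lines.append(f"recommended set: {', '.join(self.recommended)}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<StabilitySelectionResults: {len(self.per_method)} methods, "
                f"{self.model.ct.n_genes} genes>")
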