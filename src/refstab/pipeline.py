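"""Full-workflow orchestration: screen -> stability x 4 -> comprehensive
rank -> optimal n -> (optional) target quantification, per sample subset.

A run is described by a :class:`RunConfig`; every subset produces the
per-method tables, the comprehensive ranking, the geNorm V series with
the optimal reference-gene count, and the recommended gene set.  The
run summary records every parameter and an input checksum so identical
configs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import CtMatrix, StabilityResult, ct_quality_check
from .errors import InputValidationError, RefstabError
from .genorm import UNDETERMINED
from .model import ALL_METHODS, ReferenceGeneStability
from .quant import normalization_factor, relative_expression
from .ranking import recommend_rgs
from .tableio import write_report

__all__ = ["RunConfig", "SubsetResult", "run_full_pipeline", "compare_methods",
           "write_pipeline_report"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run needs.

    ``subsets`` maps a subset name (e.g. ``corm_growth``) to the group
    labels it covers; an empty mapping means one subset ``all`` with
    every sample.  Optional quantification runs per subset with the
    recommended genes as the multi-gene strategy, the top gene as the
    single-gene strategy and the bottom gene as the least-stable
    strategy.
    """

    ct: CtMatrix
    subsets: Mapping[str, Sequence[str]] = field(default_factory=dict)
    methods: Sequence[str] = ALL_METHODS
    v_threshold: float = 0.15
    ct_qc_bounds: tuple[float, float] = (15.0, 30.0)
    efficiencies: float | Mapping[str, float] = 2.0
    target_ct: pd.Series | None = None
    target_efficiency: float = 2.0
    calibrator_group: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.v_threshold <= 0:
            raise InputValidationError("v_threshold must be positive")
        if self.subsets:
            if self.ct.groups is None:
                raise InputValidationError(
                    "named subsets require group labels on the Ct matrix"
                )
            known = set(self.ct.groups.values())
            for name, groups in self.subsets.items():
                missing = set(groups) - known
                if missing:
                    raise InputValidationError(
                        f"subset {name!r} references unknown group(s) "
                        f"{sorted(missing)}"
                    )


@dataclass(frozen=True)
class SubsetResult:
    """All outputs for one sample subset."""

    name: str
    per_method: Mapping[str, StabilityResult]
    comprehensive: pd.DataFrame
    v_series: dict[int, float]
    optimal_n: int | str
    recommended: list[str]
    quantification: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)


def _stage(name: str):
    """Re-raise package errors with the pipeline stage attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, RefstabError):
                raise type(exc)(f"[stage {name}] {exc}") from exc
            return False

    return _Ctx()


def run_full_pipeline(config: RunConfig) -> tuple[dict, dict[str, SubsetResult]]:
    """Execute the workflow for every subset; returns (summary, results)."""
    ct = config.ct
    subsets = dict(config.subsets) or {"all": None}
    results: dict[str, SubsetResult] = {}
    summary: dict = {
        "parameters": {
            "methods": list(config.methods),
            "v_threshold": config.v_threshold,
            "ct_qc_bounds": list(config.ct_qc_bounds),
            "seed": config.seed,
            "target_efficiency": config.target_efficiency,
            "calibrator_group": config.calibrator_group,
        },
        "n_genes": ct.n_genes,
        "n_samples": ct.n_samples,
        "input_sha256": hashlib.sha256(
            ct.data.to_csv().encode()
        ).hexdigest(),
        "subsets": {},
    }
    for name, groups in subsets.items():
        with _stage(f"subset:{name}"):
            sub = ct if groups is None else ct.subset_groups(groups)
        collected: list[str] = []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            with _stage(f"qc:{name}"):
                qc = ct_quality_check(sub, *config.ct_qc_bounds)
            with _stage(f"stability:{name}"):
                fit = ReferenceGeneStability(
                    sub, efficiencies=config.efficiencies
                ).fit(methods=config.methods, v_threshold=config.v_threshold)
            with _stage(f"ranking:{name}"):
                recommended = recommend_rgs(fit.comprehensive, fit.optimal_n) \
                    if fit.optimal_n is not None else list(
                        fit.comprehensive.table.index)
            quant_table = None
            if config.target_ct is not None:
                with _stage(f"quantify:{name}"):
                    quant_table = _quantify(config, sub, fit, recommended)
            collected = [str(w.message) for w in caught]
        flagged = qc.flags[qc.flags != "ok"]
        collected += [f"QC flag: {g} {f}" for g, f in flagged.items()]
        if fit.optimal_n == UNDETERMINED:
            collected.append("optimal reference-gene count undetermined")
        results[name] = SubsetResult(
            name=name,
            per_method=fit.per_method,
            comprehensive=fit.comprehensive.table,
            v_series=fit.v_series or {},
            optimal_n=fit.optimal_n,
            recommended=recommended,
            quantification=quant_table,
            warnings=collected,
        )
        summary["subsets"][name] = {
            "n_samples": sub.n_samples,
            "optimal_n": fit.optimal_n,
            "recommended": recommended,
            "v_series": {str(k): v for k, v in (fit.v_series or {}).items()},
            "warnings": collected,
        }
    return summary, results


def _quantify(config: RunConfig, sub: CtMatrix, fit, recommended) -> pd.DataFrame:
    ordering = list(fit.comprehensive.table.index)
    strategies = {
        "multi_optimal": recommended,
        "single_best": ordering[:1],
        "least_stable": ordering[-1:],
    }
    if config.calibrator_group is not None:
        if sub.groups is None:
            raise InputValidationError("calibrator group requires group labels")
        calibrator = [s for s in sub.sample_ids
                      if sub.groups[s] == config.calibrator_group]
        if not calibrator:
            raise InputValidationError(
                f"calibrator group {config.calibrator_group!r} has no samples "
                f"in subset {sub.sample_ids}"
            )
    else:
        calibrator = sub.sample_ids[:1]
    frames = []
    target = config.target_ct.reindex(sub.sample_ids)
    if target.isna().any():
        raise InputValidationError(
            "target Ct missing for samples: "
            f"{target.index[target.isna()].tolist()}"
        )
    for label, genes in strategies.items():
        nf = normalization_factor(sub, genes, config.efficiencies)
        res = relative_expression(
            target, nf, calibrator, target_efficiency=config.target_efficiency
        )
        frame = res.to_frame().reset_index(names="sample")
        frame.insert(0, "rg_strategy", label)
        frame.insert(1, "reference_genes", "+".join(genes))
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def compare_methods(
    results: Sequence[StabilityResult] | Mapping[str, StabilityResult],
) -> pd.DataFrame:
    """Pairwise Spearman correlation of method rankings.

    Returns a square methods x methods correlation table; the per-gene
    rank range (max - min rank across methods) is attached as the
    DataFrame attribute ``rank_ranges``.
    """
    if isinstance(results, Mapping):
        results = list(results.values())
    if len(results) < 2:
        raise InputValidationError("method comparison needs >= 2 methods")
    base = set(results[0].gene_ids)
    for r in results[1:]:
        if set(r.gene_ids) != base:
            raise InputValidationError(
                f"gene sets differ between {results[0].method} and {r.method}: "
                f"{sorted(base.symmetric_difference(r.gene_ids))}"
            )
    genes = sorted(base)
    ranks = pd.DataFrame(
        {r.method: r.ranks.reindex(genes) for r in results},
        index=pd.Index(genes, name="gene"),
    )
    methods = list(ranks.columns)
    corr = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            if ranks[a].nunique() == 1 or ranks[b].nunique() == 1:
                rho = np.nan  # constant ranking has no defined correlation
            else:
                rho = sps.spearmanr(ranks[a], ranks[b]).statistic
            corr.loc[a, b] = corr.loc[b, a] = rho
    corr.attrs["rank_ranges"] = (ranks.max(axis=1) - ranks.min(axis=1)).rename(
        "rank_range"
    )
    return corr


def write_pipeline_report(
    summary: dict, results: Mapping[str, SubsetResult], outdir: str | Path
) -> list[Path]:
    """Write all subset tables (TSV) plus the JSON run summary."""
    tables: list[tuple[str, pd.DataFrame]] = []
    for name, res in results.items():
        for method, sr in res.per_method.items():
            tables.append((f"{name}_{method}", sr.to_frame()))
        tables.append(
            (f"{name}_comprehensive", res.comprehensive.reset_index())
        )
        v_frame = pd.DataFrame(
            {"n": list(res.v_series), "v": list(res.v_series.values())}
        )
        tables.append((f"{name}_v_series", v_frame))
        if res.quantification is not None:
            tables.append((f"{name}_quantification", res.quantification))
    return write_report(tables, outdir, summary=summary)
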