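"""Model-based (NormFinder-style) stability estimation.

The model decomposes log-scale expression into a sample effect (shared
by all genes, removed by centering within each sample), a gene x group
effect d_ig (systematic regulation of gene i in condition g — the
dangerous part of an unstable reference gene), and residual intragroup
noise with gene/group variance sigma^2_ig.  Working directly on
y = -Ct is natural because Ct is already logarithmic in template
amount; per-gene constants cancel in the centering, so the sign
convention does not affect any output.

For each gene the stability value combines the two error sources:

    rho_i = mean over groups g of ( |d~_ig| + sqrt(sigma^2_ig / n_g) )

where d~ is the raw group difference shrunk toward zero in proportion
to how much of its apparent size is explainable by sampling noise
(an empirical-Bayes step controlled by gamma^2, the estimated variance
of true group differences across genes).  Lower rho = more stable.
With a single group the inter-group term vanishes and genes are ranked
by sqrt(sigma^2_i) alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import CtMatrix, GroupDesign, StabilityResult, rank_ascending
from .errors import DesignError, InsufficientDataError

__all__ = ["NormFinderResult", "normfinder_stability", "normfinder_best_pair"]


@dataclass(frozen=True)
class NormFinderResult:
    """Variance components behind the NormFinder stability values.

    ``group_diff`` and ``group_diff_shrunk`` are genes x groups tables of
    the raw and shrunken inter-group differences d and d~ (log2-cycle
    units); ``intragroup_var`` the bias-corrected sigma^2 estimates
    (floored at 0); ``gamma_sq`` the estimated variance of true group
    differences.  Within each group the raw d sum to 0 over genes by
    construction.
    """

    stability: pd.Series
    intragroup_var: pd.DataFrame
    group_diff: pd.DataFrame
    group_diff_shrunk: pd.DataFrame
    gamma_sq: float
    groups_used: list[str]
    group_sizes: dict[str, int]


def _variance_components(ct: CtMatrix, design: GroupDesign):
    genes = list(ct.gene_ids)
    n_genes = len(genes)
    if n_genes < 3:
        raise InsufficientDataError(
            "NormFinder needs >= 3 genes (the intragroup variance "
            f"correction divides by I-2); got {n_genes}"
        )
    design.validate_for(ct, min_per_group=2)
    groups = [g for g in design.group_labels
              if any(design.groups[s] == g for s in ct.sample_ids)]

    y = -ct.values                      # log-scale abundance
    z = y - y.mean(axis=0, keepdims=True)   # remove per-sample loading effect

    cols = {s: j for j, s in enumerate(ct.sample_ids)}
    s2 = np.empty((n_genes, len(groups)))
    zbar = np.empty((n_genes, len(groups)))
    n_g = {}
    for gi, group in enumerate(groups):
        idx = [cols[s] for s in ct.sample_ids if design.groups[s] == group]
        n_g[group] = len(idx)
        zg = z[:, idx]
        s2[:, gi] = zg.var(axis=1, ddof=1)
        zbar[:, gi] = zg.mean(axis=1)

    # bias correction: the per-sample centering leaks 1/I of every other
    # gene's variance into each z row; undo it and floor at 0
    correction = s2.sum(axis=0, keepdims=True) / (n_genes * (n_genes - 1))
    sigma2 = np.maximum(0.0, (n_genes / (n_genes - 2)) * (s2 - correction))
    return genes, groups, n_g, sigma2, zbar


def normfinder_stability(
    ct: CtMatrix, design: GroupDesign | None = None
) -> StabilityResult:
    """NormFinder stability values and ranks for a Ct matrix.

    ``design`` defaults to the group labels carried by the matrix; an
    unlabeled matrix is treated as a single group (ranking by pure
    intragroup variability).  Each group needs at least two samples; at
    least three genes are required.  Groups are weighted equally in the
    stability value regardless of their sample count.
    """
    if design is None:
        if ct.groups is not None:
            design = ct.design()
        else:
            design = GroupDesign({s: "all" for s in ct.sample_ids})
    genes, groups, n_g, sigma2, zbar = _variance_components(ct, design)
    n_genes, n_groups = sigma2.shape
    ng_vec = np.array([n_g[g] for g in groups], dtype=float)

    if n_groups >= 2:
        d = zbar - zbar.mean(axis=1, keepdims=True)
        noise = sigma2 / ng_vec[None, :]
        gamma_sq = max(
            0.0,
            float((d ** 2).sum() / ((n_groups - 1) * (n_genes - 1))
                  - noise.mean()),
        )
        if gamma_sq > 0:
            d_shrunk = d * gamma_sq / (gamma_sq + noise)
        else:
            d_shrunk = np.zeros_like(d)
        rho = (np.abs(d_shrunk) + np.sqrt(noise)).mean(axis=1)
    else:
        d = np.zeros((n_genes, 1))
        d_shrunk = np.zeros_like(d)
        gamma_sq = 0.0
        rho = np.sqrt(sigma2[:, 0])

    index = pd.Index(genes, name="gene")
    stability = pd.Series(rho, index=index, name="stability")
    detail = NormFinderResult(
        stability=stability,
        intragroup_var=pd.DataFrame(sigma2, index=index, columns=groups),
        group_diff=pd.DataFrame(d, index=index, columns=groups[: d.shape[1]]),
        group_diff_shrunk=pd.DataFrame(
            d_shrunk, index=index, columns=groups[: d.shape[1]]
        ),
        gamma_sq=gamma_sq,
        groups_used=list(groups),
        group_sizes={g: int(n) for g, n in n_g.items()},
    )
    return StabilityResult(
        "normfinder", stability, rank_ascending(stability), detail
    )


def normfinder_best_pair(result: NormFinderResult) -> tuple[str, str]:
    """Most stable *pair* of genes under the variance model.

    Averaging two genes halves independent noise and lets opposite-sign
    group regulation cancel.  The pair (i, k) minimizing

        mean over groups g of ( |(d~_ig + d~_kg)/2|
                                + sqrt((sigma^2_ig + sigma^2_kg) / (4 n_g)) )

    is returned; ties break lexicographically.  Requires >= 2 groups
    (with one group pairing reduces to picking the two lowest variances
    and carries no extra information).
    """
    if len(result.groups_used) < 2:
        raise DesignError("best-pair selection needs >= 2 groups")
    genes = list(result.stability.index)
    d = result.group_diff_shrunk.to_numpy()
    s2 = result.intragroup_var.to_numpy()
    ng = np.array([result.group_sizes[g] for g in result.groups_used], float)
    best: tuple[float, tuple[str, str]] | None = None
    for i, k in combinations(range(len(genes)), 2):
        pair_rho = float(
            (np.abs((d[i] + d[k]) / 2.0)
             + np.sqrt((s2[i] + s2[k]) / (4.0 * ng))).mean()
        )
        key = (pair_rho, tuple(sorted((genes[i], genes[k]))))
        if best is None or key < best:
            best = key
    assert best is not None
    return best[1]
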