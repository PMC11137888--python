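"""Synthetic qPCR / RNA-seq data with known ground truth.

The Ct generator encodes the additive log-scale model the stability
methods are built to dissect:

    Ct_ij = baseline_i + shift_{i, group(j)} + b_j + eps_ij

with ``b_j ~ N(0, tau^2)`` a per-sample loading effect shared by every
gene in sample j (RNA input / RT efficiency), ``shift`` a systematic
gene x condition regulation (what makes a reference gene *bad*), and
``eps_ij ~ N(0, noise_sd_i^2)`` gene-specific technical noise.  Noise
is normal on the Ct (log) scale, consistent with the log-linear PCR
model.  All draws come from a generator seeded in the config; the same
config + seed regenerates the data bit-identically.

A gene's designed overall instability is
``sqrt(noise_sd^2 + population variance of its group shifts)`` — the
two variance sources a stability method must detect (the shared
loading effect cancels for the pairwise/log-ratio methods and is
therefore excluded from the designed ordering).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CtMatrix, FpkmMatrix, GroupDesign
from .errors import InputValidationError, ParameterError

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_ct_dataset",
    "generate_fpkm_dataset",
    "generate_dilution_series",
    "preset_config",
    "unstable_gene_config",
    "PRESETS",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one synthetic Ct dataset.

    ``group_shift`` maps ``(gene_id, group_label)`` to a Ct shift in
    cycles (absent pairs shift 0); ``noise_sd`` maps gene id to its
    technical noise SD in cycles; ``sample_effect_sd`` is tau, the SD
    of the shared per-sample loading effect.  ``seed`` is mandatory —
    there is no global RNG state.
    """

    gene_ids: tuple[str, ...]
    groups: tuple[tuple[str, int], ...]          # (label, n_samples) pairs
    baseline_ct: Mapping[str, float]
    noise_sd: Mapping[str, float]
    seed: int
    sample_effect_sd: float = 0.0
    group_shift: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InputValidationError("duplicate gene ids in config")
        if not self.gene_ids or not self.groups:
            raise InputValidationError("config needs >= 1 gene and >= 1 group")
        for label, n in self.groups:
            if n < 2:
                raise InputValidationError(
                    f"group {label!r} needs n >= 2 samples, got {n}"
                )
        if self.sample_effect_sd < 0:
            raise ParameterError("sample_effect_sd must be >= 0")
        for g in self.gene_ids:
            if g not in self.baseline_ct:
                raise InputValidationError(f"no baseline Ct for gene {g!r}")
            if self.noise_sd.get(g, -1.0) < 0:
                raise InputValidationError(f"noise_sd missing or < 0 for {g!r}")
        labels = [label for label, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise InputValidationError("duplicate group labels")
        for gene, group in self.group_shift:
            if gene not in self.gene_ids or group not in labels:
                raise InputValidationError(
                    f"group_shift refers to unknown (gene, group) "
                    f"({gene!r}, {group!r})"
                )

    def designed_instability(self) -> pd.Series:
        """sqrt(noise^2 + population variance of group shifts), per gene."""
        labels = [label for label, _ in self.groups]
        out = {}
        for g in self.gene_ids:
            shifts = np.array(
                [self.group_shift.get((g, lab), 0.0) for lab in labels]
            )
            out[g] = float(np.sqrt(self.noise_sd[g] ** 2 + shifts.var()))
        return pd.Series(out, name="designed_instability")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated dataset (the acceptance surface)."""

    designed_order: list[str]        # most stable first; ties by gene id
    designed_instability: pd.Series
    config: SyntheticConfig
    seed: int

    @property
    def least_stable(self) -> str:
        return self.designed_order[-1]

    @property
    def most_stable(self) -> str:
        return self.designed_order[0]


def generate_ct_dataset(
    config: SyntheticConfig,
) -> tuple[CtMatrix, GroupDesign, SyntheticTruth]:
    """Draw one Ct dataset from the additive log-scale model."""
    rng = np.random.default_rng(config.seed)
    labels = [label for label, _ in config.groups]
    sample_ids: list[str] = []
    sample_group: dict[str, str] = {}
    for label, n in config.groups:
        for r in range(1, n + 1):
            sid = f"{label}_r{r}"
            sample_ids.append(sid)
            sample_group[sid] = label
    n_samples = len(sample_ids)
    genes = list(config.gene_ids)

    baseline = np.array([config.baseline_ct[g] for g in genes])
    noise_sd = np.array([config.noise_sd[g] for g in genes])
    shift = np.array(
        [[config.group_shift.get((g, sample_group[s]), 0.0) for s in sample_ids]
         for g in genes]
    )
    b = rng.normal(0.0, config.sample_effect_sd, size=n_samples)
    eps = rng.normal(0.0, 1.0, size=(len(genes), n_samples)) * noise_sd[:, None]
    ct = baseline[:, None] + shift + b[None, :] + eps

    matrix = CtMatrix(
        pd.DataFrame(ct, index=pd.Index(genes, name="gene"), columns=sample_ids),
        groups=sample_group,
    )
    designed = config.designed_instability()
    order = sorted(genes, key=lambda g: (designed[g], g))
    truth = SyntheticTruth(
        designed_order=order,
        designed_instability=designed,
        config=config,
        seed=config.seed,
    )
    return matrix, GroupDesign(sample_group), truth


def generate_fpkm_dataset(
    n_genes: int,
    n_samples: int,
    cv_targets: Sequence[float],
    mean_targets: Sequence[float],
    seed: int,
) -> tuple[FpkmMatrix, pd.DataFrame]:
    """Log-normal FPKM draws with designed per-gene mean and percent CV.

    For a log-normal with mean m and CV c (fraction), sigma^2 =
    ln(1 + c^2) and mu = ln(m) - sigma^2/2.  A CV target of 0 produces
    a constant gene.  Returns the matrix and a truth table recording
    each gene's targets and whether it was designed to pass the default
    MF >= 10, CV <= 20% screen.
    """
    cv = np.asarray(cv_targets, dtype=float)
    mean = np.asarray(mean_targets, dtype=float)
    if cv.size != n_genes or mean.size != n_genes:
        raise InputValidationError("cv_targets/mean_targets must have n_genes entries")
    if (mean <= 0).any() or (cv < 0).any():
        raise ParameterError("mean targets must be > 0 and CV targets >= 0")
    rng = np.random.default_rng(seed)
    frac = cv / 100.0
    sigma2 = np.log1p(frac ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    draws = np.exp(
        mu[:, None] + np.sqrt(sigma2)[:, None]
        * rng.standard_normal((n_genes, n_samples))
    )
    genes = [f"G{i + 1:03d}" for i in range(n_genes)]
    samples = [f"S{j + 1:02d}" for j in range(n_samples)]
    fpkm = FpkmMatrix(pd.DataFrame(draws, index=pd.Index(genes, name="gene"),
                                   columns=samples))
    truth = pd.DataFrame(
        {
            "mean_target": mean,
            "cv_target_percent": cv,
            "designed_pass": (mean >= 10.0) & (cv <= 20.0),
        },
        index=pd.Index(genes, name="gene"),
    )
    return fpkm, truth


def generate_dilution_series(
    amplification_factor: float = 2.0,
    intercept: float = 30.0,
    n_points: int = 5,
    step_log10: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy dilution series: Ct = intercept - log10(conc)/log10(E) + noise.

    Concentrations start at 1 (log10 = 0) and fall by ``step_log10``
    decades per point.  With ``noise_sd = 0`` the series inverts exactly
    to the generating amplification factor.
    """
    if amplification_factor <= 1:
        raise ParameterError("amplification factor must be > 1")
    if n_points < 3:
        raise InputValidationError("need >= 3 dilution points")
    log10_conc = -step_log10 * np.arange(n_points, dtype=float)
    ct = intercept - log10_conc / np.log10(amplification_factor)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ct = ct + rng.normal(0.0, noise_sd, size=n_points)
    return log10_conc, ct


# ---------------------------------------------------------------------------
# Study-design presets
# ---------------------------------------------------------------------------

_GENES = ("ACT", "CYP5", "EF1A", "GAPDH", "PP2A", "SAND", "TIP41", "TUBB",
          "UBC9", "UBQ10")

_BASELINES = {
    "ACT": 27.8, "CYP5": 24.5, "EF1A": 17.2, "GAPDH": 22.0, "PP2A": 25.5,
    "SAND": 26.0, "TIP41": 24.0, "TUBB": 23.5, "UBC9": 23.0, "UBQ10": 20.5,
}

# TUBB: systematically regulated across conditions (the classic unreliable
# reference gene); EF1A: high technical/biological scatter without a
# condition effect; the rest: quietly stable.
_NOISE = {g: 0.2 for g in _GENES} | {"TUBB": 0.6, "EF1A": 1.0}

_PRESET_GROUPS: dict[str, tuple[tuple[str, int], ...]] = {
    "corm_growth": (("stage1", 3), ("stage2", 3), ("stage3", 3)),
    "tissues": (("leaf", 3), ("corm", 3), ("petiole", 3), ("root", 3)),
    "drought": (
        ("corm_ctrl", 3), ("corm_drought", 3),
        ("leaf_ctrl", 3), ("leaf_drought", 3),
        ("root_ctrl", 3), ("root_drought", 3),
    ),
}
_PRESET_GROUPS["all"] = (
    _PRESET_GROUPS["corm_growth"]
    + _PRESET_GROUPS["tissues"]
    + _PRESET_GROUPS["drought"]
)

PRESETS = tuple(_PRESET_GROUPS)


def _tubb_shifts(groups: tuple[tuple[str, int], ...]) -> dict[tuple[str, str], float]:
    # TUBB drifts progressively across the condition series: 1.5-cycle span
    labels = [label for label, _ in groups]
    span = len(labels) - 1
    return {
        ("TUBB", lab): 1.5 * i / span if span else 0.0
        for i, lab in enumerate(labels)
    }


def preset_config(name: str, seed: int, sample_effect_sd: float = 0.3) -> SyntheticConfig:
    """Named study designs: corm_growth (3x3), tissues (4x3), drought
    (2x3 per tissue), all (their union); 10 genes with one systematically
    regulated gene (TUBB) and one high-variance gene (EF1A)."""
    if name not in _PRESET_GROUPS:
        raise InputValidationError(
            f"unknown preset {name!r}; choose from {sorted(_PRESET_GROUPS)}"
        )
    groups = _PRESET_GROUPS[name]
    return SyntheticConfig(
        gene_ids=_GENES,
        groups=groups,
        baseline_ct=dict(_BASELINES),
        noise_sd=dict(_NOISE),
        seed=seed,
        sample_effect_sd=sample_effect_sd,
        group_shift=_tubb_shifts(groups),
    )


def unstable_gene_config(
    seed: int,
    n_genes: int = 10,
    n_groups: int = 3,
    n_per_group: int = 6,
    shift: float = 1.5,
    noise_unstable: float = 0.6,
    noise_stable: float = 0.2,
    sample_effect_sd: float = 0.3,
) -> SyntheticConfig:
    """Benchmark design: one gene with a ``shift``-cycle regulation in the
    last group and elevated noise; all others quiet.  Used for method
    recovery checks (the shifted gene should rank last everywhere)."""
    genes = tuple(f"G{i + 1:02d}" for i in range(n_genes))
    unstable = genes[-1]
    groups = tuple((f"grp{k + 1}", n_per_group) for k in range(n_groups))
    return SyntheticConfig(
        gene_ids=genes,
        groups=groups,
        baseline_ct={g: 20.0 + i for i, g in enumerate(genes)},
        noise_sd={g: (noise_unstable if g == unstable else noise_stable)
                  for g in genes},
        seed=seed,
        sample_effect_sd=sample_effect_sd,
        group_shift={(unstable, groups[-1][0]): shift},
    )
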