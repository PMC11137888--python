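"""Core containers for RT-qPCR stability analysis.

The central object is :class:`CtMatrix`, a genes x samples table of
cycle-threshold (Ct) values with an optional sample -> group mapping.
Ct is the PCR cycle at which fluorescence crosses a fixed threshold and
is logarithmic in starting template amount, so all downstream methods
treat it as a log-scale quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, InputValidationError, ParameterError

__all__ = [
    "CtMatrix",
    "FpkmMatrix",
    "QcReport",
    "GroupDesign",
    "StabilityResult",
    "ct_quality_check",
    "rank_ascending",
]


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.has_duplicates:
        dupes = labels[labels.duplicated()].unique().tolist()
        raise InputValidationError(f"duplicate {what} id(s): {dupes}")


@dataclass(frozen=True)
class CtMatrix:
    """Gene x sample matrix of Ct values (PCR cycles).

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are genes, columns are samples, values are Ct in cycles.
        All entries must be finite and strictly positive; the stability
        methods are complete-case and missing values are rejected here
        rather than imputed.
    groups : mapping of sample id -> group label, optional
        Experimental condition of each sample (growth stage, tissue,
        treatment...). When present every sample must be labeled.
    """

    data: pd.DataFrame
    groups: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise InputValidationError("CtMatrix.data must be a DataFrame")
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        if df.size == 0:
            raise InputValidationError("CtMatrix is empty")
        values = df.to_numpy(dtype=float, copy=False)
        bad = ~np.isfinite(values) | (values <= 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise InputValidationError(
                f"invalid Ct value {df.iat[i, j]!r} for gene "
                f"{df.index[i]!r}, sample {df.columns[j]!r}: Ct must be "
                "finite and > 0 (missing values are not imputed)"
            )
        if self.groups is not None:
            missing = [s for s in df.columns if s not in self.groups]
            if missing:
                raise DesignError(f"samples without a group label: {missing}")
            object.__setattr__(
                self, "groups", {s: self.groups[s] for s in df.columns}
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "CtMatrix":
        """Restrict to the given samples (order preserved as given)."""
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise InputValidationError(f"unknown sample id(s): {missing}")
        groups = None
        if self.groups is not None:
            groups = {s: self.groups[s] for s in sample_ids}
        return CtMatrix(self.data.loc[:, list(sample_ids)], groups)

    def subset_groups(self, group_labels: Sequence[str]) -> "CtMatrix":
        """Restrict to samples whose group label is in ``group_labels``."""
        if self.groups is None:
            raise DesignError("CtMatrix has no group labels")
        wanted = set(group_labels)
        unknown = wanted - set(self.groups.values())
        if unknown:
            raise InputValidationError(f"unknown group label(s): {sorted(unknown)}")
        keep = [s for s in self.sample_ids if self.groups[s] in wanted]
        return self.subset_samples(keep)

    def subset_genes(self, gene_ids: Sequence[str]) -> "CtMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise InputValidationError(f"unknown gene id(s): {missing}")
        return CtMatrix(self.data.loc[list(gene_ids)], self.groups)

    def design(self) -> "GroupDesign":
        if self.groups is None:
            raise DesignError("CtMatrix has no group labels")
        return GroupDesign(dict(self.groups))


@dataclass(frozen=True)
class FpkmMatrix:
    """Gene x sample matrix of RNA-seq FPKM values (>= 0)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise InputValidationError("FpkmMatrix.data must be a DataFrame")
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        values = df.to_numpy(dtype=float, copy=False)
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise InputValidationError(
                f"invalid FPKM value {df.iat[i, j]!r} for gene "
                f"{df.index[i]!r}, sample {df.columns[j]!r}: FPKM must be "
                "finite and >= 0"
            )

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
class GroupDesign:
    """Sample -> group assignment for grouped (inter-condition) analyses."""

    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.groups:
            raise DesignError("empty group design")

    @property
    def group_labels(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.groups.values():
            seen.setdefault(g, None)
        return list(seen)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.groups.values():
            out[g] = out.get(g, 0) + 1
        return out

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def validate_for(self, ct: CtMatrix, min_per_group: int = 2) -> None:
        missing = [s for s in ct.sample_ids if s not in self.groups]
        if missing:
            raise DesignError(f"samples without a group label: {missing}")
        counts: dict[str, int] = {}
        for s in ct.sample_ids:
            g = self.groups[s]
            counts[g] = counts.get(g, 0) + 1
        small = {g: n for g, n in counts.items() if n < min_per_group}
        if small:
            raise DesignError(
                f"each group needs >= {min_per_group} samples; too small: {small}"
            )


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QcReport:
    """Per-gene mean-Ct screen against the recommended working range.

    Genes with mean Ct at or below ``low`` are flagged ``low_ct`` (too
    abundant), at or above ``high`` flagged ``high_ct`` (too rare).  Flags
    are advisory: no gene is removed.
    """

    mean_ct: pd.Series
    flags: pd.Series
    low: float = 15.0
    high: float = 30.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean_ct": self.mean_ct, "flag": self.flags})


def ct_quality_check(ct: CtMatrix, low: float = 15.0, high: float = 30.0) -> QcReport:
    """Flag genes whose mean Ct falls outside the (low, high) working range.

    The mean is the arithmetic mean over all samples of the gene.  The
    customary range for a usable reference gene is mean Ct strictly
    between 15 and 30 cycles; boundary values are flagged.
    """
    if low >= high:
        raise ParameterError(f"QC bounds require low < high, got {low} >= {high}")
    mean_ct = ct.data.mean(axis=1)
    flags = pd.Series("ok", index=mean_ct.index, dtype=object)
    flags[mean_ct >= high] = "high_ct"
    flags[mean_ct <= low] = "low_ct"
    return QcReport(mean_ct=mean_ct, flags=flags, low=low, high=high)


# ---------------------------------------------------------------------------
# Stability results
# ---------------------------------------------------------------------------

def rank_ascending(values: pd.Series) -> pd.Series:
    """Integer ranks, 1 = smallest value; ties share the minimum rank."""
    return values.rank(method="min", ascending=True).astype(int)


@dataclass(frozen=True)
class StabilityResult:
    """One stability method's per-gene values and ranks (lower = more stable)."""

    method: str
    values: pd.Series
    ranks: pd.Series
    detail: Any = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.ranks.index):
            raise InputValidationError(
                f"{self.method}: values and ranks cover different genes"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.values.index, "value": self.values.to_numpy(),
             "rank": self.ranks.to_numpy()}
        ).sort_values(["rank", "gene"], kind="stable").reset_index(drop=True)
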