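"""Prevalence and multi-omic association statistics.

Gene-metabolite associations are assessed on untransformed paired values
with Spearman's rank correlation (rank statistics are invariant under the
monotone log transforms used for display, so transforming first would change
nothing); raw p-values are adjusted per metabolite panel with the
Benjamini-Hochberg step-up FDR procedure. Prevalence differences between
biological groups use a Pearson chi-square test of equal proportions on the
groups x {detected, not detected} table. For display layers, zeros are
accommodated with a pseudo-count equal to half the minimum non-zero value of
the dataset before log transformation (log2 for gene abundances, log10 for
metabolite concentrations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, InvalidInputError


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_raw: float
    n: int
    undefined: bool = False  # constant input: correlation undefined, not an error


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with pairwise deletion of missing values.

    Ties get average ranks; the p-value uses the t-distribution
    approximation, adequate for the sample sizes this pipeline targets
    (tens to hundreds of paired samples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise InsufficientDataError(f"need >= 4 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(float("nan"), float("nan"), n, undefined=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = sps.spearmanr(x, y)
    # a perfect correlation yields p = 0 exactly; keep p in (0, 1] so the
    # BH adjustment's domain contract holds
    p = min(max(float(p), float(np.finfo(float).tiny)), 1.0)
    return SpearmanResult(float(rho), p, n)


def spearman_exact(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Exact permutation p-value; intended for very small n (< 10)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = spearman(x, y)
    if res.undefined:
        return res
    exact = sps.permutation_test(
        (x, y),
        lambda a, b: sps.spearmanr(a, b).statistic,
        permutation_type="pairings",
        n_resamples=np.inf,
        alternative="two-sided",
    )
    return SpearmanResult(res.rho, float(exact.pvalue), res.n)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise InvalidInputError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PrevalenceTable:
    """Per-group detection counts for a chi-square test of equal proportions."""

    groups: list[str]
    n_samples: list[int]
    n_detected: list[int]

    def __post_init__(self) -> None:
        if len(self.groups) != len(self.n_samples) or len(self.groups) != len(self.n_detected):
            raise InvalidInputError("groups, n_samples, n_detected must align")
        for g, n, d in zip(self.groups, self.n_samples, self.n_detected):
            if not 0 <= d <= n:
                raise InvalidInputError(f"group {g!r}: n_detected must be in [0, n_samples]")

    def proportions(self) -> np.ndarray:
        return np.array(self.n_detected) / np.array(self.n_samples)


def prevalence_from_presence(presence: pd.Series, groups: pd.Series) -> PrevalenceTable:
    """Aggregate a boolean per-sample presence vector by group labels."""
    joined = pd.DataFrame({"present": presence, "group": groups}).dropna()
    agg = joined.groupby("group")["present"].agg(["count", "sum"])
    return PrevalenceTable(
        [str(g) for g in agg.index],
        [int(v) for v in agg["count"]],
        [int(v) for v in agg["sum"]],
    )


def chi_square_proportions(
    table: PrevalenceTable, yates: bool = False
) -> tuple[float, float, int]:
    """Pearson chi-square on the groups x {detected, not-detected} table.

    No continuity correction by default; returns (chi2, p, df).
    """
    if len(table.groups) < 2:
        raise InvalidInputError("need at least two groups")
    detected = np.array(table.n_detected, dtype=float)
    not_detected = np.array(table.n_samples, dtype=float) - detected
    contingency = np.column_stack([detected, not_detected])
    expected = sps.contingency.expected_freq(contingency)
    if np.any(expected <= 0):
        raise InvalidInputError("degenerate table: zero expected cell count")
    chi2, p, df, _ = sps.chi2_contingency(contingency, correction=yates)
    return float(chi2), float(p), int(df)


def half_min_pseudocount(
    values: pd.DataFrame | np.ndarray, per_column: bool = False
) -> tuple[np.ndarray | pd.DataFrame, float | np.ndarray]:
    """Add half the minimum non-zero value of the dataset; returns (shifted, pc).

    ``per_column=True`` computes one pseudo-count per column instead of one
    for the whole matrix.
    """
    arr = np.asarray(values, dtype=float)
    if per_column:
        pcs = np.empty(arr.shape[1])
        for j in range(arr.shape[1]):
            col = arr[:, j]
            nz = col[col > 0]
            if nz.size == 0:
                raise InvalidInputError(f"column {j} has no non-zero values")
            pcs[j] = nz.min() / 2.0
        shifted = arr + pcs
        pc: float | np.ndarray = pcs
    else:
        nz = arr[arr > 0]
        if nz.size == 0:
            raise InvalidInputError("matrix has no non-zero values")
        pc = float(nz.min() / 2.0)
        shifted = arr + pc
    if isinstance(values, pd.DataFrame):
        shifted = pd.DataFrame(shifted, index=values.index, columns=values.columns)
    return shifted, pc


def log_transform_layer(values: pd.DataFrame, base: int, per_column: bool = False) -> pd.DataFrame:
    """Display layer: half-minimum pseudo-count then log2 or log10."""
    shifted, _ = half_min_pseudocount(values, per_column=per_column)
    log = np.log2 if base == 2 else np.log10
    if base not in (2, 10):
        raise InvalidInputError("base must be 2 or 10")
    return pd.DataFrame(log(np.asarray(shifted, dtype=float)), index=values.index, columns=values.columns)


@dataclass(frozen=True)
class AssociationRecord:
    gene_set_id: str
    metabolite_id: str
    n: int
    rho: float
    p_raw: float
    p_adj: float


def correlate_multiomics(
    gene_abundance: pd.Series,
    metabolites: pd.DataFrame,
    gene_set_id: str = "metalloBSH",
    min_pairs: int = 4,
) -> list[AssociationRecord]:
    """Spearman correlation of a gene-set abundance against a metabolite panel.

    Sample ids are intersected (paired data only); missing metabolite values
    are dropped pairwise; BH adjustment runs across the panel. Correlations
    use untransformed values.
    """
    shared = gene_abundance.index.intersection(metabolites.index)
    if len(shared) < min_pairs:
        warnings.warn(f"only {len(shared)} paired samples; no associations computed", stacklevel=2)
        return []
    abundance = gene_abundance.loc[shared].astype(float)
    panel = metabolites.loc[shared]
    partial: list[tuple[str, SpearmanResult]] = []
    for metabolite in panel.columns:
        try:
            res = spearman(abundance.to_numpy(), panel[metabolite].to_numpy(dtype=float))
        except InsufficientDataError:
            continue
        if not res.undefined:
            partial.append((str(metabolite), res))
    if not partial:
        return []
    adjusted = bh_adjust([r.p_raw for _, r in partial])
    return [
        AssociationRecord(gene_set_id, met, res.n, res.rho, res.p_raw, float(p_adj))
        for (met, res), p_adj in zip(partial, adjusted)
    ]


def associations_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_set": r.gene_set_id,
                "metabolite": r.metabolite_id,
                "n": r.n,
                "rho": r.rho,
                "p": r.p_raw,
                "p_adj": r.p_adj,
            }
            for r in records
        ]
    )
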