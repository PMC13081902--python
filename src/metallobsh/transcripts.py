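"""Transcript quantification and expression ranking.

Per-replicate counts are converted to transcripts per million (TPM) using
gene lengths, transformed as log10(TPM+1), summarized across replicates by
the median, and ranked descending. Genes in the top decile / top centile of
the ranking are flagged (ceiling boundary, deterministic tie-break by id).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError


def tpm(counts: Sequence[float] | pd.Series, lengths: Sequence[float] | pd.Series) -> np.ndarray:
    """TPM for one replicate: length-normalized rates scaled to sum to 1e6."""
    c = np.asarray(counts, dtype=float)
    l = np.asarray(lengths, dtype=float)
    if c.shape != l.shape:
        raise InvalidInputError("counts and lengths must align")
    if np.any(l <= 0):
        raise InvalidInputError("gene lengths must be > 0")
    if np.any(c < 0):
        raise InvalidInputError("counts must be non-negative")
    rate = c / l
    total = rate.sum()
    if total == 0:
        raise InvalidInputError("all-zero count column")
    return 1e6 * rate / total


def tpm_table(counts: pd.DataFrame, lengths: Mapping[str, float] | pd.Series) -> pd.DataFrame:
    """TPM matrix (genes x replicates) from a count matrix and gene lengths."""
    lv = pd.Series(lengths).reindex(counts.index)
    if lv.isna().any():
        raise InvalidInputError(f"genes without length: {list(lv.index[lv.isna()])}")
    return counts.apply(lambda col: pd.Series(tpm(col, lv), index=counts.index), axis=0)


def rank_genes(
    tpm_matrix: pd.DataFrame,
    transform_first: bool = True,
) -> pd.DataFrame:
    """Median-across-replicates expression ranking with percentile flags.

    Returns a DataFrame indexed by gene with columns ``median_log_tpm``,
    ``rank`` (1 = highest), ``top10`` and ``top1``. With
    ``transform_first=True`` (default) the log10(TPM+1) transform is applied
    before taking the median; the alternative order medians raw TPM then
    transforms — for an odd replicate count the two coincide, and the
    ranking itself is invariant either way because the transform is monotone.
    """
    if tpm_matrix.shape[1] < 1:
        raise InvalidInputError("need at least one replicate")
    if transform_first:
        med = np.log10(tpm_matrix + 1.0).median(axis=1)
    else:
        med = np.log10(tpm_matrix.median(axis=1) + 1.0)
    order = sorted(med.index, key=lambda g: (-med[g], str(g)))
    n = len(order)
    n_top10 = math.ceil(0.10 * n)
    n_top1 = math.ceil(0.01 * n)
    out = pd.DataFrame(index=pd.Index(order, name=tpm_matrix.index.name or "gene"))
    out["median_log_tpm"] = med.loc[order]
    out["rank"] = np.arange(1, n + 1)
    out["top10"] = out["rank"] <= n_top10
    out["top1"] = out["rank"] <= n_top1
    return out
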