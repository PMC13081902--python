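"""Gene abundance quantification: counts -> RPKM -> AGS-normalized -> presence.

Assigned read counts are normalized to Reads Per Kilobase Million (RPKM)
using the protein's coding length and the sample's total read depth, then
divided by the sample's average genome size (AGS, in Mb) to correct for
community genome-size differences. A gene (or the summed family) is called
present in a sample when its AGS-normalized abundance strictly exceeds a
threshold (1e-4 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import InvalidInputError
from .search import MappingResult

PRESENCE_THRESHOLD = 1e-4


@dataclass(frozen=True)
class SampleStats:
    """Per-sample sequencing depth and average genome size."""

    sample_id: str
    total_reads: int
    ags_bp: float

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise InvalidInputError(f"sample {self.sample_id!r}: total_reads must be > 0")
        if self.ags_bp <= 0:
            raise InvalidInputError(f"sample {self.sample_id!r}: ags_bp must be > 0")


def read_sample_stats(path: str | Path) -> dict[str, SampleStats]:
    df = pd.read_csv(path, sep="\t")
    return {
        row.sample_id: SampleStats(str(row.sample_id), int(row.total_reads), float(row.ags_bp))
        for row in df.itertuples()
    }


def tally(mapping: MappingResult, target_ids: Sequence[str] | None = None) -> pd.Series:
    """Assigned-read count per target; sums to the number of assigned reads."""
    counts = mapping.counts_by_target()
    if target_ids is None:
        target_ids = sorted(counts)
    return pd.Series({t: counts.get(t, 0) for t in target_ids}, dtype=int, name="raw_count")


def rpkm(
    count: float,
    protein_length_aa: int,
    total_reads: int,
    length_units: str = "coding_nt",
) -> float:
    """Reads per kilobase (of coding sequence) per million total reads.

    ``length_units='coding_nt'`` (default) converts the protein length to
    coding nucleotides (aa * 3); ``'aa'`` normalizes per kilo-amino-acid
    instead. Rank-based downstream statistics are insensitive to the choice.
    """
    if protein_length_aa <= 0:
        raise InvalidInputError("protein_length_aa must be > 0")
    if total_reads <= 0:
        raise InvalidInputError("total_reads must be > 0")
    length = protein_length_aa * (3 if length_units == "coding_nt" else 1)
    return count / ((length / 1e3) * (total_reads / 1e6))


def ags_normalize(rpkm_value: float, stats: SampleStats) -> float:
    """Divide RPKM by the sample's average genome size in Mb."""
    return rpkm_value / (stats.ags_bp / 1e6)


def call_presence(ags_norm_value: float, threshold: float = PRESENCE_THRESHOLD) -> bool:
    """Present iff the AGS-normalized abundance strictly exceeds the threshold."""
    return ags_norm_value > threshold


@dataclass
class AbundanceTable:
    """Per-sample per-gene abundance layers (samples x genes DataFrames)."""

    raw_count: pd.DataFrame
    rpkm: pd.DataFrame
    ags_norm: pd.DataFrame
    presence: pd.DataFrame
    threshold: float = PRESENCE_THRESHOLD

    def family_abundance(self) -> pd.Series:
        """Summed AGS-normalized abundance of the whole target family per sample."""
        return self.ags_norm.sum(axis=1)

    def family_presence(self) -> pd.Series:
        """Family present iff its summed abundance exceeds the threshold."""
        return self.family_abundance() > self.threshold

    def write_tsv(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        for layer in ("raw_count", "rpkm", "ags_norm", "presence"):
            getattr(self, layer).to_csv(f"{prefix}.{layer}.tsv", sep="\t")


def quantify(
    mappings: Mapping[str, MappingResult],
    protein_lengths: Mapping[str, int],
    sample_stats: Mapping[str, SampleStats],
    target_ids: Sequence[str] | None = None,
    threshold: float = PRESENCE_THRESHOLD,
    length_units: str = "coding_nt",
) -> AbundanceTable:
    """Build the full abundance table from per-sample mapping results."""
    if target_ids is None:
        target_ids = sorted({t for m in mappings.values() for t in m.counts_by_target()})
    samples = sorted(mappings)
    missing = set(samples) - set(sample_stats)
    if missing:
        raise InvalidInputError(f"samples without stats: {sorted(missing)}")
    raw = pd.DataFrame(
        {s: tally(mappings[s], target_ids) for s in samples}, dtype=int
    ).T.reindex(columns=target_ids)
    rpkm_df = pd.DataFrame(index=samples, columns=list(target_ids), dtype=float)
    ags_df = pd.DataFrame(index=samples, columns=list(target_ids), dtype=float)
    for s in samples:
        stats = sample_stats[s]
        for g in target_ids:
            r = rpkm(float(raw.at[s, g]), protein_lengths[g], stats.total_reads, length_units)
            rpkm_df.at[s, g] = r
            ags_df.at[s, g] = ags_normalize(r, stats)
    presence = ags_df > threshold
    return AbundanceTable(raw, rpkm_df, ags_df, presence, threshold)
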