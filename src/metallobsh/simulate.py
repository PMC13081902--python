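"""Synthetic data with known ground truth for every pipeline stage.

Everything the pipeline consumes can be generated here with a recorded
truth: protein families at controlled pairwise identities (with active-site
columns optionally protected), nucleotide coding sequences obtained by
deterministic reverse translation, short-read metagenomes with per-read
source labels, metabolite tables with a calibrated monotone coupling to gene
abundance, replicate transcript-count tables around a planted expression
profile, and Michaelis-Menten initial-rate datasets.

All randomness flows from a single :class:`numpy.random.Generator`, so a
fixed seed reproduces every dataset byte-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alignment import STANDARD_AA, ProteinRecord, global_align
from .assay import KineticsDataset, michaelis_menten
from .curation import KeyResidueProfile, bwbsh1_profile
from .errors import GenerationError, InvalidInputError
from .io import ReadRecord

#: most-frequent E. coli K-12 codon per amino acid — deterministic reverse
#: translation that round-trips exactly under standard-code translation
ECOLI_PREFERRED_CODON: dict[str, str] = {
    "A": "GCG", "R": "CGC", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def reverse_translate(protein: ProteinRecord) -> str:
    """Deterministic CDS using the most frequent E. coli codon per residue."""
    try:
        return "".join(ECOLI_PREFERRED_CODON[aa] for aa in protein.seq)
    except KeyError as exc:
        raise InvalidInputError(f"cannot reverse-translate residue {exc}") from exc


def random_protein(length: int, rng: np.random.Generator, prefix: str = "prot") -> ProteinRecord:
    seq = "".join(rng.choice(list(STANDARD_AA), size=length))
    return ProteinRecord(f"{prefix}_{rng.integers(1, 10**9)}", seq)


# ---------------------------------------------------------------------------
# Controlled-identity homolog generation


def mutate_to_identity(
    seq: ProteinRecord,
    target_identity: float,
    rng: np.random.Generator,
    protect: set[int] | None = None,
    new_id: str | None = None,
    indel_frac: float = 0.0,
    tolerance: float = 2.0,
    max_attempts: int = 40,
) -> ProteinRecord:
    """Random homolog at a controlled global identity to the source.

    Substitutes random positions (never the 1-based ``protect`` columns, so
    active-site profiles can be preserved) and optionally introduces a small
    number of indels (at most ``indel_frac`` of the length), re-measuring
    global percent identity until it falls within ``tolerance`` points of
    the target.
    """
    if not 0 < target_identity <= 100:
        raise InvalidInputError("target_identity must be in (0, 100]")
    protect = protect or set()
    length = seq.length_aa
    if target_identity == 100:
        return ProteinRecord(new_id or f"{seq.id}_h100", seq.seq)
    mutable = [i for i in range(length) if (i + 1) not in protect]
    aa = list(STANDARD_AA)

    def _apply(n_sub: int) -> str:
        chars = list(seq.seq)
        picks = rng.choice(len(mutable), size=min(n_sub, len(mutable)), replace=False)
        for p in picks:
            i = mutable[p]
            choices = [c for c in aa if c != chars[i]]
            chars[i] = choices[rng.integers(len(choices))]
        if indel_frac > 0:
            n_indel = int(indel_frac * length * rng.random())
            for _ in range(n_indel):
                i = int(rng.integers(len(chars)))
                if (i + 1) in protect or len(chars) <= 2:
                    continue
                if rng.random() < 0.5:
                    chars.insert(i, aa[rng.integers(len(aa))])
                else:
                    del chars[i]
        return "".join(chars)

    n_sub = round(length * (1 - target_identity / 100.0))
    for _ in range(max_attempts):
        candidate = ProteinRecord(new_id or f"{seq.id}_h{target_identity:g}", _apply(n_sub))
        measured = global_align(seq, candidate).identity_pct
        if abs(measured - target_identity) <= tolerance:
            return candidate
        # adjust mutation load proportionally to the miss
        n_sub = max(1, n_sub + round(length * (measured - target_identity) / 100.0 / 2) or 1)
    raise GenerationError(
        f"could not reach identity {target_identity}% within {max_attempts} attempts"
    )


def synthetic_reference(
    rng: np.random.Generator,
    length: int = 650,
    profile: KeyResidueProfile | None = None,
    seq_id: str = "BSH_ref",
) -> tuple[ProteinRecord, KeyResidueProfile]:
    """Random full-length reference with the canonical active-site residues planted."""
    profile = profile or bwbsh1_profile(seq_id)
    if max(profile.all_positions) > length:
        raise InvalidInputError("reference length too short for the residue profile")
    chars = list(rng.choice(list(STANDARD_AA), size=length))
    for pos, aa in profile.all_positions.items():
        chars[pos - 1] = aa
    record = ProteinRecord(seq_id, "".join(chars))
    return record, KeyResidueProfile(seq_id, dict(profile.metal_positions), dict(profile.substrate_positions))


@dataclass
class SyntheticFamily:
    """A planted metalloBSH-like family plus decoys, with its residue profile."""

    reference: ProteinRecord
    profile: KeyResidueProfile
    targets: list[ProteinRecord]  # family members incl. the reference
    decoys: list[ProteinRecord]
    background: list[ProteinRecord]  # community genes absent from the database

    def all_db_records(self) -> list[ProteinRecord]:
        return self.targets + self.decoys

    def community_records(self) -> list[ProteinRecord]:
        return self.targets + self.decoys + self.background


def synthetic_family(
    rng: np.random.Generator,
    length: int = 650,
    homolog_identities: Sequence[float] = (80.0, 60.0),
    n_decoys: int = 4,
    decoy_identity: float = 35.0,
    n_background: int = 4,
) -> SyntheticFamily:
    """Reference + protected homologs, unprotected low-identity decoys, background."""
    reference, profile = synthetic_reference(rng, length=length)
    protect = set(profile.all_positions)
    targets = [reference]
    for i, ident in enumerate(homolog_identities):
        targets.append(
            mutate_to_identity(reference, ident, rng, protect=protect, new_id=f"BSH_hom{i + 1}")
        )
    decoys = []
    for i in range(n_decoys):
        if i % 2 == 0:
            # distant relative of the family, active-site columns NOT protected
            decoys.append(
                mutate_to_identity(reference, decoy_identity, rng, new_id=f"decoy_rel{i + 1}")
            )
        else:
            d = random_protein(length, rng)
            decoys.append(ProteinRecord(f"decoy_rand{i + 1}", d.seq))
    background = [
        ProteinRecord(f"bg_{i + 1}", random_protein(length, rng).seq) for i in range(n_background)
    ]
    return SyntheticFamily(reference, profile, targets, decoys, background)


# ---------------------------------------------------------------------------
# Short-read metagenome simulation


def simulate_metagenome(
    cds_by_gene: Mapping[str, str],
    abundances: Mapping[str, float],
    n_reads: int,
    rng: np.random.Generator,
    read_len: int = 120,
    error_rate: float = 0.0,
    sample_id: str = "S1",
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Draw substitution-error short reads from coding sequences.

    Genes are sampled proportionally to ``abundance * cds_length``, start
    positions uniformly, strand uniformly; per-base substitution errors at
    ``error_rate``. Returns the reads and a truth table with one row per
    read (read_id, source_gene, start, strand, n_errors).
    """
    genes = sorted(cds_by_gene)
    if not genes:
        raise InvalidInputError("no coding sequences supplied")
    for g in genes:
        if len(cds_by_gene[g]) < read_len:
            raise InvalidInputError(f"CDS of {g!r} shorter than the read length")
    weights = np.array([abundances.get(g, 0.0) * len(cds_by_gene[g]) for g in genes])
    if weights.sum() <= 0:
        raise InvalidInputError("all abundances are zero")
    probs = weights / weights.sum()
    choices = rng.choice(len(genes), size=n_reads, p=probs)
    bases = np.array(list("ACGT"))
    reads: list[ReadRecord] = []
    truth_rows = []
    for i, gi in enumerate(choices):
        gene = genes[gi]
        cds = cds_by_gene[gene]
        start = int(rng.integers(0, len(cds) - read_len + 1))
        fragment = cds[start : start + read_len]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            fragment = reverse_complement(fragment)
        n_err = 0
        if error_rate > 0:
            chars = list(fragment)
            err_mask = rng.random(read_len) < error_rate
            for j in np.flatnonzero(err_mask):
                alternatives = bases[bases != chars[j]]
                chars[j] = alternatives[rng.integers(3)]
                n_err += 1
            fragment = "".join(chars)
        read_id = f"{sample_id}_r{i}"
        reads.append(ReadRecord(read_id, fragment, "I" * read_len))
        truth_rows.append((read_id, gene, start, strand, n_err))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "source_gene", "start", "strand", "n_errors"])
    return reads, truth


# ---------------------------------------------------------------------------
# Coupled metabolome simulation


def simulate_metabolome(
    gene_abundance: pd.Series,
    rng: np.random.Generator,
    rho_target: float = -0.45,
    noise_sd: float | None = None,
    n_null: int = 3,
    metabolite_id: str = "taurocholate",
) -> pd.DataFrame:
    """Metabolite panel with a calibrated monotone coupling to gene abundance.

    The coupled metabolite is built on the normal scores of the abundance
    ranks: for a bivariate-normal pair with Pearson correlation r the
    population Spearman correlation is (6/pi)*asin(r/2), so the mixing
    weight r = 2*sin(pi*rho_target/6) makes the realized Spearman
    correlation approximately ``rho_target`` in expectation. Values are
    exponentiated to look like concentrations (rank statistics are
    unaffected). ``noise_sd`` overrides the calibrated noise when given
    (0 gives a perfectly monotone coupling, Spearman = sign(rho_target)).
    Independent log-normal null metabolites are appended.
    """
    if not -1 <= rho_target <= 1:
        raise InvalidInputError("rho_target must lie in [-1, 1]")
    n = len(gene_abundance)
    if n < 4:
        raise InvalidInputError("need at least 4 samples")
    ranks = sps.rankdata(gene_abundance.to_numpy(dtype=float))
    z = sps.norm.ppf((ranks - 0.375) / (n + 0.25))  # Blom normal scores
    direction = 1.0 if rho_target >= 0 else -1.0
    if noise_sd is None:
        r = 2.0 * math.sin(math.pi * abs(rho_target) / 6.0)
        signal = r * z
        noise = math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
    else:
        signal = z
        noise = noise_sd * rng.standard_normal(n)
    coupled = np.exp(direction * (signal + noise))
    data = {metabolite_id: coupled}
    for j in range(n_null):
        data[f"null_{j + 1}"] = np.exp(rng.standard_normal(n))
    return pd.DataFrame(data, index=gene_abundance.index)


# ---------------------------------------------------------------------------
# Transcript counts and kinetics


def simulate_transcripts(
    rng: np.random.Generator,
    n_genes: int = 1000,
    n_replicates: int = 4,
    n_high: int = 3,
    fold: float = 10.0,
    mean_depth: int = 200_000,
    dispersion: float = 0.1,
    expr_sigma: float = 0.5,
    length_range: tuple[int, int] = (300, 3000),
) -> tuple[pd.DataFrame, pd.Series, pd.Series, list[str]]:
    """Replicate count matrix around a planted expression profile.

    Returns (counts genes x replicates, gene_lengths, true relative
    expression, ids of the planted highly-expressed genes). Counts are
    negative-binomial around mean depth * expression * length share.
    Baseline expression is log-normal with a moderate spread
    (``expr_sigma``) so that a planted fold change is a fold over the
    typical gene, not over a tail of an already-broad distribution.
    """
    genes = [f"g{i:04d}" for i in range(n_genes)]
    lengths = pd.Series(rng.integers(length_range[0], length_range[1] + 1, size=n_genes), index=genes)
    expr = np.exp(rng.normal(0.0, expr_sigma, size=n_genes))
    high_ids = list(rng.choice(genes, size=n_high, replace=False))
    expr[[genes.index(g) for g in high_ids]] *= fold
    expr = expr / expr.sum()
    rate = expr * lengths.to_numpy()
    frac = rate / rate.sum()
    counts = np.empty((n_genes, n_replicates), dtype=int)
    r_nb = 1.0 / dispersion
    for rep in range(n_replicates):
        mu = frac * mean_depth
        p = r_nb / (r_nb + mu)
        counts[:, rep] = rng.negative_binomial(r_nb, p)
    counts_df = pd.DataFrame(counts, index=genes, columns=[f"rep{r + 1}" for r in range(n_replicates)])
    return counts_df, lengths, pd.Series(expr, index=genes, name="true_expr"), high_ids


def simulate_kinetics(
    rng: np.random.Generator,
    vmax: float = 0.5,
    km: float = 250.0,
    enzyme_conc_nm: float = 5.0,
    substrate_levels: Sequence[float] = (10, 25, 50, 100, 250, 500, 1000, 2500, 5000, 10000, 15000, 20000),
    noise_frac: float = 0.0,
) -> KineticsDataset:
    """Initial-rate dataset v = Vmax*S/(Km+S)*(1+eps), eps ~ N(0, noise_frac^2).

    Default substrate span mirrors a 10-20000 uM titration of a taurine
    conjugate; rates are clipped at a small positive floor so multiplicative
    noise cannot produce non-physical negative rates.
    """
    s = np.asarray(substrate_levels, dtype=float)
    v = michaelis_menten(s, vmax, km)
    if noise_frac > 0:
        v = v * (1.0 + noise_frac * rng.standard_normal(len(s)))
        v = np.maximum(v, 1e-12)
    return KineticsDataset(tuple(s), tuple(float(x) for x in v), enzyme_conc_nm)


# ---------------------------------------------------------------------------
# Ground-truth ledger


@dataclass
class SimTruth:
    """Serializable record of everything a synthetic study planted."""

    seed: int
    abundances: dict[str, dict[str, float]] = field(default_factory=dict)  # sample -> gene -> rel. abundance
    read_sources: dict[str, str] = field(default_factory=dict)  # read_id -> source gene
    coupling: dict[str, float] = field(default_factory=dict)  # rho_target, noise parameters
    presence: dict[str, bool] = field(default_factory=dict)  # sample -> family truly present
    kinetics: dict[str, float] = field(default_factory=dict)  # vmax, km

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))
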