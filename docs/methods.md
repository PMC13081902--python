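# Methods

This note documents the models, conventions and numerical choices behind
`metallobsh`, and what the synthetic-data generators do and do not emulate.

## Scientific setting

Bile salt hydrolases (BSHs) deconjugate glycine- or taurine-conjugated bile
acids in the gut. Alongside the long-known cysteine-dependent Ntn-hydrolase
BSHs, a second class exists: secreted, metal-dependent amidohydrolases with a
dinuclear zinc site (metalloBSHs), found chiefly in *Desulfovibrionaceae*
such as *Bilophila wadsworthia*. Because these enzymes share essentially no
sequence similarity with Ntn-BSHs, quantifying them in metagenomes requires
(i) delineating the family from the broader amidohydrolase superfamily and
(ii) counting translated-read hits against a curated target/decoy database.
This package implements that computational pipeline end to end and validates
it on synthetic communities with known ground truth.

## Pairwise alignment

Global (Needleman–Wunsch) and local (Smith–Waterman) alignment with affine
gaps and BLOSUM62 scoring, via Biopython's `PairwiseAligner`. Conventions:

- A gap of length *L* costs `gap_open + L * gap_extend`. Defaults:
  global 10/0.5, local 11/1. The identities reported in the literature for
  metalloBSH homolog pairs (e.g. ~50.9% between the two *B. wadsworthia*
  3_1_6 paralogs) do not come with a named aligner or parameter set; these
  defaults are a reasoned emulation of common global-aligner and
  translated-search settings, and every threshold that depends on them is
  configurable.
- Percent identity divides by **all alignment columns** (gap columns
  included). `denominator="shorter"` divides by the shorter sequence length
  instead; the choice matters for partial overlaps, and the convention behind
  published identity values is rarely stated.
- `X` scores 0 against everything and never counts as an identity; the stop
  symbol `*` (from translated frames) keeps its BLOSUM62 penalty (−4),
  discouraging alignments across stops, and also never counts as identity.
- Co-optimal traceback ties resolve deterministically (Biopython's first
  reported alignment; the read-search kernel prefers diagonal > up > left).

A numba-compiled Smith–Waterman kernel (`_sw.py`) accelerates the
translated-search hot path. It implements the identical scoring contract and
is cross-checked in the test suite both against exhaustive alignment-path
enumeration (short sequences) and against the Biopython-backed module on
simulated reads.

## Family delineation

1. **SSN**: all-vs-all global alignment; edge iff score ≥ cutoff and
   identity ≥ minimum (defaults 122 and 31%). The published SSN score cutoff
   comes from an E-value-derived, tool-specific score; raw alignment scores
   are not on that scale, so the default here is calibrated such that
   within-family pairs (≥31% identity over full length) connect and
   unrelated pairs do not — which the synthetic two-block tests verify
   explicitly. Both thresholds are plain parameters.
2. **Cluster extraction**: connected component containing the seed enzyme.
3. **Greedy clustering** (default 65% identity) for redundancy reduction:
   sequences are visited in descending length; each joins the first cluster
   whose representative it matches at ≥ threshold; the representative is the
   member with the highest summed alignment score to its co-members (ties:
   longer, then lexicographic id). The published pipeline's clustering tool
   internals are not reproduced; only the grouping contract is.
4. **Active-site filter**: candidates are globally aligned to the
   full-length reference; the residue aligned to each profile column must
   equal the expectation. The canonical profile holds the metal-coordinating
   set H110/H112/KCX373/H441/H474/D583 (KCX, carboxylated lysine, is matched
   as K — carboxylation is invisible in primary sequence) and the
   substrate-recognition set S194/H196/Q381/N443/H544, in BwBSH1 numbering.
   Truncations that lose any metal ligand fail ("incomplete dinuclear metal
   center"); the substrate set is required by default.
5. **Database assembly**: cluster members passing the filter are targets;
   all other input sequences — outside the cluster or failing the filter —
   are decoys, so that reads more similar to non-family amidohydrolases are
   never counted toward the family.

## Translated search and assignment

Reads are translated in all six frames (stops as `*`, N-containing codons as
`X`, trailing partial codons dropped). Each frame is locally aligned against
database entries sharing at least one amino-acid 4-mer (configurable k and
required shared-k-mer count; the end-to-end study driver uses two shared
4-mers, which leaves >90%-identity matches — sharing dozens of k-mers —
untouched while skipping nearly all random-frame alignments). Hits with a
local score below 40 are not reported. E-value calibration of production
translated-search tools is deliberately not reproduced: the downstream
quantities depend on the identity filter and best-hit rule, not on E-values.

Assignment: hits at identity ≤ 90% are discarded (strictly greater, matching
the stated filter); among survivors each read goes to the highest-identity
protein (ties: higher score, then lexicographically smaller id); a read whose
winner is a decoy is discarded and counted. Identity is computed over the
local alignment length by default (`"read"` uses the translated frame
length); which convention the original analysis used is unstated.

## Abundance quantification

`RPKM = count / ((3·L_aa/1000) · (total_reads/10⁶))` — protein length is
converted to coding-nucleotide kilobases by default (`aa` kilounits
available), then divided by the sample's average genome size in Mb. AGS is a
per-sample input; its estimation from raw reads is out of scope. Presence is
a strict `> 1e-4` threshold on the AGS-normalized value. Because downstream
statistics are rank-based, consistent units matter more than absolute scale;
the synthetic spike-ins are calibrated around the default threshold rather
than asserting unit equivalence with any external study. Family-level
abundance is the sum of per-target AGS-normalized values per sample
(single-family correlations use this summed layer).

## Association statistics

- **Spearman** on untransformed paired values (pairwise deletion of missing
  values; average ranks for ties; t-approximation p-values, adequate for the
  tens-to-hundreds of samples this pipeline targets; an exact permutation
  option exists for very small n). Rank correlation is invariant under the
  monotone log transforms used for display, which the tests assert directly.
  A perfect correlation's p-value is clipped to the smallest positive float
  so the BH domain contract (p ∈ (0,1]) holds.
- **Benjamini–Hochberg** step-up across each metabolite panel (one family
  per panel per sample type; a global family across panels would be an
  alternative reading and is left to the caller).
- **Chi-square test of equal proportions** on the groups × {detected, not
  detected} table, no continuity correction by default (Yates available).
- **Display transforms**: a pseudo-count of half the minimum non-zero value
  of the whole dataset (per-column mode available — the phrase "each
  respective dataset" is ambiguous) before log₂ (gene abundances) or log₁₀
  (metabolites). Transforms feed plots only, never the statistics.

## Transcript ranking

TPM per replicate (`10⁶ · rate_g / Σ rate`, rate = count/length), log₁₀(TPM+1),
median across replicates (transform-then-median by default; the orders
coincide for odd replicate counts and the ranking is invariant either way),
descending sort with lexicographic tie-break, top-decile/top-centile flags at
`ceil(0.10·n)` / `ceil(0.01·n)` (no boundary rule is stated in the
literature; ceiling is this package's fixed choice).

## Enzyme-assay analytics

- **Michaelis–Menten**: unweighted least squares of `v = Vmax·S/(Km+S)`
  (no weighting is stated for the published fits), initialized at
  `Vmax₀ = max(v)` and `Km₀ = S` at half-max, non-negative bounds,
  non-convergence flagged rather than raised. `kcat = Vmax/[E]`,
  `kcat/Km` in M⁻¹s⁻¹. The published kcat/Km magnitudes (~1.7×10⁵ M⁻¹s⁻¹)
  serve only as realistic simulation ground truth; they cannot be recomputed
  without the raw assay data and are never asserted.
- **Relative activity / conversion rate**: `100·test/control` under initial
  rate conditions and `100·variant/wild-type` after end-point incubation
  respectively; pH-profile and dose-response data are reported as tables of
  these percentages, not fitted to 4PL curves.
- **Adduct m/z**: `(Σ counts·monoisotopic_mass − z·m_e)/|z|`, full-precision
  IUPAC/CODATA monoisotopic masses, electron mass included (printed
  "calculated" HRMS values include it); `[2M+X]⁺` doubles the neutral
  formula before adduct formation.
- **Metal-pair distance**: closest distinct pair of same-element atoms
  within one chain (coincident duplicates rejected), for checking dinuclear
  site geometry against the canonical ~3.95 Å Zn–Zn separation.

## Synthetic data: what is emulated, and what is not

All generators draw from one `numpy.random.Generator`; a fixed seed
regenerates every dataset byte-identically.

- **Protein families**: a random full-length (650 aa) reference with the
  canonical active-site residues planted at their BwBSH1 positions;
  homologs at controlled global identity (substitutions re-measured until
  within tolerance; active-site columns optionally protected; indels
  optional and off by default so per-read identity stays analytically
  predictable); decoys are distant unprotected relatives (~35% identity,
  which join the SSN cluster but fail the residue filter — exercising the
  decoy-assembly path) plus unrelated random sequences.
- **CDS**: deterministic reverse translation with most-frequent *E. coli*
  codons, so frame +1 of an error-free read translates back exactly.
- **Reads**: drawn from genes proportionally to abundance × CDS length,
  uniform start and strand, per-base substitution errors (no indels, no
  quality-score error profiles, no paired ends, no real-genome background).
- **Metabolome**: the coupled metabolite is built on Blom normal scores of
  the abundance ranks with mixing weight `r = 2·sin(π·ρ_target/6)` — the
  bivariate-normal relation between Pearson and Spearman correlation — so
  the realized Spearman correlation is ρ_target in expectation; values are
  exponentiated into concentration-like positives; independent log-normal
  nulls are appended. The default target is ρ = −0.45 (a negative
  gene-abundance/taurine-conjugate coupling of realistic strength).
- **Transcripts**: log-normal baseline expression (σ = 0.5, so a planted
  10× fold is a fold over the typical gene rather than over an already
  decade-spanning baseline — real transcriptomes are broader than this),
  negative-binomial counts (dispersion 0.1) around depth × expression ×
  length shares.
- **Kinetics**: `v = Vmax·S/(Km+S)·(1+ε)`, ε ~ N(0, σ²), over a 10–20000 µM
  substrate titration, rates floored at a small positive value.

## End-to-end study and problem sizes

`run_synthetic_study` chains everything: family generation → SSN → cluster →
residue filter → target/decoy database → per-sample read simulation →
translated search → RPKM/AGS → summed family abundance → Spearman/BH against
a metabolome coupled (ρ = −0.45) to the *true* abundance. Defaults: 209
samples (matching the intestinal-cohort scale the statistics target), 300
reads of 120 nt per sample at 1% substitution error — enough counts per
sample for rank statistics while keeping a 20-seed sweep to minutes on one
CPU; per-sample family fractions are logit-normal (roughly 2–40%). The
standalone read simulator defaults to larger read sets (2×10⁴) for
single-sample use.

Passing these synthetic recovery tests shows the pipeline's logic and
arithmetic are correct under its own assumptions; it does not show
robustness to real-data phenomena the generators omit: indel sequencing
error, strain-level variation within the family, compositional effects,
uneven coverage, contamination, or the long-tailed abundance distributions
of real gut communities.

## Known limitations

- No E-value model in the translated search; reporting is score-based.
- No paired-end awareness and no read quality filtering (quality strings are
  carried but unused).
- The SSN score cutoff is on raw alignment scores and must be recalibrated
  for databases with very different length distributions.
- Spearman p-values use the t-approximation; for n < 10 use the exact
  permutation option.
- The greedy clustering is order-dependent by design (deterministic), and is
  not a reimplementation of any specific published clustering tool.
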