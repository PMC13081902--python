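# metallobsh

Delineation and metagenomic quantification of **metalloBSHs** — secreted,
metal-dependent bile salt hydrolases of the amidohydrolase superfamily found
in gut *Desulfovibrionaceae* (e.g. *Bilophila wadsworthia*). Unlike the
canonical cysteine-dependent Ntn-hydrolase BSHs, these enzymes carry a
dinuclear zinc site and specifically deconjugate taurine-conjugated bile
acids; because they share essentially no sequence similarity with Ntn-BSHs,
standard BSH gene catalogs miss them entirely.

The package is for microbiome researchers who want to (a) carve a
metalloenzyme family out of a large superfamily by sequence similarity
networks plus an active-site residue filter, (b) quantify the family's genes
in short-read metagenomes/metatranscriptomes with a target/decoy translated
search, and (c) relate gene abundance to metabolite levels — with every step
testable against synthetic data of known ground truth.

## Pipeline

1. **Family curation** — all-vs-all SSN (edge iff alignment score ≥ cutoff
   and identity ≥ minimum, defaults 122 / 31%); connected component around
   the seed enzyme; greedy clustering at 65% identity with summed-score
   representatives; conservation filter on the metal-coordinating residues
   (H110, H112, KCX373, H441, H474, D583; BwBSH1 numbering) and
   substrate-recognition residues (S194, H196, Q381, N443, H544). Cluster
   members passing the filter become **targets**; everything else becomes a
   **decoy**.
2. **Translated search** — six-frame translation, k-mer-prefiltered
   Smith–Waterman (BLOSUM62, affine gaps); reads kept only at **> 90%**
   amino-acid identity; multi-mapping reads assigned to the single
   highest-identity protein; decoy-best reads discarded.
3. **Quantification** — `RPKM = count / ((3·L_aa/1000)·(reads/10⁶))`,
   divided by the sample's average genome size (Mb); family presence when
   the summed AGS-normalized abundance exceeds 10⁻⁴.
4. **Statistics** — Spearman ρ of family abundance vs each metabolite
   (untransformed, paired samples), Benjamini–Hochberg FDR across the panel;
   chi-square test of equal detection proportions between groups;
   half-minimum pseudo-count log transforms for display.
5. **Extras** — TPM / log₁₀(TPM+1) expression ranking with top-decile and
   top-centile flags; Michaelis–Menten fitting (`v = Vmax·S/(Km+S)`, kcat
   and kcat/Km); exact ESI adduct m/z; dinuclear-metal-site distances from
   PDB coordinates.
6. **Synthetic data** — seed-reproducible generators for protein families at
   controlled identities, short-read metagenomes with per-read provenance,
   metabolomes with a calibrated monotone coupling to gene abundance
   (`r = 2·sin(πρ/6)` normal-scores construction), transcript counts and
   kinetics datasets.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

A complete synthetic study: plant a family, rebuild it from the mixed
sequence set, map reads back, quantify, and correlate against a metabolite
generated with a true Spearman coupling of −0.45 to family abundance:

```python
from metallobsh import run_synthetic_study

result = run_synthetic_study(seed=1)
print(f"samples:             {result.n_samples}")
print(f"reads assigned:      {result.n_reads_assigned}/{result.n_reads_total}")
print(f"decoy-best excluded: {result.n_decoy_best}")
print(f"mapping accuracy:    {result.mapping_accuracy:.3f}")
print(f"realized truth rho:  {result.rho_realized:.3f}")
print(f"pipeline rho:        {result.rho_estimated:.3f}  (BH-adjusted p = {result.p_adj:.2e})")
```

```
samples:             209
reads assigned:      6382/41800
decoy-best excluded: 17407
mapping accuracy:    1.000
realized truth rho:  -0.446
pipeline rho:        -0.433  (BH-adjusted p = 2.29e-10)
```

Reading this: of 41,800 simulated community reads, 6,382 passed the strict
>90%-identity filter with a family member as best hit (every one of them
from its true source gene), 17,407 hit a decoy amidohydrolase best and were
excluded, and the family-abundance/metabolite correlation estimated by the
full pipeline (−0.433) tracks the realized ground-truth coupling (−0.446)
for this seed.

Chemistry utilities print exact monoisotopic adduct masses, e.g. the
cholylhydroxamic acid [M+H]⁺ ion:

```bash
$ metallobsh assay mz --formula C24H41NO5 --adduct "[M+H]+"
424.3057
```

A CLI mirrors the library (`metallobsh curate ...`, `search map`,
`quant run`, `stats correlate`, `transcripts rank`, `assay fit-mm`,
`simulate all`); every subcommand is a thin wrapper over the functions
shown above.

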