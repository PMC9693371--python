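# familyscan

Genome-scale characterization of MYB-type transcription-factor gene
families, built as a reusable, fully tested pipeline exercised end-to-end on
synthetic genomes with planted ground truth.

Plant MYB proteins carry 1–4 adjacent ~52-residue helix-turn-helix repeats
with a characteristic tryptophan ladder; the repeat count defines the
1R / R2R3 / 3R / 4R subfamilies, of which R2R3 dominates plant genomes.
Surveying a family genome-wide involves a fixed sequence of analyses, each
of which this package implements as an importable, unit-tested function:

- **Repeat detection & classification** (`familyscan.domain_scan`): windows
  of a position-specific scoring matrix (PSSM, bits = Σ column log-odds)
  scored over every protein; hits kept at a decoy-calibrated bit threshold
  and E-value ≤ 1e-10 (Gumbel tail fit on shuffled decoys), resolved
  greedily into non-overlapping repeats; subfamily = size of the largest
  tandem repeat array; members named `MYB1..N` in chromosome order.
- **Protein properties** (`protein_props`): length, average MW, pI (bisection
  on the Henderson–Hasselbalch net-charge curve, EMBOSS pKa set), Guruprasad
  instability index (stable < 40), Kyte–Doolittle GRAVY.
- **Phylogeny & subgroups** (`phylogeny`): profile-anchored domain alignment,
  p-distance with pairwise deletion, Saitou–Nei neighbor joining, bootstrap
  support from column resampling, subgroup labels propagated from reference
  anchors by patristic distance.
- **Logos & motifs** (`motif_logo`): per-column information content
  IC = log2 20 − H(column), conserved/near-conserved residue reports, and the
  bHLH-interaction motif scan (L-x5-L-x6-L-x3-R) in R3 repeats.
- **Promoter cis-elements** (`promoter_cis`): −2000..−1 promoter extraction
  anchored at the CDS start (strand-aware), overlap-inclusive IUPAC pattern
  census against a bundled, replaceable element table (3 groups, 19
  functional categories).
- **Duplication & Ka/Ks** (`duplication_kaks`): global-alignment pair filter
  (coverage > 70 %, identity > 70 %; a separate, looser paralog rule),
  tandem/segmental calls, codon alignment by back-translation, and
  Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction
  d = −(3/4)·ln(1 − 4p/3); ω = Ka/Ks < 1 indicates purifying selection.
- **Expression & qPCR** (`expression`): FPKM = 1e9·C/(N·L), log2(FPKM+1)
  heatmap matrix, tissue-of-maximum calls, Pearson r with exact t-based
  p-values and significance stars against flavonoid-pathway genes
  (PAL…LDOX), one-way ANOVA, and 2^−ΔΔCt qPCR quantification.
- **Synthetic data** (`synthetic_data`): every input above generated from a
  seed with planted, machine-checkable truth — repeats at known positions,
  promoters with verified element counts, duplicate pairs evolved at known
  ω, negative-binomial tissue counts with a planted correlated module, Ct
  tables from known fold changes.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
inputs (`python analysis/01_simulate_inputs.py`, then 02…07). On the default
seed the family scan prints

```
identified 85 family members: {'1R': 21, 'R2R3': 60, '3R': 4} (planted: {'1R': 21, '3R': 4, 'R2R3': 60})
classification matches truth for 85/85 members
properties: mean length 221 aa, mean pI 7.44, mean GRAVY -0.844
```

i.e. all 85 planted MYB genes among 200 are found with their exact
subfamily, and none of the 115 decoys leak in. The Ka/Ks stage reports

```
omega=0.1: mean Ks 0.33, mean omega_hat 0.102, MAE 0.020 (25 pairs x 300 codons)
omega=0.5: mean Ks 0.33, mean omega_hat 0.500, MAE 0.089 (25 pairs x 300 codons)
```

showing the NG86 estimator recovering the planted selection pressure, and
the qPCR stage recovers planted fold changes with a mean error of 1.4 %
(calibrator RQ exactly 1). Raw simulated inputs land in `scratch/simulated/`;
summary tables (family, properties, tree, logos, census, Ka/Ks,
correlations, qPCR) in `results/`.

The same stages are scriptable from the shell:

```bash
familyscan scan --proteome proteome.fasta --gff annotation.gff3 -o hits.tsv
familyscan props --proteome proteome.fasta -o props.tsv
familyscan run -c config.json       # full pipeline, all stages
```

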