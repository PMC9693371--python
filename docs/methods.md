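# Methods

## Repeat model and scanning

The MYB repeat is modelled as an ungapped 52-column PSSM over the 20-letter
alphabet. The packaged model is built from a bundled alignment of 30 repeat
sequences (`data/myb_repeat_alignment.synthetic.fasta`, a constructed
synthetic stand-in for a curated repeat-family alignment, with the conserved
tryptophans at repeat positions 2, 22 and 42 that characterize plant R2
repeats). Scoring uses log-odds in bits against a uniform background with
+0.5 pseudocounts; the emission probabilities kept alongside the matrix are
the raw column frequencies (pseudocounts regularize scoring only, so that
sequences sampled from the model have the alignment's conservation levels).

Windows are scored as the sum of per-column log-odds, vectorized over all
positions. Two retention criteria apply, both calibrated on shuffled decoys
(i.i.d. draws from the background, 600 sequences × 500 residues):

- **bit threshold** — the (1 − 1e-5) quantile of decoy window scores, so
  decoy windows pass at a rate well below 1e-4;
- **E-value ≤ 1e-10** — E = n_windows · SF(bits), with the survival function
  from a Gumbel whose location/scale are fit to the upper 1 % of decoy
  scores (mean-excess fit). Fitting the tail rather than the bulk matters:
  window scores are sums of 52 i.i.d. terms, so their upper tail decays
  faster than any bulk-fit Gumbel would predict, and a bulk fit would
  assign genuine repeats (60–160 bits) E-values orders of magnitude too
  large.

Overlapping candidate windows are resolved greedily by descending score
(ties to the leftmost), which is idempotent and leaves a non-overlapping
hit set.

**Classification.** A hit is a *full* repeat when more than 50 % of its PSSM
columns score positively (the "alignment rate > 50 %" rule); weaker hits
are *partial*. Full repeats within 30 residues of each other form one
tandem array; the subfamily is the size of the largest array: 1 → 1R,
2 → R2R3, 3 → 3R, 4 → 4R; ≥ 5 is labelled `other` with the count retained;
no full repeat but at least one partial → `partial`. The family-filter
length threshold (100 aa) is kept as a consistency check on multi-repeat
calls (two adjacent 52-residue repeats always span > 100 aa); applying it
to single-repeat proteins would contradict the retention of 1R members, so
it never gates them. Members are named `<prefix>1..N` ordered by
(chromosome, start, gene id) — the id is the deterministic tie-break.

## Physicochemical properties

MW (average residue masses), GRAVY (Kyte–Doolittle) and the Guruprasad
instability index use the ProtParam tables shipped with Biopython. The pI
solver is written in-package: bisection on the Henderson–Hasselbalch net
charge with the EMBOSS pKa set (N-term 8.6, C-term 3.6, K 10.8, R 12.5,
H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1), terminating at |charge| < 1e-6. The
charge curve is strictly decreasing in pH so the root is unique. ExPASy
uses Bjellqvist pKa values, so pI values differ from ExPASy outputs by a
few tenths of a pH unit; this is expected and deliberate (the EMBOSS table
is fully specified and reproducible).

## Phylogeny

Multiple alignment is not re-implemented: the PSSM induces it. Each
retained repeat contributes exactly its 52 window columns; repeat ranks are
left-anchored slots, and proteins with fewer repeats than the widest
protein get gap blocks. This defines column homology by the profile, which
is also how the repeat-domain trees of family surveys are effectively
built (domains only, not full-length proteins).

Distances are p-distances with pairwise deletion (Poisson correction
available); a pair with zero comparable columns is an error, except inside
bootstrap replicates where it takes the saturation value 0.75. Trees are
Saitou–Nei neighbor joining; negative branch lengths are clamped to zero
with the pair sum preserved on the sibling; an all-zero matrix returns a
star tree; for two taxa each branch is d/2; the final edge is split evenly
across the root (patristic distances, the unrooted quantity, are invariant
to the split point). On additive matrices NJ provably recovers the
generating tree, which the tests verify exactly for 4–8 taxa; topology is
cross-checked against scikit-bio's independent NJ.

Bootstrap support is the percentage of column-resampled replicate trees
containing each internal bipartition, seeded and reproducible. Subgroup
assignment gives each query the label of the patristically nearest anchor
leaf; exact ties break by the smaller enclosing clade, then anchor id.
Distances are rounded to 12 decimals before comparison so floating-point
noise cannot break tie handling. The packaged anchor panel
(`data/subgroup_anchors.synthetic.*`) is a generated stand-in for a real
labelled reference set and is user-replaceable (FASTA + id/subgroup TSV).

## Logos and motifs

Column information content is IC = log2 20 − H with H the Shannon entropy
of residue frequencies, gaps dropped per column and all-gap columns
flagged; no small-sample correction is applied (matching what logo tools
draw by default). The conserved-residue report lists positions whose modal
residue reaches the requested fraction and, for positions between 50 % and
that fraction, the substituting residues — the view in which the first R3
tryptophan's F/I/L/Y replacements show up.

The bHLH-interaction motif string is typographically ambiguous in the
field's shorthand; both readings are registered patterns: the default
literal reading `L x5 L x6 L x3 R` (18 residues) and a stricter canonical
variant `[DE] L x2 [RK] x2 L x6 L x3 R`. Matches are non-overlapping,
left-to-right.

## Promoters and cis-elements

The promoter is the 2000 bp ending 1 bp before the first CDS base (plus
strand) or the reverse complement of the 2000 bp starting 1 bp after the
last CDS base (minus strand) — anchored at the CDS, not the transcript
start, and truncated with a warning at chromosome edges. Element patterns
are IUPAC strings; counting is overlap-inclusive and forward-strand-only by
default (palindromes such as the G-box CACGTG would otherwise double), with
a both-strands option. The packaged table
(`data/cis_elements.tsv`) is a compact literature-derived stand-in: 30
elements in 19 functional categories across the three groups (plant
development PDE, stress SE — which houses the light-responsive categories —
and hormone HE). The census reports, per element, total occurrences and the
number of genes with at least one occurrence.

## Duplication and Ka/Ks

Candidate pairs come from global protein alignment (BLOSUM62, gap open −10,
extend −0.5). Coverage is shorter/longer raw length; identity is percent
matches over aligned columns with internal gap columns counted as
mismatches and terminal overhangs excluded ("similarity" is not defined in
typical survey methods, so the implementation pins it down). Two separate
filters are exposed and never conflated: the duplication rule
(coverage > 0.7 and identity > 70) and the paralog rule (CDS > 300 bp and
identity ≥ 50) used for Ka/Ks pair sets. Tandem means same chromosome and
(≤ 1 intervening gene or ≤ 100 kb span) — common plant gene-family
practice, both knobs configurable; everything else is segmental.

Codon alignments are built by back-translation: each residue column maps to
its codon, gaps become `---`, one trailing stop is tolerated, and any
translation mismatch errors with its column. Ka/Ks is classical
Nei–Gojobori (1986): per position, the fraction of the three possible
changes that are synonymous gives the S site count (averaged over the two
sequences); observed differences at 2–3-position codons are averaged with
equal weight over all minimal substitution pathways, including pathways
through stop codons; pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected.
ω is flagged undefined when Ks = 0 or p ≥ 3/4. The implementation is
verified against a literal enumeration oracle and cross-checked against
Biopython's independent NG86. Maximum-likelihood (codeml-style) ω estimates
will differ from NG86, especially at high divergence; that difference is a
property of the estimator family, not a defect.

## Expression and qPCR

FPKM_gt = 1e9 · C_gt / (N_t · L_g). Heatmap values are log2(FPKM+1); genes
with all-zero FPKM rows are flagged "not expressed". Correlations against
the flavonoid-pathway structural genes (PAL, C4H, 4CL, CHS, CHI, F3H,
F3'H, F3'5'H, DFR, LDOX) are computed on log2(FPKM+1) across the seven
tissues (n = 7; the scale is a package choice recorded in config — raw
FPKM and rank options would be trivial variants), with the exact two-sided
t transform t = r·√((n−2)/(1−r²)) on n−2 df and stars at p < 0.05 / 0.01 /
0.001. ANOVA is the classical between/within F on (k−1, N−k) df (scipy's
implementation, tested against the sums-of-squares formula); groups that
are all constant are an error. qPCR: replicate Cts are averaged per
sample×gene before ΔCt; ΔΔCt subtracts the calibrator's ΔCt, RQ = 2^−ΔΔCt,
so the calibrator's RQ is exactly 1 regardless of noise; SEM is computed
over per-replicate RQs.

## Synthetic data: what it emulates and what it does not

Every generator is a pure function of (parameters, seed) and the truth
tables fully determine the expected output of every stage.

- **Genome** (default benchmark: 6 chromosomes, 200 genes, 21 1R + 60 R2R3
  + 4 3R + 115 decoys, seed 7): MYB proteins carry repeats sampled
  column-wise from the PSSM emissions with a 5 % uniform substitution rate,
  separated by 3–11-residue linkers inside random flanks; genes get 1–8
  exons, random strand, GT..AG introns, and synonymous-uniform
  reverse-translated CDS. Plantedness is definitional: each draft repeat is
  resampled until the scanner detects exactly the planted windows, and each
  decoy until it has no hit — so the perfect recall/precision the tests
  require is a property of what "planted at default noise" means, and the
  tests verify the scanner agrees with that definition on every gene.
- **Promoters**: backgrounds are scrubbed of accidental element matches,
  requested occurrences are inserted at non-overlapping positions, and the
  final truth records counts verified with an independent overlap-counting
  matcher (insertion can legitimately nest one element inside another,
  e.g. the ACGT-core element inside a G-box; truth records what is
  actually present).
- **Duplicate pairs**: acceptance-thinned codon evolution — per lineage a
  Poisson(divergence/2 × codons) number of uniform single-base proposals;
  synonymous proposals fix, nonsynonymous fix with probability ω,
  stop-creating proposals are rejected. This is a deliberate
  simplification of codon substitution models: the goal is NG86 recovery
  under a known ω, not model realism. The benchmark divergence is 1.0
  proposals/codon (realized Ks ≈ 0.33), chosen once to sit in the
  deeply-diverged regime paralog surveys report; at much lower divergence
  the ω̂ variance over 300 codons dominates recovery error.
- **Expression**: negative-binomial counts (dispersion 0.05) around planted
  per-tissue means; correlated partners share a latent standard-normal
  tissue profile mixed as r·z + √(1−r²)·ε on the log2 scale, so the target
  r = 0.95 holds in expectation for the log-mean profiles; with n = 7
  tissues the sampling variance of r̂ is substantial, which is why
  recovery is asserted as "r̂ > 0.8 for ≈ 90 % of partners" rather than
  pointwise. Four genes are planted all-zero.
- **qPCR**: Ct_target = Ct_ref + ΔCt_cal − log2(fold) + N(0, 0.05), three
  replicates. With three replicates the fold-recovery error has ≈ 4 %
  standard deviation, so individual folds occasionally miss by > 10 %
  even though the mean error is a few percent.

Not emulated: realistic genome composition (repeat content, GC structure,
UTRs), transcript isoform diversity beyond a single mRNA per gene,
read-level sequencing noise, batch effects, and real subgroup structure in
the planted repeats (anchors and queries share constructed subgroup
consensuses instead). Passing tests therefore demonstrate correctness of
the computations against planted truth, not performance on real genomes —
on real data, recall depends on how far true repeats diverge from the
profile used.

## Numerical choices and degenerate inputs

Seeds: every stochastic routine takes an explicit seed; derived seeds stay
below 2^31. Bisection tolerance 1e-6 on charge; JC correction domain
guarded at p ≥ 0.75 ("saturated" flag); Gumbel tail fraction 1 %; NJ
negative-branch clamping as above; patristic ties rounded at 1e-12;
round-half-up (not banker's) at 2 decimals for printed percentages, which
reproduces the printed style of family tables (17.36, 9.92, 0.83, 28.93
from 21/121, 12/121, 1/121, 35/121). Problem sizes in tests and the
acceptance script (200-gene genome, 50 pairs × 300 codons, 1000 random
promoters, 100 bootstrap replicates) are the package's documented
benchmark conditions.

## Known limitations

- The PSSM is ungapped; repeats with insertions/deletions relative to the
  profile score poorly. Real surveys use profile HMMs (Plan7) for this
  reason; the decision surface (E-value + length/rate thresholds) is kept
  identical in shape.
- Subgroup assignment is nearest-anchor by patristic distance, not clade
  membership with support thresholds; with sparse anchor panels all
  queries can legitimately collapse onto one label.
- NG86 with equal-weight pathways slightly mis-weights transition-rich
  codons relative to ML estimators; Ks saturates above p ≈ 0.5.
- The duplication filter is all-vs-all global alignment, O(n²) in family
  size — fine for hundreds of proteins, not for whole proteomes.
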