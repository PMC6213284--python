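# Methods

## Coordinates and file semantics

All intervals are 0-based, half-open (BED convention). Signal tracks are
step functions with bedGraph semantics; positions not covered by a step have
value 0. Peak merging fuses intervals that overlap by at least 1 bp;
abutting intervals (end == start) remain separate, since two peaks that
merely touch are distinct binding events.

## Occupancy quantification

For one factor, peaks from all conditions are merged into a common region
set. For each region and condition:

```
occupancy = max(0, mean_bp(ChIP) · L_ref/L_chip − mean_bp(IgG) · L_ref/L_igg)
```

- `mean_bp` is the per-base-pair mean of the step function over the region,
  computed exactly from the step arrays (no binning).
- `L_ref` defaults to the largest ChIP library among the factor's
  conditions, so the best-sampled condition is left unscaled and the others
  are scaled up. Any common reference gives identical retention values
  because retention is a ratio.
- Clamping at zero reflects that "less signal than background" carries no
  occupancy information.

## Retention and status

Retention of a region in a condition is its occupancy divided by the maximum
across conditions (all-zero signal gives all-zero retention). Status per
region and condition:

- **gained** — called (peak overlap) here but not in the reference;
- **lost** — retention below the threshold (default 0.5);
- **kept** — otherwise.

The comparator is strict (`<`) by default, so a region retaining exactly half
its peak signal is kept; an `inclusive` option (`<=`) is provided because
"less than 50%" and "50% or less" are both defensible readings of a
half-maximum criterion. The boundary location itself is what matters and is
pinned by tests.

## Co-bound taxonomy

Reference-called regions of both factors are swept per chromosome and fused
into connected components of overlapping intervals; components containing
both factors are the co-bound elements. A factor is kept on an element if
any of its member regions is kept (an element still bound anywhere is not
decommissioned). The (OCT4, NANOG) status pair maps to:

| OCT4 | NANOG | label |
|------|-------|----------------|
| lost | lost | ClassI |
| kept | lost | ClassII |
| lost | kept | KeptNanogOnly |
| kept | kept | KeptBoth |

Gained regions cannot appear here by construction (elements are
reference-called).

## Gene linkage and expression

Each element links to the nearest gene body (distance 0 when overlapping)
within 20,000 bp, inclusive; ties break to the smallest gene id for
determinism. Differential expression is a Welch t-test per gene with
Benjamini–Hochberg correction (statsmodels), a deliberately simple stand-in
for moderated-variance methods; with ≥3 replicates and the generator's noise
levels it has ample power for the planted effects. Class summaries restrict
to DE genes (FDR < 0.05 by default), partition them into ClassI-only,
ClassII-only, and Both (genes linked to elements of both classes), and
report median/quartile/whisker statistics of log2 fold change versus the
reference per condition.

Ranked-tail enrichment sorts genes by (−log2FC, gene id), takes the union of
the top k and bottom k (default k = 400, requiring 2k < universe), and
computes the hypergeometric upper tail `sf(observed − 1, N, n_targets, 2k)`
for the number of target genes in that selection.

## Staging

Reference profiles cover eight ordered stages (CAV, PS, ES, MS, LMS, LS,
OBEB, LB) with replicates. Per gene, a univariate two-sample Hotelling T²
`(m1 − m2)² / (sp² (1/n1 + 1/n2))` is computed for each consecutive stage
pair and the maximum over pairs is the gene's score (0/0 → 0, positive/0 →
∞, so zero-variance separations rank first). The top 500 genes by score
(gene-id tie-break) form the staging panel; each query sample is assigned
the stage whose mean profile has the highest Pearson correlation over the
panel. Marker summaries pool early (CAV, PS) versus late (LMS, LS) stages
through the same DE stand-in to define up/down marker sets.

## Motifs

K-mers (6–8 nt) are counted in canonical strand-pooled form (a k-mer and its
reverse complement are one species; palindromes count once) using a
vectorized base-4 encoding; windows containing N are skipped. For each
k-mer, the background rate is `p0 = (bg_count + 1) / (bg_total + 1)`
(add-one smoothing so unseen background k-mers stay testable), the p-value
is the binomial upper tail of the foreground count at `p0`, and the E-value
multiplies by the number of distinct k-mers tested across the k range. This
is a simplified analogue of oligo-analysis-style motif discovery: it finds
over-represented words, not position weight matrices.

## Methylation arithmetic

Restriction-protection qPCR: a methylation-sensitive enzyme cuts only
unmethylated sites, so amplifiable template after digestion measures the
methylated fraction. With amplification efficiency `E` (default 2.0),

```
percent = 100 · E^−(Ct_digested − Ct_mock), clamped to [0, 100]
```

Undetermined digested Ct (NaN) is reported as 0% with an `undetermined`
flag.

## Synthetic generator

One synthetic chromosome carries evenly spaced elements of each planted
class. Occupancy trajectories over (EH, EM, EN): kept = (1.0, 0.85, 0.75) ×
base, lost = (1.0, 0.4, 0.05) × base, gained = (0.05, 0.3, 1.0) × base
(base 10 per bp over 400 bp elements against a background of 0.5, S/B = 20).
Tracks are emitted as `(occupancy + background) · L_cond / L_ref`, so the
normalization arithmetic recovers the planted occupancy exactly at zero
noise; multiplicative log-normal noise (σ = 0.1 by default) perturbs both
tracks and peak calling (a peak is called when noisy occupancy exceeds 2.0).
NANOG regions are offset by half a width so co-bound elements are genuine
two-factor components. A fraction of elements receives its own gene 3 kb
away; Class I genes are planted down in EN and the epiblast-like condition
(−2 log2), Class II genes slightly up (+0.5), against ~1,000 null genes.
Element sequences carry planted 6-mers (`AGGTCA` in Class I, `ATGCAA` in
Class II) above background frequency. Stage profiles give half the genes
monotone trajectories spanning 1–3 log2 units across the stage order.
Ground-truth tables (element labels, planted occupancies, gene effects,
query stages) are emitted alongside, and generation fails loudly if a
planted label is inconsistent with its own trajectories.

What the generator emulates: library-size imbalance, background
subtraction, noisy peak calling, asymmetric factor loss, class-coupled
expression, planted motifs, staged transcriptomes. What it does not:
read-level sampling, fragment-size effects, mappability, peak shape,
replicate structure in ChIP, genome-scale element counts, or realistic
sequence composition — it is a correctness instrument, not a simulator of
sequencing.

## Numerical choices

- Exact step-function interval sums via `searchsorted`; no approximation in
  occupancy.
- All randomness flows from `numpy.random.SeedSequence(seed)` substreams;
  outputs are byte-identical across runs for a fixed seed.
- Statistical tails come from scipy (`binom.sf`, `hypergeom.sf`) and
  p-value adjustment from statsmodels (`fdr_bh`); both are pinned against
  brute-force oracles in the tests.
- Deterministic tie-breaks everywhere a ranking feeds a cutoff (gene ids in
  linkage, Hotelling ranking, and tail selection; E-value then k-mer in
  motif tables).

## Limitations

- The DE stand-in assumes roughly normal within-condition log expression
  and does not moderate variances; with 2 replicates it is weakly powered.
- The taxonomy requires exactly two factors named OCT4 and NANOG in the
  bundle manifest.
- K-mer enrichment tests words independently; overlapping or shifted
  variants of one motif appear as multiple correlated hits.
- Staging assumes query and reference share gene identifiers and at least
  three panel genes in common; correlations are computed over stage means.
- The methylation model treats digestion as complete for unmethylated sites
  and ignores partial digestion and primer efficiency differences between
  sites.
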