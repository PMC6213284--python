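# occudyn

Retention-based analysis of transcription-factor occupancy loss during the
exit from naïve pluripotency, driven entirely by a synthetic data generator
with planted ground truth.

## Scientific background

When mouse embryonic stem cells leave the naïve pluripotent state, the
enhancer landscape bound by the core factors OCT4 and NANOG is progressively
dismantled. Sorting cells by the level of the naïve factor Esrrb (high →
medium → negative, `EH`/`EM`/`EN`) produces a trajectory along which
regulatory elements either retain or lose factor binding. Elements co-bound
by OCT4 and NANOG in the naïve reference state fall into a small taxonomy at
the terminal state:

- **Class I** — both OCT4 and NANOG binding is lost;
- **Class II** — NANOG is lost but OCT4 is retained;
- **KeptNanogOnly** / **KeptBoth** — the remaining, much rarer outcomes.

Class I elements behave like decommissioned naïve enhancers: their nearby
genes are down-regulated as cells progress, they carry nuclear-receptor-like
sequence motifs, and naïve-specific loci gain CpG methylation. Class II
elements keep OCT4 and their genes hold steady or rise. The package
implements the full quantitative chain behind these observations — occupancy
quantification, retention classification, co-bound taxonomy, gene linkage,
expression summaries, ranked-tail enrichment, transcriptome staging against
embryonic reference profiles, differential k-mer analysis, and
restriction-protection methylation arithmetic — and a generator that plants
every one of these effects so the chain can be verified end to end.

## Model

For each factor, peaks from all conditions are merged (overlapping, not
abutting, intervals) and each merged region is scored per condition as

```
occupancy = max(0, mean_bp(ChIP) · L_ref/L_ChIP − mean_bp(IgG) · L_ref/L_IgG)
```

where `L` are library sizes and `L_ref` is the largest ChIP library of the
factor. Retention is occupancy divided by its maximum across conditions; a
region is **lost** when terminal retention falls below 50% (strict `<` by
default) and **gained** when called only outside the reference. Overlapping
OCT4/NANOG regions co-bound in the reference are fused into elements and
classified by the pair of kept/lost calls. Elements link to the nearest gene
within 20 kb; a Welch-t + Benjamini–Hochberg differential-expression
stand-in summarizes class-wise log2 fold changes, and a hypergeometric test
asks whether linked DE genes concentrate in the top/bottom tails of the
ranked fold-change list. Staging correlates query transcriptomes (Pearson)
against stage profiles over the 500 genes with the largest per-gene
Hotelling T² between consecutive stages. Motif analysis scores canonical
(strand-pooled) 6–8 nt k-mers with a binomial upper tail against a
background set, Bonferroni-style E-values. Methylation is computed from
restriction-protection qPCR as `100 · efficiency^−(Ct_digested − Ct_mock)`.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
bundle and write tables to `results/`:

```
python analysis/01_simulate.py
python analysis/02_occupancy_classes.py
...
python analysis/06_methylation.py
```

With the default configuration (seed 1) the generator plants 215 Class I,
165 Class II, 5 KeptNanogOnly and 10 KeptBoth co-bound elements, and the
classifier recovers every one exactly:

```
                 n
class
ClassI         215
ClassII        165
KeptNanogOnly    5
KeptBoth        10
Total          395
```

Downstream, 389 elements link to a gene within 20 kb, 298 genes are called
differentially expressed, and 32.4% of linked DE genes sit in the top/bottom
50 of the ranked fold-change list (hypergeometric P = 3.7 × 10⁻⁶⁶). All
eight pure-stage query transcriptomes are staged correctly (CAV → LB), the
top differential k-mers are the planted `AGGTCA` (Class I) and `ATGCAA`
(Class II), and the methylation panel converts Ct shifts into protection,
e.g. a 0.9-cycle shift → 53.6% methylation.

The same pipeline is available as a CLI:

```
occudyn simulate --seed 1 --out bundle/
occudyn run-all --bundle bundle/ --out out/
```

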