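# Methods

## Spearman ranking (SRCCA)

For a gene-by-cell matrix, every gene is converted to average-tie ranks
across cells once, and rho against a target gene is the Pearson correlation
of rank rows. This is algebraically identical to per-gene Spearman
correlation but vectorised; the test suite checks it against the tie-free
closed form 1 − 6Σd²/(n(n²−1)) (to 1e-12) and against an independent
per-gene computation.

Conventions, fixed so lists are reproducible across platforms:

* the target gene is excluded from its own ranked list, so top-N sets and
  their intersections never contain the targets themselves;
* ties in rho break lexicographically by gene id;
* genes constant across cells have undefined rho; they are excluded and
  reported in an audit list, never assigned rho = 0;
* correlations are computed on log2(TPM+1) by default. Rho is invariant to
  the log because per-gene cross-cell ranks are; the choice only matters
  for Z-scored heatmap displays.

Heatmap matrices order cells by target expression descending (ties by cell
id) and standardise each gene row with the population standard deviation;
constant rows are emitted as zeros and flagged.

## Multi-target combination

Named top-N sets are partitioned into all 2^k − 1 Venn regions; the full
intersection is the core set. Region disjointness and conservation
(Σ region sizes = |union|) are property-tested. The shipped workflows are
the pan-RGC core signature (BRN3B, ISL1, SNCG, RBPMS; N = 200) and the
DS-RGC candidate list (FSTL4, BRN3B, SNCG; N = 1000).

Specificity contrasts compare a candidate's top-N list with the top-N list
of each negative-panel gene (progenitor, RPE, photoreceptor panels, shipped
as editable YAML along with the alias table — BRN3B→POU4F2, CART→CARTPT,
CB2→CALB2, etc.; the CB2 alias is ambiguous in the literature and is
deliberately overridable). The "minimal overlap" verdict is operationalised
as every overlap ≤ 5% of N. The default contrast N is 200: in a desk-scale
gene universe (3,000 genes) a top-1000 list is a third of all genes and two
unrelated lists would already overlap ~11% by chance; at N = 200 the chance
expectation (~7%) is still resolvable from the structural near-zero overlap
that disjoint planted populations produce.

Candidate validation is per-cell co-detection: among candidate-positive
cells, the fraction positive for each panel gene, with a pass when the
subtype-panel mean exceeds every other panel's mean by a margin (default
0.2). Positivity is expression > 0 by default, the natural cut for
zero-inflated single-cell data. The synthetic mosaic, however, models
marker off-states as a visible baseline (fold-change structure, below), so
on synthetic data positivity uses a per-gene quantile cut instead
(`detection_quantile=0.75`, i.e. the top quarter of cells); this is an
explicit argument, not a hidden default.

## qPCR pipeline

Only one-cell capture sites enter analysis; removals are reported per
category (zero-cell, multi-cell, debris). Ct maps to an expression score
max(LOD − Ct, 0) with LOD default 40 cycles (instrument-conventional,
configurable); the no-amplification sentinel maps to 0 rather than being
imputed, so "detected" ⇔ score > 0. Subtype rules are combinatorial and
multi-label, each call carrying a trace of the genes that fired; BRN3
positivity accepts any assayed POU4F isoform because the antibody used for
counting is pan-isoform while qPCR primers are isoform-specific.

## Quantification

Per-image co-expression percentages use either the reference-positive
(BRN3⁺) or total-DAPI denominator. SEM uses the sample (n−1) standard
deviation over technical replicates by default — figure-legend phrasing
("n = 36 technical replicates from 3 biological replicates") implies the
technical count — with a biological-replicate option since the convention
is ambiguous. Zero-denominator rows are excluded with a warning and the
reported n reflects the exclusion. Output formatting is `mean% ± SEM%` at
two decimals.

## Synthetic data: what it emulates and what it does not

`generate_mosaic` draws negative-binomial counts (var = μ + φμ², φ = 0.4)
with a per-cell log-normal library-size factor (σ = 0.3) over a mixed
population (40% progenitor, 10% RPE, 20% photoreceptor, 30% RGC; RGC
subtypes 20% ON-OFF DS, 25% ON DS, 18% alpha, 4% ipRGC, 5% each PV/W3B/J,
18% other — proportions in the range reported for hPSC retinal cultures).
Planted gene modules have their NB mean multiplied by the fold-change
(default 8×) in the owning population: a 150-gene pan-RGC module containing
the four classic targets, a 148-gene DS module containing FSTL4 and a
DCX-like candidate, 12-gene progenitor/RPE/photoreceptor modules seeded
with the negative-panel genes, small subtype marker sets (CARTPT, CDH6,
SPP1, KCNG4, CALB2, OPN4, PVALB, SDK2, JAM2), and ~2,650 background genes.

Two deliberate structural choices:

* **Heterogeneous target coverage.** POU4F2 and SNCG are elevated in all
  RGCs; ISL1 and RBPMS only in non-DS RGCs. Classic RGC markers do overlap
  only partially in real cultures (RBPMS notably sparser), and this
  heterogeneity is what makes a four-way intersection informative: the
  DS module correlates with POU4F2/SNCG but not with ISL1/RBPMS, so the
  core signature isolates the pan-RGC module instead of absorbing every
  RGC-adjacent module.
* **Expression-dependent dropout.** Zero inflation is applied
  post-sampling with probability π·exp(−μ/μ₀), μ₀ = 40 counts — the
  standard single-cell phenomenology in which abundant transcripts are
  rarely lost. A uniform π would put hard zeros into bright marker genes
  and cap every pairwise rho near 0.15 regardless of effect size, which is
  neither realistic nor useful as a test bed. π (default 0.2) remains the
  noise dial: mean planted-module recall over seeds is flat at π = 0 and
  degrades monotonically through π = 0.4.

Module means are log-normal around 8 counts (background around 5 with
wider spread). Marker genes are deliberately *not* brighter than that:
planted modules are ~15% of the 3,000-gene universe, hundreds of times
their genome share in real data, and making them dominate library mass
would let TPM's compositional coupling inject a shared pseudo-signal into
every background gene.

Not emulated: batch effects, UMIs/reads, doublets in RNA-seq (only in the
qPCR plate), differentiation dynamics, correlated background structure,
and realistic transcript-length/expression covariation. Passing recovery
tests therefore demonstrates the correctness and discriminative power of
the intersection logic under controlled noise, not performance on real
data, where uncontrolled covariation will inflate chance intersections.

`generate_qpcr_plate` plants single-cell identities (or zero-cell /
multi-cell / debris artifacts; multi-cell wells carry summed material of
two cells) and emits Ct = LOD − 2.5·log2(1+expression) + N(0, 0.5),
clipped to (0, LOD], with a 5% default per-gene detection dropout.
`generate_icc_counts` draws per-image Poisson totals, binomial
reference-positive counts and binomial double-positives at the planted
proportion.

## Problem sizes and numerical choices

Default mosaic scale is 500 cells × 3,000 genes (generation plus the full
four-target workflow runs in a few seconds); a `paper_scale` preset
(288 cells × 20,000 genes) approximates a multi-plate microfluidic
capture. Dropout-degradation experiments use 10 seeds per π. The qPCR
recall experiment under dropout uses a 2,304-well run so that every label
has ~200 planted cells and binomial noise on per-label recall is small.
TPM columns are validated to 1e-6 relative tolerance; heatmap rows to
1e-9; Spearman oracle agreement to 1e-12. Seeds are explicit arguments
everywhere; the same seed reproduces bit-identical data.

## Known limitations

* The intersection workflows return candidate gene lists; nothing here
  establishes biological marker status.
* QC is two explicit thresholds (library size, genes detected), a
  transparent stand-in for dedicated single-cell QC tooling.
* Alias resolution is a flat symbol map; it does not consult genome
  annotation, so unresolved symbols are surfaced rather than guessed.
* On data whose off-state is dense (including this package's own
  synthetic mosaic), threshold-0 positivity is meaningless and the
  quantile mode must be chosen explicitly.
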