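# Methods

## The triad model

The unit of analysis is a hybrid–parent **triad**: a maize F1 hybrid (H)
and its maternal (M) and paternal (P) inbred lines, profiled by bulk
RNA-seq in the same tissue (developing seed coat) at several time points
measured in days after pollination (DAP). For a gene with mean expression
levels μ_M, μ_H, μ_P, the additive (purely *cis*-driven) expectation is the
arithmetic mid-parent value

    MPV = (μ_M + μ_P) / 2.

Departures of μ_H from the MPV are the expression-level signature of
nonadditive regulation: **expression-level dominance** (ELD) when the
hybrid matches one parent while the parents differ (ELD_M when it matches
the maternal line, ELD_P the paternal), and **transgressive**
(overdominant) expression when the hybrid lies above both parents
(transgressive up) or below both (transgressive down).

## Differential expression

Each pairwise contrast (M vs P, H vs M, H vs P) is tested per gene on
log2(x + 1)-transformed replicate expression values with a two-sided
pooled-variance two-sample t-test; p-values are Benjamini–Hochberg
adjusted across genes, and a gene is called *up*/*down* when
|log2 FC| ≥ 1 (fold change computed on replicate means with a pseudo-count
of 1; bound inclusive) and adjusted p < 0.05 (strict).

The pooled-variance t, rather than Welch's unequal-variance t, is a
deliberate choice for this design: with 3 replicates per group the
Welch–Satterthwaite degrees-of-freedom estimate is so noisy that the test
is markedly conservative (empirical size ≈ 0.034 at nominal 0.05 even on
ideal normal data), whereas the pooled t is exactly sized when the two
groups share a variance — which the design (equal replication, same
protocol, same tissue) makes a reasonable default. The null-calibration
acceptance test verifies the resulting size empirically on simulated null
genes. Welch's form is retained in the phenotype module's
hybrid-vs-mid-parent test, where the two samples (hybrid replicates vs the
pseudo-MPV sample) differ in size by an order of magnitude.

Degenerate variance rule: when both groups are constant, the t statistic
is undefined; the test returns p = 1 if the constants agree and p = 0 if
they differ (zero observed noise makes any difference certain). This
arises only for all-zero or saturated genes.

## 13-way pattern classification

Each gene's three signed calls — s_MP ∈ {M>P, M<P, ns},
s_MH ∈ {H>M, H<M, ns}, s_PH ∈ {H>P, H<P, ns} — are mapped to one of 13
classes in five categories, evaluated in priority order:

| priority | condition | category (classes) |
|---|---|---|
| 1 | H>M and H>P | transgressive up (×3, by s_MP) |
| 2 | H<M and H<P | transgressive down (×3, by s_MP) |
| 3 | s_MP ≠ ns, s_MH = ns, s_PH ≠ ns | ELD_M (×2: H≈M>P, H≈M<P) |
| 4 | s_MP ≠ ns, s_PH = ns, s_MH ≠ ns | ELD_P (×2) |
| 5 | M>H>P or M<H<P, all significant | additive-intermediate (×2) |
| 6 | all ns | additive-conserved (×1) |
| 7 | anything else | distance fallback |

Non-significance is accepted as ≈; no second equivalence test is applied.
The ELD rules require the *far* parent's hybrid contrast to be
significant: the doubly-ambiguous pattern (parents differ, hybrid
indistinguishable from both) matches no idealized pattern, and routing it
to one dominance side would break the symmetry that relabelling the two
parents must map ELD_M onto ELD_P exactly. It falls instead to the
distance fallback, as do all other conflicting combinations: the gene goes
to the category whose idealized hybrid position (mid-parent for additive;
the matched parent for dominance) is nearest to the observed hybrid mean,
with ties resolved in favour of additive (then ELD_M, then ELD_P — exact
ties are measure-zero for continuous means).

Class numbering is canonical here (transgressive up 1–3, transgressive
down 4–6, ELD_M 7–8, ELD_P 9–10, additive-intermediate 11–12,
additive-conserved 13); category-level totals are invariant to numbering.

The three-way parent-level summary maps additive classes to *mid-parent*,
transgressive up plus dominance-of-the-higher-parent classes (7, 9) to
*high-parent*, and transgressive down plus dominance-of-the-lower-parent
classes (8, 10) to *low-parent*.

The classification universe at each focal time point is the set of genes
expressed (replicate-mean FPKM ≥ 1) in all three genotypes.

### A structural property worth knowing

A gene whose hybrid sits exactly at the arithmetic mid-parent is **never**
two-fold below the higher parent, because (μ_M + μ_P)/2 ≥ μ_M/2 always.
With a 2-fold call threshold, a perfectly additive gene with
differentially expressed parents therefore always shows the call pattern
(M>P, ns, H>P) — which the decision table, by definition, labels ELD_M
(or, mirrored, ELD_P). Call-pattern classification thus systematically
assigns mid-parent genes with strongly divergent parents to the dominance
categories. This is a property of the scheme, not of any implementation;
it is why the end-to-end consistency test compares pipeline output against
the decision table applied to the *true* means (a noise-free oracle)
rather than against the generating class proportions, and it is one reason
dominance fractions in published triad tables should be read as upper
bounds.

## Synthetic triad generator

No public per-gene generative model accompanies the study design this
package targets, so the simulator uses the standard bulk RNA-seq model:

1. each gene draws a class from a 13-way mixture and a baseline expression
   level b ~ LogNormal(meanlog = 3.0, sdlog = 1.5) (relative units; only
   ratios matter after normalization);
2. the class fixes (μ_M, μ_H, μ_P) exactly: parents that differ are placed
   2^(±effect_log2/2) around the baseline; the hybrid goes to the
   arithmetic MPV (additive), the matched parent (ELD), or a further
   2^effect_log2 beyond the extreme parent (transgressive);
3. expected fragment counts are proportional to abundance × gene length
   (lengths uniform on 500–5000 bp), scaled so each sample's expected
   total is the library size (2 × 10⁷ fragments);
4. observed counts are negative-binomial with var = μ + φμ²
   (Poisson when φ = 0), independently per replicate.

Defaults and rationale:

| parameter | default | rationale |
|---|---|---|
| n_genes | 20,000 | the scale of the expressed-gene universe in maize seed coat (~23k of ~39k annotated) |
| n_reps | 3 | the study design |
| class mixture | 85.2% additive, 13.3% ELD, 0.5% transgressive | the composition observed at 3 DAP in the target study design |
| effect_log2 | 3.0 | large enough that every nonadditive pattern is detectable at 3 replicates after BH correction, so the default regime reproduces the decision-table-predicted composition |
| dispersion φ | 0.08 | calibrated so replicate-pair R² on log2(FPKM+1) is ≈ 0.93, the reproducibility level typical of good bulk RNA-seq triplicates |
| library_size | 2 × 10⁷ | tens of millions of mapped fragments per library |

With effect_log2 = 0 every class collapses onto a single mean, so all
truth labels are reported as additive-conserved.

What the generator deliberately does **not** emulate: temporal
autocorrelation (each DAP is an independent draw, so cross-time-point
expressed-gene overlap is far lower than in real data, where most genes
are stably expressed across development); per-gene effect-size
distributions (one global effect size); mean–dispersion trends;
length/GC biases; and read-level artifacts (the pipeline starts at the
count matrix). Passing tests therefore demonstrate the correctness and
calibration of the pipeline's operations under a clean NB regime, not
end-to-end fidelity to any particular real data set.

The phenotype generator produces logistic trait trajectories
K / (1 + exp(−r (t − t0))) per genotype over 0–15 DAP with additive
Gaussian replicate noise truncated at 0. Default parameters (asymptote K
in mm², rate r per day, inflection t0 in DAP: M 95/0.55/6.0,
H 110/0.60/7.5, P 75/0.55/6.5) put the hybrid below the mid-parent curve
early, crossing between 7 and 8 DAP and diverging above it afterwards —
the late-emerging seed-coat heterosis pattern the transcriptome time
points bracket.

## Expression accounting

* FPKM[g, s] = counts[g, s] · 10⁹ / (length_bp[g] · total_counts[s]).
* Expressed-gene rule: replicate-mean FPKM ≥ 1 at a (genotype, DAP) group
  (threshold configurable; the exact rule behind published expressed-gene
  totals is rarely stated, so those totals are treated as data-dependent).
* Replicate agreement: mean pairwise squared Pearson correlation on
  log2(FPKM + 1) (raw-scale correlation is dominated by a few high
  expressors; a switch allows raw). Constant replicate vectors make the
  correlation undefined; such pairs are excluded with a warning.
* Overlap accounting is an exact Venn decomposition (region counts per
  membership pattern); core fractions are reported as 100 · core / set
  total, half-up rounded to 2 decimals like all percentages here.

## Phenotype statistics

* MPV of a trait: (m + p)/2 on per-genotype means.
* Relative growth rate: RGR(t) = (x̄_t − x̄_{t−1}) / x̄_{t−1} on the daily
  grid (undefined where the previous mean is 0); the classical
  log-difference form ln x̄_t − ln x̄_{t−1} is available via
  `method="log"`. For exponential growth at rate r the two give e^r − 1
  and r respectively.
* Hybrid-vs-MPV significance: the hybrid replicates are tested (Welch,
  two-sided) against the pseudo-MPV sample {(m_i + p_j)/2} over all parent
  replicate pairs, subsampled to at most 200 seeded random pairs. This
  reproduces the direction and timing of mid-parent heterosis, not any
  particular published p-value (which depends on the original measurements
  and the exact ANOVA employed there).
* qPCR: Livak 2^(−ΔΔCt) with ΔCt averaged per group before differencing;
  the calibrator group is 1 by construction.

## Numerical conventions

* Percentages are rounded half away from zero to 2 decimals (the
  convention of hand-formatted tables; Python's built-in rounding is
  banker's).
* BH adjustment delegates to statsmodels (`fdr_bh`); the test suite keeps
  an independent step-up implementation as an oracle.
* Up/down percentages of an empty DEG set are reported as undefined
  (`None`), never 0/0.
* The simulator is bit-reproducible for a given spec + seed
  (`numpy.random.default_rng`); multi-time-point runs derive child seeds
  via `SeedSequence.spawn`.

## Problem sizes used by the shipped runs

The analysis drivers and the acceptance script run the full design at
20,000 genes × 6 time points × 3 genotypes × 3 replicates (differential
testing and classification at the two focal time points, 3 and 8 DAP);
the null-calibration run uses 10,000 genes with effect_log2 = 0; the
strong-effect recovery run uses 5,000 genes with effect_log2 = 3 and
φ = 0.05. Each completes in seconds on a single core.

## Known limitations

* Per-gene testing at n = 3 without variance shrinkage (no empirical-Bayes
  moderation); power at small fold changes is accordingly limited, and the
  simulation's recovery numbers quantify exactly that.
* Call-pattern classification inherits the mid-parent/dominance conflation
  described above; a dedicated additivity test (H vs (M+P)/2) would
  separate the two but is not part of the scheme implemented here.
* Expression-pattern classes are assigned independently per time point;
  no temporal modelling.
* FPKM is within-sample normalization only; no TMM/median-ratio
  between-sample correction (the simulator's uniform library sizes make
  this immaterial for the shipped runs; a per-sample depth jitter option
  exists to exercise the depth-cancellation property).
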