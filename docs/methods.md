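# Methods

This note documents the models, defaults and design choices behind
sipscope: what the simulator emulates, how the analysis statistics are
defined, and where the genuinely open decisions were made.

## The experimental design being modeled

A total-RNA SIP experiment incubates an environmental community with a
¹³C-labeled substrate alongside a ¹²C control. RNA extracted from each
incubation is separated by isopycnic centrifugation; each gradient is
collected densest-first into a small number of fractions whose density is
measured by weighing known volumes and whose rRNA content is quantified by
RT-qPCR. Because direct (amplification-free) sequencing needs a minimum
RNA input, fractions from duplicate gradients are pooled into four
libraries — ¹²C-light, ¹²C-heavy, ¹³C-light, ¹³C-heavy — and each library
is sequenced as total RNA and classified into SSU rRNA, LSU rRNA, mRNA
and other non-rRNA reads. sipscope consumes those classified count tables;
read QC and classification are upstream tools' business, and the simulator
stands in for them when testing.

## Buoyant-density model

The mean buoyant density of a species' RNA is linear in its ¹³C atom
fraction α and (weakly) in its GC content:

    rho(alpha, GC) = rho0 + delta_max * alpha + gamma * (GC - gc_ref)

| parameter | default | units | why |
|---|---|---|---|
| `rho0` | 1.7785 | g/ml | midpoint of the unlabeled-light pool window (1.778–1.779 g/ml) |
| `delta_max` | 0.0475 | g/ml | calibrated so α = 1 bands at 1.8260 g/ml, the labeled-heavy window midpoint (1.824–1.828 g/ml) |
| `gamma` | 0.0004 | g/ml per GC % | weak GC dependence, matching the ~1.5 % GC rise observed between ~1.78 and ~1.83 g/ml non-rRNA |
| `gc_ref` | 55 | % | reference GC of bacterial rRNA |
| `sigma` | 0.012 | g/ml | within-species band width; see below |

Within a species, molecules band as a Gaussian of width `sigma` truncated
to the gradient span and renormalized, so no mass is lost at the edges.
The default span is 1.755–1.845 g/ml cut into 7 equal fractions, fraction
1 densest (SIP fractions are collected densest-first). A warning is
emitted whenever a band's ±3σ range exceeds the span; with the default
geometry this is routine and harmless — about 2 % of an unlabeled band is
truncated at the light edge.

**Why sigma = 0.012.** The band width controls how far a partially labeled
band leaks into both pool windows. A narrower band (≈0.008 g/ml) makes a
half-labeled community (α = 0.5) band so cleanly between the windows that
the light pool contains no labeled reads at all, and EFs saturate at their
fully-labeled values — labeling intensity becomes unmeasurable. At 0.012
g/ml a species spans roughly three of seven fractions, partial labeling
leaves measurable signal on both gradient slopes, and the median labeled
EF rises monotonically with α, which is the qualitative behaviour a
graded labeling response must show. This value was fixed once as part of
the model design.

## Simulator

* **Community.** Relative abundances are symmetric Dirichlet(0.5) — a
  heavy-tailed prior producing the few-dominant-families structure typical
  of enrichment microcosms. Lineages are drawn on a random nested
  hierarchy (≈ n/12 phyla … n/3 families); the genus is unique per taxon
  so genus-level EFs map one-to-one onto ground truth. rRNA GC is
  N(55, 3) clipped to [40, 70] %. Exactly `n_labeled` taxa get α = 1
  (sweepable afterwards); the rest α = 0. Each taxon expresses 1–4
  transcripts with Dirichlet(1) expression weights and GC ~ N(58, 5),
  attached to a shared category→pathway hierarchy.
* **Read classes.** Default mix (SSU, LSU, mRNA, other) =
  (0.35, 0.64, 0.009, 0.001), i.e. 1 % non-rRNA — within the 0.6–2.2 %
  per-library range seen in total-RNA-seq of gradient fractions.
* **qPCR noise.** Multiplicative lognormal with CV 0.2 and mean multiplier
  1 (signal stays positive and unbiased); CV 0 returns the truth.
* **Duplicate gradients.** Two fractionations per isotope are combined by
  descending-density rank (identical fraction edges make rank equivalent
  to matching by density window) before pool selection; pool membership is
  then expanded back to the source-gradient fractions for read sampling.
* **Read sampling.** Multinomial at the library depth, with probability ∝
  species mass in the pool × class mix × (for mRNA) expression weight.
  Sequencing normalizes input mass, so only pool composition matters;
  default desk-scale depth is 10⁵ reads per library (real libraries run
  ~3×10⁷ — the statistics scale, the runtimes do not need to).
* **Linear amplification.** mRNA counts are resampled with per-feature
  weights w = exp(−κ(GC − 50)); rRNA rows are copied untouched (SSU GC is
  empirically insensitive to amplification). Default κ = 0.08 per GC %
  yields a mean mRNA GC drop near 2 percentage points at the default GC
  spread, matching the reported 2.1 ± 0.9 % shift in direction and size.
  The ≥300-fold mass gain of amplification is recorded as metadata only,
  since read counts are depth-normalized.

What the simulator does **not** emulate: nucleotide sequences and FASTQ,
classifier error and LCA ambiguity, chimeras, primer/copy-number bias,
eukaryotic or archaeal reads, isotope fractionation chemistry, substrate
kinetics. Passing tests therefore demonstrate the *arithmetic* of the
pipeline on communities with known truth — not robustness to annotation
error in real data.

## Pool selection

All four pools grow greedily from their gradient end (densest for heavy
pools, lightest for light pools) inward, stopping at the first fraction
where cumulative qPCR mass reaches `min_mass` (default 120 ng, the minimum
for direct sequencing plus parallel amplification). Pools of one isotope
never share a fraction; an impossible assignment raises an error naming
the failing pool. Ties in density break toward the lower fraction index
(collected earlier = heavier). The `heavy_cutoff` (default 1.815 g/ml)
marks where a labeled band is expected; when the ¹³C-heavy pool is forced
below it — as in an unlabeled control experiment with no dense band — the
selection proceeds with the heaviest fractions that yield sufficient RNA
(exactly the published control-fraction logic) and emits a warning.
Selection always uses the measured qPCR signal, never the simulator's
hidden true masses, so re-running the stage from a written fraction table
reproduces the pipeline bit for bit.

## Enrichment factors

EF = (heavy¹³C/light¹³C) − (heavy¹²C/light¹²C) on relative abundances.
Choices that the bare formula leaves open:

* **Normalization basis.** Taxa over the library's SSU reads; transcripts
  over its mRNA reads (matching the separate rRNA/mRNA treatment of the
  design). Reads whose lineage does not reach the requested level land in
  an `unclassified` bucket that counts toward denominators but is never
  ranked. A `classified_only` flag restricts denominators to classified
  reads for sensitivity analysis.
* **Zero handling.** Default pseudo-abundance = half the smallest nonzero
  proportion across the four libraries. With pseudo = 0 a zero light
  abundance is reported as undefined rather than infinite — infinite EFs
  are never emitted.
* **Hierarchy.** Each level is re-aggregated from counts with its own
  normalization; drill-downs restrict to the children of a named parent
  clade or category.
* **Display filters.** Taxa: mean relative abundance strictly above 1 %
  (so exactly 1 % is dropped); transcripts: at least 20 reads summed over
  the four libraries (so exactly 20 is kept). The mean is taken over the
  four libraries of the analyzed set; amplified and unamplified sets are
  never mixed in one EF.
* **Calling threshold.** The `interpretation` field follows the sign of
  the EF (positive = labeled). For automated calls against ground truth
  the pipeline additionally applies `ef_call_threshold` (default 1.0):
  at desk-scale depths the EF noise of unlabeled taxa has a standard
  deviation well under 0.2, so 1.0 sits far above the noise floor while
  genuinely labeled taxa score in the hundreds to tens of thousands. A
  sign rule alone would call roughly half of an unlabeled community
  labeled, which is useless as a detector.

## Accounting and diversity

Class tallies, count-weighted GC per class (GC is carried per feature —
count tables, not reads, are the exchange format), rare-feature counts,
and the paired two-tailed Student's t-test used for the three
amplified-vs-unamplified contrasts (non-rRNA %, mean mRNA GC, Shannon;
n = 4 pairs; p-values are reported raw, with no multiple-testing
correction, as in the motivating analysis). Shannon diversity is natural-log
and Chao1 is the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)), both
computed via scikit-bio; libraries are compared at native depth without
rarefaction (depths are recorded so users can subsample upstream).

## Numerical and reproducibility choices

* Fraction masses come from exact Gaussian CDF differences; tests verify
  them against brute-force quadrature at 10⁴ grid points per fraction.
* All randomness flows from one root seed through named substreams
  (`community`, `qpcr:<gradient>`, `reads:<pool>`, `amp:<pool>`) derived
  via `SeedSequence`, so stages are independently reproducible and two
  runs of one configuration are byte-identical.
* Output TSVs carry a header comment with the config hash and seed.
* Desk-scale problem sizes used throughout tests and the acceptance
  script: 20 taxa, 5 labeled, 10⁵ reads per library, 7 fractions, 20
  seeds — large enough for the multinomial statistics to stabilize, small
  enough to run the whole suite in seconds.

## Known limitations

* EFs carry no uncertainty; the calling threshold is calibrated to the
  simulator's noise regime, and real data with classifier noise,
  compositional coupling across taxa, or much shallower mRNA coverage will
  have a different (likely higher) noise floor.
* The density model is linear and species bands are Gaussian; real
  gradients show tailing, wall effects and RNA-modification effects that
  are not modeled.
* Pool selection assumes duplicate gradients share fraction geometry;
  strongly mismatched duplicates would need density-window matching finer
  than rank matching.
* The `other` non-rRNA class is a single undifferentiated bucket (tRNA
  and unclassifiable reads are not distinguished).
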