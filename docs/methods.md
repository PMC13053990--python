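# Methods

## Interactor calling

The calling statistic for a prey protein is the worst-case enrichment ratio
`R = min(observed bait intensities) / max(observed control intensities)`:
with typical designs of 3 bait and 4 control replicates it is the most
conservative of the 12 possible replicate-pair ratios, so a protein scores
highly only when *every* bait replicate exceeds *every* control replicate.
Calling proceeds in log2 space:

* **Fence.** The threshold is the upper Tukey outlier fence
  `Q3 + k·(Q3 − Q1)` (default `k = 1.5`) over the log2 ratios of all
  proteins quantified on both sides. At least 4 defined ratios are required;
  with fewer, quartiles are unstable and the caller refuses to run. The fence
  is data-dependent: a published threshold value from one experiment is the
  fence *of that dataset*, not a constant to reuse.
* **Quartile convention.** Linear interpolation between order statistics
  (the default of mainstream numeric libraries). Tukey hinges
  (median-of-halves) are selectable through `CallingParameters`; the two
  conventions differ by design on small n, which is why the convention is an
  explicit, recorded parameter.
* **Comparison.** Inclusive (`log2 R ≥ fence`) by default — the fence is a
  *minimum* ratio threshold — with a strict mode available.
* **Spectral-count rule.** mean(bait SC) / mean(control SC) ≥ 2. Means, not
  sums, so unequal replicate counts per side do not bias the rule. A zero
  control mean with nonzero bait counts gives +inf (passes); a zero bait mean
  gives 0 (fails). This keeps one uniform rule across both evidence routes.
* **Bait-only route.** Proteins never observed in controls have undefined
  `R`. They are called when ≥1 observed bait intensity strictly exceeds Q1 of
  the pooled distribution of every observed intensity cell in the experiment,
  and the spectral-count rule holds (automatically satisfied when control
  counts are all zero but bait counts are not).
* **Degenerate routes.** No observed bait intensity → `not_evaluable`, never
  an interactor. We require only ≥1 observed bait value before taking
  `min(bait)`; requiring more replicates is a stricter variant a user can
  impose upstream.
* **Ordering.** Calls are sorted by descending log2 ratio, with bait-only
  calls (nominally infinite enrichment) first and non-evaluable proteins
  last; ties break on protein id.

Two structural invariants are tested: global intensity rescaling leaves the
call set unchanged (every rule is scale-free), and raising a single bait
intensity can never un-call a protein (all rules are monotone in bait
intensity).

## Differential filtering

Both the two-condition proteome and the wild-type vs. motif-mutant
interactome comparisons use the same rule: class `up` iff `log2FC > 1` and
Welch `p < 0.05`; `down` iff `log2FC < −1` and `p < 0.05`; both inequalities
strict, so a protein at exactly 2-fold is never called. The fold change is
`log2(mean B / mean A)` on arithmetic means of observed linear intensities.
The Welch statistic is computed on log2-transformed observed intensities:
label-free intensities are approximately log-normal, and the log scale is
where the test's normality assumption is closest to holding; the fold change
and the test therefore use deliberately different aggregations (ratio of
means vs. difference of log-means), both reported per protein. Condition
orientation follows the lexicographic order of the two labels
(`conditionA` → `conditionB`), so relabelling, not column layout, controls
the sign.

Proteins observed in fewer than 2 replicates of either group are
`not_tested`. Zero-variance degenerate cases follow a fixed convention:
equal means → `t = 0, p = 1`; unequal means with zero variance in both
groups → `p = 0` with the result flagged degenerate. No multiple-testing
correction enters the classing rule; BH q-values are emitted alongside for
users who want them. The interactome comparison is gated on the wild-type
interactor list: proteins not called are excluded from the output entirely
rather than classed `ns`.

**Known limitation — small-sample size of Welch's test.** With 3 replicates
per group the Welch–Satterthwaite approximation is conservative: on the null
simulator the empirical rejection rate at `p < 0.05` is ≈ 0.03, not 0.05
(the scipy reference implementation reproduces the same value on pure normal
samples, so this is a property of the test at n = 3, not of this
implementation). The p-value distribution under the null is still close to
uniform (KS distance < 0.05 at 2000 proteins). Practitioners should read the
0.05 cutoff at n = 3 as slightly stricter than nominal.

## Synthetic data

The simulators generate the statistical structure the pipeline assumes, not
mass spectra:

* **AP-MS tables** (`generate_apms`): per-protein baseline
  `N(background_log2_mean = 25, background_log2_sd = 1.5)` shared between
  conditions, per-cell replicate noise `N(0, replicate_log2_sd = 0.25)`,
  planted interactors shifted by `enrichment_log2` (default 8) in bait
  samples only, with 3 bait and 4 control replicates by default. Missingness
  is missing-not-at-random: each cell is observed with probability
  `logistic(slope · (log2 I − midpoint))`; the midpoint defaults to `None`
  (dropout off) and is set near the background mean to produce the
  "detected only in bait IPs" regime that exercises the bait-only route.
  Spectral counts are Poisson with mean
  `sc_per_log2 · 2^(log2 I − background mean)` (default 5 at the background
  mean) and are forced to 0 where the intensity is unobserved — the simplest
  link producing correlated intensity/SC evidence. One seed per call;
  per-protein substreams via `SeedSequence(seed, spawn_key=(i,))`, so adding
  proteins never perturbs earlier rows. The planted interactors are the
  first `n_true_interactors` protein ids; an optional per-protein effect
  override lets the pipeline simulate a motif-mutant bait in which a subset
  of interactors drops to a residual enrichment.
* **Proteomes** (`generate_proteome`): same baseline scheme, two conditions,
  replicate noise `sd` (default 0.5 log2 units; 0.3 in recovery settings),
  planted proteins shifted by `diff_log2` in condition B, no missingness —
  the near-complete-quantification DIA regime.
* **Sequences** (`generate_sequences`): uniform random 20-letter sequences
  with motif literals overwritten at stated 1-based positions; the default
  demo plants a 6-residue motif at residues 21–26 of a 71-residue
  microprotein-sized sequence.

What the simulators do **not** emulate: peptide-level quantification and
roll-up, correlated contaminant structure across runs, batch effects,
intensity-dependent variance, shared-peptide ambiguity, and real disorder
structure in sequences. Passing recovery tests therefore demonstrates the
correctness of the rules and their implementation under the stated
generative model, not performance on real AP-MS data.

## SLiM scanning and partner inference

Patterns are matched at every start position independently (regex leftmost
semantics would drop overlapping occurrences); zero-length matches are
ignored. Coordinates are 1-based inclusive throughout. A match is
`in_disorder` only when wholly inside a supplied disordered region (disorder
prediction itself is out of scope; regions are inputs). Classes flagged
`requires_disorder` report only in-disorder matches, and inference can be
restricted to taxon-validated classes. Partner inference is pure set logic —
a protein is predicted iff it carries ≥1 domain signature templated by ≥1
matched motif class — and is tested against brute-force enumeration. The
bundled library is a synthetic toy (invented patterns, Pfam-style domain
ids); real ELM class regexes are curated data the user supplies as the same
TSV format.

## Phenotype formulas

All formulas are direct transcriptions of their definitions: mean-1 volume
normalization per reference group (the percent-smaller headline statistic is
reported on medians, with a mean-based variant); integrated density /
volume; `G1 = 100 − (S + G2 + M)`; wing cell density = hairs / area and mean
cell area = area / hairs (one hair per cell, 0.01 mm² default square);
`2^−ΔΔCt`; per-replicate median normalization of split-luciferase
luminescence with fold = mean(normalized candidate) / mean(normalized
control). Group comparisons use one-way ANOVA with Tukey HSD post-hoc
(statsmodels); two-group wing comparisons default to Student's t with a
Welch option elsewhere.

## Pipeline and problem sizes

`pipeline.run` drives simulate → call → differential (interactome and
proteome) → motif scan/mutate/infer/overlap from one YAML config and one
seed, writing every stage table plus `run_metadata.json` (seed, parameters,
computed fence, per-stage counts). Deterministic: identical config + seed
give byte-identical TSVs. Default sizes — 500-protein AP-MS tables with 20
planted interactors, 1000–2000-protein proteomes, 100-seed recovery sweeps —
were chosen so the full test suite and the acceptance script each complete
in well under a minute on a single core while keeping Monte-Carlo error on
recovery and calibration estimates below a percentage point.
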