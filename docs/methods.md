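# Methods

## Data model

The unit of analysis is a normalized genes × samples intensity matrix on an
absolute fluorescence scale, with a sample design mapping each column to a
condition: stem base (SB) at 0, 2, 6, 24, 72, 96, 144 or 192 hours
post-excision (hpe), fresh leaf, wounded leaf, or developed root.  Leaf and
root samples are organs, not timepoints; they carry fixed bookkeeping hpe
tags (0, 2, and a −1 sentinel respectively) only so that
(tissue, hpe, replicate) triples are unique, and all comparisons involving
them are keyed by tissue.  Intensities are never re-normalized: the
organ-identity cutoff of 500 is defined on the input scale.  Validation
requires at least two replicates per condition, unique opaque gene
identifiers, and finite non-negative values.  Probe-to-gene summarization
is upstream of this package: inputs are gene-level values, and no
probe-level handling is attempted.

## Rank Product test

For conditions A and B with nA and nB replicates, every pairwise replicate
ratio a_i/b_j forms one of K = nA·nB comparison columns (unequal
replication, e.g. 3 vs 4, is handled naturally by K = 12).  Within each
column genes are ranked by fold change — descending for the up direction,
ascending for down, ties receiving average ranks — and the statistic is the
geometric mean of the K ranks.  The down-direction statistic equals the
up-direction statistic on the elementwise reciprocal matrix.  Intensities
below a floor (default 1.0 on the input scale, far below signal) are
clamped before ratios so log-ratios stay finite.

Significance is a pooled permutation estimate with the add-one correction:

    p_g = (1 + #{permuted RP ≤ RP_g, pooled over genes and permutations})
          / (1 + N·n)

and the percentage of false positives is pfp_g = p_g·n / rank(RP_g).  Two
null schemes are implemented:

* **`arrays` (default).**  Each replicate array's values are independently
  permuted across genes, and ratios, ranks and rank products are recomputed.
  Ratio columns that share a replicate array still share it after
  permutation, so the correlation structure among the K columns is
  preserved.  This is the calibrated scheme: on a 5 000-gene null dataset
  (4 vs 4 replicates, noise CV 0.3, 1000 permutations) the test suite
  verifies that the fraction of genes with p < 0.01 stays within
  [0.005, 0.02] and the Kolmogorov–Smirnov distance of the p-values from
  uniform is below 0.02.
* **`ranks`.**  Rank values are permuted independently within each ratio
  column.  This treats the K columns as independent; because columns built
  from shared replicates are substantially correlated (≈0.5 for pairs
  sharing an array), the scheme overstates significance roughly ten-fold at
  the 1% level when K > 1.  It is retained because it is exactly enumerable
  on small instances — the suite checks the Monte-Carlo estimator against
  full enumeration over all (n!)^K within-column rank configurations — and
  because some descriptions of the method present this construction.

In both schemes the permuted columns are sorted once before shuffling, so
the permutation stream depends only on each column's value multiset; as a
consequence permuting the input gene order permutes all outputs identically
rather than merely in distribution.  Comparisons of permuted against
observed rank products are done on the log scale with a 1e-9 tolerance so
that rank multisets with equal products (e.g. {1,4} and {2,2}) compare
equal despite floating-point summation.

## Differential expression calls

Condition means are arithmetic means of replicate intensities, and
M = log2(mean_A/mean_B) is computed on the means (not as a mean of
per-replicate log-ratios).  A gene is called up when M > m_cut and the
up-direction p-value is below p_cut, down when M < −m_cut with the
down-direction p-value below p_cut, otherwise not significant; defaults
m_cut = 1 (two-fold) and p_cut = 0.01.  Whether the 0.01 threshold applies
to the raw permutation p-value or to the pfp is genuinely ambiguous in the
source analysis; the default thresholds the p-value and
`threshold_on="pfp"` switches, with no claim that either exactly matches
the original.  The standard comparison set is: every SB timepoint vs
0 hpe, consecutive SB timepoints (including the 72-vs-24 hpe window),
wounded vs fresh leaf, and root vs SB at 0 hpe.  Relative qPCR expression
is plain 2^−ΔCT without efficiency correction.

## Identity tracking

Wound-regulated genes are those called in either direction in the leaf
comparison; they are subtracted (plain set difference, idempotent) from
each timepoint's regulated set.  The subtraction is applied at every
timepoint, not only the early ones, mirroring the tabular presentation of
the original analysis.

The construction of the organ-identity sets is not fully specified in the
source; the implemented policy — deliberately explicit and configurable —
is the most literal reading of "organ-specific": a gene is SB-identity
(resp. root-identity) when it is significantly higher (per the joint
M/rank-product rule) in that organ than in *each* of the other two organs
(SB at 0 hpe, fresh leaf, root), and its focal-organ mean exceeds the
cutoff of 500.  No claim is made of matching the original 339/476 set
memberships, whose defining data are not available; 339 and 476 are used
as the default planted set sizes in the simulator.

The identity-shift table counts, per timepoint: regulated genes vs 0 hpe
(all, and minus wound), SB-identity genes whose mean at t fell below 500,
and root-identity genes whose mean at t rose above 500.  The largest-shift
interval maximizes |Δ repressed| + |Δ induced| over consecutive timepoint
pairs, ties resolving to the earlier interval.

## Category representation

The representation ratio of a category in one direction is
(N°xp/N°xt)/(N°ap/N°at).  The criterion is purely fold-based (flag "over"
at ratio ≥ 2, "under" at ≤ 1/2); no hypergeometric or Fisher p-value is
attached, matching the source analysis, whose "statistically over- or
under-represented" phrasing is otherwise unexplained.  Categories with
fewer than `min_category_size` genes (default 10; the source excluded
small hormone categories without stating a number) are excluded rather
than reported.  M = log2(ratio) is −inf when no category gene is regulated;
the raw counts are always retained.  Unannotated genes count toward N°at
and N°ap by default (they are genes and can be regulated); a switch
restricts the universe to annotated genes.  The same computation applied to
phytohormone categories across all timepoint-vs-baseline comparisons gives
the hormone time-course matrix.  Tables carry all counts, ratios, m-values
and flags; no plot rendering is included — the tab-separated matrices are
the interface.

## Synthetic data generator

The generator emulates the study conditions by default: 25 000 genes, SB
timepoints (0, 2, 6, 24, 72, 96, 144, 192 hpe), fresh/wounded leaf and
root, 3 replicates per condition, baseline intensities log-normal with
log-mean 6.2 and log-sd 1.0 (median ≈ 490, bulk spanning tens to
thousands, straddling the 500 cutoff), and multiplicative log-normal
replicate noise: intensity = mean·exp(N(−σ²/2, σ²)) with σ² = ln(1+CV²),
so replicate means are unbiased.  Default noise CV 0.3 is a typical
between-replicate variation for normalized array intensities.

Planted structure, all from disjoint gene pools:

* per comparison (default 200 genes, fold 4, half up/half down): an
  intensity *pulse* at one timepoint for each timepoint-vs-baseline
  comparison, a sustained *step* for each consecutive-timepoint comparison,
  and dedicated wound-only and root-vs-SB genes;
* *wound-shared* genes: a fraction (default 0.3) of the early (first two
  post-excision timepoints) pulse genes also regulated in wounded leaves,
  same direction;
* *identity* genes (defaults 339 SB / 476 root, the printed set sizes):
  step trajectories between 2000 and 100 crossing the 500 cutoff at
  scheduled timepoints, expressed only in their organ;
* *categories*: a plan of category sizes and enrichment ratios; a category
  of size n_xt planted at ratio r against a reference comparison receives
  round(r·n_xt·n_ap/n_at) members from that comparison's true up set, the
  rest from unregulated genes.  The default plan mirrors the study's
  annotation: five functional categories enriched in the 24→72 hpe window,
  hormone categories of realistic size with ethylene and jasmonate
  enriched, and cytokinin/brassinosteroid/salicylic-acid categories
  deliberately below the exclusion size.

Because pulses, steps and identity trajectories overlap across
comparisons, the ground truth is *derived* from the exact noise-free
condition means (a gene is true-DE in a comparison iff its mean ratio
differs from 1) rather than recorded per planting mechanism; this is the
only self-consistent scoring reference for every stage.  With the default
fold of 4 every true-DE gene also clears the M > 1 call threshold; folds
≤ 2 would plant effects below the callable threshold and are not
meaningful test conditions.  Enrichment ratios are exact at truth level
for the reference scope; the per-timepoint scope distributes quotas across
comparisons and is approximate when up-sets overlap.

What the generator does **not** emulate: dye bias, spatial or batch
artifacts, probe-level effects, intensity-dependent variance, correlated
gene modules, or partial annotation.  Tests passing on these data
therefore demonstrate algorithmic correctness and statistical calibration
under the stated noise model, not robustness to real-array artifacts.

## Pipeline and reproducibility

`run_pipeline` executes data → rank product/DE → gene sets → identity
shift → representation in order, writing tab-separated outputs and a JSON
manifest (config snapshot, package version, SHA-256 checksum per output,
stage wall times, and — for simulated data — sensitivity/FDP per comparison
against the planted truth).  One global seed is split via
`numpy.random.SeedSequence.spawn` into per-stage integer substreams
(< 2³¹), so stages are independently reproducible and two runs with the
same config and seed are byte-identical in every data output (manifest
wall-times excepted).  Stage errors abort the run with the failing stage
named.

## Problem sizes in the test and acceptance runs

The calibration and recovery checks run at 5 000 genes (null calibration,
spike recovery, 1000 permutations), 4 000 genes (enrichment recovery,
500 permutations, 5 seeds), 1 500 genes (noise-free identity exactness)
and 400–3 000 genes for structural and pipeline checks — sizes at which
the measured quantities are statistically stable while a full suite run
completes in about a minute.  Exhaustive-enumeration checks use 4-gene,
2-column instances (576 configurations).

## Known limitations

* The organ-identity policy and the p-vs-pfp thresholding are explicit
  choices where the source is silent; both are configurable.
* The pooled permutation p-value has resolution 1/(1+N·n); on very small
  gene sets (a handful of genes) the p < 0.01 criterion is unattainable
  and nothing will be called significant.
* pfp is reported per gene without monotonicity enforcement across the
  ranked list (no step-down smoothing).
* The `ranks` null is anti-conservative by construction for K > 1 and
  should only be used for enumeration-based verification.
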