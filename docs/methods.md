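# Methods

This note documents the models, defaults and numerical choices behind
condensate-profiler, and what the synthetic data do and do not establish.

## Profile assembly

The unit of analysis is a protein's relative elution profile across the
ordered fractions IP, P, S, T, U of every sample set (bait x condition x
time), averaged over replicates. Zeros in input tables are treated as
non-detections, matching label-free MS practice where absence of a
quantification means the signal fell below detection rather than a true
zero. The filter chain is fixed:

read → flag filter (reverse/contaminant/site-only rows, when the dialect
carries flags) → elution-detection filter (drop proteins never detected
in any IP column) → tagged-IP filter (keep proteins detected in at least
one *tagged* elution, any condition) → imputation → peptide→protein
rollup (sum of peptide intensities; pairwise-ratio LFQ reconstruction is
out of scope and a monotone aggregate exercises the same downstream
path) → replicate averaging → row sum-normalization over *all* fraction
columns → split into condition groups → per-row standardization (mean 0,
sd 1 within each condition's vector).

Both filters are kept, in that order, because they answer different
questions (detected at all vs. detected in a tagged elution); the
IP-centric filter controls the final protein set. Sum normalization
before the condition split keeps the two condition vectors on one shared
relative-abundance scale; standardization afterwards gives the clustering
shape-only vectors. Constant rows at standardization are dropped with a
logged warning rather than aborting a run. Imputation is applied at
whatever level is ingested (protein-level by default; peptide-level
tables are imputed before rollup) — with a sum rollup the two orders
differ only through the censoring model, and the choice is exposed by
simply ingesting the level you want.

## Missing-value imputation

Missingness in these data is left-censored (missing-not-at-random), so
the default is QRILC-style quantile-regression imputation: per column,
the sorted observed values are regressed on the standard-normal quantiles
of their plotting positions *within the full column* — the censored cells
occupy the lowest ranks — giving estimates (mu, sigma) of the underlying
complete distribution. Missing cells are then drawn from
N(mu, sigma^2) truncated above at the (missing-fraction + quantile_cut)
quantile, i.e. inside the censored left tail; `quantile_cut` (default
0.01) is the small buffer above the censoring point, as in the reference
implementation of the method. Observed cells are never altered, columns
with fewer than 5 observed values are refused, and everything is
deterministic given the seed. The alternative Perseus-style scheme draws
from N(mu − 1.8 sigma, (0.3 sigma)^2) with the conventional width/shift
defaults.

## Clustering and assignment

Fuzzy c-means with Euclidean distance; memberships initialized from a
symmetric Dirichlet(1) per row; best of `n_starts = 10` seeded starts by
final objective; convergence when max |ΔU| < 1e-6 or 1000 iterations.
Points coinciding with a centroid receive membership 1 there (split
equally over coincident centroids). The objective is evaluated after each
membership update, so the trace is non-increasing by construction of the
alternating minimization.

The fuzzifier comes from the Schwämmle–Jensen estimate (the formula
behind Mfuzz's `mestimate`), a function of N and D only. The cluster
count is the smallest c (scanning c = 2 … min(N−1, 25)) at which the two
marker proteins take different argmax clusters on the best-of-starts
model; the scan record (per-c separation and objectives) is part of the
output, and failure to separate raises with those diagnostics. Ties at
the argmax resolve to the lowest cluster index and are logged. Markers
may be their cluster's only member.

Assignment: argmax in a marker cluster → that granule; two highest
memberships being the two marker clusters with min(score_A, score_B) ≥
τ = 0.001 → "both"; anything else → "none". τ, the `s0 = 2` of the
baseline t-test, the down-shift parameters (0.3, 1.8) and the polyA
minimum run (8) are the field-standard values for this analysis and are
all exposed in config.

## Set statistics

Identifiers are normalized (trimmed, case-folded, and the yeast
protein-name "p" suffix after a digit removed) because published lists
mix Dcp1/Dcp1p forms. Enrichment is the upper-tail hypergeometric test
(lower tail for depletion) with Benjamini–Hochberg adjustment across
terms — the default of the standard enrichment tooling when no method is
named. The s0-moderated t-test adds s0 to the Welch standard error;
q-values use a label-permutation null (complete enumeration when the
number of distinct relabelings is at most `n_perm`, else seeded
sampling), with the Storey-style ratio of mean null exceedances to
observed exceedances, clipped to [0, 1] and monotonized in |t|. This is a
fully specified stand-in for the version-dependent permutation FDR of the
usual desktop software.

## Sequence features

PolyA tracts are maximal runs of ≥ 8 adenosines, scanned case-insensitively
with U ≡ T, on the whole transcript by default (a CDS-only mode is
provided since coding-region composition is also of interest; which
region the original analyses scanned is not stated). Coordinates are
0-based half-open internally and 1-based inclusive in exported tables.
UTR candidates are selected per (transcript, side) by highest read
support, ties to the longest then first-in-input (logged). Count
normalization is median-of-ratios; TE = log2((footprint + 0.5) /
(total + 0.5)) on normalized counts — a documented simplification of the
shrinkage-based estimate, adequate at simulated depths. Mann–Whitney
comparisons use the exact null (no ties, smaller group ≤ 20) or the
tie- and continuity-corrected normal approximation, with the usual
*/**/*** codes at 0.05/0.01/0.001. Amino-acid composition profiling
reports (C_sample − C_background)/C_background per residue and per named
property group (aromatic FWY, Kyte–Doolittle hydrophobic, Vihinen
flexible, disorder-promoting; editable data file), with two-sided
bootstrap p-values from resampling whole sequences within each
collection.

## Synthetic data: what it emulates and what it does not

The proteome generator plants seven protein classes — one seed (marker)
per bait, granule-unique members of each condensate, dual-localized
proteins (convex 0.5/0.5 mixtures of the two granule templates, designed
to produce intermediate membership scores), sticky contaminants (high IP
signal in every bait including untagged) and background — with per-class
fraction-weight templates, a log2-normal abundance distribution
(mean 23, sd 1.5, LFQ-like), multiplicative log-normal noise (sd 0.3)
and logistic-in-log-intensity missingness calibrated to a 10% marginal
rate. The default study conditions are ~400 proteins (2 markers, 2 x 20
granule-unique, 10 dual, remainder background) in triplicate under the
two-marker, two-condition design (15/20 profile values). The bait is
always detected in its own elution, as it is in any successful IP. Noise
and missingness parameters are stand-ins — the real data's noise
structure is uncharacterized — so passing recovery tests demonstrates
correctness of the pipeline's logic under a plausible generative model,
not performance on real spectra; peptide chemistry, protein inference
ambiguity and batch structure are not simulated.

Transcript groups control region lengths (log-normal with configurable
CV), base composition and planted polyA tracts; when tracts are
requested, accidental ≥ 8 A-runs are first broken so the planted count is
exact by construction. RIP-seq counts are gamma-Poisson (NB) with planted
fold changes in IP libraries and configurable size factors.

## Reported problem sizes

The acceptance computations use the default study conditions above
(~400 proteins), 2000-gene RIP-seq simulations, and the small worked
examples (20-element universe, 3-vs-3 t-test toy); these sizes make every
quantity reproducible in seconds while keeping the planted effects at the
magnitudes described.

## Known limitations

- Protein inference from shared peptides is first-mapped-wins; no
  grouping.
- The pipeline assumes the two markers exist in the profile matrix and
  that their clusters are distinct; inseparable markers are a hard error
  by design.
- The permutation FDR and the TE estimate are specified simplifications
  of desktop-software behaviour (see above), not re-implementations of
  any particular version.
- Disorder scores, polyA tail lengths, structure indices and half-lives
  are consumed as published per-gene columns, never recomputed.
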