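# condensate-profiler

Quantitative assignment of proteins to P-bodies (PBs) and stress granules
(SGs) from multi-fraction immunoprecipitation proteomics, with the
downstream set-overlap, enrichment and RNA sequence-feature analyses used
to characterize the resulting granule proteomes and transcriptomes.

## The problem

PBs and SGs are membrane-less ribonucleoprotein condensates that, in
budding yeast, form upon stresses such as glucose starvation. They are
hard to purify cleanly: a plain tagged-vs-untagged IP comparison is
dominated by abundant false positives. A LOPIT-style alternative measures
each protein's label-free quantification (LFQ) intensity across an ordered
series of fractions — elution (IP), 20,000 g pellet (P), supernatant (S),
total lysate (T) and IP-unbound (U) — for each bait strain (Dcp1-myc for
PBs, Pbp1-myc for SGs, plus untagged controls) and condition, and assigns
proteins to condensates by the *shape* of the whole elution profile rather
than by a single contrast.

This package implements that analysis as a tested, reusable pipeline:

1. **quant_ingest** — read protein/peptide tables (generic TSV or MaxQuant
   `peptides.txt` / `proteinGroups.txt` dialects), treat zeros as
   non-detections, filter to proteins seen in at least one tagged
   elution, impute left-censored missing values (QRILC, or Perseus-style
   down-shifted normal), roll peptides up to proteins, average replicates,
   sum-normalize each protein's profile and standardize it per condition.
   Under the two-marker design this gives one 15-dimensional vector per
   protein for untreated samples (3 sample sets x 5 fractions) and one
   20-dimensional vector for glucose-depleted samples (4 x 5).
2. **granule_clustering** — fuzzy c-means on the standardized profiles.
   The fuzzifier *m* is estimated from the data shape (Schwämmle–Jensen
   formula). The cluster count *c* is chosen by a marker-anchored rule:
   increase *c* until the two bait proteins fall in different clusters.
   Each protein's membership vector **u** (rows sum to 1) then drives the
   assignment: argmax in a marker's cluster → that granule; two highest
   memberships in the two marker clusters with the lower ≥ τ = 0.001 →
   member of *both*.
3. **set_analysis** — exact Euler-region counts between granule lists,
   hypergeometric enrichment against custom gene sets with
   Benjamini–Hochberg correction, and the classical IP-enrichment
   baseline: a Welch t-test moderated by `s0` (default 2) with a
   label-permutation FDR.
4. **seq_features** — transcript length decomposition (5'UTR/CDS/3'UTR),
   UTR selection by read support, adenosine/AU content, polyA tracts
   (maximal runs of ≥ 8 A's), median-of-ratios count normalization,
   RIP-seq log2 IP/total enrichment, translational efficiency
   (TE = log2 footprint/total), Mann–Whitney comparisons against a
   background set, and amino-acid composition profiling.
5. **synthetic_data** — seeded generators for fractionation proteomics
   (planted granule/dual/background classes, log-normal noise,
   intensity-dependent missingness), transcript sets with planted polyA
   tracts and composition, and negative-binomial IP-vs-total counts with
   planted enrichment. Every downstream stage is testable against known
   ground truth without external downloads.
6. **cli / pipeline** — `condensate-profiler` orchestrates everything
   end-to-end with one config and a single global seed (per-stage seeds
   are derived deterministically), producing a machine-readable run
   report.

## The model in brief

Fuzzy c-means minimizes

    J = sum_i sum_j  u_ij^m  || x_j - v_i ||^2,    sum_i u_ij = 1,

by alternating the membership and centroid updates

    u_ij = 1 / sum_k (d_ij / d_kj)^(2/(m-1)),
    v_i  = sum_j u_ij^m x_j / sum_j u_ij^m.

The fuzzifier is estimated from N proteins in D dimensions as

    m = 1 + (1418/N + 22.05) D^-2
          + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134).

## Worked example

```python
from condensate_profiler import (
    packaged_gene_set, set_overlap, granule_ip_design, generate_quant_dataset,
    ingest_pipeline, estimate_fuzzifier, select_cluster_count, assign_membership,
)

# published interactor tables
pb, sg = packaged_gene_set("pb"), packaged_gene_set("sg")
res = set_overlap(pb, sg)
print(f"PB proteins: {res.n_a}, SG proteins: {res.n_b}, shared: {res.n_intersection}")

# synthetic study: simulate -> ingest -> cluster -> assign
design = granule_ip_design()
quant, truth = generate_quant_dataset(design=design, seed=1)
profiles, report = ingest_pipeline(quant, design, seed=1)
glucose = [p for p in profiles if p.condition == "glucose_depleted"][0]
print(f"profiles: {glucose.n_proteins} proteins x {glucose.dimensionality} values")

m = estimate_fuzzifier(glucose.n_proteins, glucose.dimensionality)
selection, model = select_cluster_count(glucose, ("seed_A", "seed_B"), m=m, seed=1)
assignment = assign_membership(model, ("seed_A", "seed_B"), tau=0.001)
print(f"fuzzifier m = {m:.3f}, clusters c = {selection.selected_c}")
print(assignment.table["label"].value_counts().to_dict())
```

prints

```
PB proteins: 47, SG proteins: 84, shared: 38
profiles: 391 proteins x 20 values
fuzzifier m = 1.159, clusters c = 3
{'none': 339, 'granule_B': 22, 'granule_A': 21, 'both': 9}
```

The packaged bait-interactor tables share 38 proteins between PBs and SGs
while the two pre-stress lists are disjoint. On the simulated study the
pipeline keeps 391 of 400 planted proteins after the tagged-elution
filter, estimates a fuzzifier of 1.159 for the 20-dimensional
glucose-depleted profiles, separates the two markers at c = 3, and
recovers the planted granule-A (20+marker), granule-B (20+marker) and
dual (10) classes almost exactly.

The same steps are available from the shell:

```
condensate-profiler simulate proteome --seed 1 --out out/
condensate-profiler ingest --quant out/quant.tsv --seed 1 --out out/
condensate-profiler cluster --profiles out/profiles_glucose_depleted.tsv \
    --markers seed_A,seed_B --seed 1 --out out/
condensate-profiler run --seed 1 --out out/   # everything at once
```

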