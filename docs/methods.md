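# Methods

## Overview

`chemoclass` implements an ecometabolomics workflow that assigns unknown
DDA MS2 fragment spectra to ChemOnt compound classes and carries the class
assignments through to community-level statistics: per-sample class-count
matrices, diversity indices, chemotaxonomic trees and their comparison to a
phylogeny, and variation partitioning over study factors.

The workflow has six stages, each usable on its own:

1. **Extraction** (`spectra_io`) — MS2 scans are read from mzML, replicate
   fragmentation events are merged, and the evaluated mass/retention-time
   window is applied.
2. **Library and ontology** (`ontology`) — a reference spectral library
   whose entries carry ChemOnt class lineages, and per-class
   foreground/background training splits.
3. **Classification** (`classification`) — one binary classifier per
   compound class, with empirical p-values against the background score
   distribution.
4. **Evaluation** (`evaluation`) — cross-validated precision–recall
   metrics per class.
5. **Chemodiversity** (`chemodiversity`, `tree_comparison`) — count
   matrices, Shannon/Pielou indices, Bray–Curtis dendrograms,
   cophenetic/Mantel/Robinson–Foulds tree comparison.
6. **Ecological statistics** (`eco_stats`) — dbRDA variation partitioning,
   envfit vector fitting, one-way ANOVA with Tukey HSD letters.

## Spectrum extraction and merging

An MS2 scan becomes a `FragmentSpectrum` (precursor m/z, retention time in
seconds, peak list sorted ascending in m/z). Scans without a precursor
record are skipped with a warning rather than aborting a whole run, since
vendor conversions occasionally drop precursor elements.

Replicate fragmentation events of one compound are merged per sample by
**single-linkage connected components** over the graph joining spectrum
pairs with |Δprecursor m/z| ≤ 0.01 Da and |Δrt| ≤ 5 s. Single linkage is
the only order-independent reading of pairwise "similar spectra were
merged"; any greedy scheme would depend on scan order and break
reproducibility. Consequences: merging is idempotent, invariant under
permutation of the input, and conserves members (the member counts of the
output sum to the input size). Chains can extend beyond one tolerance from
end to end; with 0.01 Da at DDA precursor spacing this is rare and
accepted.

The consensus spectrum of a component uses intensity-weighted means
(weight = total peak intensity of the member) for precursor m/z and
retention time, and pools fragment peaks re-binned at 0.01 Da keeping the
maximum member intensity per bin — the strongest evidence for each
fragment survives, and low-quality members cannot dilute it.

The evaluated window — precursor mass 50–1000 Da, retention time
10–1020 s — is applied with **inclusive** bounds ("between x and y" read
inclusively; the boundary behaviour is fixed so conservation-style checks
are well defined). The mass window is interpreted on precursor m/z,
matching the instrument scan range; neutral-mass reconstruction from
charge states is out of scope. Merging ignores collision energy: DDA
ramps collision energy with precursor mass, and the merge rule is defined
on mass and time only, so stepped-energy replicates of one precursor
merge into one entity.

mzML parsing is implemented directly on `lxml` (controlled-vocabulary
terms for ms level, scan start time with unit normalization, selected ion
m/z, charge, collision energy; base64 32/64-bit float peak arrays with
optional zlib compression). Spectra are exchanged on disk in the NIST MSP
text dialect (`Name`, `PrecursorMZ`, `RetentionTime`, optional `Comment`,
`Num Peaks`, then one `mz intensity` pair per line); m/z round-trips at
4-decimal precision. Reference libraries carry their annotations in the
Comment field as `InChIKey=<key>; ChemOnt=<id;id;...>`.

## Ontology and training splits

The ontology is a rooted hierarchy of classes keyed by 7-digit ChemOnt
ids. The packaged table (`data/chemont_classes.tsv`) covers the 35
compound classes evaluated in the bryophyte study plus an
"Organic compounds" root; each class is parented to its nearest ancestor
that is itself in the table, i.e. the hierarchy is pruned to the study's
classes (intermediate ChemOnt nodes are not represented). Carbohydrates
and carbohydrate conjugates is keyed by its actual ChemOnt id 0000011;
0001542 belongs to Disaccharides.

A spectrum's **class lineage** is the closure of its most specific
class(es) under the parent relation, so a flavonoid glycoside belongs to
Flavonoid glycosides, Flavonoids, Phenylpropanoids and polyketides, and
the root. For a target class, the **foreground** is every library spectrum
whose lineage contains the class and the **background** is everything
else; foreground counts are therefore monotone from child to parent.
Classes with fewer than 10 foreground spectra (or an empty background,
e.g. the root) are flagged untrainable and reported with zero metrics —
an empirical p-value and a PR curve are meaningless below that.

## The per-class classifier

Each spectrum is reduced to the set of 0.01 Da fragment bins
(`floor(mz / w)`) occupied by peaks with intensity strictly above the
abundance threshold of 100 counts. The classifier is a naive-Bayes-style
log-likelihood ratio on these binary bins:

    score(x) = Σ_{b ∈ bins(x)} log( fg_rate(b) / bg_rate(b) )

with Laplace-smoothed occurrence rates
`fg_rate(b) = (count_fg(b) + α) / (n_fg + 2α)` (α = 1), and likewise for
the background. A bin never seen in training contributes the baseline
ratio `log((n_bg + 2α)/(n_fg + 2α))` per occupied bin. The classifier is
deliberately simple: it trains directly from the foreground/background
presence data, yields a continuous score that admits an empirical
p-value, and has no tuned hyperparameters, so retraining is bit-for-bit
reproducible. Fragment presence/absence is used rather than intensity
weighting; intensities enter only through the abundance threshold.
Neutral losses are not featurized (an extension point).

Significance of a score s is the add-one right tail of the background
score distribution, `p = (1 + #{background scores ≥ s}) / (N + 1)` — the
standard permutation-test convention, with ties counted toward the tail so
p ∈ (0, 1]. Predictions with p ≤ 0.05 are retained. Output is
multi-label with no mutual exclusion, including ancestor/descendant
co-assignment; a spectrum with no retained assignment is "not matched".

**Leave-one-out background scoring.** The background score distribution is
computed by scoring each background spectrum with its own contribution
removed from the background bin counts
(`(count(b) − 1 + α)/(n_bg − 1 + 2α)` for its occupied bins). In-sample
scoring would be anti-conservative: every bin of a training background
spectrum is by construction "seen", so such spectra never receive the
positive unseen-bin baseline that any fresh spectrum's novel noise bins
receive, which deflates the null distribution and inflates the retained
rate far above α (measured ≈0.4 instead of 0.05 on a no-signal library).
With leave-one-out scoring the null scores are exchangeable with the
scores of fresh background-distributed spectra and the retained rate per
class matches α within binomial error.

## Evaluation

Because foreground/background ratios are heavily imbalanced, performance
is summarized with the **area under the precision–recall curve** and the
sensitivity at a fixed operating point. The PR curve sweeps all distinct
score thresholds descending, processing tied scores as one block;
`auc_pr` integrates right-continuous steps over recall (equal to average
precision). The operating-point metric (`tpr_at_rate`, reported as
TPR-FNR) picks the smallest threshold at which at most 5% of negatives
score at or above it — i.e. 95% specificity — and reports TP/P there. It
is 1 for a perfect classifier and ≈0.05 under the null.

Cross-validation is **compound-grouped** k-fold (default k = 5): all
spectra of one compound stay in one fold, so near-identical replicate
spectra cannot leak between training and test. Out-of-fold scores are
pooled over folds before computing the metrics. Classes whose foreground
is smaller than max(k, 10) — or that lose trainability inside a fold —
are reported as (0, 0), the convention for "could not assign enough
spectra".

## Chemodiversity statistics

A **chemical entity** is one merged, filtered MS2 spectrum, treated as a
proxy for one compound. Count matrices tally distinct entities per
(group, class), where the group is the sample or a factor level (species,
season); an entity is counted once per cell regardless of how many
spectra or samples support it. Sunburst aggregation adds each entity to
every class in the union of the lineages of its retained assignments, so
parents accumulate descendants and the root equals the number of matched
entities; unmatched entities are reported separately.

Shannon diversity H′ = −Σ pᵢ ln pᵢ uses the natural log (the vegan
default) and Pielou evenness J = H′/ln S, undefined for richness ≤ 1.
Uniqueness per factor level counts entities present at that level and
nowhere else. Heatmap exports use log(1 + x) so zero counts stay finite.

## Trees and their comparison

Species-level count matrices give Bray–Curtis dissimilarities
d = Σ|x−y| / Σ(x+y) ∈ [0, 1] (undefined and a hard error for all-zero
rows). The chemotaxonomic dendrogram uses agglomerative clustering,
average linkage (UPGMA) by default — the standard choice for Bray–Curtis
community dendrograms — with single/complete/ward available. Inputs are
processed in sorted label order so tied merges resolve deterministically.

Tree comparison offers three complementary statistics:

- **Cophenetic correlation** — Pearson correlation of the two cophenetic
  distance vectors (merge height of the lowest common ancestor for
  dendrograms, patristic path length for phylogenies; a phylogeny without
  branch lengths falls back to unit lengths with a warning).
- **Mantel test** — Pearson r between off-diagonal distance vectors;
  significance by jointly permuting rows and columns of the second
  matrix, add-one p-value, 999 permutations by default.
- **Robinson–Foulds** — trees treated as unrooted; the symmetric
  difference of the nontrivial bipartition sets, normalized by the total
  number of nontrivial bipartitions of both trees so the value lies in
  [0, 1] and tolerates polytomies. The normalization convention is
  recorded in output metadata because reported values depend on it.

## dbRDA, variation partitioning, envfit, Tukey letters

dbRDA applies Gower double-centering to −½d², keeps the
positive-eigenvalue principal coordinates (the dropped negative-eigenvalue
magnitude is logged; Bray–Curtis is non-Euclidean, and a Lingoes-corrected
mode is available), regresses the coordinates on presence–absence coded
factors, and reports constrained / total positive inertia as the
explained fraction. With Euclidean input distances this reduces exactly
to classical RDA R². The Ezekiel adjustment
1 − (1 − R²)(n − 1)/(n − p − 1) is emitted alongside, with p the rank of
the centered predictor matrix.

Two-factor variation partitioning runs the three fits A, B and A+B:
unique(A) = R²(A+B) − R²(B), unique(B) symmetric, shared =
R²(A) + R²(B) − R²(A+B), residual the complement — the four fractions sum
to 1 identically. Both unadjusted and adjusted versions are reported;
the unadjusted fractions are the primary figures. Shared fractions can be
negative (suppression), which is expected behaviour, and a dominating
shared fraction triggers a confounding warning.

envfit regresses each external variable on the first two ordination axes;
r² is the squared multiple correlation, the direction the normalized
coefficient vector, and significance the add-one permutation tail of r²
under row shuffling of the variable. Constant variables are flagged with
r² = 0, p = 1.

Group comparisons use a one-way ANOVA F test with all-pairs Tukey HSD
(studentized range, pooled within-group variance, via statsmodels) and an
insert-and-absorb **compact letter display**: groups share a letter if and
only if their Tukey-adjusted p ≥ α. Equal variances are assumed (no Welch
variant). Zero-variance inputs with equal means yield a single shared
letter.

## Synthetic data generator

The generator exists so every stage can be exercised against known ground
truth without external data. It emulates two objects:

**Reference libraries.** Each compound class owns a *motif*: a set of
signature fragment bins (default 8 per class, pairwise disjoint across
classes). A member spectrum contains each signature bin with probability
p_in (default 0.9); a non-member with p_bg (default 0.05). On top, a
Poisson(noise_rate = 5) number of uniform noise peaks is added with
log-uniform intensities over [10, 10⁵], so roughly 70% of noise peaks
exceed the abundance-100 threshold and the threshold bites realistically;
signature peaks are always above threshold. The defaults put the
generator in a signal-dominated regime — several reliable diagnostic
fragments against a few noise peaks — which is the regime the
parameter-recovery checks describe (p_in 0.9 vs p_bg 0.05 with at least
five signature bins); under heavier noise the binned log-likelihood
ratio degrades gracefully but recovery is no longer near-perfect.
Precursor masses and retention times are uniform inside the evaluated
windows, so window filtering passes everything by construction and
violations can be injected deliberately.

**Study designs.** A fully crossed species × season design (defaults:
9 species, 4 seasons, 3 replicates — 108 samples, n = 12 per species and
n = 27 per season). Per-class expected entity counts are log-linear:
species traits are evolved by Brownian motion along a random ultrametric
species tree (so the true tree is consistent with the species effect
structure) and scaled by the species effect size; season traits are i.i.d.
normal scaled by the season effect. Defaults 1.0 vs 0.1 give the
10:1 species-dominated structure; realized counts are Poisson with the
expected value capped at 50 per (sample, class) to bound simulation size.
Each entity becomes one spectrum drawn from its class motif, plus a small
number of unclassifiable noise-only entities per sample. All generators
are pure functions of (parameters, seed).

What the generator does **not** emulate: real fragmentation chemistry,
isotope patterns, chromatographic peak shape, correlated noise across
spectra, retention-time drift, or library/class imbalance of real
MassBank data. Passing recovery tests therefore demonstrates the
statistical machinery is correct and calibrated, not that real-data
classification reaches any particular accuracy.

## Numerical and protocol choices

- Fragment bin width 0.01 Da (matches the merge tolerance); abundance
  threshold 100 counts, strict inequality ("above").
- Empirical p-values always use the add-one form with ties counted ≥, for
  Mantel and envfit permutation tests as well as classifier scores.
- Tied classifier scores enter/leave confusion matrices as one block.
- PCoA eigenvalues below 1e−10 · |λ₁| are treated as zero.
- Mantel, envfit and cross-validation take explicit seeds; identical
  seeds give bit-identical results.
- Problem sizes in the packaged checks (6 classes, 50 spectra/class
  libraries, 1,000 null unknowns, 100-seed design simulations, 99–999
  permutations) were chosen as the smallest sizes at which the binomial /
  Monte-Carlo error bands of the calibration and recovery properties are
  informative.

## Known limitations

- The per-class classifiers ignore fragment intensities and neutral
  losses; both are natural extensions of the fragment-vector contract.
- Single-linkage merging can chain across more than one tolerance width
  in very dense precursor regions.
- The empirical p-values are marginal per class; no multiplicity
  correction is applied across classes (by design, mirroring per-class
  reporting), so family-wise error over 35 classes is larger than α.
- dbRDA drops negative-eigenvalue axes by default; for strongly
  non-Euclidean dissimilarities the Lingoes-corrected mode changes the
  reported fractions, and both conventions are printed in reports.
- The pruned packaged ontology encodes only the study's 35 classes;
  analyses over other class sets must supply their own table.
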