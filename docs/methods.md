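# Methods

## Problem and model

Most peptides predicted to bind an HLA class-I molecule are never
recognized by T cells: binding is necessary but far from sufficient for
immunogenicity.  `epiforest` models the residual signal that separates
immunogenic from non-immunogenic HLA-I ligands using only
sequence-derived quantities plus one upstream binding statistic, and
applies the same machinery to single-substitution neoantigens.

A peptide of length L (8–12 residues in routine use) is split into HLA
**anchor positions** — the N-terminus, position 2 and the C-terminus,
buried in the binding groove — and **TCR-contact positions** 3..L−1
(1-based), assumed accessible to the T-cell receptor.  All sequence
features are computed over the contact positions only; positions are
1-based and the anchor set {1, 2, L} is fixed, not configurable.

The feature vector has 24 entries in antigen mode:

* **C1–C21** — for each of 21 per-residue physicochemical/structural
  scales (hydrophobicity, molecular weight, bulkiness, polarity,
  flexibility, secondary-structure propensities, …), the mean scale value
  over contact positions: `P_c = Σ_contact scale(P[x]) / (L − 3)`.
* **C22, frequency score** — `Σ_contact [f⁺(P[x]) − f⁻(P[x])]`, where
  f⁺/f⁻ are the amino-acid frequencies at contact positions of
  immunogenic / non-immunogenic training peptides, pooled across
  positions.  The sum is deliberately not length-normalized (a
  `normalize_frequency_score` flag exists, default off).
* **C23, peptide entropy** — `−Σ_contact f_bg(P[x]) log₂ f_bg(P[x]) /
  (L − 3)`, where f_bg is the residue's frequency in the human reference
  proteome; each position contributes its own term even for repeated
  residues.
* **C24, rank(%)** — the eluted-ligand percentile rank produced upstream
  by an MHC-binding predictor and supplied as input (never computed
  here; < 0.5 strong binder, 0.5–2 weak, > 2 non-binder).

Neoantigen mode adds, for a wild-type/mutant pair differing at exactly
one position: **C25** the Kyte–Doolittle difference of the substituted
residue pair (mutant − wild type), **C26** the differential agretopicity
index DAI = wt rank(%) − mut rank(%) (positive when the mutation improves
binding), and **C27** a 0/1 flag for a mutation at an anchor position.
C1–C24 are computed on the mutant sequence — the candidate presented
species; the wild type contributes only through C25/C26.  C25 is defined
at residue level rather than as a difference of peptide averages so that
it stays informative for anchor mutations (the peptide-average variant is
available via an option and differs only by the 1/(L−3) factor for
interior mutations).

The classifier is a random forest (500 trees by default; `mtry` — the
number of features tried per split — 15 in antigen mode, 14 in
neoantigen mode, capped at the number of available features).  Its score
is the fraction of trees voting immunogenic, banded as: score > 0.5
positive-high, 0.4 ≤ score ≤ 0.5 positive-low, score < 0.4
negative-high.  Boundary values fall into the middle band by decision:
the published band description leaves exactly-0.4/0.5 ambiguous.

## Frequency model and smoothing

f⁺/f⁻ are estimated pooled over all contact positions of all training
peptides of a class (a single 20-entry table per class, not per-position
tables, which would be data-starved at realistic corpus sizes).  A
Laplace pseudocount of 1 per amino acid (configurable) keeps rare
residues at nonzero frequency, stabilizes C22, and guarantees C23's
logarithm is defined.  The default background table is a frozen
approximation of the human proteome's residue composition shipped with
the package; a proteome FASTA may be supplied to recompute it (also
pseudocounted).  One pooled frequency model is estimated over all
supertypes, mirroring the single published model; supertype-stratified
estimation can be layered on by filtering the training set first.

C22 is intentionally label-derived: each training record's residues
contribute to the class tables it is scored against.  This is inherent
to the feature's construction.  Consequence: at effect size 0 a
training-data importance measure (Gini) can detect the small self-
contribution; the default shadow-screen importance is therefore computed
on a held-out split, where the null screen is clean.

## Curation cascade

Training corpora are filtered in the fixed order length → deduplication
→ rank → proteome → supertype, with every removal logged:

* length 8–11 for training (8–12 accepted at prediction time);
* one record per (sequence, allele); a label conflict keeps the
  immunogenic record (any validated T-cell response makes a peptide
  immunogenic);
* negatives with rank(%) strictly greater than 2 are removed (they were
  likely never presented, so they say nothing about TCR recognition);
  the boundary value 2.0 is retained;
* negatives occurring verbatim as a substring of a reference protein are
  removed (central tolerance, not TCR preference); matching is exact
  substring because epitopes are protein fragments;
* records whose allele is unmapped or outside the allowed supertypes are
  removed when a supertype restriction is requested.

Positives are never removed by the rank or proteome filters.  The
cascade is idempotent and its per-class stage counts are monotonically
non-increasing.

## Shadow-feature screen

The all-relevant screen duplicates every active feature, permutes each
duplicate, fits a 100-tree forest on the joined table and counts a *hit*
for a real feature whose importance exceeds the maximum shadow
importance.  A feature indistinguishable from its shadows earns hits
like a Binomial(n, ½) draw, so a two-sided binomial test at α = 0.01
confirms (significantly many hits) or rejects (significantly few);
rejected features leave the forest, and whatever is undecided at
`max_iter` is tentative.  With α = 0.01 the earliest possible decision
is at 8 iterations (0 or 8 hits) and confirmation at 15 iterations needs
≥ 13 hits, so short runs do not weaken the decision rule.  Importance is
the mean decrease in held-out accuracy over 3 shuffles (30% stratified
validation split, all permuted copies scored in one batched forest
predict); impurity (Gini) importance is available via
`importance="gini"` but is more sensitive to the C22 self-contribution
noted above.

## Cross-validation and AUC

Generalization is estimated by stratified 5-fold CV repeated 3 times;
each record is scored exactly once per repeat by a fold model that never
saw it.  Out-of-fold scores are pooled within a repeat, an AUC is
computed per repeat, and the reported AUC is the mean over repeats
(per-fold AUCs are also kept).  Sensitivity and specificity are
evaluated at the 0.5 threshold on the pooled scores.  AUC is computed by
the rank-sum (Mann–Whitney) identity with mid-ranks, so tied
positive/negative pairs count one half; this equals brute-force pairwise
counting exactly and is tested against that oracle to 1e-12.  One master
seed drives fold assignment, forest construction and shadow
permutations; fold seeds are spawned deterministically from it.

## Synthetic data generator

The generator produces labeled corpora with the three structural
properties the method exploits, and nothing else:

* **Anchors** follow the presenting allele's published motif (17 common
  class-I alleles bundled, e.g. A02:01: position 2 ∈ {L, M}, C-terminus
  ∈ {I, L, V}); unconstrained anchors are uniform.  Default allele mix
  is A02:01-heavy (35%), echoing real corpora.
* **Contact composition**: class distributions are exponential tilts of
  the human background — immunogenic peptides up-weight the hydrophobic
  set {L, W, P, A, V, M} and down-weight the charged D and K by
  `exp(±effect · 0.35)`; non-immunogenic peptides get the opposite tilt.
  Effect size 0 makes the classes identically distributed; named levels
  none/weak/medium/strong = 0/0.25/0.5/1.
* **rank(%)** is log-normal (σ = 0.6) around a median of 0.8%, shifted
  down by `0.9·effect` log units for positives and up by `0.45·effect`
  for negatives, clipped to [0.01, 100].

Lengths are drawn from {8: 0.15, 9: 0.55, 10: 0.20, 11: 0.10},
approximating the class-I length distribution.  Mutant pairs draw a
wild-type from the neutral background, substitute one position (a
configurable fraction at anchors), and couple ranks so that immunogenic
pairs have positive mean DAI (wild-type rank inflated by 1.2·effect log
units over the mutant's).

What the generator does **not** emulate: proteasomal cleavage and TAP
preferences, per-position contact heterogeneity, linkage between
neighboring residues, allele-specific rank distributions, and the severe
class imbalance of real corpora (configurable but defaulting to
balanced).  Passing tests therefore demonstrate that the pipeline
recovers the statistical structure it assumes — not that real IEDB-scale
performance is reproduced, which would require the original corpus and
an MHC-binding predictor.

## Numerical and design choices

* Peptides must use the 20 standard residues; B/J/O/U/X/Z are rejected
  at construction (the scales are undefined for them).  Minimum length 4
  (the denominators L−3), recommended 8–12.
* The 21 scale tables are frozen in a diffable TSV with per-scale
  citations; where a characteristic exists in several published numeric
  variants the shipped variant is named in the citation column
  (e.g. Fauchère–Pliska for the second hydrophobicity scale, Browne's
  TFA coefficients for HPLC retention).
* DAI is defined on the rank(%) scale because that is the binding
  quantity the package ingests; an affinity column can be substituted
  upstream without code changes (the formula is the same difference).
* Model bundles are saved as a directory (serialized forest + JSON
  metadata with feature list, thresholds, seed, schema version and a
  content fingerprint of the training table); loading refuses a
  schema-version mismatch.
* Test and acceptance runs use reduced forest sizes (30–200 trees) and
  modest corpus sizes (hundreds to 1000 per class); these are the
  package's own default experiment sizes chosen so the full property
  suite runs on a laptop, and all statistical decision rules (α,
  thresholds, CV layout) are identical at any size.

## Known limitations

* No indels, frameshifts or multi-substitution neoantigens; pairs must
  be same-length single substitutions.
* rank(%) is an input; the package neither runs nor replaces an
  MHC-binding predictor, and predictions for records with rank(%) ≥ 2
  carry an explicit warning flag because the annotated allele likely
  does not present the peptide.
* The frequency model is pooled across supertypes; strongly
  supertype-specific TCR preferences are only captured through the
  anchor-aware features, not through per-supertype frequency tables.
* C22's training-label dependence means feature tables computed with a
  model's own frequency snapshot are mildly optimistic in-sample; use
  the persisted bundle's frequency model when scoring new data.
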