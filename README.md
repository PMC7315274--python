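# epiforest

Random-forest prediction of T-cell HLA class-I **epitope immunogenicity**
— for antigen peptides and single-substitution **neoantigens** — from
sequence-derived amino-acid features.

Most peptides predicted to bind an HLA class-I molecule never elicit a
T-cell response; binding predictors alone leave a large false-positive
burden for vaccine design and neoantigen prioritization.  `epiforest`
models the residual signal that separates immunogenic from
non-immunogenic HLA-I ligands, for immunologists and computational
biologists who already have MHC-binding predictions and want to rank the
binders by their chance of actually being recognized.

## The method

A peptide's N-terminus, position 2 and C-terminus are HLA anchor sites;
the remaining **TCR-contact positions** 3..L−1 carry the recognition
signal.  Over those positions the package computes, per peptide:

* **C1–C21** — mean values of 21 per-residue physicochemical scales,
  `P_c = Σ_contact scale(P[x]) / (L − 3)` (Kyte–Doolittle
  hydrophobicity, molecular weight, bulkiness, polarity, …);
* **C22** — frequency score `Σ_contact [f⁺(P[x]) − f⁻(P[x])]`, the
  contact-site amino-acid preference of immunogenic over
  non-immunogenic training peptides;
* **C23** — peptide entropy
  `−Σ_contact f_bg(P[x]) log₂ f_bg(P[x]) / (L − 3)` under the human
  proteome background f_bg;
* **C24** — the eluted-ligand percentile rank(%) from an upstream
  MHC-binding predictor (supplied as input, never computed here).

Neoantigen mode adds **C25** (hydrophobicity change at the mutated
position), **C26** (DAI, wt rank − mut rank) and **C27** (anchor-mutation
flag) for wild-type/mutant pairs differing at exactly one position.

A random forest (500 trees; mtry 15 antigen / 14 neoantigen) scores each
record by its fraction of immunogenic tree votes, banded as
positive-high (> 0.5), positive-low (0.4–0.5) or negative-high (< 0.4).
Training-set curation (rank > 2 negatives and proteome-identical
negatives removed, deduplication, supertype mapping), a Boruta-style
shadow-feature relevance screen, and repeated stratified 5-fold
cross-validation with rank-sum AUC complete the pipeline.  A synthetic
corpus generator with supertype anchor motifs, class-dependent contact
composition and class-dependent rank(%) makes everything testable
end-to-end.  See `docs/methods.md` for the full model description.

## Worked example

Simulate a strongly separated corpus, curate it, train, and score:

```bash
epiforest simulate --n-pos 300 --n-neg 300 --effect strong --seed 7 --out sim
epiforest curate   --input sim/peptides.tsv --out cur
epiforest train    --input cur/curated.tsv --seed 7 --n-trees 200 --out trained
epiforest predict  --input sim/peptides.tsv --model trained/model --out pred
```

which prints:

```
wrote 600 peptides to sim/peptides.tsv
curation cascade (kept counts):
  input                  positive=300    negative=300    unlabeled=0
  length                 positive=300    negative=300    unlabeled=0
  dedup                  positive=300    negative=300    unlabeled=0
  rank                   positive=300    negative=241    unlabeled=0
  removed records: 59
CV AUC (mean over 3 repeats of 5-fold): 0.930  sensitivity 0.886  specificity 0.848
scored 600 record(s); 59 carry a rank(%)>=2 HLA-mismatch warning
```

The cascade removed the 59 non-immunogenic records with rank(%) > 2
(peptides that were likely never presented, hence uninformative about
TCR recognition).  The cross-validated AUC of 0.93 says the forest
separates the generator's immunogenic class — hydrophobic-enriched
contact sites and lower rank(%) — almost completely; sensitivity and
specificity are evaluated at the 0.5 score threshold.  The prediction
table (`pred/predictions.tsv`) holds one row per input peptide:

```
id	score	category	rank_warning
syn000001	0.935	positive-high	False
syn000002	0.99	positive-high	False
```

`score` is the fraction of trees voting immunogenic, `category` the
score band, and `rank_warning` flags records with rank(%) ≥ 2, whose
annotated HLA allele likely does not present them.

The same works programmatically:

```python
from epiforest import GeneratorConfig, generate_dataset, train_antigen_model

peptides = generate_dataset(GeneratorConfig(n_pos=300, n_neg=300,
                                            effect_size="strong", seed=7))
bundle, cv, _ = train_antigen_model(peptides, seed=7, n_trees=200)
print(round(cv.auc, 3))   # 0.945
```

Neoantigen mode uses `epiforest simulate --neo`, `--mode neoantigen` for
training, and `epiforest neo-predict` with a wild-type/mutant pair table.

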