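"""End-to-end workflows tying featurization, selection, training and prediction.

These are the functions the command-line interface wraps; they are also
the convenient programmatic entry points:

>>> from epiforest import pipeline, synthetic
>>> config = synthetic.GeneratorConfig(n_pos=300, n_neg=300,
...                                    effect_size="strong", seed=7)
>>> peptides = synthetic.generate_dataset(config)
>>> bundle, cv = pipeline.train_antigen_model(peptides, seed=7)
>>> round(cv.auc, 2) >= 0.9
True
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .features import EpitopeFeaturizer
from .model import CVResult, ModelBundle, train
from .mutations import NeoantigenFeaturizer
from .peptides import MutantPair, Peptide
from .selection import SelectionResult, ShadowFeatureSelector

#: rank(%) above which an HLA-subtype mismatch warning is attached to
#: predictions: a weak/non-binder rank suggests the allele does not
#: present the peptide and the score is unreliable
RANK_WARNING_THRESHOLD = 2.0


def _check_labeled(records: Sequence) -> list[str]:
    labels = [r.label for r in records]
    if any(lab is None for lab in labels):
        n = sum(lab is None for lab in labels)
        raise ValueError(f"training requires labeled records; {n} are unlabeled")
    return labels


def train_antigen_model(
    peptides: Sequence[Peptide],
    seed: int | None = None,
    mtry: int | None = None,
    n_trees: int = 500,
    select: bool = False,
    selection_params: Mapping | None = None,
    smoothing: float = 1.0,
    background=None,
    **train_kwargs,
) -> tuple[ModelBundle, CVResult, SelectionResult | None]:
    """Featurize labeled peptides, optionally screen features, train and CV.

    When ``select`` is true a shadow-feature screen runs first and the
    model uses only confirmed features (falling back to all features if
    the screen confirms none).
    """
    labels = _check_labeled(peptides)
    featurizer = EpitopeFeaturizer(smoothing=smoothing, background=background)
    features = featurizer.fit(peptides).transform(peptides)
    selection = None
    feature_names = list(features.columns)
    if select:
        selector = ShadowFeatureSelector(
            random_state=seed, **(selection_params or {})
        )
        selector.fit(features, labels)
        selection = selector.result_
        if selection.confirmed:
            feature_names = selection.confirmed
    bundle, cv = train(
        features, labels, mode="antigen",
        frequency_model=featurizer.frequency_model_,
        mtry=mtry, n_trees=n_trees, seed=seed,
        feature_names=feature_names, **train_kwargs,
    )
    return bundle, cv, selection


def train_neoantigen_model(
    pairs: Sequence[MutantPair],
    seed: int | None = None,
    mtry: int | None = None,
    n_trees: int = 500,
    select: bool = False,
    selection_params: Mapping | None = None,
    smoothing: float = 1.0,
    background=None,
    **train_kwargs,
) -> tuple[ModelBundle, CVResult, SelectionResult | None]:
    """Neoantigen-mode counterpart of :func:`train_antigen_model`."""
    labels = _check_labeled(pairs)
    featurizer = NeoantigenFeaturizer(smoothing=smoothing, background=background)
    features = featurizer.fit(pairs).transform(pairs)
    selection = None
    feature_names = list(features.columns)
    if select:
        selector = ShadowFeatureSelector(
            random_state=seed, **(selection_params or {})
        )
        selector.fit(features, labels)
        selection = selector.result_
        if selection.confirmed:
            feature_names = selection.confirmed
    bundle, cv = train(
        features, labels, mode="neoantigen",
        frequency_model=featurizer.frequency_model_,
        mtry=mtry, n_trees=n_trees, seed=seed,
        feature_names=feature_names, **train_kwargs,
    )
    return bundle, cv, selection


def _featurize_for_bundle(bundle: ModelBundle, records) -> pd.DataFrame:
    if bundle.mode == "antigen":
        featurizer = EpitopeFeaturizer()
        featurizer.frequency_model_ = bundle.frequency_model
        featurizer.feature_names_ = [f"C{i}" for i in range(1, 25)]
    else:
        featurizer = NeoantigenFeaturizer()
        featurizer.frequency_model_ = bundle.frequency_model
        featurizer.feature_names_ = [f"C{i}" for i in range(1, 28)]
    return featurizer.transform(records)


def predict_records(
    bundle: ModelBundle, records: Sequence[Peptide] | Sequence[MutantPair]
) -> pd.DataFrame:
    """Score peptides (antigen bundle) or pairs (neoantigen bundle).

    Output columns: id, score, category, rank_warning.  ``rank_warning``
    is set when the record's rank(%) is >= 2: at that rank the peptide is
    likely not presented by the annotated allele and the score should be
    treated with caution.
    """
    features = _featurize_for_bundle(bundle, records)
    result = bundle.predict(features[bundle.feature_names])
    ranks = [
        (r.rank_percent if isinstance(r, Peptide) else r.mut_rank_percent)
        for r in records
    ]
    result["rank_warning"] = [
        bool(rk is not None and rk >= RANK_WARNING_THRESHOLD) for rk in ranks
    ]
    return result
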