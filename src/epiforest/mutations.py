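"""Neoantigen mutation features (C25--C27) and the 27-feature vector.

Neoantigens differ from their wild-type counterparts at (here) exactly one
position, and the properties of that substitution carry signal beyond the
mutant sequence itself:

* C25 — hydrophobicity delta: Kyte-Doolittle value of the mutant residue
  minus that of the wild-type residue at the mutated position.
* C26 — differential agretopicity index (DAI): wild-type rank(%) minus
  mutant rank(%); positive when the mutation improves predicted MHC
  binding.  Operationalized on the eluted-ligand percentile-rank scale
  this package ingests (an affinity column may be substituted upstream).
* C27 — anchor-mutation flag: 1 when the substitution sits at an HLA
  anchor position (N-terminus, position 2 or C-terminus), else 0.

The remaining C1--C24 block is computed on the MUTANT sequence — the
candidate presented species — with C24 the mutant's rank(%).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .features import (
    NEOANTIGEN_FEATURES,
    FrequencyModel,
    assemble_features,
    estimate_contact_frequencies,
)
from .peptides import MutantPair, Peptide, find_mutation
from .scales import KYTE_DOOLITTLE, get_scale

__all__ = [
    "find_mutation",
    "hydrophobicity_delta",
    "dai",
    "anchor_mutation_flag",
    "assemble_neo_features",
    "NeoantigenFeaturizer",
]


def hydrophobicity_delta(pair: MutantPair, peptide_average: bool = False) -> float:
    """Hydrophobicity change introduced by the substitution (C25).

    Default: Kyte-Doolittle value of the substituted residue pair,
    ``kd(mut) - kd(wt)`` at the mutated position.  With
    ``peptide_average=True`` the difference of the whole-peptide
    contact-site averages is used instead (zero for anchor mutations).
    """
    kd = get_scale(KYTE_DOOLITTLE)
    if peptide_average:
        from .features import compute_scale_feature

        return compute_scale_feature(pair.mut, kd) - compute_scale_feature(pair.wt, kd)
    pos = pair.mutation_position - 1
    return kd[pair.mut.sequence[pos]] - kd[pair.wt.sequence[pos]]


def dai(pair: MutantPair) -> float:
    """Differential agretopicity index (C26): wt rank(%) - mut rank(%)."""
    if pair.wt_rank_percent is None or pair.mut_rank_percent is None:
        raise ValueError(
            f"pair {pair.id!r}: both wild-type and mutant rank_percent are "
            "required to compute the DAI"
        )
    return pair.wt_rank_percent - pair.mut_rank_percent


def anchor_mutation_flag(pair: MutantPair) -> int:
    """1 when the mutation sits at an anchor position {1, 2, len}, else 0 (C27)."""
    return int(pair.is_anchor_mutation)


def assemble_neo_features(
    pair: MutantPair,
    model: FrequencyModel,
    scales=None,
    normalize_frequency_score: bool = False,
) -> dict[str, float]:
    """The 27-entry neoantigen feature vector for one pair, C1..C27 in order.

    C1--C23 are computed on the mutant sequence, C24 is the mutant's
    rank(%), and C25--C27 are the mutation features above.
    """
    if pair.mut.rank_percent is None:
        raise ValueError(
            f"pair {pair.id!r}: mutant peptide has no rank_percent; supply the "
            "eluted-ligand percentile rank for both members of the pair"
        )
    vector = assemble_features(
        pair.mut, model, scales=scales,
        normalize_frequency_score=normalize_frequency_score,
    )
    vector["C25"] = hydrophobicity_delta(pair)
    vector["C26"] = dai(pair)
    vector["C27"] = float(anchor_mutation_flag(pair))
    return vector


class NeoantigenFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer from wild-type/mutant pairs to the 27-feature table.

    ``fit`` estimates the contact-site :class:`FrequencyModel` from the
    MUTANT sequences of labeled pairs (a pair's label applies to its
    mutant); ``transform`` emits one row per pair with columns C1..C27,
    indexed by pair id.  Parameters mirror
    :class:`~epiforest.features.EpitopeFeaturizer`.
    """

    def __init__(
        self,
        smoothing: float = 1.0,
        background: Mapping[str, float] | None = None,
        normalize_frequency_score: bool = False,
    ) -> None:
        self.smoothing = smoothing
        self.background = background
        self.normalize_frequency_score = normalize_frequency_score

    def fit(self, X: Sequence[MutantPair], y=None) -> "NeoantigenFeaturizer":
        labels = list(y) if y is not None else [pair.label for pair in X]
        mutants = [
            Peptide(p.id, p.mut.sequence, p.mut.hla_allele, p.mut.rank_percent, lab)
            for p, lab in zip(X, labels)
        ]
        self.frequency_model_ = estimate_contact_frequencies(
            mutants, background=self.background, smoothing=self.smoothing
        )
        self.feature_names_ = list(NEOANTIGEN_FEATURES)
        return self

    def transform(self, X: Sequence[MutantPair]) -> pd.DataFrame:
        if not hasattr(self, "frequency_model_"):
            raise RuntimeError("NeoantigenFeaturizer must be fitted before transform")
        from .scales import list_scales

        scales = list_scales()
        rows = [
            assemble_neo_features(
                pair,
                self.frequency_model_,
                scales=scales,
                normalize_frequency_score=self.normalize_frequency_score,
            )
            for pair in X
        ]
        index = pd.Index([pair.id for pair in X], name="id")
        return pd.DataFrame(rows, index=index, columns=self.feature_names_, dtype=float)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
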