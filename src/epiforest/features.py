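"""Sequence-derived immunogenicity features for HLA class-I peptides.

All features are computed over the TCR-contact positions of a peptide:
the N-terminus, position 2 and the C-terminus are treated as HLA anchor
sites buried in the binding groove and are excluded throughout.  For a
peptide of length L the contact positions are 3..L-1 (1-based), L-3 of
them.

The antigen-mode feature vector has 24 entries:

* C1--C21 — the mean of a per-residue property scale over the contact
  positions,

      P_c = sum_{x in contact} scale(P[x]) / (L - 3)

* C22 — the immunogenic-peptide frequency score: the sum over contact
  positions of the difference between the contact-site amino-acid
  frequency in immunogenic peptides and in non-immunogenic peptides,

      P_score = sum_{x in contact} [ f+ (P[x]) - f- (P[x]) ]

  (an unnormalized sum; a length-normalization flag exists but is off by
  default),

* C23 — peptide entropy: the background-frequency information content of
  the contact residues, length-normalized,

      P_H = - sum_{x in contact} f_bg(P[x]) * log2 f_bg(P[x]) / (L - 3)

* C24 — the eluted-ligand percentile rank supplied with the record
  (produced upstream by an MHC-binding predictor; never computed here).

The class-conditional contact-site frequencies f+ / f- and the background
frequencies f_bg live in a :class:`FrequencyModel`, estimated from a
labeled training set by :func:`estimate_contact_frequencies` (or by
fitting an :class:`EpitopeFeaturizer`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .peptides import NEGATIVE, POSITIVE, Peptide, validate_sequence
from .peptides import STANDARD_AA
from .scales import AminoAcidScale, list_scales

ANTIGEN_FEATURES = tuple(f"C{i}" for i in range(1, 25))
NEOANTIGEN_FEATURES = tuple(f"C{i}" for i in range(1, 28))

_FREQ_TOL = 1e-9


class FrequencyModelError(ValueError):
    """Raised for invalid frequency estimation inputs or tables."""


def tcr_contact_positions(peptide: Peptide | str) -> list[int]:
    """1-based TCR-contact positions of a peptide: 3..len-1.

    Positions 1, 2 and the C-terminus are anchor sites and excluded.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else validate_sequence(peptide)
    return list(range(3, len(seq)))


def _contact_residues(seq: str) -> str:
    # slice equivalent of tcr_contact_positions: 1-based 3..len-1
    return seq[2 : len(seq) - 1]


def compute_scale_feature(peptide: Peptide | str, scale: AminoAcidScale) -> float:
    """Mean scale value over the TCR-contact positions (features C1--C21)."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else validate_sequence(peptide)
    contact = _contact_residues(seq)
    total = 0.0
    for offset, aa in enumerate(contact):
        try:
            total += scale.values[aa]
        except KeyError:
            raise KeyError(
                f"residue {aa!r} at position {offset + 3} has no value in "
                f"scale {scale.id}"
            ) from None
    return total / len(contact)


def _normalize(counts: Mapping[str, float], pseudocount: float) -> dict[str, float]:
    total = sum(counts.get(a, 0.0) for a in STANDARD_AA) + 20 * pseudocount
    if total <= 0:
        raise FrequencyModelError("cannot normalize an empty frequency table")
    return {a: (counts.get(a, 0.0) + pseudocount) / total for a in STANDARD_AA}


@dataclass(frozen=True)
class FrequencyModel:
    """Class-conditional contact-site and background residue frequencies.

    ``f_pos``/``f_neg`` are the pooled relative frequencies of each amino
    acid over all TCR-contact positions of immunogenic / non-immunogenic
    training peptides; ``f_background`` is the residue composition of the
    human reference proteome (or a user-supplied one).  ``n_pos``/``n_neg``
    record how many contact-site residues each estimate is based on.
    """

    f_pos: Mapping[str, float]
    f_neg: Mapping[str, float]
    f_background: Mapping[str, float]
    n_pos: int
    n_neg: int
    smoothing: float = 1.0

    def __post_init__(self) -> None:
        for name, table in (("f_pos", self.f_pos), ("f_neg", self.f_neg),
                            ("f_background", self.f_background)):
            if set(table) != set(STANDARD_AA):
                raise FrequencyModelError(f"{name} must cover the 20 standard amino acids")
            vals = np.array([table[a] for a in STANDARD_AA])
            if (vals < 0).any():
                raise FrequencyModelError(f"{name} contains negative frequencies")
            if abs(vals.sum() - 1.0) > _FREQ_TOL:
                raise FrequencyModelError(
                    f"{name} must sum to 1 (got {vals.sum():.12f})"
                )
        object.__setattr__(self, "f_pos", dict(self.f_pos))
        object.__setattr__(self, "f_neg", dict(self.f_neg))
        object.__setattr__(self, "f_background", dict(self.f_background))

    def swapped_classes(self) -> "FrequencyModel":
        """The model with immunogenic and non-immunogenic tables exchanged."""
        return FrequencyModel(
            f_pos=self.f_neg, f_neg=self.f_pos, f_background=self.f_background,
            n_pos=self.n_neg, n_neg=self.n_pos, smoothing=self.smoothing,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"f_pos": self.f_pos, "f_neg": self.f_neg, "f_background": self.f_background}
        ).loc[list(STANDARD_AA)]


def default_background() -> dict[str, float]:
    """The frozen human-proteome residue composition shipped with the package."""
    path = resources.files("epiforest.data").joinpath("background_frequencies.tsv")
    with path.open("r", encoding="utf-8") as fh:
        rows = [line.split("\t") for line in fh.read().splitlines()[1:]]
    table = {aa: float(v) for aa, v in rows}
    total = sum(table.values())
    return {a: table[a] / total for a in STANDARD_AA}


def background_from_proteome(
    sequences: Iterable[str], pseudocount: float = 1.0
) -> dict[str, float]:
    """Residue composition of a protein collection, with a pseudocount so
    every amino acid has strictly positive frequency (the entropy formula
    takes a logarithm of it)."""
    counts: Counter[str] = Counter()
    for seq in sequences:
        counts.update(a for a in seq.upper() if a in STANDARD_AA)
    if not counts:
        raise FrequencyModelError("proteome source contains no standard residues")
    return _normalize(counts, pseudocount)


def estimate_contact_frequencies(
    peptides: Iterable[Peptide],
    background: Mapping[str, float] | Iterable[str] | None = None,
    smoothing: float = 1.0,
) -> FrequencyModel:
    """Estimate class-conditional contact-site frequencies from labeled peptides.

    Residues at TCR-contact positions are pooled across all peptides of a
    class (one table per class, not per position).  A Laplace pseudocount
    (``smoothing``, default 1 per amino acid) keeps rare residues at
    nonzero frequency; set ``smoothing=0`` for raw relative frequencies.

    ``background`` may be a ready frequency table, an iterable of protein
    sequences to count, or ``None`` for the shipped human-proteome table.
    """
    pos_counts: Counter[str] = Counter()
    neg_counts: Counter[str] = Counter()
    for pep in peptides:
        contact = _contact_residues(pep.sequence)
        if pep.label == POSITIVE:
            pos_counts.update(contact)
        elif pep.label == NEGATIVE:
            neg_counts.update(contact)
    n_pos = sum(pos_counts.values())
    n_neg = sum(neg_counts.values())
    if n_pos == 0 or n_neg == 0:
        raise FrequencyModelError(
            "frequency estimation requires labeled peptides of both classes "
            f"(got {n_pos} immunogenic and {n_neg} nonimmunogenic contact residues)"
        )
    if background is None:
        f_bg = default_background()
    elif isinstance(background, Mapping):
        f_bg = _normalize(background, 0.0)
    else:
        f_bg = background_from_proteome(background)
    return FrequencyModel(
        f_pos=_normalize(pos_counts, smoothing),
        f_neg=_normalize(neg_counts, smoothing),
        f_background=f_bg,
        n_pos=n_pos,
        n_neg=n_neg,
        smoothing=smoothing,
    )


def frequency_score(
    peptide: Peptide | str, model: FrequencyModel, normalize: bool = False
) -> float:
    """Immunogenic-peptide frequency score (C22).

    Sum over contact positions of ``f_pos(residue) - f_neg(residue)``.
    The canonical form is an unnormalized sum; ``normalize=True`` divides
    by the number of contact positions.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else validate_sequence(peptide)
    contact = _contact_residues(seq)
    score = sum(model.f_pos[a] - model.f_neg[a] for a in contact)
    return score / len(contact) if normalize else score


def peptide_entropy(peptide: Peptide | str, model: FrequencyModel) -> float:
    """Peptide entropy (C23): background-weighted information of contact residues.

    ``-(sum over contact positions of f_bg(residue) * log2 f_bg(residue))
    / (len - 3)``, using the background frequency of each position's
    residue identity (duplicate residues are counted once per position).
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else validate_sequence(peptide)
    contact = _contact_residues(seq)
    total = 0.0
    for offset, aa in enumerate(contact):
        f = model.f_background[aa]
        if f <= 0:
            raise FrequencyModelError(
                f"background frequency of residue {aa!r} (position {offset + 3}) "
                "is zero; use a smoothed background"
            )
        total += f * np.log2(f)
    return -total / len(contact)


def assemble_features(
    peptide: Peptide,
    model: FrequencyModel,
    scales: Sequence[AminoAcidScale] | None = None,
    normalize_frequency_score: bool = False,
) -> dict[str, float]:
    """The 24-entry antigen feature vector for one peptide, C1..C24 in order.

    C24 is the eluted-ligand percentile rank carried by the record; it is
    an input, so a peptide without ``rank_percent`` is an error.
    """
    if peptide.rank_percent is None:
        raise ValueError(
            f"record {peptide.id!r} has no rank_percent; supply the eluted-ligand "
            "percentile rank column (from an MHC-binding predictor) before "
            "assembling features"
        )
    if scales is None:
        scales = list_scales()
    vector = {s.id: compute_scale_feature(peptide, s) for s in scales}
    vector["C22"] = frequency_score(peptide, model, normalize=normalize_frequency_score)
    vector["C23"] = peptide_entropy(peptide, model)
    vector["C24"] = peptide.rank_percent
    return vector


class EpitopeFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer from labeled/unlabeled peptides to the 24-feature table.

    ``fit`` estimates the :class:`FrequencyModel` (contact-site frequencies
    per class plus background) from labeled training peptides; ``transform``
    assembles one feature row per peptide.  Composes with scikit-learn
    pipelines: X is a sequence of :class:`~epiforest.peptides.Peptide`
    records and the output is a :class:`pandas.DataFrame` indexed by record
    id with columns C1..C24.

    Parameters
    ----------
    smoothing : float, default 1.0
        Laplace pseudocount for the frequency estimates.
    background : mapping, iterable of str, or None
        Background residue frequencies; ``None`` uses the shipped
        human-proteome table.
    normalize_frequency_score : bool, default False
        Divide C22 by the number of contact positions.
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

    def fit(self, X: Sequence[Peptide], y=None) -> "EpitopeFeaturizer":
        peptides = list(X)
        if y is not None:
            peptides = [
                Peptide(p.id, p.sequence, p.hla_allele, p.rank_percent, label)
                for p, label in zip(peptides, y)
            ]
        self.frequency_model_ = estimate_contact_frequencies(
            peptides, background=self.background, smoothing=self.smoothing
        )
        self.feature_names_ = list(ANTIGEN_FEATURES)
        return self

    def transform(self, X: Sequence[Peptide]) -> pd.DataFrame:
        if not hasattr(self, "frequency_model_"):
            raise RuntimeError("EpitopeFeaturizer must be fitted before transform")
        scales = list_scales()
        rows = [
            assemble_features(
                p,
                self.frequency_model_,
                scales=scales,
                normalize_frequency_score=self.normalize_frequency_score,
            )
            for p in X
        ]
        index = pd.Index([p.id for p in X], name="id")
        return pd.DataFrame(rows, index=index, columns=self.feature_names_, dtype=float)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
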