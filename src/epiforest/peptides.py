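"""Peptide and mutant-pair records: the units of prediction.

A :class:`Peptide` is a short HLA class-I candidate ligand (8--12 residues
in routine use) optionally annotated with its presenting HLA allele, an
eluted-ligand percentile rank produced upstream by an MHC-binding
predictor, and an immunogenicity label.  A :class:`MutantPair` is a
wild-type/mutant peptide pair differing at exactly one position, the input
of neoantigen-mode prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(STANDARD_AA)

#: label value for experimentally immunogenic records
POSITIVE = "immunogenic"
#: label value for validated non-immunogenic records
NEGATIVE = "nonimmunogenic"

VALID_LABELS = frozenset({POSITIVE, NEGATIVE})

#: shortest sequence for which contact-site features are defined
#: (the per-position averages divide by ``len - 3``)
MIN_SEQUENCE_LENGTH = 4

#: recommended length range for prediction
DEFAULT_LENGTH_RANGE = (8, 12)


class InvalidPeptideError(ValueError):
    """Raised when a sequence violates the peptide contract."""


def validate_sequence(sequence: str) -> str:
    """Validate and return an uppercase peptide sequence.

    The sequence must use the 20 standard one-letter codes only and be at
    least :data:`MIN_SEQUENCE_LENGTH` residues long.  Nonstandard codes
    (B, J, O, U, X, Z) are rejected because the per-residue property
    scales are undefined for them.
    """
    if not isinstance(sequence, str) or not sequence:
        raise InvalidPeptideError("peptide sequence must be a non-empty string")
    seq = sequence.upper()
    bad = sorted(set(seq) - _AA_SET)
    if bad:
        raise InvalidPeptideError(
            f"sequence {seq!r} contains nonstandard residue(s) {''.join(bad)!r}; "
            f"only the 20 standard one-letter codes are supported"
        )
    if len(seq) < MIN_SEQUENCE_LENGTH:
        raise InvalidPeptideError(
            f"sequence {seq!r} has length {len(seq)} < {MIN_SEQUENCE_LENGTH}; "
            f"contact-site features are undefined for such short peptides"
        )
    return seq


@dataclass(frozen=True)
class Peptide:
    """An annotated peptide record.

    Parameters
    ----------
    id : str
        Record identifier, unique within a dataset.
    sequence : str
        Uppercase sequence over the 20 standard amino acids, length >= 4.
    hla_allele : str, optional
        Presenting HLA allele, e.g. ``"A02:01"`` (any common notation is
        accepted by :func:`epiforest.curation.normalize_allele`).
    rank_percent : float, optional
        Eluted-ligand percentile rank from an upstream MHC-binding
        predictor; smaller is a stronger binder (<0.5 strong, 0.5--2 weak,
        >2 non-binder).  Required for feature assembly.
    label : str, optional
        ``"immunogenic"``, ``"nonimmunogenic"`` or ``None`` (unlabeled).
    """

    id: str
    sequence: str
    hla_allele: str | None = None
    rank_percent: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))
        if self.rank_percent is not None:
            rp = float(self.rank_percent)
            if rp < 0:
                raise InvalidPeptideError(
                    f"record {self.id!r}: rank_percent must be non-negative, got {rp}"
                )
            object.__setattr__(self, "rank_percent", rp)
        if self.label is not None and self.label not in VALID_LABELS:
            raise InvalidPeptideError(
                f"record {self.id!r}: label must be one of {sorted(VALID_LABELS)} "
                f"or None, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE


class MutationError(ValueError):
    """Raised for wild-type/mutant pairs that are not a single substitution."""


def find_mutation(wt: str, mut: str) -> int:
    """Locate the single substitution between two equal-length sequences.

    Returns the 1-based position at which ``wt`` and ``mut`` differ.
    Raises :class:`MutationError` for identical sequences, for pairs
    differing at two or more positions (only single-substitution
    neoantigens are supported), and for unequal lengths.
    """
    if len(wt) != len(mut):
        raise MutationError(
            f"wild-type and mutant lengths differ ({len(wt)} vs {len(mut)}); "
            "only same-length single substitutions are supported"
        )
    diffs = [i for i, (a, b) in enumerate(zip(wt, mut)) if a != b]
    if not diffs:
        raise MutationError("wild-type and mutant sequences are identical")
    if len(diffs) > 1:
        positions = [i + 1 for i in diffs]
        raise MutationError(
            f"sequences differ at {len(diffs)} positions {positions}; "
            "multi-substitution pairs are unsupported"
        )
    return diffs[0] + 1


@dataclass(frozen=True)
class MutantPair:
    """A wild-type/mutant peptide pair differing at exactly one position.

    ``mutation_position`` is derived (1-based) and must not be supplied.
    Each member carries its own ``rank_percent``.
    """

    id: str
    wt: Peptide
    mut: Peptide
    label: str | None = None
    mutation_position: int = field(init=False)

    def __post_init__(self) -> None:
        pos = find_mutation(self.wt.sequence, self.mut.sequence)
        object.__setattr__(self, "mutation_position", pos)
        if self.label is not None and self.label not in VALID_LABELS:
            raise InvalidPeptideError(
                f"pair {self.id!r}: label must be one of {sorted(VALID_LABELS)} "
                f"or None, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.wt.sequence)

    @property
    def wt_rank_percent(self) -> float | None:
        return self.wt.rank_percent

    @property
    def mut_rank_percent(self) -> float | None:
        return self.mut.rank_percent

    @property
    def is_anchor_mutation(self) -> bool:
        """True when the substitution sits at an HLA anchor position
        (N-terminus, position 2 or C-terminus)."""
        return self.mutation_position in (1, 2, len(self))

    def swapped(self) -> "MutantPair":
        """The pair with wild-type and mutant roles exchanged."""
        return MutantPair(id=self.id, wt=self.mut, mut=self.wt, label=self.label)
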