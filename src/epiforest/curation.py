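"""Training-set curation: negative-set filters, deduplication, supertype mapping.

Experimentally validated non-immunogenic records can be uninformative for
two reasons unrelated to TCR recognition: the peptide was never presented
(eluted-ligand rank(%) > 2, i.e. a non-binder), or it matches the human
reference proteome exactly and is subject to central tolerance.  Both
filters therefore remove NEGATIVE records only; a validated immunogenic
peptide is kept regardless.

The full cascade runs in a fixed order — length filter, deduplication,
rank filter, proteome filter, supertype filter — and every removal is
logged with its reason in a :class:`CurationReport` whose per-stage counts
are monotonically non-increasing per class.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .peptides import NEGATIVE, POSITIVE, Peptide

SUPERTYPE_LABELS = ("A1", "A2", "A3", "A24", "B7", "B8", "B27", "B44", "B58", "B62")

_ALLELE_RE = re.compile(r"^(?:HLA-)?([ABC])\*?(\d{2}):?(\d{2,3})$")


def normalize_allele(allele: str) -> str | None:
    """Canonicalize an HLA class-I allele name to e.g. ``"A02:01"``.

    Accepts ``"HLA-A*02:01"``, ``"A*02:01"``, ``"A02:01"``, ``"A0201"``;
    returns None when the name cannot be parsed.
    """
    if not allele:
        return None
    m = _ALLELE_RE.match(allele.strip().upper())
    if not m:
        return None
    locus, group, protein = m.groups()
    return f"{locus}{group}:{protein}"


@dataclass(frozen=True)
class SupertypeMap:
    """Mapping from normalized HLA allele names to functional supertypes."""

    alleles: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {a: s for a, s in self.alleles.items() if s not in SUPERTYPE_LABELS}
        if bad:
            raise ValueError(f"unknown supertype label(s): {bad}")
        object.__setattr__(self, "alleles", dict(self.alleles))

    def lookup(self, allele: str | None) -> str | None:
        """Supertype of an allele (any accepted notation), or None if unmapped."""
        if allele is None:
            return None
        norm = normalize_allele(allele)
        if norm is None:
            return None
        return self.alleles.get(norm)

    @property
    def supertypes(self) -> set[str]:
        return set(self.alleles.values())


@lru_cache(maxsize=1)
def load_default_supertype_map() -> SupertypeMap:
    """The shipped allele-to-supertype table (17 common class-I alleles)."""
    path = resources.files("epiforest.data").joinpath("supertypes.tsv")
    with path.open("r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    return SupertypeMap({r["allele"]: r["supertype"] for r in rows})


def map_allele_to_supertype(
    allele: str, supertype_map: SupertypeMap | None = None
) -> str | None:
    """Supertype label for an allele, or None when unmapped."""
    if supertype_map is None:
        supertype_map = load_default_supertype_map()
    return supertype_map.lookup(allele)


@dataclass
class CurationReport:
    """Bookkeeping of the filter cascade.

    ``stages`` records (stage name, n kept positive, n kept negative,
    n kept unlabeled) after each step; ``removals`` records
    (record id, stage, reason) for every dropped record.
    """

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)
    removals: list[tuple[str, str, str]] = field(default_factory=list)

    def log_stage(self, name: str, records: Sequence[Peptide]) -> None:
        n_pos = sum(1 for r in records if r.label == POSITIVE)
        n_neg = sum(1 for r in records if r.label == NEGATIVE)
        self.stages.append((name, n_pos, n_neg, len(records) - n_pos - n_neg))

    def log_removal(self, record_id: str, stage: str, reason: str) -> None:
        self.removals.append((record_id, stage, reason))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["stage", "n_positive", "n_negative", "n_unlabeled"]
        )

    def removals_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removals, columns=["id", "stage", "reason"])

    def summary(self) -> str:
        lines = ["curation cascade (kept counts):"]
        for name, n_pos, n_neg, n_unl in self.stages:
            lines.append(f"  {name:<22} positive={n_pos:<6} negative={n_neg:<6} unlabeled={n_unl}")
        lines.append(f"  removed records: {len(self.removals)}")
        return "\n".join(lines)


def filter_by_length(
    records: Sequence[Peptide],
    min_length: int = 8,
    max_length: int = 11,
    report: CurationReport | None = None,
) -> list[Peptide]:
    """Keep records with min_length <= len <= max_length.

    Training default is 8--11 (the curated corpus range); prediction-time
    use typically allows up to 12.
    """
    kept = []
    for r in records:
        if min_length <= len(r) <= max_length:
            kept.append(r)
        elif report is not None:
            report.log_removal(r.id, "length", f"length {len(r)} outside [{min_length}, {max_length}]")
    if report is not None:
        report.log_stage("length", kept)
    return kept


def deduplicate(
    records: Sequence[Peptide], report: CurationReport | None = None
) -> list[Peptide]:
    """One record per (sequence, allele); a label conflict keeps the positive.

    Rationale for the tie-break: a peptide with any validated T-cell
    response is immunogenic.
    """
    kept: dict[tuple[str, str | None], Peptide] = {}
    for r in records:
        key = (r.sequence, r.hla_allele)
        prev = kept.get(key)
        if prev is None:
            kept[key] = r
        elif r.label == POSITIVE and prev.label != POSITIVE:
            if report is not None:
                report.log_removal(prev.id, "dedup", f"duplicate of {r.id} (positive kept)")
            kept[key] = r
        else:
            if report is not None:
                report.log_removal(r.id, "dedup", f"duplicate of {prev.id}")
    result = list(kept.values())
    if report is not None:
        report.log_stage("dedup", result)
    return result


def filter_negatives_by_rank(
    records: Sequence[Peptide],
    threshold: float = 2.0,
    report: CurationReport | None = None,
) -> list[Peptide]:
    """Drop NEGATIVE records with rank(%) strictly greater than ``threshold``.

    A non-immunogenic peptide that is not even predicted to be presented
    (rank(%) > 2) says nothing about TCR recognition.  Positives are kept
    regardless of rank.  Every record must carry a rank value.
    """
    missing = [r.id for r in records if r.rank_percent is None]
    if missing:
        raise ValueError(
            f"rank filter requires rank_percent on every record; missing for "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    kept = []
    for r in records:
        if r.label == NEGATIVE and r.rank_percent > threshold:
            if report is not None:
                report.log_removal(
                    r.id, "rank", f"negative with rank(%) {r.rank_percent} > {threshold}"
                )
        else:
            kept.append(r)
    if report is not None:
        report.log_stage("rank", kept)
    return kept


def _proteome_kmer_index(proteome: Sequence[str], lengths: set[int]) -> set[str]:
    kmers: set[str] = set()
    for prot in proteome:
        seq = prot.upper()
        for k in lengths:
            if len(seq) >= k:
                kmers.update(seq[i : i + k] for i in range(len(seq) - k + 1))
    return kmers


def filter_negatives_by_proteome(
    records: Sequence[Peptide],
    proteome: Sequence[str],
    report: CurationReport | None = None,
) -> list[Peptide]:
    """Drop NEGATIVE records occurring verbatim inside a reference protein.

    A non-immunogenic self peptide reflects central tolerance rather than a
    TCR preference.  Matching is exact substring (epitopes are protein
    fragments); positives are never removed.
    """
    proteome = list(proteome)
    if not proteome:
        raise ValueError("proteome filter requires a non-empty protein collection")
    neg_lengths = {len(r) for r in records if r.label == NEGATIVE}
    kmers = _proteome_kmer_index(proteome, neg_lengths) if neg_lengths else set()
    kept = []
    for r in records:
        if r.label == NEGATIVE and r.sequence in kmers:
            if report is not None:
                report.log_removal(r.id, "proteome", "negative matches reference proteome 100%")
        else:
            kept.append(r)
    if report is not None:
        report.log_stage("proteome", kept)
    return kept


def filter_by_supertype(
    records: Sequence[Peptide],
    allowed: Iterable[str],
    supertype_map: SupertypeMap | None = None,
    report: CurationReport | None = None,
) -> list[Peptide]:
    """Keep records whose allele maps to one of the allowed supertypes.

    Records with unmapped or missing alleles are removed: peptides of the
    same supertype are assumed to share binding properties, so a record
    outside the training supertypes cannot be scored comparably.
    """
    allowed = set(allowed)
    if not allowed:
        raise ValueError("allowed supertype set must be non-empty")
    if supertype_map is None:
        supertype_map = load_default_supertype_map()
    kept = []
    for r in records:
        st = supertype_map.lookup(r.hla_allele)
        if st in allowed:
            kept.append(r)
        elif report is not None:
            reason = (
                f"supertype {st} not in allowed set" if st is not None
                else f"allele {r.hla_allele!r} unmapped"
            )
            report.log_removal(r.id, "supertype", reason)
    if report is not None:
        report.log_stage("supertype", kept)
    return kept


def curate(
    records: Sequence[Peptide],
    proteome: Sequence[str] | None = None,
    min_length: int = 8,
    max_length: int = 11,
    rank_threshold: float = 2.0,
    allowed_supertypes: Iterable[str] | None = None,
    supertype_map: SupertypeMap | None = None,
) -> tuple[list[Peptide], CurationReport]:
    """Run the full cascade: length -> dedup -> rank -> proteome -> supertype.

    The proteome and supertype stages run only when their inputs are
    supplied.  Returns the curated records and the stage-by-stage report.
    The cascade is idempotent: re-running it on its own output changes
    nothing.
    """
    report = CurationReport()
    report.log_stage("input", records)
    kept = filter_by_length(records, min_length, max_length, report)
    kept = deduplicate(kept, report)
    kept = filter_negatives_by_rank(kept, rank_threshold, report)
    if proteome is not None:
        kept = filter_negatives_by_proteome(kept, proteome, report)
    if allowed_supertypes is not None:
        kept = filter_by_supertype(kept, allowed_supertypes, supertype_map, report)
    return kept, report
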