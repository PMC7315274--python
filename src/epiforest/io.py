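"""Readers and writers for the package's plain-text formats.

Tab-separated tables (header row, UTF-8, ``.`` decimal, no quoting) for
peptide records, mutant pairs and feature matrices; FASTA (via Biopython)
for sequence-only peptide input and reference proteomes.  Peptide TSV
columns: ``id  sequence  hla_allele  rank_percent  label`` (the last three
optional).  Pair TSV columns: ``id  wt_sequence  mut_sequence  hla_allele
wt_rank_percent  mut_rank_percent  label``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .peptides import MutantPair, Peptide

_NA = ""


class ParseError(ValueError):
    """Raised when an input file violates its schema."""


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == _NA:
        return None
    return str(value)


def _opt_float(value) -> float | None:
    v = _opt(value)
    return float(v) if v is not None else None


def read_peptides_tsv(path: str | Path, require_rank: bool = False) -> list[Peptide]:
    """Read a peptide table; raises :class:`ParseError` with the offending line."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required column(s) {sorted(missing)}")
    if require_rank and "rank_percent" not in df.columns:
        raise ParseError(
            f"{path}: missing 'rank_percent' column; supply the eluted-ligand "
            "percentile rank from an MHC-binding predictor"
        )
    peptides = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            rank = _opt_float(d.get("rank_percent"))
            if require_rank and rank is None:
                raise ValueError("empty rank_percent")
            peptides.append(
                Peptide(
                    id=str(d["id"]),
                    sequence=str(d["sequence"]),
                    hla_allele=_opt(d.get("hla_allele")),
                    rank_percent=rank,
                    label=_opt(d.get("label")),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}, line {i}: {exc}") from exc
    return peptides


def write_peptides_tsv(peptides: Sequence[Peptide], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [p.id for p in peptides],
            "sequence": [p.sequence for p in peptides],
            "hla_allele": [p.hla_allele or _NA for p in peptides],
            "rank_percent": [p.rank_percent if p.rank_percent is not None else _NA
                             for p in peptides],
            "label": [p.label or _NA for p in peptides],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_pairs_tsv(
    path: str | Path, errors: str = "raise"
) -> tuple[list[MutantPair], list[tuple[str, str]]]:
    """Read a wild-type/mutant pair table.

    With ``errors="collect"`` invalid rows (multi-substitution, identical
    sequences, bad residues) are skipped and returned as (id, message)
    tuples so the rest of the file can still be processed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "wt_sequence", "mut_sequence"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required column(s) {sorted(missing)}")
    pairs: list[MutantPair] = []
    failures: list[tuple[str, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        pid = str(d["id"])
        try:
            allele = _opt(d.get("hla_allele"))
            pairs.append(
                MutantPair(
                    id=pid,
                    wt=Peptide(f"{pid}_wt", str(d["wt_sequence"]), allele,
                               _opt_float(d.get("wt_rank_percent"))),
                    mut=Peptide(f"{pid}_mut", str(d["mut_sequence"]), allele,
                                _opt_float(d.get("mut_rank_percent"))),
                    label=_opt(d.get("label")),
                )
            )
        except ValueError as exc:
            if errors == "collect":
                failures.append((pid, f"line {i}: {exc}"))
            else:
                raise ParseError(f"{path}, line {i}: {exc}") from exc
    return pairs, failures


def write_pairs_tsv(pairs: Sequence[MutantPair], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [p.id for p in pairs],
            "wt_sequence": [p.wt.sequence for p in pairs],
            "mut_sequence": [p.mut.sequence for p in pairs],
            "hla_allele": [p.wt.hla_allele or _NA for p in pairs],
            "wt_rank_percent": [p.wt_rank_percent if p.wt_rank_percent is not None
                                else _NA for p in pairs],
            "mut_rank_percent": [p.mut_rank_percent if p.mut_rank_percent is not None
                                 else _NA for p in pairs],
            "label": [p.label or _NA for p in pairs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_fasta_peptides(
    path: str | Path, sidecar_tsv: str | Path | None = None
) -> list[Peptide]:
    """Read peptides from FASTA; ranks/alleles/labels come from an optional
    sidecar TSV keyed by record id."""
    meta: dict[str, dict] = {}
    if sidecar_tsv is not None:
        df = pd.read_csv(sidecar_tsv, sep="\t", dtype=str, keep_default_na=False)
        if "id" not in df.columns:
            raise ParseError(f"{sidecar_tsv}: sidecar table must have an 'id' column")
        meta = {str(r["id"]): r for _, r in df.iterrows()}
    peptides = []
    for record in SeqIO.parse(str(path), "fasta"):
        extra = meta.get(record.id, {})
        peptides.append(
            Peptide(
                id=record.id,
                sequence=str(record.seq),
                hla_allele=_opt(extra.get("hla_allele")),
                rank_percent=_opt_float(extra.get("rank_percent")),
                label=_opt(extra.get("label")),
            )
        )
    return peptides


def read_proteome_fasta(path: str | Path) -> list[str]:
    """Protein sequences of a reference proteome FASTA."""
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]


def write_features_tsv(features: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table; full float precision so round-trips are exact."""
    features.to_csv(path, sep="\t", index=True)


def read_features_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


def write_manifest(path: str | Path, payload: dict) -> None:
    """Machine-readable run manifest (config, package version, fingerprints)."""
    from . import __version__

    payload = {"package": "epiforest", "version": __version__, **payload}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
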