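"""Synthetic labeled peptide datasets with the structure the method assumes.

The generator emulates three properties of curated HLA class-I
immunogenicity corpora:

1. *Supertype-consistent anchors* — position 2 and the C-terminus are
   drawn from the presenting allele's published binding motif (e.g.
   A02:01: position 2 in {L, M}, C-terminus in {I, L, V}); the N-terminus
   and non-motif anchors are uniform.
2. *Class-dependent TCR-contact composition* — contact residues of
   immunogenic peptides are enriched in hydrophobic amino acids
   (L, W, P, A, V, M) and depleted in the charged D and K relative to
   non-immunogenic peptides, by an exponential tilt of the human
   background composition whose strength is the ``effect_size``
   (0 = identical distributions).
3. *Class-dependent rank(%)* — eluted-ligand percentile ranks are
   log-normal with a class- and effect-dependent location (immunogenic
   peptides bind better, i.e. lower rank).

Mutant-pair generation adds a controllable fraction of anchor-position
substitutions and a DAI shift (wild-type rank inflated relative to the
mutant) for the immunogenic class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

from .features import default_background
from .peptides import NEGATIVE, POSITIVE, MutantPair, Peptide, STANDARD_AA

#: residues enriched at contact sites of immunogenic peptides
HYDROPHOBIC_ENRICHED = "LWPAVM"
#: charged residues enriched in non-immunogenic peptides
CHARGED_DEPLETED = "DK"

#: named effect-size levels
EFFECT_LEVELS = {"none": 0.0, "weak": 0.25, "medium": 0.5, "strong": 1.0}

#: anchor motifs (position-2 residues, C-terminal residues) per allele,
#: from published supertype binding motifs; None = unconstrained
ANCHOR_MOTIFS: dict[str, tuple[str | None, str | None]] = {
    "A01:01": ("ST", "Y"),
    "A26:01": ("ITV", "FMY"),
    "A02:01": ("LM", "ILV"),
    "A11:01": ("IMSTV", "K"),
    "A03:01": ("ILMTV", "K"),
    "A24:02": ("WY", "FIW"),
    "A23:01": ("WY", "F"),
    "B35:01": ("P", "FMY"),
    "B07:02": ("P", "FLM"),
    "B51:01": ("P", "IV"),
    "B08:01": (None, "FILMV"),
    "B27:05": ("R", None),
    "B37:01": (None, None),
    "B40:01": (None, None),
    "B44:02": ("E", "FIWY"),
    "B58:01": ("AST", "W"),
    "B15:01": ("LMQ", "FY"),
}

#: first-position motif constraints where published (rarely anchored at P1)
P1_MOTIFS: dict[str, str] = {"A26:01": "DE", "B27:05": "RY"}

_DEFAULT_LENGTHS = {8: 0.15, 9: 0.55, 10: 0.20, 11: 0.10}
_DEFAULT_SUPERTYPE_MIX = {
    "A02:01": 0.35,
    "A01:01": 0.15,
    "A03:01": 0.15,
    "A24:02": 0.10,
    "B07:02": 0.10,
    "B08:01": 0.08,
    "B27:05": 0.07,
}


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Parameters
    ----------
    n_pos, n_neg : int
        Class sizes (default 1000 each; the curated corpora this emulates
        are thousands of records).
    effect_size : float or str
        Separation between the classes, 0..1 or one of
        ``none/weak/medium/strong``.  Drives both the contact-composition
        tilt and the rank(%) separation; 0 makes the classes identically
        distributed.
    length_weights : mapping length -> probability over {8..11}.
    allele_weights : mapping allele -> probability (alleles must have a
        motif entry).
    contact_tilt : float
        Log-scale tilt applied (times effect_size) to the hydrophobic /
        charged residue sets at contact positions.
    rank_log_mu, rank_log_sigma : float
        Baseline location/scale of log rank(%).
    rank_shift_pos, rank_shift_neg : float
        Effect-size-scaled shifts of log rank(%) for the two classes
        (positives down = better binders, negatives up).
    seed : int
        Master seed; identical configs generate identical datasets.
    """

    n_pos: int = 1000
    n_neg: int = 1000
    effect_size: float | str = "medium"
    length_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_LENGTHS))
    allele_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SUPERTYPE_MIX))
    contact_tilt: float = 0.35
    rank_log_mu: float = float(np.log(0.8))
    rank_log_sigma: float = 0.6
    rank_shift_pos: float = 0.9
    rank_shift_neg: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.effect_size, str):
            if self.effect_size not in EFFECT_LEVELS:
                raise ConfigError(
                    f"unknown effect level {self.effect_size!r}; use one of "
                    f"{sorted(EFFECT_LEVELS)} or a float in [0, 1]"
                )
            self.effect_size = EFFECT_LEVELS[self.effect_size]
        if not 0 <= self.effect_size <= 1:
            raise ConfigError(f"effect_size must be in [0, 1], got {self.effect_size}")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ConfigError("n_pos and n_neg must be positive")
        for name, dist in (("length_weights", self.length_weights),
                           ("allele_weights", self.allele_weights)):
            total = sum(dist.values())
            if not dist or abs(total - 1.0) > 1e-9 or min(dist.values()) < 0:
                raise ConfigError(f"{name} must be a probability distribution summing to 1")
        unknown = set(self.allele_weights) - set(ANCHOR_MOTIFS)
        if unknown:
            raise ConfigError(f"alleles without a motif entry: {sorted(unknown)}")
        if any(ln < 8 for ln in self.length_weights):
            raise ConfigError("generated lengths below 8 are not supported")

    def contact_distribution(self, label: str) -> dict[str, float]:
        """Contact-site residue distribution for one class.

        Exponential tilt of the background: immunogenic up-weights the
        hydrophobic set and down-weights D/K; non-immunogenic the reverse.
        """
        sign = 1.0 if label == POSITIVE else -1.0
        bg = default_background()
        weights = {}
        for aa in STANDARD_AA:
            s = 0.0
            if aa in HYDROPHOBIC_ENRICHED:
                s = self.contact_tilt
            elif aa in CHARGED_DEPLETED:
                s = -self.contact_tilt
            weights[aa] = bg[aa] * float(np.exp(sign * self.effect_size * s))
        total = sum(weights.values())
        return {aa: w / total for aa, w in weights.items()}

    def rank_log_location(self, label: str) -> float:
        shift = -self.rank_shift_pos if label == POSITIVE else self.rank_shift_neg
        return self.rank_log_mu + self.effect_size * shift

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "length_weights" in raw:
            raw["length_weights"] = {int(k): v for k, v in raw["length_weights"].items()}
        return cls(**raw)


def _choice(rng: np.random.Generator, symbols: str, p=None) -> str:
    return symbols[rng.choice(len(symbols), p=p)]


def _draw_sequence(
    rng: np.random.Generator,
    length: int,
    allele: str,
    contact_p: np.ndarray,
) -> str:
    p2_motif, ct_motif = ANCHOR_MOTIFS[allele]
    p1_motif = P1_MOTIFS.get(allele)
    residues = []
    residues.append(_choice(rng, p1_motif) if p1_motif else _choice(rng, STANDARD_AA))
    residues.append(_choice(rng, p2_motif) if p2_motif else _choice(rng, STANDARD_AA))
    for _ in range(length - 3):
        residues.append(_choice(rng, STANDARD_AA, p=contact_p))
    residues.append(_choice(rng, ct_motif) if ct_motif else _choice(rng, STANDARD_AA))
    return "".join(residues)


def _draw_rank(rng: np.random.Generator, config: GeneratorConfig, label: str) -> float:
    mu = config.rank_log_location(label)
    rank = float(np.exp(rng.normal(mu, config.rank_log_sigma)))
    return min(max(rank, 0.01), 100.0)


def generate_dataset(config: GeneratorConfig) -> list[Peptide]:
    """Generate a labeled peptide collection under the configured conditions.

    Deterministic given the config (including its seed).  Every record
    carries an allele, a rank(%) value and a label, and passes the default
    curation length filter.
    """
    rng = np.random.default_rng(config.seed)
    lengths = sorted(config.length_weights)
    length_p = np.array([config.length_weights[ln] for ln in lengths], dtype=float)
    alleles = sorted(config.allele_weights)
    allele_p = np.array([config.allele_weights[a] for a in alleles], dtype=float)

    peptides = []
    counter = 0
    for label, n in ((POSITIVE, config.n_pos), (NEGATIVE, config.n_neg)):
        contact = config.contact_distribution(label)
        contact_p = np.array([contact[a] for a in STANDARD_AA])
        for _ in range(n):
            counter += 1
            length = lengths[rng.choice(len(lengths), p=length_p)]
            allele = alleles[rng.choice(len(alleles), p=allele_p)]
            seq = _draw_sequence(rng, length, allele, contact_p)
            peptides.append(
                Peptide(
                    id=f"syn{counter:06d}",
                    sequence=seq,
                    hla_allele=allele,
                    rank_percent=round(_draw_rank(rng, config, label), 3),
                    label=label,
                )
            )
    return peptides


def generate_mutant_pairs(
    config: GeneratorConfig,
    n_pairs: int | None = None,
    anchor_fraction: float = 0.2,
    dai_shift: float = 1.2,
) -> list[MutantPair]:
    """Generate single-substitution wild-type/mutant pairs.

    ``anchor_fraction`` of the pairs mutate an anchor position (1, 2 or
    C-terminus), the rest an interior contact position.  For immunogenic
    pairs the mutant's contact residues follow the positive-class
    distribution and the wild-type rank(%) is inflated by ``dai_shift``
    log units (times effect size) over the mutant's, so the DAI is
    positive on average; non-immunogenic pairs get near-zero DAI.
    """
    if not 0 <= anchor_fraction <= 1:
        raise ConfigError(f"anchor_fraction must be in [0, 1], got {anchor_fraction}")
    rng = np.random.default_rng(config.seed + 1)
    lengths = sorted(config.length_weights)
    length_p = np.array([config.length_weights[ln] for ln in lengths], dtype=float)
    alleles = sorted(config.allele_weights)
    allele_p = np.array([config.allele_weights[a] for a in alleles], dtype=float)
    class_sizes = (
        [(POSITIVE, config.n_pos), (NEGATIVE, config.n_neg)]
        if n_pairs is None
        else [(POSITIVE, n_pairs // 2 + n_pairs % 2), (NEGATIVE, n_pairs // 2)]
    )

    pairs = []
    counter = 0
    neutral = default_background()
    neutral_p = np.array([neutral[a] for a in STANDARD_AA])
    for label, n in class_sizes:
        contact = config.contact_distribution(label)
        contact_p = np.array([contact[a] for a in STANDARD_AA])
        for _ in range(n):
            counter += 1
            length = lengths[rng.choice(len(lengths), p=length_p)]
            allele = alleles[rng.choice(len(alleles), p=allele_p)]
            wt_seq = _draw_sequence(rng, length, allele, neutral_p)
            if rng.random() < anchor_fraction:
                pos = int(rng.choice([1, 2, length]))
            else:
                pos = int(rng.integers(3, length))
            # substitute: class-tilted at contact positions, uniform at anchors
            p = contact_p if 3 <= pos <= length - 1 else None
            while True:
                new = _choice(rng, STANDARD_AA, p=p)
                if new != wt_seq[pos - 1]:
                    break
            mut_seq = wt_seq[: pos - 1] + new + wt_seq[pos:]
            mut_rank = _draw_rank(rng, config, label)
            shift = dai_shift * config.effect_size if label == POSITIVE else 0.0
            wt_rank = min(
                max(mut_rank * float(np.exp(shift + rng.normal(0, 0.3))), 0.01), 100.0
            )
            pid = f"pair{counter:06d}"
            pairs.append(
                MutantPair(
                    id=pid,
                    wt=Peptide(f"{pid}_wt", wt_seq, allele, round(wt_rank, 3)),
                    mut=Peptide(f"{pid}_mut", mut_seq, allele, round(mut_rank, 3)),
                    label=label,
                )
            )
    return pairs
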