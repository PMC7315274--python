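"""Formula oracles and invariants for the sequence-derived features."""

import numpy as np
import pytest

from epiforest import (
    EpitopeFeaturizer,
    FrequencyModel,
    NEGATIVE,
    POSITIVE,
    Peptide,
    assemble_features,
    compute_scale_feature,
    default_background,
    estimate_contact_frequencies,
    frequency_score,
    peptide_entropy,
    tcr_contact_positions,
)
from epiforest.features import FrequencyModelError
from epiforest.peptides import STANDARD_AA, InvalidPeptideError
from epiforest.scales import get_scale, list_scales

from conftest import random_peptides


def brute_force_scale_average(seq, scale):
    """Independent oracle: explicit per-position loop excluding 1, 2, len."""
    total, count = 0.0, 0
    for pos in range(1, len(seq) + 1):  # 1-based
        if pos in (1, 2, len(seq)):
            continue
        total += scale.values[seq[pos - 1]]
        count += 1
    return total / count


uniform_model = FrequencyModel(
    f_pos={a: 0.05 for a in STANDARD_AA},
    f_neg={a: 0.05 for a in STANDARD_AA},
    f_background={a: 0.05 for a in STANDARD_AA},
    n_pos=20,
    n_neg=20,
)


class TestContactPositions:
    def test_nine_mer(self):
        assert tcr_contact_positions("ALAKAAAAV") == [3, 4, 5, 6, 7, 8]

    def test_eight_mer(self):
        assert tcr_contact_positions("SIINFEKL") == [3, 4, 5, 6, 7]

    def test_too_short_rejected(self):
        with pytest.raises(InvalidPeptideError):
            tcr_contact_positions("ACD")

    def test_count_is_len_minus_three(self, rng):
        for pep in random_peptides(rng, 50):
            assert len(tcr_contact_positions(pep)) == len(pep) - 3


class TestScaleFeature:
    def test_siinfekl_hand_sum(self):
        """Contact residues I,N,F,E,K on Kyte-Doolittle average to -0.72."""
        value = compute_scale_feature("SIINFEKL", get_scale("C1"))
        assert value == pytest.approx(-0.72, abs=1e-12)

    def test_homopolymer_equals_residue_value(self):
        for scale in list_scales():
            assert compute_scale_feature("AAAAAAAA", scale) == pytest.approx(
                scale["A"], abs=1e-12
            )

    def test_matches_brute_force_on_random_peptides(self, rng):
        """Per-position oracle equivalence to 1e-12 on 1000 random peptides."""
        peptides = random_peptides(rng, 1000)
        scales = list_scales()
        for pep in peptides:
            scale = scales[int(rng.integers(len(scales)))]
            assert compute_scale_feature(pep, scale) == pytest.approx(
                brute_force_scale_average(pep.sequence, scale), abs=1e-12
            )

    def test_anchor_positions_do_not_matter(self):
        a = compute_scale_feature("SIINFEKL", get_scale("C1"))
        b = compute_scale_feature("WWINFEKW", get_scale("C1"))
        assert a == b


class TestFrequencyEstimation:
    def test_single_symbol_pools_unsmoothed(self):
        peps = [
            Peptide("p", "AAAAAAAAA", label=POSITIVE),
            Peptide("n", "LLLLLLLLL", label=NEGATIVE),
        ]
        model = estimate_contact_frequencies(peps, smoothing=0.0)
        assert model.f_pos["A"] == 1.0
        assert model.f_neg["L"] == 1.0
        assert model.n_pos == model.n_neg == 6

    def test_identical_class_pools_give_equal_tables(self, rng):
        seqs = random_peptides(rng, 20)
        peps = [
            Peptide(f"p{i}", p.sequence, label=POSITIVE) for i, p in enumerate(seqs)
        ] + [
            Peptide(f"n{i}", p.sequence, label=NEGATIVE) for i, p in enumerate(seqs)
        ]
        model = estimate_contact_frequencies(peps)
        for a in STANDARD_AA:
            assert model.f_pos[a] == pytest.approx(model.f_neg[a], abs=1e-12)

    def test_tables_sum_to_one_after_smoothing(self, frequency_model):
        for table in (frequency_model.f_pos, frequency_model.f_neg,
                      frequency_model.f_background):
            assert sum(table.values()) == pytest.approx(1.0, abs=1e-9)
            assert min(table.values()) >= 0

    def test_single_class_input_rejected(self):
        peps = [Peptide("p", "AAAAAAAAA", label=POSITIVE)]
        with pytest.raises(FrequencyModelError, match="both classes"):
            estimate_contact_frequencies(peps)

    def test_enrichment_recovered_from_generated_data(self, strong_dataset):
        """Positives are hydrophobic-enriched, negatives D/K-enriched."""
        model = estimate_contact_frequencies(strong_dataset)
        assert model.f_pos["L"] > model.f_neg["L"]
        assert model.f_neg["D"] > model.f_pos["D"]


class TestFrequencyScore:
    def test_zero_when_distributions_identical(self, rng):
        for pep in random_peptides(rng, 20):
            assert frequency_score(pep, uniform_model) == 0.0

    def test_direct_sum_for_constant_contacts(self):
        f_pos = {a: 0.045 for a in STANDARD_AA}
        f_pos["L"] = 0.10
        rest = (1 - 0.10 - 0.04) / 18
        f_neg = {a: rest for a in STANDARD_AA}
        f_neg["L"] = 0.04
        f_neg["A"] = 0.04 + rest - 0.045  # keep both normalized
        f_pos["A"] = f_neg["A"] + 0.045 - rest
        f_pos = {a: v / sum(f_pos.values()) for a, v in f_pos.items()}
        f_neg = {a: v / sum(f_neg.values()) for a, v in f_neg.items()}
        model = FrequencyModel(
            f_pos=f_pos, f_neg=f_neg,
            f_background={a: 0.05 for a in STANDARD_AA}, n_pos=1, n_neg=1,
        )
        # nine-mer with all six contact residues L: score = 6 * (f+ - f-)[L]
        pep = "AALLLLLLV"
        expected = 6 * (model.f_pos["L"] - model.f_neg["L"])
        assert frequency_score(pep, model) == pytest.approx(expected, abs=1e-12)

    def test_swapping_classes_negates_score(self, rng, frequency_model):
        swapped = frequency_model.swapped_classes()
        for pep in random_peptides(rng, 100):
            assert frequency_score(pep, swapped) == pytest.approx(
                -frequency_score(pep, frequency_model), abs=1e-12
            )

    def test_unnormalized_sum_grows_with_length(self, frequency_model):
        """Appending a contact residue with f+ > f- raises the score."""
        best = max(STANDARD_AA,
                   key=lambda a: frequency_model.f_pos[a] - frequency_model.f_neg[a])
        base = "AAAAAV"  # contact residues: A at 3..5
        extended = "AAAAA" + best + "V"  # one extra contact residue `best`
        assert frequency_score(extended, frequency_model) > frequency_score(
            base, frequency_model
        )


class TestPeptideEntropy:
    def test_homopolymer_closed_form(self):
        f = 0.25
        bg = {a: 0.75 / 19 for a in STANDARD_AA}
        bg["A"] = f
        model = FrequencyModel(
            f_pos={a: 0.05 for a in STANDARD_AA},
            f_neg={a: 0.05 for a in STANDARD_AA},
            f_background=bg, n_pos=1, n_neg=1,
        )
        assert peptide_entropy("AAAAAAAAA", model) == pytest.approx(0.5, abs=1e-12)

    def test_uniform_background_is_sequence_independent(self, rng):
        expected = -0.05 * np.log2(0.05)
        for pep in random_peptides(rng, 50):
            assert peptide_entropy(pep, uniform_model) == pytest.approx(
                expected, abs=1e-12
            )
        assert expected == pytest.approx(0.2161, abs=1e-4)

    def test_non_negative_for_any_background(self, rng, frequency_model):
        for pep in random_peptides(rng, 100):
            assert peptide_entropy(pep, frequency_model) >= 0

    def test_zero_background_frequency_rejected(self):
        bg = {a: 1 / 19 for a in STANDARD_AA}
        bg["W"] = 0.0
        model = FrequencyModel(
            f_pos={a: 0.05 for a in STANDARD_AA},
            f_neg={a: 0.05 for a in STANDARD_AA},
            f_background=bg, n_pos=1, n_neg=1,
        )
        with pytest.raises(FrequencyModelError, match="zero"):
            peptide_entropy("AAWWWWWA", model)


class TestAssembly:
    def test_vector_schema_and_rank_passthrough(self, frequency_model):
        pep = Peptide("x", "SIINFEKL", rank_percent=0.3)
        vec = assemble_features(pep, frequency_model)
        assert list(vec) == [f"C{i}" for i in range(1, 25)]
        assert vec["C24"] == 0.3
        assert all(np.isfinite(v) for v in vec.values())

    def test_missing_rank_is_an_error(self, frequency_model):
        pep = Peptide("x", "SIINFEKL")
        with pytest.raises(ValueError, match="rank_percent"):
            assemble_features(pep, frequency_model)

    def test_deterministic(self, frequency_model):
        pep = Peptide("x", "SIINFEKLM", rank_percent=1.2)
        assert assemble_features(pep, frequency_model) == assemble_features(
            pep, frequency_model
        )

    def test_anchor_blindness_of_c1_to_c23(self, rng, frequency_model):
        """Mutating positions 1, 2 or len leaves C1-C23 unchanged."""
        for pep in random_peptides(rng, 30):
            seq = list(pep.sequence)
            for pos in (0, 1, len(seq) - 1):
                seq[pos] = "W" if seq[pos] != "W" else "Y"
            mutant = Peptide(pep.id, "".join(seq), rank_percent=pep.rank_percent)
            v1 = assemble_features(pep, frequency_model)
            v2 = assemble_features(mutant, frequency_model)
            for fid in [f"C{i}" for i in range(1, 24)]:
                assert v1[fid] == v2[fid], fid


class TestFeaturizer:
    def test_fit_transform_shape_and_index(self, strong_dataset):
        fz = EpitopeFeaturizer().fit(strong_dataset)
        table = fz.transform(strong_dataset[:10])
        assert table.shape == (10, 24)
        assert list(table.columns) == [f"C{i}" for i in range(1, 25)]
        assert list(table.index) == [p.id for p in strong_dataset[:10]]

    def test_transform_before_fit_raises(self, strong_dataset):
        with pytest.raises(RuntimeError):
            EpitopeFeaturizer().transform(strong_dataset)

    def test_sklearn_param_round_trip(self):
        fz = EpitopeFeaturizer(smoothing=0.5)
        assert EpitopeFeaturizer(**fz.get_params()).smoothing == 0.5


def test_default_background_is_normalized_and_positive():
    bg = default_background()
    assert set(bg) == set(STANDARD_AA)
    assert sum(bg.values()) == pytest.approx(1.0, abs=1e-9)
    assert min(bg.values()) > 0
    assert bg["L"] == max(bg.values())  # leucine is the most common residue
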