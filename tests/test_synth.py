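"""Synthetic-data generators: determinism, truth bookkeeping, zero-noise round trips."""

import numpy as np
import pytest

from resistkit.doseresponse import DoseLadder, FourPLFit, compute_tgi, fit_4pl, predict_4pl
from resistkit.synergy import delta_bliss_surface
from resistkit.synth import (
    ConfigurationError,
    SimTruth,
    fusion_study_transcriptome,
    make_coding_transcript,
    make_fusion_transcript,
    make_transcript,
    simulate_cnv_track,
    simulate_combination,
    simulate_plate,
    simulate_read_pairs,
)

LADDER = DoseLadder(top=10e-6, fold=4, n_points=9)
TRUTH = FourPLFit(lower=0.0, upper=1.0, ic50=10e-9, hill=1.0)


class TestPlates:
    def test_zero_noise_round_trip_is_exact(self):
        plate, _ = simulate_plate(TRUTH, LADDER, noise_cv=0.0, replicates=2, seed=0)
        for _, _, dose, count in plate.wells:
            assert compute_tgi(count, plate).tgi == pytest.approx(
                predict_4pl(TRUTH, dose), abs=1e-12
            )

    def test_flat_truth_keeps_treated_at_untreated_level(self):
        flat = FourPLFit(lower=0.0, upper=0.0, ic50=1e-6, hill=1.0)
        plate, _ = simulate_plate(flat, LADDER, noise_cv=0.0, seed=0)
        for _, _, _, count in plate.wells:
            assert count == pytest.approx(plate.untreated_mean)

    def test_noisy_recovery_within_ten_percent_geometric_mean(self):
        fits = []
        for seed in range(8):
            plate, _ = simulate_plate(TRUTH, LADDER, noise_cv=0.05, replicates=3, seed=seed)
            doses = [w[2] for w in plate.wells]
            tgis = [compute_tgi(w[3], plate).tgi for w in plate.wells]
            fits.append(fit_4pl(doses, tgis).ic50)
        gm = float(np.exp(np.mean(np.log(fits))))
        assert gm == pytest.approx(TRUTH.ic50, rel=0.10)

    def test_deterministic_per_seed(self):
        p1, _ = simulate_plate(TRUTH, LADDER, noise_cv=0.05, seed=5)
        p2, _ = simulate_plate(TRUTH, LADDER, noise_cv=0.05, seed=5)
        assert p1 == p2

    def test_invalid_means_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_plate(TRUTH, LADDER, baseline_mean=1000.0, untreated_mean=500.0)


FLAT = FourPLFit(lower=0.0, upper=0.0, ic50=1e-6, hill=1.0)
FULL_RESCUE = FourPLFit(lower=1.0, upper=1.0, ic50=1e-8, hill=1.0)


class TestCombinations:
    def test_bliss_model_is_additive_by_construction(self):
        pa = FourPLFit(lower=0.0, upper=0.8, ic50=1e-7, hill=1.0)
        la = DoseLadder(top=1e-5, fold=4, n_points=5)
        obs, da, db, _ = simulate_combination(pa, pa, "bliss", la, la, seed=0)
        surface = delta_bliss_surface(obs, da, db)
        assert surface.delta == pytest.approx(np.zeros_like(obs), abs=1e-12)

    def test_rescue_model_reaches_delta_ceiling(self):
        la = DoseLadder(top=1e-5, fold=4, n_points=5)
        obs, da, db, _ = simulate_combination(
            FLAT, FLAT, "rescue", la, la, rescue_params=FULL_RESCUE, seed=0
        )
        surface = delta_bliss_surface(obs, da, db)
        assert surface.delta.max() == 1.0

    def test_antagonism_model_shows_negative_signed_excess(self):
        pa = FourPLFit(lower=0.0, upper=0.9, ic50=1e-7, hill=1.0)
        la = DoseLadder(top=1e-5, fold=4, n_points=5)
        obs, da, db, _ = simulate_combination(pa, pa, "antagonism", la, la, seed=0)
        surface = delta_bliss_surface(obs, da, db)
        assert surface.signed_excess.min() < 0

    def test_unknown_model_rejected(self):
        la = DoseLadder(top=1e-5, fold=4, n_points=3)
        with pytest.raises(ConfigurationError):
            simulate_combination(FLAT, FLAT, "loewe", la, la)


class TestTranscripts:
    def test_deterministic_per_seed_and_correct_length(self):
        assert make_transcript(3522, seed=1) == make_transcript(3522, seed=1)
        assert len(make_transcript(2947, seed=2)) == 2947

    def test_zero_length_rejected(self):
        with pytest.raises(ConfigurationError):
            make_transcript(0)

    def test_fusion_length_identity_at_study_coordinates(self):
        tx5 = make_transcript(3522, seed=3)
        tx3 = make_transcript(2947, seed=4)
        fusion = make_fusion_transcript(tx5, 2006, tx3, 1202)
        assert len(fusion) == 2006 + (2947 - 1202 + 1) == 3752

    def test_fusion_boundary_cases(self):
        tx5, tx3 = "ACGTAC", "TTGGCC"
        assert make_fusion_transcript(tx5, 6, tx3, 1) == tx5 + tx3
        assert make_fusion_transcript(tx5, 1, tx3, 6) == "AC"

    def test_out_of_range_junction_rejected(self):
        with pytest.raises(ConfigurationError):
            make_fusion_transcript("ACGT", 5, "ACGT", 1)

    def test_coding_transcript_has_clean_orf(self):
        seq, cds = make_coding_transcript(50, utr5=10, utr3=20, seed=5)
        assert cds == 11
        assert seq[cds - 1 : cds + 2] == "ATG"
        stops = {"TAA", "TAG", "TGA"}
        codons = [seq[i : i + 3] for i in range(cds - 1, cds - 1 + 150, 3)]
        assert not any(c in stops for c in codons)
        assert seq[cds - 1 + 150 : cds + 152] == "TAA"

    def test_study_transcriptome_has_zero_junction_homology(self):
        study = fusion_study_transcriptome(seed=23)
        tx5, tx3, j5, j3 = study["tx5"], study["tx3"], study["j5"], study["j3"]
        assert study["fusion"] == tx5[:j5] + tx3[j3 - 1 :]
        assert tx5[j5] != tx3[j3 - 1]  # split cannot slide right
        assert tx3[j3 - 2] != tx5[j5 - 1]  # split cannot slide left


class TestReadPairs:
    def test_conservation_of_pair_count_and_read_length(self):
        tx = {"t": make_transcript(2000, seed=6)}
        pairs, truth = simulate_read_pairs(tx, {"t": 1.0}, n_pairs=500, seed=7)
        assert len(pairs) == 500
        assert all(len(s1) == 75 and len(s2) == 75 for _, s1, s2 in pairs)
        assert len(truth.records["fragments"]["t"]) == 500

    def test_error_free_reads_are_exact_substrings(self):
        from resistkit.mapping import revcomp

        seq = make_transcript(1500, seed=8)
        pairs, _ = simulate_read_pairs({"t": seq}, {"t": 1.0}, n_pairs=200, seed=9)
        for _, s1, s2 in pairs:
            assert s1 in seq
            assert revcomp(s2) in seq

    def test_fragments_respect_transcript_bounds(self):
        seq = make_transcript(400, seed=10)
        pairs, truth = simulate_read_pairs({"t": seq}, {"t": 1.0}, n_pairs=300,
                                           seed=11, insert_mean=350, insert_sd=80)
        for start, insert in truth.records["fragments"]["t"]:
            assert 0 <= start and start + insert <= 400 and insert >= 75

    def test_deterministic_per_seed(self):
        tx = {"t": make_transcript(800, seed=12)}
        p1, _ = simulate_read_pairs(tx, {"t": 1.0}, n_pairs=100, seed=13)
        p2, _ = simulate_read_pairs(tx, {"t": 1.0}, n_pairs=100, seed=13)
        assert p1 == p2

    def test_no_positive_abundance_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_read_pairs({"t": "A" * 100}, {"t": 0.0}, n_pairs=10)


class TestCNVTrack:
    def test_zero_noise_track_is_piecewise_constant(self):
        track, truth = simulate_cnv_track([(50, 0.0), (30, 2.0)], noise_sd=0.0)
        assert np.all(track.log2_ratio[:50] == 0.0)
        assert np.all(track.log2_ratio[50:] == 2.0)
        assert truth.records["boundaries"] == [0, 50, 80]

    def test_empty_truth_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_cnv_track([])


def test_simtruth_round_trips_through_json():
    truth = SimTruth(params={"seed": 3, "ic50": 1e-8},
                     records={"tgi": [0.1, 0.9], "fragments": {"t": [[0, 250]]}})
    again = SimTruth.from_json(truth.to_json())
    assert again.params == truth.params
    assert again.records == truth.records
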