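"""Profile construction, Gumbel E-value calibration, and database search."""

import math

import numpy as np
import pytest

from phytascan._aminoacids import ALPHABET, BACKGROUND
from phytascan.profiles import (
    CalibrationError,
    CalibrationParams,
    align_to_representative,
    build_profile,
    calibrate_evalues,
    calibration_from_scores,
    score_sequence,
    search_profiles,
)
from phytascan.synthetic import plant_homologs, random_proteome


class TestBuildProfile:
    def test_single_sequence_profile_peaks_at_its_residues(self):
        profile = build_profile(["ACD"], pseudocount_weight=0.0)
        tops = [ALPHABET[i] for i in profile.matrix.argmax(axis=1)]
        assert tops == ["A", "C", "D"]

    def test_duplicated_sequences_change_nothing(self):
        one = build_profile(["ACDK"], 1.0)
        two = build_profile(["ACDK", "ACDK"], 1.0)
        assert np.allclose(one.probabilities, two.probabilities)

    def test_emissions_match_count_oracle(self):
        members = ["ACD", "ACD", "AVD", "GCD", "AVE"]
        profile = build_profile(members, pseudocount_weight=1.0)
        # hand-computed oracle: (counts/n + w*background) / (1 + w), per column
        for col, residues in enumerate(zip(*members)):
            counts = np.zeros(20)
            for r in residues:
                counts[ALPHABET.index(r)] += 1
            expected = (counts / len(residues) + BACKGROUND) / 2.0
            assert np.allclose(profile.probabilities[col], expected)
            assert profile.probabilities[col].sum() == pytest.approx(1.0)

    def test_majority_gap_columns_dropped(self):
        profile = build_profile(["A-CD", "A-CD", "AK-D"], 1.0)
        # column 2 has 2/3 gaps -> dropped; column 3 has 1/3 -> kept
        assert profile.length == 3

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_profile(["ACD", "AC"])


class TestCalibration:
    def test_same_seed_reproduces_parameters(self, abl_profile):
        a = calibrate_evalues(abl_profile, n_random=150, seed=7)
        b = calibrate_evalues(abl_profile, n_random=150, seed=7)
        assert a.lam == b.lam and a.log_kappa == b.log_kappa

    def test_shift_absorbed_into_kappa_not_lambda(self):
        rng = np.random.default_rng(3)
        maxima = rng.gumbel(20.0, 2.5, size=2000)
        base = calibration_from_scores(maxima)
        shifted = calibration_from_scores(maxima + 10.0)
        assert shifted.lam == pytest.approx(base.lam, rel=1e-9)
        assert shifted.log_kappa - base.log_kappa == pytest.approx(10.0 * base.lam, rel=1e-9)

    def test_fitted_tail_matches_empirical_tail(self, abl_profile):
        # empirical exceedance at the 95th percentile vs the fitted Gumbel sf
        rng = np.random.default_rng(42)
        maxima = np.empty(300)
        for i in range(300):
            n = max(30, int(rng.normal(300, 60)))
            seq = "".join(
                ALPHABET[j] for j in rng.choice(20, size=n, p=BACKGROUND)
            )
            maxima[i], _, _ = score_sequence(abl_profile, seq)
        params = calibration_from_scores(maxima)
        q95 = np.quantile(maxima, 0.95)
        fitted_tail = math.exp(params.log_kappa - params.lam * q95)
        # one-term tail approximation of the Gumbel sf; MC error ~ 3*sqrt(p q / n)
        assert abs(fitted_tail - 0.05) < 3 * math.sqrt(0.05 * 0.95 / 300) + 0.01

    def test_degenerate_scores_raise(self):
        with pytest.raises(CalibrationError, match="zero variance"):
            calibration_from_scores(np.full(200, 5.0))

    def test_too_few_random_sequences_rejected(self, abl_profile):
        with pytest.raises(ValueError, match="n_random"):
            calibrate_evalues(abl_profile, n_random=50, seed=1)

    def test_evalue_monotone_in_score(self):
        params = CalibrationParams(lam=0.7, log_kappa=3.0, database_size=1000)
        scores = np.linspace(-50, 2000, 97)
        evalues = [params.evalue(s) for s in scores]
        assert all(a >= b for a, b in zip(evalues, evalues[1:]))
        assert all(e > 0 for e in evalues)


class TestSearch:
    def test_exact_copy_of_representative_is_top_hit(self, abl, abl_profile, abl_calibration):
        proteins = random_proteome(50, seed=1)
        proteins["self_copy"] = abl.sequence
        hits = search_profiles([abl_profile], proteins, 1e-30, {"BPP_ABL": abl_calibration})
        assert hits and hits[0].query_id == "self_copy"
        assert hits[0].clade_label == "BPP_ABL"

    def test_planted_homologs_recovered_and_randoms_rejected(
        self, abl, abl_profile, abl_calibration
    ):
        proteins, truth = plant_homologs(
            random_proteome(200, seed=13), abl, copies=5, target_identity=0.6, seed=13
        )
        hits = search_profiles([abl_profile], proteins, 1e-30, {"BPP_ABL": abl_calibration})
        assert {h.query_id for h in hits} == set(truth.seq_id)

    def test_sensitivity_monotone_in_planted_identity(self, abl, abl_profile, abl_calibration):
        recovered = []
        for ident in (0.4, 0.6, 0.8):
            proteins, truth = plant_homologs(
                random_proteome(60, seed=4), abl, copies=6, target_identity=ident, seed=4
            )
            hits = search_profiles(
                [abl_profile], proteins, 1e-30, {"BPP_ABL": abl_calibration}
            )
            recovered.append(len({h.query_id for h in hits} & set(truth.seq_id)))
        assert recovered == sorted(recovered)
        assert recovered[-1] == 6

    def test_zero_cutoff_returns_nothing(self, abl, abl_profile, abl_calibration):
        proteins = {"self_copy": abl.sequence}
        assert search_profiles([abl_profile], proteins, 0.0, {"BPP_ABL": abl_calibration}) == []

    def test_empty_database_warns_and_returns_empty(self, abl_profile, abl_calibration, caplog):
        with caplog.at_level("WARNING"):
            assert search_profiles([abl_profile], {}, 1e-30, {"BPP_ABL": abl_calibration}) == []
        assert "empty" in caplog.text

    def test_missing_calibration_is_an_error(self, abl_profile):
        with pytest.raises((KeyError, ValueError)):
            search_profiles([abl_profile], {"q": "ACDEF"}, 1e-30, {})

    def test_null_database_hit_counts_bounded_by_evalue(self, abl_profile, abl_calibration):
        proteins = random_proteome(400, seed=77)
        for t in (1.0, 5.0):
            hits = search_profiles(
                [abl_profile], proteins, t, {"BPP_ABL": abl_calibration}
            )
            assert len(hits) <= 2 * t + 2


class TestCrossBackend:
    def test_hmmer_backend_agrees_on_qualified_sequences(self, reps, abl):
        """The pyhmmer profile-HMM backend and the built-in engine must
        qualify the same sequences after motif screening."""
        pyhmmer = pytest.importorskip("pyhmmer")  # noqa: F841
        from phytascan.profiles import build_profile, calibrate_evalues, search_profiles_hmmer
        from phytascan.screen import screen_candidates

        proteins, truth_i = plant_homologs(
            random_proteome(200, seed=21), abl, 5, 0.6, True, seed=21
        )
        proteins, truth_b = plant_homologs(proteins, abl, 3, 0.6, False, seed=22)

        profile = build_profile([abl.sequence], 1.0, clade_label="BPP_ABL", family="BPP")
        calib = calibrate_evalues(profile, n_random=200, seed=5)
        hits_builtin = search_profiles([profile], proteins, 1e-30, {"BPP_ABL": calib})
        hits_hmmer = search_profiles_hmmer(
            {"BPP_ABL": ("BPP", [abl.sequence])}, proteins, 1e-30
        )
        qualified_builtin = {
            r.query_id
            for r in screen_candidates(hits_builtin, proteins, reps)
            if r.qualified
        }
        qualified_hmmer = {
            r.query_id
            for r in screen_candidates(hits_hmmer, proteins, reps)
            if r.qualified
        }
        assert qualified_builtin == qualified_hmmer == set(truth_i.seq_id)


class TestAlignToRepresentative:
    def test_identity_map_for_identical_sequences(self, abl):
        aln = align_to_representative(abl.sequence, abl.sequence)
        assert all(
            aln.map_a_to_b(i) == i for i in range(1, len(abl.sequence) + 1)
        )

    def test_internal_deletion_marks_exactly_the_deleted_positions(self):
        rng = np.random.default_rng(9)
        rep = "".join(ALPHABET[j] for j in rng.choice(20, size=60, p=BACKGROUND))
        candidate = rep[:25] + rep[30:]  # positions 26..30 deleted
        aln = align_to_representative(candidate, rep)
        gapped = {i for i in range(1, 61) if aln.map_a_to_b(i) is None}
        assert gapped == {26, 27, 28, 29, 30}

    def test_alignment_score_matches_dp_oracle_on_short_prefixes(self):
        """Gotoh affine-gap DP oracle (free end gaps) on 25-residue prefixes."""
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")

        def gotoh(a, b, open_=10.0, ext=0.5):
            # exhaustive global affine-gap DP (Gotoh), end gaps penalized
            n, m = len(a), len(b)
            neg = -1e18
            M = np.full((n + 1, m + 1), neg)
            X = np.full((n + 1, m + 1), neg)  # gap in b
            Y = np.full((n + 1, m + 1), neg)  # gap in a
            M[0, 0] = 0.0
            for i in range(1, n + 1):
                X[i, 0] = -(open_ + (i - 1) * ext)
            for j in range(1, m + 1):
                Y[0, j] = -(open_ + (j - 1) * ext)
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    s = blosum[a[i - 1], b[j - 1]]
                    M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
                    X[i, j] = max(
                        M[i - 1, j] - open_, X[i - 1, j] - ext, Y[i - 1, j] - open_
                    )
                    Y[i, j] = max(
                        M[i, j - 1] - open_, X[i, j - 1] - open_, Y[i, j - 1] - ext
                    )
            return max(M[n, m], X[n, m], Y[n, m])

        rng = np.random.default_rng(2)
        for _ in range(4):
            a = "".join(ALPHABET[j] for j in rng.choice(20, size=25, p=BACKGROUND))
            b = "".join(ALPHABET[j] for j in rng.choice(20, size=25, p=BACKGROUND))
            aln = align_to_representative(b, a)
            assert aln.score == pytest.approx(gotoh(a, b), abs=1e-6)

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            align_to_representative("AC1D", "ACDE")
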