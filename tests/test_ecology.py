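"""Ordination, diversity, distance decay, and the stochasticity ratio."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from phytascan.ecology import (
    CommunityMatrix,
    alpha_richness,
    bray_curtis_matrix,
    distance_decay,
    haversine_km,
    hellinger,
    nst,
    pcoa,
    permanova_test,
    tb_rda,
)
from phytascan.synthetic import simulate_community_assembly


def _frame(rows, samples=None, taxa=None):
    rows = np.asarray(rows, dtype=float)
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    taxa = taxa or [f"t{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=samples, columns=taxa)


class TestBrayCurtis:
    def test_identical_rows_have_zero_dissimilarity(self):
        d = bray_curtis_matrix(_frame([[1, 2, 3], [1, 2, 3]]))
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_rows_have_unit_dissimilarity(self):
        d = bray_curtis_matrix(_frame([[1, 0, 2], [0, 3, 0]]))
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_textbook_value(self):
        d = bray_curtis_matrix(_frame([[1, 1, 0], [1, 0, 0]]))
        assert d.iloc[0, 1] == pytest.approx(1 / 3)

    def test_zero_row_names_the_sample(self):
        with pytest.raises(ValueError, match="s1"):
            bray_curtis_matrix(_frame([[1, 1], [0, 0]]))

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(0)
        d = bray_curtis_matrix(_frame(rng.poisson(5, (10, 20)) + 1e-9))
        assert np.allclose(d, d.T)
        assert ((d.values >= 0) & (d.values <= 1)).all()
        assert np.allclose(np.diag(d), 0)


class TestPCoA:
    def test_euclidean_configuration_reconstructed(self):
        points = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0], [2.0, 2.0]])
        d = pd.DataFrame(squareform(pdist(points)))
        result = pcoa(d)
        recon = squareform(pdist(result.coordinates.values))
        assert np.allclose(recon, d.values, atol=1e-8)
        assert result.correction == "none"

    def test_collinear_points_need_one_axis(self):
        d = pd.DataFrame([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        result = pcoa(d)
        assert result.eigenvalues[0] > 0
        assert result.proportion_explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_duplicate_samples_coincide(self):
        rows = _frame([[5, 1, 0], [5, 1, 0], [0, 2, 7]])
        result = pcoa(bray_curtis_matrix(rows))
        assert np.allclose(
            result.coordinates.iloc[0], result.coordinates.iloc[1], atol=1e-10
        )

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(d)

    def test_agrees_with_skbio_on_bray_curtis_toy(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(7)
        frame = _frame(rng.poisson(8, (6, 12)) + 0.5)
        d = bray_curtis_matrix(frame)
        ours = pcoa(d)
        theirs = skbio_pcoa(d.values, warn_neg_eigval=False)
        if ours.correction == "none":
            k = min(3, ours.coordinates.shape[1])
            ref = theirs.samples.values[:, :k]
            got = ours.coordinates.values[:, :k]
            for axis in range(k):
                assert np.allclose(
                    np.abs(got[:, axis]), np.abs(ref[:, axis]), atol=1e-6
                )
        else:  # Lingoes-corrected: distances, not raw axes, must agree
            recon = squareform(pdist(ours.coordinates.values))
            corrected = np.sqrt(d.values**2 + 2 * abs(theirs.eigvals.min()))
            np.fill_diagonal(corrected, 0.0)
            assert recon == pytest.approx(corrected, abs=0.05)


class TestAlphaRichness:
    def test_counts_positive_entries(self):
        richness = alpha_richness(_frame([[0.1, 0, 3, 0], [0, 0, 0, 0]]))
        assert list(richness) == [2, 0]

    def test_group_difference_detected_by_rank_sum(self):
        rng = np.random.default_rng(3)
        rows, labels = [], []
        for g, k in (("low", 20), ("high", 60)):
            for _ in range(15):
                row = np.zeros(100)
                row[rng.choice(100, size=k, replace=False)] = 1.0
                rows.append(row)
                labels.append(g)
        frame = _frame(rows)
        groups = pd.Series(labels, index=frame.index)
        _richness, pvals = alpha_richness(frame, groups)
        assert pvals.loc["low", "high"] < 0.01


class TestTbRda:
    def test_hellinger_closed_form(self):
        out = hellinger(_frame([[1, 1, 2]]))
        assert np.allclose(out.values[0], [0.5, 0.5, np.sqrt(0.5)])

    def test_block_design_explains_most_inertia(self):
        rng = np.random.default_rng(5)
        block_a = rng.poisson(20, (8, 5)) + np.array([50, 40, 30, 0, 0])
        block_b = rng.poisson(20, (8, 5)) + np.array([0, 0, 30, 40, 50])
        frame = _frame(np.vstack([block_a, block_b]))
        design = pd.DataFrame(
            {"habitat": ["sed"] * 8 + ["wat"] * 8}, index=frame.index
        )
        result = tb_rda(frame, design)
        assert result.constrained_fraction > 0.9
        axis1 = result.site_scores["RDA1"]
        assert (axis1[:8] > 0).all() != (axis1[8:] > 0).all()

    def test_orthogonal_constraint_explains_little(self):
        rng = np.random.default_rng(6)
        frame = _frame(rng.poisson(15, (20, 10)) + 1.0)
        design = pd.DataFrame({"noise": rng.normal(size=20)}, index=frame.index)
        result = tb_rda(frame, design)
        assert result.constrained_fraction < 0.1

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(7)
        frame = _frame(rng.poisson(15, (10, 6)) + 1.0)
        x = rng.normal(size=10)
        design = pd.DataFrame({"x1": x, "x2": 2 * x}, index=frame.index)
        with pytest.raises(ValueError, match="collinear"):
            tb_rda(frame, design)


class TestDistanceDecay:
    def test_constant_similarity_gives_zero_slope(self):
        fit = distance_decay([0.4] * 10, np.linspace(1, 100, 10))
        assert fit.slope == 0.0

    def test_exact_linear_input_recovered(self):
        g = np.logspace(0.5, 3, 40)
        sim = 1 - 0.2 * np.log10(g)
        fit = distance_decay(sim, g)
        assert fit.slope == pytest.approx(-0.2, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)

    def test_noisy_decay_recovered_within_tolerance(self):
        rng = np.random.default_rng(5)
        g = np.logspace(0, 3.5, 100)
        sim = 1 - 0.2 * np.log10(g) + rng.normal(0, 0.05, 100)
        fit = distance_decay(sim, g)
        assert fit.slope == pytest.approx(-0.2, abs=0.05)
        assert fit.ci95[0] < -0.2 < fit.ci95[1]

    def test_nonpositive_distance_rejected_on_log_scale(self):
        with pytest.raises(ValueError, match="log"):
            distance_decay([0.5, 0.4, 0.3], [0.0, 1.0, 2.0])

    def test_haversine_known_distance(self):
        # one degree of longitude at the equator
        assert haversine_km(0, 0, 0, 1) == pytest.approx(111.19, abs=0.1)


class TestNST:
    def test_neutral_assembly_reads_stochastic(self):
        m = simulate_community_assembly("neutral", 20, seed=2)
        (res,) = nst(m, reps=300, seed=2)
        assert res.nst_percent > 50
        assert res.classification == "stochastic"

    def test_selection_assembly_reads_deterministic(self):
        m = simulate_community_assembly("selection", 20, seed=2)
        (res,) = nst(m, reps=300, seed=2)
        assert res.nst_percent < 50
        assert res.classification == "deterministic"

    def test_null_drawn_communities_score_near_the_ceiling(self):
        """Data produced by the null model itself must not read deterministic."""
        m = simulate_community_assembly("neutral", 12, n_taxa=60, seed=9)
        (res,) = nst(m, reps=200, seed=9)
        assert res.nst_percent > 80

    def test_same_seed_reproduces_result(self):
        m = simulate_community_assembly("neutral", 10, n_taxa=60, seed=4)
        a = nst(m, reps=150, seed=11)[0].nst_percent
        b = nst(m, reps=150, seed=11)[0].nst_percent
        assert a == b

    def test_invariant_to_sample_and_taxon_order(self):
        m = simulate_community_assembly("selection", 10, n_taxa=60, seed=4)
        base = nst(m.abundance, reps=150, seed=11)[0].nst_percent
        shuffled = m.abundance.iloc[::-1, ::-1]
        assert nst(shuffled, reps=150, seed=11)[0].nst_percent == pytest.approx(base)

    def test_small_groups_skipped_with_warning(self, caplog):
        m = simulate_community_assembly("neutral", 8, n_taxa=40, seed=1)
        groups = pd.Series(
            ["big"] * 6 + ["tiny"] * 2, index=m.abundance.index
        )
        with caplog.at_level("WARNING"):
            results = nst(m.abundance, groups=groups, reps=150, seed=3)
        assert [r.group for r in results] == ["big"]
        assert "tiny" in caplog.text

    def test_bad_arguments_rejected(self):
        m = simulate_community_assembly("neutral", 8, n_taxa=40, seed=1)
        with pytest.raises(ValueError, match="null model"):
            nst(m, null_model="XX", reps=150, seed=1)
        with pytest.raises(ValueError, match="reps"):
            nst(m, reps=10, seed=1)
        with pytest.raises(ValueError, match="seed"):
            nst(m, reps=150)

    def test_jaccard_incidence_variant_preserves_dichotomy(self):
        sel = simulate_community_assembly("selection", 12, n_taxa=80, seed=6)
        (res,) = nst(sel, reps=150, seed=6, metric="jaccard")
        assert 0 <= res.nst_percent <= 100


class TestPermanova:
    def test_detects_clear_group_separation(self):
        rng = np.random.default_rng(8)
        a = rng.poisson(5, (6, 10)) + np.r_[np.full(5, 30), np.zeros(5)]
        b = rng.poisson(5, (6, 10)) + np.r_[np.zeros(5), np.full(5, 30)]
        frame = _frame(np.vstack([a, b]))
        d = bray_curtis_matrix(frame)
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=frame.index)
        result = permanova_test(d, groups, permutations=199, seed=1)
        assert result["p-value"] < 0.05


class TestCommunityMatrix:
    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            CommunityMatrix(_frame([[1, -1]]))

    def test_missing_group_labels_rejected(self):
        frame = _frame([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="without group"):
            CommunityMatrix(frame, groups=pd.Series({"s0": "x"}))
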