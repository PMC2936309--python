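import numpy as np
import pandas as pd
import pytest
from scipy import stats

import clonosim as cs
from clonosim.aflp import AFLPMatrix


def toy_matrix(values, individuals=None):
    values = np.asarray(values, dtype=float)
    ids = individuals or [f"i{r + 1}" for r in range(values.shape[0])]
    cols = [f"M{c + 1}" for c in range(values.shape[1])]
    return AFLPMatrix(pd.DataFrame(values, index=ids, columns=cols))


class TestParentalFrequencies:
    def test_shape_and_bounds(self):
        model = cs.sample_parental_frequencies(4, 195, 0.25, seed=11)
        assert model.p.shape == (4, 195)
        assert np.all((model.p >= 0) & (model.p <= 1))

    def test_beta_moments_match_closed_form(self):
        # Balding-Nichols: Var(p_k | a) = F a (1 - a); check pooled over
        # many populations at one ancestral value by regenerating with K big
        F = 0.25
        model = cs.sample_parental_frequencies(500, 50, F, seed=4)
        # each column is 500 draws around its own ancestral value; its
        # variance estimates F * a * (1 - a) with a estimated by the mean
        a_hat = model.p.mean(axis=0)
        var_expected = F * a_hat * (1 - a_hat)
        ratio = model.p.var(axis=0, ddof=1) / var_expected
        assert abs(np.median(ratio) - 1.0) < 0.15

    def test_low_divergence_tracks_ancestral(self):
        tight = cs.sample_parental_frequencies(4, 300, 0.001, seed=7)
        spread = tight.p.max(axis=0) - tight.p.min(axis=0)
        assert np.median(spread) < 0.05

    def test_divergence_bounds_enforced(self):
        for bad in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(ValueError):
                cs.sample_parental_frequencies(2, 10, bad, seed=0)


class TestSimulateMatrix:
    def test_certain_band(self):
        model = cs.PopulationModel(np.ones((1, 20)))
        anc = cs.TrueAncestry.pure([5])
        mat = cs.simulate_matrix(model, anc, seed=0)
        assert (mat.values() == 1.0).all()

    def test_impossible_band(self):
        model = cs.PopulationModel(np.zeros((2, 20)))
        anc = cs.TrueAncestry(np.full((4, 2), 0.5))
        mat = cs.simulate_matrix(model, anc, seed=0)
        assert (mat.values() == 0.0).all()

    def test_diploid_band_frequency_oracle(self):
        # band frequency for a pure diploid is 1 - (1 - p)^2
        p = 0.3
        L = 100_000
        model = cs.PopulationModel(np.full((1, L), p))
        anc = cs.TrueAncestry.pure([1])
        mat = cs.simulate_matrix(model, anc, seed=13)
        expected = 1 - (1 - p) ** 2
        freq = float(mat.values().mean())
        se = np.sqrt(expected * (1 - expected) / L)
        assert abs(freq - expected) < 4 * se

    def test_copy_number_aware_banding(self):
        # with c copies the band probability rises to 1 - (1 - p)^c
        p, L, c = 0.3, 100_000, 4
        model = cs.PopulationModel(np.full((1, L), p))
        anc = cs.TrueAncestry(
            np.ones((1, 1)), ("tetra",), copy_number=np.array([c])
        )
        mat = cs.simulate_matrix(model, anc, seed=13)
        expected = 1 - (1 - p) ** c
        se = np.sqrt(expected * (1 - expected) / L)
        assert abs(float(mat.values().mean()) - expected) < 4 * se

    def test_values_restricted(self):
        model = cs.sample_parental_frequencies(2, 40, 0.3, seed=2)
        anc = cs.TrueAncestry(np.tile([0.5, 0.5], (6, 1)))
        mat = cs.inject_missing(cs.simulate_matrix(model, anc, seed=2), 0.1, 2)
        vals = mat.values()
        assert np.isin(vals[~np.isnan(vals)], [0.0, 1.0]).all()

    def test_dimension_mismatch_rejected(self):
        model = cs.PopulationModel(np.full((3, 10), 0.5))
        anc = cs.TrueAncestry.pure([2, 2])
        with pytest.raises(ValueError):
            cs.simulate_matrix(model, anc, seed=0)


class TestFragmentElimination:
    def test_exact_marker_count(self):
        model = cs.PopulationModel(np.full((2, 100), 0.5))
        out = cs.apply_fragment_elimination(model, 0.14, 0, seed=1)
        assert len(out.eliminated) == 14
        assert (out.p[0, list(out.eliminated)] == 0).all()

    def test_other_parent_untouched(self):
        model = cs.PopulationModel(np.full((2, 100), 0.5))
        out = cs.apply_fragment_elimination(model, 0.14, 0, seed=1)
        assert (out.p[1] == 0.5).all()

    def test_zero_fraction_is_identity(self):
        model = cs.PopulationModel(np.full((2, 50), 0.4))
        out = cs.apply_fragment_elimination(model, 0.0, 1, seed=1)
        assert np.array_equal(out.p, model.p)

    def test_full_elimination_silences_parent(self):
        model = cs.PopulationModel(np.full((2, 50), 0.4))
        out = cs.apply_fragment_elimination(model, 1.0, 1, seed=1)
        assert (out.p[1] == 0).all()
        anc = cs.TrueAncestry(np.tile([0.0, 1.0], (3, 1)))
        mat = cs.simulate_matrix(out, anc, seed=5)
        assert (mat.values() == 0.0).all()

    def test_invalid_parent_rejected(self):
        model = cs.PopulationModel(np.full((2, 50), 0.4))
        with pytest.raises(ValueError):
            cs.apply_fragment_elimination(model, 0.1, 5, seed=0)


class TestMissingData:
    def test_zero_rate_identity(self):
        mat = toy_matrix([[1, 0], [0, 1]])
        out = cs.inject_missing(mat, 0.0, seed=0)
        assert out.data.equals(mat.data)

    def test_rate_within_binomial_ci(self):
        mat = toy_matrix(np.ones((27, 195)))
        out = cs.inject_missing(mat, 0.04, seed=8)
        n = 27 * 195
        k = int(out.data.isna().sum().sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.04)
        assert lo <= k <= hi

    def test_deterministic_given_seed(self):
        mat = toy_matrix(np.ones((2, 2)))
        a = cs.inject_missing(mat, 0.5, seed=21)
        b = cs.inject_missing(mat, 0.5, seed=21)
        assert a.data.equals(b.data)


class TestMarkerFilter:
    def test_five_percent_boundary_is_kept(self):
        # 20 individuals: 0, 1 and 2 missing cells = 0 %, 5 %, 10 %
        vals = np.ones((20, 3))
        vals[0, 1] = np.nan
        vals[0, 2] = np.nan
        vals[1, 2] = np.nan
        out = cs.filter_markers(toy_matrix(vals), 0.05)
        assert out.markers == ("M1", "M2")

    def test_max_missing_one_is_identity(self):
        vals = np.ones((4, 3))
        vals[:, 0] = np.nan
        mat = toy_matrix(vals)
        assert cs.filter_markers(mat, 1.0).markers == mat.markers

    def test_idempotent(self):
        vals = np.ones((20, 5))
        vals[:3, 2] = np.nan
        once = cs.filter_markers(toy_matrix(vals))
        twice = cs.filter_markers(once)
        assert once.data.equals(twice.data)


class TestIO:
    @pytest.mark.parametrize("fmt", ["csv", "structure"])
    def test_round_trip(self, tmp_path, fmt):
        vals = np.array([[1, 0, np.nan], [0, np.nan, 1]])
        mat = toy_matrix(vals)
        path = tmp_path / f"m.{fmt}"
        cs.write_matrix(mat, path, fmt)
        back = cs.read_matrix(path, fmt)
        assert back.individuals == mat.individuals
        assert back.markers == mat.markers
        assert np.array_equal(back.values(), mat.values(), equal_nan=True)

    def test_structure_missing_code(self, tmp_path):
        vals = np.array([[1.0, np.nan]])
        path = tmp_path / "m.str"
        cs.write_matrix(toy_matrix(vals), path, "structure")
        assert "-9" in path.read_text()

    def test_ragged_structure_names_row(self, tmp_path):
        path = tmp_path / "bad.str"
        path.write_text("M1 M2\nind1 1 0\nind2 1\n")
        with pytest.raises(ValueError, match="row 3"):
            cs.read_matrix(path, "structure")

    def test_invalid_cell_values_rejected(self):
        with pytest.raises(ValueError):
            toy_matrix([[2, 0]])


class TestSurveyFixture:
    def test_survey_shape(self, survey_fixture):
        matrix, ancestry, model = survey_fixture
        assert (matrix.n_individuals, matrix.n_markers) == (27, 195)
        assert model.K == 4
        assert np.allclose(ancestry.Q_true.sum(axis=1), 1.0)

    def test_missingness_survives_filter_rule(self, survey_fixture):
        matrix, _, _ = survey_fixture
        assert (matrix.missing_fraction() <= 0.05 + 1e-12).all()

    def test_contains_pure_and_admixed(self, survey_fixture):
        _, ancestry, _ = survey_fixture
        maxq = ancestry.Q_true.max(axis=1)
        assert (maxq == 1.0).sum() == 17
        assert (maxq == 0.5).sum() == 10
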