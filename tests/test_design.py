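"""Spline bases, mass-univariate design and sparse time expansion."""

import numpy as np
import pandas as pd
import pytest

import fixdeconv as fd
from fixdeconv.design import FIXATION, STIMULUS, n_lags


def event_frame(n_fix=20, n_stim=2, seed=0):
    rng = np.random.default_rng(seed)
    fix = pd.DataFrame({
        "event_type": FIXATION,
        "time": np.sort(rng.uniform(1, 60, n_fix)),
        "category": rng.choice(fd.CATEGORIES, n_fix),
        "fixation_rank": np.arange(1, n_fix + 1, dtype=float),
        "fixation_duration": rng.gamma(5, 0.05, n_fix),
        "incoming_saccade_size": rng.gamma(2.5, 1.6, n_fix),
        "outgoing_saccade_size": rng.gamma(2.5, 1.6, n_fix),
        "y": rng.uniform(-15, 15, n_fix),
    })
    stim = pd.DataFrame({"event_type": STIMULUS,
                         "time": np.linspace(0, 50, n_stim)})
    return pd.concat([fix, stim], ignore_index=True)


class TestSplineBasis:
    def test_knots_on_equally_spaced_quantiles(self, rng):
        values = rng.uniform(0, 100, 5000)
        basis = fd.make_spline_basis(values, n_basis=5)
        # 3 quantile-placed knots (0/50/100th percentiles of the sample)
        expect = np.quantile(values, [0.0, 0.5, 1.0])
        np.testing.assert_allclose(basis.interior_knots, expect)
        # clamped: boundary knots carry multiplicity 4, 5 basis functions
        assert len(basis.knots) == 9
        assert basis.evaluate([50.0], drop=False).shape == (1, 5)

    def test_partition_of_unity_before_drop(self, rng):
        values = rng.gamma(3, 2, 500)
        basis = fd.make_spline_basis(values, 5)
        x = np.linspace(values.min(), values.max(), 101)
        total = basis.evaluate(x, drop=False).sum(axis=1)
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_identifiability_drop_leaves_four_columns(self, rng):
        basis = fd.make_spline_basis(rng.uniform(0, 1, 50), 5)
        assert basis.evaluate([0.3, 0.7]).shape == (2, 4)

    def test_out_of_range_clamped_to_boundary(self, rng):
        values = rng.uniform(0, 10, 100)
        basis = fd.make_spline_basis(values, 5)
        np.testing.assert_allclose(basis.evaluate([-5.0]),
                                   basis.evaluate([values.min()]))

    def test_quantiles_invariant_to_permutation(self, rng):
        values = rng.uniform(0, 1, 200)
        a = fd.make_spline_basis(values, 5)
        b = fd.make_spline_basis(np.sort(values)[::-1], 5)
        np.testing.assert_array_equal(a.knots, b.knots)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fd.make_spline_basis([1.0, 1.0, 2.0, 2.0, 3.0], 5)


class TestMassDesign:
    def test_stimulus_intercept_only(self):
        events = event_frame()
        formula = fd.ModelFormula({STIMULUS: (fd.Intercept(),)})
        mass = fd.build_mass_design(events, formula)
        assert mass.P == 1
        stim_rows = events["event_type"] == STIMULUS
        np.testing.assert_array_equal(mass.X[stim_rows, 0], 1.0)
        np.testing.assert_array_equal(mass.X[~stim_rows, 0], 0.0)

    def test_default_formula_has_25_predictors(self):
        events = event_frame(n_fix=40)
        mass = fd.build_mass_design(events, fd.default_formula())
        assert mass.P == 25
        kinds = [(c.kind, c.event_type) for c in mass.columns]
        assert kinds.count(("intercept", FIXATION)) == 1
        assert kinds.count(("dummy", FIXATION)) == 3
        assert kinds.count(("spline", FIXATION)) == 20
        assert kinds.count(("intercept", STIMULUS)) == 1

    def test_treatment_coding_reference_row(self):
        events = event_frame(n_fix=40)
        formula = fd.ModelFormula({FIXATION: (
            fd.Intercept(),
            fd.Categorical("category", fd.CATEGORIES, "other"))})
        mass = fd.build_mass_design(events, formula)
        assert mass.P == 4
        ref = (events["category"] == "other") & (events["event_type"] == FIXATION)
        np.testing.assert_array_equal(mass.X[ref],
                                      np.tile([1, 0, 0, 0], (ref.sum(), 1)))
        # each non-reference row has exactly one dummy set
        nonref = (events["category"] != "other") & (events["event_type"] == FIXATION)
        assert (mass.X[nonref][:, 1:].sum(axis=1) == 1).all()

    def test_unknown_level_rejected(self):
        events = event_frame()
        formula = fd.ModelFormula({FIXATION: (
            fd.Intercept(),
            fd.Categorical("category", ("precursor", "other"), "other"))})
        with pytest.raises(ValueError, match="unknown"):
            fd.build_mass_design(events, formula)


class TestConfigAndExport:
    def test_formula_roundtrip_from_yaml(self, tmp_path):
        cfg = tmp_path / "formula.yaml"
        cfg.write_text(
            "fixation:\n"
            "  - intercept\n"
            "  - categorical: {name: category, levels: [precursor, refixation,"
            " ordinary, other], reference: other}\n"
            "  - spline: {name: fixation_rank, n_basis: 5}\n"
            "  - spline: {name: fixation_duration, n_basis: 5}\n"
            "  - spline: {name: incoming_saccade_size, n_basis: 5}\n"
            "  - spline: {name: outgoing_saccade_size, n_basis: 5}\n"
            "  - spline: {name: y, n_basis: 5}\n"
            "stimulus:\n"
            "  - intercept\n")
        formula = fd.formula_from_yaml(cfg)
        assert formula == fd.default_formula()
        assert formula.n_columns() == 25

    def test_sparse_triplet_export(self, tmp_path):
        events = pd.DataFrame({"event_type": [STIMULUS], "time": [4.0]})
        mass = fd.build_mass_design(
            events, fd.ModelFormula({STIMULUS: (fd.Intercept(),)}))
        exp = fd.time_expand(mass, [4.0], (-0.2, 0.5), 250.0, 3000)
        out = tmp_path / "design.txt"
        exp.save_triplets(out)
        lines = out.read_text().splitlines()
        assert lines[0] == "# 3000 175 175"  # 1 predictor x 175 lags
        assert len(lines) == 176


class TestTimeExpansion:
    def test_lag_and_column_counts(self):
        assert n_lags((-0.2, 0.5), 250.0) == 175
        events = event_frame(n_fix=40)
        mass = fd.build_mass_design(events, fd.default_formula())
        exp = fd.time_expand(mass, events["time"], (-0.2, 0.5), 250.0, 20000)
        assert exp.L == 175
        assert exp.X.shape == (20000, 4375)

    def test_single_event_diagonal_structure(self):
        events = pd.DataFrame({"event_type": [STIMULUS], "time": [4.0]})
        mass = fd.build_mass_design(
            events, fd.ModelFormula({STIMULUS: (fd.Intercept(),)}))
        exp = fd.time_expand(mass, [4.0], (-0.2, 0.5), 250.0, 3000)
        coo = exp.X.tocoo()
        assert exp.X.nnz == 175
        np.testing.assert_array_equal(np.sort(coo.row), np.arange(950, 1125))
        # one nonzero per expanded column, at its own lag
        np.testing.assert_array_equal(np.sort(coo.col), np.arange(175))
        np.testing.assert_array_equal(coo.row - 1000, exp.lag_offsets[coo.col])

    def test_edge_events_truncated(self):
        events = pd.DataFrame({"event_type": [STIMULUS, STIMULUS],
                               "time": [0.0, 11.9]})
        mass = fd.build_mass_design(
            events, fd.ModelFormula({STIMULUS: (fd.Intercept(),)}))
        exp = fd.time_expand(mass, events["time"], (-0.2, 0.5), 250.0, 3000)
        # first event loses its 50 pre-onset lags (rows would be negative);
        # the late one (sample 2975) keeps only lags below +25 samples
        assert exp.X.nnz == (175 - 50) + (50 + 25)

    def test_overlapping_events_sum(self):
        events = pd.DataFrame({"event_type": [STIMULUS] * 2, "time": [4.0, 4.0]})
        mass = fd.build_mass_design(
            events, fd.ModelFormula({STIMULUS: (fd.Intercept(),)}))
        exp = fd.time_expand(mass, events["time"], (-0.2, 0.5), 250.0, 3000)
        assert exp.X.max() == 2.0

    def test_sparsity_bound(self):
        events = event_frame(n_fix=30)
        mass = fd.build_mass_design(events, fd.default_formula())
        exp = fd.time_expand(mass, events["time"], (-0.2, 0.5), 250.0, 20000)
        per_row_nnz = (mass.X != 0).sum(axis=1)
        assert exp.X.nnz <= per_row_nnz.sum() * exp.L

    def test_empty_event_list_warns_all_zero(self):
        events = event_frame(n_fix=5)
        mass = fd.build_mass_design(events, fd.default_formula())
        empty = fd.MassDesign(X=mass.X[:0], columns=mass.columns,
                              formula=mass.formula, bases=mass.bases,
                              event_types=mass.event_types[:0])
        with pytest.warns(UserWarning, match="empty"):
            exp = fd.time_expand(empty, [], (-0.2, 0.5), 250.0, 1000)
        assert exp.X.nnz == 0


class TestZeroOut:
    @pytest.fixture
    def expanded(self):
        events = pd.DataFrame({"event_type": [STIMULUS], "time": [4.0]})
        mass = fd.build_mass_design(
            events, fd.ModelFormula({STIMULUS: (fd.Intercept(),)}))
        return fd.time_expand(mass, [4.0], (-0.2, 0.5), 250.0, 3000)

    def test_disjoint_interval_no_change(self, expanded):
        out = fd.zero_out_intervals(expanded, [(2000, 2500)])
        assert (out.X != expanded.X).nnz == 0

    def test_full_recording_all_zero(self, expanded):
        out = fd.zero_out_intervals(expanded, [(0, 3000)])
        assert out.X.nnz == 0
        assert out.X.shape == expanded.X.shape

    def test_half_lag_window_halves_nonzeros(self, expanded):
        # the event occupies rows 950..1124; zero its first half
        out = fd.zero_out_intervals(expanded, [(950, 1037)])
        assert out.X.nnz == expanded.X.nnz - 87

    def test_inverted_range_rejected(self, expanded):
        with pytest.raises(ValueError, match="inverted"):
            fd.zero_out_intervals(expanded, [(100, 50)])
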