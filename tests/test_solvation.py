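"""SASA computation, SASA–Log(PF) regression and ALPF classification."""

import math

import biotite.structure.info as info
import numpy as np
import pytest

from _oracles import mc_atom_sasa
from fps import fixtures, solvation


class TestResidueSASA:
    def test_isolated_atom_matches_closed_form(self):
        plan = fixtures.GeometryPlan().add("A", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0))
        arr = fixtures.synth_toy_structure(plan)
        (res,) = solvation.residue_sasa(arr, probe=1.4, point_number=5000)
        r = info.vdw_radius_single("C")
        assert res.sasa == pytest.approx(4 * math.pi * (r + 1.4) ** 2, rel=0.01)

    def test_three_residue_structure_matches_monte_carlo(self, three_residue_structure):
        arr = three_residue_structure
        radii = np.array([info.vdw_radius_single(e) for e in arr.element])
        mc = mc_atom_sasa(arr.coord, radii, probe=1.4, n_points=20000, seed=7)
        impl = {r.residue: r.sasa for r in solvation.residue_sasa(arr, point_number=2000)}
        sidechain = {
            1: [2],          # ALA CB
            2: [5, 6],       # SER CB, OG
            3: [8, 9, 10],   # VAL CB, CG1, CG2
        }
        for res_id, atom_idx in sidechain.items():
            expected = mc[atom_idx].sum()
            assert impl[res_id] == pytest.approx(expected, rel=0.03)

    def test_occlusion_monotonicity(self, three_residue_structure):
        """A residue in a complex is never more exposed than in isolation."""
        arr = three_residue_structure
        full = {r.residue: r.sasa for r in solvation.residue_sasa(arr, point_number=2000)}
        for res_id in (1, 2, 3):
            alone = arr[arr.res_id == res_id]
            (iso,) = solvation.residue_sasa(alone, point_number=2000)
            assert full[res_id] <= iso.sasa + 1e-6

    def test_missing_chain_lists_available(self, three_residue_structure):
        with pytest.raises(ValueError, match="'A'"):
            solvation.residue_sasa(three_residue_structure, chain="B")

    def test_whole_residue_exceeds_sidechain_only(self, three_residue_structure):
        side = solvation.residue_sasa(three_residue_structure, point_number=2000)
        whole = solvation.residue_sasa(
            three_residue_structure, point_number=2000, sidechain_only=False
        )
        for s, w in zip(side, whole):
            assert w.sasa >= s.sasa - 1e-6


class TestRegression:
    def test_collinear_points(self):
        model = solvation.fit_sasa_logpf([(0, 0), (10, -1), (20, -2)])
        assert model.slope == pytest.approx(-0.1)
        assert model.pearson_r == pytest.approx(-1.0)
        assert model.band_halfwidth(10.0) == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            solvation.fit_sasa_logpf([(0, 0), (10, -1)])

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            solvation.fit_sasa_logpf([(5, 0), (5, -1), (5, -2)])

    def test_band_widens_away_from_mean(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, 30)
        y = -0.05 * x + rng.normal(0, 0.2, 30)
        model = solvation.fit_sasa_logpf(list(zip(x, y)))
        hw_center = model.band_halfwidth(model.x_mean)
        assert model.band_halfwidth(model.x_mean + 50) > hw_center
        assert model.band_halfwidth(model.x_mean - 50) > hw_center

    def test_slope_ci_coverage(self):
        """The true slope lands inside its own 95% CI in >= 93% of replicates.

        Coverage of the OLS t-interval is exactly nominal under Gaussian
        noise; 1000 replicates keep the binomial noise of the observed rate
        well clear of the 93% acceptance bound.
        """
        from scipy import stats
        rng = np.random.default_rng(123)
        n_rep = 1000
        hits = 0
        for _ in range(n_rep):
            x = rng.uniform(0, 100, 30)
            y = -0.05 * x + rng.normal(0, 0.2, 30)
            model = solvation.fit_sasa_logpf(list(zip(x, y)))
            se_slope = model.residual_sd / math.sqrt(model.sxx)
            tcrit = stats.t.ppf(0.975, model.n - 2)
            if abs(model.slope + 0.05) <= tcrit * se_slope:
                hits += 1
        assert hits >= 0.93 * n_rep

    def test_vertical_shift_moves_intercept_only(self):
        pts = [(0.0, 0.0), (10.0, -0.9), (20.0, -2.1), (30.0, -3.0)]
        m1 = solvation.fit_sasa_logpf(pts)
        m2 = solvation.fit_sasa_logpf([(x, y + 2.5) for x, y in pts])
        assert m2.slope == pytest.approx(m1.slope)
        assert m2.intercept == pytest.approx(m1.intercept + 2.5)


class TestClassifyALPF:
    @pytest.fixture()
    def model(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 100, 20)
        y = -0.05 * x + rng.normal(0, 0.1, 20)
        return solvation.fit_sasa_logpf(list(zip(x, y)))

    def test_point_on_line_is_normal(self, model):
        (call,) = solvation.classify_alpf([(1, 50.0, float(model.predict(50.0)))], model)
        assert call.status == "normal"

    def test_point_far_below_is_anomalous(self, model):
        low = float(model.lower(50.0) - 10 * model.band_halfwidth(50.0) - 1.0)
        (call,) = solvation.classify_alpf([(1, 50.0, low)], model)
        assert call.status == "anomalous_low"

    def test_planted_outliers_recovered_exactly(self):
        """20 on-line points + 3 outliers at -5 sigma -> exactly those 3 called."""
        rng = np.random.default_rng(11)
        sigma = 0.1
        x = rng.uniform(0, 100, 20)
        y = -0.05 * x + rng.normal(0, sigma, 20)
        model = solvation.fit_sasa_logpf(list(zip(x, y)))
        records = [(i, float(xi), float(model.predict(xi)))
                   for i, xi in enumerate(x)]
        planted = [(100 + j, xi, float(model.predict(xi)) - 5 * sigma)
                   for j, xi in enumerate([15.0, 50.0, 85.0])]
        calls = solvation.classify_alpf(records + planted, model)
        anomalous = {c.residue for c in calls if c.status == "anomalous_low"}
        assert anomalous == {100, 101, 102}

    def test_order_invariance_and_level_monotonicity(self, model):
        rng = np.random.default_rng(2)
        records = [(i, float(x), float(model.predict(x)) + float(d))
                   for i, (x, d) in enumerate(zip(rng.uniform(0, 100, 30),
                                                  rng.normal(0, 0.3, 30)))]
        calls_fwd = solvation.classify_alpf(records, model)
        calls_rev = solvation.classify_alpf(records[::-1], model)
        assert {(c.residue, c.status) for c in calls_fwd} == \
               {(c.residue, c.status) for c in calls_rev}
        import dataclasses
        narrow = dataclasses.replace(model, level=0.80)
        set95 = {c.residue for c in calls_fwd if c.status == "anomalous_low"}
        set80 = {c.residue for c in solvation.classify_alpf(records, narrow)
                 if c.status == "anomalous_low"}
        assert set95 <= set80


class TestDeltaMetrics:
    def test_identical_states_give_zero(self):
        a = {1: {"logPF": -1.0, "sasa": 30.0}, 2: {"logPF": 0.5, "sasa": 80.0}}
        per_res, groups = solvation.delta_metrics(a, a, groups={1: "polar", 2: "polar"})
        assert all(v["dlogPF"] == 0 and v["dsasa"] == 0 for v in per_res.values())
        assert groups["polar"]["dlogPF"] == (0.0, 0.0)

    def test_uniform_shift_recovered(self):
        b = {1: {"logPF": -1.0, "sasa": 30.0}, 2: {"logPF": 0.5, "sasa": 80.0}}
        a = {k: {"logPF": v["logPF"] + 0.3, "sasa": v["sasa"]} for k, v in b.items()}
        _, groups = solvation.delta_metrics(a, b, groups={1: "g", 2: "g"})
        assert groups["g"]["dlogPF"] == (pytest.approx(0.3), pytest.approx(0.0))

    def test_planted_group_shifts_recovered(self):
        b = {i: {"logPF": -0.02 * i, "sasa": float(i)} for i in range(1, 9)}
        shifts = {"polar": 0.5, "aromatic": -0.2}
        labels = {i: ("polar" if i <= 4 else "aromatic") for i in range(1, 9)}
        a = {i: {"logPF": v["logPF"] + shifts[labels[i]], "sasa": v["sasa"] + 3.0}
             for i, v in b.items()}
        _, groups = solvation.delta_metrics(a, b, groups=labels)
        assert groups["polar"]["dlogPF"][0] == pytest.approx(0.5)
        assert groups["aromatic"]["dlogPF"][0] == pytest.approx(-0.2)
        assert groups["polar"]["dsasa"][0] == pytest.approx(3.0)

    def test_disjoint_states_rejected(self):
        with pytest.raises(ValueError):
            solvation.delta_metrics({1: {"logPF": 0, "sasa": 0}},
                                    {2: {"logPF": 0, "sasa": 0}})
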