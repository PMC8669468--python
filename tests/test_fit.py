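"""Flux estimation: objective arithmetic, recovery, CIs, gating, precision."""

import numpy as np
import pytest

import gluconeoflux as gf
from gluconeoflux import synth
from gluconeoflux.fit import (FitProblem, FluxEstimate, MeasurementSet,
                              MIDMeasurement, RateMeasurement,
                              gate_unlabeled_influx, precision_score)
from gluconeoflux.mid import TracerSpec

U_TRACER = {"suc_U": TracerSpec("A", [("11", 1.0)], purity=0.99)}
DILUTION_TRUTH = {"UPT": 100.0, "A_IN": 5.0, "V1": 105.0, "B_IN": 10.0,
                  "OUT": 115.0}


def dilution_measurements(model, noise_sd=0.005, seed=0, replicates=3,
                          renormalize=False):
    truth = gf.FluxVector(dict(DILUTION_TRUTH))
    sims = gf.simulate_metabolites(model, truth, U_TRACER["suc_U"], ["A", "B"])
    rng = np.random.default_rng(seed)
    mids = []
    for rep in range(1, replicates + 1):
        for frag in ("A", "B"):
            f = sims[frag].fractions.copy()
            if noise_sd:
                f = f + rng.normal(0, noise_sd, f.shape)
                if renormalize:
                    f = np.clip(f, 0, None)
                    f = f / f.sum()
            mids.append(MIDMeasurement("suc_U", rep, frag, f,
                                       np.full_like(f, max(noise_sd, 1e-6))))
    return MeasurementSet(mids, [])


class TestObjective:
    def test_simulated_equals_measured_gives_zero(self, dilution_model):
        ms = dilution_measurements(dilution_model, noise_sd=0.0)
        prob = FitProblem(dilution_model, ms, U_TRACER,
                          enabled_influxes=("A_IN", "B_IN"))
        # params at truth
        truth = gf.FluxVector(dict(DILUTION_TRUTH))
        vt = truth.as_array(dilution_model)
        u, *_ = np.linalg.lstsq(prob.N, vt - prob.v0, rcond=None)
        assert prob.ssr(u) == pytest.approx(0.0, abs=1e-16)

    def test_single_residual_contribution(self):
        # sim 0.5, meas 0.4, sd 0.05 -> ((0.1)/0.05)^2 = 4
        res = (0.5 - 0.4) / 0.05
        assert res ** 2 == pytest.approx(4.0)

    def test_doubling_sds_divides_ssr_by_four(self, dilution_model):
        ms1 = dilution_measurements(dilution_model, noise_sd=0.005, seed=1)
        mids2 = [MIDMeasurement(m.tracer_id, m.replicate, m.fragment,
                                m.fractions, 2 * m.sd) for m in ms1.mids]
        ms2 = MeasurementSet(mids2, [])
        prob1 = FitProblem(dilution_model, ms1, U_TRACER,
                           enabled_influxes=("A_IN", "B_IN"), sd_floor=0.0)
        prob2 = FitProblem(dilution_model, ms2, U_TRACER,
                           enabled_influxes=("A_IN", "B_IN"), sd_floor=0.0)
        u = np.zeros(prob1.k)
        assert prob2.ssr(u) == pytest.approx(prob1.ssr(u) / 4.0)

    def test_ssr_invariant_to_measurement_row_order(self, dilution_model):
        ms = dilution_measurements(dilution_model, seed=2)
        shuffled = MeasurementSet(list(reversed(ms.mids)), [])
        p1 = FitProblem(dilution_model, ms, U_TRACER,
                        enabled_influxes=("A_IN", "B_IN"))
        p2 = FitProblem(dilution_model, shuffled, U_TRACER,
                        enabled_influxes=("A_IN", "B_IN"))
        u = np.zeros(p1.k) + 0.5
        assert p1.ssr(u) == pytest.approx(p2.ssr(u))


class TestFit:
    def test_noiseless_recovery_on_dilution_toy(self, dilution_model):
        ms = dilution_measurements(dilution_model, noise_sd=0.0)
        res = gf.fit(dilution_model, ms, U_TRACER, n_starts=5, seed=3,
                     enabled_influxes=("A_IN", "B_IN"))
        assert res.ssr < 1e-8
        for rid, v in DILUTION_TRUTH.items():
            assert res.best_fluxes.values[rid] == pytest.approx(v, abs=1e-3)

    def test_determinism_same_seed_same_result(self, dilution_model):
        ms = dilution_measurements(dilution_model, seed=4)
        r1 = gf.fit(dilution_model, ms, U_TRACER, n_starts=4, seed=9,
                    enabled_influxes=("A_IN", "B_IN"))
        r2 = gf.fit(dilution_model, ms, U_TRACER, n_starts=4, seed=9,
                    enabled_influxes=("A_IN", "B_IN"))
        assert r1.ssr == r2.ssr
        assert r1.per_start_ssr == r2.per_start_ssr
        np.testing.assert_array_equal(r1.best_params, r2.best_params)

    def test_best_ssr_bounded_by_every_start(self, dilution_model):
        ms = dilution_measurements(dilution_model, seed=5)
        res = gf.fit(dilution_model, ms, U_TRACER, n_starts=6, seed=1,
                     enabled_influxes=("A_IN", "B_IN"))
        assert all(res.ssr <= s + 1e-9 for s in res.per_start_ssr)

    def test_misspecified_model_rejected_by_chi_square(self, demo_model):
        """Data from an active glyoxylate shunt fitted with the shunt
        forced off fail the chi-square acceptance at small SDs."""
        target = gf.FluxVector({**synth.DEMO_TRUE_FLUXES, "ICL": 20.0,
                                "MS": 20.0})
        truth = synth.project_to_feasible(demo_model, target,
                                          fixed_fluxes={"ICL": 20.0})
        assert truth.values["ICL"] == pytest.approx(20.0)
        cfg = synth.ScenarioConfig(mid_noise_sd=0.002, rate_noise_sd=0.5,
                                   rate_sd=0.5, seed=6)
        ms = synth.make_mid_dataset(demo_model, truth, cfg)
        res = gf.fit(demo_model, ms, synth.DEFAULT_TRACERS, n_starts=6,
                     seed=2, fixed_fluxes={"ICL": 0.0, "MS": 0.0},
                     sd_floor=0.002)
        assert not res.accepted

    def test_biomass_imprecision_option_doubles_rate_sds(self, dilution_model):
        ms = MeasurementSet(dilution_measurements(dilution_model).mids,
                            [RateMeasurement("OUT", 115.0, 2.0),
                             RateMeasurement("V1", 105.0, 1.0)])
        wide = ms.with_inflated_rate_sds(2.0, ["OUT"])
        assert wide.rates[0].sd == 4.0
        assert wide.rates[1].sd == 1.0


class TestConfidenceIntervals:
    def test_tight_noiseless_interval_collapses(self, dilution_model):
        ms = dilution_measurements(dilution_model, noise_sd=0.0)
        # tiny SDs stand in for near-perfect data
        mids = [MIDMeasurement(m.tracer_id, m.replicate, m.fragment,
                               m.fractions, np.full_like(m.sd, 1e-4))
                for m in ms.mids]
        res = gf.fit(dilution_model, MeasurementSet(mids, []), U_TRACER,
                     n_starts=4, seed=3, enabled_influxes=("A_IN", "B_IN"),
                     sd_floor=1e-4)
        ci = gf.confidence_interval(res, "A_IN")
        assert ci.width < 0.2

    def test_interval_nesting_99_contains_95(self, dilution_model):
        ms = dilution_measurements(dilution_model, seed=8)
        res = gf.fit(dilution_model, ms, U_TRACER, n_starts=4, seed=3,
                     enabled_influxes=("A_IN", "B_IN"))
        ci95 = gf.confidence_interval(res, "A_IN", alpha=0.05)
        ci99 = gf.confidence_interval(res, "A_IN", alpha=0.01)
        assert ci99.lb95 <= ci95.lb95 + 1e-6
        assert ci99.ub95 >= ci95.ub95 - 1e-6

    def test_profile_bounds_match_grid_scan_oracle(self, dilution_model):
        """Dense grid scan of the profile SSR surface reproduces the
        bisection bounds."""
        from gluconeoflux.fit import _profile_ssr
        from scipy.stats import chi2
        ms = dilution_measurements(dilution_model, seed=12)
        res = gf.fit(dilution_model, ms, U_TRACER, n_starts=4, seed=3,
                     enabled_influxes=("A_IN", "B_IN"))
        ci = gf.confidence_interval(res, "A_IN")
        thresh = res.ssr + chi2.ppf(0.95, 1)
        grid = np.linspace(ci.value - 3, ci.value + 3, 121)
        prof = []
        warm = res.best_params.copy()
        for c in grid:
            s, warm = _profile_ssr(res.problem, "A_IN", float(c), warm)
            prof.append(s)
        prof = np.array(prof)
        inside = grid[prof <= thresh]
        assert inside.min() == pytest.approx(ci.lb95, abs=0.1)
        assert inside.max() == pytest.approx(ci.ub95, abs=0.1)

    def test_structurally_nonidentifiable_flux_spans_box(self):
        """Two parallel identical routes: only their sum is identifiable,
        so each route's CI runs to the feasibility limits and is flagged."""
        from gluconeoflux.network import AtomTransition, NetworkModel, Reaction
        t = lambda s, p: (AtomTransition(((s, "ab"),), ((p, "ab"),)),)
        model = NetworkModel([
            Reaction("UPT", {"X": 1}, {"A": 1}, kind="uptake",
                     atom_transitions=t("X", "A")),
            Reaction("P1", {"A": 1}, {"B": 1}, atom_transitions=t("A", "B")),
            Reaction("P2", {"A": 1}, {"B": 1}, atom_transitions=t("A", "B")),
            Reaction("OUT", {"B": 1}, {"BX": 1}, kind="secretion",
                     atom_transitions=t("B", "BX")),
        ])
        truth = gf.FluxVector({"UPT": 100.0, "P1": 60.0, "P2": 40.0,
                               "OUT": 100.0})
        tr = {"u": TracerSpec("A", [("11", 1.0)], purity=0.99)}
        sims = gf.simulate_metabolites(model, truth, tr["u"], ["A", "B"])
        mids = [MIDMeasurement("u", 1, f, sims[f].fractions,
                               np.full(3, 0.005)) for f in ("A", "B")]
        res = gf.fit(model, MeasurementSet(mids, []), tr, n_starts=4, seed=5)
        ci = gf.confidence_interval(res, "P1")
        assert ci.lb95 == pytest.approx(0.0, abs=0.5)
        assert ci.ub95 >= 99.0


class TestPrecisionScore:
    def test_equal_widths_score_one(self):
        a = FluxEstimate("R", 5.0, 3.0, 7.0)
        assert precision_score(a, a) == pytest.approx(1.0)

    def test_widths_4_and_2_score_4(self):
        a = FluxEstimate("R", 5.0, 3.0, 7.0)   # width 4
        b = FluxEstimate("R", 5.0, 4.0, 6.0)   # width 2
        assert precision_score(a, b) == pytest.approx(4.0)

    def test_zero_washed_width_gives_infinity(self):
        a = FluxEstimate("R", 5.0, 3.0, 7.0)
        b = FluxEstimate("R", 5.0, 5.0, 5.0)
        assert precision_score(a, b) == float("inf")

    def test_sd_derived_from_bounds(self):
        est = FluxEstimate("R", 5.0, 3.0, 7.0)
        assert est.sd == pytest.approx(4.0 / (2 * 1.96), rel=1e-3)


class TestGating:
    def test_worked_example_enables_exactly_five_influxes(self):
        m0 = {"MAL": 0.05, "PYR": 0.05, "G6P": 0.02, "DHAP": 0.03,
              "ACCOA": 0.02, "FUM": 0.004, "CIT": 0.009}
        flagged = gate_unlabeled_influx(list(m0.items()))
        assert flagged == {"MAL", "PYR", "G6P", "DHAP", "ACCOA"}

    def test_all_below_threshold_gives_empty_set(self):
        assert gate_unlabeled_influx([("MAL", 0.005), ("PYR", 0.01)]) == set()

    def test_boundary_value_excluded_strictly(self):
        assert gate_unlabeled_influx([("MAL", 0.01)]) == set()
        assert gate_unlabeled_influx([("MAL", 0.0100001)]) == {"MAL"}

    def test_replicates_are_averaged(self):
        mids = [("MAL", 0.02), ("MAL", 0.004), ("MAL", 0.004)]
        assert gate_unlabeled_influx(mids) == set()  # mean 0.0093

    def test_model_mapping_returns_influx_reaction_ids(self, pputida_model):
        m0 = [("MAL", 0.05), ("PYR", 0.05), ("G6P", 0.02), ("DHAP", 0.03),
              ("ACCOA", 0.02)]
        rids = gate_unlabeled_influx(m0, pputida_model)
        assert rids == {"MAL_IN", "PYR_IN", "G6P_IN", "DHAP_IN", "ACCOA_IN"}
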