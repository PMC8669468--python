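"""EMU decomposition and forward simulation, checked against the
brute-force isotopomer oracle and label-conservation arguments."""

import numpy as np
import pytest

import gluconeoflux as gf
from gluconeoflux import synth
from gluconeoflux.emu import EMUNode, decompose, simulate
from gluconeoflux.errors import DegenerateFluxError, GluconeofluxError
from gluconeoflux.mid import TracerSpec
from gluconeoflux.network import AtomTransition, FluxVector, NetworkModel, Reaction


def _t(*pairs):
    subs = tuple(p for p in pairs if p[2] == "s")
    prods = tuple(p for p in pairs if p[2] == "p")
    return (AtomTransition(tuple((m, lab) for m, lab, _ in subs),
                           tuple((m, lab) for m, lab, _ in prods)),)


class TestDecompose:
    def test_single_transfer_reaction_traces_to_substrate(self, chain_model):
        net = decompose(chain_model, ["B"])
        nodes = set(net.producers)
        assert EMUNode("B", (1, 2)) in nodes
        assert EMUNode("A", (1, 2)) in nodes

    def test_cleavage_keeps_only_needed_substrate_carbons(self):
        model = NetworkModel([
            Reaction("UPT", {"X": 1}, {"A": 1}, kind="uptake",
                     atom_transitions=_t(("X", "abc", "s"), ("A", "abc", "p"))),
            Reaction("V1", {"A": 1}, {"B": 1, "C": 1},
                     atom_transitions=_t(("A", "abc", "s"), ("B", "ab", "p"),
                                         ("C", "c", "p"))),
            Reaction("O1", {"B": 1}, {}, kind="biomass_drain"),
            Reaction("O2", {"C": 1}, {}, kind="biomass_drain"),
        ])
        net = decompose(model, ["B"])
        mets_sizes = {(n.metabolite, n.positions) for n in net.producers}
        assert ("A", (1, 2)) in mets_sizes
        assert ("A", (3,)) not in mets_sizes
        assert ("A", (1, 2, 3)) not in mets_sizes

    def test_node_count_matches_exhaustive_closure_oracle(self, demo_model):
        """Every node reported is reachable and the closure is minimal:
        re-running the closure by brute force from the targets gives the
        same node set."""
        targets = ["CIT", "MAL"]
        net = decompose(demo_model, targets)
        # brute-force closure: repeatedly expand source sets until fixpoint
        needed = {EMUNode(t, tuple(range(1, c + 1)))
                  for t, c in [("CIT", 6), ("MAL", 4)]}
        changed = True
        while changed:
            changed = False
            for node in list(needed):
                for term in net.producers.get(node, []):
                    for kind, src in term.sources:
                        if kind == "internal" and src not in needed:
                            needed.add(src)
                            changed = True
        assert needed == set(net.producers)

    def test_unreachable_target_raises(self, chain_model):
        with pytest.raises(GluconeofluxError,
                           match="unreachable|balanced|no atom-mapped"):
            decompose(chain_model, ["Z"])


class TestSimulate:
    def test_uniform_tracer_labels_everything(self, demo_model,
                                              demo_truth_fluxes):
        tracer = TracerSpec("SUC", [("1111", 1.0)], purity=1.0)
        sims = gf.simulate_metabolites(demo_model, demo_truth_fluxes, tracer,
                                       ["MAL", "FUM", "CIT", "AKG"])
        for met in ("MAL", "FUM"):
            np.testing.assert_allclose(sims[met].fractions, [0, 0, 0, 0, 1],
                                       atol=1e-12)

    def test_unlabeled_tracer_gives_m0_everywhere(self, demo_model,
                                                  demo_truth_fluxes):
        tracer = TracerSpec("SUC", [("0000", 1.0)])
        sims = gf.simulate_metabolites(demo_model, demo_truth_fluxes, tracer,
                                       ["MAL", "CIT", "G6P"])
        for met, mid in sims.items():
            assert mid.fractions[0] == pytest.approx(1.0, abs=1e-12)

    def test_mids_are_probability_vectors(self, demo_model, demo_truth_fluxes):
        sims = gf.simulate_metabolites(demo_model, demo_truth_fluxes,
                                       synth.DEFAULT_TRACERS["suc_14"],
                                       list(synth.DEMO_MEASURED_FRAGMENTS))
        for mid in sims.values():
            assert np.all(mid.fractions >= 0)
            assert mid.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mix_of_double_labeled_tracers_passthrough_is_m2(self):
        model = NetworkModel([
            Reaction("UPT", {"SX": 1}, {"P": 1}, kind="uptake",
                     atom_transitions=_t(("SX", "abcd", "s"), ("P", "abcd", "p"))),
            Reaction("OUT", {"P": 1}, {}, kind="biomass_drain"),
        ])
        tracer = TracerSpec("P", [("1001", 0.5), ("0110", 0.5)], purity=1.0)
        sims = gf.simulate_metabolites(
            model, FluxVector({"UPT": 10.0, "OUT": 10.0}), tracer, ["P"])
        np.testing.assert_allclose(sims["P"].fractions, [0, 0, 1, 0, 0],
                                   atol=1e-12)

    def test_matches_brute_force_oracle_on_toys(self, toy_models):
        tracer = {"toy_chain_split": TracerSpec("A", [("110", 1.0)], purity=0.98),
                  "toy_cycle_scramble": TracerSpec("A", [("10", 1.0)], purity=0.98),
                  "toy_reversible_mix": TracerSpec("A", [("101", 1.0)], purity=0.98)}
        for name, model in toy_models.items():
            fls = gf.sample_true_fluxes(model, seed=7, exchange_range=(0, 40), n=5)
            mets = sorted(model.balanced_metabolites)
            for fl in fls:
                emu_mids = gf.simulate_metabolites(model, fl, tracer[name], mets)
                oracle = gf.simulate_isotopomers(model, fl, tracer[name])
                for met in mets:
                    np.testing.assert_allclose(
                        emu_mids[met].fractions, oracle[met].fractions,
                        atol=1e-8, err_msg=f"{name}:{met}")

    def test_label_conservation_with_single_full_tracer(self, toy_models):
        """Mean enrichment of every pool equals tracer enrichment when
        there is no unlabeled inflow."""
        model = toy_models["toy_chain_split"]
        tracer = TracerSpec("A", [("111", 1.0)], purity=0.95)
        fl = gf.sample_true_fluxes(model, seed=3)
        sims = gf.simulate_metabolites(model, fl, tracer,
                                       sorted(model.balanced_metabolites))
        for met, mid in sims.items():
            assert mid.mean_enrichment() == pytest.approx(0.95, abs=1e-9)

    def test_unlabeled_influx_decreases_descendant_enrichment(self, demo_model):
        """Carry-over monotonicity: a 5% unlabeled malate influx strictly
        lowers the mean enrichment of malate and its pure descendants."""
        cfg0 = synth.ScenarioConfig(carryover_fraction=0.0)
        cfg1 = synth.ScenarioConfig(carryover_fraction=0.05)
        _, clean = synth.demo_truth(cfg0)
        _, dirty = synth.demo_truth(cfg1)
        tracer = synth.UNIFORM_TRACER
        mets = ["MAL", "OAA", "CIT", "AKG", "PEP", "PG3", "G6P"]
        s0 = gf.simulate_metabolites(demo_model, clean, tracer, mets)
        s1 = gf.simulate_metabolites(demo_model, dirty, tracer, mets)
        for met in mets:
            assert s1[met].mean_enrichment() < s0[met].mean_enrichment()
            assert s1[met].fractions[0] > s0[met].fractions[0]

    def test_degenerate_flux_error_names_the_emu(self):
        """A consumed pool with zero production raises, naming the EMU."""
        model = NetworkModel([
            Reaction("UPT", {"X": 1}, {"A": 1}, kind="uptake",
                     atom_transitions=_t(("X", "a", "s"), ("A", "a", "p"))),
            Reaction("R0", {"A": 1}, {"M": 1},
                     atom_transitions=_t(("A", "a", "s"), ("M", "a", "p"))),
            Reaction("V2", {"M": 1}, {"C": 1},
                     atom_transitions=_t(("M", "a", "s"), ("C", "a", "p"))),
            Reaction("O1", {"C": 1}, {}, kind="biomass_drain"),
        ])
        # R0 carries no flux, so M is a dead pool that still feeds C
        fl = FluxVector({"UPT": 10.0, "R0": 0.0, "V2": 10.0, "O1": 10.0})
        with pytest.raises(DegenerateFluxError, match="M"):
            gf.simulate_metabolites(model, fl, None, ["C"])
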