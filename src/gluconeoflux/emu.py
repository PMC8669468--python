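"""Elementary-metabolite-unit (EMU) decomposition and forward labeling model.

An EMU is a subset of a metabolite's carbons whose mass-isotopomer
distribution can be balanced independently of the rest of the molecule.
Starting from the observed fragments, the decomposition traces atoms
backwards through the atom transitions and keeps only the EMUs actually
required, stratified by size.  Simulation then solves one linear system
per size (smaller sizes feed larger ones through convolution), which is
exact at isotopic steady state.

Reversible reactions enter the balances as two opposing flows (net +
exchange expanded to forward/backward).  Rotationally symmetric
metabolites are handled by alternative atom maps on the producing
reactions, which share the flux equally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import DegenerateFluxError, GluconeofluxError
from .mid import MIDVector, TracerSpec, unlabeled_mid
from .network import FluxVector, NetworkModel


class EMUNode(NamedTuple):
    metabolite: str
    positions: tuple[int, ...]  # 1-based carbon indices, sorted

    @property
    def size(self) -> int:
        return len(self.positions)

    def __str__(self) -> str:  # e.g. MAL[1,2,3]
        return f"{self.metabolite}[{','.join(map(str, self.positions))}]"


@dataclass(frozen=True)
class ProducerTerm:
    """One producing flux contribution to an EMU balance.

    ``sources`` lists the EMU(s) supplying the carbons: a single same-size
    EMU, or several strictly smaller EMUs joined by convolution.  Boundary
    EMUs (external substrates, unlabeled influx) are marked so their MIDs
    come from the tracer specification instead of the linear system.
    """

    reaction_id: str
    direction: int  # +1 forward, -1 backward
    weight: float   # alternative-atom-map share of the reaction flux
    sources: tuple[tuple[str, EMUNode], ...]  # (kind, node); kind: internal|boundary|unlabeled


@dataclass
class EMUNetwork:
    model: NetworkModel
    targets: list[EMUNode]
    producers: dict[EMUNode, list[ProducerTerm]]
    boundary_metabolites: set[str]

    @property
    def nodes(self) -> list[EMUNode]:
        out = sorted(self.producers, key=lambda n: (n.size, n.metabolite, n.positions))
        return out

    def size_levels(self) -> list[int]:
        return sorted({n.size for n in self.producers})


def _parse_target(model: NetworkModel, target, carbon_counts) -> EMUNode:
    if isinstance(target, EMUNode):
        return target
    if isinstance(target, tuple):
        met, positions = target
        return EMUNode(met, tuple(sorted(positions)))
    met = str(target)
    if met not in carbon_counts:
        raise GluconeofluxError(
            f"target metabolite {met!r} has no atom-mapped production path")
    return EMUNode(met, tuple(range(1, carbon_counts[met] + 1)))


def decompose(model: NetworkModel, targets) -> EMUNetwork:
    """Minimal EMU dependency network sufficient to simulate ``targets``."""
    carbon_counts = model.carbon_counts()
    balanced = model.balanced_metabolites
    target_nodes = [_parse_target(model, t, carbon_counts) for t in targets]
    for node in target_nodes:
        if node.metabolite not in balanced:
            raise GluconeofluxError(
                f"target {node} is not a balanced metabolite of the model")

    # producing transition instances per metabolite: (reaction, direction,
    # weight, transition) with direction-adjusted substrate/product sides
    producing: dict[str, list] = {}
    for r in model.reactions:
        directions = [(+1, t) for t in r.atom_transitions]
        if r.reversible:
            directions += [(-1, t.reversed()) for t in r.atom_transitions]
        if r.kind == "unlabeled_influx":
            met = next(iter(r.products))
            producing.setdefault(met, []).append((r, +1, 1.0, None))
            continue
        n_alt = max(len(r.atom_transitions), 1)
        for direction, t in directions:
            for met, _labels in t.product_atoms:
                producing.setdefault(met, []).append((r, direction, 1.0 / n_alt, t))

    producers: dict[EMUNode, list[ProducerTerm]] = {}
    boundary_mets: set[str] = set()
    stack = list(dict.fromkeys(target_nodes))
    while stack:
        node = stack.pop()
        if node in producers:
            continue
        terms: list[ProducerTerm] = []
        mapped_producers = producing.get(node.metabolite, [])
        if not mapped_producers:
            raise GluconeofluxError(
                f"EMU {node} unreachable: no atom-mapped production path "
                f"for {node.metabolite}")
        for r, direction, weight, t in mapped_producers:
            if t is None:  # unlabeled influx
                terms.append(ProducerTerm(r.id, direction, weight,
                                          (("unlabeled", node),)))
                continue
            # every product instance of this metabolite is a separate term
            for met, labels in t.product_atoms:
                if met != node.metabolite:
                    continue
                letters = [labels[p - 1] for p in node.positions]
                per_sub: dict[int, list[int]] = {}
                for letter in letters:
                    found = False
                    for si, (_smet, slabels) in enumerate(t.substrate_atoms):
                        pos = slabels.find(letter)
                        if pos >= 0:
                            per_sub.setdefault(si, []).append(pos + 1)
                            found = True
                            break
                    if not found:
                        raise GluconeofluxError(
                            f"reaction {r.id}: carbon {letter!r} of {met} "
                            "not found on substrate side")
                sources = []
                for si in sorted(per_sub):
                    smet = t.substrate_atoms[si][0]
                    snode = EMUNode(smet, tuple(sorted(per_sub[si])))
                    if smet in balanced:
                        sources.append(("internal", snode))
                        if snode not in producers:
                            stack.append(snode)
                    else:
                        sources.append(("boundary", snode))
                        boundary_mets.add(smet)
                terms.append(ProducerTerm(r.id, direction, weight, tuple(sources)))
        producers[node] = terms
    return EMUNetwork(model, target_nodes, producers, boundary_mets)


def directional_fluxes(model: NetworkModel, fluxes: FluxVector,
                       clip_tol: float = 1e-9) -> dict[tuple[str, int], float]:
    """Expand (net, exchange) pairs to forward/backward flow magnitudes."""
    out: dict[tuple[str, int], float] = {}
    for r in model.reactions:
        net = fluxes.values.get(r.id, 0.0)
        if r.reversible:
            xch = fluxes.exchange(r.id)
            out[(r.id, +1)] = max(net, 0.0) + xch
            out[(r.id, -1)] = max(-net, 0.0) + xch
        else:
            out[(r.id, +1)] = max(net, 0.0)  # small infeasible negatives clipped
            out[(r.id, -1)] = 0.0
    return out


def _boundary_mid(node: EMUNode, tracers: dict[str, TracerSpec]) -> np.ndarray:
    spec = tracers.get(node.metabolite)
    if spec is None:
        return unlabeled_mid(node.size)
    return spec.emu_mid(node.positions)


def _resolve_tracers(model: NetworkModel, emu: EMUNetwork, tracer) -> dict[str, TracerSpec]:
    """Map boundary metabolites to tracer specs.

    A tracer whose ``substrate`` names an uptake reaction's *product*
    (e.g. "SUC") is applied to the corresponding external metabolite.
    """
    if tracer is None:
        return {}
    specs = list(tracer.values()) if isinstance(tracer, dict) else [tracer]
    out: dict[str, TracerSpec] = {}
    for spec in specs:
        name = spec.substrate
        if name in emu.boundary_metabolites:
            out[name] = spec
            continue
        hits = [r for r in model.reactions
                if r.kind == "uptake" and name in r.products]
        placed = False
        for r in hits:
            for t in r.atom_transitions:
                for smet, _ in t.substrate_atoms:
                    if smet in emu.boundary_metabolites:
                        out[smet] = spec
                        placed = True
        if not placed and name not in out:
            raise GluconeofluxError(
                f"tracer substrate {name!r} does not feed the EMU network")
    return out


class SimulationEngine:
    """Precompiled EMU cascade solver.

    Compiles the dependency network into flat index arrays once so that
    repeated evaluations (inside the fitter) cost only the per-size linear
    solves.  Flux input is the pair (net flux array in model reaction
    order, exchange array over reversible reactions).
    """

    def __init__(self, emu: EMUNetwork):
        self.emu = emu
        model = emu.model
        self.ridx = {r.id: i for i, r in enumerate(model.reactions)}
        self.rev_ids = [r.id for r in model.reactions if r.reversible]
        self.rev_pos = {rid: i for i, rid in enumerate(self.rev_ids)}
        self.rev_mask = np.array([r.reversible for r in model.reactions])
        n = len(model.reactions)

        def fidx(rid: str, direction: int) -> int:
            return 2 * self.ridx[rid] + (0 if direction > 0 else 1)

        self.n_flux = 2 * n
        self.levels = []
        node_level: dict[EMUNode, tuple[int, int]] = {}
        for li, size in enumerate(emu.size_levels()):
            nodes = sorted((nd for nd in emu.producers if nd.size == size),
                           key=lambda nd: (nd.metabolite, nd.positions))
            index = {nd: i for i, nd in enumerate(nodes)}
            for nd, i in index.items():
                node_level[nd] = (li, i)
            diag_rows, diag_f, diag_w = [], [], []
            off_rows, off_cols, off_f, off_w = [], [], [], []
            known = []   # (row, flux index, weight, sources)
            for nd in nodes:
                i = index[nd]
                for term in emu.producers[nd]:
                    k = fidx(term.reaction_id, term.direction)
                    diag_rows.append(i)
                    diag_f.append(k)
                    diag_w.append(term.weight)
                    if (len(term.sources) == 1
                            and term.sources[0][0] == "internal"):
                        src = term.sources[0][1]
                        off_rows.append(i)
                        off_cols.append(index[src])
                        off_f.append(k)
                        off_w.append(term.weight)
                    else:
                        known.append((i, k, term.weight, term.sources))
            self.levels.append({
                "size": size, "nodes": nodes, "index": index,
                "diag_rows": np.array(diag_rows, dtype=int),
                "diag_f": np.array(diag_f, dtype=int),
                "diag_w": np.array(diag_w),
                "off_rows": np.array(off_rows, dtype=int),
                "off_cols": np.array(off_cols, dtype=int),
                "off_f": np.array(off_f, dtype=int),
                "off_w": np.array(off_w),
                "known": known,
            })
        self.node_level = node_level
        # consumers of each internal node (for degenerate-flux detection)
        self.consumers: dict[EMUNode, list[tuple[int, float]]] = {}
        for nd, terms in emu.producers.items():
            for term in terms:
                k = fidx(term.reaction_id, term.direction)
                for kind, src in term.sources:
                    if kind == "internal":
                        self.consumers.setdefault(src, []).append((k, term.weight))
        self._boundary_cache: dict[tuple, dict] = {}
        self.targets = emu.targets

    def flux_array(self, v: np.ndarray, xch: np.ndarray) -> np.ndarray:
        """(2n,) array of forward/backward flow magnitudes."""
        f = np.zeros(self.n_flux)
        fwd = np.maximum(v, 0.0)
        bwd = np.maximum(-v, 0.0)
        bwd[~self.rev_mask] = 0.0
        if len(self.rev_ids):
            x = np.zeros(len(v))
            x[[self.ridx[r] for r in self.rev_ids]] = xch
            fwd = fwd + np.where(self.rev_mask, x, 0.0)
            bwd = bwd + np.where(self.rev_mask, x, 0.0)
        f[0::2] = fwd
        f[1::2] = bwd
        return f

    def _boundaries(self, tracer) -> dict[EMUNode, np.ndarray]:
        key = None
        if tracer is not None:
            specs = sorted(tracer.items()) if isinstance(tracer, dict) else [(tracer.substrate, tracer)]
            key = tuple((n, tuple(s.mixture), s.purity) for n, s in specs)
        if key in self._boundary_cache:
            return self._boundary_cache[key]
        tracers = _resolve_tracers(self.emu.model, self.emu, tracer)
        table: dict[EMUNode, np.ndarray] = {}
        for level in self.levels:
            for _, _, _, sources in level["known"]:
                for kind, src in sources:
                    if kind == "boundary" and src not in table:
                        table[src] = _boundary_mid(src, tracers)
        self._boundary_cache[key] = table
        return table

    def run(self, v: np.ndarray, xch: np.ndarray, tracer=None
            ) -> dict[EMUNode, np.ndarray]:
        fl = self.flux_array(v, xch)
        boundaries = self._boundaries(tracer)
        scale = max(fl.max(initial=0.0), 1.0)
        tol = 1e-12 * scale
        solved: list[np.ndarray] = []
        for level in self.levels:
            m = len(level["nodes"])
            size = level["size"]
            A = np.zeros((m, m))
            totals = np.zeros(m)
            np.add.at(totals, level["diag_rows"],
                      fl[level["diag_f"]] * level["diag_w"])
            if len(level["off_rows"]):
                np.subtract.at(A, (level["off_rows"], level["off_cols"]),
                               fl[level["off_f"]] * level["off_w"])
            B = np.zeros((m, size + 1))
            for row, k, w, sources in level["known"]:
                f = fl[k] * w
                if f <= tol:
                    continue
                conv = None
                for kind, src in sources:
                    if kind == "internal":
                        sl, si = self.node_level[src]
                        smid = solved[sl][si]
                    elif kind == "boundary":
                        smid = boundaries[src]
                    else:
                        smid = unlabeled_mid(src.size)
                    conv = smid if conv is None else np.convolve(conv, smid)
                B[row] += f * conv
            dead = totals <= tol
            if dead.any():
                for i in np.flatnonzero(dead):
                    nd = level["nodes"][i]
                    for k, w in self.consumers.get(nd, ()):
                        if fl[k] * w > 1e-6 * scale:
                            raise DegenerateFluxError(
                                f"EMU {nd} has zero total influx but is "
                                "consumed downstream")
                    A[i, :] = 0.0
                    B[i] = unlabeled_mid(size)
                totals = np.where(dead, 1.0, totals)
            A[np.arange(m), np.arange(m)] += totals
            X = np.linalg.solve(A, B)
            np.clip(X, 0.0, None, out=X)
            sums = X.sum(axis=1)
            if np.any(sums <= 0):
                bad = level["nodes"][int(np.argmin(sums))]
                raise DegenerateFluxError(f"EMU {bad}: degenerate balance")
            X /= sums[:, None]
            solved.append(X)
        out = {}
        for t in self.targets:
            sl, si = self.node_level[t]
            out[t] = solved[sl][si]
        return out


def simulate(emu: EMUNetwork, fluxes: FluxVector, tracer=None,
             unlabeled_influxes=None, engine: SimulationEngine | None = None
             ) -> dict[str, MIDVector]:
    """Solve the EMU cascade; returns one MID per target.

    ``tracer`` is a TracerSpec (or dict of them) for the fed substrate(s);
    boundary metabolites without a tracer and all ``unlabeled_influx``
    reactions contribute unlabeled material.  ``unlabeled_influxes``
    optionally restricts which influx reactions may carry flux (others are
    checked to be zero).
    """
    model = emu.model
    if unlabeled_influxes is not None:
        allowed = set(unlabeled_influxes)
        for r in model.reactions:
            if r.kind == "unlabeled_influx" and r.id not in allowed:
                if abs(fluxes.values.get(r.id, 0.0)) > 1e-9:
                    raise GluconeofluxError(
                        f"influx {r.id} carries flux but is not enabled")
    engine = engine or SimulationEngine(emu)
    v = np.array([fluxes.values.get(r.id, 0.0) for r in model.reactions])
    xch = np.array([fluxes.exchange(rid) for rid in engine.rev_ids])
    raw = engine.run(v, xch, tracer)
    return {str(t): MIDVector(str(t), mid) for t, mid in raw.items()}


def simulate_metabolites(model: NetworkModel, fluxes: FluxVector, tracer,
                         metabolites) -> dict[str, MIDVector]:
    """Convenience wrapper: decompose + simulate full-molecule MIDs."""
    emu = decompose(model, metabolites)
    raw = simulate(emu, fluxes, tracer)
    counts = model.carbon_counts()
    out = {}
    for met in metabolites:
        node = EMUNode(met, tuple(range(1, counts[met] + 1)))
        out[met] = MIDVector(met, raw[str(node)].fractions)
    return out
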