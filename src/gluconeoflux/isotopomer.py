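"""Brute-force isotopomer simulation over all 2^n labeling states.

Independent cross-check for the EMU cascade: every metabolite pool is
represented by the full vector of its 2^c positional isotopomer
fractions, and the steady state is found by fixed-point iteration of the
flux-weighted mixing map

    x_M  <-  sum_j f_j * T_j(x_substrates) / sum_j f_j

where T_j maps joint substrate isotopomer states through the reaction's
atom transition (substrate pools assumed well mixed and independent).
Drains make the map a contraction on every path from the inputs, so the
iteration converges geometrically.  Exponential in carbon count - intended
for toy networks (<= ~14 total carbons), not production use.
"""

from __future__ import annotations

import numpy as np

from .errors import GluconeofluxError
from .emu import directional_fluxes
from .mid import MIDVector, TracerSpec
from .network import FluxVector, NetworkModel


def _tracer_isotopomers(spec: TracerSpec) -> np.ndarray:
    n = spec.n_carbons
    out = np.zeros(2 ** n)
    for pattern, frac in spec.mixture:
        enr = spec.position_enrichments(pattern)
        dist = np.array([1.0])
        for q in enr:  # position i -> bit i
            dist = np.concatenate([dist * (1 - q), dist * q])
        out += frac * dist
    return out


def _unlabeled_isotopomers(n: int) -> np.ndarray:
    out = np.zeros(2 ** n)
    out[0] = 1.0
    return out


def mid_from_isotopomers(dist: np.ndarray) -> np.ndarray:
    n = int(np.log2(len(dist)))
    weights = np.array([bin(s).count("1") for s in range(len(dist))])
    return np.bincount(weights, weights=dist, minlength=n + 1)


def simulate_isotopomers(model: NetworkModel, fluxes: FluxVector, tracer=None,
                         tol: float = 1e-13, max_iter: int = 200000
                         ) -> dict[str, MIDVector]:
    """Full isotopomer steady state; returns the MID of every balanced,
    atom-mapped metabolite."""
    counts = model.carbon_counts()
    balanced = sorted(m for m in model.balanced_metabolites if m in counts)
    dfl = directional_fluxes(model, fluxes)

    tracers: dict[str, TracerSpec] = {}
    if tracer is not None:
        specs = list(tracer.values()) if isinstance(tracer, dict) else [tracer]
        for spec in specs:
            name = spec.substrate
            if name in counts and name not in balanced:
                tracers[name] = spec
            else:
                for r in model.reactions:
                    if r.kind == "uptake" and name in r.products:
                        for t in r.atom_transitions:
                            for smet, _ in t.substrate_atoms:
                                tracers[smet] = spec

    # fixed boundary distributions
    boundary: dict[str, np.ndarray] = {}
    for met, c in counts.items():
        if met in balanced:
            continue
        if met in tracers:
            boundary[met] = _tracer_isotopomers(tracers[met])
        else:
            boundary[met] = _unlabeled_isotopomers(c)

    # precompute producing terms: (flux, substrate mets, product state map)
    terms: dict[str, list] = {m: [] for m in balanced}
    totals: dict[str, float] = {m: 0.0 for m in balanced}
    for r in model.reactions:
        if r.kind == "unlabeled_influx":
            met = next(iter(r.products))
            if met in terms:
                f = dfl[(r.id, +1)]
                terms[met].append((f, (), None, counts[met]))
                totals[met] += f
            continue
        trans = [(+1, t) for t in r.atom_transitions]
        if r.reversible:
            trans += [(-1, t.reversed()) for t in r.atom_transitions]
        n_alt = max(len(r.atom_transitions), 1)
        for direction, t in trans:
            f = dfl[(r.id, direction)] / n_alt
            subs = t.substrate_atoms
            sub_mets = tuple(m for m, _ in subs)
            sub_bits = [counts[m] for m in sub_mets]
            n_joint = int(np.prod([2 ** b for b in sub_bits])) if sub_bits else 1
            for pmet, plabels in t.product_atoms:
                if pmet not in terms:
                    continue
                # product carbon p comes from (substrate index, bit position)
                origin = []
                for letter in plabels:
                    for si, (_m, slabels) in enumerate(subs):
                        pos = slabels.find(letter)
                        if pos >= 0:
                            origin.append((si, pos))
                            break
                    else:
                        raise GluconeofluxError(
                            f"reaction {r.id}: unmapped carbon {letter!r}")
                # joint state -> product state lookup table
                state_map = np.zeros(n_joint, dtype=np.int64)
                # joint index = sum_i state_i * prod_{k<i} 2^bits_k
                strides = np.ones(len(sub_bits), dtype=np.int64)
                for i in range(1, len(sub_bits)):
                    strides[i] = strides[i - 1] * (2 ** sub_bits[i - 1])
                joint = np.arange(n_joint, dtype=np.int64)
                sub_states = [(joint // strides[i]) % (2 ** sub_bits[i])
                              for i in range(len(sub_bits))]
                for p, (si, pos) in enumerate(origin):
                    bit = (sub_states[si] >> pos) & 1
                    state_map |= bit << p
                terms[pmet].append((f, sub_mets, (state_map, strides, sub_bits),
                                    counts[pmet]))
                totals[pmet] += f

    x = {m: _unlabeled_isotopomers(counts[m]) for m in balanced}
    scale = max(max(totals.values(), default=1.0), 1.0)

    for _ in range(max_iter):
        delta = 0.0
        for met in balanced:
            if totals[met] <= 1e-12 * scale:
                continue
            acc = np.zeros(2 ** counts[met])
            for f, sub_mets, mapping, _c in terms[met]:
                if f <= 1e-14 * scale:
                    continue
                if mapping is None:  # unlabeled influx
                    acc[0] += f
                    continue
                state_map, strides, sub_bits = mapping
                # joint distribution with substrate 0 varying fastest, to
                # match the stride convention of state_map
                dist = np.array([1.0])
                for m in sub_mets:
                    d = x[m] if m in x else boundary[m]
                    dist = np.kron(d, dist)
                acc += np.bincount(state_map, weights=f * dist,
                                   minlength=2 ** counts[met])
            total = acc.sum()
            if total <= 0:
                continue
            # renormalize: the sum-1 manifold is neutrally/unstably invariant
            # under condensation cycles, so project back each sweep
            new = acc / total
            delta = max(delta, float(np.abs(new - x[met]).max()))
            x[met] = new
        if delta < tol:
            break
    else:
        raise GluconeofluxError("isotopomer fixed point did not converge")

    return {m: MIDVector(m, mid_from_isotopomers(x[m])) for m in balanced}
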