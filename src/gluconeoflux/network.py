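"""Atom-mapped metabolic network models.

A model is an ordered list of reactions, each carrying carbon atom
transitions (one letter per carbon), cofactor stoichiometry for the three
pools tracked in energy accounting (NADH/UQH2, NADPH, ATP) and a pathway
tag used for production attribution.  Models are stored in a line-oriented
TSV dialect with a JSON header line (``#! {...}``) so that files diff and
hand-edit cleanly::

    #! {"species": "...", "normalization": "uptake=100"}
    # id  equation  atom_map  reversible  kind  nadh_uqh2  nadph  atp  pathway
    SDH   1 SUC -> 1 FUM     SUC:abcd -> FUM:abcd; SUC:abcd -> FUM:dcba  0  internal  1  0  0  TCA

Alternative atom maps separated by ``;`` share the reaction flux equally;
this is how rotationally symmetric metabolites (succinate, fumarate) are
scrambled.  Balanced (intracellular, steady-state) metabolites are by
default every species that is both produced and consumed somewhere in the
model; the header may override with an explicit ``"balanced"`` list.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .errors import CarbonBalanceError, ModelParseError

COFACTOR_KEYS = ("nadh_uqh2", "nadph", "atp")
REACTION_KINDS = ("internal", "uptake", "secretion", "biomass_drain", "unlabeled_influx")


@dataclass(frozen=True)
class AtomTransition:
    """Carbon map for one reaction: per-molecule-instance ordered labels.

    ``substrate_atoms`` and ``product_atoms`` are lists of
    ``(metabolite_id, labels)`` pairs, one per molecule instance, with one
    letter per carbon (e.g. succinate ``"abcd"``).
    """

    substrate_atoms: tuple[tuple[str, str], ...]
    product_atoms: tuple[tuple[str, str], ...]

    def validate(self, reaction_id: str = "?") -> None:
        for side_name, side in (("substrate", self.substrate_atoms),
                                ("product", self.product_atoms)):
            letters = [c for _, labels in side for c in labels]
            if len(letters) != len(set(letters)):
                raise CarbonBalanceError(
                    f"reaction {reaction_id}: duplicate carbon label on {side_name} side")
        sub = sorted(c for _, labels in self.substrate_atoms for c in labels)
        prod = sorted(c for _, labels in self.product_atoms for c in labels)
        if sub != prod:
            raise CarbonBalanceError(
                f"reaction {reaction_id}: carbon imbalance "
                f"({len(sub)} substrate vs {len(prod)} product carbons, "
                f"labels {''.join(sub)!r} vs {''.join(prod)!r})")

    def reversed(self) -> "AtomTransition":
        return AtomTransition(self.product_atoms, self.substrate_atoms)


@dataclass
class Reaction:
    id: str
    reactants: dict[str, float]
    products: dict[str, float]
    reversible: bool = False
    atom_transitions: tuple[AtomTransition, ...] = ()
    cofactor_deltas: dict[str, float] = field(default_factory=dict)
    kind: str = "internal"
    pathway: str = ""

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ModelParseError(f"reaction {self.id}: unknown kind {self.kind!r}")
        for key in self.cofactor_deltas:
            if key not in COFACTOR_KEYS:
                raise ModelParseError(
                    f"reaction {self.id}: unknown cofactor key {key!r} "
                    f"(expected one of {COFACTOR_KEYS})")
        for side in (self.reactants, self.products):
            for met, coef in side.items():
                if coef <= 0:
                    raise ModelParseError(
                        f"reaction {self.id}: non-positive stoichiometry for {met}")
        if self.kind == "unlabeled_influx" and (self.reactants or len(self.products) != 1):
            raise ModelParseError(
                f"reaction {self.id}: unlabeled_influx must have exactly one "
                "product and no reactants")
        for t in self.atom_transitions:
            t.validate(self.id)

    @property
    def has_atom_map(self) -> bool:
        return len(self.atom_transitions) > 0


@dataclass
class NetworkModel:
    """Ordered reaction set plus the balanced-metabolite convention."""

    reactions: list[Reaction]
    species_tag: str = ""
    metadata: dict = field(default_factory=dict)
    _balanced_override: set[str] | None = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ModelParseError(f"duplicate reaction ids: {sorted(dup)}")

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def balanced_metabolites(self) -> set[str]:
        if self._balanced_override is not None:
            return set(self._balanced_override)
        produced = {m for r in self.reactions for m in r.products}
        consumed = {m for r in self.reactions for m in r.reactants}
        return produced & consumed

    @property
    def metabolites(self) -> set[str]:
        return ({m for r in self.reactions for m in r.reactants}
                | {m for r in self.reactions for m in r.products})

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Signed S over balanced metabolites; returns (S, metabolite order)."""
        mets = sorted(self.balanced_metabolites)
        idx = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, c in r.reactants.items():
                if m in idx:
                    S[idx[m], j] -= c
            for m, c in r.products.items():
                if m in idx:
                    S[idx[m], j] += c
        return S, mets

    def carbon_counts(self) -> dict[str, int]:
        """Carbon number per metabolite, inferred from atom maps."""
        counts: dict[str, int] = {}
        for r in self.reactions:
            for t in r.atom_transitions:
                for met, labels in t.substrate_atoms + t.product_atoms:
                    n = len(labels)
                    if counts.setdefault(met, n) != n:
                        raise CarbonBalanceError(
                            f"inconsistent carbon count for {met}: "
                            f"{counts[met]} vs {n} (reaction {r.id})")
        return counts

    def producing_reactions(self, met: str) -> list[Reaction]:
        return [r for r in self.reactions
                if met in r.products or (r.reversible and met in r.reactants)]


@dataclass
class FluxVector:
    """Net fluxes per reaction plus nonnegative exchange fluxes.

    ``units`` is ``"percent"`` (uptake normalized to 100) or ``"absolute"``
    (mmol gCDW^-1 h^-1); the cofactor ledger refuses normalized input.
    """

    values: dict[str, float]
    exchange_values: dict[str, float] = field(default_factory=dict)
    units: str = "percent"

    def as_array(self, model: NetworkModel) -> np.ndarray:
        return np.array([self.values.get(r.id, 0.0) for r in model.reactions])

    def to_absolute(self, q_uptake: float) -> "FluxVector":
        """Rescale normalized fluxes by the measured specific uptake rate."""
        if self.units == "absolute":
            return self
        f = q_uptake / 100.0
        return FluxVector({k: v * f for k, v in self.values.items()},
                          {k: v * f for k, v in self.exchange_values.items()},
                          units="absolute")

    def exchange(self, rid: str) -> float:
        return self.exchange_values.get(rid, 0.0)


@dataclass
class FreeFluxBasis:
    """Null-space parameterization of S v = 0.

    ``complete(free_values)`` returns the full net flux vector (reaction
    order of the model); the free coordinates are actual reaction fluxes
    (the non-pivot columns of S under column-pivoted QR).
    """

    model: NetworkModel
    free_reaction_ids: list[str]
    _completion: np.ndarray  # (n_reactions, n_free)

    @property
    def dim(self) -> int:
        return len(self.free_reaction_ids)

    def complete(self, free_values) -> np.ndarray:
        u = np.asarray(free_values, dtype=float)
        if u.shape != (self.dim,):
            raise ValueError(f"expected {self.dim} free fluxes, got {u.shape}")
        return self._completion @ u

    def complete_to_flux_vector(self, free_values, exchange=None) -> FluxVector:
        v = self.complete(free_values)
        return FluxVector(dict(zip(self.model.reaction_ids, v)),
                          dict(exchange or {}))


# ---------------------------------------------------------------------------
# validation

@dataclass
class Finding:
    category: str  # carbon_imbalance | orphan_metabolite | dead_end
    subject: str
    message: str


@dataclass
class DiagnosticsReport:
    findings: list[Finding]

    @property
    def ok(self) -> bool:
        return not self.findings

    def by_category(self, category: str) -> list[Finding]:
        return [f for f in self.findings if f.category == category]

    def __str__(self) -> str:
        if self.ok:
            return "model OK: no findings"
        return "\n".join(f"[{f.category}] {f.subject}: {f.message}"
                         for f in self.findings)


def validate_model(model: NetworkModel) -> DiagnosticsReport:
    """Diagnostics (not exceptions): carbon imbalance, orphans, dead ends."""
    findings: list[Finding] = []
    for r in model.reactions:
        for t in r.atom_transitions:
            try:
                t.validate(r.id)
            except CarbonBalanceError as exc:
                findings.append(Finding("carbon_imbalance", r.id, str(exc)))
                break
    produced = {m for r in model.reactions for m in r.products}
    consumed = {m for r in model.reactions for m in r.reactants}
    for met in sorted(model.balanced_metabolites):
        prod = met in produced or any(r.reversible and met in r.reactants
                                      for r in model.reactions)
        cons = met in consumed or any(r.reversible and met in r.products
                                      for r in model.reactions)
        if not (prod and cons):
            which = "never consumed" if prod else "never produced"
            findings.append(Finding("dead_end", met,
                                    f"balanced metabolite {which}"))
    # orphan: balanced metabolite that appears in exactly one reaction
    appearance: dict[str, int] = {}
    for r in model.reactions:
        for m in set(r.reactants) | set(r.products):
            appearance[m] = appearance.get(m, 0) + 1
    for met, n in sorted(appearance.items()):
        if n == 1 and met in model.balanced_metabolites:
            findings.append(Finding("orphan_metabolite", met,
                                    "balanced metabolite used by a single reaction"))
    return DiagnosticsReport(findings)


# ---------------------------------------------------------------------------
# free-flux parameterization

def parameterize(model: NetworkModel, rank_tol: float = 1e-9) -> FreeFluxBasis:
    """Null-space basis of S with actual reactions as free coordinates.

    The dimension equals ``n_reactions - rank(S)``; completing any free
    assignment satisfies S v = 0 to floating tolerance.
    """
    S, _ = model.stoichiometric_matrix()
    n = len(model.reactions)
    if S.size == 0:
        comp = np.eye(n)
        return FreeFluxBasis(model, model.reaction_ids, comp)
    _, R, piv = scipy.linalg.qr(S, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    thresh = rank_tol * max(diag.max(), 1.0)
    rank = int((diag > thresh).sum())
    dep = sorted(piv[:rank])
    free = sorted(piv[rank:])
    # v_dep solves S_dep v_dep = -S_free v_free (consistent by construction)
    M = np.linalg.lstsq(S[:, dep], -S[:, free], rcond=None)[0] if dep else \
        np.zeros((0, len(free)))
    comp = np.zeros((n, len(free)))
    for k, j in enumerate(free):
        comp[j, k] = 1.0
    for k, j in enumerate(dep):
        comp[j, :] = M[k, :]
    resid = np.abs(S @ comp).max() if len(free) else 0.0
    if resid > 1e-8:
        raise np.linalg.LinAlgError(
            f"free-flux completion inconsistent (residual {resid:.2e})")
    return FreeFluxBasis(model, [model.reactions[j].id for j in free], comp)


# ---------------------------------------------------------------------------
# model dialect I/O

_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S+)\s*$")


def _parse_side(text: str, rid: str, line: int) -> dict[str, float]:
    out: dict[str, float] = {}
    text = text.strip()
    if not text or text == "-":
        return out
    for term in text.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise ModelParseError(f"reaction {rid}: bad equation term {term!r}", line)
        coef = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        out[met] = out.get(met, 0.0) + coef
    return out


def _parse_equation(text: str, rid: str, line: int):
    if "->" not in text:
        raise ModelParseError(f"reaction {rid}: equation missing '->'", line)
    left, right = text.split("->", 1)
    return _parse_side(left, rid, line), _parse_side(right, rid, line)


def _parse_atom_side(text: str, rid: str, line: int) -> tuple[tuple[str, str], ...]:
    text = text.strip()
    if not text or text == "-":
        return ()
    out = []
    for term in text.split("+"):
        term = term.strip()
        if ":" not in term:
            raise ModelParseError(
                f"reaction {rid}: atom-map term {term!r} missing ':'", line)
        met, labels = term.split(":", 1)
        out.append((met.strip(), labels.strip()))
    return tuple(out)


def _parse_atom_map(text: str, rid: str, line: int) -> tuple[AtomTransition, ...]:
    text = text.strip()
    if not text or text == "-":
        return ()
    alts = []
    for alt in text.split(";"):
        if "->" not in alt:
            raise ModelParseError(f"reaction {rid}: atom map missing '->'", line)
        left, right = alt.split("->", 1)
        alts.append(AtomTransition(_parse_atom_side(left, rid, line),
                                   _parse_atom_side(right, rid, line)))
    return tuple(alts)


def load_model(path) -> NetworkModel:
    """Load a model file, validating carbon balance reaction by reaction."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ModelParseError(f"empty model file: {path}")
    metadata: dict = {}
    reactions: list[Reaction] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#!"):
            try:
                metadata.update(json.loads(line[2:].strip()))
            except json.JSONDecodeError as exc:
                raise ModelParseError(f"bad JSON header: {exc}", lineno) from exc
            continue
        if line.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 5:
            raise ModelParseError(
                f"expected >=5 tab-separated fields, got {len(fields)}", lineno)
        rid = fields[0].strip()
        reactants, products = _parse_equation(fields[1], rid, lineno)
        atom_transitions = _parse_atom_map(fields[2], rid, lineno)
        reversible = fields[3].strip() in ("1", "true", "True", "R", "reversible")
        kind = fields[4].strip() or "internal"
        cof = {}
        for key, pos in zip(COFACTOR_KEYS, (5, 6, 7)):
            if len(fields) > pos and fields[pos].strip():
                try:
                    val = float(fields[pos])
                except ValueError as exc:
                    raise ModelParseError(
                        f"reaction {rid}: bad {key} value {fields[pos]!r}",
                        lineno) from exc
                if val != 0.0:
                    cof[key] = val
        pathway = fields[8].strip() if len(fields) > 8 else ""
        try:
            reactions.append(Reaction(rid, reactants, products, reversible,
                                      atom_transitions, cof, kind, pathway))
        except (CarbonBalanceError, ModelParseError) as exc:
            if isinstance(exc, CarbonBalanceError):
                raise CarbonBalanceError(f"line {lineno}: {exc}") from exc
            raise
    if not reactions:
        raise ModelParseError(f"model file has no reactions: {path}")
    balanced = set(metadata["balanced"]) if "balanced" in metadata else None
    return NetworkModel(reactions, species_tag=metadata.get("species", ""),
                        metadata=metadata, _balanced_override=balanced)


def write_model(model: NetworkModel, path) -> None:
    """Write a model back out in the TSV dialect (round-trips load_model)."""
    path = Path(path)
    lines = []
    meta = dict(model.metadata)
    if model.species_tag:
        meta.setdefault("species", model.species_tag)
    if model._balanced_override is not None:
        meta["balanced"] = sorted(model._balanced_override)
    if meta:
        lines.append("#! " + json.dumps(meta, sort_keys=True))
    lines.append("# id\tequation\tatom_map\treversible\tkind\t"
                 "nadh_uqh2\tnadph\tatp\tpathway")
    for r in model.reactions:
        def side(d):
            return " + ".join(f"{c:g} {m}" for m, c in d.items()) or "-"
        eq = f"{side(r.reactants)} -> {side(r.products)}"
        if r.atom_transitions:
            parts: list[str] = []
            for t in r.atom_transitions:
                left = " + ".join(f"{m}:{lab}" for m, lab in t.substrate_atoms) or "-"
                right = " + ".join(f"{m}:{lab}" for m, lab in t.product_atoms) or "-"
                parts.append(f"{left} -> {right}")
            amap = "; ".join(parts)
        else:
            amap = "-"
        cof = [f"{r.cofactor_deltas.get(k, 0):g}" for k in COFACTOR_KEYS]
        lines.append("\t".join([r.id, eq, amap, "1" if r.reversible else "0",
                                r.kind, *cof, r.pathway]))
    path.write_text("\n".join(lines) + "\n")
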