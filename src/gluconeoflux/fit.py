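"""Flux estimation from parallel-tracer MID data.

The estimator minimizes the variance-weighted sum of squared residuals
between simulated and measured mass-isotopomer fractions (all tracers and
replicates jointly) plus measured rates (secretion rates, biosynthetic
effluxes), over a null-space parameterization of the steady-state flux
cone.  Optimization restarts from random feasible points (default 100) to
approach the global optimum; a fit is statistically acceptable when the
minimized SSR is below the chi-square cutoff at the 95% confidence level
for the residual degrees of freedom.  Confidence bounds are profiled:
each flux is constrained, the others re-optimized, and the 95% bound is
where the SSR exceeds the optimum by chi2(1, 0.95) = 3.84.

Exchange fluxes of reversible reactions are optimized on the bounded
transform t = x / (1 + x) in [0, 0.9999].  Infeasible completions (sign
violations of irreversible fluxes) are discouraged by a finite smooth
penalty instead of an exception so that every start can recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.optimize import least_squares, linprog
from scipy.stats import chi2

from .emu import EMUNode, SimulationEngine, decompose, simulate
from .errors import DegenerateFluxError, FitError, GluconeofluxError, InfeasibleError
from .mid import TracerSpec
from .network import FluxVector, NetworkModel

MID_SD_FLOOR = 0.005     # absolute SD floor on mass-isotopomer fractions
PENALTY_WEIGHT = 1.0e3   # weight of constraint-violation residuals
SIM_FAILURE_RESIDUAL = 1.0e3
EXCHANGE_T_MAX = 0.9999


@dataclass
class MIDMeasurement:
    tracer_id: str
    replicate: int
    fragment: str                 # metabolite id (full carbon backbone)
    fractions: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.fractions.shape != self.sd.shape:
            raise ValueError(f"{self.fragment}: fractions/sd shape mismatch")


@dataclass
class RateMeasurement:
    quantity_id: str              # reaction id
    value: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"{self.quantity_id}: rate SD must be > 0")


@dataclass
class MeasurementSet:
    mids: list[MIDMeasurement]
    rates: list[RateMeasurement] = field(default_factory=list)

    def with_sd_floor(self, floor: float = MID_SD_FLOOR) -> "MeasurementSet":
        mids = [MIDMeasurement(m.tracer_id, m.replicate, m.fragment,
                               m.fractions, np.maximum(m.sd, floor))
                for m in self.mids]
        return MeasurementSet(mids, list(self.rates))

    def with_inflated_rate_sds(self, factor: float = 2.0,
                               quantity_ids=None) -> "MeasurementSet":
        """Imprecision option: widen selected rate SDs (e.g. biosynthetic
        effluxes by two standard deviations -> factor 2)."""
        ids = set(quantity_ids) if quantity_ids is not None else None
        rates = [RateMeasurement(r.quantity_id, r.value,
                                 r.sd * factor if ids is None or r.quantity_id in ids
                                 else r.sd)
                 for r in self.rates]
        return MeasurementSet(list(self.mids), rates)

    @property
    def tracer_ids(self) -> list[str]:
        return sorted({m.tracer_id for m in self.mids})

    @property
    def fragments(self) -> list[str]:
        return sorted({m.fragment for m in self.mids})

    @property
    def n_residuals(self) -> int:
        """Number of fitted measurements: every MID entry plus every rate.

        MID vectors sum to one, so their entries are not strictly
        independent; counting them all follows common MFA software
        practice and matches the effective dimension of renormalized
        truncated-Gaussian measurement noise.
        """
        return sum(len(m.fractions) for m in self.mids) + len(self.rates)


@dataclass
class FluxEstimate:
    reaction_id: str
    value: float
    lb95: float
    ub95: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.lb95 - 1e-9 <= self.value <= self.ub95 + 1e-9):
            raise ValueError(
                f"{self.reaction_id}: point {self.value} outside "
                f"[{self.lb95}, {self.ub95}]")

    @property
    def width(self) -> float:
        return self.ub95 - self.lb95

    @property
    def sd(self) -> float:
        """SD derived from the 95% bounds: (UB95 - LB95) / (2 * 1.96)."""
        return self.width / (2 * 1.959963984540054)


def precision_score(ci_unwashed: FluxEstimate, ci_washed: FluxEstimate) -> float:
    """Squared ratio of 95% CI widths; > 1 means the washed condition is
    more precise."""
    if ci_washed.width == 0:
        return math.inf
    return (ci_unwashed.width / ci_washed.width) ** 2


# ---------------------------------------------------------------------------

class FitProblem:
    """Caches the EMU decomposition and the flux-space parameterization."""

    def __init__(self, model: NetworkModel, measurements: MeasurementSet,
                 tracers: dict[str, TracerSpec], *,
                 uptake_reaction: str | None = None, uptake_value: float = 100.0,
                 enabled_influxes=(), fixed_fluxes: dict[str, float] | None = None,
                 sd_floor: float = MID_SD_FLOOR):
        self.model = model
        self.measurements = measurements.with_sd_floor(sd_floor)
        self.tracers = dict(tracers)
        self.rids = model.reaction_ids
        self.ridx = {r: i for i, r in enumerate(self.rids)}
        n = len(self.rids)

        if uptake_reaction is None:
            ups = [r.id for r in model.reactions if r.kind == "uptake"]
            if len(ups) != 1:
                raise GluconeofluxError("specify uptake_reaction explicitly")
            uptake_reaction = ups[0]
        self.uptake_reaction = uptake_reaction
        self.uptake_value = float(uptake_value)

        enabled = set(enabled_influxes)
        fixed: dict[str, float] = {uptake_reaction: self.uptake_value}
        for r in model.reactions:
            if r.kind == "unlabeled_influx" and r.id not in enabled:
                fixed[r.id] = 0.0
        fixed.update(fixed_fluxes or {})
        self.fixed_fluxes = fixed
        self.enabled_influxes = enabled

        S, _ = model.stoichiometric_matrix()
        rows = [S] if S.size else []
        b = [np.zeros(S.shape[0])] if S.size else []
        for rid, val in sorted(fixed.items()):
            e = np.zeros(n)
            e[self.ridx[rid]] = 1.0
            rows.append(e[None, :])
            b.append([val])
        A = np.vstack(rows)
        bv = np.concatenate([np.atleast_1d(x) for x in b])
        v0, *_ = np.linalg.lstsq(A, bv, rcond=None)
        if np.abs(A @ v0 - bv).max() > 1e-6 * max(self.uptake_value, 1.0):
            raise InfeasibleError(
                "no flux vector satisfies the stoichiometric and fixed-flux "
                "constraints")
        self.v0 = v0
        self.N = scipy.linalg.null_space(A)
        self.k = self.N.shape[1]

        # inequality constraints G v >= h (sign constraints and influx caps)
        G_rows, h_vals, labels = [], [], []
        for r in model.reactions:
            i = self.ridx[r.id]
            if r.id in fixed:
                continue
            if not r.reversible:
                e = np.zeros(n)
                e[i] = 1.0
                G_rows.append(e)
                h_vals.append(0.0)
                labels.append((r.id, "lb"))
            if r.kind == "unlabeled_influx":
                e = np.zeros(n)
                e[i] = -1.0
                G_rows.append(e)
                h_vals.append(-self.uptake_value)
                labels.append((r.id, "ub"))
        self.G = np.array(G_rows) if G_rows else np.zeros((0, n))
        self.h = np.array(h_vals)
        self.constraint_labels = labels

        self.xch_rids = [r.id for r in model.reactions if r.reversible]
        self.n_params = self.k + len(self.xch_rids)

        self.emu = decompose(model, self.measurements.fragments)
        self.engine = SimulationEngine(self.emu)
        counts = model.carbon_counts()
        self._frag_node = {f: EMUNode(f, tuple(range(1, counts[f] + 1)))
                           for f in self.measurements.fragments}
        self._by_tracer: dict[str, list[MIDMeasurement]] = {}
        for m in self.measurements.mids:
            self._by_tracer.setdefault(m.tracer_id, []).append(m)
        for tid in self._by_tracer:
            if tid not in self.tracers:
                raise GluconeofluxError(f"no TracerSpec for tracer id {tid!r}")
        self._n_mid_entries = sum(len(m.fractions) for m in self.measurements.mids)
        # flat measurement arrays per tracer for fast residuals
        self._tracer_blocks = []
        pos = 0
        for tid in sorted(self._by_tracer):
            nodes, meas, sds = [], [], []
            for m in self._by_tracer[tid]:
                nodes.append(self._frag_node[m.fragment])
                meas.append(m.fractions)
                sds.append(m.sd)
            block_len = sum(len(x) for x in meas)
            self._tracer_blocks.append(
                (tid, nodes, np.concatenate(meas), np.concatenate(sds),
                 slice(pos, pos + block_len)))
            pos += block_len

    # -- parameter packing ---------------------------------------------------

    def flux_vector(self, params: np.ndarray) -> FluxVector:
        u = params[:self.k]
        t = params[self.k:]
        v = self.v0 + (self.N @ u if self.k else 0.0)
        xch = {rid: float(ti / (1.0 - ti))
               for rid, ti in zip(self.xch_rids, t)}
        return FluxVector(dict(zip(self.rids, v)), xch)

    def _violations(self, v: np.ndarray) -> np.ndarray:
        if self.G.shape[0] == 0:
            return np.zeros(0)
        return np.minimum(self.G @ v - self.h, 0.0)

    def residuals(self, params: np.ndarray) -> np.ndarray:
        u = params[:self.k]
        t = params[self.k:]
        v = self.v0 + (self.N @ u if self.k else 0.0)
        xch = t / (1.0 - t) if len(t) else t
        pen = PENALTY_WEIGHT * self._violations(v)
        mid_res = np.empty(self._n_mid_entries)
        try:
            for tid, nodes, meas, sds, block in self._tracer_blocks:
                raw = self.engine.run(v, xch, self.tracers[tid])
                sim = np.concatenate([raw[nd] for nd in nodes])
                mid_res[block] = (sim - meas) / sds
        except (DegenerateFluxError, np.linalg.LinAlgError):
            mid_res[:] = SIM_FAILURE_RESIDUAL
        rate_res = np.array([(v[self.ridx[r.quantity_id]] - r.value) / r.sd
                             for r in self.measurements.rates])
        return np.concatenate([mid_res, rate_res, pen])

    def ssr(self, params: np.ndarray) -> float:
        res = self.residuals(params)
        data = res[:self._n_mid_entries + len(self.measurements.rates)]
        return float(data @ data)

    # -- feasible sampling ---------------------------------------------------

    def _u_constraints(self):
        Gu = self.G @ self.N if self.k else np.zeros((self.G.shape[0], 0))
        hu = self.h - self.G @ self.v0
        return Gu, hu

    def interior_point(self) -> np.ndarray:
        if self.k == 0:
            return np.zeros(0)
        Gu, hu = self._u_constraints()
        norms = np.maximum(np.linalg.norm(Gu, axis=1), 1e-12)
        # max s subject to Gu u - s*norm >= hu
        A_ub = np.hstack([-Gu, norms[:, None]])
        b_ub = -hu
        c = np.zeros(self.k + 1)
        c[-1] = -1.0
        bounds = [(None, None)] * self.k + [(None, 0.25 * self.uptake_value)]
        sol = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
        if not sol.success or sol.x[-1] <= 1e-9:
            raise InfeasibleError("flux cone has empty interior under the "
                                  "stated constraints")
        return sol.x[:-1]

    def sample_feasible(self, rng: np.random.Generator, n_samples: int,
                        n_steps: int | None = None) -> list[np.ndarray]:
        """Hit-and-run samples of the free-flux polytope interior."""
        if self.k == 0:
            return [np.zeros(0) for _ in range(n_samples)]
        Gu, hu = self._u_constraints()
        u = self.interior_point()
        steps = n_steps or max(10 * self.k, 50)
        out = []
        total = n_samples * steps
        done = 0
        while len(out) < n_samples:
            for _ in range(steps):
                d = rng.standard_normal(self.k)
                d /= np.linalg.norm(d)
                Gd = Gu @ d
                slack = Gu @ u - hu
                lo, hi = -np.inf, np.inf
                with np.errstate(divide="ignore", invalid="ignore"):
                    tmax = np.where(Gd < -1e-12, slack / -Gd, np.inf)
                    tmin = np.where(Gd > 1e-12, -slack / Gd, -np.inf)
                hi = min(np.min(tmax), 2 * self.uptake_value)
                lo = max(np.max(tmin), -2 * self.uptake_value)
                if hi <= lo:
                    continue
                u = u + (lo + (hi - lo) * rng.uniform(0.05, 0.95)) * d
                done += 1
            out.append(u.copy())
            if done > 100 * total:
                raise InfeasibleError("feasible sampling stalled")
        return out


def objective(problem: FitProblem, params: np.ndarray) -> float:
    """Variance-weighted SSR at the given parameter point (data terms only)."""
    return problem.ssr(params)


def weighted_ssr(sim_by_fragment, measurements: MeasurementSet) -> float:
    """SSR between precomputed simulated MIDs and a measurement set.

    ``sim_by_fragment`` maps (tracer_id, fragment) or fragment -> MIDVector.
    """
    total = 0.0
    for m in measurements.mids:
        key = (m.tracer_id, m.fragment)
        sim = sim_by_fragment.get(key) or sim_by_fragment.get(m.fragment)
        if sim is None:
            raise KeyError(f"no simulation for {key}")
        total += float(np.sum(((sim.fractions - m.fractions) / m.sd) ** 2))
    return total


@dataclass
class FitResult:
    best_fluxes: FluxVector
    ssr: float
    dof: int
    chi2_cutoff_95: float
    accepted: bool
    per_start_ssr: list[float]
    seed: int
    best_params: np.ndarray
    problem: FitProblem

    def estimate(self, rid: str) -> float:
        return self.best_fluxes.values[rid]


def fit(model: NetworkModel, measurements: MeasurementSet,
        tracers: dict[str, TracerSpec], n_starts: int = 100, seed: int = 0,
        *, uptake_reaction: str | None = None, uptake_value: float = 100.0,
        enabled_influxes=(), fixed_fluxes: dict[str, float] | None = None,
        sd_floor: float = MID_SD_FLOOR,
        problem: FitProblem | None = None) -> FitResult:
    """Multi-start variance-weighted least squares flux estimation."""
    if problem is None:
        problem = FitProblem(model, measurements, tracers,
                             uptake_reaction=uptake_reaction,
                             uptake_value=uptake_value,
                             enabled_influxes=enabled_influxes,
                             fixed_fluxes=fixed_fluxes,
                             sd_floor=sd_floor)
    rng = np.random.default_rng(seed)
    starts_u = problem.sample_feasible(rng, n_starts)
    nx = len(problem.xch_rids)
    lb = np.concatenate([np.full(problem.k, -50.0 * problem.uptake_value),
                         np.zeros(nx)])
    ub = np.concatenate([np.full(problem.k, 50.0 * problem.uptake_value),
                         np.full(nx, EXCHANGE_T_MAX)])
    best = None
    per_start = []
    for i, u0 in enumerate(starts_u):
        t0 = rng.uniform(0.0, 0.7, size=nx)
        x0 = np.clip(np.concatenate([u0, t0]), lb, ub)
        try:
            sol = least_squares(problem.residuals, x0, bounds=(lb, ub),
                                method="trf", xtol=1e-9, ftol=1e-9,
                                gtol=1e-9, max_nfev=60 * (problem.n_params + 1))
        except Exception:
            per_start.append(math.inf)
            continue
        ssr = problem.ssr(sol.x)
        per_start.append(ssr)
        if best is None or ssr < best[0] - 1e-12:
            best = (ssr, sol.x.copy(), i)
    if best is None:
        raise FitError("all optimization starts failed")
    # polish the winning start with tight tolerances
    sol = least_squares(problem.residuals, best[1], bounds=(lb, ub),
                        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                        max_nfev=600 * (problem.n_params + 1))
    ssr = min(problem.ssr(sol.x), best[0])
    params = sol.x if problem.ssr(sol.x) <= best[0] else best[1]
    dof = max(problem.measurements.n_residuals - problem.n_params, 1)
    cutoff = float(chi2.ppf(0.95, dof))
    return FitResult(problem.flux_vector(params), ssr, dof, cutoff,
                     ssr <= cutoff, per_start, seed, params, problem)


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals

def _profile_ssr(problem: FitProblem, rid: str, value: float,
                 warm: np.ndarray) -> tuple[float, np.ndarray]:
    """Minimize SSR with reaction ``rid`` constrained to ``value``."""
    i = problem.ridx[rid]
    a = problem.N[i, :] if problem.k else np.zeros(0)
    a0 = problem.v0[i]
    if problem.k == 0 or np.abs(a).max() < 1e-12:
        return (problem.ssr(warm) if abs(a0 - value) < 1e-9 else math.inf, warm)
    j = int(np.argmax(np.abs(a)))
    others = [q for q in range(problem.k) if q != j]

    def expand(reduced: np.ndarray) -> np.ndarray:
        u = np.empty(problem.k)
        u[others] = reduced[:len(others)]
        u[j] = (value - a0 - a[others] @ reduced[:len(others)]) / a[j]
        return np.concatenate([u, reduced[len(others):]])

    def reduced_residuals(reduced: np.ndarray) -> np.ndarray:
        return problem.residuals(expand(reduced))

    nx = len(problem.xch_rids)
    warm_u, warm_t = warm[:problem.k], warm[problem.k:]
    red0 = np.concatenate([warm_u[others], warm_t])
    lb = np.concatenate([np.full(len(others), -np.inf), np.zeros(nx)])
    ub = np.concatenate([np.full(len(others), np.inf),
                         np.full(nx, EXCHANGE_T_MAX)])
    red0 = np.clip(red0, lb, ub)
    sol = least_squares(reduced_residuals, red0, bounds=(lb, ub), method="trf",
                        xtol=1e-8, ftol=1e-8, gtol=1e-8,
                        max_nfev=60 * (len(red0) + 1))
    return problem.ssr(expand(sol.x)), expand(sol.x)


def confidence_interval(fit_result: FitResult, rid: str, alpha: float = 0.05,
                        bisect_tol: float = 1e-4, box_limit: float | None = None
                        ) -> FluxEstimate:
    """Profile-likelihood CI: bound where SSR crosses best + chi2(1, 1-alpha)."""
    problem = fit_result.problem
    point = fit_result.best_fluxes.values[rid]
    threshold = fit_result.ssr + float(chi2.ppf(1 - alpha, 1))
    if box_limit is None:
        box_limit = 3.0 * problem.uptake_value
    i = problem.ridx[rid]
    a = problem.N[i, :] if problem.k else np.zeros(0)
    if problem.k == 0 or np.abs(a).max() < 1e-12:
        return FluxEstimate(rid, point, point, point, flags=("determined",))

    flags: list[str] = []
    bounds = {}
    hard_lb = 0.0 if not problem.model.reaction(rid).reversible else -box_limit
    for side, direction, hard in (("ub", +1.0, box_limit), ("lb", -1.0, hard_lb)):
        step = max(0.05 * max(abs(point), 1.0), 0.5)
        inner = point
        warm = fit_result.best_params.copy()
        outer = None
        for _ in range(60):
            cand = inner + direction * step
            if direction > 0 and cand >= hard:
                cand = hard
            if direction < 0 and cand <= hard:
                cand = hard
            ssr, warm = _profile_ssr(problem, rid, cand, warm)
            if ssr > threshold:
                outer = cand
                break
            inner = cand
            step *= 2.0
            if cand == hard:
                break
        if outer is None:
            bounds[side] = hard
            flags.append(f"{side}_at_box_limit")
            continue
        lo, hi = (inner, outer) if direction > 0 else (outer, inner)
        # bisect on the crossing
        for _ in range(100):
            if hi - lo <= bisect_tol:
                break
            mid = 0.5 * (lo + hi)
            ssr, warm = _profile_ssr(problem, rid, mid, warm)
            above = ssr > threshold
            if direction > 0:
                lo, hi = (lo, mid) if above else (mid, hi)
            else:
                lo, hi = (mid, hi) if above else (lo, mid)
        bounds[side] = 0.5 * (lo + hi)
    lb95 = min(bounds["lb"], point)
    ub95 = max(bounds["ub"], point)
    return FluxEstimate(rid, point, lb95, ub95, flags=tuple(flags))


# ---------------------------------------------------------------------------

def gate_unlabeled_influx(corrected_mids, model: NetworkModel | None = None,
                          threshold: float = 0.01):
    """Enable carry-over influxes where the unlabeled fraction exceeds 1%.

    ``corrected_mids`` is a list of MIDMeasurement (or (metabolite, m0)
    pairs) from a fully-labeled tracer experiment after natural-abundance
    correction.  The mean M+0 over replicates is compared strictly against
    ``threshold``; if a model is given, the matching ``unlabeled_influx``
    reaction ids are returned, otherwise the metabolite ids.
    """
    m0: dict[str, list[float]] = {}
    for item in corrected_mids:
        if isinstance(item, MIDMeasurement):
            m0.setdefault(item.fragment, []).append(float(item.fractions[0]))
        else:
            met, val = item
            m0.setdefault(met, []).append(float(val))
    flagged = {met for met, vals in m0.items()
               if float(np.mean(vals)) > threshold}
    if model is None:
        return flagged
    out = set()
    for r in model.reactions:
        if r.kind == "unlabeled_influx" and next(iter(r.products)) in flagged:
            out.add(r.id)
    return out
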