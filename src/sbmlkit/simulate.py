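"""Deterministic (ODE) and exact stochastic (SSA) simulation.

The ODE right-hand side of each state species is the stoichiometry-weighted
sum of its compiled reaction rates; rate-rule targets integrate their rule
expression directly.  Events are handled as numeric residuals: between
accepted integrator steps each residual is monitored for a sign change in
either direction, the crossing is refined by bisection on the dense output,
the event assignments are applied (simultaneous read, sequential write, in
document order) and integration restarts from the post-event state.  Scalar
algebraic rules are enforced by a root solve for their solved variable at
every right-hand-side evaluation.

The stochastic path implements Gillespie's direct method.  Propensities are
evaluated on raw species amounts (no compartment-volume division): models
that need concentration-based propensities must either set
``hasOnlySubstanceUnits`` or use constant unit volumes.

Rate laws, rules and residuals are compiled once to Python bytecode, so the
integrator and SSA inner loops never walk expression trees.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root_scalar

from .errors import (
    IntegrationError, ModelError, ResolutionError, RunawayEventError,
    UnsupportedFeatureError,
)
from .expressions import (
    Apply, MathNode, Number, TIME_ID, free_symbols, substitute, to_code,
    compile_function,
)
from .network import CompiledEvent, ReactionNetwork


@dataclass
class ODESystem:
    state_order: list[str]
    rhs: dict[str, MathNode]
    observed: dict[str, MathNode]
    observed_order: list[str]
    residual_events: list[CompiledEvent]
    algebraic: list[tuple[MathNode, str]]
    initial_state: np.ndarray
    constants: dict[str, float]
    algebraic_initial: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


@dataclass
class Trajectory:
    times: np.ndarray            # strictly increasing
    states: np.ndarray           # (len(times), n_states)
    state_order: list[str]
    observed: np.ndarray         # (len(times), n_observed)
    observed_order: list[str]
    event_log: list[tuple[float, str]] = field(default_factory=list)

    def state(self, sid: str) -> np.ndarray:
        try:
            return self.states[:, self.state_order.index(sid)]
        except ValueError:
            return self.observed[:, self.observed_order.index(sid)]

    def to_csv(self, fileobj=None) -> str | None:
        header = ["time"] + self.state_order + self.observed_order
        cols = [self.times]
        cols += [self.states[:, i] for i in range(self.states.shape[1])]
        cols += [self.observed[:, i] for i in range(self.observed.shape[1])]
        buf = fileobj or _io.StringIO()
        buf.write(",".join(header) + "\n")
        for row in zip(*cols):
            buf.write(",".join(repr(float(v)) for v in row) + "\n")
        if fileobj is None:
            return buf.getvalue()
        return None

    def event_log_csv(self) -> str:
        lines = ["time,event"] + [f"{repr(t)},{eid}" for t, eid in self.event_log]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# ODE construction

def build_ode(network: ReactionNetwork) -> ODESystem:
    """Assemble the ODE system from a compiled network.

    ``ds/dt = sum_r nu[r, s] * rate_r`` for reaction-driven states; rate-rule
    targets take their rule expression; event-only targets get a zero
    derivative.  States with no flux, rule or event dependence are constant
    by construction and demoted to constants with a warning.
    """
    warnings: list[str] = []
    flux_targets = {sp for r in network.reactions for sp in r.net_stoichiometry}
    event_targets = {v for ev in network.events for v, _ in ev.assignments}
    constants = dict(network.constants)

    states: list[str] = []
    for sid in network.states:
        if sid in flux_targets or sid in network.rate_rules or sid in event_targets:
            states.append(sid)
        else:
            constants[sid] = network.initial[sid]
            warnings.append(
                f"state {sid!r} has no reaction flux, rate rule or event "
                f"dependence; demoted to a constant")

    rhs: dict[str, MathNode] = {}
    for sid in states:
        if sid in network.rate_rules:
            rhs[sid] = network.rate_rules[sid]
            continue
        terms: list[MathNode] = []
        for rxn in network.reactions:
            st = rxn.net_stoichiometry.get(sid)
            if st is None:
                continue
            if st == 1.0:
                terms.append(rxn.rate)
            elif st == -1.0:
                terms.append(Apply("minus", (rxn.rate,)))
            else:
                terms.append(Apply("times", (Number(st), rxn.rate)))
        if not terms:
            rhs[sid] = Number(0.0)  # event-only state
        elif len(terms) == 1:
            rhs[sid] = terms[0]
        else:
            rhs[sid] = Apply("plus", tuple(terms))

    y0 = np.array([network.initial[s] for s in states], dtype=float)
    return ODESystem(
        state_order=states, rhs=rhs,
        observed=dict(network.assignment_rules),
        observed_order=list(network.observed_order),
        residual_events=list(network.events),
        algebraic=list(network.algebraic_rules),
        initial_state=y0, constants=constants,
        algebraic_initial=dict(network.algebraic_initial),
        warnings=list(network.warnings) + warnings)


def _observed_topo(observed: dict[str, MathNode], order: list[str]) -> list[str]:
    """Observed variables sorted so each definition only uses earlier ones."""
    deps = {v: free_symbols(m) & set(observed) for v, m in observed.items()}
    out: list[str] = []
    state: dict[str, int] = {}

    def visit(v, stack):
        if state.get(v) == 2:
            return
        if state.get(v) == 1:
            raise ResolutionError(
                "cyclic assignment rules: " + " -> ".join(stack + [v]))
        state[v] = 1
        for d in sorted(deps[v]):
            visit(d, stack + [v])
        state[v] = 2
        out.append(v)

    for v in order:
        visit(v, [])
    return out


def structural_simplify(system: ODESystem) -> ODESystem:
    """Inline observed (assignment-rule) variables into the equations.

    Substitution runs to a fixed point through chains of observed
    definitions; cyclic definitions are an error.  The observed mapping is
    kept (fully inlined) so trajectories still report those variables.
    Simulation results are unchanged; the right-hand sides simply no longer
    reference defined variables.
    """
    topo = _observed_topo(system.observed, system.observed_order)
    flat: dict[str, MathNode] = {}
    for v in topo:
        flat[v] = substitute(system.observed[v], flat)
    return ODESystem(
        state_order=list(system.state_order),
        rhs={s: substitute(m, flat) for s, m in system.rhs.items()},
        observed=flat, observed_order=list(system.observed_order),
        residual_events=[
            CompiledEvent(e.id, substitute(e.residual, flat),
                          [(v, substitute(m, flat)) for v, m in e.assignments])
            for e in system.residual_events],
        algebraic=[(substitute(m, flat), v) for m, v in system.algebraic],
        initial_state=system.initial_state.copy(),
        constants=dict(system.constants),
        algebraic_initial=dict(system.algebraic_initial),
        warnings=list(system.warnings))


# ---------------------------------------------------------------------------
# compiled evaluation machinery

class _CompiledODE:
    """Bytecode-compiled right-hand side, observed, residual and algebraic
    functions over (t, y, c, a) where c = constants, a = algebraic values."""

    def __init__(self, system: ODESystem):
        self.system = system
        self.const_names = list(system.constants)
        self.c = tuple(float(system.constants[k]) for k in self.const_names)
        self.alg_vars = [v for _, v in system.algebraic]

        symmap: dict[str, str] = {}
        for i, s in enumerate(system.state_order):
            symmap[s] = f"y[{i}]"
        for j, k in enumerate(self.const_names):
            symmap[k] = f"c[{j}]"
        for k, v in enumerate(self.alg_vars):
            symmap[v] = f"a[{k}]"
        topo = _observed_topo(system.observed, system.observed_order)
        prelude = []
        for n, v in enumerate(topo):
            code = to_code(system.observed[v], symmap)
            name = f"_o{n}"
            prelude.append(f"{name} = {code}")
            symmap[v] = name
        self.symmap = symmap
        self.prelude = prelude
        args = ["t", "y", "c", "a"]

        self.rhs_fn = compile_function(
            [to_code(system.rhs[s], symmap) for s in system.state_order],
            args, prelude) if system.state_order else None
        self.obs_fn = compile_function(
            [symmap[v] for v in system.observed_order], args, prelude) \
            if system.observed_order else None
        self.residual_fns = [
            compile_function([to_code(e.residual, symmap)], args, prelude)
            for e in system.residual_events]
        self.alg_fns = [
            compile_function([to_code(m, symmap)], args, prelude)
            for m, _ in system.algebraic]
        self.assign_fns = [
            compile_function([to_code(m, symmap) for _, m in e.assignments],
                             args, prelude)
            for e in system.residual_events]
        self.a_last = np.array(
            [system.algebraic_initial.get(v, 1.0) for v in self.alg_vars], float)

    def solve_algebraic(self, t, y) -> np.ndarray:
        if not self.alg_fns:
            return self.a_last
        a = self.a_last.copy()
        for k, fn in enumerate(self.alg_fns):
            def g(x, k=k, a=a):
                a[k] = x
                return fn(t, y, self.c, a)[0]
            x0 = a[k]
            sol = root_scalar(g, x0=x0, x1=x0 + max(1.0, abs(x0)) * 1e-3,
                              method="secant", xtol=1e-12, maxiter=100)
            if not sol.converged:
                raise IntegrationError(
                    f"algebraic solve for {self.alg_vars[k]!r} failed", time=t)
            a[k] = sol.root
        self.a_last = a
        return a

    def rhs(self, t, y):
        a = self.solve_algebraic(t, y)
        return np.asarray(self.rhs_fn(t, y, self.c, a), dtype=float)

    def residual(self, i, t, y):
        a = self.solve_algebraic(t, y)
        return float(self.residual_fns[i](t, y, self.c, a)[0])

    def observed_row(self, t, y):
        if self.obs_fn is None:
            return ()
        a = self.solve_algebraic(t, y)
        return self.obs_fn(t, y, self.c, a)

    def apply_event(self, i, t, y) -> np.ndarray:
        """Simultaneous-read, sequential-write event assignments."""
        a = self.solve_algebraic(t, y)
        values = self.assign_fns[i](t, y, self.c, a)
        new_y = np.array(y, dtype=float, copy=True)
        for (var, _), value in zip(self.system.residual_events[i].assignments, values):
            try:
                idx = self.system.state_order.index(var)
            except ValueError:
                raise ModelError(
                    f"event {self.system.residual_events[i].id!r} assigns "
                    f"{var!r}, which is not a dynamic state") from None
            new_y[idx] = value
        return new_y


# ---------------------------------------------------------------------------
# integration with event localization

def _bisect_crossing(g, t_lo, t_hi, r_lo, r_hi):
    """Refine a sign change of g on [t_lo, t_hi] by bisection until the
    residual magnitude is below 1e-9 of its local scale."""
    scale = max(1.0, abs(r_lo), abs(r_hi))
    tol = 1e-9 * scale
    for _ in range(200):
        t_mid = 0.5 * (t_lo + t_hi)
        r_mid = g(t_mid)
        if abs(r_mid) <= tol or (t_hi - t_lo) <= 1e-14 * max(1.0, abs(t_mid)):
            return t_mid
        if (r_lo < 0) == (r_mid < 0):
            t_lo, r_lo = t_mid, r_mid
        else:
            t_hi, r_hi = t_mid, r_mid
    return 0.5 * (t_lo + t_hi)


def integrate(system: ODESystem, t_span: tuple[float, float],
              rel_tol: float = 1e-8, abs_tol: float = 1e-10,
              max_events: int = 1000, n_out: int = 201,
              method: str = "LSODA") -> Trajectory:
    """Integrate the system over ``t_span`` onto ``n_out`` evenly spaced
    output times, firing residual events on zero crossings in either
    direction.

    Events are located by a sign change of their residual between accepted
    integrator steps and refined by bisection on the dense output;
    assignments use pre-event values on their right-hand sides and are
    written in document order; integration then restarts.  Simultaneous
    candidates fire at the earliest located time, ties broken by event
    order.  More than ``max_events`` firings raises
    :class:`RunawayEventError`.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not (np.isfinite(t0) and np.isfinite(t1) and t0 < t1):
        raise ValueError(f"invalid t_span {t_span!r}")
    if n_out < 2:
        raise ValueError("n_out must be at least 2")
    comp = _CompiledODE(system)
    n_states = len(system.state_order)
    out_t = np.linspace(t0, t1, n_out)
    states = np.empty((n_out, n_states))
    states[0] = system.initial_state
    out_idx = 1
    event_log: list[tuple[float, str]] = []
    t_cur, y = t0, np.array(system.initial_state, dtype=float)
    n_events = len(system.residual_events)

    while t_cur < t1:
        sol = solve_ivp(comp.rhs, (t_cur, t1), y, method=method,
                        rtol=rel_tol, atol=abs_tol, dense_output=True)
        if not sol.success:
            raise IntegrationError(f"integration failed: {sol.message}",
                                   time=float(sol.t[-1]))
        if not np.all(np.isfinite(sol.y)):
            bad = np.where(~np.isfinite(sol.y).all(axis=0))[0][0]
            raise IntegrationError("non-finite state encountered",
                                   time=float(sol.t[bad]))
        t_event, ev_idx = None, None
        if n_events:
            r_prev = [comp.residual(i, sol.t[0], sol.y[:, 0]) for i in range(n_events)]
            for k in range(1, len(sol.t)):
                tk, yk = sol.t[k], sol.y[:, k]
                best_t, best_i = None, None
                for i in range(n_events):
                    r_k = comp.residual(i, tk, yk)
                    crossed = (r_prev[i] != 0.0 and
                               ((r_prev[i] < 0) != (r_k < 0) or r_k == 0.0))
                    if crossed:
                        def g(tt, i=i):
                            return comp.residual(i, tt, sol.sol(tt))
                        t_star = _bisect_crossing(g, sol.t[k - 1], tk,
                                                  r_prev[i], r_k)
                        if best_t is None or t_star < best_t - 1e-12:
                            best_t, best_i = t_star, i
                    r_prev[i] = r_k
                if best_t is not None:
                    t_event, ev_idx = best_t, best_i
                    break
        t_stop = t1 if t_event is None else t_event
        while out_idx < n_out and out_t[out_idx] <= t_stop:
            states[out_idx] = sol.sol(out_t[out_idx])
            out_idx += 1
        if t_event is None:
            t_cur = t1
            y = sol.y[:, -1]
        else:
            y_star = sol.sol(t_event)
            y = comp.apply_event(ev_idx, t_event, y_star)
            event_log.append((float(t_event),
                              system.residual_events[ev_idx].id))
            if len(event_log) > max_events:
                raise RunawayEventError(
                    f"more than {max_events} event firings", time=float(t_event))
            if t_event <= t_cur:  # no progress; nudge past the root
                t_event = np.nextafter(t_cur, t1)
            t_cur = t_event

    obs_order = list(system.observed_order) + [v for _, v in system.algebraic]
    observed = np.empty((n_out, len(obs_order)))
    if obs_order:
        # observed values are recomputed from states; rows after an event at
        # exactly an output time reflect pre-event states, like the states
        for r in range(n_out):
            row = comp.observed_row(out_t[r], states[r])
            a = comp.solve_algebraic(out_t[r], states[r]) if system.algebraic else ()
            observed[r] = tuple(row) + tuple(a)
    return Trajectory(times=out_t, states=states,
                      state_order=list(system.state_order),
                      observed=observed, observed_order=obs_order,
                      event_log=event_log)


def simulate_ode(network: ReactionNetwork, t_span, *, simplify: bool = True,
                 **kwargs) -> Trajectory:
    """Compile, (optionally) structurally simplify and integrate."""
    system = build_ode(network)
    if simplify:
        system = structural_simplify(system)
    return integrate(system, t_span, **kwargs)


# ---------------------------------------------------------------------------
# stochastic simulation (Gillespie direct method)

def _ssa_check(network: ReactionNetwork) -> None:
    if network.rate_rules:
        raise UnsupportedFeatureError(
            "stochastic simulation cannot handle rate rules", feature="rate-rule")
    if network.assignment_rules:
        raise UnsupportedFeatureError(
            "stochastic simulation cannot handle assignment rules",
            feature="assignment-rule")
    if network.algebraic_rules:
        raise UnsupportedFeatureError(
            "stochastic simulation cannot handle algebraic rules",
            feature="algebraic-rule")
    if network.events:
        raise UnsupportedFeatureError(
            "stochastic simulation cannot handle events", feature="event")
    for r in network.reactions:
        if not r.stochastic_ok:
            raise UnsupportedFeatureError(
                f"reaction {r.source[0]!r} is reversible but its kinetic law "
                f"could not be split into forward/reverse parts; stochastic "
                f"simulation is disallowed", feature="unsplit-reversible")
        for sp, st in r.net_stoichiometry.items():
            if st != int(st):
                raise UnsupportedFeatureError(
                    f"non-integer stoichiometry of {sp!r} in {r.id!r}",
                    feature="non-integer-stoichiometry")
    for sid in network.states:
        v = network.initial[sid]
        if abs(v - round(v)) > 1e-9:
            raise UnsupportedFeatureError(
                f"initial amount of {sid!r} is not an integer ({v})",
                feature="non-integer-initial")


def gillespie(network: ReactionNetwork, t_span: tuple[float, float],
              seed, max_steps: int = 50_000_000) -> Trajectory:
    """Exact direct-method SSA path, reproducible for a given seed.

    Propensities are the compiled rate expressions evaluated on the current
    integer amounts; the waiting time is exponential with the propensity
    sum and the next channel is chosen proportionally to its propensity.
    Returns the jump-time trajectory (state after each jump, plus the
    endpoints).
    """
    _ssa_check(network)
    t0, t1 = float(t_span[0]), float(t_span[1])
    states = list(network.states)
    index = {s: i for i, s in enumerate(states)}
    const_names = list(network.constants)
    c = tuple(float(network.constants[k]) for k in const_names)
    symmap = {s: f"x[{i}]" for s, i in index.items()}
    symmap.update({k: f"c[{j}]" for j, k in enumerate(const_names)})
    prop_fn = compile_function(
        [to_code(r.rate_amounts, symmap) for r in network.reactions],
        ["t", "x", "c"])
    stoich = np.zeros((len(network.reactions), len(states)))
    for j, r in enumerate(network.reactions):
        for sp, st in r.net_stoichiometry.items():
            stoich[j, index[sp]] = round(st)

    rng = np.random.default_rng(seed)
    x = np.array([round(network.initial[s]) for s in states], dtype=float)
    t = t0
    times = [t0]
    path = [x.copy()]
    exp = rng.exponential
    uni = rng.random
    for _ in range(max_steps):
        props = prop_fn(t, x, c)
        total = 0.0
        for j, p in enumerate(props):
            if p < 0:
                raise ModelError(
                    f"negative propensity {p!r} for reaction "
                    f"{network.reactions[j].id!r} at t={t}")
            total += p
        if total == 0.0:
            break
        t_next = t + exp(1.0 / total)
        if t_next > t1:
            break
        threshold = uni() * total
        acc = 0.0
        for j, p in enumerate(props):
            acc += p
            if acc >= threshold:
                break
        x = x + stoich[j]
        t = t_next
        times.append(t)
        path.append(x.copy())
    else:
        raise ModelError(f"SSA exceeded {max_steps} steps")
    times.append(t1)
    path.append(x.copy())
    return Trajectory(times=np.array(times), states=np.array(path),
                      state_order=states,
                      observed=np.empty((len(times), 0)), observed_order=[],
                      event_log=[])


def sample_states(traj: Trajectory, times) -> np.ndarray:
    """Piecewise-constant (right-continuous) sampling of a jump trajectory."""
    times = np.asarray(times, dtype=float)
    idx = np.searchsorted(traj.times, times, side="right") - 1
    idx = np.clip(idx, 0, len(traj.times) - 1)
    return traj.states[idx]


def gillespie_ensemble(network: ReactionNetwork, t_span, n_paths: int, seed,
                       sample_times=None):
    """Yield ``n_paths`` independent SSA trajectories derived from one seed.

    If ``sample_times`` is given, yields (n_times, n_states) arrays instead
    of Trajectory objects.
    """
    seeds = np.random.SeedSequence(seed).spawn(n_paths)
    for ss in seeds:
        traj = gillespie(network, t_span, ss)
        yield sample_states(traj, sample_times) if sample_times is not None else traj
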