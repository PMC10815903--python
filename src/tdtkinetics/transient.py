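"""Stopped-flow fluorescence transients: simulation and fitting.

The observable in a stopped-flow experiment is a linear readout of the
species concentrations,

    F_ideal(t) = F0 + sum_i r_i * c_i(t),

attenuated by photobleaching of the fluorophore under continuous
irradiation,

    F_obs(t) = (F_ideal(t) - F0) * exp(-kbleach * t) + F0,

where F0 is the background intensity and ``kbleach`` the bleaching rate.
The inverse transform (multiplying the background-subtracted signal by
exp(+kbleach*t)) recovers the unbleached signal and is exposed as
:func:`correct_photobleach`.

Global fitting follows the classic numerical approach to pre-steady-state
data: all traces of a concentration series are fitted simultaneously to the
mass-action ODE model of a mechanism.  The response coefficients and
backgrounds enter the model linearly, so the fit uses variable projection —
the nonlinear optimiser only searches over the rate constants (in log
space) while the linear coefficients are solved exactly at each step.  This
keeps the objective low-dimensional, well-scaled and fast.

Several experiments can be analysed jointly (:func:`fit_global_multi`):
e.g. the primer-free nucleotide-binding series and the full incorporation
series watch the same fluorophore environments, so their response
coefficients are shared, which is what makes the rate constants of the
larger mechanism well determined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import odeint
from scipy.optimize import curve_fit, least_squares

from .mechanisms import (
    CompiledMechanism,
    Mechanism,
    RateParameters,
    derive_rhs,
)

__all__ = [
    "DEAD_TIME_S",
    "Trace",
    "ObservableModel",
    "GlobalFitResult",
    "JointFitResult",
    "Experiment",
    "MultiExpFit",
    "BleachEstimate",
    "simulate_concentrations",
    "simulate_trace",
    "correct_photobleach",
    "estimate_kbleach",
    "fit_global",
    "fit_global_multi",
    "fit_multiexponential",
    "relative_activity",
    "initial_state",
    "fluorophore_response_basis",
    "trp_response_basis",
]

#: stopped-flow mixing dead time (s); points earlier than this are not observable
DEAD_TIME_S = 1.38e-3


@dataclass
class Trace:
    """A time-stamped fluorescence record with concentration metadata."""

    times: np.ndarray  # s, strictly increasing
    signal: np.ndarray  # a.u.
    channel: str = "CPy"  # "Trp" or "CPy"
    conc_enzyme: float = 0.0  # µM
    conc_primer: float = 0.0  # µM
    conc_nucleotide: float = 0.0  # µM
    id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal must have the same length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")
        for name in ("conc_enzyme", "conc_primer", "conc_nucleotide"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ObservableModel:
    """Linear fluorescence readout: per-species responses, background, bleaching."""

    responses: dict[str, float]  # species name -> a.u./µM
    F0: float = 0.0  # background, a.u.
    kbleach: float = 0.0  # s⁻¹

    def __post_init__(self) -> None:
        if self.kbleach < 0:
            raise ValueError("kbleach must be >= 0")


@dataclass
class BleachEstimate:
    kbleach: float  # s⁻¹
    F0: float  # a.u.
    flagged: bool = False  # True when the trace showed no decay


@dataclass
class GlobalFitResult:
    parameters: RateParameters
    observables: dict[str, ObservableModel]  # per channel
    rss: float
    stderr: dict[str, float]
    converged: bool
    n_starts_used: int
    message: str = ""


@dataclass
class JointFitResult:
    """Result of a multi-experiment global fit."""

    parameters: dict[str, float]  # global parameter name -> value
    experiment_parameters: list[RateParameters]
    observables: list[dict[str, ObservableModel]]  # per experiment, per channel
    rss: float
    stderr: dict[str, float]
    converged: bool
    n_starts_used: int
    message: str = ""


@dataclass
class MultiExpFit:
    """Empirical sum-of-exponentials description of one transient."""

    n_phases: int
    amplitudes: np.ndarray  # a.u., signed, matched to kobs order
    kobs: np.ndarray  # s⁻¹, sorted descending
    offset: float
    rss: float = 0.0
    collapsed: bool = False  # two phases within 1% of each other


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def simulate_concentrations(
    mechanism: Mechanism,
    params: RateParameters,
    initial: Mapping[str, float],
    times: np.ndarray,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    compiled: CompiledMechanism | None = None,
) -> np.ndarray:
    """Integrate the mass-action ODEs from t=0; return c(t) at ``times``.

    ``times`` need not start at 0 (stopped-flow observation begins at the
    instrument dead time); integration always starts from the mixing instant.
    Shape of the result is (len(times), n_species).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    y0 = np.zeros(len(mechanism.species))
    names = mechanism.species_names
    for name, c in initial.items():
        if name not in names:
            raise ValueError(f"unknown species {name!r} in initial state")
        if c < 0:
            raise ValueError(f"negative initial concentration for {name!r}")
        y0[mechanism.index(name)] = c
    f = compiled if compiled is not None else derive_rhs(mechanism, params)
    tgrid = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    y, info = odeint(
        f,
        y0,
        tgrid,
        Dfun=f.jac_odeint,
        rtol=rtol,
        atol=atol,
        full_output=True,
        mxstep=10000,
    )
    if info["message"] != "Integration successful.":
        raise RuntimeError(f"ODE integration failed: {info['message']}")
    return y if times[0] == 0.0 else y[1:]


def _apply_observable(
    conc: np.ndarray,
    species_names: Sequence[str],
    obs: ObservableModel,
    times: np.ndarray,
) -> np.ndarray:
    r = np.array([obs.responses.get(name, 0.0) for name in species_names])
    ideal = obs.F0 + conc @ r
    return (ideal - obs.F0) * np.exp(-obs.kbleach * times) + obs.F0


def simulate_trace(
    mechanism: Mechanism,
    params: RateParameters,
    obs: ObservableModel,
    initial: Mapping[str, float],
    times: np.ndarray,
    *,
    channel: str = "CPy",
    trace_id: str = "",
    conc_enzyme: float = 0.0,
    conc_primer: float = 0.0,
    conc_nucleotide: float = 0.0,
    rtol: float = 1e-8,
) -> Trace:
    """Forward-simulate one stopped-flow trace (bleaching included)."""
    times = np.asarray(times, dtype=float)
    conc = simulate_concentrations(mechanism, params, initial, times, rtol=rtol)
    signal = _apply_observable(conc, mechanism.species_names, obs, times)
    return Trace(
        times=times,
        signal=signal,
        channel=channel,
        conc_enzyme=conc_enzyme,
        conc_primer=conc_primer,
        conc_nucleotide=conc_nucleotide,
        id=trace_id,
    )


# ---------------------------------------------------------------------------
# photobleaching
# ---------------------------------------------------------------------------


def correct_photobleach(trace: Trace, F0: float, kbleach: float) -> Trace:
    """Undo exponential photobleaching: F = (F_obs − F0)·exp(kbleach·t) + F0."""
    if kbleach < 0:
        raise ValueError("kbleach must be >= 0")
    corrected = (trace.signal - F0) * np.exp(kbleach * trace.times) + F0
    return Trace(
        times=trace.times.copy(),
        signal=corrected,
        channel=trace.channel,
        conc_enzyme=trace.conc_enzyme,
        conc_primer=trace.conc_primer,
        conc_nucleotide=trace.conc_nucleotide,
        id=trace.id,
    )


def estimate_kbleach(trace: Trace) -> BleachEstimate:
    """Fit F0 + A·exp(−kbleach·t) to a chemically static calibration trace.

    Returns kbleach = 0 with a warning flag when the trace does not decay.
    """
    t, y = trace.times, trace.signal
    span = y.max() - y.min()
    if span <= 0 or y[-1] >= y[0]:
        return BleachEstimate(kbleach=0.0, F0=float(np.mean(y)), flagged=True)
    # crude initial guesses from the data
    f0_guess = y.min()
    a_guess = y[0] - f0_guess
    # time at which the decay has fallen to half its span
    half = f0_guess + 0.5 * a_guess
    below = np.nonzero(y <= half)[0]
    t_half = t[below[0]] if below.size else t[len(t) // 2]
    k_guess = np.log(2.0) / max(t_half, t[1] if len(t) > 1 else 1.0)

    def model(tt, f0, a, k):
        return f0 + a * np.exp(-k * tt)

    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=(f0_guess, a_guess, k_guess),
            bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        return BleachEstimate(kbleach=0.0, F0=float(np.mean(y)), flagged=True)
    f0, _, k = popt
    return BleachEstimate(kbleach=float(k), F0=float(f0), flagged=False)


# ---------------------------------------------------------------------------
# global fitting
# ---------------------------------------------------------------------------


def initial_state(mechanism: Mechanism, trace: Trace) -> dict[str, float]:
    """Map trace concentration metadata to an initial species state.

    For primer-containing schemes the enzyme–primer complex is pre-formed
    before mixing, so its initial concentration is the limiting one of
    enzyme and primer (free excess enzyme is spectroscopically silent and
    absorbed into the background).  For the primer-free scheme the free
    enzyme itself is the starting species.
    """
    if mechanism.name in ("scheme1", "scheme3"):
        return {
            "ED": min(trace.conc_enzyme, trace.conc_primer),
            "N": trace.conc_nucleotide,
        }
    if mechanism.name == "scheme2":
        return {"E": trace.conc_enzyme, "N": trace.conc_nucleotide}
    raise ValueError(
        f"no default initial-state mapping for mechanism {mechanism.name!r}; "
        "pass initial_state_fn explicitly"
    )


def fluorophore_response_basis(mechanism: Mechanism) -> dict[str, dict[str, float]]:
    """Additive per-fluorophore response basis for nucleotide-analogue channels.

    The fluorescent group is the nucleotide itself, so each species'
    response is the sum of the responses of the fluorophore environments it
    contains: ``free`` (unbound analogue), ``site1``/``site2`` (bound in the
    first/second binding stage), ``inc`` for the first incorporated residue
    and ``inc2`` per further incorporated residue.  The last group is kept
    separate because consecutive incorporated fluorophores stack on each
    other and quench, so their emission is not additive with the first
    residue's.  This constrains the linear readout of mechanisms with a
    second binding cycle, whose species would otherwise allow rate/response
    compensation; it also makes response coefficients shareable between
    experiments that watch the same environments (e.g. binding with and
    without a primer).
    """
    basis: dict[str, dict[str, float]] = {}
    for s in mechanism.species:
        terms: dict[str, float] = {}
        n_bound = s.composition.get("nucleotide", 0) - s.n_incorporated
        if s.role == "nucleotide":
            terms["free"] = 1.0
        elif n_bound > 0:
            stage = "site2" if s.name.startswith(("C2", "X2")) else "site1"
            terms[stage] = float(n_bound)
        if s.n_incorporated:
            terms["inc"] = 1.0
            if s.n_incorporated > 1:
                terms["inc2"] = float(s.n_incorporated - 1)
        if terms:
            basis[s.name] = terms
    return basis


def trp_response_basis(mechanism: Mechanism) -> dict[str, dict[str, float]]:
    """Per-species response basis for the intrinsic-tryptophan channel.

    The reporter is the enzyme's tryptophan environment, so every
    enzyme-containing species has its own response while the free
    nucleotide is dark (it carries no tryptophan).
    """
    return {
        s.name: {s.name: 1.0}
        for s in mechanism.species
        if s.role != "nucleotide"
    }


def _identity_basis(species_names: Sequence[str]) -> dict[str, dict[str, float]]:
    return {s: {s: 1.0} for s in species_names}


@dataclass
class Experiment:
    """One stopped-flow concentration series entering a joint global fit.

    ``prefix`` namespaces this experiment's rate constants in the joint
    parameter vector (empty prefix = bare names); experiments using the
    same global name for a rate share that rate.  Response groups, in
    contrast, are shared across experiments by group name within a channel.
    """

    mechanism: Mechanism
    traces: list[Trace]
    prefix: str = ""
    kbleach: float | Sequence[float] = 0.0
    response_basis: Mapping[str, Mapping[str, Mapping[str, float]]] | None = None
    initial_state_fn: Callable[[Mechanism, Trace], Mapping[str, float]] | None = None

    def param_name(self, rate: str) -> str:
        return f"{self.prefix}{rate}" if self.prefix else rate

    def kbleach_list(self) -> list[float]:
        if np.isscalar(self.kbleach):
            return [float(self.kbleach)] * len(self.traces)
        kb = [float(k) for k in self.kbleach]
        if len(kb) != len(self.traces):
            raise ValueError("kbleach must be scalar or one value per trace")
        return kb


def _solve_linear_readout(
    blocks: list[tuple[np.ndarray, Trace, list[str], float, Mapping | None, object]],
    fix_responses: Mapping[str, float] | None,
) -> tuple[np.ndarray, dict[str, float], dict[object, float], np.ndarray]:
    """Solve the linear readout (response groups + backgrounds) for one channel.

    ``blocks`` holds one entry per trace: (concentration matrix, trace,
    species names, kbleach, response basis, background key).  Response
    groups are shared across all blocks by name; each distinct background
    key gets its own F0 column (one per experiment).  ``fix_responses``
    pins selected group coefficients (the identifiability normalization).
    Returns (residuals, group values, F0 per background key, fitted signal).
    """
    groups: list[str] = []
    f0_keys: list[object] = []
    for _, _, names, _, basis, f0_key in blocks:
        b = basis if basis is not None else _identity_basis(names)
        for terms in b.values():
            for g in terms:
                if g not in groups:
                    groups.append(g)
        if f0_key not in f0_keys:
            f0_keys.append(f0_key)
    free_groups = [g for g in groups if not (fix_responses and g in fix_responses)]

    rows = []
    rhs = []
    for conc, tr, names, kb, basis, f0_key in blocks:
        b = basis if basis is not None else _identity_basis(names)
        bleach = np.exp(-kb * tr.times)
        gcols = {g: np.zeros_like(tr.times) for g in groups}
        for s, terms in b.items():
            c_s = conc[:, names.index(s)]
            for g, w in terms.items():
                gcols[g] += w * c_s
        cols = [gcols[g] * bleach for g in free_groups]
        for key in f0_keys:  # F0 columns are bleach-invariant
            cols.append(np.ones_like(tr.times) if key == f0_key else np.zeros_like(tr.times))
        rows.append(np.column_stack(cols))
        y = tr.signal.copy()
        if fix_responses:
            for g, val in fix_responses.items():
                if g in gcols:
                    y -= val * gcols[g] * bleach
        rhs.append(y)
    A = np.vstack(rows)
    y = np.concatenate(rhs)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ coef
    gvals = {g: float(c) for g, c in zip(free_groups, coef)}
    if fix_responses:
        gvals.update({g: float(v) for g, v in fix_responses.items() if g in groups})
    f0s = {key: float(c) for key, c in zip(f0_keys, coef[len(free_groups):])}
    return y - fitted, gvals, f0s, fitted


def _species_responses(
    basis: Mapping[str, Mapping[str, float]] | None,
    species_names: Sequence[str],
    gvals: Mapping[str, float],
) -> dict[str, float]:
    b = basis if basis is not None else _identity_basis(species_names)
    return {
        s: float(sum(w * gvals.get(g, 0.0) for g, w in terms.items()))
        for s, terms in b.items()
    }


def fit_global_multi(
    experiments: Sequence[Experiment],
    *,
    free_parameters: Sequence[str] | None = None,
    fixed_parameters: Mapping[str, float] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 20,
    seed: int = 0,
    fix_responses: Mapping[str, Mapping[str, float]] | None = None,
    rss_tol: float | None = None,
    rtol: float = 1e-8,
    max_nfev: int | None = 400,
) -> JointFitResult:
    """Joint global fit of one or more stopped-flow concentration series.

    Each experiment pairs a mechanism with its traces; rate constants are
    namespaced by the experiment's ``prefix`` (shared when two experiments
    use the same global name), and response-group coefficients are shared
    across experiments within each channel, with one background (F0) per
    experiment and channel.  The nonlinear search runs over the free rate
    constants in log10 space, multi-started from log-uniform draws within
    ``bounds`` (deterministic per ``seed``); linear coefficients are solved
    exactly at every step (variable projection).  A coarse search (ODE
    rtol 1e-6) is followed by a high-accuracy polish of the best start.

    ``fix_responses`` maps channel -> {group: value} and pins the response
    scale (e.g. the free-analogue response measured in a separate
    calibration), which is required for identifiability when the rates and
    responses could otherwise compensate.  ``rss_tol`` stops the
    multi-start early once the residual sum of squares falls below it.
    """
    experiments = list(experiments)
    all_traces = [t for e in experiments for t in e.traces]
    if len(all_traces) < 2:
        raise ValueError("global fitting requires at least 2 traces")
    concs = {(t.conc_enzyme, t.conc_primer, t.conc_nucleotide) for t in all_traces}
    if len(concs) < 2:
        raise ValueError("traces must span at least 2 distinct concentrations")

    # global parameter list
    param_names: list[str] = []
    for e in experiments:
        for r in e.mechanism.rate_names():
            g = e.param_name(r)
            if g not in param_names:
                param_names.append(g)
    fixed_parameters = dict(fixed_parameters or {})
    if free_parameters is None:
        free_parameters = [p for p in param_names if p not in fixed_parameters]
    free_parameters = list(free_parameters)
    missing = [
        p for p in param_names
        if p not in free_parameters and p not in fixed_parameters
    ]
    if missing:
        raise ValueError(f"rate constants {missing} are neither free nor fixed")

    default_bounds = (1e-2, 1e2)
    lo = np.array([np.log10((bounds or {}).get(p, default_bounds)[0]) for p in free_parameters])
    hi = np.array([np.log10((bounds or {}).get(p, default_bounds)[1]) for p in free_parameters])

    # degenerate input: no usable signal anywhere
    scale = max(float(np.max(np.abs(t.signal))) for t in all_traces)
    span = max(float(np.ptp(t.signal)) for t in all_traces)
    if span <= 1e-12 * max(scale, 1.0):
        nan_vals = {p: np.nan for p in free_parameters} | fixed_parameters
        return JointFitResult(
            parameters=nan_vals,
            experiment_parameters=[
                _params_for_experiment(e, nan_vals) for e in experiments
            ],
            observables=[{} for _ in experiments],
            rss=0.0,
            stderr={},
            converged=False,
            n_starts_used=0,
            message="non-identifiable: traces carry no signal variation",
        )

    kb_lists = [e.kbleach_list() for e in experiments]
    initials = [
        [dict((e.initial_state_fn or initial_state)(e.mechanism, t)) for t in e.traces]
        for e in experiments
    ]
    channels = sorted({t.channel for t in all_traces})

    def values_from_theta(theta: np.ndarray) -> dict[str, float]:
        vals = {p: 10.0 ** th for p, th in zip(free_parameters, theta)}
        vals.update(fixed_parameters)
        return vals

    def residuals(theta: np.ndarray, ode_rtol: float) -> np.ndarray:
        values = values_from_theta(theta)
        conc_all: list[list[np.ndarray]] = []
        try:
            for e, inits in zip(experiments, initials):
                params = _params_for_experiment(e, values)
                compiled = derive_rhs(e.mechanism, params)
                conc_all.append(
                    [
                        simulate_concentrations(
                            e.mechanism, params, init, t.times,
                            rtol=ode_rtol, compiled=compiled,
                        )
                        for init, t in zip(inits, e.traces)
                    ]
                )
        except (RuntimeError, ValueError):
            return np.full(sum(t.times.size for t in all_traces), 1e6)
        res = []
        for ch in channels:
            blocks = []
            for ei, e in enumerate(experiments):
                names = e.mechanism.species_names
                basis_ch = (e.response_basis or {}).get(ch)
                for ti, t in enumerate(e.traces):
                    if t.channel != ch:
                        continue
                    blocks.append(
                        (conc_all[ei][ti], t, names, kb_lists[ei][ti], basis_ch, ei)
                    )
            if blocks:
                r, *_ = _solve_linear_readout(blocks, (fix_responses or {}).get(ch))
                res.append(r)
        return np.concatenate(res)

    rng = np.random.default_rng(seed)
    starts = [0.5 * (lo + hi)]  # geometric-mean start, always included
    for _ in range(max(n_starts - 1, 0)):
        starts.append(rng.uniform(lo, hi))

    def minimize(x0: np.ndarray, ode_rtol: float, nfev: int | None, diff: float):
        # finite-difference steps must stay well above the ODE solver's
        # relative tolerance or the numerical gradients drown in solver noise
        return least_squares(
            residuals,
            x0,
            args=(ode_rtol,),
            bounds=(lo, hi),
            method="trf",
            x_scale="jac",
            diff_step=diff,
            ftol=1e-12,
            xtol=1e-12,
            gtol=1e-12,
            max_nfev=nfev,
        )

    # coarse multi-start search, then a high-accuracy polish of the best start
    search_rtol = max(rtol, 1e-6)
    best = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        sol = minimize(x0, search_rtol, max_nfev, 1e-3)
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
        if rss_tol is not None and best[0] <= rss_tol:
            break

    sol = minimize(best[1].x, rtol, max_nfev, 1e-5)
    rss = float(np.sum(sol.fun**2))
    values = values_from_theta(sol.x)
    exp_params = [_params_for_experiment(e, values) for e in experiments]

    # reconstruct the linear readout at the optimum
    observables: list[dict[str, ObservableModel]] = [{} for _ in experiments]
    n_linear = 0
    conc_final = [
        [
            simulate_concentrations(
                e.mechanism, p, init, t.times, rtol=rtol,
                compiled=derive_rhs(e.mechanism, p),
            )
            for init, t in zip(inits, e.traces)
        ]
        for e, p, inits in zip(experiments, exp_params, initials)
    ]
    for ch in channels:
        blocks = []
        for ei, e in enumerate(experiments):
            names = e.mechanism.species_names
            basis_ch = (e.response_basis or {}).get(ch)
            for ti, t in enumerate(e.traces):
                if t.channel != ch:
                    continue
                blocks.append(
                    (conc_final[ei][ti], t, names, kb_lists[ei][ti], basis_ch, ei)
                )
        if not blocks:
            continue
        _, gvals, f0s, _ = _solve_linear_readout(blocks, (fix_responses or {}).get(ch))
        n_linear += len(gvals) + len(f0s)
        for ei, e in enumerate(experiments):
            if ei not in f0s:
                continue
            responses = _species_responses(
                (e.response_basis or {}).get(ch), e.mechanism.species_names, gvals
            )
            observables[ei][ch] = ObservableModel(
                responses=responses, F0=f0s[ei], kbleach=kb_lists[ei][0]
            )

    npts = sum(t.times.size for t in all_traces)
    dof = max(npts - len(free_parameters) - n_linear, 1)
    stderr: dict[str, float] = {}
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * rss / dof
        for i, p in enumerate(free_parameters):
            se_log = float(np.sqrt(max(cov[i, i], 0.0)))
            stderr[p] = np.log(10.0) * values[p] * se_log
    except np.linalg.LinAlgError:
        stderr = {p: np.nan for p in free_parameters}

    converged = bool(sol.success) and np.isfinite(rss)
    return JointFitResult(
        parameters=values,
        experiment_parameters=exp_params,
        observables=observables,
        rss=rss,
        stderr=stderr,
        converged=converged,
        n_starts_used=n_used,
        message="" if converged else "optimizer did not converge on any start",
    )


def fit_global(
    traces: Sequence[Trace],
    mechanism: Mechanism,
    *,
    free_parameters: Sequence[str] | None = None,
    fixed_parameters: Mapping[str, float] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 20,
    seed: int = 0,
    kbleach: float | Sequence[float] = 0.0,
    fix_responses: Mapping[str, Mapping[str, float]] | None = None,
    response_basis: Mapping[str, Mapping[str, Mapping[str, float]]] | None = None,
    initial_state_fn: Callable[[Mechanism, Trace], Mapping[str, float]] | None = None,
    rss_tol: float | None = None,
    rtol: float = 1e-8,
    max_nfev: int | None = 400,
) -> GlobalFitResult:
    """Fit rate constants to a single concentration series of traces.

    Thin wrapper over :func:`fit_global_multi` with one experiment; see
    there for the fitting strategy and the meaning of the keyword options.
    """
    exp = Experiment(
        mechanism=mechanism,
        traces=list(traces),
        kbleach=kbleach,
        response_basis=response_basis,
        initial_state_fn=initial_state_fn,
    )
    joint = fit_global_multi(
        [exp],
        free_parameters=free_parameters,
        fixed_parameters=fixed_parameters,
        bounds=bounds,
        n_starts=n_starts,
        seed=seed,
        fix_responses=fix_responses,
        rss_tol=rss_tol,
        rtol=rtol,
        max_nfev=max_nfev,
    )
    return GlobalFitResult(
        parameters=joint.experiment_parameters[0],
        observables=joint.observables[0],
        rss=joint.rss,
        stderr=joint.stderr,
        converged=joint.converged,
        n_starts_used=joint.n_starts_used,
        message=joint.message,
    )


def _params_for_experiment(
    exp: Experiment, values: Mapping[str, float]
) -> RateParameters:
    """Assemble an experiment's RateParameters from the global value map."""
    local: dict[str, float] = {}
    for r in exp.mechanism.rate_names():
        g = exp.param_name(r)
        if g in values:
            local[r] = values[g]
    core = {k: local.pop(k, None) for k in ("k1", "k_minus1", "k2", "k_minus2", "kpol", "kt")}
    return RateParameters(
        k1=core["k1"] if core["k1"] is not None else 0.0,
        k_minus1=core["k_minus1"] if core["k_minus1"] is not None else 0.0,
        k2=core["k2"] if core["k2"] is not None else 0.0,
        k_minus2=core["k_minus2"] if core["k_minus2"] is not None else 0.0,
        kpol=core["kpol"],
        kt=core["kt"],
        extra=local,
    )


# ---------------------------------------------------------------------------
# empirical multi-exponential description
# ---------------------------------------------------------------------------


def fit_multiexponential(trace: Trace, n_phases: int) -> MultiExpFit:
    """Fit offset + sum of up to three exponentials to one transient.

    Uses variable projection (amplitudes and offset solved linearly) with a
    deterministic grid of rate starting points, so repeated calls give
    identical results.  Phases are reported sorted by kobs descending; a
    collapse of two phases onto each other (rates within 1%) is flagged.
    """
    if not 1 <= n_phases <= 3:
        raise ValueError("n_phases must be 1, 2 or 3")
    t, y = trace.times, trace.signal
    if 2 * n_phases + 1 >= t.size:
        raise ValueError("too few points for the requested number of phases")

    span = float(np.ptp(y))
    if span <= 1e-14 * max(1.0, float(np.max(np.abs(y)))):
        return MultiExpFit(
            n_phases=n_phases,
            amplitudes=np.zeros(n_phases),
            kobs=np.full(n_phases, 1.0 / max(t[-1], 1e-12)),
            offset=float(np.mean(y)),
            rss=float(np.sum((y - np.mean(y)) ** 2)),
            collapsed=True,
        )

    t_lo = t[0] if t[0] > 0 else (t[1] if t.size > 1 else 1e-3)
    k_min, k_max = 1.0 / (3.0 * t[-1]), 3.0 / t_lo
    log_lo, log_hi = np.log10(k_min), np.log10(k_max)

    def residuals_factory(logk: np.ndarray):
        k = 10.0**logk
        A = np.column_stack([np.exp(-np.outer(t, k)), np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return y - A @ coef, k, coef

    def objective(logk: np.ndarray) -> np.ndarray:
        return residuals_factory(logk)[0]

    # deterministic starts: nested log-spaced grids with varying spread
    starts = []
    for margin in (0.0, 0.5, 1.0, 1.5):
        lo_m, hi_m = log_lo + margin, log_hi - margin
        if hi_m <= lo_m:
            continue
        starts.append(np.linspace(lo_m, hi_m, n_phases + 2)[1:-1])
    rng = np.random.default_rng(0)
    for _ in range(4):
        starts.append(np.sort(rng.uniform(log_lo, log_hi, n_phases)))

    best = None
    for x0 in starts:
        sol = least_squares(
            objective,
            x0,
            bounds=(np.full(n_phases, log_lo - 1), np.full(n_phases, log_hi + 1)),
            method="trf",
            ftol=1e-14,
            xtol=1e-14,
            gtol=1e-14,
            max_nfev=300,
        )
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    rss, logk = best
    _, k, coef = residuals_factory(logk)
    order = np.argsort(k)[::-1]
    k_sorted = k[order]
    amps = coef[:-1][order]
    collapsed = bool(
        n_phases > 1 and np.any(k_sorted[:-1] / np.maximum(k_sorted[1:], 1e-300) < 1.01)
    ) or bool(np.any(np.abs(amps) < 1e-3 * span))
    if collapsed:
        warnings.warn(
            "multi-exponential fit is over-parameterised (phase collapse); "
            "consider a reduced model",
            stacklevel=2,
        )
    return MultiExpFit(
        n_phases=n_phases,
        amplitudes=amps,
        kobs=k_sorted,
        offset=float(coef[-1]),
        rss=rss,
        collapsed=collapsed,
    )


def relative_activity(mutant: MultiExpFit, wildtype: MultiExpFit) -> np.ndarray:
    """Per-phase kobs ratios mutant/wild-type, phases matched by sorted order."""
    if mutant.n_phases != wildtype.n_phases:
        raise ValueError(
            f"phase-count mismatch: mutant has {mutant.n_phases}, "
            f"wild type has {wildtype.n_phases}"
        )
    return mutant.kobs / wildtype.kobs
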