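"""Seeded amyloid aggregation kinetics under two-moment models.

The aggregating system is described by the first two moments of the fibril
length distribution: the number concentration of fibrils ``P`` and the mass
concentration of monomer incorporated into fibrils ``M`` (both molar, monomer
equivalents).  With free monomer ``m = m_tot - M`` the moments evolve as

    dP/dt = k_n * m**n_c  +  k_2 * m**n_2 / (1 + (m/K_M)**n_2) * M  +  k_minus * M
    dM/dt = 2 * k_plus * m * P

i.e. primary nucleation, (saturating) surface-catalysed secondary nucleation
and fibril fragmentation all create new growth-competent ends, while mass is
gained exclusively through elongation at those ends.  ``K_M -> inf`` recovers
the unsaturated secondary-nucleation model; ``k_2 = 0, k_minus > 0`` is the
pure fragmentation model.  Both self-replicating mechanisms produce the
characteristic weak monomer dependence of seeded half-times
(``gamma = dlog t_half / dlog m0 ~ -1/2``).

Everything here works in SI internally: seconds and molar.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit
import lmfit

__all__ = [
    "RateParameters",
    "KineticTrace",
    "GlobalFitResult",
    "NO_AGGREGATION",
    "NoAggregation",
    "KineticsError",
    "simulate_aggregation",
    "extract_half_time",
    "scaling_exponent",
    "global_fit",
    "model_preset",
]


class KineticsError(RuntimeError):
    """Integration or fitting failure in the kinetics layer."""


class NoAggregation:
    """Sentinel for traces whose signal never leaves baseline."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "<no aggregation>"

    def __bool__(self) -> bool:
        return False


#: Returned by :func:`extract_half_time` when a trace is flat.
NO_AGGREGATION = NoAggregation()


@dataclass
class RateParameters:
    """Rate constants and reaction orders of one aggregation condition.

    Parameters
    ----------
    k_plus : float
        Elongation rate constant (M^-1 s^-1).
    k_n : float
        Primary nucleation rate constant (concentration-order-adjusted, s^-1
        when multiplied by ``m**n_c``).
    n_c : float
        Primary nucleation reaction order (>= 0).
    k_2 : float
        Secondary nucleation rate constant (concentration-order-adjusted).
    n_2 : float
        Secondary nucleation reaction order (>= 0).
    K_M : float
        Saturation constant of secondary nucleation (M).  ``inf`` means the
        unsaturated model.
    k_minus : float
        Fragmentation rate constant (s^-1).
    m_tot : float
        Total monomer-equivalent protein concentration (M).
    M_0 : float
        Initial seed mass concentration (M, monomer equivalents).
    P_0 : float
        Initial seed number concentration (M).
    """

    k_plus: float = 0.0
    k_n: float = 0.0
    n_c: float = 2.0
    k_2: float = 0.0
    n_2: float = 2.0
    K_M: float = math.inf
    k_minus: float = 0.0
    m_tot: float = 5e-6
    M_0: float = 0.0
    P_0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_plus", "k_n", "n_c", "k_2", "n_2", "k_minus",
                     "m_tot", "M_0", "P_0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.K_M > 0:
            raise ValueError("K_M must be positive (use inf for unsaturated)")
        if self.M_0 > self.m_tot * (1 + 1e-12):
            raise ValueError("seed mass M_0 cannot exceed m_tot")
        if self.P_0 > self.M_0 * (1 + 1e-12) and self.M_0 > 0:
            raise ValueError("P_0 cannot exceed M_0 (a fibril has >=1 monomer)")
        if self.P_0 > 0 and self.M_0 == 0:
            raise ValueError("P_0 > 0 requires M_0 > 0")

    def evolve(self, **changes) -> "RateParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass
class KineticTrace:
    """One well's time series plus fitted summary quantities.

    ``signal`` may be raw fluorescence (AU) or normalized aggregate mass
    fraction; ``meta`` carries condition labels (monomer concentration, seed
    concentration, compound, dose, replicate and, for simulated traces, the
    molar ``m_tot``/``M_0``/``P_0`` ground truth).
    """

    time: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)
    fitted_baseline: float | None = None
    fitted_plateau: float | None = None
    half_time: float | None = None
    half_time_flag: str | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.signal.shape:
            raise ValueError("time and signal must be 1-D and equal length")
        if len(self.time) >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def span(self) -> float:
        return float(self.time[-1])


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def _moment_rhs(t, y, p: RateParameters):
    P, M = y
    m = p.m_tot - M
    if m < 0.0:
        m = 0.0
    sec = 0.0
    if p.k_2 > 0.0 and m > 0.0:
        mn = m ** p.n_2
        if math.isfinite(p.K_M):
            sec = p.k_2 * mn / (1.0 + (m / p.K_M) ** p.n_2)
        else:
            sec = p.k_2 * mn
    dP = p.k_n * (m ** p.n_c if m > 0.0 else 0.0) + (sec + p.k_minus) * M
    dM = 2.0 * p.k_plus * m * P
    return (dP, dM)


def simulate_aggregation(
    params: RateParameters,
    time_grid: Sequence[float],
    rtol: float = 1e-8,
    meta: Mapping | None = None,
) -> KineticTrace:
    """Integrate the moment equations and return the mass fraction M(t)/m_tot.

    The system is stiff when self-replication is fast relative to the sampling
    interval, so an LSODA integrator is used with tight tolerances.  Mass
    conservation ``m + M = m_tot`` holds by construction; the integration is
    rejected if ``M`` overshoots ``m_tot`` beyond tolerance.
    """
    t = np.asarray(time_grid, dtype=float)
    if t[0] != 0.0:
        raise ValueError("time_grid must start at 0")
    y0 = (params.P_0, params.M_0)
    if t.size == 1:
        return KineticTrace(t, np.array([params.M_0 / params.m_tot]),
                            dict(meta or {}))
    scale = max(params.P_0, params.m_tot * 1e-6, 1e-15)
    sol = solve_ivp(
        _moment_rhs, (0.0, float(t[-1])), y0, t_eval=t, args=(params,),
        method="LSODA", rtol=rtol, atol=[scale * 1e-8, params.m_tot * 1e-10],
    )
    if not sol.success:
        raise KineticsError(f"integration failed for {params!r}: {sol.message}")
    M = sol.y[1]
    tol = 1e-6 * params.m_tot
    if np.any(M > params.m_tot + 100 * tol) or np.any(M < -100 * tol):
        raise KineticsError(f"concentration excursion beyond tolerance for {params!r}")
    M = np.clip(M, 0.0, params.m_tot)
    # smooth out integrator-level non-monotonicity (clipped at tolerance above)
    M = np.maximum.accumulate(M)
    trace_meta = dict(meta or {})
    trace_meta.setdefault("m_tot", params.m_tot)
    trace_meta.setdefault("M_0", params.M_0)
    trace_meta.setdefault("P_0", params.P_0)
    return KineticTrace(t, M / params.m_tot, trace_meta)


def model_preset(model: str, params: RateParameters) -> RateParameters:
    """Zero out the rate constants a named mechanism excludes.

    ``secondary``   : unsaturated secondary nucleation (no fragmentation).
    ``saturating``  : saturating (multistep) secondary nucleation.
    ``fragmentation``: fragmentation only.
    """
    if model == "secondary":
        return params.evolve(k_minus=0.0, K_M=math.inf)
    if model == "saturating":
        if not math.isfinite(params.K_M):
            raise ValueError("saturating model requires finite K_M")
        return params.evolve(k_minus=0.0)
    if model == "fragmentation":
        return params.evolve(k_2=0.0)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Half-time extraction
# ---------------------------------------------------------------------------

def _logistic(t, base, amp, t50, tau):
    return base + amp / (1.0 + np.exp(-(t - t50) / tau))


def estimate_noise_sd(signal: np.ndarray) -> float:
    """Robust noise SD from lag-1 differences (MAD-scaled)."""
    d = np.diff(np.asarray(signal, dtype=float))
    if d.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / math.sqrt(2.0))


def extract_half_time(
    trace: KineticTrace,
    noise_multiple: float = 5.0,
) -> float | NoAggregation:
    """Half-time as the midpoint of a four-parameter logistic fit.

    The raw signal is fitted with ``base + amp / (1 + exp(-(t - t50)/tau))``;
    ``t50`` is the reported half-time and ``base``/``base + amp`` are stored on
    the trace as fitted baseline and plateau.  A trace whose dynamic range is
    below ``noise_multiple`` times the estimated noise SD is declared
    non-aggregating and the :data:`NO_AGGREGATION` sentinel is returned.  A
    transition that has not completed by the end of the trace yields a flagged
    estimate (``half_time_flag = "incomplete"``) with a warning.
    """
    t, y = trace.time, trace.signal
    if t.size < 5:
        raise ValueError("need at least 5 points to fit a sigmoid")
    sd = estimate_noise_sd(y)
    # percentile range: ~3.9 sd for pure noise, ~= plateau - baseline for a
    # real transition, so the 5-sd rule is robust to trace length
    lo_p, hi_p = np.percentile(y, [2.5, 97.5])
    rng_y = float(hi_p - lo_p)
    if rng_y <= noise_multiple * sd or rng_y == 0.0:
        trace.half_time = None
        trace.half_time_flag = "no_aggregation"
        return NO_AGGREGATION

    base0 = float(np.median(y[: max(3, t.size // 20)]))
    plat0 = float(np.median(y[-max(3, t.size // 20):]))
    mid = 0.5 * (base0 + plat0)
    above = np.nonzero(y >= mid)[0]
    t50_0 = float(t[above[0]]) if above.size else float(t[-1] * 0.8)
    tau0 = max(trace.span / 20.0, float(t[1] - t[0]))
    p0 = (base0, plat0 - base0, t50_0, tau0)
    lo = (-np.inf, 0.0, 0.0, (t[1] - t[0]) / 100.0)
    hi = (np.inf, np.inf, 5.0 * trace.span, trace.span)
    try:
        popt, _ = curve_fit(_logistic, t, y, p0=p0, bounds=(lo, hi),
                            maxfev=20000)
    except RuntimeError as exc:
        raise KineticsError(f"sigmoid fit failed: {exc}") from exc
    base, amp, t50, tau = popt
    trace.fitted_baseline = float(base)
    trace.fitted_plateau = float(base + amp)
    trace.half_time = float(t50)
    if t50 + 2.0 * tau > trace.span or t50 > trace.span:
        trace.half_time_flag = "incomplete"
        warnings.warn(
            f"aggregation incomplete at t_max={trace.span:.0f}s; half-time "
            f"{t50:.0f}s is an extrapolated estimate", stacklevel=2)
    else:
        trace.half_time_flag = None
    return float(t50)


# ---------------------------------------------------------------------------
# Half-time scaling with monomer concentration
# ---------------------------------------------------------------------------

def scaling_exponent(
    half_times: Sequence[float],
    monomer_concs: Sequence[float],
) -> tuple[float, float]:
    """Scaling exponent gamma of half-time versus monomer concentration.

    Fits ``log t_half = gamma * log m0 + c`` by ordinary least squares and
    returns ``(gamma, standard_error)``.  Secondary-process-dominated seeded
    aggregation gives gamma near -1/2; strong monomer dependence (|gamma|
    well above 1) points at nucleation-dominated mechanisms instead.
    """
    th = np.asarray(half_times, dtype=float)
    m0 = np.asarray(monomer_concs, dtype=float)
    if th.size != m0.size:
        raise ValueError("half_times and monomer_concs must have equal length")
    if th.size < 3:
        raise ValueError("need at least 3 concentrations")
    if np.any(~np.isfinite(th)) or np.any(th <= 0) or np.any(m0 <= 0):
        raise ValueError("half-times and concentrations must be finite and positive")
    res = stats.linregress(np.log(m0), np.log(th))
    return float(res.slope), float(res.stderr)


# ---------------------------------------------------------------------------
# Global fitting across a dilution series
# ---------------------------------------------------------------------------

#: Default log-uniform search bounds for free rate constants.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k_plus": (1e1, 1e8),
    "k_n": (1e-12, 1e2),
    "k_2": (1e-4, 1e12),
    "k_minus": (1e-13, 1e-3),
    "K_M": (1e-9, 1e-2),
}


@dataclass
class GlobalFitResult:
    """Outcome of a multi-start global fit."""

    params: RateParameters
    values: dict[str, float]
    stderr: dict[str, float | None]
    per_trace_sse: list[float]
    total_sse: float
    n_starts: int
    seed: int | None
    start_sses: list[float]
    at_bound: list[str]

    def to_dict(self) -> dict:
        return {
            "parameters": self.values,
            "standard_errors": self.stderr,
            "per_trace_misfit": self.per_trace_sse,
            "total_misfit": self.total_sse,
            "starts": self.n_starts,
            "start_misfits": self.start_sses,
            "seed": self.seed,
            "at_bound": self.at_bound,
        }


def _trace_params(template: RateParameters, trace: KineticTrace) -> RateParameters:
    """Per-trace concentrations come from the trace metadata."""
    upd = {}
    for key in ("m_tot", "M_0", "P_0"):
        if key in trace.meta:
            upd[key] = float(trace.meta[key])
    return template.evolve(**upd) if upd else template


def _residuals(log_values, names, template, traces, rtol):
    consts = {n: 10.0 ** v for n, v in zip(names, log_values)}
    out = []
    for tr in traces:
        p = _trace_params(template.evolve(**consts), tr)
        try:
            sim = simulate_aggregation(p, tr.time, rtol=rtol)
        except KineticsError:
            out.append(np.full(tr.signal.size, 1e3))
            continue
        out.append(sim.signal - tr.signal)
    return np.concatenate(out)


def global_fit(
    traces: Iterable[KineticTrace],
    template: RateParameters,
    free: Sequence[str] = (),
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 20,
    seed: int | None = 0,
    rtol: float = 1e-8,
) -> GlobalFitResult:
    """Fit shared rate constants to a set of traces jointly.

    All traces share the constants named in ``free``; everything else is held
    at the value in ``template``.  Per-trace concentrations (``m_tot``,
    ``M_0``, ``P_0``) are taken from each trace's metadata where present.
    Traces must be normalized to aggregate mass fraction.

    The loss surface of moment-model fits is multimodal in the rate constants
    (only combinations such as ``k_plus * k_2`` are well determined from bulk
    traces), so the optimisation restarts from ``n_starts`` log-uniform draws
    within the bounds and keeps the best solution.  Fitting is performed in
    log10 parameter space.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces supplied")
    free = list(free)
    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)

    def misfit_only() -> GlobalFitResult:
        per = []
        for tr in traces:
            p = _trace_params(template, tr)
            sim = simulate_aggregation(p, tr.time, rtol=rtol)
            per.append(float(np.sum((sim.signal - tr.signal) ** 2)))
        return GlobalFitResult(
            params=template, values={}, stderr={}, per_trace_sse=per,
            total_sse=float(sum(per)), n_starts=0, seed=seed,
            start_sses=[], at_bound=[])

    if not free:
        return misfit_only()

    unknown = [n for n in free if n not in bnds]
    if unknown:
        raise ValueError(f"no bounds known for free parameters {unknown}")

    rng = np.random.default_rng(seed)
    lo = np.array([math.log10(bnds[n][0]) for n in free])
    hi = np.array([math.log10(bnds[n][1]) for n in free])

    starts = [np.array([math.log10(max(getattr(template, n), bnds[n][0]))
                        for n in free])]
    starts[0] = np.clip(starts[0], lo, hi)
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform(lo, hi))

    best = None
    start_sses: list[float] = []
    for x0 in starts:
        pars = lmfit.Parameters()
        for n, v, a, b in zip(free, x0, lo, hi):
            pars.add(f"log10_{n}", value=float(v), min=float(a), max=float(b))
        try:
            res = lmfit.minimize(
                lambda p: _residuals([p[f"log10_{n}"].value for n in free],
                                     free, template, traces, rtol),
                pars, method="least_squares")
        except Exception:
            start_sses.append(math.inf)
            continue
        sse = float(res.chisqr)
        start_sses.append(sse)
        if best is None or sse < best[0]:
            best = (sse, res)
    if best is None:
        raise KineticsError("global fit failed to converge from any start")

    _, res = best
    values, stderr, at_bound = {}, {}, []
    for n in free:
        p = res.params[f"log10_{n}"]
        values[n] = 10.0 ** p.value
        stderr[n] = (values[n] * math.log(10) * p.stderr
                     if p.stderr is not None else None)
        if (p.value - p.min) < 1e-3 or (p.max - p.value) < 1e-3:
            at_bound.append(n)
    if at_bound:
        warnings.warn(f"fitted parameter(s) at imposed bound: {at_bound}",
                      stacklevel=2)

    fitted = template.evolve(**values)
    per = []
    for tr in traces:
        p = _trace_params(fitted, tr)
        sim = simulate_aggregation(p, tr.time, rtol=rtol)
        per.append(float(np.sum((sim.signal - tr.signal) ** 2)))
    return GlobalFitResult(
        params=fitted, values=values, stderr=stderr, per_trace_sse=per,
        total_sse=float(sum(per)), n_starts=len(starts), seed=seed,
        start_sses=start_sses, at_bound=at_bound)
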