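"""Quantifying small-molecule effects on seeded aggregation.

The screen's primary potency metric is the half-time of a compound-treated
reaction normalized to the vehicle (DMSO) control: ratios above 1 mark
inhibitors, below 1 inducers, with strict thresholds of 1.5 ("potent", the
hit definition) and 2 ("highly potent").  Mechanism is resolved by refitting
the kinetic model per dose with only the secondary-nucleation and/or
elongation rate constants free, by linear elongation rates from high-seed
experiments, and by a KIC50 — the dose at which the approximate reaction
rate (1/t_half, normalized so vehicle = 100 and complete arrest = 0) is
halved.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .kinetics import (
    NO_AGGREGATION,
    GlobalFitResult,
    KineticTrace,
    KineticsError,
    RateParameters,
    extract_half_time,
    global_fit,
)

__all__ = [
    "DoseSeries",
    "MechanismReport",
    "Kic50Result",
    "InvalidAssayError",
    "HIT_THRESHOLD",
    "HIGHLY_POTENT_THRESHOLD",
    "INDUCER_THRESHOLD",
    "normalized_half_time",
    "classify_hit",
    "fit_dose_mechanism",
    "elongation_slope",
    "kic50",
]


class InvalidAssayError(RuntimeError):
    """The control condition does not support the requested comparison."""


#: Strict thresholds on the mean normalized half-time.
HIT_THRESHOLD = 1.5
HIGHLY_POTENT_THRESHOLD = 2.0
#: Ratios below this mark aggregation inducers (1/HIT_THRESHOLD, i.e. the
#: hit threshold mirrored on the log scale).
INDUCER_THRESHOLD = 1.0 / HIT_THRESHOLD


@dataclass
class DoseSeries:
    """Traces (or pre-extracted half-times) indexed by inhibitor dose.

    ``traces`` maps dose (molar; 0.0 is the vehicle control) to a list of
    replicate traces.  Exactly one dose must be 0.
    """

    compound_id: str
    traces: dict[float, list[KineticTrace]] = field(default_factory=dict)
    half_times: dict[float, list[float]] = field(default_factory=dict)
    control_half_time: float | None = None

    def __post_init__(self) -> None:
        doses = self.doses
        if len(set(doses)) != len(doses):
            raise ValueError("doses must be unique")
        if any(d < 0 for d in doses):
            raise ValueError("doses must be non-negative")
        if doses and 0.0 not in doses:
            raise ValueError("a 0-dose vehicle control is required")

    @property
    def doses(self) -> list[float]:
        keys = set(self.traces) | set(self.half_times)
        return sorted(keys)

    @property
    def max_dose(self) -> float:
        return max(self.doses)


@dataclass
class MechanismReport:
    """Per-compound mechanistic deconvolution.

    Fractional reductions are ``1 - k(dose)/k(control)`` in [-1, 1]; negative
    values mean acceleration.  Headline values refer to the highest dose.
    """

    compound_id: str
    delta_k2: float | None = None
    delta_k2_err: float | None = None
    delta_kplus: float | None = None
    delta_kplus_err: float | None = None
    per_dose: dict[float, dict] = field(default_factory=dict)
    elongation_slopes: dict[float, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "compound": self.compound_id,
            "delta_k2": self.delta_k2,
            "delta_k2_err": self.delta_k2_err,
            "delta_kplus": self.delta_kplus,
            "delta_kplus_err": self.delta_kplus_err,
            "per_dose": {f"{d:g}": v for d, v in self.per_dose.items()},
            "elongation_slopes": {f"{d:g}": v
                                  for d, v in self.elongation_slopes.items()},
            "flags": self.flags,
        }


# ---------------------------------------------------------------------------
# Normalized half-time and hit classification
# ---------------------------------------------------------------------------

def normalized_half_time(trace: KineticTrace, control: KineticTrace) -> float:
    """Half-time ratio of a compound trace to its vehicle control.

    Both half-times are extracted (logistic fit) if not already present.
    A non-aggregating control invalidates the assay.
    """
    t_ctrl = control.half_time
    if t_ctrl is None:
        t_ctrl = extract_half_time(control)
    if t_ctrl is NO_AGGREGATION or control.half_time_flag == "no_aggregation":
        raise InvalidAssayError("control trace shows no aggregation")
    t_cmp = trace.half_time
    if t_cmp is None:
        t_cmp = extract_half_time(trace)
    if t_cmp is NO_AGGREGATION:
        return math.inf
    return float(t_cmp) / float(t_ctrl)


def classify_hit(ratio: float) -> str:
    """Map a normalized half-time to a potency class.

    Strict thresholds: ratio > 2 is ``highly_potent``, ratio > 1.5 is
    ``potent`` (the hit definition), ratio < 1/1.5 is ``inducer``, anything
    else is ``inactive``.  Every finite ratio maps to exactly one class;
    ``inf`` (complete arrest) counts as highly potent.
    """
    if math.isnan(ratio):
        raise ValueError("ratio must not be NaN")
    if ratio > HIGHLY_POTENT_THRESHOLD:
        return "highly_potent"
    if ratio > HIT_THRESHOLD:
        return "potent"
    if ratio < INDUCER_THRESHOLD:
        return "inducer"
    return "inactive"


# ---------------------------------------------------------------------------
# Per-dose mechanistic refits
# ---------------------------------------------------------------------------

def fit_dose_mechanism(
    series: DoseSeries,
    baseline_params: RateParameters,
    free_per_dose: Sequence[str] = ("k_2",),
    high_seed: DoseSeries | None = None,
    n_starts: int = 5,
    seed: int | None = 0,
    rtol: float = 1e-7,
) -> MechanismReport:
    """Attribute dose-dependent inhibition to secondary nucleation/elongation.

    The vehicle (0-dose) traces are fitted first with ``free_per_dose``
    floating to pin the control rate constants; every other dose is then
    refitted with only that same subset free, all structural constants
    (orders, saturation, primary nucleation) held at ``baseline_params``.
    Fractional reductions are ``1 - k(dose)/k(control)``, headline values at
    the highest dose.

    If ``high_seed`` is given and ``k_plus`` is in the free set, each dose is
    fitted jointly on its low-seed and high-seed traces: the high-seed
    (elongation-dominated) data pin ``k_plus`` while the low-seed data pin
    the self-replication constants, resolving the two mechanisms in one
    global fit per dose.
    """
    free = list(free_per_dose)
    bad = [f for f in free if f not in ("k_2", "k_plus")]
    if bad:
        raise ValueError(f"free_per_dose may only contain k_2/k_plus, got {bad}")
    if "k_plus" in free and "k_2" not in free and high_seed is not None:
        # k_plus alone is pinned by the high-seed data only
        series, high_seed = high_seed, None
    report = MechanismReport(compound_id=series.compound_id)

    def traces_for(dose: float) -> list[KineticTrace]:
        traces = list(series.traces.get(dose, []))
        if high_seed is not None:
            traces += list(high_seed.traces.get(dose, []))
        return traces

    doses = series.doses
    fits: dict[float, GlobalFitResult] = {}
    tmpl = baseline_params
    for dose in doses:
        traces = traces_for(dose)
        if not traces:
            continue
        try:
            res = global_fit(traces, tmpl, free=free,
                             n_starts=n_starts, seed=seed, rtol=rtol)
        except KineticsError as exc:
            if dose == 0.0:
                raise InvalidAssayError(f"control fit failed: {exc}") from exc
            report.flags.append(f"dose {dose:g}: fit failed ({exc})")
            continue
        fits[dose] = res
        if dose == 0.0:
            # pin the control estimates as the template for dose refits
            tmpl = res.params
    if 0.0 not in fits:
        raise InvalidAssayError("no control traces to fit")
    for d, r in fits.items():
        entry = report.per_dose.setdefault(d, {})
        for name, val in r.values.items():
            entry[name] = val
            entry[f"{name}_err"] = r.stderr.get(name)
        entry["sse"] = r.total_sse

    top = series.max_dose

    def _reduction(name: str):
        vals = {d: v[name] for d, v in report.per_dose.items() if name in v}
        errs = {d: v.get(f"{name}_err") for d, v in report.per_dose.items()}
        if 0.0 not in vals or top not in vals:
            return None, None
        k0, kt = vals[0.0], vals[top]
        red = 1.0 - kt / k0
        err = None
        e0, et = errs.get(0.0), errs.get(top)
        if e0 is not None and et is not None and k0 > 0 and kt > 0:
            err = (kt / k0) * math.sqrt((et / kt) ** 2 + (e0 / k0) ** 2)
        return red, err

    if "k_2" in free:
        report.delta_k2, report.delta_k2_err = _reduction("k_2")
    if "k_plus" in free:
        report.delta_kplus, report.delta_kplus_err = _reduction("k_plus")
    for name, val in (("delta_k2", report.delta_k2),
                      ("delta_kplus", report.delta_kplus)):
        if val is not None and not -1.0 <= val <= 1.0:
            report.flags.append(f"{name} outside [-1, 1]: {val:.3f}")
    return report


# ---------------------------------------------------------------------------
# Elongation rates from high-seed experiments
# ---------------------------------------------------------------------------

def elongation_slope(
    trace: KineticTrace,
    window_hours: float = 10.0,
) -> tuple[float, float]:
    """OLS slope of the signal over the first ``window_hours`` of reaction.

    High-seed reactions grow (to first order) linearly at rate
    ``2 k_plus m0 P0``, so the slope ratio versus control measures elongation
    inhibition directly.  Returns ``(slope, standard_error)`` in signal units
    per second.
    """
    window_s = window_hours * 3600.0
    if trace.span < window_s:
        raise ValueError(
            f"trace spans {trace.span:.0f}s, shorter than the "
            f"{window_s:.0f}s regression window")
    sel = trace.time <= window_s
    if sel.sum() < 3:
        raise ValueError("fewer than 3 points inside the regression window")
    res = stats.linregress(trace.time[sel], trace.signal[sel])
    return float(res.slope), float(res.stderr)


# ---------------------------------------------------------------------------
# KIC50 from normalized approximate rates
# ---------------------------------------------------------------------------

@dataclass
class Kic50Result:
    """KIC50 estimate with uncertainty, or a '> max dose' bound."""

    value: float | None
    stderr: float | None
    hill: float | None
    bound: float | None = None
    flags: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        if self.value is None:
            return f"KIC50 > {self.bound:g} (no 50% rate reduction observed)"
        return f"KIC50 = {self.value:.3g} ± {self.stderr:.2g}"


def kic50(
    doses: Sequence[float],
    half_times: Sequence[float],
    control_half_time: float,
) -> Kic50Result:
    """Dose halving the normalized approximate aggregation rate.

    The approximate rate of each reaction is ``1/t_half``, normalized so the
    vehicle control is 100 and complete arrest is 0.  A descending logistic
    in log dose with top fixed at 100 and bottom fixed at 0 (Hill slope free)
    is fitted; the KIC50 is the dose at which the curve crosses 50.

    Series in which no dose brings the rate below 75 carry no information on
    the midpoint: a ``> max dose`` bound is returned instead of an estimate.
    Non-monotone series are flagged but still fitted.
    """
    d = np.asarray(doses, dtype=float)
    th = np.asarray(half_times, dtype=float)
    if d.size != th.size:
        raise ValueError("doses and half_times must have equal length")
    if d.size < 4:
        raise ValueError("need at least 4 doses spanning the transition")
    if np.any(d < 0) or np.any(th <= 0) or control_half_time <= 0:
        raise ValueError("doses must be >=0 and half-times positive")
    rates = 100.0 * control_half_time / th

    flags = []
    order = np.argsort(d)
    r_sorted = rates[order]
    if np.any(np.diff(r_sorted) > 10.0):
        flags.append("non-monotone dose-response")
        warnings.warn("dose-response is not monotone", stacklevel=2)

    if rates.min() > 75.0:
        return Kic50Result(value=None, stderr=None, hill=None,
                           bound=float(d.max()), flags=flags)

    pos = d > 0
    logd = np.log10(d[pos])

    def model(x, log_ic50, hill):
        return 100.0 / (1.0 + 10.0 ** (hill * (x - log_ic50)))

    mid_guess = float(np.interp(50.0, r_sorted[::-1], np.log10(
        np.clip(d[order], d[pos].min(), None))[::-1]))
    try:
        popt, pcov = curve_fit(
            model, logd, rates[pos], p0=(mid_guess, 1.0),
            bounds=((np.log10(d[pos].min()) - 3, 0.05),
                    (np.log10(d.max()) + 3, 20.0)),
            maxfev=20000)
    except RuntimeError as exc:
        raise KineticsError(f"KIC50 fit failed: {exc}") from exc
    log_ic50, hill = popt
    perr = np.sqrt(np.diag(pcov))
    value = 10.0 ** log_ic50
    stderr = value * math.log(10) * perr[0] if np.isfinite(perr[0]) else None
    return Kic50Result(value=float(value), stderr=stderr, hill=float(hill),
                       flags=flags)
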