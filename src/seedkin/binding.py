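"""Compound-fibril affinity from fluorescence-polarization titrations.

A fixed concentration of compound (typically 10 uM) is titrated with
increasing concentrations of fibrils (in monomer equivalents); binding slows
the tumbling of the fluorophore and raises polarization.  The change in
polarization is fitted with a one-site binding curve

    delta_mP([F]) = B_max * [F] / (K_D + [F])

yielding the dissociation constant K_D and the saturating amplitude B_max.
Fibril concentration is interpreted in monomer equivalents as plotted; site
multiplicity is folded into B_max.  A quadratic ligand-depletion variant is
available for the regime where ligand and K_D are comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["BindingTitration", "BindingFit", "fit_one_site_binding"]


@dataclass
class BindingTitration:
    """One FP titration: fibril concentration versus polarization change."""

    compound_id: str
    fibril_concs: np.ndarray  # molar, monomer equivalents, strictly increasing
    delta_mP: np.ndarray
    sd: np.ndarray | None = None
    ligand_conc: float = 10e-6  # molar

    def __post_init__(self) -> None:
        self.fibril_concs = np.asarray(self.fibril_concs, dtype=float)
        self.delta_mP = np.asarray(self.delta_mP, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if self.fibril_concs.shape != self.delta_mP.shape:
            raise ValueError("fibril_concs and delta_mP must match in length")
        if np.any(self.fibril_concs < 0):
            raise ValueError("fibril concentrations must be non-negative")
        if np.any(np.diff(self.fibril_concs) <= 0):
            raise ValueError("fibril concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.delta_mP)):
            raise ValueError("delta_mP must be finite")
        if len(self.fibril_concs) < 4:
            raise ValueError("need at least 4 concentration levels")


@dataclass
class BindingFit:
    """One-site binding fit: K_D (molar) and B_max (mP) with asymptotic SDs."""

    K_D: float
    B_max: float
    K_D_sd: float
    B_max_sd: float
    poorly_determined: bool = False
    model: str = "hyperbolic"
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "K_D_M": self.K_D,
            "K_D_sd_M": self.K_D_sd,
            "B_max_mP": self.B_max,
            "B_max_sd_mP": self.B_max_sd,
            "poorly_determined": self.poorly_determined,
            "model": self.model,
            "flags": self.flags,
        }


def _hyperbola(F, B_max, K_D):
    return B_max * F / (K_D + F)


def _depletion(F, B_max, K_D, L0):
    # fraction of ligand bound when ligand depletion matters
    b = L0 + F + K_D
    bound = (b - np.sqrt(b * b - 4.0 * L0 * F)) / (2.0 * L0)
    return B_max * bound


def fit_one_site_binding(
    titration: BindingTitration,
    depletion: bool = False,
    weighted: bool = False,
) -> BindingFit:
    """Least-squares one-site binding fit of an FP titration.

    By default the non-depleting hyperbola ``B_max*[F]/(K_D+[F])`` is fitted
    (the conventional one-step binding curve); with ``depletion=True`` the
    quadratic exact-binding form accounting for the finite ligand
    concentration is used instead.  The fit is unweighted unless
    ``weighted=True``: per-level SDs estimated from a handful of replicates
    are too noisy to serve as stable weights and can destabilize the K_D
    estimate badly when the curve is weakly saturating.

    The K_D is flagged as poorly determined when the titration shows no
    saturation evidence (maximum signal below twice the
    lowest-concentration signal, or the fitted curve reaching less than
    ~60% of its plateau at the top tested concentration, i.e. K_D above
    two-thirds of the fibril range) or when the asymptotic SD of K_D
    reaches half the estimate — the regime where the planted affinity sits
    at or beyond the top of the tested fibril-concentration range.
    """
    F = titration.fibril_concs
    y = titration.delta_mP
    sigma = titration.sd if weighted and titration.sd is not None and \
        np.all(titration.sd > 0) else None

    amp0 = float(np.max(y))
    if amp0 <= 0:
        raise ValueError("signal never rises above zero; nothing to fit")
    half = 0.5 * amp0
    above = np.nonzero(y >= half)[0]
    kd0 = float(F[above[0]]) if above.size else float(F[-1])
    kd0 = max(kd0, float(F[F > 0].min()) if np.any(F > 0) else 1e-9)

    if depletion:
        L0 = titration.ligand_conc
        fun = lambda f, b, k: _depletion(f, b, k, L0)
        model = "depletion"
    else:
        fun = _hyperbola
        model = "hyperbolic"

    popt, pcov = curve_fit(
        fun, F, y, p0=(amp0, kd0), sigma=sigma, absolute_sigma=sigma is not None,
        bounds=((0.0, 1e-12), (np.inf, np.inf)), maxfev=20000)
    B_max, K_D = popt
    perr = np.sqrt(np.diag(pcov))

    flags = []
    lowest_pos = y[F > 0][0] if np.any(F > 0) else y[0]
    no_saturation = lowest_pos > 0 and float(np.max(y)) < 2.0 * float(lowest_pos)
    if no_saturation:
        flags.append("no saturation evidence within titration range")
    # fitted curve reaches < ~60% of plateau at the top concentration
    weak_saturation = K_D >= (2.0 / 3.0) * float(F.max())
    if weak_saturation:
        flags.append("K_D at or beyond the tested fibril range")
    sd_comparable = perr[1] >= 0.5 * K_D
    if sd_comparable:
        flags.append("K_D SD comparable to estimate")

    return BindingFit(
        K_D=float(K_D), B_max=float(B_max),
        K_D_sd=float(perr[1]), B_max_sd=float(perr[0]),
        poorly_determined=bool(no_saturation or weak_saturation
                               or sd_comparable),
        model=model, flags=flags)
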