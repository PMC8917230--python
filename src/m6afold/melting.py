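"""Two-state optical-melting analysis.

Absorbance melting curves of short duplexes are modelled as a two-state
equilibrium between duplex and single strands with linear upper and lower
baselines (the MeltWin convention).  For a total strand concentration C_T
the fraction of strands in duplex f(T) follows from the equilibrium
constant K(T) = exp(-(dH - T dS)/RT):

* non-self-complementary (A + B -> AB, molecularity factor a = 4):
  K = 2 f / ((1 - f)^2 C_T)
* self-complementary (2A -> A2, a = 1):
  K = f / (2 (1 - f)^2 C_T)

At the melting temperature (f = 1/2) K = a / C_T, giving the linear
relation 1/T_M = (R / dH) ln(C_T / a) + dS / dH that underlies the
T_M^-1 vs ln(C_T/a) analysis.  Free energies used downstream are the ones
from those linear fits.

Loop-motif increments are extracted from fitted duplex stabilities by
subtracting the nearest-neighbor reference terms; uncertainties propagate
as sigma^2 = sum (n_i sigma_i)^2, with 4% of |dG37| as the per-experiment
uncertainty convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .constants import R_KCAL, T37

_K0 = 273.15


class MeltFitError(RuntimeError):
    """No transition detected or the two-state fit failed."""


@dataclass(frozen=True)
class MeltingCurve:
    temperatures: np.ndarray  # degC, ascending
    absorbance: np.ndarray    # arbitrary units at 260 nm
    C_T: float                # total strand concentration, M
    a: int                    # molecularity factor: 4 non-self, 1 self

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if t.shape != ab.shape:
            raise ValueError("temperature and absorbance lengths differ")
        if self.C_T <= 0:
            raise ValueError("C_T must be positive")
        if self.a not in (1, 4):
            raise ValueError("molecularity factor a must be 1 or 4")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "absorbance", ab)


@dataclass(frozen=True)
class VantHoffFit:
    dH: float                  # kcal/mol
    dS: float                  # kcal/(mol K)
    dG37: float                # kcal/mol
    tm_at_1e4: float           # degC at C_T = 1e-4 M
    sigma_dG37: float          # kcal/mol
    a: int = 4

    def __post_init__(self):
        if abs(self.dG37 - (self.dH - T37 * self.dS)) > 1e-6:
            raise ValueError("dG37 inconsistent with dH - T*dS")
        if self.sigma_dG37 < 0:
            raise ValueError("sigma must be >= 0")


def melting_temperature(dH: float, dS: float, C_T: float, a: int) -> float:
    """T_M in degC from 1/T_M = (R/dH) ln(C_T/a) + dS/dH."""
    inv = (R_KCAL / dH) * math.log(C_T / a) + dS / dH
    return 1.0 / inv - _K0


def fraction_duplex(dH: float, dS: float, C_T: float, a: int,
                    T_celsius) -> np.ndarray:
    """Fraction of strands in duplex at each temperature."""
    T = np.asarray(T_celsius, dtype=float) + _K0
    K = np.exp(-(dH - T * dS) / (R_KCAL * T))
    kc = K * C_T
    with np.errstate(invalid="ignore", divide="ignore"):
        if a == 4:
            b = 2 * kc + 2
            f = (b - np.sqrt(b * b - 4 * kc * kc)) / (2 * kc)
            f = np.where(kc < 1e-12, kc / 2.0, f)
        else:
            b = 4 * kc + 1
            f = (b - np.sqrt(b * b - 16 * kc * kc)) / (4 * kc)
            f = np.where(kc < 1e-12, 2.0 * kc, f)
    return np.clip(f, 0.0, 1.0)


def simulate_melt_curve(dH: float, dS: float, C_T: float, a: int = 4,
                        baselines=(0.60, 5e-4, 1.00, 1e-3),
                        noise_sd: float = 0.0, seed: int | None = 0,
                        temperatures=None) -> MeltingCurve:
    """Synthetic two-state absorbance melting curve.

    *baselines* is (lower intercept, lower slope, upper intercept, upper
    slope); the lower baseline is the duplex state.  Gaussian noise of the
    given standard deviation is added with the given seed.
    """
    if dH >= 0 or dS >= 0:
        raise ValueError("folding requires dH < 0 and dS < 0")
    if temperatures is None:
        temperatures = np.arange(0.0, 95.0, 0.5)
    T = np.asarray(temperatures, dtype=float)
    f = fraction_duplex(dH, dS, C_T, a, T)
    bl, ml, bu, mu = baselines
    ab = f * (bl + ml * T) + (1 - f) * (bu + mu * T)
    if noise_sd:
        rng = np.random.default_rng(seed)
        ab = ab + rng.normal(0.0, noise_sd, size=ab.shape)
    return MeltingCurve(T, ab, C_T, a)


def _ds_from_tm(dH, tm_K, C_T, a):
    # dH - Tm dS = -R Tm ln(a/C_T)
    return dH / tm_K + R_KCAL * math.log(a / C_T)


def _curve_model(C_T, a):
    """Two-state curve parameterized by (dH, T_M) to decorrelate the
    van't Hoff parameters."""

    def model(T, dH, tm_K, bl, ml, bu, mu):
        dS = _ds_from_tm(dH, tm_K, C_T, a)
        f = fraction_duplex(dH, dS, C_T, a, T)
        return f * (bl + ml * T) + (1 - f) * (bu + mu * T)
    return model


def fit_single_curve(curve: MeltingCurve) -> VantHoffFit:
    """Nonlinear least-squares two-state fit with sloping baselines."""
    T, A = curve.temperatures, curve.absorbance
    if len(T) < 8:
        raise MeltFitError("too few points for a two-state fit")
    span = float(np.ptp(A))
    if span < 1e-9:
        raise MeltFitError("no transition detected: flat absorbance")
    # initial guesses: baselines from the curve ends, T_M from the
    # steepest smoothed slope
    k = max(3, len(T) // 8)
    ml, bl = np.polyfit(T[:k], A[:k], 1)
    mu, bu = np.polyfit(T[-k:], A[-k:], 1)
    smooth = np.convolve(np.pad(A, 2, mode="edge"), np.ones(5) / 5,
                         mode="valid")
    dA = np.gradient(smooth, T)
    tm_guess = float(T[np.argmax(dA)]) + _K0
    best = None
    for dh0 in (-50.0, -80.0, -120.0):
        try:
            popt, _ = curve_fit(
                _curve_model(curve.C_T, curve.a), T, A,
                p0=[dh0, tm_guess, bl, ml, bu, mu], maxfev=20000)
        except RuntimeError:
            continue
        resid = A - _curve_model(curve.C_T, curve.a)(T, *popt)
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, popt, resid)
    if best is None:
        raise MeltFitError("two-state fit failed to converge")
    _, popt, resid = best
    dH, tm_K = float(popt[0]), float(popt[1])
    dS = _ds_from_tm(dH, tm_K, curve.C_T, curve.a)
    tmid = float(np.mean(T))
    amp = abs((popt[4] + popt[5] * tmid) - (popt[2] + popt[3] * tmid))
    if dH >= 0 or not (T.min() - 15 < tm_K - _K0 < T.max() + 15) \
            or amp < 5 * max(float(np.std(resid)), 1e-12):
        raise MeltFitError("no transition detected within the temperature range")
    dg = dH - T37 * dS
    return VantHoffFit(dH=dH, dS=dS, dG37=dg,
                       tm_at_1e4=melting_temperature(dH, dS, 1e-4, curve.a),
                       sigma_dG37=experimental_sigma(dg), a=curve.a)


def fit_tm_plot(points, a: int) -> VantHoffFit:
    """Van't Hoff analysis of T_M^-1 vs ln(C_T/a).

    *points* is a sequence of (C_T in M, T_M in degC); at least three
    concentrations are required.  slope = R/dH, intercept = dS/dH.
    """
    pts = list(points)
    if len(pts) < 3:
        raise MeltFitError("need at least 3 concentrations")
    x = np.array([math.log(ct / a) for ct, _ in pts])
    y = np.array([1.0 / (tm + _K0) for _, tm in pts])
    if float(np.ptp(x)) < 1e-12:
        raise MeltFitError("zero variance in ln(C_T/a)")
    slope, intercept = np.polyfit(x, y, 1)
    dH = R_KCAL / slope
    dS = dH * intercept
    dg = dH - T37 * dS
    return VantHoffFit(dH=float(dH), dS=float(dS), dG37=float(dg),
                       tm_at_1e4=melting_temperature(dH, dS, 1e-4, a),
                       sigma_dG37=experimental_sigma(dg), a=a)


def two_state_check(dh_curvefits: float, dh_tmplot: float,
                    tolerance: float = 0.15) -> bool:
    """Two-state consistency: the curve-fit and T_M-plot enthalpies agree
    within 15%."""
    return abs(dh_curvefits - dh_tmplot) <= tolerance * abs(dh_tmplot)


# ----------------------------------------------------------------------
# loop-motif increments

def motif_increment_terminal(dg_duplex_with_two_motifs: float,
                             dg_reference: float) -> float:
    """Dangling-end / terminal-mismatch increment from a self-complementary
    duplex carrying the motif at both ends (hence the factor of two)."""
    return (dg_duplex_with_two_motifs - dg_reference) / 2.0


def motif_increment_hairpin(dg_stemloop: float,
                            dg_helical_stacks: float) -> float:
    """Hairpin-loop increment: stem-loop stability minus its helical
    stacks."""
    return dg_stemloop - dg_helical_stacks


def motif_increment_internal(dg_duplex: float, dg_stacks: float,
                             dg_init: float, dg_symmetry: float) -> float:
    """Interior-loop increment: duplex stability minus helical stacks,
    duplex initiation, and the symmetry correction."""
    return dg_duplex - dg_stacks - dg_init - dg_symmetry


# ----------------------------------------------------------------------
# uncertainty propagation

@dataclass(frozen=True)
class UncertaintyBudget:
    """Independent uncertainty terms (sigma_i, n_i occurrences)."""

    terms: tuple = field(default_factory=tuple)

    def __post_init__(self):
        terms = tuple((float(s), int(n)) for s, n in self.terms)
        for s, n in terms:
            if s < 0 or n < 1:
                raise ValueError("need sigma >= 0 and n >= 1")
        object.__setattr__(self, "terms", terms)


def propagate_uncertainty(budget: UncertaintyBudget) -> float:
    """sigma = sqrt(sum (n_i sigma_i)^2) for uncorrelated terms."""
    return math.sqrt(sum((n * s) ** 2 for s, n in budget.terms))


def experimental_sigma(dg37: float) -> float:
    """Uncertainty convention for an optical melting experiment: 4% of the
    magnitude of dG37."""
    return 0.04 * abs(dg37)
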