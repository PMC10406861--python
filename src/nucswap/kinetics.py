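"""Kinetic model of inter-nucleosomal H2A-H2B dimer exchange.

The measured observable is the fraction of surface-immobilized (DNA-labeled)
nucleosomes that carry a Cy5.5-labeled dimer in the entry-*distal* slot and
an unlabeled dimer in the entry-proximal slot (species e).  Under random
pairwise exchange at bimolecular rate constant k between all nucleosomes at
total concentration C_total, with dimer labeling efficiency F in the
histone-labeled half of a 1:1 mix, this fraction follows

    f_e(t) = (F/2)(1 - F/2) * (1 - exp(-((1+F)/2) * k * C_total * t))

The amplitude (F/2)(1−F/2) is the equilibrium probability that a given slot
is labeled (F/2, the overall labeled-dimer fraction of the mix) while the
other slot is not.  The exponent coefficient (1+F)/2 collects the
statistical ½ factors of the partially labeled collision partners.  At the
labeling efficiency used here, F = 0.537, the amplitude rounds to 0.196 and
the coefficient to 0.77.

Rate constants are fitted by Levenberg-Marquardt nonlinear least squares;
the reported error is the standard error of the fit (square root of the
residual-variance-scaled covariance diagonal).  Two fits are compared by
the difference-versus-sum-of-errors criterion: the difference is called
significant iff |k1 − k2| exceeds se1 + se2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

DEFAULT_F = 0.537
DEFAULT_C_TOTAL = 4e-7  # 400 nM total nucleosome
DEFAULT_C_REF = 7e-5  # 70 uM, nuclear-density reference concentration


def _check_F(F: float) -> None:
    if not 0.0 <= F <= 1.0:
        raise ValueError(f"labeling efficiency F must be in [0,1], got {F}")


def equilibrium_fraction(F: float) -> float:
    """Equilibrium fraction of distal-only-labeled nucleosomes, (1−F/2)(F/2).

    After full randomization every H2A-H2B slot carries a label with
    probability F/2 (half the nucleosomes entered with labeling efficiency
    F); the distal-labeled/proximal-unlabeled combination therefore occurs
    with probability (F/2)(1−F/2).
    """
    _check_F(F)
    return (F / 2.0) * (1.0 - F / 2.0)


def exponent_coefficient(F: float) -> float:
    """Exponent coefficient (1+F)/2 of the closed-form exchange model."""
    _check_F(F)
    return (1.0 + F) / 2.0


@dataclass
class ExchangeModel:
    """Parameters of the closed-form distal-exchange model."""

    k: float  # bimolecular rate constant, M^-1 s^-1
    F: float = DEFAULT_F
    C_total: float = DEFAULT_C_TOTAL  # molar

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("rate constant k must be >= 0")
        _check_F(self.F)
        if self.C_total <= 0:
            raise ValueError("C_total must be positive")

    @property
    def amplitude(self) -> float:
        return equilibrium_fraction(self.F)

    @property
    def exponent_coeff(self) -> float:
        return exponent_coefficient(self.F)


def closed_form_fraction(t, model: ExchangeModel):
    """Distal-exchanged fraction f_e(t) = A(1 − exp(−c·k·C·t)).

    ``t`` is in seconds (scalar or array, all >= 0).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time t must be non-negative")
    rate = model.exponent_coeff * model.k * model.C_total
    out = model.amplitude * -np.expm1(-rate * t)
    return float(out) if out.ndim == 0 else out


def ode_rhs_printed(x: float, model: ExchangeModel) -> float:
    """dx/dt of the early-time mole-fraction rate equation for species B.

    Evaluates, term by term, the displayed rate equation for the production
    of singly-labeled immobilized nucleosomes (mole fraction x), multiplied
    by C_total to carry concentration units (result in s^-1):

        dx/dt = k·C·[ (0.5−x)(0.5F²−x) + ½(0.5−x)(x+½F(1−F))
                      − ½x(0.5F²−x) − ½x(x+0.5F(1−F))
                      − ½x·0.5(1−F)² − ½x² ]

    This early-time form neglects back-reactions (production of B from the
    doubly-exchanged species); it is provided as a diagnostic and its
    long-time plateau is *not* the closed-form amplitude.  Use
    :func:`closed_form_fraction` for fitting.
    """
    if not 0.0 <= x <= 0.5:
        raise ValueError("mole fraction x must lie in [0, 0.5]")
    F = model.F
    terms = (
        (0.5 - x) * (0.5 * F**2 - x)
        + 0.5 * (0.5 - x) * (x + 0.5 * F * (1.0 - F))
        - 0.5 * x * (0.5 * F**2 - x)
        - 0.5 * x * (x + 0.5 * F * (1.0 - F))
        - 0.5 * x * 0.5 * (1.0 - F) ** 2
        - 0.5 * x**2
    )
    return model.k * model.C_total * terms


def integrate_printed_ode(model: ExchangeModel, t_grid: Sequence[float]):
    """Numerically integrate the printed rate equation from x(0) = 0.

    Returns ``(x, e)`` arrays on ``t_grid`` where e(t) = x(t)/2 is the
    distal-exchanged fraction implied by the symmetric proximal/distal
    split of species B.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1:
        raise ValueError("t_grid must be a 1-D array of times")
    if t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must increase strictly from 0")
    sol = solve_ivp(
        lambda t, y: [ode_rhs_printed(float(np.clip(y[0], 0.0, 0.5)), model)],
        (0.0, float(t_grid[-1])),
        [0.0],
        t_eval=t_grid,
        rtol=1e-8,
        atol=1e-12,
        method="RK45",
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    x = sol.y[0]
    return x, x / 2.0


@dataclass
class RateFit:
    """Result of a rate-constant fit."""

    k_hat: float  # M^-1 s^-1
    se_k: float
    amplitude: float
    exponent_coeff: float
    C_total: float
    F: float
    amplitude_fixed: bool
    residuals: np.ndarray
    fitted: np.ndarray
    t_s: np.ndarray
    condition: str = ""
    flags: list = field(default_factory=list)

    @property
    def k_rounded(self) -> float:
        """k to 3 significant figures, the reporting precision used here."""
        if self.k_hat == 0:
            return 0.0
        return float(f"{self.k_hat:.3g}")


@dataclass
class ExchangeTimescale:
    """Characteristic exchange time 1/(k·C_ref) at a reference concentration."""

    t_exchange: float  # seconds
    se_t: float
    C_ref: float

    @property
    def t_rounded(self) -> int:
        return int(round(self.t_exchange))

    @property
    def se_rounded(self) -> int:
        return int(round(self.se_t))


class ExchangeRateModel(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares estimator of the bimolecular exchange rate.

    Fits f(t) = A·(1 − exp(−c·k·C_total·t)) to a measured time course of
    distal-exchanged fractions, with A = (F/2)(1−F/2) and c = (1+F)/2
    fixed by the labeling efficiency (default) or A left free.

    Parameters
    ----------
    F : float
        H2A-H2B labeling efficiency (default 0.537).
    C_total : float
        Total nucleosome concentration in molar (default 4e-7, i.e. 400 nM).
    amplitude_fixed : bool
        Fix the amplitude at (F/2)(1−F/2) (default True).
    weighted : bool
        Weight points by the replicate standard deviations passed to
        :meth:`fit` (default False: unweighted).

    Attributes
    ----------
    k_ : float
        Fitted rate constant in M^-1 s^-1.
    k_se_ : float
        Standard error of the fit (residual-variance-scaled covariance).
    amplitude_ : float
        Amplitude used (fixed) or fitted.
    fit_result_ : RateFit
        Full fit record.
    """

    def __init__(
        self,
        F: float = DEFAULT_F,
        C_total: float = DEFAULT_C_TOTAL,
        amplitude_fixed: bool = True,
        weighted: bool = False,
    ):
        self.F = F
        self.C_total = C_total
        self.amplitude_fixed = amplitude_fixed
        self.weighted = weighted

    # -- scikit-learn API -------------------------------------------------
    def fit(self, X, y, sd: Optional[Sequence[float]] = None, condition: str = ""):
        """Fit the rate constant.

        Parameters
        ----------
        X : array-like of shape (n_points,) or (n_points, 1)
            Reaction times in **seconds**.
        y : array-like of shape (n_points,)
            Measured distal-exchanged fractions.
        sd : array-like, optional
            Per-point replicate standard deviations; used as weights when
            ``weighted=True``.
        """
        _check_F(self.F)
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != y.shape:
            raise ValueError("X and y must have the same length")
        mask = np.isfinite(t) & np.isfinite(y)
        t, y = t[mask], y[mask]
        if len(t) < 3:
            raise ValueError("need >= 3 time points with defined fractions")

        amp = equilibrium_fraction(self.F)
        coeff = exponent_coefficient(self.F)
        flags: list = []

        sigma = None
        if self.weighted and sd is not None:
            sd_arr = np.asarray(sd, dtype=float).reshape(-1)[mask]
            floor = max(1e-4, np.nanmedian(sd_arr[sd_arr > 0]) * 0.1) if np.any(sd_arr > 0) else 1e-4
            sigma = np.where(np.isfinite(sd_arr) & (sd_arr > 0), sd_arr, floor)

        if np.all(y == 0.0):
            # least-squares optimum is pinned at the k >= 0 boundary
            k_hat, se_k = 0.0, 0.0
            fitted = np.zeros_like(y)
            amplitude = amp
            flags.append("k_at_zero_boundary")
        else:
            k0 = self._initial_guess(t, y, amp, coeff)
            if self.amplitude_fixed:
                def f(tt, k):
                    return amp * -np.expm1(-coeff * k * self.C_total * tt)

                popt, pcov = curve_fit(
                    f, t, y, p0=[k0], sigma=sigma, absolute_sigma=False,
                    method="lm", maxfev=20000, xtol=1e-14, ftol=1e-14,
                )
                k_hat = float(popt[0])
                se_k = float(np.sqrt(max(pcov[0, 0], 0.0)))
                amplitude = amp
                fitted = f(t, k_hat)
            else:
                def f(tt, k, a):
                    return a * -np.expm1(-coeff * k * self.C_total * tt)

                popt, pcov = curve_fit(
                    f, t, y, p0=[k0, amp], sigma=sigma, absolute_sigma=False,
                    method="lm", maxfev=20000, xtol=1e-14, ftol=1e-14,
                )
                k_hat, amplitude = float(popt[0]), float(popt[1])
                se_k = float(np.sqrt(max(pcov[0, 0], 0.0)))
                fitted = f(t, k_hat, amplitude)
            if k_hat < 0:
                flags.append("k_negative_clamped")
                k_hat = 0.0
            if not np.all(np.isfinite([k_hat, se_k])):
                raise RuntimeError(
                    "rate fit did not converge: k is unidentified (measured "
                    "fractions sit at or above the model plateau; add earlier "
                    "time points or free the amplitude)"
                )

        self.k_ = k_hat
        self.k_se_ = se_k
        self.amplitude_ = amplitude
        self.exponent_coeff_ = coeff
        self.fit_result_ = RateFit(
            k_hat=k_hat, se_k=se_k, amplitude=amplitude, exponent_coeff=coeff,
            C_total=self.C_total, F=self.F, amplitude_fixed=self.amplitude_fixed,
            residuals=y - fitted, fitted=fitted, t_s=t, condition=condition,
            flags=flags,
        )
        return self

    def predict(self, X):
        """Model fractions at times ``X`` (seconds) using the fitted k."""
        if not hasattr(self, "k_"):
            raise RuntimeError("ExchangeRateModel is not fitted")
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.amplitude_ * -np.expm1(
            -self.exponent_coeff_ * self.k_ * self.C_total * t
        )

    @staticmethod
    def _initial_guess(t, y, amp, coeff):
        # invert the model at the first informative point; fall back to a
        # mid-range guess when every point is saturated or zero
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.clip(y / amp, 0.0, 0.95)
            ok = (frac > 0.01) & (t > 0)
            if np.any(ok):
                i = np.argmax(ok)
                return float(-np.log1p(-frac[i]) / (coeff * t[i]))
        return 100.0


def fit_rate_constant(
    time_s,
    fraction,
    sd=None,
    F: float = DEFAULT_F,
    C_total: float = DEFAULT_C_TOTAL,
    amplitude_fixed: bool = True,
    weighted: bool = False,
    condition: str = "",
) -> RateFit:
    """Functional wrapper over :class:`ExchangeRateModel`."""
    est = ExchangeRateModel(F=F, C_total=C_total,
                            amplitude_fixed=amplitude_fixed, weighted=weighted)
    est.fit(time_s, fraction, sd=sd, condition=condition)
    return est.fit_result_


def exchange_timescale(fit: RateFit, C_ref: float = DEFAULT_C_REF) -> ExchangeTimescale:
    """Characteristic exchange time 1/(k·C_ref) with propagated error.

    At a reference nucleosome concentration C_ref (default 70 μM, the
    nuclear density used for the in-vivo extrapolation), the mean time per
    exchange event is 1/(k·C_ref); its first-order standard error is
    (se_k/k)·t.
    """
    if C_ref <= 0:
        raise ValueError("C_ref must be positive")
    if fit.k_hat <= 0:
        return ExchangeTimescale(t_exchange=math.inf, se_t=math.inf, C_ref=C_ref)
    t = 1.0 / (fit.k_hat * C_ref)
    se_t = (fit.se_k / fit.k_hat) * t
    return ExchangeTimescale(t_exchange=t, se_t=se_t, C_ref=C_ref)


@dataclass
class RateComparison:
    difference: float
    sum_of_errors: float
    significant: bool


def compare_rates(fit1, fit2) -> RateComparison:
    """Difference-versus-sum-of-errors significance criterion.

    Accepts :class:`RateFit` objects or plain ``(k, se)`` pairs.  The
    difference |k1 − k2| is deemed statistically significant iff it exceeds
    se1 + se2.
    """
    k1, se1 = _as_k_se(fit1)
    k2, se2 = _as_k_se(fit2)
    diff = abs(k1 - k2)
    errsum = se1 + se2
    return RateComparison(difference=diff, sum_of_errors=errsum,
                          significant=bool(diff > errsum))


def _as_k_se(fit):
    if isinstance(fit, RateFit):
        return fit.k_hat, fit.se_k
    k, se = fit
    return float(k), float(se)
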