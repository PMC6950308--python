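"""Tight-binding inhibition kinetics.

When the inhibitor concentration is comparable to the enzyme concentration
the classical IC50/Langmuir treatment fails and the fractional activity
follows the quadratic tight-binding (Morrison) form

    v/v0 = 1 - [(E + I + Ki') - sqrt((E + I + Ki')^2 - 4 E I)] / (2 E)

with Ki' the apparent inhibition constant at the assay substrate load,
related to the true competitive constant by Ki = Ki' / (1 + S/Km).

`MorrisonKiModel` fits Ki' (and hence Ki) by least squares on v/v0 with
the active-site-titrated enzyme concentration held fixed; standard errors
come from the Jacobian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "InhibitionAssay",
    "KineticFit",
    "MorrisonKiModel",
    "MorrisonKiResults",
    "morrison_fraction",
    "ki_from_ki_app",
    "fit_ki",
    "residual_activity",
]


def morrison_fraction(E, I, Ki_app):
    """Fractional residual activity v/v0 under tight-binding inhibition.

    All concentrations in the same unit (nM here). Vectorised over I.
    """
    E = float(E)
    if E <= 0:
        raise ValueError("enzyme concentration must be > 0")
    if np.any(np.asarray(Ki_app) <= 0):
        raise ValueError("Ki_app must be > 0")
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("inhibitor concentrations must be >= 0")
    s = E + I + Ki_app
    disc = s * s - 4.0 * E * I
    frac = 1.0 - (s - np.sqrt(np.clip(disc, 0.0, None))) / (2.0 * E)
    frac = np.clip(frac, 0.0, 1.0)
    return float(frac) if frac.ndim == 0 else frac


def ki_from_ki_app(Ki_app: float, S: float, Km: float) -> float:
    """Correct the apparent constant for competitive substrate occupancy."""
    if Km <= 0:
        raise ValueError("Km must be > 0")
    return Ki_app / (1.0 + S / Km)


def residual_activity(rates, v0: float):
    """Rates as percentages of the uninhibited rate."""
    if v0 <= 0:
        raise ValueError("v0 must be > 0")
    return 100.0 * np.asarray(rates, dtype=float) / v0


@dataclass
class InhibitionAssay:
    """One dose-response table with its enzymological context.

    enzyme_nM is the active-site titrated enzyme concentration; substrate_uM
    and km_uM describe the chromogenic substrate used for the competitive
    correction; rates are raw hydrolysis rates (e.g. ΔOD405/min) measured at
    inhibitor_nM, with v0 the uninhibited rate.
    """

    enzyme_nM: float
    substrate_uM: float
    km_uM: float
    inhibitor_nM: np.ndarray
    rates: np.ndarray
    v0: float
    replicates: int = 1

    def __post_init__(self) -> None:
        self.inhibitor_nM = np.asarray(self.inhibitor_nM, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.inhibitor_nM.shape != self.rates.shape:
            raise ValueError("inhibitor_nM and rates must have the same length")
        if np.any(self.inhibitor_nM < 0):
            raise ValueError("inhibitor concentrations must be >= 0")
        if self.v0 <= 0:
            raise ValueError("v0 must be > 0")
        if self.enzyme_nM <= 0:
            raise ValueError("enzyme_nM must be > 0")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        enzyme_nM: float,
        substrate_uM: float,
        km_uM: float,
        v0: float | None = None,
        replicates: int = 1,
    ) -> "InhibitionAssay":
        """Build from a table with columns ``inhibitor_nM`` and ``rate``.

        If ``v0`` is omitted it is taken from the rate at zero inhibitor.
        """
        I = df["inhibitor_nM"].to_numpy(dtype=float)
        v = df["rate"].to_numpy(dtype=float)
        if v0 is None:
            zero = I == 0
            if not zero.any():
                raise ValueError("v0 not given and no zero-inhibitor row present")
            v0 = float(v[zero].mean())
        return cls(enzyme_nM, substrate_uM, km_uM, I, v, v0, replicates)


@dataclass
class KineticFit:
    """Fit result contract: Ki with its SE, the apparent constant, residuals."""

    Ki: float
    Ki_SE: float
    Ki_app: float
    Ki_app_SE: float
    residuals: np.ndarray
    converged: bool
    n_iter: int = 0


class MorrisonKiModel:
    """Tight-binding inhibition model for one dose-response assay.

    Parameters are fitted in log(Ki_app) to enforce positivity; the enzyme
    concentration stays fixed at the titrated value unless ``fit_enzyme``
    is requested.
    """

    def __init__(self, assay: InhibitionAssay, fit_enzyme: bool = False):
        self.assay = assay
        self.fit_enzyme = fit_enzyme

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **context) -> "MorrisonKiModel":
        return cls(InhibitionAssay.from_dataframe(df, **context))

    def _initial_ki_app(self) -> float:
        a = self.assay
        frac = a.rates / a.v0
        # at half-maximal inhibition I50 = Ki_app + E/2
        i_half = a.inhibitor_nM[np.argmin(np.abs(frac - 0.5))]
        guess = i_half - a.enzyme_nM / 2.0
        if guess <= 0:
            pos = a.inhibitor_nM[a.inhibitor_nM > 0]
            guess = float(np.median(pos)) if pos.size else 1.0
        return float(guess)

    def fit(self) -> "MorrisonKiResults":
        a = self.assay
        if np.unique(a.inhibitor_nM).size < 5:
            raise ValueError("need >= 5 distinct inhibitor concentrations")
        if np.allclose(a.rates, 0):
            raise ValueError("all rates are zero; nothing to fit")
        y = a.rates / a.v0

        if self.fit_enzyme:
            def resid(theta):
                return morrison_fraction(np.exp(theta[1]), a.inhibitor_nM,
                                         np.exp(theta[0])) - y
            x0 = [np.log(self._initial_ki_app()), np.log(a.enzyme_nM)]
        else:
            def resid(theta):
                return morrison_fraction(a.enzyme_nM, a.inhibitor_nM,
                                         np.exp(theta[0])) - y
            x0 = [np.log(self._initial_ki_app())]

        sol = least_squares(resid, x0, xtol=1e-12, ftol=1e-12, gtol=1e-12,
                            max_nfev=500)
        log_ki_app = sol.x[0]
        ki_app = float(np.exp(log_ki_app))
        n, p = y.size, sol.x.size
        dof = max(n - p, 1)
        ssr = float(sol.fun @ sol.fun)
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * ssr / dof
            log_se = float(np.sqrt(max(cov[0, 0], 0.0)))
        except np.linalg.LinAlgError:
            log_se = np.nan
        ki_app_se = ki_app * log_se  # delta method from the log scale
        corr = 1.0 + a.substrate_uM / a.km_uM
        fit = KineticFit(
            Ki=ki_app / corr,
            Ki_SE=ki_app_se / corr,
            Ki_app=ki_app,
            Ki_app_SE=ki_app_se,
            residuals=sol.fun,
            converged=bool(sol.success),
            n_iter=int(sol.nfev),
        )
        return MorrisonKiResults(self, fit)


@dataclass
class MorrisonKiResults:
    """Estimates, uncertainties and diagnostics of a tight-binding fit."""

    model: MorrisonKiModel
    fit: KineticFit

    @property
    def ki(self) -> float:
        return self.fit.Ki

    @property
    def ki_se(self) -> float:
        return self.fit.Ki_SE

    @property
    def ki_app(self) -> float:
        return self.fit.Ki_app

    @property
    def converged(self) -> bool:
        return self.fit.converged

    def conf_int(self, nsig: float = 2.0) -> tuple[float, float]:
        return self.ki - nsig * self.ki_se, self.ki + nsig * self.ki_se

    def predict(self, inhibitor_nM=None):
        a = self.model.assay
        I = a.inhibitor_nM if inhibitor_nM is None else inhibitor_nM
        return morrison_fraction(a.enzyme_nM, I, self.fit.Ki_app)

    @property
    def resid(self) -> np.ndarray:
        return self.fit.residuals

    def summary(self) -> str:
        a = self.model.assay
        lines = [
            "Morrison tight-binding inhibition fit",
            "=" * 45,
            f"observations:        {a.rates.size}",
            f"enzyme (fixed):      {a.enzyme_nM:g} nM",
            f"substrate / Km:      {a.substrate_uM:g} / {a.km_uM:g} uM",
            f"converged:           {self.fit.converged}",
            f"Ki_app:              {self.fit.Ki_app:.4g} +/- {self.fit.Ki_app_SE:.2g} nM",
            f"Ki:                  {self.fit.Ki:.4g} +/- {self.fit.Ki_SE:.2g} nM",
            f"residual SD (v/v0):  {np.std(self.fit.residuals):.3g}",
        ]
        return "\n".join(lines)


def fit_ki(assay: InhibitionAssay, fit_enzyme: bool = False) -> KineticFit:
    """Functional wrapper around :class:`MorrisonKiModel`."""
    return MorrisonKiModel(assay, fit_enzyme=fit_enzyme).fit().fit
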