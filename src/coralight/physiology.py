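"""Photosynthesis and growth analysis from microsensor and count data.

* Diffusive O2 flux through the diffusive boundary layer (DBL) via Fick's
  first law, J = -D dC/dz, with automatic selection of the linear DBL
  window.
* Gross photosynthesis by the light-dark shift method: the initial slope of
  the O2 decline immediately after darkening.
* Photosynthesis-irradiance (PI) curves fitted to the saturating
  exponential P = Pmax (1 - exp(-E/Ek)).
* Fluence-rate depth profiles normalized to the incident downwelling
  irradiance E_d.
* Logistic growth fits with delta-method 95% confidence and prediction
  bands (computed on log densities, matching multiplicative replicate
  scatter).

Units follow microsensor practice: depths in um, concentrations in
umol L^-1, D in cm^2 s^-1, fluxes in nmol O2 cm^-2 s^-1, irradiance in
umol photons m^-2 s^-1, cell densities in cells mL^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phantoms import D_O2_CM2_S, GrowthSeries, O2ProfileData

__all__ = [
    "FluxEstimate",
    "PIFit",
    "FluenceProfile",
    "GrowthFit",
    "diffusive_flux",
    "gross_photosynthesis",
    "fit_pi_curve",
    "normalize_fluence",
    "fit_growth",
]

#: (umol L^-1 um^-1) -> (nmol cm^-4): 1 umol/L = 1 nmol/cm^3; 1 um = 1e-4 cm
_SLOPE_TO_NMOL_CM4 = 1.0e4


@dataclass
class FluxEstimate:
    """Diffusive O2 flux; positive J means O2 leaving the surface."""

    J: float  # nmol O2 cm^-2 s^-1
    D: float  # cm^2 s^-1
    slope: float  # dC/dz on the depth axis, umol L^-1 um^-1
    slope_err: float
    J_err: float
    window_um: Tuple[float, float]  # depth bounds of the linear region used
    r_squared: float


@dataclass
class PIFit:
    Pmax: float
    Ek: float  # umol photons m^-2 s^-1
    covariance: np.ndarray
    residuals: np.ndarray

    def predict(self, E) -> np.ndarray:
        return self.Pmax * (1.0 - np.exp(-np.asarray(E, dtype=float) / self.Ek))


@dataclass
class FluenceProfile:
    """Scalar irradiance E_0 vs depth, in % of incident downwelling E_d."""

    depth_um: np.ndarray
    e0_percent: np.ndarray
    wavelength: float = float("nan")

    def at_depth(self, depth_um: float) -> float:
        return float(np.interp(depth_um, self.depth_um, self.e0_percent))

    def fold_change_at(self, other: "FluenceProfile", depth_um: float) -> float:
        """Ratio of this profile's E_0 to another's at the given depth."""
        return self.at_depth(depth_um) / other.at_depth(depth_um)


@dataclass
class GrowthFit:
    r: float  # day^-1
    K: float  # cells/mL
    N0: float
    covariance: np.ndarray  # on (log K, r, log N0)
    sigma_log: float  # residual SD of log densities
    dof: int

    def predict(self, day) -> np.ndarray:
        t = np.asarray(day, dtype=float)
        return self.K / (1.0 + ((self.K - self.N0) / self.N0) * np.exp(-self.r * t))

    def _band(self, day, prediction: bool) -> Tuple[np.ndarray, np.ndarray]:
        t = np.atleast_1d(np.asarray(day, dtype=float))
        lk, r, ln0 = math.log(self.K), self.r, math.log(self.N0)
        # gradient of log N(t) wrt (log K, r, log N0), numerically
        def logn(p, tt):
            K, rr, N0 = math.exp(p[0]), p[1], math.exp(p[2])
            return np.log(
                np.maximum(K / (1.0 + ((K - N0) / N0) * np.exp(-rr * tt)), 1e-300)
            )

        p = np.array([lk, r, ln0])
        grads = np.empty((t.size, 3))
        for j in range(3):
            h = 1e-6 * max(1.0, abs(p[j]))
            pp = p.copy()
            pm = p.copy()
            pp[j] += h
            pm[j] -= h
            grads[:, j] = (logn(pp, t) - logn(pm, t)) / (2 * h)
        var = np.einsum("ij,jk,ik->i", grads, self.covariance, grads)
        if prediction:
            var = var + self.sigma_log**2
        tq = stats.t.ppf(0.975, self.dof) if self.dof > 0 else 1.96
        mid = np.log(self.predict(t))
        lo = np.exp(mid - tq * np.sqrt(var))
        hi = np.exp(mid + tq * np.sqrt(var))
        return lo, hi

    def confidence_band(self, day) -> Tuple[np.ndarray, np.ndarray]:
        """95% confidence band for the mean trajectory (cells/mL)."""
        return self._band(day, prediction=False)

    def prediction_band(self, day) -> Tuple[np.ndarray, np.ndarray]:
        """95% prediction band for a new replicate observation."""
        return self._band(day, prediction=True)


# --------------------------------------------------------------------------


def diffusive_flux(
    profile: O2ProfileData,
    D: float = D_O2_CM2_S,
    window_um: Optional[Tuple[float, float]] = None,
    min_points: int = 3,
    r2_threshold: float = 0.95,
) -> FluxEstimate:
    """O2 flux across the DBL from the linear part of a depth profile.

    The slope dC/dz is estimated by linear regression over the DBL window:
    either user-specified depth bounds, or the maximal-R^2 window among the
    contiguous windows of at least ``min_points`` points that end at the
    surface-most measurement (depth <= 0) — the DBL gradient region is by
    definition anchored at the surface.  Flux is J = -D dC/dz converted to
    nmol O2 cm^-2 s^-1; a flat profile returns J = 0.
    """
    depth = np.asarray(profile.depth_um, dtype=float)
    conc = np.asarray(profile.conc_umol_l, dtype=float)
    if np.any(np.diff(depth) <= 0):
        raise ValueError("depths must be strictly increasing")
    if window_um is not None:
        sel = (depth >= window_um[0]) & (depth <= window_um[1])
        idx = np.flatnonzero(sel)
        if idx.size < min_points:
            raise ValueError("user window contains fewer than min_points points")
        windows = [(idx[0], idx[-1] + 1)]
    else:
        upper = np.flatnonzero(depth <= 0)
        if upper.size < min_points:
            raise ValueError("need at least 3 points at or above the surface")
        i_max = upper[-1] + 1
        # the DBL gradient region is anchored at the surface: candidate
        # windows all end at the surface-most point and extend upward
        windows = [(i, i_max) for i in range(0, i_max - min_points + 1)]

    scale = float(np.max(np.abs(conc))) or 1.0
    best = None
    for i, j in windows:
        x = depth[i:j]
        y = conc[i:j]
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot <= (1e-12 * scale) ** 2 * y.size:
            r2 = 1.0  # flat profile: perfectly linear with zero slope
        else:
            r2 = 1.0 - ss_res / ss_tot
        key = (r2, j - i)
        if best is None or key > best[0]:
            dof = j - i - 2
            sxx = float(np.sum((x - x.mean()) ** 2))
            se = math.sqrt(ss_res / dof / sxx) if dof > 0 and sxx > 0 else 0.0
            best = (key, slope, se, (float(x[0]), float(x[-1])), r2)
    assert best is not None
    _, slope, se, bounds, r2 = best
    if window_um is None and r2 < r2_threshold:
        raise ValueError(
            f"no DBL window reached R^2 >= {r2_threshold}; best window "
            f"{bounds} um had R^2 = {r2:.3f}"
        )
    J = -D * _SLOPE_TO_NMOL_CM4 * slope
    return FluxEstimate(
        J=float(J),
        D=D,
        slope=float(slope),
        slope_err=float(se),
        J_err=float(D * _SLOPE_TO_NMOL_CM4 * se),
        window_um=bounds,
        r_squared=float(r2),
    )


def gross_photosynthesis(
    time_s: np.ndarray,
    conc: np.ndarray,
    darkening_time: float,
    window_s: float = 1.0,
) -> Tuple[float, float]:
    """Gross photosynthesis by the light-dark shift method.

    Fits a line to the O2 trace over ``[darkening_time, darkening_time +
    window_s]`` and returns ``(rate, rate_err)`` with rate = -slope: the
    initial O2 depletion rate right after darkening equals the gross
    photosynthesis rate at that point.  Units follow the trace (conc units
    per second).
    """
    time_s = np.asarray(time_s, dtype=float)
    conc = np.asarray(conc, dtype=float)
    t_end = darkening_time + window_s
    if darkening_time < time_s[0] or t_end > time_s[-1]:
        raise ValueError("slope window extends beyond the recorded trace")
    sel = (time_s >= darkening_time) & (time_s <= t_end)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 samples in the slope window")
    x = time_s[sel]
    y = conc[sel]
    slope, intercept = np.polyfit(x, y, 1)
    dof = x.size - 2
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    sxx = float(np.sum((x - x.mean()) ** 2))
    se = math.sqrt(ss_res / dof / sxx) if dof > 0 and sxx > 0 else 0.0
    return float(-slope), float(se)


def fit_pi_curve(rates: Sequence[float], irradiances: Sequence[float]) -> PIFit:
    """Fit the saturating exponential P = Pmax (1 - exp(-E / Ek)).

    At E = Ek the modelled rate is Pmax (1 - 1/e) ~= 0.632 Pmax.  Requires
    at least 3 distinct irradiance levels including a near-zero one.
    """
    P = np.asarray(rates, dtype=float)
    E = np.asarray(irradiances, dtype=float)
    if P.shape != E.shape:
        raise ValueError("rates and irradiances must have equal length")
    levels = np.unique(E)
    if levels.size < 3:
        raise ValueError("need at least 3 distinct irradiance levels")
    if levels.min() > 0.05 * levels.max():
        raise ValueError("need a near-zero (dark) irradiance level")

    def model(e, pmax, ek):
        return pmax * (1.0 - np.exp(-e / ek))

    p0 = (float(np.max(P)) if np.max(P) > 0 else 1.0, float(np.mean(levels[levels > 0])) / 3)
    try:
        popt, pcov = optimize.curve_fit(
            model, E, P, p0=p0, bounds=([1e-12, 1e-9], [np.inf, np.inf]), maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"PI fit did not converge (initial guess Pmax={p0[0]:.3g}, "
            f"Ek={p0[1]:.3g})"
        ) from exc
    resid = P - model(E, *popt)
    return PIFit(Pmax=float(popt[0]), Ek=float(popt[1]), covariance=pcov, residuals=resid)


def normalize_fluence(
    depth_um: np.ndarray,
    raw: np.ndarray,
    e_d_reference: float,
    wavelength: float = float("nan"),
) -> FluenceProfile:
    """Express a raw scalar-irradiance profile as % of incident E_d.

    ``e_d_reference`` is the downwelling irradiance measured with the same
    sensor over a black light well.
    """
    if not e_d_reference > 0:
        raise ValueError("E_d reference must be positive")
    raw = np.asarray(raw, dtype=float)
    return FluenceProfile(
        depth_um=np.asarray(depth_um, dtype=float),
        e0_percent=100.0 * raw / e_d_reference,
        wavelength=wavelength,
    )


def fit_growth(series: GrowthSeries) -> GrowthFit:
    """Fit logistic growth to replicated cell counts (on log densities).

    N(t) = K / (1 + ((K - N0)/N0) exp(-r t)); the fit minimizes residuals
    of log N, consistent with multiplicative replicate scatter, and the
    delta-method bands in :class:`GrowthFit` are computed on the log scale.
    """
    t = np.asarray(series.day, dtype=float)
    y = np.asarray(series.cells_per_ml, dtype=float)
    if np.unique(t).size < 4:
        raise ValueError("need at least 4 distinct time points")
    if np.any(y <= 0):
        raise ValueError("cell densities must be positive")
    logy = np.log(y)

    def model(tt, log_k, r, log_n0):
        K = np.exp(log_k)
        N0 = np.exp(log_n0)
        # clip guards transient K < N0 iterates from producing NaN logs
        return np.log(np.maximum(K / (1.0 + ((K - N0) / N0) * np.exp(-r * tt)), 1e-300))

    n0_guess = max(float(np.exp(logy[t == t.min()].mean())), 1e-3)
    k_guess = max(float(np.exp(logy[t == t.max()].mean())), n0_guess * 2)
    p0 = (math.log(k_guess), 0.5, math.log(n0_guess))
    popt, pcov = optimize.curve_fit(model, t, logy, p0=p0, maxfev=40000)
    K = float(math.exp(popt[0]))
    N0 = float(math.exp(popt[2]))
    r = float(popt[1])
    if not K > N0 > 0 or r < 0:
        import warnings

        warnings.warn("degenerate growth fit (no growth signal)", stacklevel=2)
    resid = logy - model(t, *popt)
    dof = max(t.size - 3, 1)
    sigma_log = float(np.sqrt(np.sum(resid**2) / dof))
    return GrowthFit(
        r=r, K=K, N0=N0, covariance=pcov, sigma_log=sigma_log, dof=dof
    )
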