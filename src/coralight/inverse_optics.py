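"""Inverse estimation of optical properties from transmission measurements.

Three measurement regimes are covered:

* **Diffusive** (multiply scattering skeleton material): total transmittance
  vs slab thickness follows the diffusion approximation with extrapolated
  boundary conditions.  The angular distribution of transmitted light fixes
  the extrapolation length ``z_e``; total-transmission data then yield the
  absorption length ``l_a`` and the transport mean free path ``l_t``.
* **Ballistic / weakly scattering** (printed tissue): the diffusion
  approximation does not apply and the extinction coefficient is obtained
  from the Beer-Lambert law.
* **Brewster refractometry**: the refractive index follows from the angle of
  vanishing p-polarized reflectance, ``n2 = n1 * tan(theta_B)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "TransmissionSeries",
    "AngularScan",
    "DiffusionFit",
    "RefractiveIndexEstimate",
    "ExtinctionFit",
    "p_mu",
    "fit_extrapolation_length",
    "diffusion_transmission",
    "fit_diffusion",
    "fit_beer_lambert",
    "brewster_index",
    "find_brewster",
]


@dataclass
class TransmissionSeries:
    """Total transmittance vs sample thickness (integrating-sphere data)."""

    L: np.ndarray  # thickness, mm, sorted ascending
    T: np.ndarray  # total transmittance in (0, 1]
    wavelength: float = float("nan")  # nm
    sigma: Optional[np.ndarray] = None  # per-point uncertainty on T

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.L.ndim != 1 or self.L.shape != self.T.shape:
            raise ValueError("L and T must be 1D arrays of equal length")
        if np.any(self.L <= 0):
            raise ValueError("thicknesses must be strictly positive")
        if np.any(np.diff(self.L) < 0):
            order = np.argsort(self.L)
            self.L = self.L[order]
            self.T = self.T[order]
            if self.sigma is not None:
                self.sigma = np.asarray(self.sigma, dtype=float)[order]
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        data = {"L_mm": self.L, "T": self.T}
        if self.sigma is not None:
            data["sigma"] = self.sigma
        return pd.DataFrame(data)

    @classmethod
    def from_csv(cls, path) -> "TransmissionSeries":
        df = pd.read_csv(path)
        return cls(
            L=df["L_mm"].to_numpy(),
            T=df["T"].to_numpy(),
            sigma=df["sigma"].to_numpy() if "sigma" in df else None,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class AngularScan:
    """Angular distribution of light vs detection angle (goniometer scan).

    ``theta`` is the signed detection angle in degrees; ``intensity`` is
    normalized so its maximum equals 1.
    """

    theta: np.ndarray  # degrees
    intensity: np.ndarray
    wavelength: float = float("nan")
    sigma: Optional[np.ndarray] = None  # per-point uncertainty on intensity

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.theta.shape != self.intensity.shape or self.theta.ndim != 1:
            raise ValueError("theta and intensity must be 1D arrays of equal length")
        m = np.nanmax(self.intensity)
        if m > 0:
            self.intensity = self.intensity / m
            if self.sigma is not None:
                self.sigma = np.asarray(self.sigma, dtype=float) / m

    @property
    def mu(self) -> np.ndarray:
        """Cosine of the detection angle."""
        return np.cos(np.radians(self.theta))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"theta_deg": self.theta, "intensity": self.intensity})

    @classmethod
    def from_csv(cls, path) -> "AngularScan":
        df = pd.read_csv(path)
        return cls(theta=df["theta_deg"].to_numpy(), intensity=df["intensity"].to_numpy())

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class DiffusionFit:
    l_a: float  # absorption length, mm
    l_t: float  # transport mean free path, mm
    z_e: float  # extrapolation length, dimensionless
    l_a_err: float = float("nan")
    l_t_err: float = float("nan")
    z_e_err: float = float("nan")
    n_iterations: int = 0
    converged: bool = False


@dataclass
class RefractiveIndexEstimate:
    theta_B: float  # Brewster angle, degrees
    n: float  # index of the dense medium (n2)
    n_ambient: float = 1.0  # index of the surrounding medium (n1)
    theta_B_err: float = float("nan")


@dataclass
class ExtinctionFit:
    mu_ext: float  # extinction coefficient, mm^-1
    intercept: float
    r_squared: float
    mu_ext_err: float = float("nan")


def p_mu(mu, z_e: float):
    """Angular transmittance of a diffusive slab.

    P(mu) = mu (z_e + mu) / (z_e/2 + 1/3), where mu is the cosine of the
    transmission angle relative to the incident ballistic beam.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or np.any(mu > 1):
        raise ValueError("mu must lie in (0, 1]")
    if not z_e > 0:
        raise ValueError("z_e must be positive")
    out = mu * (z_e + mu) / (0.5 * z_e + 1.0 / 3.0)
    return float(out) if out.ndim == 0 else out


def fit_extrapolation_length(
    scan: AngularScan, mu_min: float = 0.17, mu_max: float = 0.9998
):
    """Least-squares fit of a * P(mu; z_e) to an angular scan.

    The overall scale ``a`` is free, so the estimate is invariant under any
    positive rescaling of the intensities.  Per-point uncertainties on the
    scan, when present, weight the fit.

    Two angular cuts are applied by default.  Angles within ~1 degree of
    the ballistic axis are excluded (``mu_max``): any unscattered residual
    beam concentrates there and does not belong to the diffuse model.
    Angles beyond ~80 degrees are excluded (``mu_min`` = cos 80 deg):
    grazing exit angles are where the diffusion boundary treatment is least
    accurate (exact transport falls below the linear-in-mu radiance) and
    where goniometer scans are cut off in practice.

    Returns ``(z_e, z_e_err)``.
    """
    mu = scan.mu
    keep = (mu > mu_min) & (mu <= mu_max)
    mu_f = mu[keep]
    y = scan.intensity[keep]
    if mu_f.size < 10:
        raise ValueError("need at least 10 angular points with mu > mu_min")
    if np.ptp(np.abs(scan.theta[keep])) < 60:
        raise ValueError("scan must span at least 60 degrees of the forward hemisphere")
    sigma = None
    if scan.sigma is not None:
        sigma = np.clip(scan.sigma[keep], np.max(scan.sigma[keep]) * 1e-3, None)

    def model(m, a, z_e):
        return a * m * (z_e + m) / (0.5 * z_e + 1.0 / 3.0)

    p0 = (float(np.max(y)) / 2.5, 1.0)
    popt, pcov = optimize.curve_fit(
        model,
        mu_f,
        y,
        p0=p0,
        sigma=sigma,
        bounds=([0.0, 1e-6], [np.inf, 100.0]),
        maxfev=10000,
    )
    z_e = float(popt[1])
    z_e_err = float(np.sqrt(pcov[1, 1]))
    return z_e, z_e_err


def diffusion_transmission(L, l_a: float, l_t: float, z_e: float, as_printed: bool = False):
    """Total transmittance of a diffusive slab of thickness ``L`` (mm).

    Default mode evaluates the diffusive-slab solution with extrapolated
    boundaries: an isotropic source at depth ``l_t``, zero photon density at
    the extrapolated planes ``-z_e*l_t`` and ``L + z_e*l_t``, and diffusive
    attenuation over the absorption scale ``L_alpha = sqrt(l_a*l_t/3)``:

        T = sinh(k*(l_t + z_e*l_t)) * cosh(k*z_e*l_t) / sinh(k*(L + 2*z_e*l_t))

    with k = 1/L_alpha.  In the absorption-free limit this reduces to
    ``(l_t + z_e*l_t) / (L + 2*z_e*l_t)``.

    ``as_printed=True`` switches to a literal transcription of the published
    closed form (which carries a 1/l_a prefactor and a squared sinh in the
    numerator); it is retained for transparency but is not used by the
    fitting routines.
    """
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0) or l_a <= 0 or l_t <= 0 or z_e <= 0:
        raise ValueError("all lengths must be positive")
    if np.any(L < 3 * l_t):
        warnings.warn(
            "slab thinner than ~3 transport mean free paths: diffusion "
            "approximation is unreliable",
            stacklevel=2,
        )
    ze_mm = z_e * l_t
    if as_printed:
        out = (1.0 / l_a) * np.sinh(ze_mm / l_a) ** 2 / np.sinh((L + ze_mm) / l_a)
        return float(out) if out.ndim == 0 else out
    k = math.sqrt(3.0 / (l_a * l_t))  # 1 / L_alpha
    # guard the deep-absorption regime against overflow by using exp forms
    arg_num = k * (l_t + ze_mm)
    arg_cosh = k * ze_mm
    arg_den = k * (L + 2.0 * ze_mm)
    if np.any(np.asarray(arg_den) > 700):
        # asymptotic ratio sinh(a)cosh(b)/sinh(c) ~ exp(a+b-c)/2
        out = 0.5 * np.exp(arg_num + arg_cosh - arg_den) * (1 - np.exp(-2 * arg_num)) * (
            1 + np.exp(-2 * arg_cosh)
        )
    else:
        out = np.sinh(arg_num) * np.cosh(arg_cosh) / np.sinh(arg_den)
    return float(out) if np.ndim(out) == 0 else out


def fit_diffusion(
    series: TransmissionSeries,
    scan: AngularScan,
    tol: float = 0.01,
    max_iter: int = 50,
) -> DiffusionFit:
    """Estimate (l_a, l_t) from transmission-vs-thickness at measured z_e.

    Step 1 estimates the extrapolation length from the angular scan; step 2
    fits the diffusive-slab transmission over (l_a, l_t) at fixed z_e; the
    fit is then repeated from the previous optimum until successive
    estimates change by less than ``tol`` (an explicit stability iteration).
    """
    if series.L.size < 4:
        raise ValueError("need at least 4 thicknesses for a diffusion fit")
    z_e, z_e_err = fit_extrapolation_length(scan)
    sigma = series.sigma

    def model(L, log_la, log_lt):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return diffusion_transmission(L, math.exp(log_la), math.exp(log_lt), z_e)

    # initial guesses: l_t from the thinnest sample's transmittance in the
    # absorption-free limit, l_a generously large
    T0 = float(series.T[0])
    L0 = float(series.L[0])
    lt0 = max(T0 * L0 / max(1e-9, (1 + z_e) - 2 * z_e * T0), 1e-3)
    p = np.array([math.log(50.0 * series.L.max()), math.log(lt0)])
    n_it = 0
    converged = False
    pcov = np.full((2, 2), np.nan)
    for n_it in range(1, max_iter + 1):
        try:
            popt, pcov = optimize.curve_fit(
                model,
                series.L,
                series.T,
                p0=p,
                sigma=sigma,
                absolute_sigma=sigma is not None,
                maxfev=20000,
            )
        except RuntimeError:
            break
        rel = np.max(np.abs(np.exp(popt) - np.exp(p)) / np.exp(popt))
        p = popt
        if rel < tol:
            converged = True
            break
    l_a = float(math.exp(p[0]))
    l_t = float(math.exp(p[1]))
    # delta method for standard errors of exp(log-parameters)
    l_a_err = float(l_a * math.sqrt(abs(pcov[0, 0]))) if np.isfinite(pcov[0, 0]) else float("nan")
    l_t_err = float(l_t * math.sqrt(abs(pcov[1, 1]))) if np.isfinite(pcov[1, 1]) else float("nan")
    return DiffusionFit(
        l_a=l_a,
        l_t=l_t,
        z_e=z_e,
        l_a_err=l_a_err,
        l_t_err=l_t_err,
        z_e_err=z_e_err,
        n_iterations=n_it,
        converged=converged,
    )


def fit_beer_lambert(series: TransmissionSeries) -> ExtinctionFit:
    """Extinction coefficient from -ln(T) vs L (weakly scattering regime)."""
    if series.L.size < 3:
        raise ValueError("need at least 3 thicknesses")
    if np.any(series.T <= 0):
        raise ValueError("transmittance must be positive")
    y = -np.log(series.T)
    res = np.polynomial.polynomial.polyfit(series.L, y, 1, full=True)
    intercept, slope = res[0]
    yhat = intercept + slope * series.L
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = series.L.size - 2
    if dof > 0:
        sxx = float(np.sum((series.L - series.L.mean()) ** 2))
        se = math.sqrt(ss_res / dof / sxx) if sxx > 0 else float("nan")
    else:
        se = float("nan")
    return ExtinctionFit(
        mu_ext=float(slope), intercept=float(intercept), r_squared=r2, mu_ext_err=se
    )


def brewster_index(theta_B: float, n_ambient: float = 1.0) -> RefractiveIndexEstimate:
    """Refractive index from the Brewster angle: n2 = n1 * tan(theta_B)."""
    if not 0.0 < theta_B < 90.0:
        raise ValueError("Brewster angle must lie in (0, 90) degrees")
    n = n_ambient * math.tan(math.radians(theta_B))
    return RefractiveIndexEstimate(theta_B=float(theta_B), n=float(n), n_ambient=n_ambient)


def find_brewster(scan: AngularScan) -> RefractiveIndexEstimate:
    """Locate the p-polarized reflectance minimum by parabolic interpolation.

    The scan must bracket the minimum (it may not sit on either edge).
    Returns the interpolated Brewster angle, its half-width estimate and the
    implied refractive index against ambient index 1.
    """
    theta = scan.theta
    y = scan.intensity
    i = int(np.argmin(y))
    if i == 0 or i == theta.size - 1:
        raise ValueError("reflectance minimum lies on the scan edge; widen the scan")
    # parabola through the three points around the minimum
    x0, x1, x2 = theta[i - 1], theta[i], theta[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0) + x0 * x0 * (y1 - y2)) / denom
    if a <= 0:
        theta_b = float(x1)
        half_width = float(abs(x2 - x0))
    else:
        theta_b = float(-b / (2 * a))
        half_width = float(math.sqrt(max(y1, 1e-12) / a)) if a > 0 else float("nan")
    est = brewster_index(theta_b)
    est.theta_B_err = half_width
    return est
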