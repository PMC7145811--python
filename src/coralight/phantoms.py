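"""Synthetic datasets with known ground truth for every pipeline stage.

Each generator emulates one measurement the package analyses — integrating
sphere transmission series, goniometer angular scans (diffuse transmission
and Brewster reflectance), OCT-like corallite volumes, confocal-like
aggregate stacks, O2 microprofiles, photosynthesis-irradiance tables and
growth series — and attaches the exact parameters used (:class:`GroundTruth`)
so that inverse routines can be validated by round trip.  The fitting code
never reads the ground truth.

Noise model: multiplicative Gaussian on optical intensities and image data
(photon-counting-dominated detectors), additive-on-log (i.e. multiplicative)
replicate scatter on cell densities, additive Gaussian on O2 concentrations.
All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .inverse_optics import AngularScan, TransmissionSeries, diffusion_transmission, p_mu
from .oct_pipeline import ImageVolume

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "GrowthSeries",
    "O2ProfileData",
    "make_corallite_volume",
    "make_transmission_series",
    "make_angular_scan",
    "make_brewster_scan",
    "make_o2_profile",
    "make_pi_data",
    "make_growth_series",
    "make_aggregate_stack",
    "D_O2_CM2_S",
]

#: molecular diffusion coefficient for O2 at 25 degC, salinity 30, cm^2/s
D_O2_CM2_S = 2.255e-5

#: OCT acquisition resolution: z 4.5 um, x-y 8 um
OCT_SPACING_UM = (4.5, 8.0, 8.0)


@dataclass(frozen=True)
class PhantomConfig:
    """Shared generator settings.

    ``grid_spacing`` is (z, y, x) voxel pitch in micrometres for image
    phantoms; ``noise_rel`` is the relative noise amplitude (0 disables all
    noise, making every generator analytically exact).
    """

    seed: int = 0
    noise_rel: float = 0.02
    grid_spacing: Tuple[float, float, float] = OCT_SPACING_UM
    wavelength: float = 550.0  # nm

    def __post_init__(self) -> None:
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """True parameters attached to a generated dataset (never fitted on)."""

    params: Dict[str, float | list]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.params, fh, indent=1, default=float)

    def __getitem__(self, key: str):
        return self.params[key]


@dataclass
class GrowthSeries:
    """Replicated cell-density counts over time."""

    day: np.ndarray  # one entry per observation
    replicate: np.ndarray
    cells_per_ml: np.ndarray
    truth: Optional[GroundTruth] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.day,
                "replicate": self.replicate,
                "cells_per_mL": self.cells_per_ml,
            }
        )


@dataclass
class O2ProfileData:
    """O2 concentration vs depth (um; negative above the sample surface)."""

    depth_um: np.ndarray
    conc_umol_l: np.ndarray
    temperature_c: float = 25.0
    salinity: float = 30.0
    truth: Optional[GroundTruth] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"depth_um": self.depth_um, "conc_umolL": self.conc_umol_l})


# --------------------------------------------------------------------------
# image phantoms


def make_corallite_volume(
    config: PhantomConfig,
    cup_diameter_um: float = 1000.0,
    cup_depth_um: float = 1000.0,
    wall_um: float = 150.0,
    n_tentacles: int = 8,
    tentacle_diameter_um: float = 200.0,
    tentacle_length_um: float = 1000.0,
    fg_value: int = 30000,
    bg_value: int = 500,
) -> ImageVolume:
    """16-bit volume of a corallite-like cup with radial tentacle cylinders.

    The cup is a hemispherical shell (default 1 mm diameter and depth, as in
    the printed skeleton's functional unit) opening toward z = 0; cylinders
    of 200 um diameter and 1 mm length stand on its rim, mimicking the
    tissue tentacles.  Speckle-like multiplicative noise is applied when
    ``noise_rel > 0``; at zero noise the volume contains exactly two
    intensity levels.
    """
    dz, dy, dx = config.grid_spacing
    max_spacing = tentacle_diameter_um / 8.0
    if max(dz, dy, dx) > max_spacing:
        raise ValueError(
            f"grid spacing {config.grid_spacing} um too coarse to resolve "
            f"{tentacle_diameter_um} um tentacles; need <= {max_spacing} um"
        )
    R = cup_diameter_um / 2.0
    depth_total = tentacle_length_um + cup_depth_um
    nz = int(round(depth_total / dz)) + 2
    ny = int(round((cup_diameter_um + 2 * dy) / dy))
    nx = int(round((cup_diameter_um + 2 * dx) / dx))
    zc = (np.arange(nz) + 0.5) * dz
    yc = ((np.arange(ny) + 0.5) - ny / 2.0) * dy
    xc = ((np.arange(nx) + 0.5) - nx / 2.0) * dx
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")

    fg = np.zeros((nz, ny, nx), dtype=bool)

    # cup shell: semi-ellipsoidal bowl (radius R in xy, cup_depth_um along
    # z) opening upward, with a wall of finite thickness
    z_rim = tentacle_length_um
    rho_out = np.sqrt(
        ((Z - z_rim) / cup_depth_um) ** 2 + (Y**2 + X**2) / R**2
    )
    rho_in = np.sqrt(
        ((Z - z_rim) / max(cup_depth_um - wall_um, 1.0)) ** 2
        + (Y**2 + X**2) / max(R - wall_um, 1.0) ** 2
    )
    fg |= (rho_out <= 1.0) & (rho_in >= 1.0) & (Z >= z_rim)

    # tentacles: vertical cylinders on the rim circle (inset so the xy
    # footprint stays within the cup diameter)
    r_t = tentacle_diameter_um / 2.0
    ring = R - r_t - wall_um / 2.0
    for k in range(n_tentacles):
        phi = 2 * math.pi * k / n_tentacles
        cx = ring * math.cos(phi)
        cy = ring * math.sin(phi)
        cyl = ((X - cx) ** 2 + (Y - cy) ** 2 <= r_t**2) & (Z < z_rim)
        fg |= cyl

    vol = np.where(fg, float(fg_value), float(bg_value))
    if config.noise_rel > 0:
        rng = config.rng()
        vol = vol * (1.0 + config.noise_rel * rng.standard_normal(vol.shape))
    vol = np.clip(np.rint(vol), 0, 65535).astype(np.uint16)
    truth = GroundTruth(
        {
            "cup_diameter_um": cup_diameter_um,
            "cup_depth_um": cup_depth_um,
            "wall_um": wall_um,
            "n_tentacles": n_tentacles,
            "tentacle_diameter_um": tentacle_diameter_um,
            "tentacle_length_um": tentacle_length_um,
            "fg_value": fg_value,
            "bg_value": bg_value,
            "foreground_voxels": int(fg.sum()),
        }
    )
    return ImageVolume(
        data=vol, spacing_um=(dz, dy, dx), truth=truth, foreground_mask=fg
    )


def make_aggregate_stack(
    config: PhantomConfig,
    n_particles: int = 44,
    diameter_range_um: Tuple[float, float] = (30.0, 50.0),
    target_sphericity: float = 0.75,
    sphericity_sd: float = 0.05,
    shape: Optional[Tuple[int, int, int]] = None,
    fg_value: int = 3000,
    bg_value: int = 100,
    max_tries: int = 20000,
    clearance_um: Optional[float] = None,
) -> ImageVolume:
    """Confocal-like stack of non-overlapping ellipsoidal algal aggregates.

    Particle volumes match spheres of the requested diameters; each
    particle is a prolate spheroid whose axis ratio is solved so that its
    analytic sphericity pi^(1/3) (6V)^(2/3) / A equals a draw from
    N(target_sphericity, sphericity_sd) (clipped to (0.4, 1.0]).  Intensity
    uses a 12-bit scale (0-4095).
    """
    if not 0 < target_sphericity <= 1:
        raise ValueError("target_sphericity must lie in (0, 1]")
    dz, dy, dx = config.grid_spacing
    rng = config.rng()
    d_lo, d_hi = diameter_range_um
    if clearance_um is None:
        # keep gaps wider than the downstream morphological-closing scale
        clearance_um = 5.0 * max(dz, dy, dx) + 2.0

    def spheroid_area(a: float, c: float) -> float:
        # surface area of a spheroid with equatorial radius a, polar c
        if abs(c - a) < 1e-9 * a:
            return 4 * math.pi * a * a
        if c > a:  # prolate
            e = math.sqrt(1 - (a / c) ** 2)
            return 2 * math.pi * a * a * (1 + (c / (a * e)) * math.asin(e))
        e = math.sqrt(1 - (c / a) ** 2)  # oblate
        return 2 * math.pi * a * a * (1 + ((1 - e * e) / e) * math.atanh(e))

    def axis_ratio_for(psi: float) -> float:
        """Prolate c/a ratio whose sphericity equals psi (1 -> sphere)."""
        if psi >= 0.9999:
            return 1.0
        lo, hi = 1.0, 50.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            # unit volume spheroid: a^2 c = 1 -> a = mid^(-1/3), c = a*mid
            a = mid ** (-1.0 / 3.0)
            c = a * mid
            vol = 4 / 3 * math.pi
            area = spheroid_area(a, c)
            s = math.pi ** (1 / 3) * (6 * vol) ** (2 / 3) / area
            if s > psi:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # draw all particle shapes first, then place them on a jittered grid
    # whose cell size exceeds the largest bounding diameter plus clearance
    params = []
    for _ in range(n_particles):
        d = rng.uniform(d_lo, d_hi)
        psi = float(np.clip(rng.normal(target_sphericity, sphericity_sd), 0.55, 1.0))
        q = axis_ratio_for(psi)
        r_eq = d / 2.0
        a = r_eq * q ** (-1.0 / 3.0)
        c = a * q
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        params.append(
            {"diameter_um": d, "sphericity": psi, "axis_ratio": q,
             "a_um": a, "c_um": c, "axis": u.tolist()}
        )
    c_max = max(p["c_um"] for p in params)
    cell = 2.0 * c_max + clearance_um
    if shape is None:
        side_cells = int(math.ceil(n_particles ** (1.0 / 3.0)))
        dims_cells = [side_cells] * 3
        shape = (
            int(math.ceil(side_cells * cell / dz)),
            int(math.ceil(side_cells * cell / dy)),
            int(math.ceil(side_cells * cell / dx)),
        )
    else:
        dims_cells = [
            int(shape[0] * dz // cell),
            int(shape[1] * dy // cell),
            int(shape[2] * dx // cell),
        ]
        if np.prod(dims_cells) < n_particles:
            raise RuntimeError(
                f"cannot pack {n_particles} particles of bounding diameter "
                f"{2 * c_max:.0f} um (+{clearance_um:.0f} um clearance) into "
                f"the requested volume; enlarge it"
            )
    nz, ny, nx = shape
    order = rng.permutation(int(np.prod(dims_cells)))[:n_particles]
    centres = []
    for p, cidx in zip(params, order):
        icz, rem = divmod(int(cidx), dims_cells[1] * dims_cells[2])
        icy, icx = divmod(rem, dims_cells[2])
        c = p["c_um"]
        slack = max(cell / 2.0 - c - clearance_um / 2.0, 0.0)
        centres.append(
            (
                (icz + 0.5) * cell + rng.uniform(-slack, slack),
                (icy + 0.5) * cell + rng.uniform(-slack, slack),
                (icx + 0.5) * cell + rng.uniform(-slack, slack),
            )
        )

    vol = np.full(shape, float(bg_value), dtype=np.float32)
    zc = (np.arange(nz) + 0.5) * dz
    yc = (np.arange(ny) + 0.5) * dy
    xc = (np.arange(nx) + 0.5) * dx
    for (czi, cyi, cxi), p in zip(centres, params):
        a, c = p["a_um"], p["c_um"]
        u = np.asarray(p["axis"])
        # evaluate only inside the bounding box
        iz = np.searchsorted(zc, [czi - c, czi + c])
        iy = np.searchsorted(yc, [cyi - c, cyi + c])
        ix = np.searchsorted(xc, [cxi - c, cxi + c])
        Z, Y, X = np.meshgrid(
            zc[iz[0] : iz[1]] - czi,
            yc[iy[0] : iy[1]] - cyi,
            xc[ix[0] : ix[1]] - cxi,
            indexing="ij",
        )
        par = Z * u[0] + Y * u[1] + X * u[2]
        perp2 = Z**2 + Y**2 + X**2 - par**2
        inside = (par / c) ** 2 + perp2 / a**2 <= 1.0
        sub = vol[iz[0] : iz[1], iy[0] : iy[1], ix[0] : ix[1]]
        sub[inside] = float(fg_value)
    if config.noise_rel > 0:
        vol = vol * (1.0 + config.noise_rel * rng.standard_normal(vol.shape))
    vol = np.clip(np.rint(vol), 0, 4095).astype(np.uint16)
    truth = GroundTruth(
        {
            "n_particles": n_particles,
            "particles": params,
            "fg_value": fg_value,
            "bg_value": bg_value,
        }
    )
    return ImageVolume(data=vol, spacing_um=(dz, dy, dx), truth=truth)


# --------------------------------------------------------------------------
# optical measurement phantoms


def make_transmission_series(
    l_a: float,
    l_t: float,
    z_e: float,
    thicknesses: Sequence[float],
    config: PhantomConfig,
) -> TransmissionSeries:
    """Integrating-sphere total transmittance vs slab thickness (mm)."""
    L = np.asarray(thicknesses, dtype=float)
    if L.size < 4:
        raise ValueError("need at least 4 thicknesses")
    if np.any(L <= 0):
        raise ValueError("thicknesses must be positive")
    if l_a <= 0 or l_t <= 0:
        raise ValueError("l_a and l_t must be positive")
    import warnings

    if l_t >= L.min():
        warnings.warn(
            "l_t >= thinnest sample: diffusion regime assumption violated",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        T = diffusion_transmission(L, l_a, l_t, z_e)
    rng = config.rng()
    if config.noise_rel > 0:
        T = T * (1.0 + config.noise_rel * rng.standard_normal(L.shape))
    sigma = config.noise_rel * np.abs(T) if config.noise_rel > 0 else None
    series = TransmissionSeries(L=L, T=T, wavelength=config.wavelength, sigma=sigma)
    series.truth = GroundTruth({"l_a": l_a, "l_t": l_t, "z_e": z_e})  # type: ignore[attr-defined]
    return series


def make_angular_scan(z_e: float, config: PhantomConfig) -> AngularScan:
    """Goniometer scan of diffuse angular transmittance, +-89 deg, 1 deg steps."""
    if z_e <= 0:
        raise ValueError("z_e must be positive")
    theta = np.arange(-89.0, 90.0, 1.0)
    mu = np.cos(np.radians(theta))
    inten = p_mu(np.clip(mu, 1e-9, 1.0), z_e)
    rng = config.rng()
    if config.noise_rel > 0:
        inten = inten * (1.0 + config.noise_rel * rng.standard_normal(theta.shape))
    scan = AngularScan(theta=theta, intensity=inten, wavelength=config.wavelength)
    scan.truth = GroundTruth({"z_e": z_e})  # type: ignore[attr-defined]
    return scan


def make_brewster_scan(
    n: float,
    config: PhantomConfig,
    step_deg: float = 0.5,
    n_ambient: float = 1.0,
) -> AngularScan:
    """p-polarized reflectance vs incidence angle for a medium of index n.

    The reflectance minimum sits at the Brewster angle arctan(n / n_ambient).
    A degenerate matched-index pair returns identically zero reflectance.
    """
    if n < 1.0:
        raise ValueError("n must be >= 1")
    theta = np.arange(0.0, 89.0 + step_deg / 2, step_deg)
    ti = np.radians(theta)
    if n == n_ambient:
        rp = np.zeros_like(theta)  # index-matched: no reflection at any angle
    else:
        st = n_ambient / n * np.sin(ti)
        tt = np.arcsin(st)
        with np.errstate(divide="ignore", invalid="ignore"):
            rp = (np.tan(ti - tt) / np.tan(ti + tt)) ** 2
        rp[theta == 0.0] = ((n - n_ambient) / (n + n_ambient)) ** 2
        rp = np.nan_to_num(rp, nan=0.0)
    rng = config.rng()
    if config.noise_rel > 0 and np.any(rp > 0):
        rp = rp * (1.0 + config.noise_rel * rng.standard_normal(theta.shape))
    scan = AngularScan(theta=theta, intensity=rp, wavelength=config.wavelength)
    scan.truth = GroundTruth({"n": n, "theta_B": math.degrees(math.atan2(n, n_ambient))})  # type: ignore[attr-defined]
    return scan


# --------------------------------------------------------------------------
# physiology phantoms


def make_o2_profile(
    J: float,
    D: float = D_O2_CM2_S,
    dbl_thickness_um: float = 300.0,
    config: PhantomConfig = PhantomConfig(),
    bulk_conc_umol_l: float = 210.0,
    step_um: float = 25.0,
    span_above_um: float = 600.0,
) -> O2ProfileData:
    """Linear-DBL O2 depth profile with flux ``J`` (nmol O2 cm^-2 s^-1).

    Within the diffusive boundary layer (surface depth 0 up to
    ``-dbl_thickness_um``) the concentration is linear with slope
    ``-J/D`` on the depth axis (positive J = flux out of the surface), and
    constant at the bulk value above the DBL.  Additive Gaussian noise of
    amplitude ``noise_rel * bulk_conc`` is applied.
    """
    if D <= 0 or dbl_thickness_um <= 0:
        raise ValueError("D and dbl_thickness must be positive")
    depth = np.arange(-span_above_um, 0.0 + step_um / 2, step_um)
    # slope on the depth axis in umol L^-1 um^-1; J in nmol cm^-2 s^-1,
    # D in cm^2 s^-1: 1 umol/L/um = 1e4 nmol cm^-4 => slope = -J / (D * 1e4)
    slope = -J / (D * 1.0e4)
    conc = np.full_like(depth, bulk_conc_umol_l, dtype=float)
    in_dbl = depth >= -dbl_thickness_um
    c_surface = bulk_conc_umol_l + slope * dbl_thickness_um  # value at depth 0
    conc[in_dbl] = c_surface - slope * (-depth[in_dbl])
    rng = config.rng()
    if config.noise_rel > 0:
        conc = conc + config.noise_rel * bulk_conc_umol_l * rng.standard_normal(
            depth.shape
        )
    truth = GroundTruth(
        {"J": J, "D": D, "dbl_thickness_um": dbl_thickness_um, "slope_umolL_per_um": slope}
    )
    return O2ProfileData(depth_um=depth, conc_umol_l=conc, truth=truth)


def make_pi_data(
    Pmax: float,
    Ek: float,
    irradiances: Sequence[float] = (0.0, 110.0, 220.0, 1200.0),
    config: PhantomConfig = PhantomConfig(),
    replicates: int = 3,
) -> pd.DataFrame:
    """Photosynthesis-irradiance table P = Pmax (1 - exp(-E/Ek)) + noise.

    The default irradiance levels are the microsensor experiment's light
    steps (0, 110, 220 and 1200 umol photons m^-2 s^-1).
    """
    E = np.asarray(irradiances, dtype=float)
    if not np.any(E == 0):
        raise ValueError("irradiances should include 0 (dark reference)")
    rng = config.rng()
    rows = []
    for rep in range(replicates):
        P = Pmax * (1.0 - np.exp(-E / Ek))
        if config.noise_rel > 0:
            P = P * (1.0 + config.noise_rel * rng.standard_normal(E.shape))
        for e, p in zip(E, P):
            rows.append({"irradiance": e, "replicate": rep, "rate": p})
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {"Pmax": Pmax, "Ek": Ek}
    return df


def make_growth_series(
    r: float = 0.8,
    K: float = 9.0e8,
    N0: float = 1.0e6,
    days: Sequence[float] = (0.0, 3.0, 6.0, 10.0, 12.0),
    config: PhantomConfig = PhantomConfig(),
    replicates: int = 4,
) -> GrowthSeries:
    """Logistic growth N(t) = K / (1 + ((K-N0)/N0) exp(-r t)) with replicates.

    Defaults emulate the culture experiment: inoculation at 1e6 cells/mL,
    sampling at days 0/3/6/10/12, and a calibration (K = 9e8, r = 0.8/day)
    under which the density exceeds 8e8 cells/mL by day 12.  Replicate
    scatter is multiplicative (log-normal).
    """
    if K <= 0 or N0 <= 0 or K <= N0:
        raise ValueError("need K > N0 > 0")
    days_arr = np.asarray(days, dtype=float)
    rng = config.rng()
    day_col = []
    rep_col = []
    val_col = []
    for rep in range(replicates):
        N = K / (1.0 + ((K - N0) / N0) * np.exp(-r * days_arr))
        if config.noise_rel > 0:
            N = N * np.exp(config.noise_rel * rng.standard_normal(days_arr.shape))
        day_col.extend(days_arr.tolist())
        rep_col.extend([rep] * days_arr.size)
        val_col.extend(N.tolist())
    truth = GroundTruth({"r": r, "K": K, "N0": N0})
    return GrowthSeries(
        day=np.asarray(day_col),
        replicate=np.asarray(rep_col),
        cells_per_ml=np.asarray(val_col),
        truth=truth,
    )
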