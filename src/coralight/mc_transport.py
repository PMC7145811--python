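"""Forward Monte Carlo photon transport in layered and voxelized media.

The simulator launches photon packets at normal incidence, propagates them
by sampled extinction steps with Henyey-Greenstein scattering and survival
weighting, applies unpolarized Fresnel reflection/refraction at refractive
index mismatches, and records

* the launched-energy partition (transmitted / reflected / absorbed),
* depth- and time-resolved fluence (relative to the incident irradiance),
* the angular histogram of transmitted light, directly comparable to a
  goniometer scan.

Time of flight accumulates ``n * s / c`` per sub-step with
c = 299.792458 mm/ns, so time-gated fluence maps (TPSF snapshots) can be
extracted after the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from . import _kernels
from ._kernels import C0
from .geometry import LayeredSlab, SourceSpec, VoxelGrid
from .inverse_optics import AngularScan

__all__ = [
    "FluenceGrid",
    "TPSF",
    "DepthProfile",
    "SimResult",
    "simulate",
    "angular_transmittance",
    "fluence_depth_profile",
    "tpsf_snapshot",
    "fresnel_unpolarized",
    "sample_hg_cosines",
]


def fresnel_unpolarized(n1: float, n2: float, cos_i: float) -> float:
    """Unpolarized Fresnel reflectance for incidence cosine ``cos_i``."""
    r, _ = _kernels._fresnel(n1, n2, cos_i)
    return float(r)


def sample_hg_cosines(g: float, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` Henyey-Greenstein deflection cosines (mean -> g)."""
    return _kernels.sample_hg_cosines(g, n, seed)


@dataclass
class FluenceGrid:
    """Fluence rate relative to the incident irradiance.

    ``values`` is 1D (per depth bin, laterally averaged) for slab runs or 3D
    (per voxel) for voxel runs; a value of 1 equals the unscattered incident
    level.  ``spacing`` is the bin size in mm (scalar for 1D, (dz, dy, dx)
    for 3D).
    """

    values: np.ndarray
    spacing: Union[float, tuple]
    kind: str = "depth"  # "depth" | "voxel"

    @property
    def depth_mm(self) -> np.ndarray:
        nz = self.values.shape[0]
        dz = self.spacing if self.kind == "depth" else self.spacing[0]
        return (np.arange(nz) + 0.5) * dz


@dataclass
class TPSF:
    """Time-binned depth-resolved fluence (temporal point spread function).

    ``values[i, j]`` is the fluence deposited in time bin ``i`` and depth
    bin ``j``, normalized so the sum over time bins equals the steady-state
    depth fluence.  ``n_per_bin`` carries the refractive index of each depth
    bin, used to convert a fluence snapshot to photon density (1/mm^3 scale)
    via ``density = fluence * n / (c * dt)``.
    """

    values: np.ndarray  # (nt, nz)
    time_edges: np.ndarray  # ns, length nt + 1
    dz: float  # mm
    n_per_bin: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.time_edges[1] - self.time_edges[0])


@dataclass
class DepthProfile:
    """A laterally averaged quantity vs depth into the sample."""

    depth_mm: np.ndarray
    values: np.ndarray
    units: str = "%E_d"


@dataclass
class SimResult:
    T_total: float
    R_total: float
    A_total: float
    lost: float
    fluence: FluenceGrid
    tpsf: TPSF
    trans_hist: np.ndarray  # transmitted weight per 1-degree exit-angle bin
    refl_hist: np.ndarray
    n_transmitted: int
    n_photons: int
    seed: int

    @property
    def energy_total(self) -> float:
        return self.T_total + self.R_total + self.A_total + self.lost


def _validate(geometry, n_photons: int) -> None:
    if n_photons < 1000:
        raise ValueError("n_photons must be at least 1000")
    if isinstance(geometry, LayeredSlab):
        mats = [lay.material for lay in geometry.layers]
    elif isinstance(geometry, VoxelGrid):
        mats = list(geometry.materials.values())
    else:
        raise TypeError(f"unsupported geometry type {type(geometry)!r}")
    for m in mats:
        for v in (m.mu_a, m.mu_s, m.g, m.n):
            if not math.isfinite(v):
                raise ValueError(f"non-finite optical property in material {m!r}")


def simulate(
    geometry: Union[LayeredSlab, VoxelGrid],
    source: Optional[SourceSpec] = None,
    n_photons: int = 100_000,
    seed: int = 0,
    dz: Optional[float] = None,
    dt: float = 0.05,
    t_max: float = 6.0,
) -> SimResult:
    """Run the Monte Carlo and return energy partitions plus fluence fields.

    Parameters
    ----------
    geometry:
        :class:`LayeredSlab` or :class:`VoxelGrid` domain.
    source:
        Pencil beam (default) or plane wave at normal incidence.  The two
        are equivalent for a laterally infinite slab.
    dz:
        Depth-bin size in mm for the fluence profile (default: total
        thickness / 200 for slabs; the voxel z-spacing for voxel grids).
    dt, t_max:
        Time-bin width and range in ns for the time-resolved fluence; later
        arrivals accumulate in the final bin.
    """
    source = source or SourceSpec()
    _validate(geometry, n_photons)
    nt = max(2, int(round(t_max / dt)))
    seed = int(seed) % (2**31)

    if isinstance(geometry, LayeredSlab):
        mats = [lay.material for lay in geometry.layers]
        mu_a = np.array([m.mu_a for m in mats])
        mu_s = np.array([m.mu_s for m in mats])
        g = np.array([m.g for m in mats])
        n = np.array([m.n for m in mats])
        zb = geometry.boundaries
        L = float(zb[-1])
        if dz is None:
            dz = L / 200.0
        nz = max(1, int(round(L / dz)))
        fluence_tz = np.zeros((nt, nz))
        trans_hist = np.zeros(90)
        refl_hist = np.zeros(90)
        T, R, A, lost, n_trans = _kernels.run_layered(
            mu_a,
            mu_s,
            g,
            n,
            zb,
            geometry.n_above,
            geometry.n_below,
            n_photons,
            seed,
            fluence_tz,
            dt,
            dz,
            trans_hist,
            refl_hist,
        )
        # deposited path per (photon * bin thickness) = relative fluence rate
        fluence_tz /= n_photons * dz
        centers = (np.arange(nz) + 0.5) * dz
        n_per_bin = n[np.clip(np.searchsorted(zb, centers) - 1, 0, len(mats) - 1)]
        fl = FluenceGrid(values=fluence_tz.sum(axis=0), spacing=float(dz), kind="depth")
    else:
        grid: VoxelGrid = geometry
        mu_a, mu_s, g, n = grid.material_arrays()
        dz_v, dy, dx = grid.spacing
        nz_v, ny, nx = grid.labels.shape
        fluence_vox = np.zeros((nz_v, ny, nx))
        fluence_tz = np.zeros((nt, nz_v))
        trans_hist = np.zeros(90)
        refl_hist = np.zeros(90)
        plane = source.kind == "plane"
        x0 = grid.labels.shape[2] * dx / 2.0 + source.position[0]
        y0 = grid.labels.shape[1] * dy / 2.0 + source.position[1]
        T, R, A, lost, n_trans = _kernels.run_voxel(
            grid.labels.astype(np.int64),
            mu_a,
            mu_s,
            g,
            n,
            dz_v,
            dy,
            dx,
            grid.n_above,
            grid.n_below,
            n_photons,
            seed,
            plane,
            x0,
            y0,
            fluence_vox,
            fluence_tz,
            dt,
            trans_hist,
            refl_hist,
        )
        if plane:
            # uniform illumination over the periodic cell: relative fluence
            fluence_vox /= n_photons * dx * dy * dz_v / (nx * dx * ny * dy)
            fluence_tz /= n_photons * dz_v
        else:
            # pencil beam: fluence per unit area (1/mm^2 per launched photon)
            fluence_vox /= n_photons * dx * dy * dz_v
            fluence_tz /= n_photons * dz_v
        labels_mid = grid.labels[:, ny // 2, nx // 2]
        n_per_bin = n[labels_mid]
        dz = dz_v
        fl = FluenceGrid(
            values=fluence_vox, spacing=(dz_v, dy, dx), kind="voxel"
        )

    tpsf = TPSF(
        values=fluence_tz,
        time_edges=np.arange(nt + 1) * dt,
        dz=float(dz),
        n_per_bin=np.asarray(n_per_bin, dtype=float),
    )
    return SimResult(
        T_total=T / n_photons,
        R_total=R / n_photons,
        A_total=A / n_photons,
        lost=lost / n_photons,
        fluence=fl,
        tpsf=tpsf,
        trans_hist=trans_hist,
        refl_hist=refl_hist,
        n_transmitted=int(n_trans),
        n_photons=int(n_photons),
        seed=seed,
    )


def angular_transmittance(result: SimResult, min_photons: int = 100) -> AngularScan:
    """Normalized angular intensity of transmitted light at 1-degree steps.

    The per-bin weights are converted to intensity per solid angle (what a
    goniometer's fixed small detector measures) and mirrored onto signed
    angles spanning the forward hemisphere.
    """
    if result.n_transmitted == 0:
        raise ValueError("no transmitted photons recorded")
    if result.n_transmitted < min_photons:
        raise ValueError(
            f"only {result.n_transmitted} transmitted photons; "
            f"need at least {min_photons}"
        )
    edges = np.radians(np.arange(91.0))
    solid = 2.0 * np.pi * (np.cos(edges[:-1]) - np.cos(edges[1:]))
    intensity = result.trans_hist / solid
    # Poisson-scale uncertainty: per-bin variance ~ deposited weight
    sigma = np.sqrt(np.maximum(result.trans_hist, 1.0)) / solid
    theta = np.arange(90) + 0.5
    theta_signed = np.concatenate([-theta[::-1], theta])
    inten_signed = np.concatenate([intensity[::-1], intensity])
    sig_signed = np.concatenate([sigma[::-1], sigma])
    return AngularScan(theta=theta_signed, intensity=inten_signed, sigma=sig_signed)


def fluence_depth_profile(result: SimResult) -> DepthProfile:
    """Laterally averaged fluence rate vs depth, in % of incident irradiance.

    100% corresponds to the unscattered incident level just below the
    surface; a voxel-grid result is averaged over the lateral plane.
    """
    fl = result.fluence
    if fl.kind == "voxel":
        values = fl.values.mean(axis=(1, 2))
        dz = fl.spacing[0]
    else:
        values = fl.values
        dz = fl.spacing
    nz = values.shape[0]
    depth = (np.arange(nz) + 0.5) * dz
    return DepthProfile(depth_mm=depth, values=100.0 * values, units="%E_d")


def tpsf_snapshot(result: SimResult, t: float) -> DepthProfile:
    """Photon-density depth profile for the time bin containing ``t`` (ns).

    The time-binned fluence is converted to photon density via
    ``density = fluence * n / (c * dt)`` (units 1/mm per unit incident
    irradiance, i.e. 1/mm^3 when the incident beam is resolved per mm^2).
    """
    tp = result.tpsf
    if t < tp.time_edges[0] or t > tp.time_edges[-1]:
        raise ValueError(
            f"t={t} ns outside the simulated time range "
            f"[{tp.time_edges[0]}, {tp.time_edges[-1]}] ns"
        )
    i = min(int(t / tp.dt), tp.values.shape[0] - 1)
    density = tp.values[i] * tp.n_per_bin / (C0 * tp.dt)
    depth = (np.arange(tp.values.shape[1]) + 0.5) * tp.dz
    return DepthProfile(depth_mm=depth, values=density, units="1/mm^3")
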