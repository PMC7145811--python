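"""Simulation domains and sources for the photon-transport model.

Two domain types are supported: an infinite :class:`LayeredSlab` (ordered
stack of homogeneous layers, clear ambient media above and below) and a
:class:`VoxelGrid` (3D label array with a label -> material map, laterally
periodic).  All lengths are millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

import numpy as np

from .materials import Material

__all__ = ["Layer", "LayeredSlab", "VoxelGrid", "SourceSpec"]


@dataclass(frozen=True)
class Layer:
    material: Material
    thickness: float  # mm

    def __post_init__(self) -> None:
        if not (self.thickness > 0 and math.isfinite(self.thickness)):
            raise ValueError(f"layer thickness must be > 0, got {self.thickness}")


@dataclass(frozen=True)
class LayeredSlab:
    """Stack of homogeneous layers; z = 0 at the illuminated top surface.

    ``n_above`` / ``n_below`` are the refractive indices of the clear
    (non-scattering, non-absorbing) ambient half spaces.
    """

    layers: Tuple[Layer, ...]
    n_above: float = 1.0
    n_below: float = 1.0

    def __init__(
        self,
        layers: Sequence[Layer | Tuple[Material, float]],
        n_above: float = 1.0,
        n_below: float = 1.0,
    ) -> None:
        norm = tuple(
            lay if isinstance(lay, Layer) else Layer(material=lay[0], thickness=lay[1])
            for lay in layers
        )
        if not norm:
            raise ValueError("LayeredSlab needs at least one layer")
        if n_above < 1 or n_below < 1:
            raise ValueError("ambient refractive indices must be >= 1")
        object.__setattr__(self, "layers", norm)
        object.__setattr__(self, "n_above", float(n_above))
        object.__setattr__(self, "n_below", float(n_below))

    @property
    def total_thickness(self) -> float:
        return sum(lay.thickness for lay in self.layers)

    @property
    def boundaries(self) -> np.ndarray:
        """Layer boundary depths [0, z1, ..., L] in mm."""
        return np.concatenate([[0.0], np.cumsum([l.thickness for l in self.layers])])

    def flipped(self) -> "LayeredSlab":
        """The same slab illuminated from the other side."""
        return LayeredSlab(tuple(reversed(self.layers)), self.n_below, self.n_above)


@dataclass(frozen=True)
class VoxelGrid:
    """Labelled voxel domain, laterally periodic, illuminated along +z.

    ``labels`` is a (nz, ny, nx) integer array; every distinct label must be
    mapped to a :class:`Material`.  ``spacing`` is (dz, dy, dx) in mm.
    Ambient clear media with indices ``n_above`` / ``n_below`` sit above the
    first and below the last z-plane.
    """

    labels: np.ndarray
    spacing: Tuple[float, float, float]
    materials: Mapping[int, Material]
    n_above: float = 1.0
    n_below: float = 1.0

    def __post_init__(self) -> None:
        labels = np.ascontiguousarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("labels must be a 3D (nz, ny, nx) array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        present = set(np.unique(labels).tolist())
        missing = present - set(self.materials)
        if missing:
            raise ValueError(f"labels without material mapping: {sorted(missing)}")
        object.__setattr__(self, "labels", labels)

    @property
    def total_thickness(self) -> float:
        return self.labels.shape[0] * self.spacing[0]

    def material_arrays(self) -> tuple[np.ndarray, ...]:
        """Dense (mu_a, mu_s, g, n) arrays indexed by label id."""
        nmax = int(max(self.materials)) + 1
        mu_a = np.zeros(nmax)
        mu_s = np.zeros(nmax)
        g = np.zeros(nmax)
        n = np.ones(nmax)
        for lbl, mat in self.materials.items():
            mu_a[lbl] = mat.mu_a
            mu_s[lbl] = mat.mu_s
            g[lbl] = mat.g
            n[lbl] = mat.n
        return mu_a, mu_s, g, n


@dataclass(frozen=True)
class SourceSpec:
    """Illumination: collimated pencil beam (default) or plane wave.

    ``position`` is the (x, y) entry point in mm for a pencil beam (ignored
    for a plane wave, which uniformly covers the domain).  ``direction``
    must currently be the downward surface normal (0, 0, 1).
    """

    kind: str = "pencil"  # "pencil" | "plane"
    position: Tuple[float, float] = (0.0, 0.0)
    direction: Tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.kind not in ("pencil", "plane"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        d = np.asarray(self.direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0):
            raise ValueError("source direction must be a unit vector")
        if not np.allclose(d, (0.0, 0.0, 1.0)):
            raise ValueError("only normal-incidence (0, 0, 1) sources are supported")
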