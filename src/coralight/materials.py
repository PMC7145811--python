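"""Optical material definitions.

A :class:`Material` bundles the four inherent optical properties that drive
photon transport in a turbid medium: the absorption coefficient ``mu_a``
(mm^-1), the scattering coefficient ``mu_s`` (mm^-1), the scattering
anisotropy ``g`` (mean cosine of the single-scattering deflection angle) and
the refractive index ``n``.

Presets are provided for the printed coral-inspired constructs:

``skeleton``
    PEGDA hydrogel doped with cellulose-nanocrystal aggregates.  Measured to
    scatter nearly isotropically with a scattering mean free path of 3 mm,
    which for g = 0 coincides with the transport mean free path, hence
    mu_s = 1/3 mm^-1 and g = 0.
``tissue``
    GelMA hydrogel hosting microalgae.  Absorption scales with algal cell
    density (15 mm^-1 at 1e9 cells/mL); scattering is weak and strongly
    forward-peaked (a forward cone), modelled here as mu_s = 10 mm^-1 with
    g = 0.9 (transport mean free path 1 mm).
``gelma``
    Plain (cell-free matrix) non-scattering GelMA reference slab; absorption
    set by the same algal density scaling when cells are suspended in it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Material",
    "WATER_N",
    "tissue",
    "skeleton",
    "gelma",
    "water",
    "air",
    "MU_A_PER_CELL_ML",
]

#: refractive index of seawater in the visible
WATER_N = 1.33

#: absorption coefficient per algal cell density: 15 mm^-1 at 1e9 cells/mL
MU_A_PER_CELL_ML = 15.0 / 1e9


@dataclass(frozen=True)
class Material:
    """Inherent optical properties of one medium at one wavelength."""

    mu_a: float  # absorption coefficient, mm^-1
    mu_s: float  # scattering coefficient, mm^-1
    g: float = 0.0  # scattering anisotropy, dimensionless, in (-1, 1)
    n: float = 1.0  # refractive index, >= 1
    name: str = ""

    def __post_init__(self) -> None:
        for attr in ("mu_a", "mu_s", "g", "n"):
            v = getattr(self, attr)
            if not math.isfinite(v):
                raise ValueError(f"{attr} must be finite, got {v!r}")
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"g must lie in (-1, 1), got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def mu_t(self) -> float:
        """Extinction (interaction) coefficient mu_a + mu_s, mm^-1."""
        return self.mu_a + self.mu_s

    @property
    def albedo(self) -> float:
        """Single-scattering albedo mu_s / (mu_a + mu_s); 0 for clear media."""
        mt = self.mu_t
        return self.mu_s / mt if mt > 0 else 0.0

    @property
    def l_t(self) -> float:
        """Transport mean free path 1 / (mu_s (1 - g)), mm (inf if mu_s=0)."""
        mus_red = self.mu_s * (1.0 - self.g)
        return 1.0 / mus_red if mus_red > 0 else math.inf


def tissue(cell_density_per_ml: float = 5e6) -> Material:
    """Coral-inspired printed tissue (GelMA + algae), forward scattering.

    Parameters
    ----------
    cell_density_per_ml:
        Microalgal cell density setting the absorption coefficient via the
        calibration 15 mm^-1 at 1e9 cells/mL.  The default 5e6 cells/mL is
        the density of the fluence-rate profiling experiments.
    """
    return Material(
        mu_a=MU_A_PER_CELL_ML * cell_density_per_ml,
        mu_s=10.0,
        g=0.9,
        n=1.37,
        name="tissue",
    )


def skeleton() -> Material:
    """Printed skeleton (PEGDA + CNC): diffuse, near-isotropic scattering.

    Scattering mean free path 3 mm with g = 0, so the transport mean free
    path is also 3 mm.  Residual matrix absorption is tiny.
    """
    return Material(mu_a=0.003, mu_s=1.0 / 3.0, g=0.0, n=1.47, name="skeleton")


def gelma(cell_density_per_ml: float = 0.0) -> Material:
    """Non-scattering GelMA slab, optionally loaded with absorbing algae."""
    return Material(
        mu_a=MU_A_PER_CELL_ML * cell_density_per_ml,
        mu_s=0.0,
        g=0.0,
        n=1.37,
        name="gelma",
    )


def water() -> Material:
    """Clear ambient seawater."""
    return Material(mu_a=0.0, mu_s=0.0, g=0.0, n=WATER_N, name="water")


def air() -> Material:
    """Clear ambient air."""
    return Material(mu_a=0.0, mu_s=0.0, g=0.0, n=1.0, name="air")
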