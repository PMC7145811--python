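"""Image-stack processing: surface extraction for printing and particle stats.

The printing chain converts a 3D image stack (OCT-like) to printable
geometry: 3D median denoising, per-slice multilevel Otsu segmentation,
isosurface extraction to a triangle mesh (written as STL in micrometres),
hole filling, and even-odd slicing into binary printer masks.

The confocal chain segments fluorescent algal aggregates by intensity
window, size filtering, hole filling and morphological smoothing, and
reports per-particle surface area, volume, equivalent diameter and
sphericity psi = pi^(1/3) (6V)^(2/3) / A.

Conventions: voxel index (0,0,0) is the stack's top-left corner with z
increasing into the sample; physical coordinates are micrometres; the STL
is written in micrometre units (STL itself is unitless).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from numba import njit
from scipy import ndimage
from skimage import filters, measure, morphology

__all__ = [
    "ImageVolume",
    "SurfaceMesh",
    "MaskStack",
    "ParticleStats",
    "denoise_median3d",
    "segment_surface",
    "extract_surface",
    "fill_holes",
    "slice_masks",
    "segment_particles",
]


@dataclass
class ImageVolume:
    """A 3D image stack with physical voxel spacing.

    ``data`` is (nz, ny, nx); ``spacing_um`` is (z, y, x) micrometres per
    voxel.  ``truth``/``foreground_mask`` may carry phantom ground truth.
    """

    data: np.ndarray
    spacing_um: Tuple[float, float, float]
    truth: Optional[object] = None
    foreground_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("ImageVolume data must be 3D (nz, ny, nx)")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.data, metadata={"spacing_um": self.spacing_um})

    @classmethod
    def from_tiff(cls, path, spacing_um) -> "ImageVolume":
        import tifffile

        return cls(data=tifffile.imread(path), spacing_um=tuple(spacing_um))


@dataclass
class SurfaceMesh:
    """Triangle mesh in micrometres with outward-oriented faces."""

    vertices: np.ndarray  # (n, 3) x, y, z um
    faces: np.ndarray  # (m, 3) vertex indices

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)

    @property
    def boundary_edges(self) -> np.ndarray:
        """Directed edges that appear in exactly one face (holes)."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        # a directed edge (a,b) is a boundary edge if (b,a) never occurs
        keys = e[:, 0].astype(np.int64) * (self.vertices.shape[0] + 1) + e[:, 1]
        rev = e[:, 1].astype(np.int64) * (self.vertices.shape[0] + 1) + e[:, 0]
        return e[~np.isin(keys, rev)]

    @property
    def is_watertight(self) -> bool:
        return self.boundary_edges.shape[0] == 0

    def volume(self) -> float:
        """Enclosed volume via the divergence theorem, um^3."""
        v = self.vertices
        t = v[self.faces]
        return float(abs(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum()) / 6.0)

    def area(self) -> float:
        """Total surface area, um^2."""
        t = self.vertices[self.faces]
        return float(
            0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1).sum()
        )

    @property
    def z_extent(self) -> float:
        return float(self.vertices[:, 2].max() - self.vertices[:, 2].min())

    def to_stl(self, path) -> None:
        """Write ASCII STL (units: micrometres)."""
        v = self.vertices
        with open(path, "w") as fh:
            fh.write("solid coralight\n")
            for f in self.faces:
                a, b, c = v[f[0]], v[f[1]], v[f[2]]
                nrm = np.cross(b - a, c - a)
                norm = np.linalg.norm(nrm)
                if norm > 0:
                    nrm = nrm / norm
                fh.write(f"facet normal {nrm[0]:.6e} {nrm[1]:.6e} {nrm[2]:.6e}\n")
                fh.write(" outer loop\n")
                for p in (a, b, c):
                    fh.write(f"  vertex {p[0]:.6e} {p[1]:.6e} {p[2]:.6e}\n")
                fh.write(" endloop\nendfacet\n")
            fh.write("endsolid coralight\n")


@dataclass
class MaskStack:
    """Ordered binary printer masks with layer thickness and pixel pitch."""

    masks: np.ndarray  # (n_layers, ny, nx) bool
    layer_um: float
    pixel_um: float
    origin_um: Tuple[float, float] = (0.0, 0.0)  # (x, y) of pixel (0, 0) centre

    @property
    def n_layers(self) -> int:
        return self.masks.shape[0]

    def volume(self) -> float:
        """Total solid volume represented by the stack, um^3."""
        return float(self.masks.sum()) * self.layer_um * self.pixel_um**2


@dataclass
class ParticleStats:
    """Per-particle morphology and the per-volume particle density."""

    surface_area_um2: np.ndarray
    volume_um3: np.ndarray
    equivalent_diameter_um: np.ndarray
    sphericity: np.ndarray
    density_per_mm3: float

    @property
    def n_particles(self) -> int:
        return int(self.volume_um3.size)


# --------------------------------------------------------------------------


def denoise_median3d(vol: ImageVolume, radius: int = 1) -> ImageVolume:
    """3D median filter over a (2r+1)^3 neighbourhood, reflected edges."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if 2 * radius + 1 > min(vol.shape):
        raise ValueError("filter radius exceeds the smallest volume dimension")
    out = ndimage.median_filter(vol.data, size=2 * radius + 1, mode="reflect")
    return ImageVolume(data=out, spacing_um=vol.spacing_um, truth=vol.truth)


def segment_surface(
    vol: ImageVolume, n_classes: int = 3
) -> Tuple[ImageVolume, List[Optional[float]]]:
    """Per-slice multilevel Otsu; the top intensity class is foreground.

    Returns the binary volume and the per-slice thresholds used (the
    provenance log).  A slice without enough distinct grey levels inherits
    the nearest valid slice's threshold (recorded as that value).
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    nz = vol.shape[0]
    thresholds: List[Optional[float]] = [None] * nz
    for i in range(nz):
        sl = vol.data[i]
        n_distinct = np.unique(sl).size
        if n_distinct < 2:
            continue
        classes = min(n_classes, n_distinct)
        try:
            # float conversion keeps the histogram at 256 bins regardless of
            # the integer dynamic range (a 65k-bin multi-class search is
            # prohibitively slow and no more accurate here)
            th = filters.threshold_multiotsu(
                sl.astype(np.float32), classes=classes, nbins=256
            )
        except ValueError:
            continue
        t = float(th[-1])
        # bimodality guard: a slice containing only background noise still
        # yields a threshold, but its class separation is on the noise
        # scale; such slices inherit a neighbour's threshold instead
        lo_px = sl[sl <= t]
        hi_px = sl[sl > t]
        if lo_px.size and hi_px.size:
            sep = float(hi_px.mean() - lo_px.mean())
            spread = float(lo_px.std() + hi_px.std())
            if sep > 2.0 * spread:
                thresholds[i] = t
    valid = [i for i, t in enumerate(thresholds) if t is not None]
    if not valid:
        raise ValueError("no slice had enough distinct grey levels to threshold")
    for i in range(nz):
        if thresholds[i] is None:
            j = min(valid, key=lambda v: abs(v - i))
            thresholds[i] = thresholds[j]
    binary = np.zeros(vol.shape, dtype=bool)
    for i in range(nz):
        binary[i] = vol.data[i] > thresholds[i]
    return (
        ImageVolume(data=binary, spacing_um=vol.spacing_um, truth=vol.truth),
        thresholds,
    )


def extract_surface(binary: ImageVolume, smooth_sigma: float = 1.0) -> SurfaceMesh:
    """Triangulated boundary surface of a binary volume, scaled to um.

    The isosurface is taken at 0.5 on a lightly Gaussian-smoothed copy of
    the binary field (``smooth_sigma`` in voxels), which suppresses the
    staircase bias of a raw binary isosurface; set it to 0 for the raw
    surface.  Vertices are returned in (x, y, z) micrometres.
    """
    mask = binary.data.astype(bool)
    if not mask.any():
        raise ValueError("empty foreground: nothing to mesh")
    dz, dy, dx = binary.spacing_um
    # pad so surfaces at the array border are closed
    f = np.pad(mask, 1).astype(np.float32)
    if smooth_sigma > 0:
        sm = ndimage.gaussian_filter(f, smooth_sigma)
        # keep the isolevel crossing inside the padded frame
        sm[0], sm[-1] = 0, 0
        sm[:, 0], sm[:, -1] = 0, 0
        sm[:, :, 0], sm[:, :, -1] = 0, 0
        # structures thinner than the smoothing kernel would vanish; fall
        # back to the raw binary isosurface for those
        if sm.max() > 0.5:
            f = sm
    verts, faces, _normals, _vals = measure.marching_cubes(
        f, level=0.5, spacing=(dz, dy, dx)
    )
    verts -= np.array([dz, dy, dx])  # undo padding offset
    # (z, y, x) -> (x, y, z)
    verts = verts[:, ::-1]
    mesh = SurfaceMesh(vertices=verts, faces=faces)
    # orient faces so the enclosed volume is positive (outward normals)
    t = mesh.vertices[mesh.faces]
    signed = np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0
    if signed < 0:
        mesh.faces = mesh.faces[:, [0, 2, 1]]
    return mesh


def _boundary_loops(mesh: SurfaceMesh) -> List[List[int]]:
    edges = mesh.boundary_edges
    nxt: Dict[int, int] = {}
    for a, b in edges:
        nxt[int(a)] = int(b)
    loops: List[List[int]] = []
    visited: set = set()
    for start in list(nxt):
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        cur = nxt.get(start)
        while cur is not None and cur != start and cur not in visited:
            loop.append(cur)
            visited.add(cur)
            cur = nxt.get(cur)
        if cur == start and len(loop) >= 3:
            loops.append(loop)
    return loops


def fill_holes(
    mesh: SurfaceMesh, max_hole_edges: int = 100
) -> Tuple[SurfaceMesh, List[int]]:
    """Fan-triangulate boundary loops with at most ``max_hole_edges`` edges.

    Returns the (possibly) repaired mesh and a report listing the sizes of
    holes left untouched.  A watertight mesh is returned unchanged.
    """
    if mesh.is_watertight:
        return mesh, []
    new_faces = []
    skipped: List[int] = []
    for loop in _boundary_loops(mesh):
        if len(loop) > max_hole_edges:
            skipped.append(len(loop))
            continue
        # boundary edges run a->b along existing face winding; the patch
        # must traverse the loop in reverse to keep outward orientation
        loop = loop[::-1]
        v0 = loop[0]
        for i in range(1, len(loop) - 1):
            new_faces.append([v0, loop[i], loop[i + 1]])
    if new_faces:
        faces = np.concatenate([mesh.faces, np.asarray(new_faces, dtype=np.int64)])
    else:
        faces = mesh.faces
    return SurfaceMesh(vertices=mesh.vertices.copy(), faces=faces), skipped


@njit(cache=True)
def _column_crossings(verts, faces, x0, y0, pixel, nx, ny, max_hits):
    """Signed z-crossings of a vertical ray through each pixel centre.

    The crossing sign is +1 where the ray (travelling +z) enters the solid
    and -1 where it leaves, taken from the face orientation; a running sum
    > 0 marks the interior.  Signed counting is robust to the duplicate
    hits a ray produces when it passes a shared-edge projection.
    """
    ncol = nx * ny
    hits = np.full((ncol, max_hits), np.nan)
    signs = np.zeros((ncol, max_hits), dtype=np.int8)
    counts = np.zeros(ncol, dtype=np.int64)
    for fi in range(faces.shape[0]):
        a = verts[faces[fi, 0]]
        b = verts[faces[fi, 1]]
        c = verts[faces[fi, 2]]
        xmin = min(a[0], min(b[0], c[0]))
        xmax = max(a[0], max(b[0], c[0]))
        ymin = min(a[1], min(b[1], c[1]))
        ymax = max(a[1], max(b[1], c[1]))
        d00x = b[0] - a[0]
        d00y = b[1] - a[1]
        d01x = c[0] - a[0]
        d01y = c[1] - a[1]
        det = d00x * d01y - d01x * d00y
        if det == 0.0:
            continue  # vertical triangle: zero-measure for a z-ray
        s = -1 if det > 0.0 else 1  # det sign follows the face normal's z
        ix_lo = max(int(math.ceil((xmin - x0) / pixel)), 0)
        ix_hi = min(int(math.floor((xmax - x0) / pixel)), nx - 1)
        iy_lo = max(int(math.ceil((ymin - y0) / pixel)), 0)
        iy_hi = min(int(math.floor((ymax - y0) / pixel)), ny - 1)
        for iy in range(iy_lo, iy_hi + 1):
            y = y0 + iy * pixel
            for ix in range(ix_lo, ix_hi + 1):
                x = x0 + ix * pixel
                rx = x - a[0]
                ry = y - a[1]
                u = (rx * d01y - ry * d01x) / det
                v = (d00x * ry - d00y * rx) / det
                if u >= 0.0 and v >= 0.0 and u + v <= 1.0:
                    z = a[2] + u * (b[2] - a[2]) + v * (c[2] - a[2])
                    ci = iy * nx + ix
                    k = counts[ci]
                    if k < max_hits:
                        hits[ci, k] = z
                        signs[ci, k] = s
                        counts[ci] = k + 1
    return hits, signs, counts


def slice_masks(
    mesh: SurfaceMesh, layer_um: float, pixel_um: float = 10.0
) -> MaskStack:
    """Slice a watertight mesh into binary printer masks (even-odd fill).

    A vertical ray is cast through each pixel centre; sorted surface
    crossings pair into interior intervals, and each layer's mid-plane is
    tested against them.  The layer count is ceil(z extent / layer_um).
    """
    if layer_um <= 0 or pixel_um <= 0:
        raise ValueError("layer_um and pixel_um must be positive")
    if not mesh.is_watertight:
        raise ValueError("mesh has open boundary loops; run fill_holes first")
    v = mesh.vertices
    xmin, ymin = v[:, 0].min(), v[:, 1].min()
    z0 = v[:, 2].min()
    nx = int(math.ceil((v[:, 0].max() - xmin) / pixel_um)) + 1
    ny = int(math.ceil((v[:, 1].max() - ymin) / pixel_um)) + 1
    n_layers = int(math.ceil(mesh.z_extent / layer_um))
    # off-centre jitter avoids rays passing exactly through mesh vertices
    x0 = xmin + 0.37 * pixel_um
    y0 = ymin + 0.37 * pixel_um
    hits, signs, counts = _column_crossings(
        np.ascontiguousarray(v),
        np.ascontiguousarray(mesh.faces),
        x0,
        y0,
        pixel_um,
        nx,
        ny,
        64,
    )
    masks = np.zeros((n_layers, ny, nx), dtype=bool)
    z_mid = z0 + (np.arange(n_layers) + 0.5) * layer_um
    for ci in range(nx * ny):
        k = counts[ci]
        if k < 2:
            continue
        order = np.argsort(hits[ci, :k])
        zs = hits[ci, :k][order]
        cum = np.cumsum(signs[ci, :k][order])
        iy, ix = divmod(ci, nx)
        inside = cum > 0
        for j in range(k - 1):
            if inside[j]:
                sel = (z_mid >= zs[j]) & (z_mid < zs[j + 1])
                masks[sel, iy, ix] = True
    return MaskStack(
        masks=masks, layer_um=layer_um, pixel_um=pixel_um, origin_um=(x0, y0)
    )


def segment_particles(
    vol: ImageVolume,
    lo: int = 229,
    hi: int = 4095,
    clean_factor: float = 6.0,
    smooth_factor: int = 2,
    base_volume_voxels: int = 27,
) -> ParticleStats:
    """Segment fluorescent aggregates and report per-particle morphology.

    Pipeline: intensity window [lo, hi] -> remove objects smaller than
    ``clean_factor * base_volume_voxels`` voxels -> fill internal holes ->
    morphological closing with a ball of radius ``smooth_factor`` ->
    26-connected labelling -> per-particle surface area (isosurface mesh),
    volume (voxel count), equivalent sphere diameter and sphericity
    psi = pi^(1/3) (6V)^(2/3) / A.  Touching particles closer than the
    smoothing scale merge (a documented morphology effect).
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    dz, dy, dx = vol.spacing_um
    mask = (vol.data >= lo) & (vol.data <= hi)
    min_vox = int(round(clean_factor * base_volume_voxels))
    if min_vox > 0:
        lab0, n0 = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
        if n0:
            sizes = ndimage.sum_labels(mask, lab0, index=np.arange(1, n0 + 1))
            small = np.flatnonzero(sizes < min_vox) + 1
            mask &= ~np.isin(lab0, small)
    mask = ndimage.binary_fill_holes(mask)
    if smooth_factor > 0:
        ball = morphology.ball(smooth_factor)
        mask = ndimage.binary_erosion(
            ndimage.binary_dilation(mask, structure=ball), structure=ball
        )
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        import warnings

        warnings.warn("empty segmentation: no particles found", stacklevel=2)
        empty = np.empty(0)
        return ParticleStats(empty, empty, empty, empty, 0.0)
    voxel_vol = dz * dy * dx
    areas = np.zeros(n)
    vols = np.zeros(n)
    objects = ndimage.find_objects(labels)
    for i, slc in enumerate(objects):
        sub = labels[slc] == (i + 1)
        vols[i] = sub.sum() * voxel_vol
        m = extract_surface(
            ImageVolume(data=sub, spacing_um=vol.spacing_um), smooth_sigma=1.0
        )
        areas[i] = m.area()
    eq_d = (6.0 * vols / math.pi) ** (1.0 / 3.0)
    spher = math.pi ** (1.0 / 3.0) * (6.0 * vols) ** (2.0 / 3.0) / areas
    total_mm3 = np.prod(vol.shape) * voxel_vol * 1e-9
    return ParticleStats(
        surface_area_um2=areas,
        volume_um3=vols,
        equivalent_diameter_um=eq_d,
        sphericity=np.clip(spher, 0.0, 1.0),
        density_per_mm3=n / total_mm3,
    )
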