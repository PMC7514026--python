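"""Planar kernel density estimation over the study grid, and basis assembly.

Each POI class (and the crime point set) is smoothed into a raster by
summing a radially symmetric kernel centred on every point and sampling
the result at the grid cell centres.  Kernels are normalised so that their
integral over the plane is 1: a single point contributes exactly one
point's worth of mass, and grid values are on an intensity scale of
points per square kilometre (the raster sums, times cell area, to the
point count times any sampling-compensation ``scale_factor``).

The flattened rasters of the POI classes form the columns of the basis
matrix regressed against the flattened crime raster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geodata_io import PointSet, StudyArea, grid_geometry

logger = logging.getLogger(__name__)

__all__ = [
    "KernelSpec",
    "DensityGrid",
    "BasisMatrix",
    "KERNEL_KINDS",
    "kernel_profile",
    "estimate_density",
    "build_basis",
]

# Dimensionless radial profiles k(u), u = distance / bandwidth, and the
# constants c(h) that make the planar integral  c * \int k(r/h) 2 pi r dr
# equal 1 (all closed form).
_PROFILES = {
    "gaussian": lambda u: np.exp(-0.5 * u ** 2),
    "tophat": lambda u: (u <= 1).astype(float),
    "epanechnikov": lambda u: np.clip(1 - u ** 2, 0, None) * (u <= 1),
    "exponential": lambda u: np.exp(-u),
    "linear": lambda u: np.clip(1 - u, 0, None),
    "cosine": lambda u: np.cos(np.pi * u / 2) * (u <= 1),
}
_NORMS = {
    "gaussian": lambda h: 1.0 / (2 * np.pi * h ** 2),
    "tophat": lambda h: 1.0 / (np.pi * h ** 2),
    "epanechnikov": lambda h: 2.0 / (np.pi * h ** 2),
    "exponential": lambda h: 1.0 / (2 * np.pi * h ** 2),
    "linear": lambda h: 3.0 / (np.pi * h ** 2),
    "cosine": lambda h: 1.0 / ((4 - 8 / np.pi) * h ** 2),
}
KERNEL_KINDS = tuple(_PROFILES)

#: m^2 per km^2 — converts per-square-metre intensity to per-square-km.
M2_PER_KM2 = 1e6


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and spatial scale of the distance-decay law.

    ``kind`` is one of gaussian, tophat, epanechnikov, exponential, linear
    (triangular) or cosine; ``bandwidth`` is in metres (default convention:
    study-area side / 40, i.e. 75 m for a 3 km area).
    """

    kind: str = "exponential"
    bandwidth: float = 75.0

    def __post_init__(self):
        if self.kind not in _PROFILES:
            raise ValueError(
                f"unknown kernel kind {self.kind!r}; expected one of {KERNEL_KINDS}")
        if not self.bandwidth > 0:
            raise ValueError("bandwidth must be positive")


def kernel_profile(spec: KernelSpec, distance) -> np.ndarray | float:
    """Normalised planar kernel value at a distance in metres.

    Returns ``c(h) * k(distance / h)`` where the constant makes the
    profile integrate to 1 over the plane, so values have units 1/m^2.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    out = _NORMS[spec.kind](spec.bandwidth) * _PROFILES[spec.kind](d / spec.bandwidth)
    return float(out) if np.isscalar(distance) else out


@dataclass
class DensityGrid:
    """Estimated density raster over a study area.

    ``values`` has shape (n, n) with rows indexed by y (row-major flatten
    matches :func:`poicrime.geodata_io.grid_geometry`), units points per
    km^2 on the intensity scale: ``values.sum() * cell_area_km2`` is
    ``n_source_points * scale_factor`` up to boundary truncation.
    """

    values: np.ndarray
    area: StudyArea
    source_label: str
    n_source_points: int
    scale_factor: float = 1.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = self.area.n_cells_per_side
        if v.shape != (n, n):
            raise ValueError(f"values shape {v.shape} != grid ({n}, {n})")
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("density values must be finite and non-negative")
        self.values = v

    def flatten(self) -> np.ndarray:
        return self.values.ravel()

    def to_csv(self, path) -> None:
        """Serialise as a headered CSV raster (metadata lines then rows)."""
        with open(path, "w") as fh:
            fh.write(f"# label,{self.source_label}\n")
            fh.write(f"# centre_x,{self.area.centre_x!r}\n")
            fh.write(f"# centre_y,{self.area.centre_y!r}\n")
            fh.write(f"# side,{self.area.side!r}\n")
            fh.write(f"# n_cells_per_side,{self.area.n_cells_per_side}\n")
            fh.write(f"# bandwidth_divisor,{self.area.bandwidth_divisor!r}\n")
            fh.write(f"# n_source_points,{self.n_source_points}\n")
            fh.write(f"# scale_factor,{self.scale_factor!r}\n")
            np.savetxt(fh, self.values, delimiter=",")

    @classmethod
    def from_csv(cls, path) -> "DensityGrid":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition(",")
                    meta[key.strip()] = val
                elif line.strip():
                    rows.append([float(t) for t in line.split(",")])
        area = StudyArea(centre_x=float(meta["centre_x"]),
                         centre_y=float(meta["centre_y"]),
                         side=float(meta["side"]),
                         n_cells_per_side=int(meta["n_cells_per_side"]),
                         bandwidth_divisor=float(meta["bandwidth_divisor"]))
        return cls(values=np.array(rows), area=area,
                   source_label=meta["label"],
                   n_source_points=int(meta["n_source_points"]),
                   scale_factor=float(meta["scale_factor"]))

    def to_png(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots()
        im = ax.imshow(self.values, origin="lower", cmap="inferno",
                       extent=[self.area.xmin, self.area.xmin + self.area.side,
                               self.area.ymin, self.area.ymin + self.area.side])
        fig.colorbar(im, ax=ax, label=f"{self.source_label} per km$^2$")
        fig.savefig(path, dpi=150)
        plt.close(fig)


def estimate_density(points: PointSet, area: StudyArea, kernel: KernelSpec,
                     scale_factor: float = 1.0, chunk: int | None = None,
                     ) -> DensityGrid:
    """KDE of a point set sampled at the grid cell centres.

    The caller is expected to have windowed ``points`` with pad equal to
    the bandwidth, so contributors just outside the area still count
    (border-effect padding).  Evaluation is exact (dense, chunked over
    grid cells); an empty point set yields an all-zero grid with a logged
    warning.
    """
    n_side = area.n_cells_per_side
    grid = grid_geometry(area)
    npts = len(points)
    if npts == 0:
        logger.warning("empty point set %r: all-zero density", points.label)
        return DensityGrid(np.zeros((n_side, n_side)), area, points.label, 0,
                           scale_factor)
    p = points.points
    if chunk is None:
        # keep the (chunk x npts) distance block around ~32 MB
        chunk = max(64, int(4e6 / npts))
    out = np.empty(grid.shape[0])
    norm = _NORMS[kernel.kind](kernel.bandwidth)
    prof = _PROFILES[kernel.kind]
    inv_h = 1.0 / kernel.bandwidth
    for start in range(0, grid.shape[0], chunk):
        g = grid[start:start + chunk]
        dx = g[:, 0, None] - p[None, :, 0]
        dy = g[:, 1, None] - p[None, :, 1]
        u = np.sqrt(dx * dx + dy * dy) * inv_h
        out[start:start + chunk] = prof(u).sum(axis=1)
    values = (out * norm * M2_PER_KM2 * scale_factor).reshape(n_side, n_side)
    return DensityGrid(values, area, points.label, npts, scale_factor)


@dataclass
class BasisMatrix:
    """Column-stacked flattened per-class density rasters (the regressors)."""

    columns: list[str]
    matrix: np.ndarray           # (n_cells^2, n_classes)
    area: StudyArea
    kernel: KernelSpec

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.area.n_cells_per_side ** 2, len(self.columns)):
            raise ValueError("basis matrix shape does not match grid/columns")

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.columns.index(name)]


def build_basis(class_sets: list[PointSet], area: StudyArea, kernel: KernelSpec,
                scale_factor: float = 1.0) -> BasisMatrix:
    """One basis column per class, in the caller's class order.

    Column j is the row-major flattening of the class-j density raster,
    identical in ordering to :func:`grid_geometry`.
    """
    cols = [estimate_density(ps, area, kernel, scale_factor).flatten()
            for ps in class_sets]
    matrix = (np.column_stack(cols) if cols
              else np.empty((area.n_cells_per_side ** 2, 0)))
    return BasisMatrix([ps.label for ps in class_sets], matrix, area, kernel)
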