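"""Organelle spatial-distribution quantification.

Counts pigmented particles in the perinuclear band — the region extending a
fixed distance (2 μm by default) outward from the nucleus border, clipped to
the cell outline — and normalizes by the band area. Geometry is handled by
shapely; outlines may be arbitrary simple polygons or circle approximations.
Particles enter as centroid + size records (the package operates on
coordinates, not pixels; segmentation of micrographs is out of scope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .errors import InvalidParameterError


def _circle_polygon(center: Tuple[float, float], radius: float, resolution: int = 256) -> Polygon:
    """Regular-polygon approximation of a circle (resolution = vertices/quadrant)."""
    return Point(center).buffer(radius, quad_segs=resolution)


@dataclass
class CellGeometry:
    """Nucleus and cell outlines (shapely polygons, μm) plus the band width."""

    nucleus: Polygon
    cell: Polygon
    band_width: float = 2.0

    def __post_init__(self):
        if self.band_width < 0:
            raise InvalidParameterError("band_width must be >= 0")
        for name, poly in (("nucleus", self.nucleus), ("cell", self.cell)):
            if not poly.is_valid:
                raise InvalidParameterError(f"{name} outline is not a simple polygon")

    @classmethod
    def from_circles(
        cls,
        nucleus_center: Tuple[float, float],
        nucleus_radius: float,
        cell_center: Tuple[float, float],
        cell_radius: float,
        band_width: float = 2.0,
        resolution: int = 256,
    ) -> "CellGeometry":
        if not nucleus_radius > 0 or not cell_radius > 0:
            raise InvalidParameterError("radii must be > 0")
        return cls(
            nucleus=_circle_polygon(nucleus_center, nucleus_radius, resolution),
            cell=_circle_polygon(cell_center, cell_radius, resolution),
            band_width=band_width,
        )

    @property
    def nucleus_center(self) -> Tuple[float, float]:
        """Centroid of the nucleus outline (the radial reference point)."""
        c = self.nucleus.centroid
        return (c.x, c.y)


@dataclass
class ParticleSet:
    """Detected particles: centroids in μm, characteristic sizes in nm."""

    x: np.ndarray
    y: np.ndarray
    size_nm: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.size_nm = np.asarray(self.size_nm, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.size_nm)):
            raise InvalidParameterError("x, y, size_nm must have equal length")
        if len(self.size_nm) and np.any(self.size_nm <= 0):
            raise InvalidParameterError("sizes must be > 0")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise InvalidParameterError("centroids must be finite")

    def __len__(self):
        return len(self.x)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ParticleSet":
        return cls(df["x_um"].to_numpy(), df["y_um"].to_numpy(), df["size_nm"].to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"x_um": self.x, "y_um": self.y, "size_nm": self.size_nm})


def read_particles(path, delimiter: str = ",") -> ParticleSet:
    """Read a delimited particle table with columns x_um, y_um, size_nm."""
    return ParticleSet.from_dataframe(pd.read_csv(path, sep=delimiter))


def filter_particles(particles: ParticleSet, min_size_nm: float = 150.0) -> ParticleSet:
    """Retain particles with size ≥ min_size_nm (inclusive); order preserved.

    The inclusive 150 nm default selects resolvable pigmented structures.
    """
    if not min_size_nm > 0:
        raise InvalidParameterError("min_size_nm must be > 0")
    keep = particles.size_nm >= min_size_nm
    return ParticleSet(particles.x[keep], particles.y[keep], particles.size_nm[keep])


def perinuclear_band(geom: CellGeometry):
    """The perinuclear region and its area in μm².

    region = (dilate(nucleus, band_width) − nucleus) ∩ cell.
    A zero band width yields an empty region.
    """
    if geom.band_width == 0:
        from shapely.geometry import Polygon as _P

        return _P(), 0.0
    dilated = geom.nucleus.buffer(geom.band_width, quad_segs=256)
    region = dilated.difference(geom.nucleus).intersection(geom.cell)
    return region, float(region.area)


@dataclass
class PerinuclearResult:
    count: int
    band_area_um2: float
    density_per_um2: float


def perinuclear_density(particles: ParticleSet, geom: CellGeometry) -> PerinuclearResult:
    """Count particles whose centroid lies in the perinuclear band and
    normalize by the band area (count/μm²).

    Centroids on the band boundary count as inside. Apply
    :func:`filter_particles` first to restrict to resolvable structures.
    """
    region, area = perinuclear_band(geom)
    if area == 0.0:
        if len(particles) and any(
            region.covers(Point(x, y)) for x, y in zip(particles.x, particles.y)
        ):
            raise InvalidParameterError("zero-area band cannot contain particles")
        return PerinuclearResult(count=0, band_area_um2=0.0, density_per_um2=0.0)
    prepared = prep(region)
    count = sum(
        1 for x, y in zip(particles.x, particles.y) if prepared.covers(Point(x, y))
    )
    return PerinuclearResult(
        count=count, band_area_um2=area, density_per_um2=count / area
    )


def em_area(length: float, width: float, corrected: bool = False) -> float:
    """Melanosome cross-section 'area' from its length and width.

    The default reproduces the legacy tooling formula length·width·π used for
    the reported measurements; ``corrected=True`` returns the true area of an
    ellipse with those axes as diameters, length·width·π/4. Symmetric in its
    arguments; units follow the caller's (nm in → nm² out).
    """
    if not (length > 0 and width > 0):
        raise InvalidParameterError("length and width must be > 0")
    area = length * width * math.pi
    return area / 4.0 if corrected else area
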