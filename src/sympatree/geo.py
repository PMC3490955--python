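"""Quadrat-grid species ranges and pairwise degree of sympatry.

Point locality records are turned into species ranges by rasterising a small
circular neighbourhood of every collection spot onto a fixed latitude x
longitude grid (default 0.025 degree cells, 8 km diameter circles).  Range
size is then a quadrat count times the cell area, and the degree of sympatry
of two species is the number of shared quadrats divided by the quadrat count
of the smaller range -- 0 for fully allopatric pairs, 1 when the smaller
range is nested inside the larger.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "EARTH_RADIUS_KM",
    "KM_PER_DEG_LAT",
    "GridSpec",
    "LocalityTable",
    "RangeMap",
    "OverlapMatrix",
    "haversine_km",
    "rasterize_ranges",
    "range_area_km2",
    "degree_of_sympatry",
    "overlap_matrix",
]

EARTH_RADIUS_KM = 6371.0
#: Length of one degree of latitude (and of longitude at the equator).
KM_PER_DEG_LAT = 111.32


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = (
        math.sin(dphi / 2.0) ** 2
        + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


@dataclass(frozen=True)
class GridSpec:
    """Rasterisation grid: cell size, lattice anchor and range-circle radius.

    ``radius_km`` is half the diameter of the circular area credited to each
    locality (default 4 km, i.e. an 8 km diameter circle).  Quadrat ``(i, j)``
    is the half-open cell ``[lat0 + i*cell, lat0 + (i+1)*cell) x
    [lon0 + j*cell, lon0 + (j+1)*cell)``.
    """

    cell_deg: float = 0.025
    origin: tuple[float, float] = (0.0, 0.0)
    radius_km: float = 4.0

    def __post_init__(self):
        if not self.cell_deg > 0:
            raise ValueError("cell_deg must be > 0")
        if not self.radius_km > 0:
            raise ValueError("radius_km must be > 0")

    def quadrat_of(self, lat: float, lon: float) -> tuple[int, int]:
        lat0, lon0 = self.origin
        return (
            int(math.floor((lat - lat0) / self.cell_deg)),
            int(math.floor((lon - lon0) / self.cell_deg)),
        )

    def center(self, i: int, j: int) -> tuple[float, float]:
        lat0, lon0 = self.origin
        return (
            lat0 + (i + 0.5) * self.cell_deg,
            lon0 + (j + 0.5) * self.cell_deg,
        )

    def to_dict(self) -> dict:
        return {
            "cell_deg": self.cell_deg,
            "origin": list(self.origin),
            "radius_km": self.radius_km,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GridSpec":
        return cls(
            cell_deg=float(d["cell_deg"]),
            origin=tuple(d["origin"]),
            radius_km=float(d["radius_km"]),
        )


@dataclass(frozen=True)
class LocalityTable:
    """Validated point locality records: (species, lat, lon) rows."""

    records: tuple[tuple[str, float, float], ...]

    def __post_init__(self):
        if not self.records:
            raise ValueError("locality table is empty")
        for k, (sp, lat, lon) in enumerate(self.records):
            if not sp:
                raise ValueError(f"record {k}: empty species name")
            if not (-90.0 <= lat <= 90.0):
                raise ValueError(
                    f"record {k} ({sp}): latitude {lat} outside [-90, 90]"
                )
            if not (-180.0 <= lon <= 180.0):
                raise ValueError(
                    f"record {k} ({sp}): longitude {lon} outside [-180, 180]"
                )

    @classmethod
    def from_records(cls, rows: Iterable[tuple[str, float, float]]):
        return cls(tuple((str(s), float(a), float(o)) for s, a, o in rows))

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for sp, _, _ in self.records:
            seen.setdefault(sp)
        return list(seen)

    def by_species(self) -> dict[str, list[tuple[float, float]]]:
        out: dict[str, list[tuple[float, float]]] = {}
        for sp, lat, lon in self.records:
            out.setdefault(sp, []).append((lat, lon))
        return out

    def counts(self) -> dict[str, int]:
        return {sp: len(v) for sp, v in self.by_species().items()}

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class RangeMap:
    """Species -> set of occupied integer quadrat indices on a grid."""

    quadrats: Mapping[str, frozenset]
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self):
        for sp, qs in self.quadrats.items():
            if not qs:
                raise ValueError(f"species {sp!r} has an empty quadrat set")

    @property
    def species(self) -> list[str]:
        return list(self.quadrats)

    def __contains__(self, sp: str) -> bool:
        return sp in self.quadrats

    def __getitem__(self, sp: str) -> frozenset:
        if sp not in self.quadrats:
            raise KeyError(f"species {sp!r} not in range map")
        return self.quadrats[sp]

    def to_json(self) -> str:
        payload = {
            "grid": self.grid.to_dict(),
            "quadrats": {
                sp: sorted(map(list, qs)) for sp, qs in self.quadrats.items()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RangeMap":
        d = json.loads(text)
        return cls(
            quadrats={
                sp: frozenset(map(tuple, qs))
                for sp, qs in d["quadrats"].items()
            },
            grid=GridSpec.from_dict(d["grid"]),
        )


class OverlapMatrix:
    """Symmetric species x species degree-of-sympatry matrix, diagonal 1."""

    def __init__(self, species: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(species)
        if values.shape != (n, n):
            raise ValueError("matrix shape does not match species list")
        if len(set(species)) != n:
            raise ValueError("duplicate species names")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("overlap matrix must be symmetric")
        if np.any(values < -1e-12) or np.any(values > 1 + 1e-12):
            raise ValueError("overlap values must lie in [0, 1]")
        if not np.allclose(np.diag(values), 1.0, atol=1e-12):
            raise ValueError("overlap diagonal must be 1")
        self.species = list(species)
        self.values = np.clip(values, 0.0, 1.0)
        self._idx = {sp: k for k, sp in enumerate(self.species)}

    def index_of(self, sp: str) -> int:
        return self._idx[sp]

    def value(self, a: str, b: str) -> float:
        return float(self.values[self._idx[a], self._idx[b]])

    def reorder(self, species: list[str]) -> "OverlapMatrix":
        ix = [self._idx[sp] for sp in species]
        return OverlapMatrix(species, self.values[np.ix_(ix, ix)])

    def to_tsv(self) -> str:
        header = "species\t" + "\t".join(self.species)
        rows = [
            sp + "\t" + "\t".join(f"{v:.6g}" for v in self.values[k])
            for k, sp in enumerate(self.species)
        ]
        return "\n".join([header] + rows) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "OverlapMatrix":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        species = lines[0].split("\t")[1:]
        vals = np.array(
            [[float(v) for v in ln.split("\t")[1:]] for ln in lines[1:]]
        )
        return cls(species, vals)


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------
def _circle_quadrats(
    lat: float, lon: float, grid: GridSpec
) -> set[tuple[int, int]]:
    """Quadrats whose centers lie within radius_km of the point.

    The quadrat containing the point itself is always included, so even a
    degenerate configuration (radius smaller than half a cell) yields a
    non-empty range.
    """
    out = {grid.quadrat_of(lat, lon)}
    dlat_cells = int(
        math.ceil(grid.radius_km / (KM_PER_DEG_LAT * grid.cell_deg))
    ) + 1
    coslat = max(math.cos(math.radians(lat)), 1e-9)
    dlon_cells = int(
        math.ceil(grid.radius_km / (KM_PER_DEG_LAT * coslat * grid.cell_deg))
    ) + 1
    i0, j0 = grid.quadrat_of(lat, lon)
    for i in range(i0 - dlat_cells, i0 + dlat_cells + 1):
        for j in range(j0 - dlon_cells, j0 + dlon_cells + 1):
            clat, clon = grid.center(i, j)
            if haversine_km(lat, lon, clat, clon) <= grid.radius_km:
                out.add((i, j))
    return out


def rasterize_ranges(
    localities: LocalityTable, grid: GridSpec | None = None
) -> RangeMap:
    """Union, per species, of the quadrat circles around its localities."""
    grid = grid or GridSpec()
    quadrats: dict[str, frozenset] = {}
    for sp, points in localities.by_species().items():
        qs: set[tuple[int, int]] = set()
        for lat, lon in points:
            qs |= _circle_quadrats(lat, lon, grid)
        quadrats[sp] = frozenset(qs)
    return RangeMap(quadrats=quadrats, grid=grid)


def range_area_km2(rangemap: RangeMap, species: str) -> float:
    """Occupied-quadrat count times cell area at the range's mean latitude.

    Cell area is ``(cell*111.32 km) x (cell*111.32*cos(phi) km)`` with phi
    the mean latitude of the species' occupied quadrat centers; over an
    island spanning ~2 degrees of latitude the error of this flat-cell
    approximation is below 1%.
    """
    qs = rangemap[species]
    grid = rangemap.grid
    mean_lat = float(np.mean([grid.center(i, j)[0] for i, j in qs]))
    side = grid.cell_deg * KM_PER_DEG_LAT
    area_cell = side * side * math.cos(math.radians(mean_lat))
    if not area_cell > 0:
        raise ValueError("degenerate cell area at |latitude| >= 90")
    return len(qs) * area_cell


def degree_of_sympatry(rangemap: RangeMap, a: str, b: str) -> float:
    """|Qa & Qb| / min(|Qa|, |Qb|) -- shared fraction of the smaller range."""
    qa, qb = rangemap[a], rangemap[b]
    return len(qa & qb) / min(len(qa), len(qb))


def overlap_matrix(rangemap: RangeMap) -> OverlapMatrix:
    """All pairwise degrees of sympatry (symmetric, unit diagonal)."""
    species = rangemap.species
    n = len(species)
    if n < 2:
        raise ValueError("need at least 2 species for an overlap matrix")
    vals = np.eye(n)
    for x in range(n):
        for y in range(x + 1, n):
            v = degree_of_sympatry(rangemap, species[x], species[y])
            vals[x, y] = vals[y, x] = v
    return OverlapMatrix(species, vals)
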