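"""The 24-2 and 30-2 perimetric test grids.

Coordinates follow the right-eye convention: x is horizontal eccentricity in
degrees with temporal positive (so the physiologic blind spot sits at +15),
y is vertical eccentricity with superior positive.  Left-eye data are
mirrored (x -> -x) at ingestion so that one canonical frame is used for all
pooling.  The 24-2 pattern has 54 points on a 6-degree lattice offset 3
degrees from both meridians, extending to 27 degrees on the nasal side of
the two rows straddling the horizontal meridian; two points fall on the
blind spot and are excluded from every analysis.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

import pandas as pd

#: eccentricity bands used when stratifying variability by distance from fixation
BANDS = ("central10", "mid10to20", "peripheral_gt20")

BLIND_SPOT_XY = ((15.0, 3.0), (15.0, -3.0))


def band_of(eccentricity_deg: float) -> str:
    """Eccentricity band with cut points at 10 and 20 degrees."""
    if eccentricity_deg < 10.0:
        return "central10"
    if eccentricity_deg <= 20.0:
        return "mid10to20"
    return "peripheral_gt20"


@dataclass(frozen=True)
class TestLocation:
    """A single perimetric test location."""

    index: int
    x_deg: float
    y_deg: float
    is_blind_spot: bool

    @property
    def eccentricity_deg(self) -> float:
        return math.hypot(self.x_deg, self.y_deg)

    @property
    def band(self) -> str:
        return band_of(self.eccentricity_deg)


def _lattice(rows: dict[float, Iterable[float]], blind_spot: tuple = ()) -> tuple[TestLocation, ...]:
    pts = []
    # top row first, left to right, as the points are usually printed
    for y in sorted(rows, reverse=True):
        for x in sorted(rows[y]):
            pts.append((x, y))
    return tuple(
        TestLocation(index=i, x_deg=x, y_deg=y, is_blind_spot=(x, y) in blind_spot)
        for i, (x, y) in enumerate(pts)
    )


@lru_cache(maxsize=None)
def grid_24_2() -> tuple[TestLocation, ...]:
    """The 54-point 24-2 grid (right-eye convention, temporal positive x).

    Rows at y = +/-3 carry the 27-degree nasal extension (x = -27); the
    blind spot is at (15, +/-3).
    """
    half = [-21.0, -15.0, -9.0, -3.0, 3.0, 9.0, 15.0, 21.0]
    rows = {
        21.0: [-9.0, -3.0, 3.0, 9.0],
        15.0: [-15.0, -9.0, -3.0, 3.0, 9.0, 15.0],
        9.0: half,
        3.0: [-27.0] + half,
        -3.0: [-27.0] + half,
        -9.0: half,
        -15.0: [-15.0, -9.0, -3.0, 3.0, 9.0, 15.0],
        -21.0: [-9.0, -3.0, 3.0, 9.0],
    }
    return _lattice(rows, BLIND_SPOT_XY)


@lru_cache(maxsize=None)
def grid_30_2() -> tuple[TestLocation, ...]:
    """The 76-point 30-2 grid; the 24-2 pattern is a subset of it."""
    rows = {}
    for ay, nx in ((3.0, 5), (9.0, 5), (15.0, 4), (21.0, 3), (27.0, 2)):
        xs = [3.0 + 6.0 * k for k in range(nx)]
        xs = [-x for x in reversed(xs)] + xs
        rows[ay] = xs
        rows[-ay] = list(xs)
    return _lattice(rows, BLIND_SPOT_XY)


N_LOCATIONS = 54
NON_BLIND_INDICES = tuple(loc.index for loc in grid_24_2() if not loc.is_blind_spot)
BLIND_SPOT_INDICES = tuple(loc.index for loc in grid_24_2() if loc.is_blind_spot)


def subset_30_2_indices() -> tuple[int, ...]:
    """Indices into the 30-2 grid selecting the 54 shared 24-2 locations,
    ordered exactly as :func:`grid_24_2`."""
    lookup = {(loc.x_deg, loc.y_deg): loc.index for loc in grid_30_2()}
    out = []
    for loc in grid_24_2():
        key = (loc.x_deg, loc.y_deg)
        if key not in lookup:  # pragma: no cover - grids are fixed
            raise ValueError(f"24-2 location {key} missing from the 30-2 grid")
        out.append(lookup[key])
    return tuple(out)


def grid_frame(grid: tuple[TestLocation, ...] | None = None) -> pd.DataFrame:
    """Tabular view of a grid (index, x_deg, y_deg, blind_spot, band)."""
    grid = grid_24_2() if grid is None else grid
    return pd.DataFrame(
        {
            "index": [p.index for p in grid],
            "x_deg": [p.x_deg for p in grid],
            "y_deg": [p.y_deg for p in grid],
            "blind_spot": [p.is_blind_spot for p in grid],
            "band": [p.band for p in grid],
        }
    )


def export_grid(path, grid: tuple[TestLocation, ...] | None = None) -> None:
    grid_frame(grid).to_csv(path, sep="\t", index=False)


def grid_hash() -> str:
    """Stable content hash of the 24-2 grid (serialization invariance check)."""
    payload = ";".join(
        f"{p.index},{p.x_deg:.1f},{p.y_deg:.1f},{int(p.is_blind_spot)},{p.band}"
        for p in grid_24_2()
    )
    return hashlib.sha256(payload.encode()).hexdigest()
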