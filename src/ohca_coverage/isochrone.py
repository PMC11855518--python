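"""Ambulance service areas: travel-time field from bases and 5/10/15-min bands.

The field is a raster (cell-level) classification on the demand grid:
each cell's time is the straight-line travel time from its centroid to the
nearest ambulance base under ideal conditions (free-flow speed, no dispatch
delay).  A ``realistic`` flag adds the median dispatch delay and the
day-average congestion multiplier, for maps of observed rather than ideal
coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mclp import DemandGrid
from .synth_city import SyntheticCity

BANDS = ("<=5 min", "<=10 min", "<=15 min", ">15 min")
_BAND_EDGES_MIN = (5.0, 10.0, 15.0)


def classify_band(minutes: float) -> str:
    for edge, label in zip(_BAND_EDGES_MIN, BANDS):
        if minutes <= edge:
            return label
    return BANDS[-1]


@dataclass(frozen=True)
class TravelTimeField:
    grid: DemandGrid
    minutes_to_nearest_base: np.ndarray  # per cell, aligned with grid.cells
    band: tuple[str, ...]


def travel_time_field(
    city: SyntheticCity, grid: DemandGrid, realistic: bool = False
) -> TravelTimeField:
    """Minutes from each cell centroid to the nearest base.

    Ideal conditions by default: distance / ambulance free-flow speed, no
    dispatch component.  With ``realistic=True`` the travel leg is scaled by
    the day-average congestion multiplier and the median dispatch delay is
    added, approximating observed response times.
    """
    if not city.bases:
        raise ValueError("city has no ambulance bases configured")
    cells = grid.cells
    if not cells:
        return TravelTimeField(grid, np.zeros(0), ())
    cents = np.array([c.centroid for c in cells], dtype=float)
    bases = np.array(city.bases, dtype=float)
    d = np.linalg.norm(cents[:, None, :] - bases[None, :, :], axis=2).min(axis=1)
    seconds = d / city.ambulance_speed
    if realistic:
        hours = np.linspace(0.0, 24.0, 97)[:-1]
        seconds = seconds * float(np.mean(city.congestion.multiplier(hours)))
        seconds = seconds + city.dispatch_delay_params[0]
    minutes = seconds / 60.0
    return TravelTimeField(
        grid=grid,
        minutes_to_nearest_base=minutes,
        band=tuple(classify_band(m) for m in minutes),
    )


def band_areas(field: TravelTimeField) -> dict[str, float]:
    """Total cell area (m^2) per band; bands partition the grid area."""
    cell_area = field.grid.cell_size_m ** 2
    out = {b: 0.0 for b in BANDS}
    for b in field.band:
        out[b] += cell_area
    return out
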