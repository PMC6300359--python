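"""Sarcomere filament geometry and the force-sarcomere-length relation.

Normalized active force as a function of sarcomere length (SL) follows
from thin/thick filament overlap.  With thin filament length TFL, thick
filament length 1.6 um and bare-zone width 0.15 um, force is maximal
(plateau) where the thin filament tips lie within the bare zone,
SL in [2*TFL - bare, 2*TFL + bare]; it decreases linearly on the
descending limb to zero at zero overlap (2*TFL + thick) and on the
ascending limb below the plateau, both with slope magnitude
1/(thick - bare) per um (~69% of maximal force per um).

Working-range averages are computed on a 0.05 um SL grid; auxiliary
conversions cover thin-filament length from Tmod-Tmod epitope distances,
end-inspiration SL from strain amplitude, serial sarcomere counts, and
sarcomere length during whole-muscle stretch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

THICK_FILAMENT_UM = 1.6
BARE_ZONE_UM = 0.15


@dataclass(frozen=True)
class FilamentGeometry:
    """Filament lengths in um."""

    thin_filament_length: float
    thick_filament_length: float = THICK_FILAMENT_UM
    bare_zone: float = BARE_ZONE_UM

    def __post_init__(self) -> None:
        if not 0 < self.bare_zone < self.thick_filament_length:
            raise InvalidInputError(
                "bare_zone must satisfy 0 < bare_zone < thick_filament_length"
            )
        if self.thin_filament_length <= self.thick_filament_length / 2:
            raise InvalidInputError(
                "thin_filament_length must exceed half the thick filament length"
            )


@dataclass(frozen=True)
class ForceSLRelation:
    """Piecewise-linear normalized force vs SL with explicit breakpoints."""

    plateau_lo: float
    plateau_hi: float
    zero_overlap: float
    limb_slope: float  # fraction of maximal force per um

    def force_at(self, sl):
        """Normalized force in [0, 1] at sarcomere length ``sl`` (um)."""
        sl_arr = np.asarray(sl, dtype=float)
        if np.any(sl_arr <= 0):
            raise InvalidInputError("sarcomere length must be positive")
        descending = 1.0 - self.limb_slope * (sl_arr - self.plateau_hi)
        ascending = 1.0 - self.limb_slope * (self.plateau_lo - sl_arr)
        out = np.where(
            sl_arr > self.plateau_hi,
            descending,
            np.where(sl_arr < self.plateau_lo, ascending, 1.0),
        )
        out = np.clip(out, 0.0, 1.0)
        return float(out) if np.isscalar(sl) else out


@dataclass(frozen=True)
class WorkingRange:
    """In vivo sarcomere-length span, um."""

    sl_min: float
    sl_max: float

    def __post_init__(self) -> None:
        if not 0 < self.sl_min < self.sl_max:
            raise InvalidInputError("require 0 < sl_min < sl_max")


def build_force_sl_relation(
    geometry: FilamentGeometry,
    plateau_convention: str = "bare-zone-edge",
) -> ForceSLRelation:
    """Force-SL relation from filament geometry.

    ``plateau_convention="bare-zone-edge"`` (default) starts the ascending
    limb where the thin filament tip passes the bare-zone edge of the
    adjacent half-sarcomere (plateau from 2*TFL - bare); ``"tfl"`` starts
    it at 2*TFL (no lower plateau extension).
    """
    if plateau_convention not in ("bare-zone-edge", "tfl"):
        raise InvalidInputError(f"unknown plateau convention {plateau_convention!r}")
    tfl, thick, bare = (
        geometry.thin_filament_length,
        geometry.thick_filament_length,
        geometry.bare_zone,
    )
    plateau_lo = 2 * tfl - bare if plateau_convention == "bare-zone-edge" else 2 * tfl
    return ForceSLRelation(
        plateau_lo=plateau_lo,
        plateau_hi=2 * tfl + bare,
        zero_overlap=2 * tfl + thick,
        limb_slope=1.0 / (thick - bare),
    )


def force_at(relation: ForceSLRelation, sl):
    """Functional alias for :meth:`ForceSLRelation.force_at`."""
    return relation.force_at(sl)


def working_range_grid(
    sl_min: float, sl_max: float, step: float = 0.05
) -> np.ndarray:
    """SL grid anchored at sl_min with sl_max appended if off-grid."""
    if not 0 < sl_min < sl_max:
        raise InvalidInputError("require 0 < sl_min < sl_max")
    grid = np.arange(sl_min, sl_max + 1e-9, step)
    if grid[-1] < sl_max - 1e-9:
        grid = np.append(grid, sl_max)
    return grid


def average_force_in_range(
    relation: ForceSLRelation,
    working_range: WorkingRange | tuple[float, float],
    step: float = 0.05,
) -> float:
    """Mean normalized force over the working range, as percent of maximal.

    Forces are evaluated at ``step`` (default 0.05 um) increments starting
    at the range minimum, with the maximum appended when off-grid.
    """
    if isinstance(working_range, tuple):
        working_range = WorkingRange(*working_range)
    if working_range.sl_max > relation.zero_overlap + 1e-9:
        raise InvalidInputError(
            "working range extends beyond zero-overlap sarcomere length"
        )
    grid = working_range_grid(working_range.sl_min, working_range.sl_max, step)
    return float(100.0 * np.mean(relation.force_at(grid)))


def tfl_from_tmod_distance(tmod_to_tmod_nm: float) -> float:
    """Thin filament length (nm): half the Tmod-Tmod distance across a Z-disk.

    The result includes the half Z-disk width by construction.
    """
    if tmod_to_tmod_nm <= 0:
        raise InvalidInputError("Tmod-Tmod distance must be positive")
    return tmod_to_tmod_nm / 2.0


def end_inspiration_sl(arrest_sl_um: float, strain_amplitude: float) -> float:
    """Minimal (end-inspiration) SL from the arrest SL and strain amplitude.

    Strain amplitude is the fractional fiber shortening during
    inspiration: SL_min = SL_arrest * (1 - eps).
    """
    if arrest_sl_um <= 0:
        raise InvalidInputError("arrest sarcomere length must be positive")
    if not 0 <= strain_amplitude < 1:
        raise InvalidInputError("strain amplitude must be in [0, 1)")
    return arrest_sl_um * (1.0 - strain_amplitude)


def serial_sarcomere_count(fiber_length_um: float, sl_um: float) -> float:
    """Number of sarcomeres in series: fiber length / sarcomere length."""
    if fiber_length_um <= 0 or sl_um <= 0:
        raise InvalidInputError("fiber length and sarcomere length must be positive")
    return fiber_length_um / sl_um


def sl_during_stretch(
    slack_sl_um: float, percent_stretch: float, fl_ml_ratio: float
) -> float:
    """SL during a whole-muscle stretch of ``percent_stretch`` of slack length.

    Fibers spanning only part of the muscle stretch more than the muscle:
    SL = SL_slack * (1 + (percent/100) / fiber-to-muscle-length ratio).
    """
    if not 0 < fl_ml_ratio <= 1:
        raise InvalidInputError("fiber length : muscle length ratio must be in (0, 1]")
    if percent_stretch < 0:
        raise InvalidInputError("percent stretch must be >= 0")
    if slack_sl_um <= 0:
        raise InvalidInputError("slack sarcomere length must be positive")
    return slack_sl_um * (1.0 + (percent_stretch / 100.0) / fl_ml_ratio)
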