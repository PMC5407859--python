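"""Morphometric quantities of the hair-bundle staircase.

Staircase steps (row-1 minus shorter-row tip heights), heights relative to
the tallest row, tip-diameter profiles, wedge-tip heights, tip-link
classification and per-cell tip-link percentages, and supernumerary counts.
Heights are tip-apex heights ("highest point" of the stereocilium),
deliberately ignoring tip-shape changes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .geometry import Bundle, GeometryError, StereociliumGeometry, _check_tau

__all__ = [
    "TipProfile",
    "Link",
    "MorphometryRecord",
    "SHAFT_SENTINEL",
    "DEFAULT_DIAMETER_POSITIONS",
    "compute_steps",
    "step_from_projection",
    "relative_heights",
    "diameter_profile",
    "wedge_tip_height",
    "classify_tip_link",
    "tip_link_percentage",
    "count_supernumerary",
    "bundle_morphometry",
]

#: Sentinel position mapping to the mid-shaft diameter.
SHAFT_SENTINEL = "shaft"

#: Default measurement positions (um from the tip apex) plus the shaft.
DEFAULT_DIAMETER_POSITIONS: tuple = (0.025, 0.05, 0.1, 0.2, SHAFT_SENTINEL)


@dataclass(frozen=True)
class TipProfile:
    """Power-law taper of a stereocilium tip.

    The diameter at axial distance ``s`` (um) from the apex is

        diameter(s) = shaft_diameter * min(1, (s / L) ** gamma)

    with ``L`` the axial extent of the tapered region and ``gamma`` a shape
    exponent: gamma ~ 0.5 renders a blunt/rounded tip, gamma ~ 1 a conical
    wedge, gamma > 1 an abnormally thin "pointed" tip.  A single exponent
    spans all three regimes observed in SEM while keeping every tip statistic
    available in closed form.
    """

    tip_length_L: float = 0.3
    taper_gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.tip_length_L < 0:
            raise ValueError(f"tip_length_L must be >= 0, got {self.tip_length_L}")
        if self.taper_gamma <= 0:
            raise ValueError(f"taper_gamma must be > 0, got {self.taper_gamma}")

    def diameter(self, s: float, shaft_diameter: float) -> float:
        """Diameter (um) at axial distance ``s`` from the apex."""
        if s < 0:
            raise ValueError(f"position must be >= 0, got {s}")
        if self.tip_length_L == 0.0 or s >= self.tip_length_L:
            return float(shaft_diameter)
        return float(shaft_diameter * (s / self.tip_length_L) ** self.taper_gamma)


@dataclass(frozen=True)
class Link:
    """An extracellular link between two stereocilia of the same bundle.

    ``origin_region`` locates where the link leaves the (shorter) origin
    stereocilium; ``direction_axis_component`` is the sign of the link vector
    along the mechanosensitivity axis (positive toward taller rows) and
    ``elevation_sign`` the sign of its vertical component.
    """

    origin_stereocilium_id: str
    target_stereocilium_id: str
    origin_region: Literal["top_cap", "tip_hemisphere_other", "shaft"]
    direction_axis_component: int
    elevation_sign: int

    def __post_init__(self) -> None:
        if self.origin_stereocilium_id == self.target_stereocilium_id:
            raise ValueError("link origin and target must be distinct stereocilia")


@dataclass
class MorphometryRecord:
    stereocilium_id: str
    row: int | str
    height: float
    relative_height_pct: float
    step_from_row1: float | None
    diameter_profile: list[tuple[object, float]]
    wedge_tip_height: float
    has_tip_link: bool


# ---------------------------------------------------------------------------
# Steps and relative heights
# ---------------------------------------------------------------------------


def compute_steps(
    bundle_heights: dict,
) -> tuple[float | None, float | None]:
    """Staircase steps (um) from per-row heights of one bundle.

    ``bundle_heights`` maps row rank to a height or an iterable of heights;
    row 1 is averaged to give the per-bundle reference.  Returns
    ``(step_1_2, step_1_3)``, each ``None`` when the corresponding row is
    absent (a missing row is reported absent, never as a zero step).
    """
    if 1 not in bundle_heights:
        raise GeometryError("cannot compute steps: bundle has no row-1 height")
    h1 = float(np.mean(np.atleast_1d(np.asarray(bundle_heights[1], dtype=float))))

    def _step(row: int) -> float | None:
        if row not in bundle_heights:
            return None
        h = float(np.mean(np.atleast_1d(np.asarray(bundle_heights[row], dtype=float))))
        return h1 - h

    return _step(2), _step(3)


def step_from_projection(
    p_step: float, tau: float, d: float, alpha: float, row: int
) -> float:
    """Staircase step directly from a front-view step projection.

    Skips the reconstruction of absolute heights (fewer calculations, hence
    more accurate for small staircase changes):

        step_1_row = (p_step + sign(tau) * (row-1) * d * cos(alpha+tau)) / |sin tau|
    """
    if row not in (2, 3):
        raise ValueError(f"row must be 2 or 3, got {row}")
    _check_tau(tau)
    t = math.radians(tau)
    a = math.radians(alpha)
    sign = 1.0 if tau > 0 else -1.0
    return float(
        (p_step + sign * (row - 1) * d * math.cos(a + t)) / abs(math.sin(t))
    )


def relative_heights(h, h1: float):
    """Height as a percent of the tallest (first) row: ``100 * h / h1``."""
    if h1 <= 0:
        raise ValueError(f"row-1 reference height must be > 0, got {h1}")
    return 100.0 * np.asarray(h, dtype=float) / h1 if np.ndim(h) else 100.0 * h / h1


# ---------------------------------------------------------------------------
# Tip shape
# ---------------------------------------------------------------------------


def diameter_profile(
    profile: TipProfile,
    shaft_diameter: float,
    positions: Sequence = DEFAULT_DIAMETER_POSITIONS,
) -> list[float]:
    """Diameters (um) at given axial positions from the apex.

    Positions are um from the tip apex; the string ``"shaft"`` is a sentinel
    for the mid-shaft diameter.
    """
    out = []
    for s in positions:
        if isinstance(s, str):
            if s != SHAFT_SENTINEL:
                raise ValueError(f"unknown position sentinel {s!r}")
            out.append(float(shaft_diameter))
        else:
            out.append(profile.diameter(float(s), shaft_diameter))
    return out


def wedge_tip_height(
    profile: TipProfile,
    shaft_diameter: float,
    threshold_fraction: float = 0.95,
) -> float:
    """Axial extent (um) of the wedge-shaped tip region.

    Smallest distance ``s`` from the apex at which the diameter reaches
    ``threshold_fraction`` of the shaft diameter; under the power-law family
    this is ``L * threshold ** (1/gamma)``.  The 0.95 default places the
    wedge boundary where the taper effectively meets the shaft.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError(
            f"threshold_fraction must be in (0, 1), got {threshold_fraction}"
        )
    if profile.tip_length_L == 0.0:
        return 0.0
    return float(profile.tip_length_L * threshold_fraction ** (1.0 / profile.taper_gamma))


# ---------------------------------------------------------------------------
# Tip links
# ---------------------------------------------------------------------------

_ROW_ORDER = {1: 1, 2: 2, 3: 3, 4: 4, 5: 5, "unranked": 99}


def _rank(row) -> int:
    try:
        return _ROW_ORDER[row]
    except KeyError:
        raise ValueError(f"unknown row rank {row!r}") from None


def classify_tip_link(link: Link, origin_row, target_row) -> bool:
    """True iff the link is a tip link.

    A tip link extends obliquely from the top cap of a shorter (lower-row)
    stereocilium, upward and toward the taller rows along the bundle's
    mechanosensitivity axis.  Links originating elsewhere on the tip
    hemisphere or on the shaft, lateral links, and downward links are not
    tip links.
    """
    return (
        link.origin_region == "top_cap"
        and _rank(origin_row) > _rank(target_row)
        and link.direction_axis_component > 0
        and link.elevation_sign > 0
    )


def tip_link_percentage(
    per_cell: Sequence[tuple[int, int]],
) -> tuple[float, float]:
    """Mean +/- SE across cells of the per-cell tip-link percentage.

    ``per_cell`` holds ``(n_with_link, n_total)`` per cell.  Per-stereocilium
    counts are converted to a percentage per cell first; dispersion is the
    standard error across cells (the convention for percentage panels).  With
    a single cell the SE is undefined and returned as NaN with a warning.
    """
    if len(per_cell) == 0:
        raise ValueError("tip_link_percentage needs at least one cell")
    pcts = []
    for k, n in per_cell:
        if n <= 0:
            raise ValueError(f"cell with n_total = {n} <= 0")
        if not 0 <= k <= n:
            raise ValueError(f"n_with_link = {k} outside [0, {n}]")
        pcts.append(100.0 * k / n)
    pcts = np.asarray(pcts, dtype=float)
    mean = float(pcts.mean())
    if len(pcts) == 1:
        warnings.warn("single cell: SE of the percentage is undefined", stacklevel=2)
        return mean, float("nan")
    se = float(pcts.std(ddof=1) / math.sqrt(len(pcts)))
    return mean, se


def count_supernumerary(bundle: Bundle) -> int:
    """Number of supernumerary stereocilia (rank >= 4 or unranked)."""
    return sum(1 for s in bundle.stereocilia if s.is_supernumerary)


# ---------------------------------------------------------------------------
# Bundle-level table
# ---------------------------------------------------------------------------


def bundle_morphometry(
    bundle: Bundle,
    diameter_positions: Sequence = DEFAULT_DIAMETER_POSITIONS,
    wedge_threshold: float = 0.95,
) -> pd.DataFrame:
    """Tidy morphometry table (one row per stereocilium) for one bundle."""
    h1 = bundle.row_mean_height(1)
    links_by_origin: dict[str, list[Link]] = {}
    for s in bundle.stereocilia:
        for link in s.links:
            links_by_origin.setdefault(link.origin_stereocilium_id, []).append(link)
    rows_by_id = {s.id: s.row for s in bundle.stereocilia}

    records = []
    for s in bundle.stereocilia:
        has_tl = any(
            classify_tip_link(link, rows_by_id[link.origin_stereocilium_id],
                              rows_by_id[link.target_stereocilium_id])
            for link in links_by_origin.get(s.id, [])
        )
        profile = s.tip_profile or TipProfile()
        rec = dict(
            bundle_id=bundle.id,
            cell_type=bundle.cell_type,
            stereocilium_id=s.id,
            row=s.row,
            height_um=s.height_h,
            relative_height_pct=relative_heights(s.height_h, h1),
            step_from_row1_um=(h1 - s.height_h) if s.row in (2, 3) else np.nan,
            wedge_tip_height_um=wedge_tip_height(profile, s.shaft_diameter,
                                                 wedge_threshold),
            has_tip_link=has_tl,
        )
        for pos, dia in zip(diameter_positions,
                            diameter_profile(profile, s.shaft_diameter,
                                             diameter_positions)):
            label = pos if isinstance(pos, str) else f"{pos:g}um"
            rec[f"diameter_{label}"] = dia
        records.append(rec)
    return pd.DataFrame(records)
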