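"""Numerical density, allometric biomass, and swarm-geometry summaries.

Density is counts per imaged volume: the number of countable (resolvable)
prey in a frame divided by the pyramidal volume that frame samples.
Biomass density multiplies numerical density by the weight of an
individual at the reference length, via the length-weight power law
``w = a * L**b`` (L in mm, w in g).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import DiveEvent
from .errors import ValidationError


@dataclass(frozen=True)
class AllometryParams:
    """Length-weight power law ``w = a * L**b`` for the prey.

    Defaults are for Antarctic krill in the Antarctic Peninsula region:
    a = 2.236e-6, b = 3.314 (L in mm total length, w in g wet weight).
    """

    a: float = 2.236e-6
    b: float = 3.314

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValidationError("allometry parameters a and b must be positive")


@dataclass(frozen=True)
class DensityResult:
    """Per-image densities and their summary statistics.

    ``per_image`` has columns ``image_id``, ``count`` and
    ``density_krill_per_m3``; summaries are recomputable from it
    (sd uses the n-1 denominator).
    """

    per_image: pd.DataFrame
    volume_m3: float
    mean: float
    sd: float
    median: float
    min: float
    max: float


def density_per_image(counts: pd.DataFrame, volume_m3: float) -> DensityResult:
    """Convert per-image counts into volumetric densities.

    Parameters
    ----------
    counts
        DataFrame with columns ``image_id`` and ``count`` (as produced by
        :func:`preyfield.annotations.countable_per_image`).  Zero counts
        are retained and contribute density 0.
    volume_m3
        Imaged volume per frame, from the optics chain.
    """
    if not volume_m3 > 0:
        raise ValidationError(f"volume_m3 must be positive, got {volume_m3}")
    if not {"image_id", "count"} <= set(counts.columns):
        raise ValidationError("counts must have columns image_id and count")
    c = counts["count"].to_numpy(dtype=float)
    if np.any(c < 0):
        raise ValidationError("counts must be non-negative")
    dens = c / volume_m3
    per_image = counts[["image_id", "count"]].copy()
    per_image["density_krill_per_m3"] = dens
    return DensityResult(
        per_image=per_image,
        volume_m3=float(volume_m3),
        mean=float(dens.mean()),
        sd=float(dens.std(ddof=1)) if dens.size > 1 else 0.0,
        median=float(np.median(dens)),
        min=float(dens.min()),
        max=float(dens.max()),
    )


def krill_weight_g(L_mm: float, params: AllometryParams | None = None) -> float:
    """Individual wet weight (g) at total length ``L_mm`` via ``w = a * L**b``."""
    if L_mm < 0:
        raise ValidationError(f"length must be non-negative, got {L_mm}")
    params = params or AllometryParams()
    return float(params.a * L_mm**params.b)


def biomass_density(density_per_m3: float, mean_weight_g: float) -> float:
    """Biomass density (g m^-3) from numerical density and mean individual weight."""
    if density_per_m3 < 0 or mean_weight_g < 0:
        raise ValidationError("density and weight must be non-negative")
    return density_per_m3 * mean_weight_g


def areal_to_volumetric(areal_g_per_m2: float, thickness_m: float) -> float:
    """Convert areal biomass (g m^-2) to volumetric (g m^-3) given swarm thickness (m)."""
    if not thickness_m > 0:
        raise ValidationError(f"thickness must be positive, got {thickness_m}")
    return areal_g_per_m2 / thickness_m


def swarm_thickness(events: list[DiveEvent]) -> pd.DataFrame:
    """Per-dive swarm thickness from the depth range spanned by feeding strikes.

    Events must be time-sorted with every strike bracketed by a
    ``dive_start``/``dive_end`` pair.  Thickness is the depth range
    (max - min) of strikes within the dive; dives with fewer than two
    strikes get thickness 0.

    Returns
    -------
    DataFrame with columns ``dive_index`` (0-based, in order of dive
    start), ``n_strikes`` and ``thickness_m``.
    """
    rows = []
    in_dive = False
    dive_index = -1
    strikes: list[float] = []
    last_t = -np.inf
    for ev in events:
        if ev.time_s < last_t:
            raise ValidationError("events must be sorted by time")
        last_t = ev.time_s
        if ev.kind == "dive_start":
            if in_dive:
                raise ValidationError(f"nested dive_start at t={ev.time_s}")
            in_dive = True
            dive_index += 1
            strikes = []
        elif ev.kind == "dive_end":
            if not in_dive:
                raise ValidationError(f"dive_end without dive_start at t={ev.time_s}")
            in_dive = False
            thickness = max(strikes) - min(strikes) if len(strikes) >= 2 else 0.0
            rows.append((dive_index, len(strikes), thickness))
        else:  # strike
            if not in_dive:
                raise ValidationError(f"strike outside any dive at t={ev.time_s}")
            strikes.append(ev.depth_m)
    if in_dive:
        raise ValidationError("dive_start without matching dive_end")
    return pd.DataFrame(rows, columns=["dive_index", "n_strikes", "thickness_m"])
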