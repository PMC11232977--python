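"""Sensitivity of range, volume and density to the boundary size, and
Monte-Carlo propagation of near-boundary uncertainty.

Two complementary views:

* :func:`boundary_grid` evaluates the full optics + density chain at a
  discrete set of boundary sizes (the near-boundary mean, +-1 and +-2
  standard deviations, and the minimum observed resolvable and
  unresolvable sizes), showing how strongly the estimates depend on
  where the resolvability limit is placed (volume scales as the inverse
  cube of the boundary size).

* :func:`propagate` draws boundary sizes from the fitted near-boundary
  normal distribution (rejecting non-positive draws), pushes each draw
  through the chain, and summarises the resulting distributions of
  range, volume and density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .density import AllometryParams, krill_weight_g
from .errors import ValidationError
from .optics import MEDIAN_PROJECTION, CameraModel, PreyLengthModel, volume_from_boundary

GRID_LABELS = (
    "mean",
    "mean-1sd",
    "mean+1sd",
    "mean-2sd",
    "mean+2sd",
    "min_resolvable",
    "min_unresolvable",
)


@dataclass(frozen=True)
class SensitivityGrid:
    """Chain outputs at a discrete set of boundary sizes.

    ``rows`` columns: label, boundary_px, range_mm, width_mm, height_mm,
    volume_m3, mean_density_krill_per_m3, biomass_g_per_m3.  Biomass uses
    the weight of an individual at the reference median length.
    """

    rows: pd.DataFrame


@dataclass(frozen=True)
class PropagationResult:
    """Monte-Carlo propagation of near-boundary size uncertainty.

    ``draws`` columns: boundary_px, range_mm, volume_m3,
    density_krill_per_m3.  ``summaries`` maps each of those columns to
    mean/sd/median/q25/q75.
    """

    draws: pd.DataFrame
    summaries: dict[str, dict[str, float]]
    seed: int
    n: int


def _chain_row(
    boundary_px: float,
    camera: CameraModel,
    prey: PreyLengthModel,
    mean_count_per_image: float,
    orientation: float,
    weight_g: float,
) -> tuple[float, float, float, float, float, float]:
    v = volume_from_boundary(boundary_px, camera, prey, orientation)
    dens = mean_count_per_image / v.volume_m3
    return (
        v.resolvable_range_mm,
        v.imaged_width_mm,
        v.imaged_height_mm,
        v.volume_m3,
        dens,
        dens * weight_g,
    )


def boundary_grid(
    mean_px: float,
    sd_px: float,
    min_res_px: float,
    min_unres_px: float,
    camera: CameraModel | None = None,
    prey: PreyLengthModel | None = None,
    mean_count_per_image: float = 0.0,
    orientation: float = MEDIAN_PROJECTION,
    allometry: AllometryParams | None = None,
) -> SensitivityGrid:
    """Evaluate the chain at the seven canonical boundary sizes.

    Raises
    ------
    ValidationError
        If ``mean_px - 2*sd_px`` is not positive (a non-physical
        boundary would enter the grid).
    """
    camera = camera or CameraModel()
    prey = prey or PreyLengthModel()
    if min(mean_px, min_res_px, min_unres_px) <= 0 or sd_px < 0:
        raise ValidationError("boundary sizes must be positive and sd non-negative")
    if mean_px - 2.0 * sd_px <= 0:
        raise ValidationError(
            f"mean - 2 sd = {mean_px - 2 * sd_px:.3g} px is not positive; "
            "grid would include a non-physical boundary"
        )
    weight = krill_weight_g(prey.median_mm, allometry)
    boundaries = (
        mean_px,
        mean_px - sd_px,
        mean_px + sd_px,
        mean_px - 2.0 * sd_px,
        mean_px + 2.0 * sd_px,
        min_res_px,
        min_unres_px,
    )
    rows = [
        (label, b, *_chain_row(b, camera, prey, mean_count_per_image, orientation, weight))
        for label, b in zip(GRID_LABELS, boundaries)
    ]
    return SensitivityGrid(
        rows=pd.DataFrame(
            rows,
            columns=[
                "label",
                "boundary_px",
                "range_mm",
                "width_mm",
                "height_mm",
                "volume_m3",
                "mean_density_krill_per_m3",
                "biomass_g_per_m3",
            ],
        )
    )


def _positive_normal_draws(
    rng: np.random.Generator, mean: float, sd: float, n: int, mode: str
) -> np.ndarray:
    """Draws from Normal(mean, sd) excluding values <= 0.

    ``mode="resample"`` rejects and redraws until exactly ``n`` positive
    values are accepted; ``mode="drop"`` draws ``n`` and discards the
    non-positive ones (sample size may shrink).
    """
    if sd == 0.0:
        if mean <= 0:
            raise ValidationError("degenerate draw at non-positive mean")
        return np.full(n, mean)
    accept = norm.sf(0.0, loc=mean, scale=sd)
    if accept < 0.01:
        raise ValidationError(
            f"P(draw > 0) = {accept:.3g} < 1%; near-boundary parameters are non-physical"
        )
    if mode == "drop":
        x = rng.normal(mean, sd, n)
        return x[x > 0]
    if mode != "resample":
        raise ValueError(f"unknown mode {mode!r}")
    out: list[np.ndarray] = []
    got = 0
    while got < n:
        x = rng.normal(mean, sd, max(n - got, 16))
        x = x[x > 0]
        out.append(x)
        got += x.size
    return np.concatenate(out)[:n]


def propagate(
    mean_px: float,
    sd_px: float,
    n: int = 1000,
    seed: int = 0,
    camera: CameraModel | None = None,
    prey: PreyLengthModel | None = None,
    mean_count_per_image: float = 0.0,
    orientation: float = MEDIAN_PROJECTION,
    mode: str = "resample",
) -> PropagationResult:
    """Monte-Carlo propagation of boundary uncertainty to range, volume, density.

    Boundary sizes are drawn from Normal(mean_px, sd_px) with
    non-positive values excluded (see ``mode``); each accepted draw runs
    the deterministic optics chain, and the per-draw density divides the
    fixed empirical mean count per image by the per-draw volume.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if sd_px < 0:
        raise ValidationError("sd must be non-negative")
    camera = camera or CameraModel()
    prey = prey or PreyLengthModel()
    rng = np.random.default_rng(seed)
    b = _positive_normal_draws(rng, mean_px, sd_px, n, mode)

    # The chain is a smooth scalar map of the boundary; evaluate it
    # vectorised rather than row by row.
    c = (b / orientation) / prey.median_mm
    height_mm = camera.height_px / c
    width_mm = camera.width_px / c
    range_mm = height_mm / (2.0 * np.tan(np.radians(camera.vfov_deg) / 2.0))
    volume_m3 = width_mm * height_mm * range_mm / 3.0 * 1e-9
    density = mean_count_per_image / volume_m3

    draws = pd.DataFrame(
        {
            "boundary_px": b,
            "range_mm": range_mm,
            "volume_m3": volume_m3,
            "density_krill_per_m3": density,
        }
    )
    summaries = {
        col: {
            "mean": float(draws[col].mean()),
            "sd": float(draws[col].std(ddof=1)) if len(draws) > 1 else 0.0,
            "median": float(draws[col].median()),
            "q25": float(draws[col].quantile(0.25)),
            "q75": float(draws[col].quantile(0.75)),
        }
        for col in draws.columns
    }
    return PropagationResult(draws=draws, summaries=summaries, seed=seed, n=len(draws))
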