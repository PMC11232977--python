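"""End-to-end density estimation from an annotation set.

Chains the stages: size-subset selection -> logistic boundary fit ->
mirrored near-boundary normal -> optics (conversion, range, volume) ->
per-image counts and densities -> biomass.  This is the library face of
the ``preyfield estimate`` command.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import annotations as anno
from . import boundary as bnd
from .density import AllometryParams, DensityResult, biomass_density, density_per_image, krill_weight_g
from .optics import MEDIAN_PROJECTION, CameraModel, PreyLengthModel, VolumeEstimate, volume_from_boundary


@dataclass(frozen=True)
class EstimateBundle:
    """All intermediate and final results of a density-estimation run."""

    boundary: bnd.LogisticBoundary
    near_boundary: bnd.NearBoundaryDistribution
    volume: VolumeEstimate
    density: DensityResult
    mean_weight_g: float
    mean_biomass_g_per_m3: float


def estimate_density(
    annotations: anno.AnnotationSet,
    camera: CameraModel | None = None,
    prey: PreyLengthModel | None = None,
    orientation: float = MEDIAN_PROJECTION,
    allometry: AllometryParams | None = None,
) -> EstimateBundle:
    """Run the full estimation chain on an annotation set.

    Counting and size-fitting use their distinct filters: the boundary is
    fitted on records with trustworthy lengths (no partial or
    packed-aggregation subtypes), while every resolvable record counts
    toward density.
    """
    camera = camera or CameraModel()
    prey = prey or PreyLengthModel()
    pairs = anno.boundary_fit_subset(annotations)
    fit = bnd.fit_logistic_boundary(pairs)
    near = bnd.mirror_near_boundary(
        bnd.near_boundary_sizes(pairs, fit.L_boundary_px), fit.L_boundary_px
    )
    volume = volume_from_boundary(fit.L_boundary_px, camera, prey, orientation)
    counts = anno.countable_per_image(annotations)
    density = density_per_image(counts, volume.volume_m3)
    weight = krill_weight_g(prey.median_mm, allometry)
    return EstimateBundle(
        boundary=fit,
        near_boundary=near,
        volume=volume,
        density=density,
        mean_weight_g=weight,
        mean_biomass_g_per_m3=biomass_density(density.mean, weight),
    )
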