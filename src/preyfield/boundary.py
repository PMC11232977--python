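"""Resolvable/unresolvable size boundary estimation.

The far limit of the imaged volume is not directly observable from a
single camera.  It is inferred from the *sizes* of imaged objects: small
objects tend to be distant and unresolvable, large ones close and
resolvable, but the two size distributions overlap because resolvability
is also degraded by motion blur and lighting.  A single-predictor
logistic regression of the binary resolvability label on imaged length
gives a principled class boundary: the length at which the predicted
probability of being resolvable is 0.5.

Boundary *uncertainty* is characterised by treating every object smaller
than the boundary as a member of the near-boundary population, mirroring
those sizes about the boundary to obtain a symmetric distribution, and
fitting a normal model by moments.  The mirrored construction is used in
place of the raw unresolvable-class distribution because that class is
contaminated by large, motion-blurred animals that sit well inside the
imaged volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import ValidationError


@dataclass(frozen=True)
class LogisticBoundary:
    """A fitted logistic size boundary.

    ``L_boundary_px`` solves predicted P(resolvable) = 0.5, i.e.
    ``-intercept/slope``.  ``degenerate`` flags a perfectly separated
    dataset, for which the maximum-likelihood fit diverges and the
    boundary is reported as the midpoint of the separating gap instead.
    """

    intercept: float
    slope: float
    L_boundary_px: float
    n_resolvable: int
    n_unresolvable: int
    converged: bool = True
    degenerate: bool = False

    def predict(self, length_px):
        """Predicted probability of resolvability at the given pixel length(s)."""
        if self.degenerate:
            return (np.asarray(length_px, dtype=float) > self.L_boundary_px).astype(float)
        from scipy.special import expit

        return expit(self.intercept + self.slope * np.asarray(length_px, dtype=float))


@dataclass(frozen=True)
class NearBoundaryDistribution:
    """Normal model of near-boundary object sizes, fitted by moments.

    The mirrored sample is symmetric about the boundary by construction,
    so the fitted mean equals the boundary (up to floating-point error);
    the standard deviation is the sample sd (n-1 denominator) of the
    mirrored set.
    """

    mean_px: float
    sd_px: float
    mirrored_sample: tuple[float, ...]


def fit_logistic_boundary(pairs) -> LogisticBoundary:
    """Fit a logistic regression of resolvability on imaged pixel length.

    Parameters
    ----------
    pairs
        Sequence of ``(imaged_length_px, is_resolvable)`` with the label
        coded 1 for resolvable, 0 for unresolvable (as produced by
        :func:`preyfield.annotations.boundary_fit_subset`).

    Returns
    -------
    LogisticBoundary
        Maximum-likelihood fit; on perfectly separated data a degenerate
        boundary at the midpoint of the separating gap, flagged via
        ``degenerate=True``.

    Raises
    ------
    ValidationError
        Fewer than two records in either class, or non-positive lengths.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("pairs must be (length, label) tuples")
    lengths, labels = arr[:, 0], arr[:, 1]
    if np.any(lengths <= 0):
        raise ValidationError("imaged lengths must be positive")
    if not np.all(np.isin(labels, (0.0, 1.0))):
        raise ValidationError("labels must be binary (0 = unresolvable, 1 = resolvable)")
    n_res = int(labels.sum())
    n_unres = int(len(labels) - n_res)
    if n_res < 2 or n_unres < 2:
        raise ValidationError(
            f"need >= 2 records of each class, got {n_res} resolvable / {n_unres} unresolvable"
        )

    res_min = lengths[labels == 1].min()
    unres_max = lengths[labels == 0].max()
    if res_min > unres_max:
        # Perfect separation: likelihood is maximised in the limit of an
        # infinitely steep curve anywhere inside the gap; report its midpoint.
        mid = 0.5 * (res_min + unres_max)
        return LogisticBoundary(
            intercept=float("nan"),
            slope=float("inf"),
            L_boundary_px=float(mid),
            n_resolvable=n_res,
            n_unresolvable=n_unres,
            converged=True,
            degenerate=True,
        )

    X = sm.add_constant(lengths)
    model = sm.Logit(labels, X)
    with np.errstate(all="ignore"):
        fit = model.fit(disp=0, maxiter=200, tol=1e-10)
    intercept, slope = (float(v) for v in fit.params)
    if slope == 0:
        raise ValidationError("logistic fit returned zero slope; boundary undefined")
    return LogisticBoundary(
        intercept=intercept,
        slope=slope,
        L_boundary_px=float(-intercept / slope),
        n_resolvable=n_res,
        n_unresolvable=n_unres,
        converged=bool(fit.mle_retvals.get("converged", True)),
        degenerate=False,
    )


def near_boundary_sizes(pairs, L_boundary_px: float) -> np.ndarray:
    """Sizes strictly below the boundary, drawn from both classes.

    Everything smaller than the fitted boundary is treated as effectively
    unresolvable (the boundary *is* the operational definition of the
    resolvability limit), so the selection ignores the analyst's label.
    """
    lengths = np.asarray([p[0] for p in pairs], dtype=float)
    return lengths[lengths < L_boundary_px]


def mirror_near_boundary(lengths, L_boundary_px: float) -> NearBoundaryDistribution:
    """Mirror sub-boundary sizes about the boundary and fit a normal model.

    The input sizes are taken to be the lower half of a symmetric
    near-boundary population.  Shifting them to have the boundary at
    zero, reflecting, and shifting back yields the mirrored sample
    ``{x} U {2*L_boundary - x}``, whose mean is the boundary exactly and
    whose sample sd quantifies the width of the marginal region.

    Raises
    ------
    ValidationError
        Empty input, or any size at or above the boundary.
    """
    x = np.asarray(lengths, dtype=float)
    if x.size == 0:
        raise ValidationError("no sizes below the boundary; cannot build mirrored distribution")
    if np.any(x >= L_boundary_px):
        raise ValidationError(
            f"all input sizes must be strictly below the boundary {L_boundary_px}"
        )
    mirrored = np.concatenate([x, 2.0 * L_boundary_px - x])
    return NearBoundaryDistribution(
        mean_px=float(mirrored.mean()),
        sd_px=float(mirrored.std(ddof=1)),
        mirrored_sample=tuple(float(v) for v in mirrored),
    )


def alternative_boundary(unresolvable_lengths, method: str = "median", bin_width_px: float = 5.0) -> float:
    """Summary-statistic alternatives to the logistic boundary.

    ``median`` is the sample median of unresolvable object sizes;
    ``mode`` is the midpoint of the most populated histogram bin of the
    given width (first such bin on ties).
    """
    x = np.asarray(unresolvable_lengths, dtype=float)
    if x.size == 0:
        raise ValidationError("need at least one unresolvable length")
    if method == "median":
        return float(np.median(x))
    if method == "mode":
        if x.size == 1:
            return float(x[0])
        lo = np.floor(x.min() / bin_width_px) * bin_width_px
        nbins = int(np.ceil((x.max() - lo) / bin_width_px)) or 1
        edges = lo + bin_width_px * np.arange(nbins + 1)
        counts, _ = np.histogram(x, bins=edges)
        i = int(np.argmax(counts))
        return float(0.5 * (edges[i] + edges[i + 1]))
    raise ValueError(f"unknown method {method!r}")


def format_boundary_report(
    fit: LogisticBoundary, near: NearBoundaryDistribution | None = None
) -> str:
    """Small key-value text report of a boundary fit."""
    lines = [
        f"intercept: {fit.intercept:.6g}",
        f"slope: {fit.slope:.6g}",
        f"L_boundary_px: {fit.L_boundary_px:.6g}",
        f"n_resolvable: {fit.n_resolvable}",
        f"n_unresolvable: {fit.n_unresolvable}",
        f"converged: {fit.converged}",
        f"degenerate: {fit.degenerate}",
    ]
    if near is not None:
        lines += [
            f"near_boundary_mean_px: {near.mean_px:.6g}",
            f"near_boundary_sd_px: {near.sd_px:.6g}",
            f"n_mirrored: {len(near.mirrored_sample)}",
        ]
    return "\n".join(lines) + "\n"
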