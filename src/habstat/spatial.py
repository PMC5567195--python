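"""Plot-placement edge bias.

Non-experts tend to place their plots near the boundary of the habitat patch
(close to roads and paths), where conditions are more marginal, while experts
seek out the ecologically typical core.  This module quantifies that bias as
the distance from each plot location to the patch boundary and compares the
group mean distances with a permutation test.

Coordinates are planar metres; geographic inputs must be projected upstream.
Points on the boundary count as inside, at distance 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from shapely.geometry import MultiPolygon, Point, Polygon, shape

from .quality import SurveyDataset

logger = logging.getLogger(__name__)

PolygonLike = Union[Polygon, MultiPolygon, dict]

__all__ = [
    "EdgeComparison",
    "as_polygon",
    "distance_to_edge",
    "compare_edge_distance",
    "permutation_mean_diff_test",
]


def as_polygon(obj: PolygonLike) -> Union[Polygon, MultiPolygon]:
    """Coerce a shapely polygon or a GeoJSON geometry mapping to shapely."""
    if isinstance(obj, (Polygon, MultiPolygon)):
        geom = obj
    elif isinstance(obj, dict):
        geom = shape(obj)
        if not isinstance(geom, (Polygon, MultiPolygon)):
            raise ValueError(f"GeoJSON geometry must be Polygon/MultiPolygon, got {geom.geom_type}")
    else:
        raise TypeError(f"cannot interpret {type(obj).__name__} as a polygon")
    if geom.is_empty or not geom.is_valid or geom.area <= 0:
        raise ValueError("polygon must be valid, non-empty and of positive area")
    return geom


def distance_to_edge(point: Union[Point, Tuple[float, float]], polygon: PolygonLike) -> float:
    """Minimum Euclidean distance (m) from an interior point to the patch boundary.

    Raises for points outside the patch; boundary points return 0.
    """
    poly = as_polygon(polygon)
    pt = point if isinstance(point, Point) else Point(point)
    if not poly.covers(pt):  # covers: boundary counts as inside
        raise ValueError(
            f"point ({pt.x:g}, {pt.y:g}) lies outside the habitat polygon"
        )
    return float(poly.boundary.distance(pt))


def distances_to_edge(points: np.ndarray, polygon: PolygonLike) -> np.ndarray:
    """Vectorised :func:`distance_to_edge` over an (n, 2) coordinate array."""
    poly = as_polygon(polygon)
    import shapely

    pts = shapely.points(np.asarray(points, dtype=float))
    inside = shapely.covers(poly, pts)
    if not inside.all():
        bad = np.asarray(points)[~inside][0]
        raise ValueError(f"point ({bad[0]:g}, {bad[1]:g}) lies outside the habitat polygon")
    return shapely.distance(poly.boundary, pts)


@dataclass(frozen=True)
class EdgeComparison:
    """Result of the expert vs. non-expert edge-distance permutation test."""

    mean_dist_expert: float
    mean_dist_nonexpert: float
    observed_diff: float  # expert mean minus non-expert mean
    p_value: float
    n_permutations: int
    seed: int
    alternative: str = "two-sided"

    def to_dict(self) -> dict:
        return {
            "mean_dist_expert": self.mean_dist_expert,
            "mean_dist_nonexpert": self.mean_dist_nonexpert,
            "observed_diff": self.observed_diff,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "alternative": self.alternative,
        }


def permutation_mean_diff_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_permutations: int = 5000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> Tuple[float, float]:
    """Permutation test on the difference of two group means (a minus b).

    Group labels are permuted over the pooled observations.  Returns
    ``(observed_diff, p_value)`` with the add-one estimator
    ``p = (#{extreme} + 1) / (n_permutations + 1)``, so p is never 0.
    ``alternative`` is ``two-sided``, ``greater`` (a > b) or ``less``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    observed = a.mean() - b.mean()
    if np.ptp(pooled) == 0:
        logger.warning("all distances identical; permutation test degenerate, p = 1")
        return float(observed), 1.0
    rng = np.random.default_rng(seed)
    perms = rng.permuted(
        np.broadcast_to(pooled, (n_permutations, pooled.size)).copy(), axis=1
    )
    diffs = perms[:, : a.size].mean(axis=1) - perms[:, a.size :].mean(axis=1)
    tol = 1e-12 * max(1.0, abs(observed))
    if alternative == "two-sided":
        extreme = np.abs(diffs) >= abs(observed) - tol
    elif alternative == "greater":
        extreme = diffs >= observed - tol
    else:
        extreme = diffs <= observed + tol
    p = (int(extreme.sum()) + 1) / (n_permutations + 1)
    return float(observed), float(p)


def compare_edge_distance(
    dataset: SurveyDataset,
    polygon: PolygonLike,
    n_permutations: int = 5000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> EdgeComparison:
    """Compare expert and non-expert mean distance-to-edge by permutation.

    Computes the distance from every plot location to the patch boundary,
    then permutes observer-status labels over plots to build the null
    distribution of the group mean difference.  All plots must lie inside
    the polygon; both groups need at least 2 plots.
    """
    poly = as_polygon(polygon)
    dist = {"expert": [], "non_expert": []}
    for plot in dataset.plots:
        dist[plot.observer_status].append(distance_to_edge(plot.location, poly))
    observed, p = permutation_mean_diff_test(
        dist["expert"], dist["non_expert"], n_permutations, seed, alternative
    )
    return EdgeComparison(
        mean_dist_expert=float(np.mean(dist["expert"])),
        mean_dist_nonexpert=float(np.mean(dist["non_expert"])),
        observed_diff=observed,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
        alternative=alternative,
    )
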