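"""Permutational ANOVA on per-plot count responses.

Per-plot indicators (number of structures & functions, of typical species, of
pressures & threats recorded per plot) are compared between observer groups
and habitat types with ANOVA whose null distribution is built by permuting
the raw response vector ("permutations on individuals") rather than assuming
normality -- appropriate for the small, unbalanced designs of field surveys
(a handful of expert plots against tens of non-expert plots).

Two designs are supported: one-way (observer status only) and two-way
main effects (status + habitat type, no interaction).  For the unbalanced
two-way design each factor's sum of squares is the sequential increment when
that factor enters the model last, i.e. SS(A | B) -- equivalent to Type-II
sums of squares in the no-interaction model.  p-values use the add-one
estimator p = (#{F_perm >= F_obs} + 1) / (n_perm + 1).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaDesign",
    "FactorResult",
    "AnovaResult",
    "f_statistic",
    "perm_anova",
    "exhaustive_oneway_perm_p",
]


def f_statistic(response: Sequence[float], factor: Sequence) -> float:
    """Classical one-way ANOVA F statistic.

    F = (SSB / (k - 1)) / (SSW / (n - k)) for k group levels over n
    observations.  Returns 0 when all group means are equal and ``inf`` (with
    a warning) when the residual variance is zero but the means differ.
    """
    y = np.asarray(response, dtype=float)
    labels = np.asarray(factor)
    if y.shape != labels.shape or y.ndim != 1:
        raise ValueError("response and factor must be 1-d and the same length")
    levels, idx = np.unique(labels, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")
    n, k = y.size, len(levels)
    if n <= k:
        raise ValueError(f"need more observations ({n}) than levels ({k})")
    grand = y.mean()
    counts = np.bincount(idx)
    means = np.bincount(idx, weights=y) / counts
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(np.sum((y - means[idx]) ** 2))
    if ssw == 0:
        if ssb == 0:
            return 0.0
        logger.warning("zero residual variance; F statistic is infinite")
        return math.inf
    return (ssb / (k - 1)) / (ssw / (n - k))


@dataclass
class AnovaDesign:
    """A permutational-ANOVA design on per-plot counts.

    ``factor_habitat`` may be omitted for one-way designs.  ``n_permutations``
    defaults to 5000; the seed is mandatory for reproducibility.
    """

    response: Sequence[float]
    factor_status: Sequence[str]
    factor_habitat: Optional[Sequence[str]] = None
    n_permutations: int = 5000
    seed: int = 0

    def __post_init__(self):
        y = np.asarray(self.response, dtype=float)
        if y.ndim != 1 or y.size < 3:
            raise ValueError("response must be 1-d with at least 3 observations")
        if len(self.factor_status) != y.size:
            raise ValueError("factor_status length must match response")
        if self.factor_habitat is not None and len(self.factor_habitat) != y.size:
            raise ValueError("factor_habitat length must match response")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass(frozen=True)
class FactorResult:
    """Permutation test result for one factor."""

    factor: str
    f_observed: float
    p_value: float
    df_num: int
    df_resid: int
    group_means: Dict[str, float]


@dataclass
class AnovaResult:
    """Per-factor F statistics and permutation p-values."""

    factors: Dict[str, FactorResult]
    n_obs: int
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_obs": self.n_obs,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "factors": {
                name: {
                    "f_observed": r.f_observed,
                    "p_value": r.p_value,
                    "df_num": r.df_num,
                    "df_resid": r.df_resid,
                    "group_means": dict(r.group_means),
                }
                for name, r in self.factors.items()
            },
        }


def _dummies(labels: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    levels = np.unique(labels)
    return (labels[:, None] == levels[None, 1:]).astype(float)


def _orth_basis(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-robust, via SVD)."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    return u[:, :rank]


def _factor_f_matrix(
    Y: np.ndarray, labels_test: np.ndarray, labels_other: Optional[np.ndarray]
) -> Tuple[np.ndarray, int, int]:
    """F statistics of one factor, fitted last, for each column of ``Y``.

    ``Y`` is (n, m): each column a (possibly permuted) response.  Returns
    (F values of length m, numerator df, residual df).
    """
    n = Y.shape[0]
    intercept = np.ones((n, 1))
    x_other = (
        intercept
        if labels_other is None
        else np.hstack([intercept, _dummies(labels_other)])
    )
    x_full = np.hstack([x_other, _dummies(labels_test)])
    q_other = _orth_basis(x_other)
    q_full = _orth_basis(x_full)
    df_num = q_full.shape[1] - q_other.shape[1]
    df_resid = n - q_full.shape[1]
    if df_num < 1:
        raise ValueError("tested factor adds no degrees of freedom")
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    ss_total = np.einsum("ij,ij->j", Y, Y)
    proj_o = q_other.T @ Y
    proj_f = q_full.T @ Y
    ss_other = np.einsum("ij,ij->j", proj_o, proj_o)
    ss_full = np.einsum("ij,ij->j", proj_f, proj_f)
    ss_effect = np.maximum(ss_full - ss_other, 0.0)
    sse = np.maximum(ss_total - ss_full, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_effect / df_num) / (sse / df_resid)
    scale = max(float(ss_total.max(initial=1.0)), 1.0)
    zero_resid = sse <= scale * 1e-12
    f = np.where(zero_resid & (ss_effect > scale * 1e-12), np.inf, f)
    f = np.where(zero_resid & (ss_effect <= scale * 1e-12), 0.0, f)
    return f, df_num, df_resid


def _group_means(y: np.ndarray, labels: np.ndarray) -> Dict[str, float]:
    return {str(lv): float(y[labels == lv].mean()) for lv in np.unique(labels)}


def perm_anova(
    design: AnovaDesign,
    factors: Sequence[str] = ("status",),
    permute_within: Optional[str] = None,
) -> AnovaResult:
    """Permutational ANOVA, one-way or two-way main effects.

    For every requested factor (``"status"`` and/or ``"habitat"``) the F
    statistic is computed with that factor entered last after the other, and
    its null distribution built by permuting the raw response vector
    ``design.n_permutations`` times.  Factors with fewer than 2 levels are
    skipped with a warning.  ``permute_within`` optionally restricts
    permutations to shuffle within the strata of the named other factor
    (default: unrestricted permutation of individuals).
    """
    y = np.asarray(design.response, dtype=float)
    labels = {"status": np.asarray(design.factor_status)}
    if design.factor_habitat is not None:
        labels["habitat"] = np.asarray(design.factor_habitat)
    for f_name in factors:
        if f_name not in labels:
            raise ValueError(f"factor {f_name!r} not present in the design")

    rng = np.random.default_rng(design.seed)
    B = design.n_permutations
    Yperm = np.broadcast_to(y[:, None], (y.size, B)).copy()
    if permute_within is None:
        Yperm = rng.permuted(Yperm, axis=0)
    else:
        if permute_within not in labels:
            raise ValueError(f"permute_within factor {permute_within!r} not in design")
        for lv in np.unique(labels[permute_within]):
            rows = np.flatnonzero(labels[permute_within] == lv)
            Yperm[rows] = rng.permuted(Yperm[rows], axis=0)
    Y = np.column_stack([y, Yperm])  # column 0 = observed

    results: Dict[str, FactorResult] = {}
    for f_name in factors:
        test = labels[f_name]
        if len(np.unique(test)) < 2:
            logger.warning("factor %r has a single level; test skipped", f_name)
            continue
        others = [labels[o] for o in labels if o != f_name and o in factors]
        other = others[0] if others else None
        fvals, df_num, df_resid = _factor_f_matrix(Y, test, other)
        f_obs = float(fvals[0])
        tol = 1e-12 * max(1.0, abs(f_obs))
        n_extreme = int(np.sum(fvals[1:] >= f_obs - tol))
        p = (n_extreme + 1) / (B + 1)
        results[f_name] = FactorResult(
            factor=f_name,
            f_observed=f_obs,
            p_value=float(p),
            df_num=df_num,
            df_resid=df_resid,
            group_means=_group_means(y, test),
        )
    return AnovaResult(
        factors=results, n_obs=y.size, n_permutations=B, seed=design.seed
    )


def exhaustive_oneway_perm_p(response: Sequence[float], factor: Sequence) -> float:
    """Exact one-way permutation p-value by full enumeration.

    Enumerates every distinct assignment of observations to group labels
    (positions of the first group among all n), so it is feasible only for
    small n.  The p-value is the exact fraction of assignments with
    F >= F_observed; no add-one correction is applied because the null
    distribution is complete.
    """
    y = np.asarray(response, dtype=float)
    labels = np.asarray(factor)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError("exhaustive enumeration implemented for 2 levels")
    n = y.size
    if n > 14:
        raise ValueError(f"n = {n} too large for full enumeration")
    n_a = int((labels == levels[0]).sum())
    f_obs = f_statistic(y, labels)
    tol = 1e-12 * max(1.0, f_obs if math.isfinite(f_obs) else 1.0)
    count = total = 0
    lab = np.empty(n, dtype=labels.dtype)
    for positions in itertools.combinations(range(n), n_a):
        lab[:] = levels[1]
        lab[list(positions)] = levels[0]
        total += 1
        if f_statistic(y, lab) >= f_obs - tol:
            count += 1
    return count / total
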