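"""Approximate entropy (ApEn) and the between-group factor screen.

ApEn quantifies the regularity of a time series: for pattern length ``m``
and tolerance ``r``, it is the (finite-N estimate of the) difference
``Phi^m(r) - Phi^{m+1}(r)``, where ``Phi^m`` is the mean log fraction of
template vectors within Chebyshev distance ``r`` of each length-``m``
template. Low values mean highly regular dynamics; white noise scores
higher than a sinusoid of equal variance.

The factor screen computes ApEn per candidate gait factor for two subject
groups and ranks factors by the absolute between-group difference: a factor
whose regularity is *similar* across groups is preferred for a state
classifier that must transfer from healthy to pathological gait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ApEnParams", "approximate_entropy", "apen_factor_table"]


@dataclass(frozen=True)
class ApEnParams:
    """Pattern length ``m`` (samples) and tolerance ``r`` (series units).

    ``r`` may be given directly or derived as ``r_factor * SD(series)``,
    the common convention (default 0.2 * SD with m = 2).
    """

    m: int = 2
    r: float | None = None
    r_factor: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("pattern length m must be >= 1")
        if self.r is not None and self.r <= 0:
            raise ValueError("tolerance r must be positive")
        if self.r is None and self.r_factor <= 0:
            raise ValueError("r_factor must be positive")

    def resolve_r(self, x: np.ndarray) -> float:
        if self.r is not None:
            return float(self.r)
        sd = float(np.std(x))
        if sd == 0:
            # constant series: any positive tolerance gives ApEn = 0
            return 1e-12
        return self.r_factor * sd


def _phi(x: np.ndarray, m: int, r: float, include_self: bool) -> float:
    """Mean log template-match fraction Phi^m(r) (Chebyshev distance)."""
    n = len(x)
    templates = sliding_window_view(x, m)  # (n - m + 1, m)
    d = np.max(np.abs(templates[:, None, :] - templates[None, :, :]), axis=2)
    counts = (d <= r).sum(axis=1).astype(float)
    denom = n - m + 1
    if not include_self:
        counts = counts - 1.0
        counts = np.maximum(counts, np.finfo(float).tiny)  # avoid log(0)
    return float(np.mean(np.log(counts / denom)))


def approximate_entropy(
    x: np.ndarray,
    params: ApEnParams | None = None,
    *,
    include_self_matches: bool = True,
) -> float:
    """Finite-N approximate entropy Phi^m(r) - Phi^{m+1}(r).

    Self-matches (j = i) are counted by default, which keeps the estimator
    non-negative up to floating point; ``include_self_matches=False`` gives a
    sample-entropy-style variant for comparison. Exact O(N^2) evaluation —
    decimate long series yourself if needed.
    """
    params = params or ApEnParams()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if len(x) <= params.m + 1:
        raise ValueError(f"series too short for m={params.m}: N={len(x)}")
    r = params.resolve_r(x)
    return _phi(x, params.m, r, include_self_matches) - _phi(
        x, params.m + 1, r, include_self_matches
    )


def apen_factor_table(
    feature_sets_by_group: dict[str, dict[str, np.ndarray]],
    params: ApEnParams | None = None,
) -> pd.DataFrame:
    """ApEn per factor per group plus the absolute between-group difference.

    ``feature_sets_by_group`` maps exactly two group names to ``factor ->
    series`` dicts sharing a factor set. Tolerance ``r`` resolves per series
    (for the default SD-relative rule each series uses its own scale).
    Returns a DataFrame indexed by factor with one ApEn column per group and
    ``abs_difference``, sorted ascending so the first row is the factor whose
    complexity transfers best across groups.
    """
    params = params or ApEnParams()
    groups = list(feature_sets_by_group)
    if len(groups) != 2:
        raise ValueError("factor screening needs exactly two groups")
    g1, g2 = groups
    factors = list(feature_sets_by_group[g1])
    if set(factors) != set(feature_sets_by_group[g2]):
        raise ValueError("both groups must provide the same factors")
    rows = {}
    for factor in factors:
        a = approximate_entropy(np.asarray(feature_sets_by_group[g1][factor]), params)
        b = approximate_entropy(np.asarray(feature_sets_by_group[g2][factor]), params)
        rows[factor] = {f"apen_{g1}": a, f"apen_{g2}": b, "abs_difference": abs(a - b)}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "factor"
    return table.sort_values("abs_difference")
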