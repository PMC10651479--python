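"""Group comparisons and density summaries for cytometry cohorts.

Nonparametric two-sample and paired tests with the effect-size convention
r = |z|/sqrt(N), where z is recovered from the two-sided P value
(z = Phi^-1(1 - P/2)) and N is the total number of samples entering the
test. Effect sizes are labelled by Cohen's criteria: 0.1-0.3 small,
0.3-0.5 moderate, > 0.5 large (boundaries assigned to the lower category,
i.e. r = 0.5 is still moderate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage import measure

from .exceptions import DegenerateInputError, ParameterError
from .gating import fluorescence_gate

__all__ = [
    "StatResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "effect_size_r",
    "cohen_label",
    "pearson_r",
    "sample_summary",
    "kde_norm",
    "significance_stars",
]


@dataclass
class StatResult:
    """One hypothesis test: statistic, z, two-sided P, effect size."""

    test: str
    statistic: float
    z: float
    p_value: float
    effect_size: float
    effect_label: str
    n: int

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Figure annotation convention: *P<0.05, **P<0.01, ***P<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def cohen_label(r: float) -> str:
    """Cohen's qualitative effect-size category for r = |z|/sqrt(N)."""
    r = abs(r)
    if r > 0.5:
        return "large"
    if r >= 0.3:
        return "moderate"
    if r >= 0.1:
        return "small"
    return "negligible"


def effect_size_r(p_two_sided: float | None = None, z: float | None = None,
                  n_total: int = 0) -> tuple[float, str]:
    """Effect size r = |z|/sqrt(N) with its Cohen label.

    Either a two-sided P (from which z = Phi^-1(1 - P/2) is recovered) or a
    z statistic must be given; the P route is the convention used for the
    published effect sizes.
    """
    if n_total < 1:
        raise ParameterError(f"n_total must be >= 1, got {n_total}")
    if z is None:
        if p_two_sided is None:
            raise ParameterError("either p_two_sided or z is required")
        if not 0.0 < p_two_sided <= 1.0:
            raise ParameterError(f"P must lie in (0, 1], got {p_two_sided}")
        z = float(sps.norm.isf(p_two_sided / 2.0))
    r = abs(float(z)) / np.sqrt(n_total)
    return r, cohen_label(r)


def _z_from_p(p: float, sign: float) -> float:
    z = float(sps.norm.isf(min(max(p, 1e-300), 1.0) / 2.0))
    return float(np.copysign(z, sign)) if sign != 0 else 0.0


def _mwu_exact_p(pooled_ranks: np.ndarray, n: int, u_obs: float) -> float:
    """Exact two-sided P over all group assignments (midrank ties allowed).

    The permutation distribution of U is symmetric about n*m/2; the
    two-sided P is the probability of a deviation from the mean at least as
    large as observed.
    """
    from itertools import combinations

    N = pooled_ranks.size
    m = N - n
    mean = n * m / 2.0
    dev = abs(u_obs - mean) - 1e-9
    hits = total = 0
    base = n * (n + 1) / 2.0
    for idx in combinations(range(N), n):
        u = pooled_ranks[list(idx)].sum() - base
        total += 1
        if abs(u - mean) >= dev:
            hits += 1
    return hits / total


def mann_whitney_u(x, y) -> StatResult:
    """Two-sided Mann-Whitney U test for two independent groups.

    U counts pairs (x_i, y_j) with x_i > y_j (ties as 1/2). The P value is
    exact — full enumeration of the permutation distribution, midrank ties
    included — when n*m <= 64, otherwise a tie-corrected normal
    approximation with continuity correction. The z statistic is recovered
    from the two-sided P, signed by the direction of the shift.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    n, m = x.size, y.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    u = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    if n * m <= 64:
        p = _mwu_exact_p(ranks, n, u)
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        p = float(min(res.pvalue, 1.0))
    sign = u - n * m / 2.0
    z = _z_from_p(p, sign)
    r, label = effect_size_r(p_two_sided=p, n_total=n + m)
    return StatResult(test="mann-whitney-u", statistic=u, z=z, p_value=p,
                      effect_size=r, effect_label=label, n=n + m)


def _wilcoxon_exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-sided P over all 2^n sign patterns (midrank ties allowed)."""
    n = ranks.size
    mean = n * (n + 1) / 4.0
    dev = abs(w_obs - mean) - 1e-9
    hits = 0
    for pattern in range(1 << n):
        w = sum(ranks[i] for i in range(n) if pattern >> i & 1)
        if abs(w - mean) >= dev:
            hits += 1
    return hits / (1 << n)


def wilcoxon_signed_rank(x, y) -> StatResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    The reported statistic is W+ (sum of ranks of positive differences,
    zero differences discarded). P is exact — enumeration of all sign
    patterns, midrank ties included — when the number of non-zero
    differences is <= 12, otherwise a normal approximation with continuity
    and tie corrections. z is recovered from P, signed by the shift, so
    swapping x and y flips z but leaves P unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    if n < 5:
        raise ParameterError(f"need >= 5 non-zero differences, got {n}")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 12:
        p = _wilcoxon_exact_p(ranks, w_plus)
    else:
        res = sps.wilcoxon(d, alternative="two-sided", method="approx",
                           correction=True)
        p = float(min(res.pvalue, 1.0))
    sign = w_plus - n * (n + 1) / 4.0
    z = _z_from_p(p, sign)
    r, label = effect_size_r(p_two_sided=p, n_total=x.size + y.size)
    return StatResult(test="wilcoxon-signed-rank", statistic=w_plus, z=z,
                      p_value=p, effect_size=r, effect_label=label,
                      n=x.size + y.size)


def pearson_r(x, y) -> tuple[float, float, int]:
    """Pearson product-moment correlation with two-sided P (t transform).

    Returns ``(r, p_value, degrees_of_freedom)`` with df = n - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("need paired samples of equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance in one of the inputs")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), int(x.size - 2)


def sample_summary(events: pd.DataFrame,
                   control: pd.DataFrame | None = None,
                   cd45_channel: str = "cd45",
                   cd45_threshold: float | None = None,
                   quantile: float = 0.99) -> dict[str, float]:
    """Per-sample medians plus %CD45+ leukocyte content.

    The CD45 positivity threshold comes either from ``cd45_threshold`` or
    from an unstained ``control`` table (quantile gate); without either, the
    fluorescence fraction is omitted.
    """
    if len(events) == 0:
        raise ParameterError("event table is empty")
    out: dict[str, float] = {}
    for col in ("deformation", "area_um2", "aspect_ratio", "area_ratio",
                "brightness_avg", "brightness_sd"):
        if col in events.columns:
            out[f"median_{col}"] = float(events[col].median())
    col = f"fl_{cd45_channel}_max"
    if col in events.columns:
        if cd45_threshold is not None:
            positives = events.loc[events[col] > cd45_threshold]
            out["pct_cd45_pos"] = 100.0 * len(positives) / len(events)
        elif control is not None:
            _, positives = fluorescence_gate(events, control, cd45_channel,
                                             quantile=quantile)
            out["pct_cd45_pos"] = 100.0 * len(positives) / len(events)
    return out


def kde_norm(events: pd.DataFrame, feature_x: str, feature_y: str,
             grid_size: int = 128,
             levels: tuple[float, ...] = (0.5, 0.95)
             ) -> tuple[np.ndarray, dict[float, list[np.ndarray]]]:
    """Max-normalized Gaussian kernel density for scatter colouring.

    Returns per-event densities scaled to [0, 1] (the densest event maps to
    1) and, per requested normalized level, the contour polygons of the
    density evaluated on a regular grid (Scott's-rule bandwidth).
    """
    for f in (feature_x, feature_y):
        if f not in events.columns:
            raise ParameterError(f"feature {f!r} not in event table")
    pts = events[[feature_x, feature_y]].to_numpy(dtype=float).T
    pts = pts[:, np.isfinite(pts).all(axis=0)]
    if pts.shape[1] < 2 or np.unique(pts, axis=1).shape[1] < 2:
        raise DegenerateInputError("need at least 2 distinct finite events")
    try:
        kde = sps.gaussian_kde(pts, bw_method="scott")
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError(f"singular data for KDE: {exc}") from exc

    dens = kde(pts)
    peak = float(dens.max())

    pad_x = 0.1 * (pts[0].max() - pts[0].min() or 1.0)
    pad_y = 0.1 * (pts[1].max() - pts[1].min() or 1.0)
    gx = np.linspace(pts[0].min() - pad_x, pts[0].max() + pad_x, grid_size)
    gy = np.linspace(pts[1].min() - pad_y, pts[1].max() + pad_y, grid_size)
    xx, yy = np.meshgrid(gx, gy)
    grid_dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)

    contours: dict[float, list[np.ndarray]] = {}
    norm_grid = grid_dens / float(grid_dens.max())
    for level in levels:
        polys = []
        for c in measure.find_contours(norm_grid, level):
            # map (row, col) grid indices back to feature coordinates
            px = np.interp(c[:, 1], np.arange(grid_size), gx)
            py = np.interp(c[:, 0], np.arange(grid_size), gy)
            polys.append(np.column_stack([px, py]))
        contours[level] = polys
    return dens / peak, contours
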