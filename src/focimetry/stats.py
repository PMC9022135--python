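"""Statistical layer: rank tests, 2x2 contingency, one-way ANOVA, 2D KDE.

All p-values are two-sided.  Reported p-values carry a display floor of
2.2e-16 (the conventional floor of R's test printouts); comparisons in code
always use the exact value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import Channel
from .quantify import MARKER_FEATURE, PositivityThreshold, classify_positive

__all__ = [
    "TwoSampleTestResult",
    "ContingencyResult",
    "AnovaResult",
    "Kde2dGrid",
    "ConditionComparison",
    "wilcoxon_rank_sum",
    "chi2_2x2",
    "anova_oneway",
    "kde2d",
    "compare_conditions",
    "P_DISPLAY_FLOOR",
]

P_DISPLAY_FLOOR = 2.2e-16

#: products n1*n2 up to this use the exact tie-free Wilcoxon distribution
EXACT_WILCOXON_CUTOFF = 10_000


def format_p(p: float) -> str:
    """R-style display: exact value, floored at 2.2e-16."""
    return f"< {P_DISPLAY_FLOOR:g}" if p < P_DISPLAY_FLOOR else f"{p:.4g}"


@dataclass(frozen=True)
class TwoSampleTestResult:
    method: str
    statistic: float
    p_value: float
    n1: int
    n2: int

    @property
    def p_display(self) -> str:
        return format_p(self.p_value)


@dataclass(frozen=True)
class ContingencyResult:
    """Yates-correctable Pearson chi-square on a 2x2 positive/negative table."""

    table: tuple[tuple[int, int], tuple[int, int]]
    statistic: float
    p_value: float
    continuity_correction: bool
    df: int = 1

    @property
    def p_display(self) -> str:
        return format_p(self.p_value)


@dataclass(frozen=True)
class AnovaResult:
    statistic: float
    p_value: float
    df_between: int
    df_within: int
    group_sizes: tuple[int, ...]
    ss_between: float
    ss_within: float
    degenerate: bool = False

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)


@dataclass
class Kde2dGrid:
    """Product-Gaussian kernel density on a rectangular grid."""

    x: np.ndarray
    y: np.ndarray
    density: np.ndarray  # shape (len(y), len(x))
    bandwidth: tuple[float, float]

    def integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.density, self.x, axis=1), self.y))

    def mode(self) -> tuple[float, float]:
        iy, ix = np.unravel_index(np.argmax(self.density), self.density.shape)
        return float(self.x[ix]), float(self.y[iy])


def wilcoxon_rank_sum(x, y) -> TwoSampleTestResult:
    """Mann-Whitney-Wilcoxon two-sample rank-sum test, two-sided.

    Uses the exact null distribution when the samples are tie-free and
    ``n1*n2`` is small; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    tie_free = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (tie_free and x.size * y.size <= EXACT_WILCOXON_CUTOFF) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return TwoSampleTestResult(
        method=f"wilcoxon-rank-sum ({method})",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=int(x.size),
        n2=int(y.size),
    )


def chi2_2x2(a: int, b: int, c: int, d: int, yates: bool = True) -> ContingencyResult:
    """Pearson chi-square on [[a, b], [c, d]], Yates-corrected by default.

    Correction subtracts ``min(0.5, |O - E|)`` from each cell's deviation.
    Rows are conditions, columns positive/negative counts (or vice versa;
    the statistic is invariant).
    """
    O = np.array([[a, b], [c, d]], dtype=np.float64)
    if np.any(O < 0):
        raise ValueError("counts must be >= 0")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("chi-square undefined: a table margin is zero")
    E = np.outer(row, col) / O.sum()
    dev = np.abs(O - E)
    if yates:
        dev = dev - np.minimum(0.5, dev)
    stat = float((dev**2 / E).sum())
    p = float(sps.chi2.sf(stat, df=1))
    return ContingencyResult(
        table=((int(a), int(b)), (int(c), int(d))),
        statistic=stat,
        p_value=p,
        continuity_correction=yates,
    )


def anova_oneway(groups: list[np.ndarray]) -> AnovaResult:
    """Standard one-way fixed-effects ANOVA, F = (SSB/df_b) / (SSW/df_w)."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs >= 2 values")
    sizes = tuple(int(g.size) for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b = len(groups) - 1
    df_w = sum(sizes) - len(groups)
    if ssw == 0 and ssb == 0:
        return AnovaResult(
            statistic=float("nan"), p_value=float("nan"), df_between=df_b,
            df_within=df_w, group_sizes=sizes, ss_between=0.0, ss_within=0.0,
            degenerate=True,
        )
    if ssw == 0:
        return AnovaResult(
            statistic=float("inf"), p_value=0.0, df_between=df_b, df_within=df_w,
            group_sizes=sizes, ss_between=ssb, ss_within=0.0,
        )
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(
        statistic=float(f), p_value=p, df_between=df_b, df_within=df_w,
        group_sizes=sizes, ss_between=ssb, ss_within=ssw,
    )


def _scott_bandwidth(values: np.ndarray) -> float:
    # per-axis Scott rule for a 2D product kernel: h = sd * n^(-1/6)
    sd = values.std(ddof=1)
    return float(sd * values.size ** (-1.0 / 6.0))


def kde2d(
    x,
    y,
    grid_size: tuple[int, int] = (128, 128),
    bandwidth: tuple[float, float] | None = None,
    extent: tuple[float, float, float, float] | None = None,
    pad_bandwidths: float = 4.0,
) -> Kde2dGrid:
    """Product-Gaussian 2D KDE on a rectangular grid, normalised to integrate to 1.

    Default bandwidths follow Scott's rule per axis; the grid spans the data
    range padded by ``pad_bandwidths`` bandwidths on each side.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 2:
        raise ValueError("need paired samples with n >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    if bandwidth is None:
        hx, hy = _scott_bandwidth(x), _scott_bandwidth(y)
        if hx == 0 or hy == 0:
            raise ValueError(
                "zero variance on an axis: Scott's rule gives bandwidth 0; "
                "pass an explicit bandwidth"
            )
    else:
        hx, hy = bandwidth
        if hx <= 0 or hy <= 0:
            raise ValueError("bandwidths must be > 0")

    if extent is None:
        extent = (
            x.min() - pad_bandwidths * hx, x.max() + pad_bandwidths * hx,
            y.min() - pad_bandwidths * hy, y.max() + pad_bandwidths * hy,
        )
    gx = np.linspace(extent[0], extent[1], grid_size[0])
    gy = np.linspace(extent[2], extent[3], grid_size[1])

    # separable kernel: density = (Ky @ Kx) / n with per-axis Gaussian matrices
    kx = np.exp(-0.5 * ((gx[None, :] - x[:, None]) / hx) ** 2) / (hx * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * ((gy[None, :] - y[:, None]) / hy) ** 2) / (hy * np.sqrt(2 * np.pi))
    density = (ky.T @ kx) / x.size
    return Kde2dGrid(x=gx, y=gy, density=density, bandwidth=(float(hx), float(hy)))


@dataclass
class ConditionComparison:
    """Treatment-vs-control report for the two damage markers.

    The "diagonal shift" of the dual-marker density is summarised as the
    signed pair of median differences (treated minus control) in 53BP1 sum
    spot intensity and gamma-H2AX mean nuclear intensity.
    """

    condition_treated: str
    condition_control: str
    wilcoxon: dict[Channel, TwoSampleTestResult]
    contingency: dict[Channel, ContingencyResult]
    positive_fraction_treated: dict[Channel, float]
    positive_fraction_control: dict[Channel, float]
    median_difference: dict[Channel, float]
    thresholds: dict[Channel, PositivityThreshold] = field(default_factory=dict)
    kde_treated: dict[str, Kde2dGrid] | None = None
    kde_control: dict[str, Kde2dGrid] | None = None


def compare_conditions(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    thresholds: dict[Channel, PositivityThreshold] | None = None,
    with_kde: bool = False,
    treated_label: str = "ETP",
    control_label: str = "control",
) -> ConditionComparison:
    """Wilcoxon + chi-square + median-shift summary per marker.

    ``thresholds`` defaults to mean + 1 SD computed from the control table
    itself.  Inputs are per-cell tables with the standard feature columns.
    """
    if len(treated) == 0 or len(control) == 0:
        raise ValueError("both condition tables must be non-empty")
    from .quantify import compute_threshold

    thresholds = dict(thresholds or {})
    wilcoxon: dict[Channel, TwoSampleTestResult] = {}
    contingency: dict[Channel, ContingencyResult] = {}
    frac_t: dict[Channel, float] = {}
    frac_c: dict[Channel, float] = {}
    med_diff: dict[Channel, float] = {}
    for marker, feature in MARKER_FEATURE.items():
        vt = treated[feature].to_numpy(dtype=np.float64)
        vc = control[feature].to_numpy(dtype=np.float64)
        if marker not in thresholds:
            thresholds[marker] = compute_threshold(vc, marker=marker)
        wilcoxon[marker] = wilcoxon_rank_sum(vt, vc)
        _, ft = classify_positive(vt, thresholds[marker])
        _, fc = classify_positive(vc, thresholds[marker])
        frac_t[marker], frac_c[marker] = ft, fc
        pos_t, pos_c = int(round(ft * vt.size)), int(round(fc * vc.size))
        contingency[marker] = chi2_2x2(
            pos_t, vt.size - pos_t, pos_c, vc.size - pos_c
        )
        med_diff[marker] = float(np.median(vt) - np.median(vc))

    kde_t = kde_c = None
    if with_kde:
        kde_t = {"53bp1_vs_gh2ax": kde2d(treated["sum_spot_53bp1"], treated["mean_gh2ax"])}
        kde_c = {"53bp1_vs_gh2ax": kde2d(control["sum_spot_53bp1"], control["mean_gh2ax"])}
    return ConditionComparison(
        condition_treated=treated_label,
        condition_control=control_label,
        wilcoxon=wilcoxon,
        contingency=contingency,
        positive_fraction_treated=frac_t,
        positive_fraction_control=frac_c,
        median_difference=med_diff,
        thresholds=thresholds,
        kde_treated=kde_t,
        kde_control=kde_c,
    )
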