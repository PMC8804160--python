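"""Nonparametric group comparisons and the proportion sample-size formula.

Mean ranks are the effect summary throughout: for independent groups the
Mann-Whitney U test (mean ranks over the pooled sample), for paired regions
of one eye the Wilcoxon signed-rank two-tail test (mean ranks of positive
and negative differences).  Tie handling uses midranks; zero paired
differences are dropped; normal approximations carry tie correction and a
0.5 continuity correction; small pooled samples (N <= 12) use exact
enumeration for the Mann-Whitney p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import DegenerateDataError, InvalidSpecError
from .io import METRIC_NAMES

EXACT_MAX_N = 12


@dataclass
class MannWhitneyResult:
    mean_rank_a: float
    mean_rank_b: float
    u: float          # min(U1, U2), the conventionally reported statistic
    u1: float
    u2: float
    n1: int
    n2: int
    z: float
    p: float
    metric: str = ""


@dataclass
class WilcoxonResult:
    mean_rank_pos: float   # mean rank among positive differences (a > b)
    mean_rank_neg: float
    n_pos: int
    n_neg: int
    n_zero: int
    w_pos: float
    w_neg: float
    z: float
    p: float
    n: int
    metric: str = ""


@dataclass
class SampleSizeParams:
    """Inputs of n = z^2 * p * (1 - p) / eps^2.

    confidence is the two-sided confidence level (z is its standard-normal
    quantile), p the anticipated population proportion, margin the margin of
    error eps — all as fractions.
    """

    confidence: float = 0.95
    p: float = 0.5
    margin: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.confidence < 1.0):
            raise InvalidSpecError("confidence must lie in (0, 1)")
        if not (0.0 < self.p < 1.0):
            raise InvalidSpecError("p must lie in (0, 1)")
        if self.margin <= 0.0:
            raise InvalidSpecError("margin of error must be > 0")

    @property
    def z(self) -> float:
        return float(norm.ppf(1.0 - (1.0 - self.confidence) / 2.0))


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).ravel()
    return x[~np.isnan(x)]


def mann_whitney(values_a, values_b, metric: str = "") -> MannWhitneyResult:
    """Mann-Whitney U test with mean ranks, midrank ties, and exact small-N p.

    U1 = n1*n2 + n1(n1+1)/2 - R1 with R1 the rank sum of sample a; the
    reported U is min(U1, U2).  For N <= 12 the two-sided p comes from
    enumerating all C(N, n1) group assignments of the pooled values;
    otherwise from the normal approximation with tie-corrected variance and
    continuity correction.
    """
    a, b = _clean(values_a), _clean(values_b)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise InvalidSpecError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    n = n1 + n2
    ranks = rankdata(pooled)
    assert abs(ranks.sum() - n * (n + 1) / 2) < 1e-8, "rank conservation violated"
    r1 = float(ranks[:n1].sum())
    r2 = float(ranks[n1:].sum())
    u1 = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1
    u2 = n1 * n2 - u1

    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        z = 0.0
    else:
        diff = u1 - mu
        z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var)

    if n <= EXACT_MAX_N:
        p = _exact_mw_p(pooled, ranks, n1, u1)
    else:
        p = 2.0 * float(norm.sf(abs(z))) if var > 0 else 1.0
    return MannWhitneyResult(r1 / n1, r2 / n2, min(u1, u2), u1, u2,
                             n1, n2, z, min(p, 1.0), metric)


def _exact_mw_p(pooled: np.ndarray, ranks: np.ndarray, n1: int, u1_obs: float) -> float:
    """Exact two-sided p: 2 * min(P(U1 <= obs), P(U1 >= obs)), capped at 1."""
    n = len(pooled)
    n2 = n - n1
    base = n1 * n2 + n1 * (n1 + 1) / 2.0
    lo = hi = total = 0
    for idx in combinations(range(n), n1):
        u = base - ranks[list(idx)].sum()
        total += 1
        if u <= u1_obs + 1e-9:
            lo += 1
        if u >= u1_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def wilcoxon_signed_rank(paired_a, paired_b, metric: str = "") -> WilcoxonResult:
    """Wilcoxon signed-rank two-tail test with positive/negative mean ranks.

    Differences d = a - b; zeros are dropped; |d| are midranked.  The mean
    rank of positive differences summarises how strongly a exceeds b (and
    vice versa).  Z uses the normal approximation with tie correction and
    continuity correction; swapping the arguments swaps the mean ranks and
    negates Z.
    """
    a = np.asarray(paired_a, dtype=np.float64).ravel()
    b = np.asarray(paired_b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise InvalidSpecError("paired samples must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n_total = len(a)
    d = a - b
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    m = len(d)
    if m == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    pos = d > 0
    w_pos = float(ranks[pos].sum())
    w_neg = float(ranks[~pos].sum())
    n_pos, n_neg = int(pos.sum()), int(m - pos.sum())
    mr_pos = w_pos / n_pos if n_pos else math.nan
    mr_neg = w_neg / n_neg if n_neg else math.nan

    mu = m * (m + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var = m * (m + 1) * (2 * m + 1) / 24.0 - float(np.sum(counts**3 - counts)) / 48.0
    if var <= 0:
        z = 0.0
    else:
        diff = w_pos - mu
        z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var)
    p = 2.0 * float(norm.sf(abs(z))) if var > 0 else 1.0
    return WilcoxonResult(mr_pos, mr_neg, n_pos, n_neg, n_zero,
                          w_pos, w_neg, z, min(p, 1.0), n_total, metric)


def required_sample_size(params: SampleSizeParams) -> int:
    """Minimum sample size n = ceil(z^2 * p * (1-p) / eps^2) for estimating a
    proportion p to within eps at the given confidence."""
    raw = params.z**2 * params.p * (1.0 - params.p) / params.margin**2
    return int(math.ceil(raw))


# ---------------------------------------------------------------------------
# cohort-level report


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_cohort(
    table: pd.DataFrame,
    radar_path=None,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Run the full three-way comparison over all eight vascular metrics.

    HC vs RRD and HC vs non-RRD use Mann-Whitney; RRD vs non-RRD pairs the
    two regions of each patient image by image_id and uses Wilcoxon.  The
    report has one row per metric x comparison with mean ranks, statistics,
    unadjusted p and significance stars (optionally a Bonferroni-adjusted
    column).  When ``radar_path`` is given, a three-panel radar plot of the
    mean ranks is written there.
    """
    regions = set(table["region"].dropna().unique())
    if "HC-cover" not in regions or not ({"RRD", "non-RRD"} & regions):
        raise InvalidSpecError(
            f"table must carry regions 'HC-cover' and 'RRD'/'non-RRD', got {sorted(regions)}"
        )
    hc = table[table["region"] == "HC-cover"]
    rrd = table[table["region"] == "RRD"]
    non = table[table["region"] == "non-RRD"]
    rows = []
    for metric in METRIC_NAMES:
        for name, other in (("HC vs RRD", rrd), ("HC vs non-RRD", non)):
            if len(other) == 0:
                continue
            res = mann_whitney(hc[metric], other[metric], metric)
            rows.append({
                "metric": metric, "comparison": name,
                "mr_1": res.mean_rank_a, "mr_2": res.mean_rank_b,
                "statistic": res.u, "z": res.z, "p": res.p,
                "n_1": res.n1, "n_2": res.n2, "stars": _stars(res.p),
            })
        if len(rrd) and len(non):
            merged = rrd.merge(non, on="image_id", suffixes=("_rrd", "_non"))
            if len(merged):
                try:
                    res = wilcoxon_signed_rank(
                        merged[f"{metric}_rrd"], merged[f"{metric}_non"], metric
                    )
                except DegenerateDataError:
                    continue
                rows.append({
                    "metric": metric, "comparison": "RRD vs non-RRD",
                    "mr_1": res.mean_rank_pos, "mr_2": res.mean_rank_neg,
                    "statistic": res.w_pos, "z": res.z, "p": res.p,
                    "n_1": res.n_pos, "n_2": res.n_neg, "stars": _stars(res.p),
                })
    report = pd.DataFrame(rows)
    if bonferroni and len(report):
        report["p_bonferroni"] = np.minimum(1.0, report["p"] * len(report))
    if radar_path is not None and len(report):
        radar_plot(report, radar_path)
    return report


def radar_plot(report: pd.DataFrame, path) -> None:
    """Three radar panels of mean ranks, axes anti-clockwise from density."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comparisons = [c for c in ("HC vs RRD", "HC vs non-RRD", "RRD vs non-RRD")
                   if c in set(report["comparison"])]
    n_ax = len(METRIC_NAMES)
    # anti-clockwise from the top in screen coordinates
    angles = np.pi / 2 + 2 * np.pi * np.arange(n_ax) / n_ax
    fig, axes = plt.subplots(
        len(comparisons), 1, figsize=(5, 4.5 * len(comparisons)),
        subplot_kw={"projection": "polar"},
    )
    axes = np.atleast_1d(axes)
    colors = {"HC vs RRD": ("green", "red"), "HC vs non-RRD": ("green", "blue"),
              "RRD vs non-RRD": ("red", "blue")}
    for ax, comp in zip(axes, comparisons):
        sub = report[report["comparison"] == comp].set_index("metric")
        sub = sub.reindex(METRIC_NAMES)
        for col, color, label in (
            ("mr_1", colors[comp][0], comp.split(" vs ")[0]),
            ("mr_2", colors[comp][1], comp.split(" vs ")[1]),
        ):
            vals = sub[col].to_numpy(dtype=float)
            th = np.append(angles, angles[0])
            vv = np.append(vals, vals[0])
            ax.plot(th, vv, color=color, label=label)
            ax.fill(th, vv, color=color, alpha=0.12)
        ax.set_xticks(angles)
        ax.set_xticklabels(METRIC_NAMES, fontsize=7)
        ax.set_title(comp, fontsize=10)
        ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
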