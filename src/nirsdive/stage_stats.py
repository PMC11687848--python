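"""Stage-wise and blood-gas statistics: Shapiro-Wilk gated paired tests.

Paired contrasts (same subjects at two sampling points or dive stages) are
tested with a paired-samples t test when the Shapiro-Wilk test does not
reject normality of the differences at alpha = 0.05, and with the Wilcoxon
signed-rank test otherwise.  The Wilcoxon statistic is reported in the
R convention V = sum of positive-difference ranks (zeros dropped), with an
exact two-sided p-value for up to 25 nonzero differences and a normal
approximation with tie correction beyond.  No multiple-testing correction
is applied by default; Holm can be enabled.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import DiveEvents, VALID_SAMPLING_POINTS

logger = logging.getLogger(__name__)

ALPHA = 0.05
ANALYTES = ("pao2", "paco2", "sao2")
#: the four between/within-depth blood-gas contrasts (bottom/end of each dive)
BLOOD_GAS_CONTRASTS = (("C", "F"), ("D", "G"), ("C", "D"), ("F", "G"))
EXACT_WILCOXON_MAX_N = 25


@dataclass
class PairedTestResult:
    """One gated paired comparison."""

    label: str
    n: int
    shapiro_w: float
    shapiro_p: float
    test_kind: str  # "paired_t" | "wilcoxon"
    statistic: float
    p_two_sided: float
    significant: bool
    df: int | None = None
    degenerate: bool = False
    p_method: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "shapiro_w": self.shapiro_w,
            "shapiro_p": self.shapiro_p,
            "test": self.test_kind,
            "statistic": self.statistic,
            "p": self.p_two_sided,
            "significant": self.significant,
        }


def shapiro_wilk(diffs: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p on paired differences (3 <= n <= 50)."""
    diffs = np.asarray(diffs, float)
    if diffs.size < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3 (got {diffs.size})")
    if diffs.size > 50:
        raise ValueError("Shapiro-Wilk gate restricted to n <= 50")
    if np.ptp(diffs) == 0:
        # identical differences: W undefined; treat as maximally nonnormal
        return float("nan"), 0.0
    w, p = stats.shapiro(diffs)
    return float(w), float(p)


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int, bool]:
    """Paired t: t = mean(d) / (sd(d)/sqrt(n)); returns (t, p, df, degenerate)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired_t needs two equal-length samples, n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        return 0.0, float("nan"), x.size - 1, True
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p), x.size - 1, False


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, zero_policy: str = "drop"
) -> tuple[float, float, str]:
    """Wilcoxon signed-rank V (sum of positive ranks) and two-sided p.

    ``zero_policy`` "drop" removes zero differences before ranking (the
    common convention); "pratt" keeps them in the ranking then discards
    their ranks.  p is exact for n' <= 25 without ties, else a normal
    approximation with tie correction; the method used is returned.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    d = x - y
    if np.all(d == 0):
        raise ValueError("all differences are zero; Wilcoxon test undefined")
    if zero_policy not in ("drop", "pratt"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    if zero_policy == "drop":
        nz = d[d != 0]
        ranks = stats.rankdata(np.abs(nz))
    else:
        ranks = stats.rankdata(np.abs(d))
        nz = d
        ranks = ranks[nz != 0]
        nz = nz[nz != 0]
    v = float(ranks[nz > 0].sum())
    n_eff = nz.size
    has_ties = np.unique(np.abs(nz)).size < n_eff
    scipy_zero = "wilcox" if zero_policy == "drop" else "pratt"
    if n_eff <= EXACT_WILCOXON_MAX_N and not has_ties and zero_policy == "drop":
        res = stats.wilcoxon(x, y, zero_method=scipy_zero, method="exact")
        method = "exact"
    else:
        res = stats.wilcoxon(
            x, y, zero_method=scipy_zero, method="approx", correction=True
        )
        method = "normal-approx-tie-corrected"
    logger.debug(
        "wilcoxon: V=%g n'=%d policy=%s p-method=%s", v, n_eff, zero_policy, method
    )
    return v, float(res.pvalue), method


def gated_compare(
    x: np.ndarray,
    y: np.ndarray,
    label: str = "",
    alpha: float = ALPHA,
    alpha_normality: float = ALPHA,
    zero_policy: str = "drop",
) -> PairedTestResult:
    """Shapiro-Wilk gate on x - y, then paired t or Wilcoxon signed-rank."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2:
        raise ValueError("gated comparison needs n >= 2 pairs")
    d = x - y
    w, p_w = shapiro_wilk(d)
    if p_w >= alpha_normality:
        t, p, df, degen = paired_t(x, y)
        return PairedTestResult(
            label=label,
            n=x.size,
            shapiro_w=w,
            shapiro_p=p_w,
            test_kind="paired_t",
            statistic=t,
            p_two_sided=p,
            significant=bool(np.isfinite(p) and p < alpha),
            df=df,
            degenerate=degen,
            p_method="t-distribution",
        )
    v, p, method = wilcoxon_signed_rank(x, y, zero_policy=zero_policy)
    return PairedTestResult(
        label=label,
        n=x.size,
        shapiro_w=w,
        shapiro_p=p_w,
        test_kind="wilcoxon",
        statistic=v,
        p_two_sided=p,
        significant=bool(np.isfinite(p) and p < alpha),
        df=None,
        p_method=method,
    )


def _paired_values(
    table: pd.DataFrame, analyte: str, point_a: str, point_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-aligned values of one analyte at two sampling points."""
    wide = table.pivot(index="subject", columns="point", values=analyte)
    if point_a not in wide.columns or point_b not in wide.columns:
        raise ValueError(f"missing sampling point {point_a}/{point_b}")
    sub = wide[[point_a, point_b]].dropna()
    if len(sub) < 2:
        raise ValueError(
            f"n < 2 complete subjects for {analyte} {point_a}-{point_b}"
        )
    return sub[point_a].to_numpy(), sub[point_b].to_numpy()


def blood_gas_comparisons(
    table: pd.DataFrame, alpha: float = ALPHA
) -> list[PairedTestResult]:
    """The 12-contrast battery: 3 analytes x {C-F, D-G, C-D, F-G}."""
    results = []
    for a, b in BLOOD_GAS_CONTRASTS:
        for analyte in ANALYTES:
            label = f"{analyte} {a}-{b}"
            try:
                xa, xb = _paired_values(table, analyte, a, b)
            except ValueError as exc:
                logger.warning("skipping %s: %s", label, exc)
                continue
            results.append(gated_compare(xa, xb, label=label, alpha=alpha))
    return results


def hb_all_pairs(
    table: pd.DataFrame, alpha: float = ALPHA, holm: bool = False
) -> list[PairedTestResult]:
    """Gated comparison of hemoglobin between every pair of sampling points.

    Mirrors testing for a splenic-contraction Hb rise across all draws; raw
    p-values by default, Holm step-down optionally.
    """
    if "hb" not in table.columns:
        raise ValueError("table has no hb column")
    points = [
        p
        for p in VALID_SAMPLING_POINTS
        if p in set(table.loc[table["hb"].notna(), "point"])
    ]
    if len(points) < 2:
        raise ValueError("hb present at fewer than 2 sampling points")
    results = []
    for a, b in itertools.combinations(points, 2):
        label = f"hb {a}-{b}"
        try:
            xa, xb = _paired_values(table, "hb", a, b)
            res = gated_compare(xa, xb, label=label, alpha=alpha)
        except ValueError as exc:
            logger.warning("hb %s-%s refused: %s", a, b, exc)
            res = PairedTestResult(
                label=label,
                n=0,
                shapiro_w=float("nan"),
                shapiro_p=float("nan"),
                test_kind="refused",
                statistic=float("nan"),
                p_two_sided=float("nan"),
                significant=False,
                degenerate=True,
            )
        results.append(res)
    if holm:
        _apply_holm(results, alpha)
    return results


def _apply_holm(results: list[PairedTestResult], alpha: float) -> None:
    valid = [r for r in results if np.isfinite(r.p_two_sided)]
    order = sorted(valid, key=lambda r: r.p_two_sided)
    m = len(order)
    crossed = False
    for i, r in enumerate(order):
        threshold = alpha / (m - i)
        if crossed or r.p_two_sided >= threshold:
            crossed = True
            r.significant = False
        else:
            r.significant = True


def dive_minima(
    time: np.ndarray,
    trace: np.ndarray,
    events: DiveEvents,
    post_extension_s: float = 0.0,
) -> float:
    """Minimum of a (masked-aware) trace over the dive interval."""
    time = np.asarray(time, float)
    trace = np.asarray(trace, float)
    sel = (time >= events.start_time) & (time <= events.end_time + post_extension_s)
    vals = trace[sel]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("dive interval fully masked; no minimum defined")
    return float(vals.min())


def results_frame(results: list[PairedTestResult]) -> pd.DataFrame:
    """Battery results as a tidy table (one row per contrast)."""
    return pd.DataFrame([r.to_dict() for r in results])


def descriptive_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +- SD of each analyte at each sampling point (sample SD)."""
    rows = []
    for analyte in [c for c in ("pao2", "paco2", "sao2", "hb") if c in table.columns]:
        for point, grp in table.groupby("point"):
            vals = grp[analyte].dropna()
            if vals.empty:
                continue
            rows.append(
                {
                    "analyte": analyte,
                    "point": point,
                    "n": len(vals),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                }
            )
    return pd.DataFrame(rows)


__all__ = [
    "PairedTestResult",
    "shapiro_wilk",
    "paired_t",
    "wilcoxon_signed_rank",
    "gated_compare",
    "blood_gas_comparisons",
    "hb_all_pairs",
    "dive_minima",
    "results_frame",
    "descriptive_means",
    "ALPHA",
    "BLOOD_GAS_CONTRASTS",
]
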