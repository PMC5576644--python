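"""Wilcoxon rank-sum comparisons of grass cover.

Grass cover is recorded on a 5% grain in 10 x 10 m plots, so the data are
heavily tied and far from normal; the two-sample comparisons therefore use
the Wilcoxon rank-sum (Mann-Whitney) test.  Both the rank-sum W of the first
sample (midranks under ties) and the Mann-Whitney U are reported, since W is
only interpretable alongside the sample sizes.  Being rank-based, the tests
cannot probe a period x use interaction; the habitat table simply reports
the three marginal comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .data_io import VegPlot

Alternative = Literal["two_sided", "greater", "less"]

EXACT_N_CAP = 25  # exact enumeration only below this pooled size and tie-free


@dataclass(frozen=True)
class RankSumResult:
    w_statistic: float  # rank-sum of the first sample, midranks for ties
    u_statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    n1: int
    n2: int
    method: Literal["exact", "normal_approx"]
    alternative: Alternative


def rank_sum_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: Alternative = "two_sided",
) -> RankSumResult:
    """Wilcoxon rank-sum test of two independent samples.

    W is the sum of sample_a's ranks in the pooled ordering (midranks for
    ties).  The p-value is exact (full enumeration of the rank assignment
    distribution) when the pooled data are tie-free and small, otherwise a
    normal approximation with tie and continuity corrections.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    u = w - a.size * (a.size + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (not has_ties) and (pooled.size <= EXACT_N_CAP)
    scipy_alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    res = stats.mannwhitneyu(
        a, b, alternative=scipy_alt, method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    return RankSumResult(
        w_statistic=w,
        u_statistic=float(u),
        p_value=float(res.pvalue),
        n1=int(a.size),
        n2=int(b.size),
        method="exact" if use_exact else "normal_approx",
        alternative=alternative,
    )


def _describe(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "n": int(values.size),
        "median": float(med),
        "iqr_low": float(q1),
        "iqr_high": float(q3),
        "mean": float(values.mean()),
    }


def habitat_comparison(
    plots: Sequence[VegPlot], alternative: Alternative = "two_sided"
) -> list[dict]:
    """The three grass-cover contrasts: fire effect and habitat selection.

    1. pre vs post, all plots pooled — did fire reduce grass cover;
    2. used vs random, pre-fire — was there selection before the fire;
    3. used vs random, post-fire — was there selection after the fire.

    Each entry carries the test result plus descriptive summaries
    (n, median, IQR) of both strata.  A comparison whose stratum is empty is
    skipped with a warning entry rather than raising.
    """
    cover = {
        (p.period, p.plot_type): [] for p in plots
    }
    for p in plots:
        cover[(p.period, p.plot_type)].append(p.grass_cover)

    def pooled(period: str) -> np.ndarray:
        return np.array(
            cover.get((period, "used"), []) + cover.get((period, "random"), []),
            dtype=float,
        )

    contrasts = [
        ("pre_vs_post_all", pooled("pre"), pooled("post")),
        (
            "used_vs_random_pre",
            np.array(cover.get(("pre", "used"), []), dtype=float),
            np.array(cover.get(("pre", "random"), []), dtype=float),
        ),
        (
            "used_vs_random_post",
            np.array(cover.get(("post", "used"), []), dtype=float),
            np.array(cover.get(("post", "random"), []), dtype=float),
        ),
    ]
    out: list[dict] = []
    for name, first, second in contrasts:
        if first.size == 0 or second.size == 0:
            out.append({"comparison": name, "skipped": True,
                        "reason": "empty stratum"})
            continue
        res = rank_sum_test(first, second, alternative=alternative)
        out.append(
            {
                "comparison": name,
                "skipped": False,
                "result": res,
                "first": _describe(first),
                "second": _describe(second),
            }
        )
    return out
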