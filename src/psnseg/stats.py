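"""Small-sample paired statistics: exact Wilcoxon signed-rank, Holm
adjustment, rank-biserial effect sizes and bootstrap confidence intervals.

With only a handful of paired patients, asymptotic p-values are meaningless;
the signed-rank null is therefore enumerated exactly (all 2^n sign
assignments of the realized rank multiset) for n <= 20, with a
normal-approximation fallback above that, flagged in the result.  Zero
differences are dropped before ranking; ties in |difference| receive
midranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "wilcoxon_exact",
    "holm_adjust",
    "rank_biserial",
    "bootstrap_ci",
    "compare_methods",
]

_EXACT_LIMIT = 20


@dataclass
class StatResult:
    """Result of one paired signed-rank comparison."""

    n_effective: int
    w_plus: float
    w_minus: float
    w: float
    p: float
    exact: bool = True
    p_holm: Optional[float] = None
    r: Optional[float] = None
    r_ci: Optional[tuple[float, float]] = None
    label: str = ""


def _signed_ranks(diffs: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(diffs, dtype=np.float64)
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; test undefined")
    ranks = sps.rankdata(np.abs(d))  # midranks on ties
    return d, ranks


def _exact_null_pmf(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """PMF of W+ over all 2^n sign assignments of the realized rank multiset.

    Ranks are doubled so midranks (.5) become integers; returns (pmf, scale)
    where ``pmf[k]`` is P(2*W+ = k) and ``scale`` = 2.
    """
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: pmf.size - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf, 2


def wilcoxon_exact(diffs: Sequence[float]) -> StatResult:
    """Two-sided Wilcoxon signed-rank test by exact enumeration (n <= 20).

    p = min(1, 2 * min(P(W+ <= w_obs), P(W+ >= w_obs))) under the exact null.
    For n > 20 a tie-corrected normal approximation is used and the result is
    flagged ``exact=False``.
    """
    d, ranks = _signed_ranks(diffs)
    n = d.size
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    if n <= _EXACT_LIMIT:
        pmf, scale = _exact_null_pmf(ranks)
        k_obs = int(round(w_plus * scale))
        p_low = float(pmf[: k_obs + 1].sum())
        p_high = float(pmf[k_obs:].sum())
        p = min(1.0, 2.0 * min(p_low, p_high))
        exact = True
    else:
        # Normal approximation with tie correction of the rank variance.
        mean = n * (n + 1) / 4.0
        var = float(np.sum(ranks**2)) / 4.0
        z = (w_plus - mean) / math.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        exact = False
    return StatResult(
        n_effective=n,
        w_plus=w_plus,
        w_minus=w_minus,
        w=min(w_plus, w_minus),
        p=p,
        exact=exact,
    )


def holm_adjust(pvals: Sequence[float]) -> list[float]:
    """Step-down Holm adjustment, order restored to the input positions."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, min(1.0, (m - i) * p[idx]))
        adjusted[idx] = running
    return adjusted.tolist()


def rank_biserial(diffs: Sequence[float]) -> float:
    """Matched-pairs rank-biserial correlation r = (W+ - W-) / (W+ + W-)."""
    d, ranks = _signed_ranks(diffs)
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    return (w_plus - w_minus) / (w_plus + w_minus)


def bootstrap_ci(
    diffs: Sequence[float],
    statistic=rank_biserial,
    n_resamples: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for a statistic of the paired
    differences; all-zero resamples (statistic undefined) are skipped."""
    d = np.asarray(diffs, dtype=np.float64)
    if d.size < 2:
        raise ValueError("bootstrap needs at least 2 paired differences")
    rng = np.random.default_rng(seed)
    values = []
    skipped = 0
    for _ in range(n_resamples):
        resample = d[rng.integers(0, d.size, size=d.size)]
        if np.all(resample == 0.0):
            skipped += 1
            continue
        values.append(statistic(resample))
    if not values:
        raise ValueError("every bootstrap resample was degenerate (all zeros)")
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(values, [alpha, 1.0 - alpha])
    return float(low), float(high)


def compare_methods(
    metric_table: pd.DataFrame,
    method_a: str,
    method_b: str,
    metrics: Sequence[str] = ("dsc", "hd95_mm", "msd_mm"),
    fractions: Optional[Sequence[int]] = None,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-fraction paired comparisons of two methods across patients.

    ``metric_table`` is tidy with columns patient, method, test_fraction and
    one column per metric.  For each (metric, fraction), differences
    (method_a - method_b) are paired by patient; the Holm family is all
    fractions within one metric (the family definition is an explicit choice;
    the convention here is per-metric across fractions).  Rows with
    0.05 < p_holm <= 0.10 are labelled "marginal"; identical paired values
    yield a "degenerate" row with p = 1 and undefined effect size.
    """
    needed = {"patient", "method", "test_fraction"}
    if not needed <= set(metric_table.columns):
        raise ValueError(f"metric table must have columns {sorted(needed)}")
    rows = []
    for metric in metrics:
        per_fraction: list[dict] = []
        frs = fractions
        if frs is None:
            frs = sorted(metric_table["test_fraction"].unique())
        for fx in frs:
            sub = metric_table[metric_table["test_fraction"] == fx]
            a = sub[sub["method"] == method_a].set_index("patient")[metric]
            b = sub[sub["method"] == method_b].set_index("patient")[metric]
            common = a.index.intersection(b.index)
            missing = a.index.symmetric_difference(b.index)
            if len(missing):
                raise ValueError(
                    f"unpaired patients for fraction {fx}: {sorted(missing)}"
                )
            diffs = (a.loc[common] - b.loc[common]).to_numpy()
            row = {
                "metric": metric,
                "test_fraction": fx,
                "method_a": method_a,
                "method_b": method_b,
                "n_pairs": len(common),
            }
            if np.all(diffs == 0.0):
                row.update(
                    w=np.nan, w_plus=np.nan, w_minus=np.nan, n_effective=0,
                    p=1.0, r=np.nan, r_low=np.nan, r_high=np.nan,
                    exact=True, label="degenerate",
                )
            else:
                res = wilcoxon_exact(diffs)
                r = rank_biserial(diffs)
                if diffs.size >= 2:
                    ci = bootstrap_ci(diffs, n_resamples=n_resamples, seed=seed)
                else:
                    ci = (np.nan, np.nan)
                row.update(
                    w=res.w, w_plus=res.w_plus, w_minus=res.w_minus,
                    n_effective=res.n_effective, p=res.p, r=r,
                    r_low=ci[0], r_high=ci[1], exact=res.exact, label="",
                )
            per_fraction.append(row)
        # Holm within the family = this metric's fractions.
        real = [r for r in per_fraction if r["label"] != "degenerate"]
        adj = holm_adjust([r["p"] for r in real]) if real else []
        for r, ph in zip(real, adj):
            r["p_holm"] = ph
            if 0.05 < ph <= 0.10:
                r["label"] = "marginal"
        for r in per_fraction:
            r.setdefault("p_holm", 1.0)
        rows.extend(per_fraction)
    return pd.DataFrame(rows)
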