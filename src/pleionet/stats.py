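"""Nonparametric group comparisons and correlations.

All tests are two-sided; directions are reported separately through group
means. Mann-Whitney uses the exact null distribution for small tie-free
samples (n_a * n_b <= 400) and the tie-corrected, continuity-corrected
normal approximation otherwise, so p-values are bit-reproducible across
runs. Spearman uses midranks for ties with the t-approximation for the
p-value; Fisher's exact test sums the probabilities of all tables at most
as probable as the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MW_MAX_PRODUCT = 400


@dataclass
class ComparisonResult:
    metric: str
    class_a: str
    class_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    statistic: float
    p_value: float

    @property
    def direction(self) -> int:
        return int(np.sign(self.mean_a - self.mean_b))


@dataclass
class CorrelationResult:
    metric: str
    rho: float
    n: int
    p_value: float


def _summary(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def mann_whitney(values_a, values_b, metric: str = "",
                 class_a: str = "a", class_b: str = "b") -> ComparisonResult:
    """Two-sided Mann-Whitney U test between two samples."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (a.size * b.size <= EXACT_MW_MAX_PRODUCT and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    mean_a, sd_a = _summary(a)
    mean_b, sd_b = _summary(b)
    return ComparisonResult(metric=metric, class_a=class_a, class_b=class_b,
                            n_a=a.size, n_b=b.size, mean_a=mean_a, mean_b=mean_b,
                            sd_a=sd_a, sd_b=sd_b, statistic=float(res.statistic),
                            p_value=float(min(res.pvalue, 1.0)))


def spearman(x, y, metric: str = "") -> CorrelationResult:
    """Spearman rank correlation (midranks for ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("spearman requires equal-length samples")
    if x.size < 3:
        raise ValueError("spearman requires n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return CorrelationResult(metric=metric, rho=float("nan"), n=x.size,
                                 p_value=float("nan"))
    res = sps.spearmanr(x, y)
    return CorrelationResult(metric=metric, rho=float(res.statistic), n=x.size,
                             p_value=float(res.pvalue))


def fisher_exact(table, metric: str = "", class_a: str = "a",
                 class_b: str = "b") -> ComparisonResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The statistic is the sample odds ratio; means are the per-class
    proportions of the first column (e.g. fraction essential).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_exact requires a non-negative 2x2 table")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("fisher_exact requires positive margins")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    n_a, n_b = int(t[0].sum()), int(t[1].sum())
    prop_a, prop_b = t[0, 0] / n_a, t[1, 0] / n_b
    return ComparisonResult(metric=metric, class_a=class_a, class_b=class_b,
                            n_a=n_a, n_b=n_b, mean_a=float(prop_a),
                            mean_b=float(prop_b),
                            sd_a=float(np.sqrt(prop_a * (1 - prop_a))),
                            sd_b=float(np.sqrt(prop_b * (1 - prop_b))),
                            statistic=float(odds), p_value=float(p))


def summarize_by_class(profile: pd.DataFrame, classified,
                       pairs: list[tuple[str, str]],
                       metrics: list[str] | None = None) -> pd.DataFrame:
    """Mean +- SD per class per metric with pairwise Mann-Whitney p-values.

    ``profile`` is a per-gene metric table indexed by gene id (e.g. the
    centrality profile); ``classified`` provides ``genes_in_class``. NaN
    metric values (e.g. clustering of degree-1 nodes) are excluded per
    metric. Comparisons whose classes have no genes in the profile are
    skipped with a warning row omitted.
    """
    if metrics is None:
        metrics = [c for c in profile.columns
                   if profile[c].dtype.kind in "fi" and c != "component_id"]
    rows = []
    for class_a, class_b in pairs:
        genes_a = sorted(classified.genes_in_class(class_a) & set(profile.index))
        genes_b = sorted(classified.genes_in_class(class_b) & set(profile.index))
        for metric in metrics:
            va = profile.loc[genes_a, metric].dropna().to_numpy()
            vb = profile.loc[genes_b, metric].dropna().to_numpy()
            if va.size == 0 or vb.size == 0:
                continue
            r = mann_whitney(va, vb, metric=metric, class_a=class_a, class_b=class_b)
            rows.append((metric, class_a, class_b, r.n_a, r.n_b, r.mean_a, r.sd_a,
                         r.mean_b, r.sd_b, r.statistic, r.p_value))
    return pd.DataFrame(rows, columns=["metric", "class_a", "class_b", "n_a", "n_b",
                                       "mean_a", "sd_a", "mean_b", "sd_b",
                                       "statistic", "p_value"])
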