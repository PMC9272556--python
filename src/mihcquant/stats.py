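"""Two-group and multi-group comparisons, correlation, ROC-AUC, PSI filter.

All tests are two-tailed. Missing values are dropped per variable, never
imputed, and no multiple-testing correction is applied by default (an
optional Benjamini–Hochberg adjustment is available for reuse in larger
screens).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class ComparisonResult:
    variable: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    statistic: float
    p_value: float
    test: str  # t_test | anova


@dataclass(frozen=True)
class PsiRecord:
    """Percent-spliced-in of one sample: fraction of transcripts carrying
    the isoform of interest."""

    sample_id: str
    psi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.psi <= 1.0):
            raise ValueError(f"sample {self.sample_id!r}: PSI {self.psi} outside [0, 1]")


def _clean(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    return arr[~np.isnan(arr)]


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    mode: str = "welch",
    variable: str = "",
    group_a: str = "a",
    group_b: str = "b",
) -> ComparisonResult:
    """Two-tailed independent-sample t-test between two groups.

    ``welch`` (default) does not assume equal variances; ``pooled`` is the
    classical equal-variance t-test. Missing values are dropped. Two groups
    that are both constant with equal means return statistic 0, p = 1.
    """
    if mode not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test mode {mode!r}")
    a = _clean(values_a)
    b = _clean(values_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.ttest_ind(a, b, equal_var=(mode == "pooled"))
    return ComparisonResult(
        variable=variable,
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        statistic=float(stat),
        p_value=float(p),
        test="t_test",
    )


def anova_groups(
    groups: Sequence[Sequence[float]], variable: str = ""
) -> ComparisonResult:
    """One-way ANOVA across ≥2 groups; F statistic and two-tailed p."""
    cleaned = [_clean(g) for g in groups]
    if len(cleaned) < 2 or any(len(g) < 2 for g in cleaned):
        raise ValueError("ANOVA needs ≥2 groups with ≥2 values each")
    pooled = np.concatenate(cleaned)
    if np.ptp(pooled) == 0:
        stat, p = 0.0, 1.0  # zero between- and within-group variance
    else:
        stat, p = sps.f_oneway(*cleaned)
    return ComparisonResult(
        variable=variable,
        group_a="group_1",
        group_b=f"group_{len(cleaned)}",
        n_a=len(cleaned[0]),
        n_b=len(cleaned[-1]),
        mean_a=float(cleaned[0].mean()),
        mean_b=float(cleaned[-1].mean()),
        statistic=float(stat),
        p_value=float(p),
        test="anova",
    )


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation coefficient with two-tailed p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    if len(xa) < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("non-finite values")
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("undefined correlation: zero variance")
    r, p = sps.pearsonr(xa, ya)
    return float(r), float(p)


def roc_auc(score: Sequence[float], label: Sequence[int]) -> float:
    """Area under the ROC curve via the rank (Mann–Whitney) statistic.

    ``label`` is binary (1 = positive class). Tied scores contribute 1/2.
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(label)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("score and label must be equal-length 1-d sequences")
    uniq = set(np.unique(y).tolist())
    if not uniq <= {0, 1} or len(uniq) != 2:
        raise ValueError("labels must contain both classes (0 and 1)")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    ranks = sps.rankdata(s)  # midranks handle ties with weight 1/2
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def filter_psi(
    records: Sequence[PsiRecord], threshold: float = 0.9
) -> list[PsiRecord]:
    """Keep samples whose PSI is strictly greater than ``threshold``.

    Used to restrict expression cohorts to samples where the isoform of
    interest dominates splicing of its gene.
    """
    return [r for r in records if r.psi > threshold]


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH-adjusted p-values (optional; the default pipeline reports raw p)."""
    return list(sps.false_discovery_control(np.asarray(p_values, dtype=float)))


def significant(p_value: float, alpha: float = 0.05) -> bool:
    return p_value < alpha
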