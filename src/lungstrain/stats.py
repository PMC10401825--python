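"""Statistical comparisons used by the analysis: paired t-tests,
Pearson/Spearman correlations, and two-way repeated-measures ANOVA
(region x ventilatory strategy, both within-subject).

The ANOVA assumes a complete balanced design with one observation per
subject x region x strategy cell; each within-subject effect is tested
against its own subject-interaction error term. No sphericity correction
is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "PairedTResult",
    "CorrelationResult",
    "paired_t",
    "correlation",
    "rm_anova_two_way",
]


@dataclass
class PairedSample:
    """Matched per-subject values under two conditions."""

    subjects: list
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (len(self.subjects) == self.a.size == self.b.size):
            raise ValueError("subjects, a and b must have equal length")
        if self.a.size < 2:
            raise ValueError("need at least two pairs")
        if np.isnan(self.a).any() or np.isnan(self.b).any():
            raise ValueError("missing pairs are not allowed")


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    mean_difference: float


@dataclass
class CorrelationResult:
    r: float
    p: float
    method: str
    n: int


def paired_t(sample: PairedSample) -> PairedTResult:
    """Two-tailed paired Student's t-test: t = mean(d) / (sd(d)/sqrt(n))."""
    d = sample.a - sample.b
    if d.std(ddof=1) == 0:
        raise ValueError("zero-variance differences; t undefined")
    res = sps.ttest_rel(sample.a, sample.b)
    return PairedTResult(
        t=float(res.statistic),
        df=int(d.size - 1),
        p=float(res.pvalue),
        mean_difference=float(d.mean()),
    )


def correlation(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson product-moment or Spearman rank correlation with two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input; correlation undefined")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(r=float(r), p=float(p), method=method, n=int(x.size))


def rm_anova_two_way(values: np.ndarray) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA on a subject x region x strategy array.

    Parameters
    ----------
    values
        Array of shape (n_subjects, n_regions, n_strategies), complete and
        balanced (one observation per cell).

    Returns
    -------
    DataFrame indexed by effect (``region``, ``strategy``,
    ``region:strategy``) with sums of squares of the effect and its error
    term, degrees of freedom, F and two-tailed p.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 3:
        raise ValueError("expected a (subject, region, strategy) array")
    if np.isnan(y).any():
        raise ValueError("design must be complete and balanced (no empty cells)")
    n, a, b = y.shape
    if n < 2 or a < 2 or b < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels per factor")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))  # subject means
    m_a = y.mean(axis=(0, 2))  # region means
    m_b = y.mean(axis=(0, 1))  # strategy means
    m_sa = y.mean(axis=2)  # subject x region
    m_sb = y.mean(axis=1)  # subject x strategy
    m_ab = y.mean(axis=0)  # region x strategy

    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * (
        (m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2
    ).sum()
    ss_sa = b * (
        (m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2
    ).sum()
    ss_sb = a * (
        (m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2
    ).sum()
    ss_sab = (
        (
            y
            - m_sa[:, :, None]
            - m_sb[:, None, :]
            - m_ab[None, :, :]
            + m_s[:, None, None]
            + m_a[None, :, None]
            + m_b[None, None, :]
            - grand
        )
        ** 2
    ).sum()

    rows = []
    for name, ss_eff, df_eff, ss_err, df_err in [
        ("region", ss_a, a - 1, ss_sa, (n - 1) * (a - 1)),
        ("strategy", ss_b, b - 1, ss_sb, (n - 1) * (b - 1)),
        ("region:strategy", ss_ab, (a - 1) * (b - 1), ss_sab, (n - 1) * (a - 1) * (b - 1)),
    ]:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        f = ms_eff / ms_err if ms_err > 0 else np.inf
        p = float(sps.f.sf(f, df_eff, df_err)) if np.isfinite(f) else 0.0
        rows.append(
            {
                "effect": name,
                "ss": float(ss_eff),
                "df": df_eff,
                "ss_error": float(ss_err),
                "df_error": df_err,
                "F": float(f),
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("effect")
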