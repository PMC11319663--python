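"""Within-subject statistics: the 2x2 repeated-measures ANOVA with partial
eta-squared, post-hoc paired t-tests with Cohen's d, and the paired-t
power / sample-size computation.

For a fully within-subject 2x2 design each ANOVA term has a single degree
of freedom and its F statistic equals the square of the paired t on the
corresponding per-subject contrast; the implementation computes the terms
that way, which makes the F = t^2 identity exact by construction and keeps
the error term per-contrast (sphericity is moot with two-level factors).

Partial eta-squared follows the one-df identity
``pes = F * df1 / (F * df1 + df2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "AnovaTerm",
    "AnovaResult",
    "rm_anova_2x2",
    "partial_eta_sq",
    "paired_t",
    "power_paired_t",
    "required_n",
]


@dataclass(frozen=True)
class AnovaTerm:
    term: str
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


@dataclass
class AnovaResult:
    terms: list[AnovaTerm]
    factor_a: str
    factor_b: str
    n_subjects: int

    def __getitem__(self, term: str) -> AnovaTerm:
        for t in self.terms:
            if t.term == term:
                return t
        raise KeyError(term)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": [t.term for t in self.terms],
                "F": [t.F for t in self.terms],
                "df1": [t.df1 for t in self.terms],
                "df2": [t.df2 for t in self.terms],
                "p": [t.p for t in self.terms],
                "partial_eta_sq": [t.partial_eta_sq for t in self.terms],
            }
        )


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Partial eta-squared of an ANOVA term from its F and degrees of
    freedom (report rounded to 2 decimals, as is conventional)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("need F >= 0 and positive degrees of freedom")
    return F * df1 / (F * df1 + df2)


def _contrast_f(contrast: np.ndarray, term: str) -> tuple[float, int, int, float]:
    n = contrast.size
    sd = contrast.std(ddof=1)
    if sd == 0:
        raise ValueError(f"zero error variance for term {term!r}")
    t = contrast.mean() / (sd / np.sqrt(n))
    F = t * t
    p = float(sps.f.sf(F, 1, n - 1))
    return float(F), 1, n - 1, p


def rm_anova_2x2(
    data: pd.DataFrame,
    dv: str,
    subject: str = "subject_id",
    within: tuple[str, str] = ("session", "response_type"),
) -> AnovaResult:
    """Two-by-two fully within-subject repeated-measures ANOVA.

    ``data`` is a long frame with one row per subject x cell; both within
    factors must have exactly two levels.  Subjects with any missing cell
    are dropped listwise (logged).  Returns main effects named after the
    factors and their interaction ``"a x b"``.
    """
    fa, fb = within
    for col in (subject, dv, fa, fb):
        if col not in data.columns:
            raise ValueError(f"rm_anova_2x2: missing column {col!r}")
    la = sorted(data[fa].unique())
    lb = sorted(data[fb].unique())
    if len(la) != 2 or len(lb) != 2:
        raise ValueError("rm_anova_2x2: both factors must have exactly 2 levels")
    wide = data.pivot_table(index=subject, columns=[fa, fb], values=dv, aggfunc="mean")
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    if dropped:
        log.warning("rm_anova_2x2: dropping incomplete subjects: %s", dropped)
    n = len(complete)
    if n < 3:
        raise ValueError(f"rm_anova_2x2: need >= 3 complete subjects, have {n}")
    cells = complete.to_numpy().reshape(n, 2, 2)  # [subject, a-level, b-level]

    c_a = cells[:, 1, :].mean(axis=1) - cells[:, 0, :].mean(axis=1)
    c_b = cells[:, :, 1].mean(axis=1) - cells[:, :, 0].mean(axis=1)
    c_ab = (cells[:, 1, 1] - cells[:, 1, 0]) - (cells[:, 0, 1] - cells[:, 0, 0])

    terms = []
    for name, contrast in ((fa, c_a), (fb, c_b), (f"{fa} x {fb}", c_ab)):
        F, df1, df2, p = _contrast_f(contrast, name)
        terms.append(AnovaTerm(name, F, df1, df2, p, partial_eta_sq(F, df1, df2)))
    return AnovaResult(terms=terms, factor_a=fa, factor_b=fb, n_subjects=n)


def paired_t(x, y, two_tailed_alpha: float = 0.05) -> dict:
    """Paired-sample t-test with Cohen's d for dependent means
    (d = mean difference / SD of the differences)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired_t: x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 2:
        raise ValueError("paired_t: need at least 2 pairs")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("paired_t: zero variance of the differences")
    t = diff.mean() / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return {
        "t": float(t),
        "df": n - 1,
        "p": p,
        "cohens_d": float(diff.mean() / sd),
        "significant": p < two_tailed_alpha,
        "alpha": two_tailed_alpha,
    }


def power_paired_t(d: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided paired t-test at effect size ``d`` (on the
    difference scores) and ``n`` pairs, via the noncentral t distribution
    with noncentrality ``d * sqrt(n)``."""
    if n < 2:
        raise ValueError("n must be >= 2")
    df = n - 1
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    ncp = d * np.sqrt(n)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def required_n(
    effect_size_d: float,
    alpha: float = 0.025,
    target_power: float = 0.8,
    n_max: int = 10_000,
) -> int:
    """Smallest number of pairs giving the paired t-test at least
    ``target_power`` against a two-sided alternative of size ``d``."""
    if effect_size_d <= 0:
        raise ValueError("effect size must be positive")
    if not 0 < alpha < 1 or not alpha < target_power < 1:
        raise ValueError("need 0 < alpha < target_power < 1")
    for n in range(2, n_max + 1):
        if power_paired_t(effect_size_d, n, alpha) >= target_power:
            return n
    raise ValueError(f"target power not reached by n = {n_max}")
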