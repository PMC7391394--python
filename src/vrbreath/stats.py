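"""One-way ANOVA from published group summaries.

Between-group results are often reported only as per-group mean, SD and
n.  For two groups, the one-way (equal-variance, pooled) ANOVA F
statistic is fully determined by those summaries:

    s2 = ((n1-1)*s1**2 + (n2-1)*s2**2) / (n1 + n2 - 2)
    F  = (m1 - m2)**2 / (s2 * (1/n1 + 1/n2)),   df = (1, n1 + n2 - 2)

which makes printed F values verifiable from printed descriptives (up to
the rounding of the summaries).  Eta squared is reported alongside as
F*df1 / (F*df1 + df2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from pydantic import BaseModel, Field
from scipy.stats import f as f_dist

__all__ = ["GroupSummary", "AnovaResult", "anova_f_from_summary"]


class GroupSummary(BaseModel):
    """Per-group descriptives: sample size, mean and standard deviation."""

    n: int = Field(ge=2)
    mean: float
    sd: float = Field(ge=0.0)


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df1: int
    df2: int
    eta_sq: float
    p: float


def anova_f_from_summary(g1: GroupSummary, g2: GroupSummary) -> AnovaResult:
    """Two-group one-way ANOVA F from group means/SDs/ns.

    Zero pooled variance yields F=0 for equal means and an infinite-F
    flag (``math.inf``) for unequal means.
    """
    df1 = 1
    df2 = g1.n + g2.n - 2
    pooled = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df2
    diff = g1.mean - g2.mean
    if pooled == 0.0:
        f = 0.0 if diff == 0.0 else math.inf
    else:
        f = diff**2 / (pooled * (1.0 / g1.n + 1.0 / g2.n))
    eta = 1.0 if math.isinf(f) else f * df1 / (f * df1 + df2)
    p = 0.0 if math.isinf(f) else float(f_dist.sf(f, df1, df2))
    return AnovaResult(f=f, df1=df1, df2=df2, eta_sq=eta, p=p)
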