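"""Chi-square goodness-of-fit test for Mendelian segregation ratios.

For observed phenotype class counts O_i and a hypothesised ratio (e.g. 3:1 for
a monogenic recessive in selfed-heterozygote progeny), expected counts are
E_i = N * ratio_i / sum(ratio) and the statistic is the uncorrected Pearson
chi-square, sum((O_i - E_i)^2 / E_i), on k-1 degrees of freedom. The classic
worked case — 73 green : 19 white against 3:1 — gives chi2 = 0.93 < 3.84, the
5% critical value at 1 df, so the 3:1 model is retained.

Yates' continuity correction is available but off by default: segregation-ratio
practice in plant genetics reports the uncorrected statistic, and the corrected
value differs noticeably at these sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["SegregationResult", "chi_square_segregation"]


@dataclass(frozen=True)
class SegregationResult:
    observed: tuple[int, ...]
    ratio: tuple[float, ...]
    expected: tuple[float, ...]
    chi2: float
    df: int
    alpha: float
    critical_value: float
    p_value: float
    reject: bool

    def summary(self) -> str:
        decision = "reject" if self.reject else "retain"
        ratio = ":".join(f"{r:g}" for r in self.ratio)
        obs = ":".join(str(o) for o in self.observed)
        return (
            f"observed {obs} vs ratio {ratio}: chi2 = {self.chi2:.2f} "
            f"(df={self.df}, critical {self.critical_value:.2f} at "
            f"alpha={self.alpha:g}, p={self.p_value:.3g}) -> {decision} the ratio"
        )


def chi_square_segregation(
    observed, ratio, alpha: float = 0.05, yates: bool = False
) -> SegregationResult:
    """Test observed class counts against an expected segregation ratio.

    ``observed`` and ``ratio`` are parallel sequences over >= 2 phenotype
    classes; the ratio need not be normalised (3:1 and 75:25 are equivalent).
    ``yates`` subtracts 0.5 from each |O - E| before squaring (continuity
    correction, 2 classes only).
    """
    obs = np.asarray(observed, dtype=float)
    rat = np.asarray(ratio, dtype=float)
    if obs.ndim != 1 or len(obs) < 2:
        raise ValueError("need counts for at least two classes")
    if len(rat) != len(obs):
        raise ValueError("ratio and observed must have the same number of classes")
    if np.any(obs < 0) or obs.sum() <= 0:
        raise ValueError("observed counts must be non-negative with positive total")
    if np.any(rat <= 0):
        raise ValueError("ratio components must be positive")
    if yates and len(obs) != 2:
        raise ValueError("continuity correction applies to two classes only")

    expected = obs.sum() * rat / rat.sum()
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float(np.sum(dev**2 / expected))
    df = len(obs) - 1
    critical = float(stats.chi2.ppf(1.0 - alpha, df))
    p_value = float(stats.chi2.sf(chi2, df))
    return SegregationResult(
        observed=tuple(int(o) for o in obs),
        ratio=tuple(float(r) for r in rat),
        expected=tuple(float(e) for e in expected),
        chi2=chi2,
        df=df,
        alpha=alpha,
        critical_value=critical,
        p_value=p_value,
        reject=chi2 > critical,
    )
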