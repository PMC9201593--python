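"""Post-hoc group comparisons with Bonferroni correction.

Welch (unequal-variance) two-sample t-tests per factor level (band, layer
pair, direction), with adjusted p = min(1, raw * m). The comparison family
size m defaults to the number of tests in the call but can be overridden to
match a predefined family (e.g. 7 bands, 9 layer pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = ["GroupComparison", "pairwise_band_tests", "welch_ttest"]


@dataclass(frozen=True)
class GroupComparison:
    factor: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_raw: float
    p_adjusted: float
    m: int


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("degenerate variance in both groups")
    t, p = sstats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def pairwise_band_tests(
    group_a: pd.DataFrame, group_b: pd.DataFrame, m: int | None = None
) -> list[GroupComparison]:
    """Welch t-test per shared column (one column per band/factor level),
    Bonferroni-corrected over ``m`` comparisons (defaults to the number of
    shared columns)."""
    factors = [c for c in group_a.columns if c in group_b.columns]
    if not factors:
        raise ValueError("groups share no factor columns")
    m_eff = m if m is not None else len(factors)
    out = []
    for f in factors:
        a = group_a[f].to_numpy(dtype=float)
        b = group_b[f].to_numpy(dtype=float)
        t, p = welch_ttest(a, b)
        out.append(
            GroupComparison(
                factor=str(f),
                mean_a=float(a.mean()),
                sd_a=float(a.std(ddof=1)),
                n_a=a.size,
                mean_b=float(b.mean()),
                sd_b=float(b.std(ddof=1)),
                n_b=b.size,
                t_statistic=t,
                p_raw=p,
                p_adjusted=min(1.0, p * m_eff),
                m=m_eff,
            )
        )
    return out
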