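"""Group-comparison statistics used by the reporting layer."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

__all__ = ["WelchResult", "welch_t"]


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    df: float
    p_two_sided: float

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "df": self.df,
            "p_two_sided": self.p_two_sided,
        }


def welch_t(sample_a, sample_b) -> WelchResult:
    """Welch's unequal-variance t-test with Welch–Satterthwaite df.

    Raises on degenerate samples (n < 2 or zero variance), for which the
    statistic is undefined.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    if np.var(a, ddof=1) == 0 or np.var(b, ddof=1) == 0:
        raise ValueError("both samples need positive variance")
    res = _st.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_two_sided=float(res.pvalue),
    )
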