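"""Method-comparison statistics: optical vs. reference mixing times.

Paired mixing times measured under the same conditions by two methods are
compared with the Pearson product-moment correlation and an ordinary
least-squares line (reference method on x, optical on y).  For simple linear
regression the coefficient of determination equals the squared correlation;
that identity is asserted as a sanity check.  No p-values are reported —
with a handful of operating conditions, inference on rho is meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, InputError

MIN_PAIRS = 3


@dataclass
class ComparisonResult:
    n: int
    rho: float
    slope: float
    intercept: float
    r_squared: float


def _validate(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or x.shape != y.shape:
        raise InputError("x and y must be equal-length 1-D vectors")
    if len(x) < MIN_PAIRS:
        raise InputError(f"need >= {MIN_PAIRS} pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("zero variance in x or y: correlation undefined")
    return x, y


def pearson(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x, y = _validate(x, y)
    return float(stats.pearsonr(x, y).statistic)


def linear_fit(x, y) -> tuple[float, float, float]:
    """OLS line y = slope·x + intercept; returns (slope, intercept, R²)."""
    x, y = _validate(x, y)
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def compare_conditions(
    pairs: list[tuple[str, float, float]]
) -> tuple[ComparisonResult, pd.DataFrame]:
    """Compare paired mixing times across conditions.

    ``pairs`` holds (condition label, reference t_mix, optical t_mix).
    Returns the summary statistics and a per-condition table with the
    optical − reference difference.
    """
    if len(pairs) < MIN_PAIRS:
        raise InputError(f"need >= {MIN_PAIRS} paired conditions")
    table = pd.DataFrame(
        pairs, columns=["condition", "ref_tmix_s", "opt_tmix_s"]
    )
    ref = table["ref_tmix_s"].to_numpy(dtype=np.float64)
    opt = table["opt_tmix_s"].to_numpy(dtype=np.float64)
    rho = pearson(ref, opt)
    slope, intercept, r2 = linear_fit(ref, opt)
    table["diff_s"] = table["opt_tmix_s"] - table["ref_tmix_s"]
    return (
        ComparisonResult(
            n=len(pairs), rho=rho, slope=slope, intercept=intercept, r_squared=r2
        ),
        table,
    )


def read_pairs_csv(path: str | Path) -> list[tuple[str, float, float]]:
    """Read ``condition,ref_tmix_s,opt_tmix_s`` rows."""
    try:
        df = pd.read_csv(Path(path), comment="#")
    except Exception as exc:
        raise FormatError(f"cannot parse pairs CSV {path}: {exc}") from exc
    required = {"condition", "ref_tmix_s", "opt_tmix_s"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: need columns {sorted(required)}, got {list(df.columns)}"
        )
    return [
        (str(r.condition), float(r.ref_tmix_s), float(r.opt_tmix_s))
        for r in df.itertuples()
    ]
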