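"""Statistics for comparing the expressed and non-expressed sets.

The two-sided Fisher exact test follows the minimum-likelihood convention of
R's ``fisher.test`` (sum the probabilities of all tables with the same
margins that are no more likely than the observed one), computed with
log-factorials so it is stable for set sizes in the tens of thousands.  The
rank comparison is the Wilcoxon rank-sum / Mann-Whitney test, exact for
small tie-free samples and normal-approximated with continuity and tie
correction otherwise, again matching the R behaviour the field reports.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import mannwhitneyu

logger = logging.getLogger(__name__)

#: Relative tolerance when comparing table probabilities, guarding against
#: floating-point ties (same convention as R's fisher.test).
_REL_TOL = 1e-7


@dataclass
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    p_two_sided: float
    odds_ratio: float


def _log_factorial(n: np.ndarray) -> np.ndarray:
    return gammaln(np.asarray(n, dtype=float) + 1)


def fisher_exact_two_sided(table) -> ContingencyResult:
    """Two-sided Fisher exact test for a 2x2 count table.

    p is the sum of hypergeometric probabilities of every table with the
    observed margins whose probability does not exceed the observed table's
    (within a relative tolerance of 1e-7).  The odds ratio is the sample
    ad/bc, with infinity when bc = 0 and ad > 0.
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("table is empty")

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    # log P(a') up to the constant term, which cancels in the comparison
    logp = -(
        _log_factorial(support)
        + _log_factorial(r1 - support)
        + _log_factorial(c1 - support)
        + _log_factorial(r2 - c1 + support)
    )
    log_obs = float(logp[a - lo])
    keep = logp <= log_obs + math.log1p(_REL_TOL)
    # normalise within the support for numerical stability
    shifted = np.exp(logp - logp.max())
    p = float(shifted[keep].sum() / shifted.sum())
    p = min(p, 1.0)

    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return ContingencyResult(((a, b), (c, d)), p, odds)


def wilcoxon_rank_sum(x, y) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum test; returns (p, mode).

    Exact when both samples have <= 25 observations and the pooled data are
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction.  Degenerate input (a single pooled value) returns
    p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        logger.warning("degenerate rank-sum input (all values identical); p = 1")
        return 1.0, "degenerate"
    tie_free = np.unique(pooled).size == pooled.size
    if x.size <= 25 and y.size <= 25 and tie_free:
        mode = "exact"
    else:
        mode = "asymptotic"
    logger.debug("wilcoxon_rank_sum mode=%s (n=%d, m=%d)", mode, x.size, y.size)
    res = mannwhitneyu(
        x, y, alternative="two-sided", method=mode, use_continuity=True
    )
    return float(res.pvalue), mode


def percent(numerator: int, denominator: int) -> tuple[str, float]:
    """Percentage rounded half-away-from-zero to an integer, e.g. "57%".

    Returns the formatted string and the raw (unrounded) percentage.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    raw = 100 * numerator / denominator
    rounded = math.floor(raw + 0.5) if raw >= 0 else math.ceil(raw - 0.5)
    return f"{rounded}%", raw


def enrichment_report(
    features: pd.DataFrame,
    set_column: str = "set",
    categorical: dict[str, str] | None = None,
    continuous: list[str] | None = None,
) -> pd.DataFrame:
    """Fisher/Wilcoxon comparisons of exRTE vs n-exRTE feature tables.

    ``features`` holds one row per element with a ``set`` column ("exRTE" /
    "n-exRTE").  ``categorical`` maps column -> level: for each entry a 2x2
    table (set x has-level) is tested with Fisher's exact test; a column may
    be boolean, in which case level "True" is conventional.  ``continuous``
    columns are compared with the Wilcoxon rank-sum test.  Attributes absent
    from the table or empty on both sides are skipped with a warning.
    """
    ex = features[features[set_column] == "exRTE"]
    nex = features[features[set_column] == "n-exRTE"]
    rows = []
    for column, level in (categorical or {}).items():
        if column not in features.columns:
            logger.warning("categorical attribute %s missing; skipped", column)
            continue
        ex_vals = ex[column].astype(str)
        nex_vals = nex[column].astype(str)
        a = int((ex_vals == level).sum())
        b = len(ex_vals) - a
        c = int((nex_vals == level).sum())
        d = len(nex_vals) - c
        if a + c == 0 and b + d == 0:
            logger.warning("attribute %s empty on both sides; skipped", column)
            continue
        res = fisher_exact_two_sided(((a, b), (c, d)))
        rows.append(
            {
                "attribute": f"{column}={level}",
                "test": "fisher_exact_two_sided",
                "ex_with": a,
                "ex_without": b,
                "nex_with": c,
                "nex_without": d,
                "statistic": res.odds_ratio,
                "p_value": res.p_two_sided,
            }
        )
    for column in continuous or []:
        if column not in features.columns:
            logger.warning("continuous attribute %s missing; skipped", column)
            continue
        xv = pd.to_numeric(ex[column], errors="coerce").dropna()
        yv = pd.to_numeric(nex[column], errors="coerce").dropna()
        xv = xv[np.isfinite(xv)]
        yv = yv[np.isfinite(yv)]
        if xv.empty or yv.empty:
            logger.warning("attribute %s empty on one side; skipped", column)
            continue
        p, mode = wilcoxon_rank_sum(xv.to_numpy(), yv.to_numpy())
        rows.append(
            {
                "attribute": column,
                "test": f"wilcoxon_rank_sum[{mode}]",
                "ex_with": len(xv),
                "ex_without": 0,
                "nex_with": len(yv),
                "nex_without": 0,
                "statistic": float(xv.median() - yv.median()),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
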