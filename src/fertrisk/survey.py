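"""Descriptive statistics, normality tests, Spearman correlation and
regulatory-limit screening of a fertilizer concentration table.

A *concentration table* is a pandas DataFrame with columns
``sample_id, region, Cr, Ni, Cu, Zn, As, Cd, Pb`` (mg/kg dry weight);
see :mod:`fertrisk.io` for validated reading and writing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .metals import METAL_COLUMNS, METALS, Metal

#: Sample-size cutoff below which Spearman p-values are exact
#: (permutation enumeration) rather than the t approximation.
EXACT_SPEARMAN_MAX_N = 10


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-metal summary statistics of a concentration table.

    Returns a frame indexed by metal symbol with columns ``n``, ``min``,
    ``max``, ``mean``, ``median``, ``sd`` (sample SD, n-1 denominator),
    ``cv_percent`` (100*sd/mean) and ``shapiro_p`` (Shapiro-Wilk test of
    normality of the raw concentrations; NaN when n < 3 or the column is
    constant, where the statistic is undefined).
    """
    rows = []
    for m in METALS:
        x = table[m.value].to_numpy(dtype=float)
        n = x.size
        if n == 0:
            raise ValueError("empty concentration table")
        mean = float(x.mean())
        sd = float(x.std(ddof=1)) if n > 1 else 0.0
        if n >= 3 and np.ptp(x) > 0:
            shapiro_p = float(stats.shapiro(x).pvalue)
        else:
            shapiro_p = math.nan
        rows.append(
            {
                "metal": m.value,
                "n": n,
                "min": float(x.min()),
                "max": float(x.max()),
                "mean": mean,
                "median": float(np.median(x)),
                "sd": sd,
                "cv_percent": 100.0 * sd / mean if mean > 0 else 0.0,
                "shapiro_p": shapiro_p,
            }
        )
    return pd.DataFrame(rows).set_index("metal")


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value for Spearman's rho.

    Enumerates all n! orderings of one rank vector (midranks preserved),
    counting |rho_perm| >= |rho_obs|.  Intended for n <= 10.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    if float(rx @ rx) == 0 or float(ry @ ry) == 0:
        return math.nan
    # the normalization is permutation-invariant, so compare raw products
    thresh = abs(float(rx @ ry)) * (1 - 1e-12)
    count = total = 0
    chunk: list[tuple[float, ...]] = []

    def flush() -> tuple[int, int]:
        arr = np.asarray(chunk)
        return int((np.abs(arr @ rx) >= thresh).sum()), len(chunk)

    for perm in itertools.permutations(ry):
        chunk.append(perm)
        if len(chunk) == 200_000:
            c, t = flush()
            count, total, chunk = count + c, total + t, []
    if chunk:
        c, t = flush()
        count, total = count + c, total + t
    return count / total


@dataclass(frozen=True)
class CorrelationMatrix:
    """Spearman rank-correlation matrix with two-sided significance."""

    rho: pd.DataFrame
    pvalues: pd.DataFrame
    n: int

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        """Boolean frame of pairs significant at ``alpha`` (diagonal False)."""
        sig = self.pvalues < alpha
        np.fill_diagonal(sig.values, False)
        return sig


def spearman_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Spearman rank correlation between all metal pairs.

    Midranks are used for ties.  Two-sided p-values use the exact
    permutation distribution for n <= 10 and the t approximation
    otherwise.  Pairs involving a constant column have undefined rho and
    are reported NaN; the diagonal is exactly 1 with p = 0.
    """
    n = len(table)
    if n < 4:
        raise ValueError("spearman_matrix requires at least 4 samples")
    cols = list(METAL_COLUMNS)
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pv = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for a, b in itertools.combinations(cols, 2):
        x = table[a].to_numpy(dtype=float)
        y = table[b].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r = p = math.nan
        elif n <= EXACT_SPEARMAN_MAX_N:
            r = float(stats.spearmanr(x, y).statistic)
            p = _exact_spearman_p(x, y)
        else:
            res = stats.spearmanr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
        rho.loc[a, b] = rho.loc[b, a] = r
        pv.loc[a, b] = pv.loc[b, a] = p
    return CorrelationMatrix(rho=rho, pvalues=pv, n=n)


def exceedance_rates(
    table: pd.DataFrame, limits: Mapping[Metal, float], jurisdiction_id: str = ""
) -> pd.DataFrame:
    """Fraction of samples whose concentration is above each limit.

    A sample exceeds only when strictly above the limit (a sample exactly
    at a "maximum acceptable concentration" complies).  Metals with no
    limit are flagged ``regulated = False`` with NaN rate.  Returns a
    frame indexed by metal with columns ``limit``, ``n_tested``,
    ``n_exceeding``, ``rate_percent``, ``regulated`` and an attached
    ``jurisdiction_id`` attribute in ``frame.attrs``.
    """
    if len(table) == 0:
        raise ValueError("empty concentration table")
    rows = []
    for m in METALS:
        x = table[m.value].to_numpy(dtype=float)
        limit = limits.get(m)
        if limit is None:
            rows.append(
                {
                    "metal": m.value,
                    "limit": math.nan,
                    "n_tested": x.size,
                    "n_exceeding": 0,
                    "rate_percent": math.nan,
                    "regulated": False,
                }
            )
        else:
            n_exc = int((x > limit).sum())
            rows.append(
                {
                    "metal": m.value,
                    "limit": float(limit),
                    "n_tested": x.size,
                    "n_exceeding": n_exc,
                    "rate_percent": 100.0 * n_exc / x.size,
                    "regulated": True,
                }
            )
    out = pd.DataFrame(rows).set_index("metal")
    out.attrs["jurisdiction_id"] = jurisdiction_id
    return out
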