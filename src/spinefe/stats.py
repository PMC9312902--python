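"""Cohort statistics: descriptives, Spearman correlation, exact Mann-Whitney.

With six subjects per cohort, the normal approximation of the Mann-Whitney U
test is inaccurate, so the two-sided p-value is computed by exhaustive
enumeration of all C(n1+n2, n1) group labelings of the pooled mid-ranks; the
same enumeration convention makes the p-value invariant under monotone
transformations of the data.  Spearman p-values are exact (all n!
permutations) for n <= 7, seeded Monte Carlo permutations for 8 <= n <= 12,
and t-approximate above.

Descriptive standard deviations use the population convention (divisor n).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


def descriptives(values, ddof: int = 0) -> tuple[float, float]:
    """(mean, SD); SD uses the population divisor n by default."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("descriptives of an empty sample")
    return float(values.mean()), float(values.std(ddof=ddof))


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    method: str
    n: int


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # min(U1, U2)
    u1: float
    p: float
    method: str
    n1: int
    n2: int


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return math.nan
    return float(rx @ ry) / denom


def spearman(x, y, n_mc: int = 20000, mc_seed: int = 0) -> SpearmanResult:
    """Spearman rank correlation with a permutation p-value for small n."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman needs two equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise ValueError("spearman needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return SpearmanResult(rho=math.nan, p=math.nan, method="undefined", n=n)

    rx = sps.rankdata(x)  # average ranks for ties
    ry = sps.rankdata(y)
    rho = _rank_rho(rx, ry)

    if n <= 7:
        count = total = 0
        for perm in itertools.permutations(ry):
            r = _rank_rho(rx, np.asarray(perm))
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return SpearmanResult(rho=rho, p=count / total, method="exact", n=n)
    if n <= 12:
        rng = np.random.default_rng(mc_seed)
        hits = 0
        for _ in range(n_mc):
            r = _rank_rho(rx, rng.permutation(ry))
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
        # add-one correction keeps the Monte Carlo p strictly positive
        return SpearmanResult(
            rho=rho, p=(hits + 1) / (n_mc + 1), method="permutation", n=n
        )
    t_res = sps.spearmanr(x, y)
    return SpearmanResult(rho=rho, p=float(t_res.pvalue), method="t-approx", n=n)


def mann_whitney_exact(a, b, exact_limit: int = 8) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U with exhaustive-enumeration p for small n.

    Mid-ranks handle ties; the exact two-sided p counts labelings at least as
    extreme (on either tail of U1) as the observed one.  For group sizes
    beyond ``exact_limit`` the tie-corrected normal approximation is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    u2 = n1 * n2 - u1
    u_min = min(u1, u2)

    if min(n1, n2) <= exact_limit:
        lo, hi = u_min, n1 * n2 - u_min
        count = total = 0
        idx_all = range(n1 + n2)
        for combo in itertools.combinations(idx_all, n1):
            r1 = ranks[list(combo)].sum()
            u1p = r1 - n1 * (n1 + 1) / 2
            total += 1
            if u1p <= lo + 1e-9 or u1p >= hi - 1e-9:
                count += 1
        return MannWhitneyResult(
            u=u_min, u1=u1, p=count / total, method="exact", n1=n1, n2=n2
        )
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(
        u=u_min, u1=u1, p=float(res.pvalue), method="normal-approx", n1=n1, n2=n2
    )


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and its t-test p (reported alongside Spearman for FL-BMD)."""
    r, p = sps.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


#: Table rows: (label, column in the records frame)
TABLE3_ROWS = (
    ("QCT BMD (mg/mL)", "bmd_qct_l1_3"),
    ("Failure load (N)", "fl"),
    ("Flexion (deg)", "theta_f"),
    ("Extension (deg)", "theta_e"),
    ("Lateral bending (deg)", "theta_l"),
    ("Twisting (deg)", "theta_t"),
)

SIGNIFICANCE_LEVEL = 0.01


def build_table3(records: pd.DataFrame, alpha: float = SIGNIFICANCE_LEVEL) -> pd.DataFrame:
    """Healthy-vs-osteoporotic comparison table (mean, SD, exact MW p).

    ``records`` needs a 'cohort' column ('healthy' / 'osteoporotic') and the
    outcome columns; missing outcomes are skipped with a warning.  The
    significance marker flags p < ``alpha``.
    """
    if "cohort" not in records:
        raise ValueError("records need a 'cohort' column")
    hc = records[records["cohort"] == "healthy"]
    op = records[records["cohort"] == "osteoporotic"]
    if len(hc) == 0 or len(op) == 0:
        raise ValueError("both cohorts must be present")

    rows = []
    for label, col in TABLE3_ROWS:
        if col not in records or records[col].isna().all():
            logger.warning("outcome %r missing; row omitted", col)
            continue
        h, o = hc[col].to_numpy(float), op[col].to_numpy(float)
        mh, sh = descriptives(h)
        mo, so = descriptives(o)
        if min(len(h), len(o)) >= 2:
            mw = mann_whitney_exact(h, o)
            p = mw.p
        else:
            p = math.nan
        rows.append({
            "parameter": label,
            "healthy_mean": mh, "healthy_sd": sh,
            "op_mean": mo, "op_sd": so,
            "p_value": p,
            "significant": bool(p < alpha) if not math.isnan(p) else False,
        })
    return pd.DataFrame(rows)


def correlation_table(records: pd.DataFrame) -> pd.DataFrame:
    """Spearman (and Pearson, for FL) of each outcome against BMD_QCT-L1-3."""
    rows = []
    x = records["bmd_qct_l1_3"].to_numpy(float)
    for label, col in TABLE3_ROWS[1:]:
        if col not in records or records[col].isna().all():
            continue
        y = records[col].to_numpy(float)
        sr = spearman(x, y)
        row = {"parameter": label, "spearman_rho": sr.rho, "spearman_p": sr.p}
        if col == "fl":
            r, p = pearson(x, y)
            row["pearson_r"] = r
            row["pearson_p"] = p
            row["r_squared"] = r * r
        rows.append(row)
    return pd.DataFrame(rows)
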