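"""Baseline-characteristics tests: Welch/pooled t-test, Fisher's exact test
by full hypergeometric enumeration, and Pearson chi-square on r x c tables.

These are the tests a clinical baseline table reports: continuous
characteristics (age, pack-years) by t-test, 2 x 2 categorical rows by
Fisher's exact test, and wider categorical rows (device serial, tumor
stage) by Pearson chi-square.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import PatientMetadata

__all__ = [
    "TTestResult",
    "FisherResult",
    "ChiSquareResult",
    "t_test_independent",
    "fisher_exact_2x2",
    "pearson_chi_square",
    "baseline_table",
]


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float
    variance_mode: str


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float  # may be inf or 0 at zero cells
    p_value: float


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def t_test_independent(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    variance_mode: str = "welch",
) -> TTestResult:
    """Two-sided independent-samples t-test (Welch by default)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            raise ValueError("zero variance in both samples and equal means: t undefined")
        raise ValueError("zero variance in both samples: t statistic undefined")
    if variance_mode == "welch":
        se2 = va / na + vb / nb
        t = (a.mean() - b.mean()) / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    elif variance_mode == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        raise ValueError("variance_mode must be 'welch' or 'pooled'")
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(statistic=float(t), df=float(df), p_value=min(p, 1.0),
                       variance_mode=variance_mode)


def _validate_counts(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table)
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("contingency table must hold integer counts")
        t = np.round(t).astype(int)
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    return t


def fisher_exact_2x2(table) -> FisherResult:
    """Fisher's exact test on a 2 x 2 table by full enumeration.

    The two-sided p-value follows the probability method: the sum of the
    hypergeometric probabilities of every table with the observed margins
    whose probability does not exceed that of the observed table (with a
    1 + 1e-7 relative slack against floating-point ties, as in common
    implementations).
    """
    t = _validate_counts(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2 x 2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("all margins must be positive")
    n = r1 + r2

    def log_prob(x: int) -> float:
        # hypergeometric pmf at table [[x, r1-x], [c1-x, ...]] in log space
        return (
            _lchoose(r1, x)
            + _lchoose(r2, c1 - x)
            - _lchoose(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    logs = np.array([log_prob(x) for x in range(lo, hi + 1)])
    probs = np.exp(logs - logs.max())
    probs = probs / probs.sum()  # exact normalization guard
    p_obs = probs[a - lo]
    p_two = float(probs[probs <= p_obs * (1.0 + 1e-7)].sum())

    if b * c == 0:
        odds = math.inf if a * d > 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    return FisherResult(odds_ratio=odds, p_value=min(p_two, 1.0))


def _lchoose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def pearson_chi_square(table, continuity_correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x c count table."""
    t = _validate_counts(table).astype(float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("all-zero row or column in contingency table")
    total = t.sum()
    expected = np.outer(row, col) / total
    diff = np.abs(t - expected)
    if continuity_correction and t.shape == (2, 2):
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return ChiSquareResult(statistic=stat, df=df, p_value=p)


# ---------------------------------------------------------------------------
# Baseline table (the report a clinical paper prints per comparison)
# ---------------------------------------------------------------------------

def baseline_table(
    metadata: Sequence[PatientMetadata], group_a: str, group_b: str
) -> pd.DataFrame:
    """Build a baseline-characteristics comparison for two diagnosis groups.

    Continuous rows (age, pack-years) use the independent t-test; binary
    rows (sex, food intake, smoking) use Fisher's exact test; multi-level
    rows (device serial, tumor stage) use Pearson chi-square.
    """
    ga = [p for p in metadata if p.label == group_a]
    gb = [p for p in metadata if p.label == group_b]
    if not ga:
        raise ValueError(f"no patients with label {group_a!r}")
    if not gb:
        raise ValueError(f"no patients with label {group_b!r}")

    rows = []

    def cont(name, fa, fb):
        res = t_test_independent([fa(p) for p in ga], [fb(p) for p in gb])
        rows.append(
            {
                "characteristic": name,
                group_a: float(np.mean([fa(p) for p in ga])),
                group_b: float(np.mean([fb(p) for p in gb])),
                "test": "t",
                "p_value": res.p_value,
            }
        )

    def binary(name, f):
        a1 = sum(f(p) for p in ga)
        b1 = sum(f(p) for p in gb)
        tab = [[a1, len(ga) - a1], [b1, len(gb) - b1]]
        try:
            res_p = fisher_exact_2x2(tab).p_value
        except ValueError:
            res_p = 1.0  # no variation in the characteristic at all
        rows.append(
            {"characteristic": name, group_a: a1, group_b: b1, "test": "fisher",
             "p_value": res_p}
        )

    def categorical(name, f, levels):
        tab = np.array(
            [[sum(f(p) == lv for p in g) for g in (ga, gb)] for lv in levels]
        )
        keep = tab.sum(axis=1) > 0
        tab = tab[keep]
        if tab.shape[0] < 2:
            p = 1.0
        else:
            p = pearson_chi_square(tab).p_value
        rows.append(
            {"characteristic": name, group_a: len(ga), group_b: len(gb),
             "test": "chi2", "p_value": p}
        )

    rows.append(
        {"characteristic": "n", group_a: len(ga), group_b: len(gb), "test": "", "p_value": np.nan}
    )
    cont("age", lambda p: p.age, lambda p: p.age)
    binary("sex_male", lambda p: p.sex == "male")
    binary("food_intake_lt4h", lambda p: p.food_intake_lt4h)
    binary("currently_smoking", lambda p: p.currently_smoking)
    cont("pack_years", lambda p: p.pack_years, lambda p: p.pack_years)
    categorical("device_serial", lambda p: p.device_serial, sorted({p.device_serial for p in ga + gb}))
    categorical("tumor_stage", lambda p: p.tumor_stage, [0, 1, 2, 3, 4])
    return pd.DataFrame(rows)
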