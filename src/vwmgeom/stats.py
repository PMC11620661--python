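"""Statistical layer: cross-decoding ratio, t tests, FDR correction,
repeated-measures ANOVA and paired-t power analysis.

The cross-decoding ratio (cross - .5) / (within - .5) expresses how
completely a decoder generalizes across contexts: 1 means cross- and
within-context decoding are equally far above chance (full
generalization, context-tolerant coding), 0 means cross-decoding is at
chance (no generalization). It is only meaningful when within-decoding
is robustly above chance; below a guard band the ratio is flagged
invalid rather than computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: within-decoding must exceed chance by this margin for a valid ratio
RATIO_GUARD = 0.02


@dataclass
class RatioResult:
    within: float
    cross: float
    ratio: Optional[float]
    valid: bool


def cross_decoding_ratio(within: float, cross: float,
                         guard: float = RATIO_GUARD) -> RatioResult:
    """(cross - .5) / (within - .5), guarded against near-chance within."""
    for v in (within, cross):
        if not 0.0 <= v <= 1.0:
            raise ValueError("accuracies must lie in [0, 1]")
    if within <= 0.5 + guard:
        return RatioResult(within, cross, None, False)
    return RatioResult(within, cross,
                       (cross - 0.5) / (within - 0.5), True)


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    tails: int
    p_adjusted: Optional[float] = None
    family: Optional[str] = None


def t_test(x: Sequence[float], y: float | Sequence[float] = 0.0,
           paired: bool = False, tails: int = 2) -> TestResult:
    """One-sample (vs a constant) or paired t test.

    One-tailed p values test the positive direction of ``x - y`` (the
    convention for decoding-above-chance tests).
    """
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    x = np.asarray(x, dtype=float)
    if np.isscalar(y) or np.ndim(y) == 0:
        d = x - float(y)
    else:
        y = np.asarray(y, dtype=float)
        if not paired:
            raise ValueError("two-sample tests must be paired here")
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        d = x - y
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return TestResult(0.0, n - 1, 1.0 if tails == 2 else 0.5, tails)
        raise ValueError("zero variance: t statistic undefined")
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    if tails == 2:
        p = 2 * sps.t.sf(abs(t), df)
    else:
        p = sps.t.sf(t, df)
    return TestResult(float(t), df, float(p), tails)


def bh_adjust(p_values: Sequence[float],
              family: Optional[Sequence] = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, within families.

    ``family`` groups tests corrected together (tests of the same type
    within an ROI or sector); ``None`` treats all inputs as one family.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    out = np.empty_like(p)
    if family is None:
        groups = {None: np.arange(p.size)}
    else:
        fam = np.asarray(family, dtype=object)
        if len(fam) != p.size:
            raise ValueError("family labels must match p values")
        groups = {f: np.flatnonzero(fam == f) for f in dict.fromkeys(fam)}
    for idx in groups.values():
        q = p[idx]
        m = q.size
        order = np.argsort(q, kind="stable")
        adj = q[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]  # enforce monotonicity
        res = np.empty(m)
        res[order] = np.minimum(adj, 1.0)
        out[idx] = res
    return out


@dataclass
class AnovaEffect:
    effect: str
    F: float
    df1: int
    df2: int
    p: float


def rm_anova2(data: pd.DataFrame, dv: str = "value", subject: str = "subject",
              factor_a: str = "A", factor_b: str = "B") -> pd.DataFrame:
    """Two-way fully repeated-measures ANOVA on a complete balanced table.

    Each (subject, A, B) cell holds one value; main effects and the
    interaction are tested against their subject-interaction error
    terms (no sphericity correction, matching the reported analyses).
    """
    d = data[[subject, factor_a, factor_b, dv]].copy()
    subjects = sorted(d[subject].unique())
    la = sorted(d[factor_a].unique())
    lb = sorted(d[factor_b].unique())
    ns, na, nb = len(subjects), len(la), len(lb)
    if len(d) != ns * na * nb or d.duplicated([subject, factor_a, factor_b]).any():
        raise ValueError("incomplete or unbalanced within-subject design")
    y = np.zeros((ns, na, nb))
    si = {s: i for i, s in enumerate(subjects)}
    ai = {a: i for i, a in enumerate(la)}
    bi = {b: i for i, b in enumerate(lb)}
    for _, row in d.iterrows():
        y[si[row[subject]], ai[row[factor_a]], bi[row[factor_b]]] = row[dv]

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = ns * nb * np.sum((m_a - grand) ** 2)
    ss_b = ns * na * np.sum((m_b - grand) ** 2)
    ss_ab = ns * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = nb * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = na * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
             - grand)
    ss_sab = np.sum(resid ** 2)

    def effect(name, ss, df1, ss_err, df2):
        if ss_err == 0:
            f = 0.0 if ss == 0 else np.inf
        else:
            f = (ss / df1) / (ss_err / df2)
        p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        return AnovaEffect(name, float(f), df1, df2, p)

    effects = [
        effect(factor_a, ss_a, na - 1, ss_sa, (ns - 1) * (na - 1)),
        effect(factor_b, ss_b, nb - 1, ss_sb, (ns - 1) * (nb - 1)),
        effect(f"{factor_a}:{factor_b}", ss_ab, (na - 1) * (nb - 1),
               ss_sab, (ns - 1) * (na - 1) * (nb - 1)),
    ]
    return pd.DataFrame([e.__dict__ for e in effects])


def power_paired_t(effect_size_dz: float, power: float = 0.80,
                   alpha: float = 0.05, tails: int = 1,
                   n_max: int = 10_000_000) -> int:
    """Smallest n giving the target power for a paired (or one-sample) t.

    Uses the noncentral t distribution with noncentrality
    ``dz * sqrt(n)`` at ``df = n - 1``.
    """
    if effect_size_dz <= 0:
        raise ValueError("effect size must be positive (dz = 0 needs infinite n)")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")

    def achieved(n: int) -> float:
        df = n - 1
        ncp = effect_size_dz * math.sqrt(n)
        if tails == 1:
            crit = sps.t.isf(alpha, df)
            return float(sps.nct.sf(crit, df, ncp))
        crit = sps.t.isf(alpha / 2, df)
        return float(sps.nct.sf(crit, df, ncp) + sps.nct.cdf(-crit, df, ncp))

    lo, hi = 2, 2
    while achieved(hi) < power:
        hi *= 2
        if hi > n_max:
            raise ValueError("required n exceeds n_max")
    while lo < hi:
        mid = (lo + hi) // 2
        if achieved(mid) >= power:
            hi = mid
        else:
            lo = mid + 1
    return lo


def significance_stars(p: float) -> str:
    """Figure-convention stars: * p<.05, ** p<.01, *** p<.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def stats_report(rows: Sequence[dict]) -> pd.DataFrame:
    """Assemble a report table and BH-adjust p values within families.

    Each row dict needs at least ``analysis``, ``family``, ``statistic``,
    ``df``, ``p``.
    """
    df = pd.DataFrame(list(rows))
    df["p_adjusted"] = bh_adjust(df["p"].to_numpy(), df["family"])
    df["stars"] = [significance_stars(p) for p in df["p_adjusted"]]
    return df
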