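"""Empirical-Bayes moderated two-group differential abundance.

Per protein, a pooled-variance two-sample model is fitted and the residual
variances are shrunk toward an ensemble prior estimated by the method of
moments on log residual variances (digamma/trigamma matching).  The
moderated statistic is

    t_mod = lfc / (s_tilde * sqrt(1/nA + 1/nB)),
    s_tilde^2 = (d0*s0^2 + df*s^2) / (d0 + df),

with a two-sided p-value from a t distribution on df + d0 degrees of
freedom.  Benjamini-Hochberg step-up adjustment and strict significance
calls (p_adj < alpha and |lfc| > lfc_min) follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ModerationHyperparams",
    "trigamma_inverse",
    "estimate_moderation",
    "moderated_ttest",
    "bh_adjust",
    "call_significant",
    "presence_sets",
]

# finite stand-in for an infinite prior df (no excess variability detected)
D0_CAP = 1e8


@dataclass
class ModerationHyperparams:
    d0: float
    s0_sq: float


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    trigamma is monotone decreasing, so the solution is unique.  Very
    small x (flat trigamma) maps to a large y, capped by the caller.
    """
    if x <= 0:
        raise ValueError("trigamma_inverse requires x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_moderation(s_sq: np.ndarray, df: float) -> ModerationHyperparams:
    """Moment-match (d0, s0^2) from the ensemble of residual variances.

    Uses the log-variance representation: for z = log(s^2),
    E[z] = log(s0^2) + digamma(d0/2) - digamma(df/2) + log(df/d0) and
    Var[z] = trigamma(df/2) + trigamma(d0/2).  When the observed variance
    of z does not exceed trigamma(df/2), the prior df is effectively
    infinite and is capped at a large finite value.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    positive = s_sq[s_sq > 0]
    if positive.size < 2:
        # no ensemble to learn from: no shrinkage
        return ModerationHyperparams(d0=0.0, s0_sq=float(np.median(s_sq)) if s_sq.size else 1.0)
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = D0_CAP
        s0_sq = float(np.exp(e_mean))
    else:
        d0 = 2.0 * trigamma_inverse(excess)
        d0 = min(d0, D0_CAP)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationHyperparams(d0=float(d0), s0_sq=s0_sq)


def moderated_ttest(table_a: pd.DataFrame, table_b: pd.DataFrame,
                    hyper: ModerationHyperparams | None = None) -> pd.DataFrame:
    """Moderated t-test of group A vs group B, one row per protein.

    ``table_a`` and ``table_b`` are imputed log2 matrices (proteins x
    samples) over the same protein index.  lfc = mean(A) - mean(B).  With a
    single protein (no ensemble) d0 is taken as 0 and the statistic reduces
    to the ordinary pooled-variance t.
    """
    if not table_a.index.equals(table_b.index):
        raise ValueError("the two groups must share the same protein index")
    n_a, n_b = table_a.shape[1], table_b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 samples")
    a = table_a.to_numpy(float)
    b = table_b.to_numpy(float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("inputs must be imputed (no missing cells)")

    lfc = a.mean(axis=1) - b.mean(axis=1)
    df = n_a + n_b - 2
    ss = a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)
    s_sq = ss / df

    if hyper is None:
        if len(lfc) < 2:
            hyper = ModerationHyperparams(d0=0.0, s0_sq=float(s_sq[0]) if len(s_sq) else 1.0)
        else:
            hyper = estimate_moderation(s_sq, df)
    d0, s0_sq = hyper.d0, hyper.s0_sq

    if np.all(s_sq == 0):
        warnings.warn("zero residual variance in every protein; "
                      "falling back to unmoderated t")
        d0 = 0.0
    if d0 > 0:
        s_tilde_sq = (d0 * s0_sq + df * s_sq) / (d0 + df)
    else:
        s_tilde_sq = s_sq
    df_total = df + d0

    se = np.sqrt(s_tilde_sq * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, 0.0, 1.0)

    out = pd.DataFrame({
        "lfc": lfc,
        "s_sq": s_sq,
        "s_tilde_sq": s_tilde_sq,
        "t_mod": t_mod,
        "df_total": df_total,
        "p": p,
    }, index=table_a.index)
    out.index.name = "protein"
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min over j >= i of p_(j) * m / j on the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def call_significant(results: pd.DataFrame, alpha: float = 0.05,
                     lfc_min: float = 1.0) -> pd.DataFrame:
    """Append BH-adjusted p-values and the strict significance flag."""
    out = results.copy()
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["p_adj"] < alpha) & (out["lfc"].abs() > lfc_min)
    return out


def presence_sets(retention: pd.DataFrame) -> dict[str, set[str]]:
    """Qualitative cohort comparison from a completeness retention report.

    Partitions the union of retained proteins into ``shared``,
    ``infant_only`` and ``adult_only`` by the per-cohort retention flags.
    """
    infant = retention.index[retention["retained_infant"].astype(bool)]
    adult = retention.index[retention["retained_adult"].astype(bool)]
    infant, adult = set(infant), set(adult)
    return {
        "shared": infant & adult,
        "infant_only": infant - adult,
        "adult_only": adult - infant,
    }
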