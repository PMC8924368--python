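"""Empirical-Bayes moderated differential expression between subtypes.

Per-gene two-sample contrasts (one subtype vs the rest) on log2(TPM+1), with
the residual variances shrunk toward a common prior fitted by the method of
moments on the log-variances (the scaled-F / inverse-chi-square model used by
moderated-t analyses): posterior variance
s2_tilde = (d0 * s0^2 + d * s2) / (d0 + d), moderated t = log2FC / (s_tilde * c),
p from a t distribution with d0 + d degrees of freedom.  Multiple testing is
handled by Benjamini-Hochberg; the retained-gene filter is
adjusted p < 0.05 and |log2FC| >= 1.5.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ADJ_P_THRESHOLD = 0.05
LOG2FC_THRESHOLD = 1.5
D0_CLAMP = (0.1, 500.0)


def passes_filter(padj, log2fc,
                  adj_p_threshold: float = ADJ_P_THRESHOLD,
                  log2fc_threshold: float = LOG2FC_THRESHOLD):
    """Retention rule for DEGs: adjusted p strictly below the threshold and
    |log2FC| at or above the fold-change threshold (inclusive)."""
    return (np.asarray(padj) < adj_p_threshold) & (
        np.abs(np.asarray(log2fc)) >= log2fc_threshold
    )


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from per-gene sample variances.

    Moments of log s2 under the scaled-F model give d0 via the inverse
    trigamma; d0 is clamped to a stable range.  Genes with zero variance are
    ignored for the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if len(s2) < 2:
        return D0_CLAMP[1], float(np.median(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e = z - special.polygamma(0, df / 2) + np.log(df / 2)
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2)
    if evar > 0:
        d0 = float(np.clip(2.0 * _trigamma_inverse(evar), *D0_CLAMP))
        s0_2 = float(np.exp(np.mean(e) + special.polygamma(0, d0 / 2) - np.log(d0 / 2)))
    else:
        # (near-)equal variances: no dispersion to fit, shrink fully toward
        # the plain average variance
        d0 = D0_CLAMP[1]
        s0_2 = float(np.mean(s2))
    return d0, s0_2


def moderated_t(
    expr_log: pd.DataFrame,
    groups: pd.Series,
    group,
    adj_p_threshold: float = ADJ_P_THRESHOLD,
    log2fc_threshold: float = LOG2FC_THRESHOLD,
) -> pd.DataFrame:
    """One-vs-rest moderated-t table for ``group`` against all other samples.

    ``expr_log`` is genes x samples on log2(TPM+1); ``groups`` is a
    per-sample label series.  Returns a per-gene DataFrame with columns
    ``log2FC``, ``ave_expr``, ``t``, ``pvalue``, ``padj``, ``passes_filter``.
    """
    groups = pd.Series(groups).reindex(expr_log.columns)
    in_mask = (groups == group).to_numpy()
    n1, n0 = int(in_mask.sum()), int((~in_mask).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError(f"contrast {group!r} needs >= 2 samples on each side (got {n1} vs {n0})")
    X = expr_log.to_numpy(dtype=float)
    x1, x0 = X[:, in_mask], X[:, ~in_mask]
    fc = x1.mean(axis=1) - x0.mean(axis=1)
    df = n1 + n0 - 2
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x0 - x0.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df
    c = np.sqrt(1.0 / n1 + 1.0 / n0)

    d0, s0_2 = fit_variance_prior(s2, df)
    s2_tilde = (d0 * s0_2 + df * s2) / (d0 + df)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / (np.sqrt(s2_tilde) * c)
    zero_var = s2 == 0
    if zero_var.any():
        logger.warning("%d zero-variance gene(s): t set to 0, p to 1", int(zero_var.sum()))
        t[zero_var] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), d0 + df)
    p[zero_var] = 1.0
    padj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "log2FC": fc,
            "ave_expr": X.mean(axis=1),
            "t": t,
            "pvalue": p,
            "padj": padj,
            "passes_filter": passes_filter(padj, fc, adj_p_threshold, log2fc_threshold),
        },
        index=expr_log.index,
    )
    out.attrs["d0"] = d0
    out.attrs["s0_2"] = s0_2
    out.attrs["contrast"] = f"{group}_vs_rest"
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving on input order."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def moderated_t_all(
    expr_log: pd.DataFrame,
    groups: pd.Series,
    adj_p_threshold: float = ADJ_P_THRESHOLD,
    log2fc_threshold: float = LOG2FC_THRESHOLD,
) -> dict:
    """One-vs-rest tables for every group label, keyed by the label."""
    return {
        g: moderated_t(expr_log, groups, g, adj_p_threshold, log2fc_threshold)
        for g in sorted(pd.Series(groups).unique())
    }


def select_degs(tables: dict) -> pd.DataFrame:
    """Union of filter-passing genes over contrasts.

    Each retained gene is annotated with the contrast of largest |log2FC|
    among the contrasts where it passes, plus that contrast's statistics.
    """
    if not tables:
        raise ValueError("need at least one contrast table")
    rows = {}
    for contrast, tab in tables.items():
        hits = tab[tab["passes_filter"]]
        for gene, rec in hits.iterrows():
            if gene not in rows or abs(rec["log2FC"]) > abs(rows[gene]["log2FC"]):
                entry = rec[["log2FC", "t", "pvalue", "padj"]].copy()
                entry["contrast"] = contrast
                rows[gene] = entry
    if not rows:
        return pd.DataFrame(columns=["log2FC", "t", "pvalue", "padj", "contrast"])
    out = pd.DataFrame(rows).T
    out.index.name = "gene"
    # stable, input-order-independent ordering
    return out.sort_index()
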