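"""Cross-cutting statistics: rank tests, chi-square, Spearman, ROC/AUC, and
the drug-sensitivity screen.

Thin, contract-enforcing wrappers over scipy/sklearn (mid-rank tie handling
throughout) plus the two-stage drug screen: a compound is a hit when its
drug-response AUC is sufficiently negatively rank-correlated with the TIC
score and the low-score decile shows significantly higher AUC than the
high-score decile, i.e. the compound preferentially benefits low-score
patients.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

logger = logging.getLogger(__name__)

SOURCE_THRESHOLDS = {"ctrp": -0.20, "prism": -0.20, "gdsc": -0.40}


def kruskal_wallis(values, group_labels) -> tuple[float, int, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square with k-1 df."""
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    labels = np.unique(group_labels)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[group_labels == lab] for lab in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    df = len(labels) - 1
    if np.all(values == values[0]):
        logger.warning("all values identical: H = 0, p = 1")
        return 0.0, df, 1.0
    H, p = stats.kruskal(*samples)
    return float(H), df, float(p)


def wilcoxon_ranksum(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Rank-sum (Mann-Whitney) test.

    Returns (W, p) where W is the rank-sum of ``a``.  Exact enumeration for
    small samples without ties, normal approximation with continuity and tie
    correction otherwise.  A statistic exactly at its null mean gives p = 1
    (two-sided symmetry).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    W = float(ranks[:n1].sum())
    U = W - n1 * (n1 + 1) / 2.0
    ties = len(np.unique(np.concatenate([a, b]))) < n1 + n2
    method = "exact" if (max(n1, n2) <= 25 and not ties) else "asymptotic"
    if alternative == "two-sided" and U == n1 * n2 / 2.0:
        return W, 1.0
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                             use_continuity=True)
    return W, float(res.pvalue)


def chisq_independence(counts) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction on a 2 x k table."""
    table = np.asarray(counts, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks); p via the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must be paired")
    if len(x) < 5:
        raise ValueError("need n >= 5")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def roc_auc(scores, binary_labels) -> tuple[float, pd.DataFrame]:
    """AUC via the rank / Mann-Whitney identity, plus the (FPR, TPR) curve.

    Ties between a positive and a negative score receive half credit, which
    matches the trapezoidal area under the tie-grouped ROC curve exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(binary_labels).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    fpr, tpr, thr = roc_curve(labels, scores)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return float(auc), curve


def drug_screen(
    tic_scores: pd.Series,
    auc_matrix: pd.DataFrame,
    source_threshold: float = -0.20,
    decile_frac: float = 0.1,
) -> pd.DataFrame:
    """Two-stage screen for compounds benefiting the low-score group.

    Stage 1 retains compounds whose AUC-vs-score Spearman rho is strictly
    below ``source_threshold``.  Stage 2 compares AUC between the lowest- and
    highest-score deciles (two-sided rank-sum with a direction check: the
    low-score decile must have the higher median AUC).  ``passes`` requires
    all three conditions.
    """
    if not (0 < decile_frac <= 0.5):
        raise ValueError("decile_frac must be in (0, 0.5]")
    tic_scores = pd.Series(tic_scores)
    auc_matrix = auc_matrix.loc[tic_scores.index]
    n = len(tic_scores)
    if n < 20:
        raise ValueError("need >= 20 samples for the decile comparison")
    n_dec = int(np.floor(n * decile_frac))
    if n_dec < 2:
        raise ValueError("fewer than 2 samples per decile")
    order = tic_scores.sort_values(kind="stable").index
    low_idx, high_idx = order[:n_dec], order[-n_dec:]
    rows = []
    for compound in auc_matrix.columns:
        vals = auc_matrix[compound]
        rho, rho_p = spearman(tic_scores.to_numpy(), vals.to_numpy())
        low, high = vals.loc[low_idx].to_numpy(), vals.loc[high_idx].to_numpy()
        _, w_p = wilcoxon_ranksum(low, high)
        direction = np.median(low) > np.median(high)
        passes = (rho < source_threshold) and direction and (w_p < 0.05)
        rows.append(
            {"compound": compound, "rho": rho, "rho_p": rho_p,
             "wilcoxon_p": w_p, "low_decile_higher": direction, "passes": passes}
        )
    return pd.DataFrame(rows).set_index("compound")
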