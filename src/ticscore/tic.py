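"""The TIC score: feature split, Boruta reduction, PC1 scoring, projection,
and the maximally selected survival cutpoint.

The score is built from subtype-associated differentially expressed genes:

1. Samples are clustered on the DEG expression matrix (gene clusters); the
   categorical cluster labels are mapped to an ordered integer code,
   clusters ordered by their mean per-sample z-score over the DEG genes so
   the ordering is deterministic and free of principal-component sign
   ambiguity.
2. DEGs positively Spearman-correlated with the code form feature alpha,
   negatively correlated genes form feature beta.
3. Boruta (shadow-feature random-forest selection) prunes each feature set
   to the genes genuinely informative about the gene-cluster label.
4. Each feature set is standardized and reduced to its first principal
   component; per-sample TIC score = PC1(alpha) - PC1(beta).  Each PC1 is
   sign-oriented to correlate positively with its gene set's mean z-score.

The fitted model (loadings, training moments, orientations) can be projected
onto an external cohort (re-standardizing within the new cohort, dropping
missing genes with loading renormalization), and a survival cutpoint is
chosen by maximizing the two-group log-rank statistic over candidate
thresholds between the 10th and 90th score percentiles (a maximally selected
statistic: the reported p-value is not adjusted for the scan, which is
anti-conservative and logged).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .survival import logrank_test

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# feature split


@dataclass
class FeatureSplit:
    """DEGs split by the sign of their correlation with the gene-cluster code."""

    alpha_genes: list[str]
    beta_genes: list[str]
    correlations: pd.Series  # per-gene Spearman rho with the ordered code
    cluster_code: pd.Series  # per-sample ordered integer code

    def __post_init__(self) -> None:
        if set(self.alpha_genes) & set(self.beta_genes):
            raise ValueError("alpha and beta gene sets must be disjoint")


def _ordered_cluster_code(deg_expr: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Map categorical gene-cluster labels to an ordered integer code.

    Clusters are ordered by their mean per-sample z-score over the DEG genes
    (ascending): a cluster whose samples sit higher across the DEG programs
    as a whole gets a larger code.  Unlike ordering on a principal component,
    this statistic has no sign ambiguity and orders every cluster, not just
    the ones separated by the dominant variance axis, so the alpha/beta
    assignment is reproducible across runs.
    """
    X = deg_expr.to_numpy(dtype=float).T  # samples x genes
    sd = X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    mean_z = pd.Series(Z.mean(axis=1), index=deg_expr.columns)
    cluster_means = mean_z.groupby(pd.Series(labels).reindex(deg_expr.columns)).mean()
    order = cluster_means.sort_values(kind="stable").index
    code_of = {lab: i + 1 for i, lab in enumerate(order)}
    return pd.Series(labels).reindex(deg_expr.columns).map(code_of).rename("cluster_code")


def split_features(
    deg_expr: pd.DataFrame,
    gene_cluster_labels: pd.Series,
    sig_level: float = 0.05,
) -> FeatureSplit:
    """Assign each DEG to feature alpha (rho > 0) or beta (rho < 0).

    ``deg_expr`` is genes x samples (log scale) restricted to the DEGs;
    ``gene_cluster_labels`` is the per-sample cluster assignment from the
    DEG-based consensus clustering.  A gene is assigned only if its
    correlation with the ordered code is significant at ``sig_level`` AND its
    per-cluster mean profile is monotone along the code in the direction of
    the correlation: a gene peaking in an interior cluster has no direction
    along the gradient (its nonzero correlation is an artifact of unequal
    cluster sizes or within-sample normalization) and would corrupt the
    principal component of whichever set absorbed it.  Constant and
    unassignable genes are excluded with a warning.
    """
    labels = pd.Series(gene_cluster_labels).reindex(deg_expr.columns)
    if labels.isna().any():
        raise ValueError("cluster labels must cover all samples")
    if labels.nunique() < 2:
        raise ValueError("need >= 2 gene clusters")
    code = _ordered_cluster_code(deg_expr, labels)
    code_arr = code.to_numpy()
    code_levels = np.unique(code_arr)
    alpha, beta, rhos = [], [], {}
    dropped = 0
    for gene in deg_expr.index:
        x = deg_expr.loc[gene].to_numpy(dtype=float)
        if np.all(x == x[0]):
            dropped += 1
            continue
        rho, p = stats.spearmanr(x, code_arr)
        if np.isnan(rho) or rho == 0 or p >= sig_level:
            dropped += 1
            continue
        profile = np.array([x[code_arr == c].mean() for c in code_levels])
        diffs = np.diff(profile) * np.sign(rho)
        span = profile.max() - profile.min()
        # tolerate small counter-direction wiggles (noise, normalization
        # coupling) up to a quarter of the profile's range
        if span > 0 and -min(diffs.min(), 0.0) > 0.25 * span:
            dropped += 1
            continue
        rhos[gene] = rho
        (alpha if rho > 0 else beta).append(gene)
    if dropped:
        logger.warning(
            "%d gene(s) excluded from the split (constant, non-significant, "
            "or non-monotone across the cluster gradient)", dropped,
        )
    return FeatureSplit(
        alpha_genes=alpha, beta_genes=beta,
        correlations=pd.Series(rhos, name="rho"), cluster_code=code,
    )


# ---------------------------------------------------------------------------
# Boruta


@dataclass
class BorutaResult:
    """Per-feature Boruta decision and the importance history."""

    status: pd.Series  # 'confirmed' | 'rejected' | 'tentative'
    importance_history: pd.DataFrame  # iterations x features (real features)
    shadow_max_history: np.ndarray  # per-iteration max shadow importance
    n_iterations: int

    @property
    def confirmed(self) -> list[str]:
        return list(self.status.index[self.status == "confirmed"])


def boruta_select(
    X: pd.DataFrame,
    y,
    max_iter: int = 100,
    alpha_level: float = 0.01,
    seed: int = 0,
    n_estimators: int = 80,
    max_depth: int = 5,
) -> BorutaResult:
    """All-relevant feature selection with shadow features.

    Each iteration appends one shuffled shadow copy per real feature, fits a
    random forest on [real | shadow], and scores a "hit" for every real
    feature whose importance exceeds the best shadow importance.  After each
    iteration, two-sided binomial tests of the hit counts (p = 0.5,
    Bonferroni-corrected over all features at
    ``alpha_level``) confirm clearly-above-chance features and reject
    clearly-below-chance ones; whatever is undecided at ``max_iter`` stays
    tentative.
    """
    if max_iter < 10:
        raise ValueError("max_iter must be >= 10")
    X = pd.DataFrame(X)
    if X.shape[0] < 5:
        raise ValueError("need >= 5 samples")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes in y")
    rng = np.random.default_rng(seed)
    features = list(X.columns)
    n_feat = len(features)
    Xv = X.to_numpy(dtype=float)

    hits = np.zeros(n_feat, dtype=int)
    trials = 0
    status = pd.Series("tentative", index=features, name="status")
    history = []
    shadow_hist = []
    for it in range(max_iter):
        shadow = Xv.copy()
        for j in range(n_feat):
            rng.shuffle(shadow[:, j])
        Xfull = np.hstack([Xv, shadow])
        forest = RandomForestClassifier(
            n_estimators=n_estimators, max_depth=max_depth,
            random_state=int(rng.integers(2**31)), n_jobs=1,
        )
        forest.fit(Xfull, y)
        imp = forest.feature_importances_
        real_imp, shadow_imp = imp[:n_feat], imp[n_feat:]
        shadow_max = shadow_imp.max()
        history.append(real_imp)
        shadow_hist.append(shadow_max)
        undecided = status == "tentative"
        hits[undecided.to_numpy()] += (real_imp[undecided.to_numpy()] > shadow_max).astype(int)
        trials += 1
        if not undecided.any():
            break
        threshold = alpha_level / n_feat  # Bonferroni over all features
        for j in np.flatnonzero(undecided.to_numpy()):
            p = stats.binomtest(int(hits[j]), trials, 0.5, alternative="two-sided").pvalue
            if p < threshold:
                status.iloc[j] = "confirmed" if hits[j] > trials / 2 else "rejected"
        if (status != "tentative").all():
            break
    return BorutaResult(
        status=status,
        importance_history=pd.DataFrame(history, columns=features),
        shadow_max_history=np.asarray(shadow_hist),
        n_iterations=len(history),
    )


# ---------------------------------------------------------------------------
# TIC model


@dataclass
class TICModel:
    """Fitted PC1 loadings and standardization moments for both feature sets."""

    alpha_loadings: pd.Series  # unit-norm PC1 weights over alpha genes
    beta_loadings: pd.Series
    train_means: pd.Series  # per-gene training means (both sets)
    train_sds: pd.Series
    train_scores: pd.Series  # per-sample TIC score on the training cohort
    cutpoint: float | None = field(default=None)

    def to_json(self, path) -> None:
        doc = {
            "alpha_loadings": self.alpha_loadings.to_dict(),
            "beta_loadings": self.beta_loadings.to_dict(),
            "train_means": self.train_means.to_dict(),
            "train_sds": self.train_sds.to_dict(),
            "train_scores": self.train_scores.to_dict(),
            "cutpoint": self.cutpoint,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TICModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            alpha_loadings=pd.Series(doc["alpha_loadings"], dtype=float),
            beta_loadings=pd.Series(doc["beta_loadings"], dtype=float),
            train_means=pd.Series(doc["train_means"], dtype=float),
            train_sds=pd.Series(doc["train_sds"], dtype=float),
            train_scores=pd.Series(doc["train_scores"], dtype=float),
            cutpoint=doc.get("cutpoint"),
        )

    @property
    def genes(self) -> pd.Index:
        return self.alpha_loadings.index.union(self.beta_loadings.index)


def _pc1(expr_log: pd.DataFrame, genes: list[str], set_name: str):
    """Oriented PC1 of a standardized gene set.

    Returns (per-sample scores, unit-norm loadings, means, sds).  The sign is
    flipped if the PC correlates negatively with the mean z-score of the set,
    so "more of the program" always means a higher feature score.
    """
    if not genes:
        raise ValueError(f"feature set {set_name!r} is empty after filtering")
    sub = expr_log.loc[genes].to_numpy(dtype=float).T  # samples x genes
    means = sub.mean(axis=0)
    sds = sub.std(axis=0)
    if (sds == 0).any():
        bad = [g for g, s in zip(genes, sds) if s == 0]
        raise ValueError(f"constant gene(s) in feature set {set_name!r}: {bad}")
    Z = (sub - means) / sds
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt[0]
    scores = Z @ loadings
    mean_z = Z.mean(axis=1)
    if len(genes) == 1:
        orient = -1.0 if loadings[0] < 0 else 1.0
    else:
        orient = -1.0 if np.corrcoef(scores, mean_z)[0, 1] < 0 else 1.0
    scores = scores * orient
    loadings = loadings * orient
    return (
        pd.Series(scores, index=expr_log.columns),
        pd.Series(loadings, index=genes),
        pd.Series(means, index=genes),
        pd.Series(sds, index=genes),
    )


def fit_tic(
    expr_log: pd.DataFrame,
    split: FeatureSplit,
    boruta_alpha: BorutaResult | None = None,
    boruta_beta: BorutaResult | None = None,
) -> TICModel:
    """Fit the score model: TIC(sample) = PC1_alpha(sample) - PC1_beta(sample).

    Optional Boruta results restrict each feature set to its confirmed genes;
    either set ending up empty is an error naming the set.
    """
    alpha = split.alpha_genes
    beta = split.beta_genes
    if boruta_alpha is not None:
        alpha = [g for g in alpha if g in boruta_alpha.confirmed]
    if boruta_beta is not None:
        beta = [g for g in beta if g in boruta_beta.confirmed]
    a_scores, a_load, a_mean, a_sd = _pc1(expr_log, alpha, "alpha")
    b_scores, b_load, b_mean, b_sd = _pc1(expr_log, beta, "beta")
    tic = (a_scores - b_scores).rename("tic_score")
    return TICModel(
        alpha_loadings=a_load,
        beta_loadings=b_load,
        train_means=pd.concat([a_mean, b_mean]),
        train_sds=pd.concat([a_sd, b_sd]),
        train_scores=tic,
    )


def project_tic(
    model: TICModel,
    new_expr_log: pd.DataFrame,
    min_overlap: float = 0.8,
) -> pd.Series:
    """Score an external cohort with a fitted model.

    Shared genes are re-standardized within the new cohort (cross-platform
    location/scale shifts make training moments non-transferable); missing
    genes are dropped from the loadings, which are renormalized to unit norm.
    Raises if the overlap falls below ``min_overlap``.
    """
    scores = {}
    for name, loadings in (("alpha", model.alpha_loadings), ("beta", model.beta_loadings)):
        shared = loadings.index.intersection(new_expr_log.index)
        overlap = len(shared) / len(loadings)
        if overlap < min_overlap:
            raise ValueError(
                f"feature {name}: only {overlap:.0%} of model genes present "
                f"(need >= {min_overlap:.0%})"
            )
        w = loadings.loc[shared]
        w = w / np.linalg.norm(w)
        sub = new_expr_log.loc[shared].to_numpy(dtype=float).T
        sd = sub.std(axis=0)
        if (sd == 0).any():
            sd = np.where(sd == 0, 1.0, sd)
        Z = (sub - sub.mean(axis=0)) / sd
        scores[name] = Z @ w.to_numpy()
    return pd.Series(scores["alpha"] - scores["beta"], index=new_expr_log.columns,
                     name="tic_score")


# ---------------------------------------------------------------------------
# optimal cutpoint


@dataclass
class CutpointResult:
    cutoff: float
    chi2: float
    pvalue: float


def optimal_cutpoint(scores: pd.Series, survival: pd.DataFrame) -> CutpointResult:
    """Maximally selected log-rank cutpoint on the score.

    Candidate cutoffs are the observed score values between the 10th and 90th
    percentiles; for each, samples are split at score > cutoff and the
    two-group log-rank statistic computed; the maximizing cutoff is returned
    with its unadjusted chi-square and p-value (the selection makes the naive
    p anti-conservative; a caveat is logged).
    """
    scores = pd.Series(scores)
    if len(scores) < 10:
        raise ValueError("need >= 10 samples")
    if scores.nunique() == 1:
        raise ValueError("all scores identical")
    survival = survival.loc[scores.index]
    time = survival["OS_time_days"].to_numpy(dtype=float)
    event = survival["OS_event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("no events")
    lo, hi = np.quantile(scores, [0.10, 0.90])
    candidates = np.unique(scores[(scores >= lo) & (scores <= hi)])
    if len(candidates) == 0:
        candidates = np.array([float(np.median(scores))])
    best = None
    for cut in candidates:
        grp = (scores.to_numpy() > cut).astype(int)
        if grp.sum() == 0 or grp.sum() == len(grp):
            continue
        try:
            res = logrank_test(time, event, grp)
        except ValueError:
            continue
        if best is None or res.chi2 > best[1]:
            best = (float(cut), res.chi2, res.pvalue)
    if best is None:
        raise ValueError("no admissible cutpoint")
    logger.info(
        "optimal cutpoint selected by maximizing the log-rank statistic; the "
        "reported p-value is not adjusted for the scan and is anti-conservative"
    )
    return CutpointResult(cutoff=best[0], chi2=best[1], pvalue=best[2])
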