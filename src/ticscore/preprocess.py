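"""Expression-matrix container, unit conversion to TPM, and multi-batch adjustment.

Bulk cohorts arrive on heterogeneous scales (raw counts, FPKM) from different
platforms.  Before pooling them, everything is converted to TPM (so each
sample's values sum to one million and are comparable across samples) and the
pooled log-scale matrix is adjusted for batch with a parametric empirical-Bayes
location/scale model (the ComBat model): per-gene standardization, per-batch
location (normal prior) and scale (inverse-gamma prior) effects shrunk toward
batch-level priors fitted by the method of moments, then back-transformation.

Convention used throughout the package: deconvolution consumes linear TPM;
every other downstream stage consumes log2(TPM + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LINEAR_SCALES = ("counts", "FPKM", "TPM")
VALID_SCALES = LINEAR_SCALES + ("log2TPM",)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a scale tag and optional batch labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
    scale
        One of ``counts``, ``FPKM``, ``TPM``, ``log2TPM``.
    batch
        Optional per-sample batch labels (index must equal the sample ids).
    """

    values: pd.DataFrame
    scale: str
    batch: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"unknown scale tag {self.scale!r}; expected one of {VALID_SCALES}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.values.isna().any().any():
            raise ValueError("missing entries in expression matrix")
        if self.scale in LINEAR_SCALES and (self.values.to_numpy() < 0).any():
            raise ValueError(f"negative values not allowed on linear scale {self.scale!r}")
        if self.batch is not None:
            self.batch = pd.Series(self.batch)
            if not self.batch.index.equals(self.values.columns):
                self.batch = self.batch.reindex(self.values.columns)
                if self.batch.isna().any():
                    raise ValueError("batch labels missing for some samples")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path) -> None:
        self.values.rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, scale: str, batch: pd.Series | None = None) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=values, scale=scale, batch=batch)


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample so values sum to 1e6: TPM = FPKM / sum(FPKM) * 1e6.

    TPM is a within-sample renormalization of FPKM, so only the column sums
    change.  Raises if a sample column sums to zero (undefined rescaling).
    """
    if m.scale != "FPKM":
        raise ValueError(f"fpkm_to_tpm expects scale 'FPKM', got {m.scale!r}")
    colsum = m.values.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero expression: {list(zero.index)}")
    values = m.values.div(colsum, axis=1) * 1e6
    return ExpressionMatrix(values=values, scale="TPM", batch=m.batch)


def counts_to_tpm(m: ExpressionMatrix, gene_lengths_kb: pd.Series) -> ExpressionMatrix:
    """Length-normalize counts to per-kb rates, then rescale each sample to 1e6."""
    if m.scale != "counts":
        raise ValueError(f"counts_to_tpm expects scale 'counts', got {m.scale!r}")
    gene_lengths_kb = pd.Series(gene_lengths_kb)
    missing = m.gene_ids.difference(gene_lengths_kb.index)
    if len(missing):
        raise ValueError(f"missing gene lengths for: {list(missing)}")
    lengths = gene_lengths_kb.reindex(m.gene_ids)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = m.values.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero.index)}")
    values = rate.div(colsum, axis=1) * 1e6
    return ExpressionMatrix(values=values, scale="TPM", batch=m.batch)


def log2_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) transform, the scale consumed by clustering / DE / scoring."""
    if m.scale != "TPM":
        raise ValueError(f"log2_tpm expects scale 'TPM', got {m.scale!r}")
    return ExpressionMatrix(values=np.log2(m.values + 1.0), scale="log2TPM", batch=m.batch)


def _combat_priors(gamma_hat: np.ndarray, delta_hat: np.ndarray):
    """Method-of-moments hyperparameters for one batch.

    Normal prior on the location effects (mean/variance over genes) and
    inverse-gamma on the scale effects (shape/rate from the mean and variance
    of the per-gene batch variances).
    """
    gamma_bar = gamma_hat.mean()
    tau2_bar = gamma_hat.var(ddof=1)
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    a_prior = (2 * s2 + m**2) / s2 if s2 > 0 else np.inf
    b_prior = (m * s2 + m**3) / s2 if s2 > 0 else np.inf
    return gamma_bar, tau2_bar, a_prior, b_prior


def _combat_solve(z: np.ndarray, gamma_hat, delta_hat, gamma_bar, tau2_bar, a_prior, b_prior,
                  conv: float = 1e-4, max_iter: int = 200):
    """Iterative conditional posterior-mode solution for one batch's EB estimates."""
    n_b = z.shape[1]
    if not np.isfinite(a_prior) or not np.isfinite(b_prior) or tau2_bar == 0:
        # degenerate prior: no shrinkage possible, keep the raw estimates
        return gamma_hat, delta_hat
    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for _ in range(max_iter):
        g_new = (n_b * tau2_bar * gamma_hat + delta_star * gamma_bar) / (n_b * tau2_bar + delta_star)
        sse = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (b_prior + 0.5 * sse) / (n_b / 2 + a_prior - 1)
        change = max(np.abs(g_new - gamma_star).max(), np.abs(d_new - delta_star).max())
        gamma_star, delta_star = g_new, d_new
        if change < conv:
            break
    return gamma_star, delta_star


def combat_adjust(m: ExpressionMatrix) -> ExpressionMatrix:
    """Parametric empirical-Bayes batch adjustment of a log-scale matrix.

    Requires ``scale == 'log2TPM'``, batch labels, and >= 2 batches each with
    >= 2 samples.  Genes constant across all samples are passed through
    unchanged (logged).
    """
    if m.scale != "log2TPM":
        raise ValueError(f"combat_adjust expects scale 'log2TPM', got {m.scale!r}")
    if m.batch is None:
        raise ValueError("batch labels required for combat_adjust")
    batches = m.batch.unique()
    if len(batches) < 2:
        raise ValueError("combat_adjust requires >= 2 batches (adjustment undefined for one batch)")
    counts = m.batch.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"batch(es) with < 2 samples: {list(small.index)}")

    Y = m.values.to_numpy(dtype=float)
    n_genes, n = Y.shape
    batch_idx = [np.flatnonzero((m.batch == b).to_numpy()) for b in batches]
    n_b = np.array([len(ix) for ix in batch_idx])

    const = Y.std(axis=1) == 0
    if const.any():
        logger.warning("%d constant gene(s) passed through unchanged by combat_adjust", const.sum())

    work = np.flatnonzero(~const)
    out = Y.copy()
    Yw = Y[work]

    # grand mean = sample-size-weighted batch means; pooled variance of residuals
    batch_means = np.stack([Yw[:, ix].mean(axis=1) for ix in batch_idx], axis=1)
    alpha = batch_means @ (n_b / n)
    resid = Yw.copy()
    for b, ix in enumerate(batch_idx):
        resid[:, ix] -= batch_means[:, [b]]
    sigma2 = (resid**2).sum(axis=1) / n
    sigma = np.sqrt(np.maximum(sigma2, 1e-12))

    Z = (Yw - alpha[:, None]) / sigma[:, None]
    Zadj = np.empty_like(Z)
    for b, ix in enumerate(batch_idx):
        zb = Z[:, ix]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        delta_hat = np.maximum(delta_hat, 1e-12)
        gbar, t2bar, ap, bp = _combat_priors(gamma_hat, delta_hat)
        gamma_star, delta_star = _combat_solve(zb, gamma_hat, delta_hat, gbar, t2bar, ap, bp)
        Zadj[:, ix] = (zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out[work] = Zadj * sigma[:, None] + alpha[:, None]
    values = pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids)
    return ExpressionMatrix(values=values, scale="log2TPM", batch=m.batch)
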