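"""Synthetic multi-batch cohorts with planted immune structure.

The generator emulates the statistical shape of a pooled bulk-expression
study of an immunologically heterogeneous tumor: several platforms (batches),
a reference signature of 22 immune cell types, infiltration subtypes planted
as distinct Dirichlet mixing profiles, subtype-linked differential-expression
programs, survival tied to a latent prognostic axis, two mutation genes with
subtype-dependent frequency, a binary immunotherapy-response label, and
per-compound drug-sensitivity AUC values linked to the same axis.

Ground truth (cell fractions, subtype labels, the latent axis) is retained on
the :class:`Cohort` so every downstream stage can be tested as a
parameter-recovery problem.

The latent prognostic axis is the per-sample standardized subtype code, with
subtypes ordered by their mean expression over the planted program genes
(program block sizes are strictly increasing by default, so the ordering is
strict).  The highest code is the good-prognosis subtype: it carries the
largest up-regulated program, its log-hazard is lowest under the default
negative ``hazard_coefficient``, and its response probability is highest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_N_CELL_TYPES = 22


@dataclass
class SignatureMatrix:
    """Reference expression profiles: genes x cell types, linear scale."""

    values: pd.DataFrame  # genes x cell types

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if (v < 0).any():
            raise ValueError("signature has negative entries")
        if (v.sum(axis=0) == 0).any():
            raise ValueError("signature has an all-zero cell-type column")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in signature")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_type_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_cell_types(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path) -> None:
        self.values.rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        return cls(values=pd.read_csv(path, sep="\t", index_col=0))


def make_signature(
    n_genes: int = 264,
    n_cell_types: int = DEFAULT_N_CELL_TYPES,
    marker_fold: float = 8.0,
    seed: int = 0,
) -> SignatureMatrix:
    """Block-marker reference signature.

    Each cell type gets a disjoint block of ``n_genes // n_cell_types`` marker
    genes up-regulated ``marker_fold``-fold over a shared log-normal baseline.
    Deterministic given ``seed``.
    """
    if n_genes <= 0 or n_cell_types <= 0:
        raise ValueError("n_genes and n_cell_types must be positive")
    if n_genes < n_cell_types:
        raise ValueError("need n_genes >= n_cell_types")
    if marker_fold < 1:
        raise ValueError("marker_fold must be >= 1")
    if marker_fold == 1:
        logger.warning("marker_fold=1: all signature columns identical (no contrast)")
    rng = np.random.default_rng(seed)
    baseline = rng.lognormal(mean=np.log(10.0), sigma=0.4, size=n_genes)
    block = n_genes // n_cell_types
    values = np.tile(baseline[:, None], (1, n_cell_types))
    for c in range(n_cell_types):
        lo = c * block
        hi = lo + block
        values[lo:hi, c] *= marker_fold
    genes = [f"SIG{i:04d}" for i in range(n_genes)]
    types = [f"CellType{c + 1:02d}" for c in range(n_cell_types)]
    return SignatureMatrix(values=pd.DataFrame(values, index=genes, columns=types))


def _default_alphas(n_subtypes: int, n_cell_types: int) -> np.ndarray:
    """One Dirichlet concentration vector per subtype.

    Each subtype up-weights a disjoint block of cell types, so subtypes have
    clearly distinct mean infiltration profiles.
    """
    alphas = np.full((n_subtypes, n_cell_types), 0.6)
    block = n_cell_types // n_subtypes
    for s in range(n_subtypes):
        lo = s * block
        hi = n_cell_types if s == n_subtypes - 1 else lo + block
        alphas[s, lo:hi] = 4.0
    return alphas


def _default_mutation_spec(n_subtypes: int) -> dict[str, list[float]]:
    """Per-gene mutation probability per subtype (index 0 = poor prognosis).

    BAP1-like: enriched in the poor-prognosis subtype; EIF1AX-like: enriched
    in the good-prognosis subtype; two background genes mutated at
    subtype-independent rates.
    """
    def interp(poor: float, good: float) -> list[float]:
        return list(np.linspace(poor, good, n_subtypes))

    return {
        "BAP1like": interp(0.55, 0.12),
        "EIF1AXlike": interp(0.08, 0.45),
        "GNAQlike": [0.50] * n_subtypes,
        "SF3B1like": [0.25] * n_subtypes,
    }


@dataclass
class CohortConfig:
    """Study-condition parameters for :func:`simulate_cohort`.

    Defaults emulate a 171-sample, 3-platform pooled design with three
    infiltration subtypes.
    """

    n_samples_per_batch: tuple[int, ...] = (80, 28, 63)
    n_subtypes: int = 3
    n_cell_types: int = DEFAULT_N_CELL_TYPES
    dirichlet_alphas: np.ndarray | None = None  # (n_subtypes, n_cell_types)
    n_genes: int = 500
    n_program_genes: tuple[int, ...] = (20, 35, 60)
    program_log2_shift: float = 3.0
    noise_sd: float = 0.2  # log-scale (natural log) multiplicative noise sd
    batch_shift_sd: float = 0.3
    batch_scale_sd: float = 0.1
    hazard_coefficient: float = -1.0  # log-hazard = coefficient * latent axis
    baseline_hazard: float = 1.0 / 1500.0  # events per day at axis = 0
    censor_rate: float = 0.43 / 1500.0  # independent exponential censoring (~30%)
    mutation_spec: dict[str, list[float]] | None = None
    response_intercept: float = -1.2
    response_logit_slope: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_samples_per_batch):
            raise ValueError("n_samples_per_batch entries must be positive")
        if self.n_subtypes < 2:
            raise ValueError("n_subtypes must be >= 2")
        if len(self.n_program_genes) != self.n_subtypes:
            raise ValueError("n_program_genes must have one entry per subtype")
        if self.noise_sd < 0 or self.batch_shift_sd < 0 or self.batch_scale_sd < 0:
            raise ValueError("noise/batch sds must be nonnegative")
        if self.dirichlet_alphas is None:
            self.dirichlet_alphas = _default_alphas(self.n_subtypes, self.n_cell_types)
        self.dirichlet_alphas = np.asarray(self.dirichlet_alphas, dtype=float)
        if self.dirichlet_alphas.shape != (self.n_subtypes, self.n_cell_types):
            raise ValueError(
                f"dirichlet_alphas must have shape ({self.n_subtypes}, {self.n_cell_types})"
            )
        if (self.dirichlet_alphas <= 0).any():
            raise ValueError("dirichlet_alphas must be positive")
        if self.mutation_spec is None:
            self.mutation_spec = _default_mutation_spec(self.n_subtypes)
        for gene, probs in self.mutation_spec.items():
            if len(probs) != self.n_subtypes:
                raise ValueError(f"mutation_spec[{gene!r}] needs one probability per subtype")

    @property
    def n_batches(self) -> int:
        return len(self.n_samples_per_batch)

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_samples_per_batch))


@dataclass
class Cohort:
    """A simulated cohort with full ground truth attached."""

    expression: ExpressionMatrix  # linear scale, tagged FPKM (arbitrary linear units)
    fractions_truth: pd.DataFrame  # samples x cell types, rows sum to 1
    subtype_truth: pd.Series  # per-sample planted subtype code (0 .. K-1)
    latent_axis: pd.Series  # standardized ordered subtype code
    survival: pd.DataFrame  # columns: OS_time_days, OS_event
    mutations: pd.DataFrame  # MAF-style records
    response: pd.Series  # binary immunotherapy-response label
    batch: pd.Series
    gene_lengths_kb: pd.Series
    signature_genes: pd.Index = field(default=None)

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.sample_ids


def simulate_cohort(config: CohortConfig, signature: SignatureMatrix) -> Cohort:
    """Draw one cohort under ``config`` using ``signature`` as the mixing basis.

    Expression is ``signature @ fractions`` on the signature genes, plus
    subtype-program genes and background genes, all under multiplicative
    log-normal noise and per-(gene, batch) location/scale distortions.
    """
    if signature.n_cell_types != config.n_cell_types:
        raise ValueError(
            f"signature has {signature.n_cell_types} cell types, config expects {config.n_cell_types}"
        )
    n_sig = len(signature.gene_ids)
    n_prog = int(sum(config.n_program_genes))
    if config.n_genes < n_sig + n_prog:
        raise ValueError("n_genes must cover signature and program genes")

    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample")

    batch_labels = np.concatenate(
        [np.full(nb, f"batch{b + 1}") for b, nb in enumerate(config.n_samples_per_batch)]
    )
    batch = pd.Series(batch_labels, index=sample_ids, name="batch")

    subtype = rng.integers(0, config.n_subtypes, size=n)
    subtype_truth = pd.Series(subtype, index=sample_ids, name="subtype_truth")

    # latent prognostic axis: subtypes ordered by mean program expression;
    # program sizes are strictly increasing by default so the order is the
    # subtype index itself (checked below), standardized over the cohort.
    order = np.argsort(np.asarray(config.n_program_genes), kind="stable")
    code_of_subtype = np.empty(config.n_subtypes, dtype=float)
    code_of_subtype[order] = np.arange(config.n_subtypes)
    code = code_of_subtype[subtype]
    axis = (code - code.mean()) / (code.std() if code.std() > 0 else 1.0)
    latent_axis = pd.Series(axis, index=sample_ids, name="latent_axis")

    # cell fractions and signature-driven expression
    fractions = np.empty((n, config.n_cell_types))
    for s in range(config.n_subtypes):
        mask = subtype == s
        if mask.any():
            fractions[mask] = rng.dirichlet(config.dirichlet_alphas[s], size=int(mask.sum()))
    fractions_truth = pd.DataFrame(fractions, index=sample_ids, columns=signature.cell_type_ids)

    sig_expr = signature.values.to_numpy() @ fractions.T  # genes x samples

    # subtype program genes: block s up-shifted 2**program_log2_shift in subtype s
    prog_base = rng.lognormal(mean=np.log(5.0), sigma=0.5, size=n_prog)
    prog_expr = np.tile(prog_base[:, None], (1, n))
    prog_gene_ids = []
    row = 0
    for s, size in enumerate(config.n_program_genes):
        mask = subtype == s
        prog_expr[row : row + size][:, mask] *= 2.0**config.program_log2_shift
        prog_gene_ids += [f"PRG{s + 1}_{i:03d}" for i in range(size)]
        row += size

    n_bg = config.n_genes - n_sig - n_prog
    bg_expr = np.tile(
        rng.lognormal(mean=np.log(8.0), sigma=0.8, size=n_bg)[:, None], (1, n)
    )
    bg_gene_ids = [f"BG{i:04d}" for i in range(n_bg)]

    expr = np.vstack([sig_expr, prog_expr, bg_expr])
    gene_ids = pd.Index(list(signature.gene_ids) + prog_gene_ids + bg_gene_ids, name="gene")
    n_genes = len(gene_ids)

    # per-(gene, batch) location shift and scale distortion on the log scale,
    # plus per-entry log-normal noise
    for b, bname in enumerate(pd.unique(batch)):
        cols = np.flatnonzero((batch == bname).to_numpy())
        shift = rng.normal(0.0, config.batch_shift_sd, size=n_genes)
        scale_fac = np.exp(rng.normal(0.0, config.batch_scale_sd, size=n_genes))
        log_noise = rng.normal(0.0, 1.0, size=(n_genes, len(cols)))
        log_noise = log_noise * (config.noise_sd * scale_fac)[:, None] + shift[:, None]
        expr[:, cols] = expr[:, cols] * np.exp(log_noise)

    expression = ExpressionMatrix(
        values=pd.DataFrame(expr, index=gene_ids, columns=sample_ids),
        scale="FPKM",
        batch=batch,
    )

    # survival: exponential PH, log-hazard = coefficient * axis; independent
    # exponential censoring
    hazard = config.baseline_hazard * np.exp(config.hazard_coefficient * axis)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / config.censor_rate, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival = pd.DataFrame(
        {"OS_time_days": np.maximum(time, 1e-3), "OS_event": event}, index=sample_ids
    )

    # mutations: Bernoulli per gene with subtype-dependent probability
    records = []
    for gene, probs in config.mutation_spec.items():
        p = np.asarray(probs, dtype=float)[subtype]
        mutated = rng.random(n) < p
        for sid in sample_ids[mutated]:
            records.append((gene, sid, "Missense_Mutation"))
    mutations = pd.DataFrame(
        records, columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]
    )

    # binary immunotherapy-response label, logit linear in the axis
    logit = config.response_intercept + config.response_logit_slope * axis
    response = pd.Series(
        (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int),
        index=sample_ids,
        name="response",
    )

    gene_lengths_kb = pd.Series(
        rng.uniform(0.5, 5.0, size=n_genes), index=gene_ids, name="length_kb"
    )

    return Cohort(
        expression=expression,
        fractions_truth=fractions_truth,
        subtype_truth=subtype_truth,
        latent_axis=latent_axis,
        survival=survival,
        mutations=mutations,
        response=response,
        batch=batch,
        gene_lengths_kb=gene_lengths_kb,
        signature_genes=signature.gene_ids,
    )


def simulate_drug_response(
    cohort: Cohort,
    n_compounds: int = 12,
    n_linked: int = 5,
    link_strength: float = 0.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample x compound drug-sensitivity AUC matrix in (0, 1).

    The first ``n_linked`` compounds have AUC negatively correlated with the
    cohort's latent prognostic axis (strength ``link_strength``); the rest are
    independent noise.  AUC values are a monotone (logistic) map of the latent
    linear predictor, so rank correlations are preserved exactly.
    """
    if not (0.0 <= link_strength <= 1.0):
        raise ValueError("link_strength must be in [0, 1]")
    if n_linked > n_compounds:
        raise ValueError("n_linked must be <= n_compounds")
    rng = np.random.default_rng(seed)
    axis = cohort.latent_axis.to_numpy()
    n = len(axis)
    resid_sd = float(np.sqrt(max(0.0, 1.0 - link_strength**2)))
    cols = {}
    for c in range(n_compounds):
        noise = rng.normal(0.0, 1.0, size=n)
        if c < n_linked:
            raw = -link_strength * axis + resid_sd * noise
        else:
            raw = noise
        cols[f"compound{c + 1:03d}"] = 1.0 / (1.0 + np.exp(-raw))
    return pd.DataFrame(cols, index=cohort.sample_ids)


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write the plain-text artifacts: expression TSV, clinical TSV, MAF."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    p = outdir / "expression.tsv"
    cohort.expression.to_tsv(p)
    paths["expression"] = str(p)

    clinical = pd.DataFrame(
        {
            "OS_time_days": cohort.survival["OS_time_days"],
            "OS_event": cohort.survival["OS_event"],
            "subtype_truth": cohort.subtype_truth,
            "batch": cohort.batch,
            "response": cohort.response,
        }
    )
    p = outdir / "clinical.tsv"
    clinical.rename_axis("sample").to_csv(p, sep="\t")
    paths["clinical"] = str(p)

    p = outdir / "mutations.maf"
    cohort.mutations.to_csv(p, sep="\t", index=False)
    paths["maf"] = str(p)

    p = outdir / "gene_lengths.tsv"
    cohort.gene_lengths_kb.rename_axis("gene").to_csv(p, sep="\t")
    paths["gene_lengths"] = str(p)
    return paths
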