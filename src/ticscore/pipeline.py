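"""Config-driven end-to-end run of the TIC-score analysis.

Stage order: preprocess -> deconvolve -> consensus on fractions -> DEGs ->
consensus on DEG expression -> feature split / Boruta / TIC fit ->
cutpoint + KM -> mutation comparison -> associations -> drug screen.

:func:`analyze_cohort` runs the chain in memory and returns every
intermediate object; :func:`run_pipeline` wraps it with file I/O and writes a
checksum manifest, so a fixed (config, seed) reproduces the run directory
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, consensus, deconvolution, diffexpr, mutation, synthetic, tic
from .preprocess import ExpressionMatrix, combat_adjust, fpkm_to_tpm, log2_tpm
from .survival import km_by_group

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat, typed pipeline parameters (unknown keys are errors).

    Thresholds default to the analysis conventions: adjusted p < 0.05 and
    |log2FC| >= 1.5 for DEGs, 1000 deconvolution permutations, 1000 consensus
    resamples, per-source Spearman thresholds for the drug screen.
    """

    simulate: bool = True  # generate a synthetic cohort (else read input paths)
    expression_path: str | None = None
    clinical_path: str | None = None
    maf_path: str | None = None
    drug_auc_path: str | None = None

    seed: int = 0
    out_dir: str = "ticscore_run"

    # deconvolution
    deconv_backend: str = "nu-svr"
    deconv_perms: int = 1000
    # per-sample permutation p-values refit the model deconv_perms times per
    # sample; off by default in the orchestrated run
    deconv_compute_pvalues: bool = False
    # consensus clustering
    k_min: int = 2
    k_max: int = 6
    resamples: int = 1000
    subsample_frac: float = 0.8
    delta_threshold: float = 0.1
    # DEG filter
    adj_p_threshold: float = 0.05
    log2fc_threshold: float = 1.5
    # Boruta
    boruta_max_iter: int = 100
    boruta_alpha: float = 0.01
    # drug screen
    screen_source: str = "ctrp"
    decile_frac: float = 0.1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        if not self.simulate and self.expression_path is None:
            raise ValueError("either simulate=true or expression_path must be given")
        if self.screen_source not in association.SOURCE_THRESHOLDS:
            raise ValueError(
                f"screen_source must be one of {sorted(association.SOURCE_THRESHOLDS)}"
            )


FAST_PRESET = dict(deconv_perms=200, resamples=250)
"""Reduced-cost profile (permutations and resamples cut 4-5x)."""


@dataclass
class AnalysisResult:
    """Every intermediate of one analysis run, for inspection or writing."""

    tpm: ExpressionMatrix
    expr_log: ExpressionMatrix
    fractions: deconvolution.CellFractionMatrix
    consensus_fractions: consensus.ConsensusResult
    subtypes: pd.Series
    deg_tables: dict
    degs: pd.DataFrame
    consensus_genes: consensus.ConsensusResult
    gene_clusters: pd.Series
    split: tic.FeatureSplit
    boruta_alpha: tic.BorutaResult | None
    boruta_beta: tic.BorutaResult | None
    model: tic.TICModel
    scores: pd.Series
    cutpoint: tic.CutpointResult | None
    score_group: pd.Series | None  # 'high'/'low' at the optimal cutpoint
    summary: dict = field(default_factory=dict)


def analyze_cohort(
    expr_raw: ExpressionMatrix,
    signature: synthetic.SignatureMatrix,
    survival: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> AnalysisResult:
    """Run preprocess -> deconvolution -> subtyping -> DEG -> TIC score.

    ``expr_raw`` is a linear-scale (FPKM-tagged) matrix with optional batch
    labels; ``survival`` (columns ``OS_time_days``, ``OS_event``) enables the
    optimal-cutpoint stage.
    """
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(seed)

    tpm = fpkm_to_tpm(expr_raw)
    expr_log = log2_tpm(tpm)
    if expr_log.batch is not None and expr_log.batch.nunique() >= 2:
        expr_log = combat_adjust(expr_log)

    fractions = deconvolution.deconvolve_cohort(
        tpm, signature, backend=cfg.deconv_backend,
        n_perm=cfg.deconv_perms if cfg.deconv_compute_pvalues else 0,
        seed=int(rng.integers(2**31)),
    )

    cc_frac = consensus.run_consensus(
        fractions.fractions, k_range=range(cfg.k_min, cfg.k_max + 1),
        n_resamples=cfg.resamples, subsample_frac=cfg.subsample_frac,
        delta_threshold=cfg.delta_threshold, seed=int(rng.integers(2**31)),
    )
    subtypes = cc_frac.assignments

    deg_tables = diffexpr.moderated_t_all(
        expr_log.values, subtypes,
        adj_p_threshold=cfg.adj_p_threshold, log2fc_threshold=cfg.log2fc_threshold,
    )
    degs = diffexpr.select_degs(deg_tables)
    if len(degs) < 2:
        raise RuntimeError("fewer than 2 DEGs; cannot build a score")
    deg_expr = expr_log.values.loc[degs.index]

    cc_gene = consensus.run_consensus(
        deg_expr.T, k_range=range(cfg.k_min, min(cfg.k_max, 4) + 1),
        n_resamples=cfg.resamples, subsample_frac=cfg.subsample_frac,
        delta_threshold=cfg.delta_threshold, seed=int(rng.integers(2**31)),
    )
    gene_clusters = cc_gene.assignments

    split = tic.split_features(deg_expr, gene_clusters)
    y = gene_clusters.reindex(deg_expr.columns).to_numpy()
    boruta_a = boruta_b = None
    if split.alpha_genes:
        boruta_a = tic.boruta_select(
            deg_expr.loc[split.alpha_genes].T, y,
            max_iter=cfg.boruta_max_iter, alpha_level=cfg.boruta_alpha,
            seed=int(rng.integers(2**31)),
        )
        if not boruta_a.confirmed:
            boruta_a = None
    if split.beta_genes:
        boruta_b = tic.boruta_select(
            deg_expr.loc[split.beta_genes].T, y,
            max_iter=cfg.boruta_max_iter, alpha_level=cfg.boruta_alpha,
            seed=int(rng.integers(2**31)),
        )
        if not boruta_b.confirmed:
            boruta_b = None
    model = tic.fit_tic(expr_log.values, split, boruta_a, boruta_b)
    scores = model.train_scores

    cut = None
    score_group = None
    if survival is not None:
        cut = tic.optimal_cutpoint(scores, survival)
        model.cutpoint = cut.cutoff
        score_group = pd.Series(
            np.where(scores > cut.cutoff, "high", "low"),
            index=scores.index, name="score_group",
        )

    summary = {
        "selected_k_fractions": cc_frac.selected_k,
        "selected_k_genes": cc_gene.selected_k,
        "n_degs": int(len(degs)),
        "n_alpha": int(len(model.alpha_loadings)),
        "n_beta": int(len(model.beta_loadings)),
    }
    if cut is not None:
        summary.update(cutpoint=cut.cutoff, cutpoint_chi2=cut.chi2,
                       cutpoint_pvalue=cut.pvalue)
    return AnalysisResult(
        tpm=tpm, expr_log=expr_log, fractions=fractions,
        consensus_fractions=cc_frac, subtypes=subtypes,
        deg_tables=deg_tables, degs=degs, consensus_genes=cc_gene,
        gene_clusters=gene_clusters, split=split,
        boruta_alpha=boruta_a, boruta_beta=boruta_b, model=model,
        scores=scores, cutpoint=cut, score_group=score_group, summary=summary,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig, signature: synthetic.SignatureMatrix | None = None
) -> dict:
    """Execute all stages with file I/O; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    rng = np.random.default_rng(config.seed)

    def save(name: str, writer) -> Path:
        path = out / name
        writer(path)
        artifacts[name] = _sha256(path)
        return path

    stage = "inputs"
    try:
        if signature is None:
            signature = synthetic.make_signature(seed=int(rng.integers(2**31)))
        save("signature.tsv", signature.to_tsv)

        if config.simulate:
            cohort_cfg = synthetic.CohortConfig(seed=int(rng.integers(2**31)))
            cohort = synthetic.simulate_cohort(cohort_cfg, signature)
            drug_auc = synthetic.simulate_drug_response(
                cohort, seed=int(rng.integers(2**31))
            )
            expr_raw = cohort.expression
            clinical = pd.DataFrame(
                {"OS_time_days": cohort.survival["OS_time_days"],
                 "OS_event": cohort.survival["OS_event"],
                 "response": cohort.response}
            )
            maf = mutation.MutationTable(records=cohort.mutations,
                                         sample_ids=expr_raw.sample_ids)
            save("expression_raw.tsv", expr_raw.to_tsv)
            save("clinical.tsv", lambda p: clinical.rename_axis("sample").to_csv(p, sep="\t"))
            save("drug_auc.tsv", lambda p: drug_auc.rename_axis("sample").to_csv(p, sep="\t"))
        else:
            clinical = pd.read_csv(config.clinical_path, sep="\t", index_col=0)
            batch = clinical["batch"] if "batch" in clinical else None
            expr_raw = ExpressionMatrix.from_tsv(config.expression_path, scale="FPKM",
                                                 batch=batch)
            maf = (mutation.read_maf(config.maf_path, sample_ids=expr_raw.sample_ids)
                   if config.maf_path else None)
            drug_auc = (pd.read_csv(config.drug_auc_path, sep="\t", index_col=0)
                        if config.drug_auc_path else None)

        logger.info("pipeline parameters: %s", dataclasses.asdict(config))
        stage = "analysis"
        res = analyze_cohort(
            expr_raw, signature,
            survival=clinical[["OS_time_days", "OS_event"]],
            config=config, seed=int(rng.integers(2**31)),
        )
        save("expression_log2tpm_adjusted.tsv", res.expr_log.to_tsv)
        save("cell_fractions.tsv", res.fractions.to_tsv)
        save("immune_subtypes.tsv",
             lambda p: res.subtypes.rename_axis("sample").to_csv(p, sep="\t"))
        cc = res.consensus_fractions
        summary_rows = pd.DataFrame(
            {"k": cc.k_range,
             "cdf_area": [cc.areas[k] for k in cc.k_range],
             "delta_area": [cc.delta_areas[k] for k in cc.k_range]}
        )
        save("consensus_cdf_summary.tsv",
             lambda p: summary_rows.to_csv(p, sep="\t", index=False))
        for k in cc.k_range:
            save(f"consensus_matrix_k{k}.tsv",
                 lambda p, k=k: pd.DataFrame(
                     cc.matrices[k], index=res.subtypes.index,
                     columns=res.subtypes.index,
                 ).to_csv(p, sep="\t"))
        save("degs.tsv", lambda p: res.degs.to_csv(p, sep="\t"))
        save("gene_clusters.tsv",
             lambda p: res.gene_clusters.rename_axis("sample").to_csv(p, sep="\t"))
        save("tic_model.json", res.model.to_json)
        save("tic_scores.tsv",
             lambda p: res.scores.rename_axis("sample").to_csv(p, sep="\t"))
        results = dict(res.summary)

        stage = "survival"
        surv = clinical[["OS_time_days", "OS_event"]]
        curves = km_by_group(surv["OS_time_days"], surv["OS_event"], res.score_group)
        km_frames = []
        for lab, curve in curves.items():
            f = curve.to_frame()
            f.insert(0, "group", lab)
            km_frames.append(f)
        save("km_curves.tsv",
             lambda p: pd.concat(km_frames).to_csv(p, sep="\t", index=False))

        stage = "mutation"
        if maf is not None:
            tmb_table = mutation.tmb(maf)
            save("tmb.tsv", lambda p: tmb_table.rename_axis("sample").to_csv(p, sep="\t"))
            freq = mutation.compare_mutation_freq(maf, res.score_group)
            save("mutation_freq.tsv", lambda p: freq.to_csv(p, sep="\t"))
            rho, p_rho = mutation.tmb_score_correlation(
                tmb_table["tmb"].reindex(res.scores.index), res.scores
            )
            results["tmb_tic_spearman_rho"] = rho
            results["tmb_tic_spearman_p"] = p_rho

        stage = "associations"
        if "response" in clinical:
            resp = clinical["response"].reindex(res.scores.index)
            auc, _ = association.roc_auc(res.scores.to_numpy(), resp.to_numpy())
            results["response_auc"] = auc
            counts = pd.crosstab(res.score_group, resp)
            if counts.shape == (2, 2):
                _, _, p_chi = association.chisq_independence(counts.to_numpy())
                results["response_rate_chi2_p"] = p_chi
                rates = counts.div(counts.sum(axis=1), axis=0)
                if 1 in rates.columns:
                    results["response_rate_high"] = float(rates.loc["high", 1])
                    results["response_rate_low"] = float(rates.loc["low", 1])

        stage = "drug_screen"
        if drug_auc is not None:
            screen = association.drug_screen(
                res.scores, drug_auc,
                source_threshold=association.SOURCE_THRESHOLDS[config.screen_source],
                decile_frac=config.decile_frac,
            )
            save("drug_screen.tsv", lambda p: screen.to_csv(p, sep="\t"))
            results["n_screen_hits"] = int(screen["passes"].sum())

        save("results.json", lambda p: p.write_text(json.dumps(results, indent=1)))
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        logger.exception("pipeline failed at stage %r", stage)
        raise

    manifest = {"seed": config.seed, "artifacts": artifacts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
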