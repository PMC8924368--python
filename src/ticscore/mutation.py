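"""MAF parsing, tumor mutational burden, and group-wise mutation comparisons.

TMB is the per-sample count of nonsynonymous variants divided by the capture
size in megabases (default 38 Mb, the usual exome convention; the raw count
is also kept).  Per-gene frequency differences between two groups use
Fisher's exact test on the 2x2 mutated/wild-type table, with a Haldane 0.5
correction on the sample odds ratio when a cell is zero, restricted to genes
mutated in at least ``min_mutated`` samples, BH-adjusted over the genes
tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import spearman
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

REQUIRED_MAF_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")

NONSYNONYMOUS = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)

KNOWN_CLASSIFICATIONS = NONSYNONYMOUS | {
    "Silent", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "RNA", "IGR",
}

DEFAULT_CAPTURE_MB = 38.0


@dataclass
class MutationTable:
    """MAF-derived variant records plus the cohort's full sample list."""

    records: pd.DataFrame  # columns: Hugo_Symbol, Tumor_Sample_Barcode, Variant_Classification
    sample_ids: pd.Index | None = field(default=None)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_MAF_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"missing required MAF column(s): {missing}")
        unknown = set(self.records["Variant_Classification"]) - KNOWN_CLASSIFICATIONS
        if unknown:
            logger.warning("unknown variant classification(s) kept: %s", sorted(unknown))
        if self.sample_ids is None:
            self.sample_ids = pd.Index(self.records["Tumor_Sample_Barcode"].unique())
        else:
            orphan = set(self.records["Tumor_Sample_Barcode"]) - set(self.sample_ids)
            if orphan:
                logger.warning("%d record sample(s) not in the cohort list", len(orphan))
        dup = self.records.duplicated().sum()
        if dup:
            logger.info("%d duplicate record(s) kept (multi-hit)", dup)

    def nonsynonymous_counts(self) -> pd.Series:
        """Per-sample nonsynonymous variant count (0 for unmutated samples)."""
        nonsyn = self.records[self.records["Variant_Classification"].isin(NONSYNONYMOUS)]
        counts = nonsyn.groupby("Tumor_Sample_Barcode").size()
        return counts.reindex(self.sample_ids, fill_value=0).rename("n_nonsynonymous")

    def mutated_samples(self, gene: str) -> pd.Index:
        hit = self.records[
            (self.records["Hugo_Symbol"] == gene)
            & self.records["Variant_Classification"].isin(NONSYNONYMOUS)
        ]
        return pd.Index(hit["Tumor_Sample_Barcode"].unique())


def read_maf(path, sample_ids: pd.Index | None = None) -> MutationTable:
    """Parse a tab-delimited MAF (comment lines starting with '#' skipped)."""
    records = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return MutationTable(records=records, sample_ids=sample_ids)


def tmb(table: MutationTable, capture_mb: float = DEFAULT_CAPTURE_MB) -> pd.DataFrame:
    """Per-sample TMB = nonsynonymous count / capture_mb, raw count alongside."""
    if capture_mb <= 0:
        raise ValueError("capture_mb must be positive")
    counts = table.nonsynonymous_counts()
    return pd.DataFrame({"n_nonsynonymous": counts, "tmb": counts / capture_mb})


def compare_mutation_freq(
    table: MutationTable,
    binary_groups: pd.Series,
    min_mutated: int = 3,
) -> pd.DataFrame:
    """Per-gene mutation frequency comparison between two groups.

    ``binary_groups`` maps sample id to one of exactly two labels.  Returns a
    table with mutated counts per group, the (Haldane-corrected) sample odds
    ratio, the two-sided Fisher exact p, and the BH-adjusted p over the genes
    tested (those mutated in >= ``min_mutated`` samples).
    """
    binary_groups = pd.Series(binary_groups)
    labels = sorted(binary_groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    g1 = binary_groups[binary_groups == labels[0]].index
    g2 = binary_groups[binary_groups == labels[1]].index
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for gene in sorted(table.records["Hugo_Symbol"].unique()):
        mutated = set(table.mutated_samples(gene))
        a = len(mutated & set(g1))
        b = len(g1) - a
        c = len(mutated & set(g2))
        d = len(g2) - c
        if a + c < min_mutated:
            continue
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        rows.append({"gene": gene, f"n_mut_{labels[0]}": a, f"n_mut_{labels[1]}": c,
                     "odds_ratio": orr, "pvalue": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
        out = out.set_index("gene")
    return out


def tmb_score_correlation(tmb_values, tic_scores) -> tuple[float, float]:
    """Spearman correlation between per-sample TMB and TIC score."""
    tmb_values = np.asarray(tmb_values, dtype=float)
    tic_scores = np.asarray(tic_scores, dtype=float)
    if len(tmb_values) != len(tic_scores):
        raise ValueError("TMB and score vectors must be paired")
    return spearman(tmb_values, tic_scores)
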