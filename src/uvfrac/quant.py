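"""Expression quantification for the fractionated time-course design.

Counts are converted to FPKM (fragments per kilobase of transcript per
million mapped reads) using the mature transcript length (sum of exon
lengths); genes are kept when any fraction reaches FPKM >= 1 in at least one
of its samples; and the chromatin/cytoplasm enrichment of each gene is the
ratio of mean chromatin FPKM to mean cytoplasm FPKM (pseudocount-guarded),
summarised per biotype with quartiles and a t test on log2 folds.

A median-of-ratios size-factor estimator backs the differential-expression
normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "validate_design",
    "compute_fpkm",
    "size_factors",
    "filter_expressed",
    "chromatin_enrichment",
]

FRACTIONS = ("cytoplasm", "chromatin")


@dataclass
class CountMatrix:
    """Genes x samples nonnegative integer counts plus gene lengths (nt)."""

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = self.counts.index.difference(self.lengths.index)
        if len(missing):
            raise ValueError(f"genes without a length: {list(missing[:5])}...")
        self.lengths = self.lengths.loc[self.counts.index]


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "fraction", "timepoint", "replicate"}
    if not required.issubset(design.columns):
        raise ValueError(f"design must have columns {sorted(required)}")
    bad = set(design["fraction"]) - set(FRACTIONS)
    if bad:
        raise ValueError(f"unknown fraction(s) {bad}")
    key = design[["fraction", "timepoint", "replicate"]]
    if key.duplicated().any():
        raise ValueError("(fraction, timepoint, replicate) triples must be unique")
    for frac in design["fraction"].unique():
        if not (design.loc[design["fraction"] == frac, "timepoint"] == 0).any():
            raise ValueError(f"fraction {frac} lacks a timepoint-0 sample")
    return design


def compute_fpkm(cm: CountMatrix) -> pd.DataFrame:
    """FPKM(g, s) = counts(g, s) * 1e9 / (length_g * column_total_s)."""
    if (cm.lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = cm.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    return cm.counts * 1e9 / np.outer(cm.lengths.to_numpy(), totals.to_numpy())


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors, rescaled to geometric mean 1.

    Only genes with nonzero counts in every sample contribute; if none exist
    the caller is advised to add a pseudocount.
    """
    x = counts.to_numpy(dtype=float)
    ref_mask = (x > 0).all(axis=1)
    if not ref_mask.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; add a pseudocount "
            "or drop empty samples"
        )
    xs = x[ref_mask]
    log_geomean = np.log(xs).mean(axis=1, keepdims=True)
    ratios = np.log(xs) - log_geomean
    factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def filter_expressed(
    fpkm: pd.DataFrame, design: pd.DataFrame, threshold: float = 1.0
) -> pd.Index:
    """Genes with FPKM >= threshold in at least one fraction.

    A gene is retained iff the maximum FPKM over the samples of at least one
    fraction reaches the (inclusive) threshold.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    validate_design(design)
    keep = np.zeros(len(fpkm), dtype=bool)
    for frac in design["fraction"].unique():
        cols = design.loc[design["fraction"] == frac, "sample_id"]
        keep |= (fpkm[cols].max(axis=1) >= threshold).to_numpy()
    return fpkm.index[keep]


def chromatin_enrichment(
    fpkm: pd.DataFrame,
    design: pd.DataFrame,
    biotypes: pd.Series | None = None,
    pseudocount: float = 0.1,
    untreated_only: bool = False,
    drop_zero_cytoplasm: bool = False,
    reference_biotype: str = "mRNA",
    equal_var: bool = False,
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Per-gene chromatin/cytoplasm FPKM fold plus a per-biotype summary.

    fold_g = (mean chromatin FPKM + eps) / (mean cytoplasm FPKM + eps),
    pooling all timepoints by default or only the untreated libraries when
    ``untreated_only``. With ``drop_zero_cytoplasm`` genes with zero mean
    cytoplasmic signal are dropped instead of pseudocount-guarded.

    When ``biotypes`` is given, the summary reports n, median and quartiles
    of the fold per biotype and a two-sample t statistic (Welch by default)
    on log2 folds against ``reference_biotype``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    validate_design(design)
    sel = design if not untreated_only else design[design["timepoint"] == 0]
    means = {}
    for frac in FRACTIONS:
        cols = sel.loc[sel["fraction"] == frac, "sample_id"]
        if cols.empty:
            raise ValueError(f"no {frac} samples selected")
        means[frac] = fpkm[cols].mean(axis=1)
    if drop_zero_cytoplasm:
        keep = means["cytoplasm"] > 0
        fold = means["chromatin"][keep] / means["cytoplasm"][keep]
    else:
        fold = (means["chromatin"] + pseudocount) / (means["cytoplasm"] + pseudocount)
    fold.name = "chromatin_fold"

    summary = None
    if biotypes is not None:
        log2fold = np.log2(fold)
        bt = biotypes.loc[fold.index]
        ref = log2fold[bt == reference_biotype]
        rows = []
        for biotype in bt.unique():
            vals = fold[bt == biotype]
            logs = log2fold[bt == biotype]
            if biotype == reference_biotype or len(ref) < 2 or len(logs) < 2:
                t_stat, p = np.nan, np.nan
            else:
                t_stat, p = stats.ttest_ind(logs, ref, equal_var=equal_var)
            rows.append(
                {
                    "biotype": biotype,
                    "n": len(vals),
                    "q1": float(vals.quantile(0.25)),
                    "median": float(vals.median()),
                    "q3": float(vals.quantile(0.75)),
                    "t_vs_ref": float(t_stat) if t_stat == t_stat else np.nan,
                    "p_vs_ref": float(p) if p == p else np.nan,
                }
            )
        summary = pd.DataFrame(rows).set_index("biotype")
    return fold, summary
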