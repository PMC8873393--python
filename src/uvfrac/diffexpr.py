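"""Negative-binomial differential expression versus the untreated baseline.

A self-contained Wald test on normalised group means replaces the usual GLM
machinery: per-gene dispersion alpha is estimated by method of moments
(pooled within-group variance vs mean) with 50/50 shrinkage toward the
trimmed mean across genes, the log2 fold change is computed on
pseudocount-stabilised normalised means, and its delta-method standard error

    SE^2 = (1/ln 2)^2 * [ (1/mu_A + alpha)/n_A + (1/mu_B + alpha)/n_B ]

feeds a two-sided normal test. p values are Benjamini-Hochberg adjusted
within each (fraction, contrast) family and genes are called up/down with
the thresholds |log2FC| >= 1 (inclusive) and padj < 0.05 (strict).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant import size_factors, validate_design

__all__ = [
    "estimate_dispersion",
    "nb_wald_test",
    "bh_adjust",
    "call_de",
    "run_de",
]

LFC_THRESHOLD = 1.0
PADJ_THRESHOLD = 0.05
PSEUDOCOUNT = 0.5  # normalised-count offset stabilising log2FC at zeros


def estimate_dispersion(
    norm_counts: pd.DataFrame,
    groups: pd.Series,
    shrink: bool = True,
    trim: float = 0.125,
) -> pd.Series:
    """Method-of-moments NB dispersion per gene.

    alpha_hat = max(0, (pooled within-group variance - pooled mean) /
    pooled mean^2), then (optionally) shrunk 50/50 toward the trimmed mean of
    alpha_hat across genes. Requires >= 2 replicates in at least one group.
    """
    groups = groups.loc[norm_counts.columns]
    sizes = groups.value_counts()
    if (sizes < 2).all():
        raise ValueError(
            "dispersion estimation needs >= 2 replicates in at least one group"
        )
    x = norm_counts.to_numpy(dtype=float)
    var_num = np.zeros(x.shape[0])
    mean_num = np.zeros(x.shape[0])
    dof = 0
    n_tot = 0
    for g in sizes.index:
        cols = np.flatnonzero((groups == g).to_numpy())
        if len(cols) < 2:
            continue
        sub = x[:, cols]
        var_num += sub.var(axis=1, ddof=1) * (len(cols) - 1)
        mean_num += sub.mean(axis=1) * len(cols)
        dof += len(cols) - 1
        n_tot += len(cols)
    pooled_var = var_num / dof
    pooled_mean = mean_num / n_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(
            pooled_mean > 0, (pooled_var - pooled_mean) / pooled_mean**2, 0.0
        )
    alpha = np.maximum(alpha, 0.0)
    if shrink:
        prior = float(stats.trim_mean(alpha, trim))
        alpha = 0.5 * alpha + 0.5 * prior
    return pd.Series(alpha, index=norm_counts.index, name="alpha")


def nb_wald_test(
    group_a: np.ndarray | pd.DataFrame,
    group_b: np.ndarray | pd.DataFrame,
    alpha: np.ndarray | float,
    pseudocount: float = PSEUDOCOUNT,
) -> tuple[np.ndarray, np.ndarray]:
    """Wald test of B vs A on normalised counts (rows = genes).

    Returns (log2fc, p_value) vectors. Genes with both group means zero get
    log2fc 0 and p 1 by definition. Inside the SE the means are floored at
    the pseudocount so on/off genes keep a finite statistic.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("both groups must be nonempty")
    alpha = np.asarray(alpha, dtype=float)
    if (alpha < 0).any():
        raise ValueError("alpha must be >= 0")
    mu_a = a.mean(axis=1)
    mu_b = b.mean(axis=1)
    log2fc = np.log2((mu_b + pseudocount) / (mu_a + pseudocount))
    se2 = (1.0 / math.log(2.0)) ** 2 * (
        (1.0 / np.maximum(mu_a, pseudocount) + alpha) / a.shape[1]
        + (1.0 / np.maximum(mu_b, pseudocount) + alpha) / b.shape[1]
    )
    z = log2fc / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    both_zero = (mu_a == 0) & (mu_b == 0)
    log2fc[both_zero] = 0.0
    p[both_zero] = 1.0
    return log2fc, np.minimum(p, 1.0)


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    log2fc: np.ndarray | pd.Series,
    padj: np.ndarray | pd.Series,
    lfc_threshold: float = LFC_THRESHOLD,
    padj_threshold: float = PADJ_THRESHOLD,
) -> np.ndarray:
    """Status per gene: up / down / ns.

    up iff log2fc >= lfc_threshold and padj < padj_threshold; down iff
    log2fc <= -lfc_threshold and padj < padj_threshold; else ns. The fold
    threshold is inclusive, the padj threshold strict.
    """
    if lfc_threshold <= 0 or padj_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    lfc = np.asarray(log2fc, dtype=float)
    q = np.asarray(padj, dtype=float)
    status = np.full(lfc.shape, "ns", dtype=object)
    sig = q < padj_threshold
    status[sig & (lfc >= lfc_threshold)] = "up"
    status[sig & (lfc <= -lfc_threshold)] = "down"
    return status


def run_de(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    baseline: float = 0.0,
    lfc_threshold: float = LFC_THRESHOLD,
    padj_threshold: float = PADJ_THRESHOLD,
) -> pd.DataFrame:
    """Per-fraction, per-timepoint DE versus the baseline timepoint.

    Size factors and dispersions are estimated within each fraction (the two
    compartments are never compared to each other); BH adjustment is applied
    separately within each (fraction, contrast) family. Returns a tidy frame
    with columns gene_id, fraction, timepoint, log2fc, p_value, padj, status.
    """
    validate_design(design)
    out = []
    for frac in design["fraction"].unique():
        sub = design[design["fraction"] == frac]
        cols = sub["sample_id"].tolist()
        sf = size_factors(counts[cols])
        norm = counts[cols] / sf
        groups = pd.Series(sub["timepoint"].to_numpy(), index=cols)
        alpha = estimate_dispersion(norm, groups)
        base_cols = sub.loc[sub["timepoint"] == baseline, "sample_id"].tolist()
        if not base_cols:
            raise ValueError(f"fraction {frac} has no baseline ({baseline} h) samples")
        for tp in sorted(t for t in sub["timepoint"].unique() if t != baseline):
            tp_cols = sub.loc[sub["timepoint"] == tp, "sample_id"].tolist()
            lfc, p = nb_wald_test(
                norm[base_cols].to_numpy(), norm[tp_cols].to_numpy(), alpha.to_numpy()
            )
            padj = bh_adjust(p)
            status = call_de(lfc, padj, lfc_threshold, padj_threshold)
            out.append(
                pd.DataFrame(
                    {
                        "gene_id": counts.index,
                        "fraction": frac,
                        "timepoint": tp,
                        "log2fc": lfc,
                        "p_value": p,
                        "padj": padj,
                        "status": status,
                    }
                )
            )
    return pd.concat(out, ignore_index=True)
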