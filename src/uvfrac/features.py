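"""Structural feature distributions for arbitrary gene sets.

Compares groups of genes (e.g. recovered vs not-recovered, or repressed vs
recovered lncRNAs) on CDS length, transcript length, exon length, exon count
and intron count, with fixed-width histograms (100 bp size classes for
lengths, width 1 for intron counts) and Welch t tests between each group and
a reference group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import GeneModel

__all__ = ["FeatureSummary", "feature_histogram", "summarize_groups"]

NUMERIC_FEATURES = ("cds_length", "tx_length", "exon_length", "intron_count")


@dataclass
class FeatureSummary:
    group: str
    n: int
    mean_cds_length: float
    median_cds_length: float
    mean_tx_length: float
    median_tx_length: float
    mean_exon_length: float
    mean_intron_count: float
    exon_count_histogram: pd.Series  # exon count -> number of genes
    single_exon_fraction: float
    p_vs_reference: dict[str, float]  # feature -> Welch (or pooled) t p value


def feature_histogram(values: Iterable[float], binwidth: float) -> pd.Series:
    """Counts per fixed-width bin [b*w, (b+1)*w), indexed by bin start.

    Empty bins inside the occupied range are emitted with count 0; counts sum
    to the number of input values.
    """
    if binwidth <= 0:
        raise ValueError("binwidth must be > 0")
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        return pd.Series(dtype=int, name="count")
    if (vals < 0).any():
        raise ValueError("values must be >= 0")
    bins = np.floor(vals / binwidth).astype(int)
    counts = np.bincount(bins - bins.min())
    index = (np.arange(bins.min(), bins.min() + len(counts)) * binwidth)
    return pd.Series(counts, index=index, name="count")


def _group_values(
    gene_ids: Sequence[str],
    models: Mapping[str, GeneModel],
    isoforms: Mapping[str, Sequence[GeneModel]] | None,
    isoform_mode: str,
) -> dict[str, np.ndarray]:
    cds, tx, exon_lens, introns, exon_counts = [], [], [], [], []
    for gid in gene_ids:
        if isoform_mode == "per_isoform" and isoforms is not None:
            records = isoforms.get(gid, [models[gid]])
        else:
            records = [models[gid]]
        for g in records:
            cds.append(g.cds_length)
            tx.append(g.tx_length)
            introns.append(g.intron_count)
            exon_counts.append(len(g.exons))
            exon_lens.extend(e - s + 1 for s, e in g.exons)
    return {
        "cds_length": np.asarray(cds, dtype=float),
        "tx_length": np.asarray(tx, dtype=float),
        "exon_length": np.asarray(exon_lens, dtype=float),
        "intron_count": np.asarray(introns, dtype=float),
        "exon_count": np.asarray(exon_counts, dtype=float),
    }


def summarize_groups(
    groups: Mapping[str, Sequence[str]],
    models: Mapping[str, GeneModel],
    reference: str | None = None,
    isoform_mode: str = "per_gene",
    isoforms: Mapping[str, Sequence[GeneModel]] | None = None,
    equal_var: bool = False,
) -> dict[str, FeatureSummary]:
    """Per-group feature summaries with t tests against a reference group.

    ``isoform_mode`` is ``per_gene`` (one record per gene) or ``per_isoform``
    (every isoform in ``isoforms`` counted, so histogram totals may exceed
    the gene count). Welch's unequal-variance t test is the default;
    ``equal_var=True`` selects the pooled-variance form.
    """
    if isoform_mode not in ("per_gene", "per_isoform"):
        raise ValueError("isoform_mode must be per_gene or per_isoform")
    unknown = sorted(
        {gid for ids in groups.values() for gid in ids if gid not in models}
    )
    if unknown:
        raise ValueError(f"unknown gene id(s): {unknown[:10]}")
    if reference is None:
        reference = next(iter(groups))
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not among groups")

    values = {
        name: _group_values(ids, models, isoforms, isoform_mode)
        for name, ids in groups.items()
    }
    ref_vals = values[reference]
    out: dict[str, FeatureSummary] = {}
    for name, v in values.items():
        pvals = {}
        for feat in NUMERIC_FEATURES:
            a, b = v[feat], ref_vals[feat]
            if name == reference or len(a) < 2 or len(b) < 2:
                pvals[feat] = float("nan")
            else:
                pvals[feat] = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
        exon_hist = feature_histogram(v["exon_count"], 1.0).astype(int)
        n = len(v["tx_length"])
        single = int(exon_hist.get(1.0, 0))
        out[name] = FeatureSummary(
            group=name,
            n=len(list(groups[name])),
            mean_cds_length=float(v["cds_length"].mean()) if n else float("nan"),
            median_cds_length=float(np.median(v["cds_length"])) if n else float("nan"),
            mean_tx_length=float(v["tx_length"].mean()) if n else float("nan"),
            median_tx_length=float(np.median(v["tx_length"])) if n else float("nan"),
            mean_exon_length=float(v["exon_length"].mean()) if n else float("nan"),
            mean_intron_count=float(v["intron_count"].mean()) if n else float("nan"),
            exon_count_histogram=exon_hist,
            single_exon_fraction=single / n if n else float("nan"),
            p_vs_reference=pvals,
        )
    return out
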