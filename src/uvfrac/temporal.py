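"""Temporal classification of post-UV expression profiles.

Each gene's chromatin (or cytoplasmic) time course is summarised by its
differential-expression status versus the untreated 0 h baseline at the three
post-UV timepoints (0.5 h, 3 h, 24 h) and mapped onto the recovery vocabulary
used for transcription-coupled-repair time courses:

* ``recovered`` — repressed immediately after UV (down at 0.5 h) and back to
  baseline (ns or up) by 24 h; ``recovery_time`` records the first restored
  timepoint (3 or 24 h).
* ``not_recovered`` — repressed at 0.5 h or 3 h and still down at 24 h.
* ``induced`` — up at one or more timepoints and never down.
* ``unchanged`` — ns throughout.
* ``other`` — any remaining pattern (e.g. down only at 24 h).

The module also provides k-means clustering of row-standardised temporal
profiles and sample-level PCA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "RecoveryCall",
    "ClusterResult",
    "label_statuses",
    "classify_recovery",
    "classify_recovery_table",
    "cluster_profiles",
    "pca_samples",
]

POST_UV_TIMEPOINTS = (0.5, 3.0, 24.0)
RECOVERY_LABELS = ("recovered", "not_recovered", "induced", "unchanged", "other")

_OK = ("ns", "up")  # "restored to normal levels" = not called down


@dataclass(frozen=True)
class RecoveryCall:
    """Recovery label for one gene in one fraction.

    ``recovery_time`` (hours) is set iff ``label == "recovered"`` and is the
    earliest post-repression timepoint at which expression is restored.
    """

    gene_id: str
    fraction: str
    label: str
    recovery_time: float | None = None

    def __post_init__(self) -> None:
        if self.label not in RECOVERY_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if (self.recovery_time is not None) != (self.label == "recovered"):
            raise ValueError("recovery_time is defined iff label == 'recovered'")


@dataclass(frozen=True)
class ClusterResult:
    k: int
    assignments: pd.Series  # gene_id -> cluster id in 1..k
    centroids: np.ndarray  # (k, n_timepoints)
    inertia: float


def label_statuses(statuses: Sequence[str]) -> tuple[str, float | None]:
    """Map DE statuses at (0.5 h, 3 h, 24 h) onto a recovery label.

    ``statuses`` are "down" / "ns" / "up" calls versus the untreated baseline.
    Returns ``(label, recovery_time)``; the same rule labels simulated ground
    truth and measured profiles, so the two are directly comparable.
    """
    if len(statuses) != 3:
        raise ValueError(
            f"expected statuses at the three post-UV timepoints, got {len(statuses)}"
        )
    bad = [s for s in statuses if s not in ("down", "ns", "up")]
    if bad:
        raise ValueError(f"invalid status values: {bad}")
    s05, s3, s24 = statuses
    if s05 == "down" and s24 in _OK:
        return "recovered", 3.0 if s3 in _OK else 24.0
    if (s05 == "down" or s3 == "down") and s24 == "down":
        return "not_recovered", None
    if "up" in statuses and "down" not in statuses:
        return "induced", None
    if all(s == "ns" for s in statuses):
        return "unchanged", None
    return "other", None


def classify_recovery(
    gene_id: str, fraction: str, statuses: Mapping[float, str] | Sequence[str]
) -> RecoveryCall:
    """Classify one time course.

    ``statuses`` is either a mapping ``{0.5: status, 3: status, 24: status}``
    or a sequence ordered by timepoint. A missing timepoint raises.
    """
    if isinstance(statuses, Mapping):
        missing = [t for t in POST_UV_TIMEPOINTS if t not in statuses]
        if missing:
            raise ValueError(f"missing timepoint(s) {missing} for gene {gene_id}")
        ordered = [statuses[t] for t in POST_UV_TIMEPOINTS]
    else:
        ordered = list(statuses)
    label, rt = label_statuses(ordered)
    return RecoveryCall(gene_id=gene_id, fraction=fraction, label=label, recovery_time=rt)


def classify_recovery_table(de: pd.DataFrame) -> pd.DataFrame:
    """Label every (gene, fraction) in a tidy DE table.

    ``de`` must carry columns gene_id, fraction, timepoint, status (the output
    of :func:`uvfrac.diffexpr.run_de`). Returns a frame with columns gene_id,
    fraction, label, recovery_time.
    """
    required = {"gene_id", "fraction", "timepoint", "status"}
    if not required.issubset(de.columns):
        raise ValueError(f"DE table must have columns {sorted(required)}")
    wide = de.pivot_table(
        index=["gene_id", "fraction"],
        columns="timepoint",
        values="status",
        aggfunc="first",
    )
    missing = [t for t in POST_UV_TIMEPOINTS if t not in wide.columns]
    if missing:
        raise ValueError(f"DE table lacks timepoint(s) {missing}")
    rows = []
    for (gene_id, fraction), row in wide.iterrows():
        statuses = [row[t] for t in POST_UV_TIMEPOINTS]
        if any(pd.isna(s) for s in statuses):
            raise ValueError(f"incomplete time course for {gene_id}/{fraction}")
        label, rt = label_statuses(statuses)
        rows.append((gene_id, fraction, label, rt))
    return pd.DataFrame(rows, columns=["gene_id", "fraction", "label", "recovery_time"])


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    out = np.zeros_like(x, dtype=float)
    np.divide(x - mu, sd, out=out, where=sd > 0)
    return out


def cluster_profiles(
    profiles: pd.DataFrame, k: int, seed: int, restarts: int = 50
) -> ClusterResult:
    """k-means on row-z-scored temporal profiles (genes x timepoints).

    k-means++ initialisation, Euclidean distance, best of ``restarts`` runs by
    inertia; deterministic for a fixed ``seed``. Zero-variance rows z-score to
    all-zeros rather than NaN. Cluster ids are 1-based.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(profiles) < k:
        raise ValueError(f"k={k} exceeds the {len(profiles)} available profiles")
    z = _zscore_rows(profiles.to_numpy(dtype=float))
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    labels = km.fit_predict(z)
    return ClusterResult(
        k=k,
        assignments=pd.Series(labels + 1, index=profiles.index, name="cluster_id"),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
    )


def pca_samples(log_expr: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-level PCA of a genes x samples log-expression matrix.

    Samples are the observations; genes are centred features. Returns the
    sample coordinates (samples x components) and the variance fraction
    explained by each component (non-increasing, summing to <= 1).
    """
    if log_expr.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = log_expr.to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    n_comp = min(x.shape[0] - 1, x.shape[1])
    total = float(np.sum(s**2))
    var_frac = (s[:n_comp] ** 2 / total) if total > 0 else np.zeros(n_comp)
    coords = pd.DataFrame(
        u[:, :n_comp] * s[:n_comp],
        index=log_expr.columns,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    return coords, var_frac
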