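"""Mechanistic synthetic data for a fractionated UV-response RNA-seq design.

The generator emulates a two-compartment (chromatin pellet vs cytoplasm)
time-course experiment on UV-C-irradiated human fibroblasts:

1. a synthetic annotation of ~10^4 genes in four biotypes (mRNA, annotated
   lncRNA, novel lncRNA, TUCP) with log-normal genomic spans, geometric exon
   counts and realistic exon lengths;
2. Poisson placement of RNAP-II-blocking photolesions on each gene's genomic
   template at 5x10^-4 lesions per base (500 per megabase at the reference
   10 J/m2 dose), with per-lesion exponential repair kinetics;
3. a lesion-blocked elongation model: nascent chromatin signal is
   proportional to the transcribable template up to the first unrepaired
   lesion, floored by a promoter-proximal window (default 25 kb) that stays
   active regardless of downstream damage;
4. first-order cytoplasmic mRNA accumulation/decay fed by exported nascent
   synthesis; and
5. negative-binomial count sampling (variance mu + alpha*mu^2) at a fixed
   library size for fraction x timepoint x replicate libraries.

Every stochastic choice flows from a single seed through per-gene derived
streams (``SeedSequence`` keyed by domain and gene index), so enlarging the
gene set never perturbs the draws of earlier genes.

Ground truth (lesion positions, per-timepoint activity, expected compartment
means, and a recovery label per fraction) is recorded per gene so that every
downstream analysis stage can be validated against known labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

from .temporal import POST_UV_TIMEPOINTS, label_statuses

__all__ = [
    "BIOTYPES",
    "NONCODING_BIOTYPES",
    "GeneModel",
    "SimConfig",
    "TruthRecord",
    "generate_gene_models",
    "place_lesions",
    "transcription_activity",
    "cytoplasm_trajectory",
    "simulate_truth",
    "simulate_counts",
    "simulate_experiment",
    "strong_effect_mask",
    "random_transcript_sequence",
    "write_fixtures",
    "read_gtf",
    "read_counts",
    "read_design",
    "read_truth",
]

BIOTYPES = ("mRNA", "annotated_lncRNA", "novel_lncRNA", "TUCP")
NONCODING_BIOTYPES = frozenset({"annotated_lncRNA", "novel_lncRNA", "TUCP"})
FRACTIONS = ("chromatin", "cytoplasm")
LN2 = math.log(2.0)

# stream-split domains (keep stable: they key the per-gene substreams)
_D_GENES, _D_LESIONS, _D_EXPR, _D_COUNTS = 1, 2, 3, 4


def _stream(seed: int, domain: int, *key: int) -> np.random.Generator:
    """Independent generator for one (domain, key) cell of the experiment."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), domain, *key]))


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A single-isoform gene annotation record.

    Coordinates are 1-based closed (GTF convention). ``exons`` are sorted,
    pairwise disjoint, start at ``tx_start`` and end at ``tx_end``.
    ``cds_length`` is 0 for every noncoding biotype.
    """

    gene_id: str
    biotype: str
    chrom: str
    strand: str  # "+", "-", or "." (unknown)
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds_length: int = 0

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")
        if not self.exons:
            raise ValueError("a gene needs at least one exon")
        if self.tx_end < self.tx_start:
            raise ValueError("tx_end < tx_start")
        prev_end = None
        for s, e in self.exons:
            if e < s:
                raise ValueError(f"empty exon ({s}, {e})")
            if prev_end is not None and s <= prev_end:
                raise ValueError("exons must be sorted and disjoint")
            prev_end = e
        if self.exons[0][0] != self.tx_start or self.exons[-1][1] != self.tx_end:
            raise ValueError("first exon must start at tx_start, last must end at tx_end")
        if self.cds_length > self.tx_length:
            raise ValueError("cds_length exceeds tx_length")
        if self.biotype != "mRNA" and self.cds_length != 0:
            raise ValueError("cds_length must be 0 for noncoding biotypes")

    @property
    def template_span(self) -> int:
        """Genomic (template) length in nt, introns included."""
        return self.tx_end - self.tx_start + 1

    @property
    def tx_length(self) -> int:
        """Mature transcript length: sum of exon lengths."""
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1


def _default_n_genes() -> dict[str, int]:
    return {"mRNA": 6000, "annotated_lncRNA": 1500, "novel_lncRNA": 2000, "TUCP": 500}


def _default_length_mu() -> dict[str, float]:
    # log-normal location of the genomic span; medians ~25 kb (mRNA),
    # ~22 kb (annotated/TUCP), ~18 kb (novel) — chromatin-associated lncRNA
    # genes span genomic lengths comparable to protein-coding genes
    return {
        "mRNA": math.log(25_000.0),
        "annotated_lncRNA": math.log(22_000.0),
        "novel_lncRNA": math.log(18_000.0),
        "TUCP": math.log(22_000.0),
    }


def _default_length_sigma() -> dict[str, float]:
    return {"mRNA": 1.1, "annotated_lncRNA": 1.3, "novel_lncRNA": 1.2, "TUCP": 1.2}


def _default_exon_count_p() -> dict[str, float]:
    # geometric success probability; mean exon count = 1/p. mRNAs average
    # ~9 exons; lncRNAs are exon-poor with ~45% single-exon transcripts.
    return {"mRNA": 0.11, "annotated_lncRNA": 0.45, "novel_lncRNA": 0.45, "TUCP": 0.4}


def _default_exon_length() -> dict[str, float]:
    # mean exon length (nt); lncRNA exons run slightly shorter than mRNA exons
    return {"mRNA": 170.0, "annotated_lncRNA": 115.0, "novel_lncRNA": 110.0, "TUCP": 130.0}


def _default_retention() -> dict[str, float]:
    # chromatin/cytoplasm partitioning multiplier: noncoding biotypes are
    # chromatin-retained, mRNA is the reference
    return {"mRNA": 1.0, "annotated_lncRNA": 4.0, "novel_lncRNA": 6.0, "TUCP": 4.0}


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Rates are per hour and per base; lengths in nt; ``timepoints`` in hours
    post-irradiation with 0 h meaning the untreated baseline library.
    ``lesion_rate`` defaults to 5e-4 lesions per template base (500 per
    megabase) at ``reference_dose``; a different ``dose`` scales it linearly.
    ``fraction_effect_direction`` selects which noncoding genes recover first:
    ``"short_first"`` (the plain lesion-load model, as for mRNA) or
    ``"long_first"`` (per-gene repair half-life ~ repair_length_scale/span, so
    longer noncoding genes clear lesions sooner).
    """

    n_genes: dict[str, int] = field(default_factory=_default_n_genes)
    length_log_mu: dict[str, float] = field(default_factory=_default_length_mu)
    length_log_sigma: dict[str, float] = field(default_factory=_default_length_sigma)
    exon_count_p: dict[str, float] = field(default_factory=_default_exon_count_p)
    mean_exon_length: dict[str, float] = field(default_factory=_default_exon_length)
    lesion_rate: float = 5e-4
    dose: float = 10.0
    reference_dose: float = 10.0
    proximal_window: int = 25_000
    repair_halflife: float = 4.0  # hours; math.inf disables repair
    repair_length_scale: float = 100_000.0  # nt, used by "long_first" only
    timepoints: tuple[float, ...] = (0.0, 0.5, 3.0, 24.0)
    mrna_decay_rate: float = 0.25  # per hour (cytoplasmic half-life ~2.8 h)
    export_fraction: float = 0.8
    chromatin_retention: dict[str, float] = field(default_factory=_default_retention)
    nb_dispersion: float = 0.05
    library_size: int = 2_000_000
    n_replicates: int = 3
    induced_fraction: float = 0.10
    induced_log2fc: float = 2.5
    fraction_effect_direction: str = "short_first"
    normalized_sampling: bool = True
    expr_log_mu: float = math.log(30.0)  # baseline expression (relative units)
    expr_log_sigma: float = 1.3
    seed: int = 0

    @property
    def effective_lesion_rate(self) -> float:
        return self.lesion_rate * self.dose / self.reference_dose

    @property
    def lesions_per_megabase(self) -> float:
        return self.lesion_rate * 1e6

    def validate(self) -> "SimConfig":
        for bt in BIOTYPES:
            if self.n_genes.get(bt, 0) < 0:
                raise ValueError(f"n_genes[{bt}] must be >= 0")
            if self.length_log_sigma.get(bt, 1.0) <= 0:
                raise ValueError("length_log_sigma must be > 0")
            p = self.exon_count_p.get(bt, 0.5)
            if not (0 < p <= 1):
                raise ValueError("exon_count_p must lie in (0, 1]")
        if self.lesion_rate < 0:
            raise ValueError("lesion_rate must be >= 0")
        if self.proximal_window < 0 or self.repair_halflife <= 0:
            raise ValueError("proximal_window >= 0 and repair_halflife > 0 required")
        tps = self.timepoints
        if len(tps) < 2 or tps[0] != 0 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing and start at 0")
        if self.mrna_decay_rate < 0:
            raise ValueError("mrna_decay_rate must be >= 0")
        if not (0 < self.export_fraction <= 1):
            raise ValueError("export_fraction must lie in (0, 1]")
        if any(v < 0 for v in self.chromatin_retention.values()):
            raise ValueError("chromatin_retention must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0 <= self.induced_fraction <= 1):
            raise ValueError("induced_fraction must lie in [0, 1]")
        if self.fraction_effect_direction not in ("short_first", "long_first"):
            raise ValueError("fraction_effect_direction must be short_first or long_first")
        return self


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one gene.

    Lesion kinetics (``unrepaired_count``, ``activity``) are indexed by hours
    *after exposure*; the 0 h entry is the instant after irradiation, whereas
    the 0 h *library* is harvested untreated, so expected means at 0 h use
    activity 1. ``labels`` holds the per-fraction truth class obtained by
    applying the recovery rule to the expected-mean log2 effects; ``effects``
    holds those log2 effects at the post-UV timepoints.
    """

    gene_id: str
    lesion_offsets: tuple[float, ...]
    unrepaired_count: dict[float, int]
    activity: dict[float, float]
    expected_mean: dict[str, tuple[float, ...]]  # fraction -> mean per timepoint
    effects: dict[str, tuple[float, ...]]  # fraction -> log2FC per post-UV timepoint
    labels: dict[str, str]  # fraction -> truth class
    induced: bool
    baseline: float


# ---------------------------------------------------------------------------
# annotation generation
# ---------------------------------------------------------------------------


def _build_exons(rng: np.random.Generator, span: int, k: int, mean_len: float
                 ) -> tuple[tuple[int, int], ...]:
    """Place k disjoint exons inside a span of the given length (offset 1)."""
    if k <= 1:
        return ((1, span),)
    sigma = 0.5
    lengths = rng.lognormal(math.log(mean_len) - sigma**2 / 2, sigma, size=k)
    lengths = np.maximum(np.round(lengths).astype(int), 10)
    total = int(lengths.sum())
    max_exonic = span - (k - 1)  # need >=1 nt per intron
    if total > max_exonic:
        lengths = np.maximum((lengths * (max_exonic / total)).astype(int), 1)
        while lengths.sum() > max_exonic:  # trim rounding overshoot
            lengths[int(np.argmax(lengths))] -= 1
    intron_total = span - int(lengths.sum())
    # composition of intron_total into k-1 parts, each >= 1
    cuts = rng.multinomial(intron_total - (k - 1), np.full(k - 1, 1.0 / (k - 1)))
    introns = cuts + 1
    exons = []
    pos = 1
    for i in range(k):
        exons.append((pos, pos + int(lengths[i]) - 1))
        pos += int(lengths[i])
        if i < k - 1:
            pos += int(introns[i])
    # last exon must close the span exactly
    exons[-1] = (exons[-1][0], span)
    return tuple(exons)


def generate_gene_models(config: SimConfig, rng_seed: int | None = None) -> list[GeneModel]:
    """Draw the synthetic annotation.

    Per biotype: genomic spans log-normal, exon counts geometric (mean 1/p),
    exon lengths log-normal around the biotype mean, CDS lengths (mRNA only)
    log-normal with median ~1.3 kb clipped to the transcript. Deterministic
    for a given seed, and per-gene streams keep earlier genes' draws stable
    when gene counts grow.
    """
    config.validate()
    seed = config.seed if rng_seed is None else rng_seed
    models: list[GeneModel] = []
    for bi, biotype in enumerate(BIOTYPES):
        n = config.n_genes.get(biotype, 0)
        if n == 0:
            continue
        mu = config.length_log_mu[biotype]
        sigma = config.length_log_sigma[biotype]
        p = config.exon_count_p[biotype]
        mean_exon = config.mean_exon_length[biotype]
        for j in range(n):
            rng = _stream(seed, _D_GENES, bi, j)
            span = int(round(rng.lognormal(mu, sigma)))
            span = min(max(span, 200), 2_500_000)
            k = int(rng.geometric(p))
            k = min(k, max(1, span // 300))
            exon_offsets = _build_exons(rng, span, k, mean_exon)
            tx_start = int(rng.integers(1, 200_000_000))
            exons = tuple((tx_start + s - 1, tx_start + e - 1) for s, e in exon_offsets)
            tx_length = sum(e - s + 1 for s, e in exons)
            cds = 0
            if biotype == "mRNA":
                cds = int(round(rng.lognormal(math.log(1300.0), 0.8)))
                cds = 3 * max(1, min(cds, tx_length) // 3)
            models.append(
                GeneModel(
                    gene_id=f"{biotype}_{j:05d}",
                    biotype=biotype,
                    chrom=f"chr{1 + (j % 20)}",
                    strand="+" if rng.random() < 0.5 else "-",
                    tx_start=tx_start,
                    tx_end=tx_start + span - 1,
                    exons=exons,
                    cds_length=cds,
                )
            )
    return models


# ---------------------------------------------------------------------------
# lesions, repair, elongation
# ---------------------------------------------------------------------------


def place_lesions(
    gene: GeneModel, lesion_rate: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Poisson lesion placement on the genomic template.

    The lesion count is Poisson(rate x template_span); positions are uniform
    offsets (nt from the TSS) on [0, template_span), returned sorted.
    """
    if lesion_rate < 0:
        raise ValueError("lesion_rate must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = int(rng.poisson(lesion_rate * gene.template_span))
    return np.sort(rng.uniform(0.0, gene.template_span, size=n))


def transcription_activity(
    gene: GeneModel,
    lesions: Sequence[float] | np.ndarray,
    t: float,
    config: SimConfig,
    repair_times: Sequence[float] | np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Fraction of the template transcribed t hours after exposure.

    Each lesion is repaired by time ``t`` with probability
    1 - exp(-ln2 * t / repair_halflife). Elongation proceeds up to the first
    unrepaired lesion, but the promoter-proximal window stays productive:
    activity = min(D, span)/span with D = max(proximal_window, first
    unrepaired offset), or D = span when no lesion remains.

    Passing ``repair_times`` (one repair time per lesion; ``inf`` = never
    repaired) makes the call deterministic and monotone in ``t``; otherwise
    repair is drawn from ``rng``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    lesions = np.asarray(lesions, dtype=float)
    if repair_times is None:
        if lesions.size and rng is None:
            raise ValueError("provide repair_times or an rng")
        repair_times = _repair_times(lesions.size, config.repair_halflife, rng)
    repair_times = np.asarray(repair_times, dtype=float)
    unrepaired = lesions[repair_times > t]
    span = gene.template_span
    if unrepaired.size == 0:
        return 1.0
    d = max(float(config.proximal_window), float(unrepaired.min()))
    return min(d, span) / span


def _repair_times(n: int, halflife: float, rng: np.random.Generator | None) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if math.isinf(halflife):
        return np.full(n, math.inf)
    assert rng is not None
    return rng.exponential(halflife / LN2, size=n)


def cytoplasm_trajectory(
    m0: float,
    synthesis: Sequence[float],
    delta: float,
    timepoints: Sequence[float],
) -> np.ndarray:
    """First-order cytoplasmic accumulation across the sampled timepoints.

    ``synthesis[i]`` is the exported synthesis rate at timepoint ``i`` (index
    0 = immediately post-exposure); the interval-mean rate is the trapezoid of
    the two endpoints. With decay rate ``delta``:

        M(t+dt) = M(t) e^(-delta dt) + (s_bar/delta)(1 - e^(-delta dt)),

    and the delta -> 0 limit M(t) + s_bar*dt.
    """
    tps = list(timepoints)
    if len(synthesis) != len(tps):
        raise ValueError("synthesis must align with timepoints")
    out = np.empty(len(tps))
    out[0] = m0
    for i in range(len(tps) - 1):
        dt = tps[i + 1] - tps[i]
        s_bar = 0.5 * (synthesis[i] + synthesis[i + 1])
        if delta > 0:
            decay = math.exp(-delta * dt)
            out[i + 1] = out[i] * decay + (s_bar / delta) * (1.0 - decay)
        else:
            out[i + 1] = out[i] + s_bar * dt
    return out


def _status(effect: float) -> str:
    if effect <= -1.0:
        return "down"
    if effect >= 1.0:
        return "up"
    return "ns"


def simulate_truth(models: Sequence[GeneModel], config: SimConfig) -> list[TruthRecord]:
    """Lesion configurations, kinetics, expected means and truth labels.

    The truth label per fraction applies the recovery rule to the *expected*
    (noise-free) log2 effects versus the untreated baseline, using the same
    status thresholds (|log2FC| >= 1) as the downstream DE caller.
    """
    config.validate()
    rate = config.effective_lesion_rate
    tps = config.timepoints
    post = [t for t in tps if t > 0]
    records: list[TruthRecord] = []
    for i, gene in enumerate(models):
        rng = _stream(config.seed, _D_LESIONS, i)
        lesions = place_lesions(gene, rate, rng)
        halflife = config.repair_halflife
        if (
            config.fraction_effect_direction == "long_first"
            and gene.biotype in NONCODING_BIOTYPES
        ):
            halflife = config.repair_halflife * config.repair_length_scale / gene.template_span
        repair = _repair_times(lesions.size, halflife, rng)
        kin_cfg = replace(config, repair_halflife=halflife)
        unrepaired = {t: int(np.sum(repair > t)) for t in tps}
        activity = {
            t: transcription_activity(gene, lesions, t, kin_cfg, repair_times=repair)
            for t in tps
        }

        erng = _stream(config.seed, _D_EXPR, i)
        baseline = float(erng.lognormal(config.expr_log_mu, config.expr_log_sigma))
        induced = bool(erng.random() < config.induced_fraction)
        fold = 2.0**config.induced_log2fc if induced else 1.0

        retention = config.chromatin_retention.get(gene.biotype, 1.0)
        # the 0 h library is untreated: activity 1, no induction yet
        chr_means = [baseline * retention]
        synth = [baseline * activity[0.0] * config.export_fraction]  # post-exposure
        for t in post:
            chr_means.append(baseline * activity[t] * fold * retention)
            synth.append(baseline * activity[t] * fold * config.export_fraction)
        delta = config.mrna_decay_rate
        m0 = baseline * config.export_fraction / delta if delta > 0 else (
            baseline * config.export_fraction * 24.0
        )
        cyt_means = cytoplasm_trajectory(m0, synth, delta, tps)

        expected = {
            "chromatin": tuple(float(x) for x in chr_means),
            "cytoplasm": tuple(float(x) for x in cyt_means),
        }
        effects: dict[str, tuple[float, ...]] = {}
        labels: dict[str, str] = {}
        for frac in FRACTIONS:
            means = expected[frac]
            eff = tuple(
                math.log2(means[k + 1] / means[0]) for k in range(len(post))
            )
            effects[frac] = eff
            if post == list(POST_UV_TIMEPOINTS):
                raw = label_statuses([_status(e) for e in eff])[0]
            else:  # non-default designs carry no label
                raw = "other"
            labels[frac] = {
                "recovered": "repressed_recovered",
                "not_recovered": "repressed_not_recovered",
            }.get(raw, raw)
        records.append(
            TruthRecord(
                gene_id=gene.gene_id,
                lesion_offsets=tuple(float(x) for x in lesions),
                unrepaired_count=unrepaired,
                activity={t: float(a) for t, a in activity.items()},
                expected_mean=expected,
                effects=effects,
                labels=labels,
                induced=induced,
                baseline=baseline,
            )
        )
    return records


# ---------------------------------------------------------------------------
# count sampling
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB counts with variance mu + alpha*mu^2 (Poisson when alpha == 0)."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def sample_id(fraction: str, timepoint: float, replicate: int) -> str:
    return f"{fraction}_t{timepoint:g}_r{replicate}"


def simulate_counts(
    models: Sequence[GeneModel],
    truths: Sequence[TruthRecord],
    config: SimConfig,
    rng_seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Draw the genes x samples count matrix plus its sample design.

    Per sample, expected relative means are rescaled to ``library_size``
    (when ``normalized_sampling``) and counts drawn NB with dispersion
    ``nb_dispersion``; replicates are i.i.d. Returns (counts, gene lengths
    used for FPKM, design). Counts are drawn from per-gene streams, so the
    matrix is deterministic given the seed and stable under appending genes.
    """
    if len(models) != len(truths):
        raise ValueError("models and truths must align one-to-one")
    config.validate()
    seed = config.seed if rng_seed is None else rng_seed
    tps = config.timepoints
    design_rows = []
    for frac in FRACTIONS:
        for t in tps:
            for rep in range(1, config.n_replicates + 1):
                design_rows.append((sample_id(frac, t, rep), frac, t, rep))
    design = pd.DataFrame(
        design_rows, columns=["sample_id", "fraction", "timepoint", "replicate"]
    )

    gene_ids = [g.gene_id for g in models]
    n_genes, n_samples = len(models), len(design)
    rel = np.empty((n_genes, n_samples))
    tp_index = {t: k for k, t in enumerate(tps)}
    for gi, truth in enumerate(truths):
        for si, (_, frac, t, _rep) in enumerate(design.itertuples(index=False)):
            rel[gi, si] = truth.expected_mean[frac][tp_index[t]]

    if config.normalized_sampling:
        totals = rel.sum(axis=0)
        totals[totals == 0] = 1.0
        mu = rel / totals * config.library_size
    else:
        # unnormalised: scale relative units so the untreated chromatin library
        # hits library_size; global activity loss then shows up as depth loss
        ref_col = next(
            si
            for si, (_, frac, t, _rep) in enumerate(design.itertuples(index=False))
            if frac == "chromatin" and t == 0
        )
        mu = rel * (config.library_size / rel[:, ref_col].sum())

    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    for gi in range(n_genes):
        rng = _stream(seed, _D_COUNTS, gi)
        counts[gi] = _nb_draw(rng, mu[gi], config.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=design["sample_id"].tolist())
    lengths = pd.Series(
        [g.tx_length for g in models], index=counts_df.index, name="tx_length"
    )
    return counts_df, lengths, design


def simulate_experiment(
    config: SimConfig,
) -> tuple[list[GeneModel], list[TruthRecord], pd.DataFrame, pd.Series, pd.DataFrame]:
    """Annotation -> truth -> counts in one call (all from ``config.seed``)."""
    models = generate_gene_models(config)
    truths = simulate_truth(models, config)
    counts, lengths, design = simulate_counts(models, truths, config)
    return models, truths, counts, lengths, design


def strong_effect_mask(
    truths: Sequence[TruthRecord],
    fraction: str = "chromatin",
    min_abs: float = 2.0,
    null_max: float = 0.25,
) -> np.ndarray:
    """Genes whose truth pattern is unambiguous at the stated effect size.

    True iff every non-ns truth status has |log2 effect| >= ``min_abs`` and
    every ns status has |log2 effect| <= ``null_max``; used to evaluate
    classifier accuracy away from the decision boundary.
    """
    mask = np.zeros(len(truths), dtype=bool)
    for i, tr in enumerate(truths):
        ok = True
        for e in tr.effects[fraction]:
            if _status(e) == "ns":
                ok &= abs(e) <= null_max
            else:
                ok &= abs(e) >= min_abs
        mask[i] = ok
    return mask


def random_transcript_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform-composition sense-strand nucleotide sequence."""
    return "".join(rng.choice(list("ACGT"), size=length))


# ---------------------------------------------------------------------------
# fixture I/O (GTF + TSV round trip)
# ---------------------------------------------------------------------------


def write_gtf(models: Iterable[GeneModel], path: Path | str) -> None:
    """GTF 2.2: one gene record plus one record per exon, 1-based closed."""
    path = Path(path)
    with path.open("w") as fh:
        for g in models:
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                f'gene_biotype "{g.biotype}"; cds_length "{g.cds_length}";'
            )
            fh.write(
                f"{g.chrom}\tuvfrac\tgene\t{g.tx_start}\t{g.tx_end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tuvfrac\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: Path | str) -> list[GeneModel]:
    """Parse a GTF written by :func:`write_gtf` back into gene models."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = sorted(
            (f.start, f.end)
            for f in db.features_of_type("exon")
            if f.attributes["gene_id"][0] == gene.attributes["gene_id"][0]
        )
        models.append(
            GeneModel(
                gene_id=gene.attributes["gene_id"][0],
                biotype=gene.attributes["gene_biotype"][0],
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in ("+", "-") else ".",
                tx_start=gene.start,
                tx_end=gene.end,
                exons=tuple(exons),
                cds_length=int(gene.attributes["cds_length"][0]),
            )
        )
    models.sort(key=lambda g: g.gene_id)
    return models


def write_fixtures(
    models: Sequence[GeneModel],
    counts: pd.DataFrame,
    design: pd.DataFrame,
    truths: Sequence[TruthRecord],
    out_dir: Path | str,
) -> dict[str, Path]:
    """Emit annotation.gtf, counts.tsv, design.tsv, truth.tsv.

    All tables are UTF-8 TSV without quoting; reading them back reproduces
    the in-memory objects exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": out / "annotation.gtf",
        "counts": out / "counts.tsv",
        "design": out / "design.tsv",
        "truth": out / "truth.tsv",
    }
    write_gtf(models, paths["gtf"])
    counts.to_csv(paths["counts"], sep="\t")
    design.to_csv(paths["design"], sep="\t", index=False)

    tps = sorted(truths[0].activity) if truths else []
    rows = []
    for tr in truths:
        row: dict[str, object] = {
            "gene_id": tr.gene_id,
            "induced": int(tr.induced),
            "baseline": repr(tr.baseline),
            "lesion_offsets": ",".join(repr(x) for x in tr.lesion_offsets),
        }
        for t in tps:
            row[f"unrepaired_{t:g}h"] = tr.unrepaired_count[t]
            row[f"activity_{t:g}h"] = repr(tr.activity[t])
        for frac in FRACTIONS:
            row[f"label_{frac}"] = tr.labels[frac]
            for k, t in enumerate(tps):
                row[f"mean_{frac}_{t:g}h"] = repr(tr.expected_mean[frac][k])
            for k, t in enumerate(t2 for t2 in tps if t2 > 0):
                row[f"log2fc_{frac}_{t:g}h"] = repr(tr.effects[frac][k])
        rows.append(row)
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_counts(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return df.astype(np.int64)


def read_design(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["timepoint"] = df["timepoint"].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    return df


def read_truth(path: Path | str) -> list[TruthRecord]:
    df = pd.read_csv(
        path, sep="\t", keep_default_na=False, float_precision="round_trip"
    )
    tps = sorted(
        float(c[len("activity_"):-1]) for c in df.columns if c.startswith("activity_")
    )
    post = [t for t in tps if t > 0]
    records = []
    for _, row in df.iterrows():
        offsets = (
            tuple(float(x) for x in str(row["lesion_offsets"]).split(","))
            if str(row["lesion_offsets"])
            else ()
        )
        expected = {}
        effects = {}
        labels = {}
        for frac in FRACTIONS:
            expected[frac] = tuple(float(row[f"mean_{frac}_{t:g}h"]) for t in tps)
            effects[frac] = tuple(float(row[f"log2fc_{frac}_{t:g}h"]) for t in post)
            labels[frac] = row[f"label_{frac}"]
        records.append(
            TruthRecord(
                gene_id=row["gene_id"],
                lesion_offsets=offsets,
                unrepaired_count={t: int(row[f"unrepaired_{t:g}h"]) for t in tps},
                activity={t: float(row[f"activity_{t:g}h"]) for t in tps},
                expected_mean=expected,
                effects=effects,
                labels=labels,
                induced=bool(int(row["induced"])),
                baseline=float(row["baseline"]),
            )
        )
    return records
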