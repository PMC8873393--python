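"""Generator contracts: annotation, lesion placement, kinetics, counts, I/O."""

import math

import numpy as np
import pytest

from conftest import make_gene
from uvfrac import SimConfig, simulate_experiment
from uvfrac.simdata import (
    cytoplasm_trajectory,
    generate_gene_models,
    place_lesions,
    read_counts,
    read_design,
    read_gtf,
    read_truth,
    simulate_counts,
    simulate_truth,
    transcription_activity,
    write_fixtures,
    write_gtf,
)


def _empty_counts():
    return {"mRNA": 0, "annotated_lncRNA": 0, "novel_lncRNA": 0, "TUCP": 0}


class TestGenerateGeneModels:
    def test_empty_config_yields_no_genes(self):
        cfg = SimConfig(n_genes=_empty_counts())
        assert generate_gene_models(cfg) == []

    def test_requested_counts_and_invariants(self, small_config, small_experiment):
        models = small_experiment[0]
        by_biotype = {}
        for g in models:
            by_biotype[g.biotype] = by_biotype.get(g.biotype, 0) + 1
            assert g.tx_length <= g.template_span
            assert g.cds_length <= g.tx_length
            assert (g.biotype == "mRNA") or g.cds_length == 0
            assert g.intron_count == len(g.exons) - 1 >= 0
            assert g.exons[0][0] == g.tx_start and g.exons[-1][1] == g.tx_end
            for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
                assert e1 < s2  # sorted and disjoint
        assert by_biotype == small_config.n_genes

    def test_same_seed_reproduces_models(self, small_config):
        assert generate_gene_models(small_config) == generate_gene_models(small_config)

    def test_lognormal_span_mean_matches_closed_form(self):
        mu, sigma = math.log(8_000.0), 0.6
        cfg = SimConfig(
            n_genes={**_empty_counts(), "mRNA": 10_000},
            length_log_mu={"mRNA": mu},
            length_log_sigma={"mRNA": sigma},
            seed=21,
        )
        spans = np.array([g.template_span for g in generate_gene_models(cfg)], float)
        expected_mean = math.exp(mu + sigma**2 / 2)
        expected_sd = expected_mean * math.sqrt(math.exp(sigma**2) - 1.0)
        se = expected_sd / math.sqrt(len(spans))
        assert abs(spans.mean() - expected_mean) < 3 * se

    def test_invalid_sigma_rejected(self):
        cfg = SimConfig(length_log_sigma={"mRNA": -1.0})
        with pytest.raises(ValueError):
            generate_gene_models(cfg)


class TestPlaceLesions:
    def test_zero_rate_places_nothing(self, rng):
        gene = make_gene(span=100_000)
        assert place_lesions(gene, 0.0, rng).size == 0

    def test_rate_on_megabase_template_averages_five_hundred(self, rng):
        gene = make_gene(span=1_000_000)
        counts = [place_lesions(gene, 5e-4, rng).size for _ in range(10_000)]
        se = math.sqrt(500.0 / 10_000)
        assert abs(np.mean(counts) - 500.0) < 3 * se

    def test_poisson_mean_on_small_template(self, rng):
        gene = make_gene(span=2_000)
        counts = np.array([place_lesions(gene, 5e-4, rng).size for _ in range(100_000)])
        se = math.sqrt(1.0 / 100_000)
        assert abs(counts.mean() - 1.0) < 3 * se

    def test_offsets_sorted_and_in_range(self, rng):
        gene = make_gene(span=50_000)
        offsets = place_lesions(gene, 1e-3, rng)
        assert (np.diff(offsets) >= 0).all()
        assert ((offsets >= 0) & (offsets < gene.template_span)).all()

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            place_lesions(make_gene(), -1e-4, rng)


class TestTranscriptionActivity:
    def test_lesion_free_gene_fully_active(self):
        cfg = SimConfig()
        gene = make_gene(span=80_000)
        for t in (0.0, 0.5, 3.0, 24.0):
            assert transcription_activity(gene, [], t, cfg) == 1.0

    def test_repair_completes_at_long_times(self, rng):
        cfg = SimConfig(repair_halflife=1.0)
        gene = make_gene(span=200_000)
        lesions = place_lesions(gene, 5e-4, rng)
        assert transcription_activity(gene, lesions, 1e6, cfg, rng=rng) == 1.0

    def test_unrepairable_midpoint_lesion_halves_activity(self):
        cfg = SimConfig(proximal_window=25_000)
        gene = make_gene(span=100_000)
        act = transcription_activity(
            gene, [50_000.0], t=3.0, config=cfg, repair_times=[math.inf]
        )
        assert act == pytest.approx(0.5)

    def test_proximal_window_floors_activity(self):
        cfg = SimConfig(proximal_window=25_000)
        gene = make_gene(span=100_000)
        act = transcription_activity(
            gene, [100.0], t=0.0, config=cfg, repair_times=[math.inf]
        )
        assert act == pytest.approx(0.25)  # window/span floor

    def test_monotone_in_lesion_rate(self):
        # higher rate (superset of lesions via thinning) never raises activity
        cfg = SimConfig()
        gene = make_gene(span=150_000)
        rng = np.random.default_rng(7)
        dense = place_lesions(gene, 1e-3, rng)
        repair = rng.exponential(cfg.repair_halflife / math.log(2), size=dense.size)
        keep = rng.random(dense.size) < 0.5  # thinned = lower-rate subset
        for t in (0.0, 0.5, 3.0, 24.0):
            a_dense = transcription_activity(gene, dense, t, cfg, repair_times=repair)
            a_thin = transcription_activity(
                gene, dense[keep], t, cfg, repair_times=repair[keep]
            )
            assert a_dense <= a_thin


class TestTruth:
    def test_unrepaired_counts_non_increasing_and_activity_consistent(
        self, small_experiment, small_config
    ):
        truths = small_experiment[1]
        tps = small_config.timepoints
        for tr in truths:
            counts = [tr.unrepaired_count[t] for t in tps]
            assert all(a >= b for a, b in zip(counts, counts[1:]))
            for t in tps:
                if tr.unrepaired_count[t] == 0:
                    assert tr.activity[t] == 1.0

    def test_zero_lesion_config_labels_everything_unchanged_or_induced(self):
        cfg = SimConfig(
            n_genes={**_empty_counts(), "mRNA": 300},
            lesion_rate=0.0,
            seed=2,
        )
        truths = simulate_truth(generate_gene_models(cfg), cfg)
        for tr in truths:
            assert all(a == 1.0 for a in tr.activity.values())
            assert tr.labels["chromatin"] in ("unchanged", "induced")

    def test_lesion_incidence_follows_span(self):
        # P(>=1 lesion) = 1 - exp(-rate * span), increasing in span
        cfg = SimConfig(
            n_genes={**_empty_counts(), "mRNA": 10_000}, seed=4, induced_fraction=0.0
        )
        models = generate_gene_models(cfg)
        truths = simulate_truth(models, cfg)
        spans = np.array([g.template_span for g in models], float)
        hit = np.array([len(t.lesion_offsets) > 0 for t in truths], float)
        edges = np.quantile(spans, [0, 0.25, 0.5, 0.75, 1.0])
        for lo, hi in zip(edges, edges[1:]):
            sel = (spans >= lo) & (spans <= hi)
            p_expected = float(np.mean(1.0 - np.exp(-cfg.lesion_rate * spans[sel])))
            p_obs = float(hit[sel].mean())
            se = math.sqrt(p_expected * (1 - p_expected) / sel.sum()) + 1e-9
            assert abs(p_obs - p_expected) < 4 * se


class TestCytoplasmKinetics:
    def test_pure_decay_matches_closed_form(self):
        delta, m0 = 0.4, 100.0
        traj = cytoplasm_trajectory(m0, [0, 0, 0, 0], delta, [0.0, 0.5, 3.0, 24.0])
        assert traj[2] == pytest.approx(m0 * math.exp(-delta * 3.0))

    def test_zero_decay_limit_accumulates_linearly(self):
        traj = cytoplasm_trajectory(5.0, [2.0, 2.0], 0.0, [0.0, 3.0])
        assert traj[1] == pytest.approx(5.0 + 2.0 * 3.0)

    def test_steady_state_is_fixed_point(self):
        delta, s = 0.25, 10.0
        traj = cytoplasm_trajectory(s / delta, [s, s, s, s], delta, [0, 0.5, 3, 24])
        assert np.allclose(traj, s / delta)


class TestSimulateCounts:
    def test_same_seed_gives_identical_matrices(self, small_config, small_experiment):
        models, truths = small_experiment[0], small_experiment[1]
        c1, _, _ = simulate_counts(models, truths, small_config, rng_seed=77)
        c2, _, _ = simulate_counts(models, truths, small_config, rng_seed=77)
        assert c1.equals(c2)

    def test_library_size_conservation(self):
        # with Poisson noise (alpha = 0) normalized sampling conserves depth
        # to multinomial accuracy
        cfg = SimConfig(
            n_genes={"mRNA": 150, "annotated_lncRNA": 40, "novel_lncRNA": 40, "TUCP": 20},
            nb_dispersion=0.0,
            library_size=200_000,
            seed=8,
        )
        _, _, counts, _, _ = simulate_experiment(cfg)
        totals = counts.sum(axis=0).to_numpy(float)
        tol = 5 * math.sqrt(cfg.library_size)
        assert (np.abs(totals - cfg.library_size) < tol).all()

    def test_nb_mean_variance_relationship(self):
        # var = mu + alpha mu^2: regress (var - mu) on mu^2 across genes
        alpha = 0.05
        cfg = SimConfig(
            n_genes={**_empty_counts(), "mRNA": 1_500},
            timepoints=(0.0, 0.5),
            n_replicates=30,
            nb_dispersion=alpha,
            lesion_rate=0.0,
            induced_fraction=0.0,
            library_size=1_000_000,
            seed=13,
        )
        models, truths, counts, _, design = simulate_experiment(cfg)
        cols = design.loc[
            (design.fraction == "chromatin") & (design.timepoint == 0), "sample_id"
        ]
        x = counts[cols].to_numpy(float)
        mu = x.mean(axis=1)
        var = x.var(axis=1, ddof=1)
        sel = mu > 200
        # robust per-gene slope of (var - mu) on mu^2
        slope = float(np.median((var - mu)[sel] / mu[sel] ** 2))
        assert abs(slope - alpha) / alpha < 0.10

    def test_misaligned_truths_rejected(self, small_experiment, small_config):
        models, truths = small_experiment[0], small_experiment[1]
        with pytest.raises(ValueError):
            simulate_counts(models, truths[:-1], small_config)


class TestFixtureIO:
    def test_round_trip_identity(self, tmp_path):
        cfg = SimConfig(
            n_genes={"mRNA": 6, "annotated_lncRNA": 2, "novel_lncRNA": 1, "TUCP": 1},
            library_size=50_000,
            seed=5,
        )
        models, truths, counts, _, design = simulate_experiment(cfg)
        paths = write_fixtures(models, counts, design, truths, tmp_path)
        assert read_gtf(paths["gtf"]) == sorted(models, key=lambda g: g.gene_id)
        assert read_counts(paths["counts"]).equals(counts)
        assert read_design(paths["design"]).equals(design)
        assert read_truth(paths["truth"]) == truths

    def test_gtf_record_count(self, tmp_path):
        cfg = SimConfig(
            n_genes={"mRNA": 8, "annotated_lncRNA": 3, "novel_lncRNA": 2, "TUCP": 1},
            seed=6,
        )
        models = generate_gene_models(cfg)
        path = tmp_path / "ann.gtf"
        write_gtf(models, path)
        n_lines = sum(1 for _ in path.open())
        assert n_lines == len(models) + sum(len(g.exons) for g in models)

    def test_unknown_strand_survives_round_trip(self, tmp_path):
        gene = make_gene(span=400, strand=".", biotype="novel_lncRNA")
        path = tmp_path / "one.gtf"
        write_gtf([gene], path)
        line = path.read_text().splitlines()[0]
        assert line.split("\t")[6] == "."
        assert read_gtf(path) == [gene]
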