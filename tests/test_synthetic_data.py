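import hashlib
from pathlib import Path

import numpy as np
import pytest

from m6a_landscape.data_model_io import read_pileup
from m6a_landscape.site_stats import (
    aggregate_condition,
    classify_isoforms,
    differential_sites,
    filter_sites,
)
from m6a_landscape.synthetic_data import (
    CONDITIONS,
    SyntheticConfig,
    crossing_probability,
    generate_annotation,
    generate_corpus,
    generate_de_and_binding,
    generate_read_level,
    generate_site_counts,
    mean_fraction_distribution,
    simulate_read_level,
)
from m6a_landscape.transcript_annotation import MotifClass, classify_motif


def _hash_dir(d: Path) -> dict:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(d.iterdir())
        if p.is_file()
    }


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SyntheticConfig(n_genes=10, coverage_mean=42.0)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert SyntheticConfig.from_yaml(p) == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SyntheticConfig.from_dict({"nope": 1})

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SyntheticConfig(restoration_fraction=1.5)

    def test_region_minimum(self):
        with pytest.raises(ValueError):
            SyntheticConfig(utr5_len=(2, 10))


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(n_genes=15, hypo_gene_set_size=4,
                              de_down_core_size=3, de_up_core_size=3,
                              de_private_per_line=2, reads_per_transcript=10)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_corpus(cfg, 7, d1)
        generate_corpus(cfg, 7, d2)
        assert _hash_dir(d1) == _hash_dir(d2)

    def test_seed_changes_output(self, tmp_path):
        cfg = SyntheticConfig(n_genes=15, hypo_gene_set_size=4,
                              de_down_core_size=3, de_up_core_size=3,
                              de_private_per_line=2, reads_per_transcript=10)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_corpus(cfg, 7, d1)
        generate_corpus(cfg, 8, d2)
        assert _hash_dir(d1) != _hash_dir(d2)


class TestAnnotationGenerator:
    def test_planted_drach_reclassify(self, small_corpus):
        ann = small_corpus["ann"]
        by_tid = {t.transcript_id: t for t in ann.transcripts}
        for s in ann.sites:
            assert classify_motif(by_tid[s.transcript_id], s.tpos) == s.motif

    def test_drach_density_matches_config(self):
        cfg = SyntheticConfig(n_genes=1000)
        ann = generate_annotation(cfg, 5)
        total_len = sum(t.length for t in ann.transcripts)
        n_drach = sum(1 for s in ann.sites if s.motif is MotifClass.DRACH)
        observed = 1000.0 * n_drach / total_len
        assert observed == pytest.approx(cfg.drach_per_kb, rel=0.10)

    def test_no_stray_adenosines(self, small_corpus):
        # every A in every transcript is a planted site centre
        ann = small_corpus["ann"]
        planted = {(s.transcript_id, s.tpos) for s in ann.sites}
        for t in ann.transcripts:
            for i, base in enumerate(t.sequence):
                if base == "A":
                    assert (t.transcript_id, i) in planted

    def test_levels_in_unit_interval(self, small_corpus):
        for s in small_corpus["ann"].sites:
            for level in s.levels.values():
                assert 0.0 <= level <= 1.0


class TestSiteCounts:
    def test_files_reparse_losslessly(self, small_corpus):
        d = small_corpus["dir"]
        cfg = small_corpus["config"]
        for cond in CONDITIONS:
            for rep in range(1, cfg.replicates + 1):
                path = d / f"pileup_{cond}_rep{rep}.tsv"
                recs = read_pileup(path, f"{cond}_rep{rep}", cond)
                assert len(recs) == len(small_corpus["ann"].sites)

    def test_coverage_moment(self):
        cfg = SyntheticConfig(n_genes=150, coverage_mean=30.0)
        ann = generate_annotation(cfg, 2)
        counts = generate_site_counts(ann, cfg, 2, conditions=("normal",))
        covs = [r.valid_cov for rep in counts["normal"] for r in rep]
        assert np.mean(covs) == pytest.approx(30.0, rel=0.05)

    def test_planted_hyper_delta_recovered(self):
        cfg = SyntheticConfig(
            n_genes=400,
            hyper_gene_fraction=0.5,
            hyper_delta=0.25,
            coverage_mean=50.0,
            p_methylated_drach=0.3,
            meth_beta=(2.0, 4.0),
            hypo_gene_set_size=0,
        )
        ann = generate_annotation(cfg, 9)
        counts = generate_site_counts(ann, cfg, 9, conditions=("normal", "tumor"))
        norm = aggregate_condition([r for rep in counts["normal"] for r in rep])
        tum = aggregate_condition([r for rep in counts["tumor"] for r in rep])
        planted = [s for s in ann.sites if s.is_hyper and s.base_level + 0.25 <= 1.0]
        assert len(planted) >= 500
        deltas = []
        for s in planted:
            if tum[s.key].mean_level is not None and norm[s.key].mean_level is not None:
                deltas.append(tum[s.key].mean_level - norm[s.key].mean_level)
        assert np.mean(deltas) == pytest.approx(0.25, abs=0.03)

    def test_null_calibration_20pct_crossings(self):
        """With zero planted effects, the number of >20% differential calls
        matches the exact binomial null (99% CI via the Poisson-binomial
        normal approximation)."""
        cfg = SyntheticConfig(
            n_genes=250,
            hyper_gene_fraction=0.0,
            hypo_gene_set_size=0,
            coverage_mean=40.0,
        )
        ann = generate_annotation(cfg, 13)
        counts = generate_site_counts(ann, cfg, 13, conditions=("normal", "tumor"))
        a = aggregate_condition([r for rep in counts["tumor"] for r in rep])
        b = aggregate_condition([r for rep in counts["normal"] for r in rep])
        joint = filter_sites(a, b, 20, 0.10)
        _, _, overall = differential_sites(joint, a, b)
        observed = overall.n_up_20 + overall.n_dn_20

        covs_a = {
            key: [r.valid_cov for rep in counts["tumor"] for r in rep if r.key == key]
            for key in joint
        }
        covs_b = {
            key: [r.valid_cov for rep in counts["normal"] for r in rep if r.key == key]
            for key in joint
        }
        truth = {s.key: s.levels["normal"] for s in ann.sites}
        ps = [
            crossing_probability(truth[k], covs_a[k], truth[k], covs_b[k], 0.20)
            for k in joint
        ]
        mean = sum(ps)
        sd = float(np.sqrt(sum(p * (1 - p) for p in ps)))
        assert mean - 2.576 * sd - 1 <= observed <= mean + 2.576 * sd + 1


class TestReadLevel:
    def test_single_site_binomial(self):
        rng = np.random.default_rng(0)
        recs = simulate_read_level([0.8], 10000, rng, "t1")
        frac = sum(1 for r in recs if r.n_mod >= 1) / len(recs)
        assert frac == pytest.approx(0.80, abs=0.012)  # 3 sigma ~ 0.012

    def test_two_sites_union_probability(self):
        rng = np.random.default_rng(1)
        recs = simulate_read_level([0.5, 0.5], 10000, rng, "t1")
        frac = sum(1 for r in recs if r.n_mod >= 1) / len(recs)
        assert frac == pytest.approx(0.75, abs=0.015)

    def test_all_zero_sites_low_class(self):
        rng = np.random.default_rng(2)
        recs = simulate_read_level([0.0, 0.0], 50, rng, "t1")
        (p,), _, _ = classify_isoforms(recs)
        assert p.level == 0.0
        assert p.iso_class.value == "LOW"

    def test_generate_read_level_covers_all_transcripts(self, small_corpus):
        ann = small_corpus["ann"]
        cfg = small_corpus["config"]
        recs = generate_read_level(ann, cfg, 11)
        tids = {r.transcript_id for r in recs}
        assert tids == {t.transcript_id for t in ann.transcripts}


class TestDEAndBinding:
    def test_core_sizes(self, small_corpus):
        ann = small_corpus["ann"]
        cfg = small_corpus["config"]
        tables, intervals, truth = generate_de_and_binding(ann, cfg, 11)
        assert len(truth["down_core"]) == cfg.de_down_core_size
        assert len(truth["up_core"]) == cfg.de_up_core_size
        assert set(tables) == set(cfg.de_lines)

    def test_seed_changes_private_but_not_core_structure(self, small_corpus):
        ann = small_corpus["ann"]
        cfg = small_corpus["config"]
        _, _, t1 = generate_de_and_binding(ann, cfg, 11)
        _, _, t2 = generate_de_and_binding(ann, cfg, 12)
        # cores are drawn from the same annotation-stage hypo set and stay
        # inside it; the per-line private sets move with the seed
        assert set(t1["down_core"]) <= small_corpus["ann"].hypo_genes
        assert set(t2["down_core"]) <= small_corpus["ann"].hypo_genes
        assert t1["private"] != t2["private"]


class TestAnalyticHelpers:
    def test_mean_fraction_distribution_sums_to_one(self):
        vals, probs = mean_fraction_distribution(0.3, [10, 15])
        assert probs.sum() == pytest.approx(1.0)
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_crossing_probability_against_monte_carlo(self):
        rng = np.random.default_rng(4)
        level, covs, thr = 0.4, [30, 50], 0.2
        n = 200_000
        fa = (rng.binomial(covs[0], level, n) / covs[0] + rng.binomial(covs[1], level, n) / covs[1]) / 2
        fb = (rng.binomial(covs[0], level, n) / covs[0] + rng.binomial(covs[1], level, n) / covs[1]) / 2
        mc = np.mean(np.abs(fa - fb) > thr)
        exact = crossing_probability(level, covs, level, covs, thr)
        assert exact == pytest.approx(mc, abs=4 * np.sqrt(mc * (1 - mc) / n) + 1e-4)

    def test_crossing_probability_one_sided(self):
        p2 = crossing_probability(0.4, [40], 0.4, [40], 0.1)
        p1 = crossing_probability(0.4, [40], 0.4, [40], 0.1, two_sided=False)
        assert p1 <= p2
        assert p2 == pytest.approx(2 * p1, rel=1e-9)  # symmetric case
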