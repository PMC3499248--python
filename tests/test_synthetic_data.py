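import numpy as np
import pytest

import generosion as g
from generosion.synthetic_data import CATEGORIES

from conftest import small_erosion_config


class TestGenerateAncestral:
    def test_orfs_are_clean_reading_frames(self):
        cfg = small_erosion_config(1, n_genes=40)
        genome = g.generate_ancestral(cfg)
        assert len(genome.orfs) == 40
        for orf in genome.orfs:
            assert orf.sequence.startswith("ATG")
            assert orf.sequence[-3:] in {"TAA", "TAG", "TGA"}
            assert orf.length % 3 == 0
            _, stops = g.translate_frame(orf.sequence)
            assert stops == []

    def test_same_seed_is_byte_identical_different_seed_differs(self):
        a = g.generate_ancestral(small_erosion_config(5))
        b = g.generate_ancestral(small_erosion_config(5))
        c = g.generate_ancestral(small_erosion_config(6))
        assert a.contigs == b.contigs
        assert a.contigs != c.contigs

    def test_gamma_length_mean_within_3_se(self):
        cfg = g.ErosionConfig(seed=9, n_genes=4000, n_neutral=1, mutation_budget=1)
        genome = g.generate_ancestral(cfg)
        lengths = np.array([o.length for o in genome.orfs], dtype=float)
        se = 950.0 / np.sqrt(2.0) / np.sqrt(4000)
        assert abs(lengths.mean() - 950.0) < 3 * se

    def test_unsatisfiable_length_mean_is_fatal(self):
        with pytest.raises(ValueError, match="unsatisfiable"):
            g.ErosionConfig(seed=0, length_mean=4.0)


class TestErode:
    def test_null_erosion_is_identity(self):
        cfg = small_erosion_config(2, mutation_budget=0, deletion_fraction=0.0)
        ancestral = g.generate_ancestral(cfg)
        derived, truth = g.erode(ancestral, cfg)
        assert derived.contigs == ancestral.contigs
        assert (truth.genes["fate"] == "intact").all()

    def test_saturation_every_neutral_gene_disrupted(self):
        # internal-indel-only mix: terminal deletions and nonsense saturate a
        # gene after a couple of events, interior indels do not, so a large
        # budget drives every neutral gene to at least one disrupting event
        cfg = small_erosion_config(
            3, n_genes=30, n_neutral=30, mutation_budget=300, deletion_fraction=0.0,
            length_shape=1e6,
            category_mix={"internal_insertion": 0.5, "internal_deletion": 0.5},
        )
        ancestral = g.generate_ancestral(cfg)
        _, truth = g.erode(ancestral, cfg)
        assert (truth.genes["fate"] == "pseudogene").all()

    def test_pseudogene_count_matches_binomial_closed_form(self):
        # nonsense-only mix keeps gene lengths constant, making the
        # closed form 1-(1-L_i/sum L)^M exact
        cfg = small_erosion_config(
            4,
            n_genes=600,
            n_neutral=600,
            mutation_budget=500,
            deletion_fraction=0.0,
            category_mix={"nonsense": 1.0},
        )
        ancestral = g.generate_ancestral(cfg)
        _, truth = g.erode(ancestral, cfg)
        L = truth.genes["ancestral_length"].to_numpy(float)
        p = 1.0 - np.power(1.0 - L / L.sum(), cfg.mutation_budget)
        expected = p.sum()
        sd = np.sqrt((p * (1.0 - p)).sum())
        observed = int((truth.genes["fate"] == "pseudogene").sum())
        assert abs(observed - expected) < 3 * sd

    def test_event_category_frequencies_converge_to_mix(self):
        cfg = small_erosion_config(
            7, n_genes=500, n_neutral=400, mutation_budget=2000, deletion_fraction=0.0
        )
        ancestral = g.generate_ancestral(cfg)
        _, truth = g.erode(ancestral, cfg)
        counts = truth.events["category"].value_counts()
        n = len(truth.events)
        assert n == 2000
        for cat in CATEGORIES:
            p = cfg.category_mix[cat]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts.get(cat, 0) / n - p) < 4 * se, cat

    def test_deletion_fraction_realized(self):
        cfg = small_erosion_config(8, deletion_fraction=0.2)
        ancestral = g.generate_ancestral(cfg)
        derived, truth = g.erode(ancestral, cfg)
        n_absent = int((truth.genes["fate"] == "absent").sum())
        assert n_absent == round(0.2 * cfg.n_neutral)
        derived_ids = {o.gene_id for o in derived.orfs}
        for gid in truth.genes.loc[truth.genes["fate"] == "absent", "gene_id"]:
            assert gid not in derived_ids

    def test_non_neutral_genes_never_receive_events(self):
        cfg = small_erosion_config(9)
        ancestral = g.generate_ancestral(cfg)
        _, truth = g.erode(ancestral, cfg)
        neutral = set(truth.genes.loc[truth.genes["is_neutral"], "gene_id"])
        assert set(truth.events["gene_id"]).issubset(neutral)

    def test_empty_is_catalog_with_is_weight_is_fatal(self):
        cfg = small_erosion_config(10, is_catalog=[])
        ancestral = g.generate_ancestral(cfg)
        with pytest.raises(ValueError, match="is_catalog"):
            g.erode(ancestral, cfg)

    def test_same_seed_identical_different_seed_differs(self):
        cfg = small_erosion_config(11)
        ancestral = g.generate_ancestral(cfg)
        d1, t1 = g.erode(ancestral, cfg)
        d2, t2 = g.erode(ancestral, cfg)
        d3, t3 = g.erode(ancestral, small_erosion_config(12, n_genes=300))
        assert d1.contigs == d2.contigs
        assert t1.events.equals(t2.events)
        assert not t1.events.equals(t3.events)

    def test_background_substitution_rate_recovery(self):
        cfg = small_erosion_config(
            13,
            n_genes=400,
            mutation_budget=0,
            deletion_fraction=0.0,
            point_sub_rate_gc4=0.05,
            point_sub_rate_gc2=0.0,
            neutral_gc2_multiplier=1.0,
        )
        ancestral = g.generate_ancestral(cfg)
        _, truth = g.erode(ancestral, cfg)
        sites = g.classify_sites(ancestral)
        n_gc4 = sum(len(v) for v in sites.gc4.values())
        n_subs = int((truth.substitutions["site_class"] == "gc4").sum())
        phat = n_subs / n_gc4
        assert abs(phat - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_gc4)


class TestSizeBias:
    def test_equal_lengths_no_expected_size_difference(self):
        # with a (near-)degenerate length distribution the disrupted and
        # intact neutral classes have equal expected ancestral length
        deltas = []
        for seed in range(15):
            cfg = small_erosion_config(
                100 + seed,
                n_genes=200,
                n_neutral=200,
                mutation_budget=100,
                deletion_fraction=0.0,
                length_shape=1e6,  # variance ~ mean^2/shape -> 0
            )
            ancestral = g.generate_ancestral(cfg)
            _, truth = g.erode(ancestral, cfg)
            tg = truth.genes
            deltas.append(
                tg.loc[tg.fate == "pseudogene", "ancestral_length"].mean()
                - tg.loc[tg.fate == "intact", "ancestral_length"].mean()
            )
        assert abs(np.mean(deltas)) < 3.0  # bases; lengths are ~950 +- <1

    def test_heterogeneous_lengths_disrupted_genes_larger(self):
        cfg = small_erosion_config(200, n_genes=400, n_neutral=300, mutation_budget=200,
                                   deletion_fraction=0.0)
        ancestral = g.generate_ancestral(cfg)
        _, truth = g.erode(ancestral, cfg)
        tg = truth.genes
        delta = (
            tg.loc[tg.fate == "pseudogene", "ancestral_length"].mean()
            - tg.loc[tg.fate == "intact", "ancestral_length"].mean()
        )
        assert delta > 0


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = small_erosion_config(21, category_mix={"IS_insertion": 0.5, "nonsense": 0.5})
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = g.ErosionConfig.from_yaml(path)
        assert back == cfg
        assert back.category_mix["is_element"] == 0.5  # alias normalized

    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sums to"):
            small_erosion_config(0, category_mix={"nonsense": 0.5})

    def test_neutral_cannot_exceed_genes(self):
        with pytest.raises(ValueError):
            small_erosion_config(0, n_genes=10, n_neutral=11)
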