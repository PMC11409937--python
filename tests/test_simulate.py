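"""Generator contracts: packing, determinism, selection model, read emission."""

import numpy as np
import pandas as pd
import pytest

from rbtnfit.counting import extract_barcodes
from rbtnfit.simulate import (
    EffectSpec,
    SimConfig,
    SimConfigError,
    barseq_reads,
    default_growth_scenario,
    make_true_effects,
    simulate_community,
    simulate_genome,
    simulate_growth_assay,
    simulate_library,
    simulate_selection,
)


class TestGenome:
    def test_coding_fraction_within_one_percent(self):
        cfg = SimConfig(genome_length=200_000, n_genes=150, coding_fraction=0.85)
        _, genes = simulate_genome(cfg)
        span = int((genes["end"] - genes["start"]).sum())
        assert 168_300 <= span <= 171_700
        # genes are non-overlapping and sorted
        assert (genes["start"].to_numpy()[1:] >= genes["end"].to_numpy()[:-1]).all()

    def test_single_gene_degenerate_packing(self):
        cfg = SimConfig(genome_length=10_000, n_genes=1, coding_fraction=0.85)
        genome, genes = simulate_genome(cfg)
        assert len(genes) == 1
        assert int(genes["end"][0] - genes["start"][0]) == 8_500
        assert len(genome) == 10_000

    def test_infeasible_packing_raises(self):
        cfg = SimConfig(genome_length=1_000, n_genes=50, coding_fraction=0.5)
        with pytest.raises(SimConfigError):
            simulate_genome(cfg)

    def test_same_seed_byte_identical_files(self, tmp_path):
        from rbtnfit import io as rio

        for sub in ("a", "b"):
            cfg = SimConfig(genome_length=20_000, n_genes=20, seed=42)
            genome, genes = simulate_genome(cfg)
            d = tmp_path / sub
            d.mkdir()
            rio.write_fasta(d / "g.fasta", {"chr1": genome})
            rio.write_gff(d / "g.gff", genes)
        assert (tmp_path / "a/g.fasta").read_bytes() == (tmp_path / "b/g.fasta").read_bytes()
        assert (tmp_path / "a/g.gff").read_bytes() == (tmp_path / "b/g.gff").read_bytes()


class TestLibrary:
    def test_uniform_placement_hits_genes_at_coding_fraction(self):
        cfg = SimConfig(seed=3)
        genome, genes = simulate_genome(cfg)
        pool = simulate_library(genome, genes, cfg)
        in_gene = int(pool["locus_tag"].notna().sum())
        # binomial(10000, 0.85): 4 sigma is ~143
        assert abs(in_gene - 8_500) < 200

    def test_no_chimeras_means_unique_barcodes(self, small_sim):
        assert not small_sim.pool["barcode"].duplicated().any()

    def test_chimera_count_matches_committed_draw(self):
        cfg = SimConfig(
            genome_length=50_000, n_genes=40, n_insertions=2_000,
            chimera_fraction=0.05, seed=11,
        )
        genome, genes = simulate_genome(cfg)
        pool = simulate_library(genome, genes, cfg)
        dup = pool["barcode"].duplicated(keep=False)
        assert pool["chimeric"].sum() == 100  # round(0.05 * 2000)
        assert set(pool.loc[pool["chimeric"], "barcode"]) == set(
            pool.loc[dup & ~pool["chimeric"], "barcode"]
        )


class TestEffects:
    def test_neutral_majority_at_least_80_percent(self, default_sim):
        wide = default_sim.effects.pivot(
            index="locus_tag", columns="condition", values="fitness"
        )
        neutral = (wide == 0).all(axis=1).mean()
        assert neutral >= 0.8

    def test_antagonistic_signs_by_condition(self, default_sim):
        eff = default_sim.effects
        ant = eff[eff["gene_class"] == "antagonistic-pleiotropic"]
        comp = default_sim.config.composition
        for row in ant.itertuples(index=False):
            if "phage" in comp[row.condition]:
                assert row.fitness > 0
            elif "fungi" in comp[row.condition]:
                assert row.fitness < 0

    def test_extinct_library_rejected(self, small_sim):
        # every strain genic and every planted fitness -inf: nothing survives
        eff = small_sim.effects.copy()
        eff["fitness"] = -np.inf
        genic = small_sim.pool[small_sim.pool["locus_tag"].notna()]
        with pytest.raises(SimConfigError):
            simulate_selection(genic, eff, small_sim.config)


def _toy_selection_setup():
    """3 genes, one strain each, equal initial abundance (sigma=0)."""
    genes = pd.DataFrame(
        {
            "locus_tag": ["g1", "g2", "g3"],
            "seqid": "chr1",
            "start": [0, 400, 800],
            "end": [300, 700, 1100],
            "strand": ["+", "+", "+"],
        }
    )
    pool = pd.DataFrame(
        {
            "barcode": ["A" * 20, "C" * 20, "G" * 20],
            "position": [150, 550, 950],
            "strand": "+",
            "chimeric": False,
            "locus_tag": ["g1", "g2", "g3"],
            "rel_pos": 0.5,
            "central": True,
        }
    )
    effects = pd.DataFrame(
        {
            "locus_tag": ["g1", "g2", "g3"],
            "gene_class": "planted",
            "condition": "alone",
            "fitness": [-2.0, 0.0, 1.0],
        }
    )
    cfg = SimConfig(
        genome_length=2_000, n_genes=3, n_insertions=3, conditions=("alone",),
        n_replicates=1, read_depth_per_sample=10_000, abundance_sigma=0.0,
        min_gene_length=10, composition={"alone": frozenset()},
    )
    return genes, pool, effects, cfg


class TestSelection:
    def test_multinomial_mean_matches_closed_form(self):
        """Planted {-2, 0, +1} on equal-abundance strains: the day-3 count
        expectation is depth * 2^f / sum(2^f); the sampled mean over 200
        seeded draws must agree within 3 standard errors."""
        _, pool, effects, cfg = _toy_selection_setup()
        p_expected = np.array([0.25, 1.0, 2.0]) / 3.25
        draws = []
        for seed in range(200):
            counts, _ = simulate_selection(
                pool, effects, cfg, np.random.default_rng(seed)
            )
            draws.append(counts["alone_r1"].to_numpy())
        mean = np.mean(draws, axis=0)
        expected = cfg.read_depth_per_sample * p_expected
        se = np.sqrt(cfg.read_depth_per_sample * p_expected * (1 - p_expected) / 200)
        assert (np.abs(mean - expected) < 3 * se + 1e-9).all()

    def test_neutral_fixed_point(self):
        """All-neutral planted effects leave the expected day-3 composition
        equal to T0's (uniform here because abundance_sigma=0)."""
        _, pool, effects, cfg = _toy_selection_setup()
        effects = effects.assign(fitness=0.0)
        draws = []
        for seed in range(200):
            counts, _ = simulate_selection(
                pool, effects, cfg, np.random.default_rng(seed)
            )
            draws.append(counts["alone_r1"].to_numpy())
        mean = np.mean(draws, axis=0)
        expected = np.full(3, cfg.read_depth_per_sample / 3)
        se = np.sqrt(cfg.read_depth_per_sample * (1 / 3) * (2 / 3) / 200)
        assert (np.abs(mean - expected) < 3 * se).all()

    def test_determinism_same_seed_identical(self, small_config):
        a = simulate_community(small_config)
        b = simulate_community(small_config)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.pool, b.pool)
        assert a.genome == b.genome


class TestBarseqReads:
    def test_error_free_round_trip_reproduces_counts(self, small_sim):
        sample = "phage_r1"
        vec = small_sim.counts[sample]
        reads, stats = barseq_reads(
            vec, small_sim.config, np.random.default_rng(0)
        )
        assert stats["n_reads"] == int(vec.sum())
        tally, rejected = extract_barcodes(reads)
        assert sum(rejected.values()) == 0
        observed = pd.Series(tally).reindex(vec.index, fill_value=0)
        assert (observed.to_numpy() == vec.to_numpy()).all()

    def test_single_barcode_count_five(self):
        cfg = SimConfig(seed=0)
        vec = pd.Series([5], index=pd.Index(["A" * 20], name="barcode"))
        reads, _ = barseq_reads(vec, cfg, np.random.default_rng(0))
        assert len(reads) == 5

    def test_corruption_count_matches_committed_draw(self):
        cfg = SimConfig(seed=0, barseq_error_rate=0.01)
        rng = np.random.default_rng(5)
        barcodes = pd.Index(
            ["".join(rng.choice(list("ACGT"), 20)) for _ in range(200)],
            name="barcode",
        )
        vec = pd.Series(50, index=barcodes)
        reads, stats = barseq_reads(vec, cfg, np.random.default_rng(9))
        # enumerate emitted reads: the barcode field occupies bases 18..38
        true_set = set(barcodes)
        corrupted = sum(1 for _, seq in reads if seq[18:38] not in true_set)
        assert corrupted == stats["n_barcode_corrupted"]


class TestGrowthAssay:
    def test_poisson_mean_arithmetic(self):
        """1e9 cfu/ml at 0.1 ml and 1e-6 dilution means ~100 colonies."""
        scenario = pd.DataFrame(
            [{"label": "alone", "day": 1, "unit": "cfu", "titer": 1e9}]
        )
        cfg = SimConfig(seed=0)
        obs = simulate_growth_assay(
            scenario, cfg, np.random.default_rng(2), n_bio=20, n_tech=10
        )
        assert (obs["dilution"] == 1e-6).all()
        # mean of 200 Poisson(100) draws: 3 s.e. is ~2.1
        assert abs(obs["count"].mean() - 100) < 3 * 10 / np.sqrt(len(obs))

    def test_zero_titer_gives_zero_counts(self):
        scenario = pd.DataFrame(
            [{"label": "x", "day": 3, "unit": "cfu", "titer": 0.0}]
        )
        obs = simulate_growth_assay(scenario, SimConfig(seed=0))
        assert (obs["count"] == 0).all()

    def test_negative_titer_rejected(self):
        scenario = pd.DataFrame(
            [{"label": "x", "day": 1, "unit": "cfu", "titer": -1.0}]
        )
        with pytest.raises(ValueError):
            simulate_growth_assay(scenario, SimConfig(seed=0))

    def test_default_scenario_has_day3_extinction_with_phage_and_fungi(self):
        sc = default_growth_scenario()
        row = sc[(sc["label"] == "phage_fungi") & (sc["day"] == 3) & (sc["unit"] == "cfu")]
        assert (row["titer"] == 0).all()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"coding_fraction": 0.0},
            {"coding_fraction": 1.5},
            {"barcode_length": 4},
            {"n_insertions": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(SimConfigError):
            SimConfig(**kwargs).validate()

    def test_effect_spec_counts_capped_by_genes(self):
        cfg = SimConfig(genome_length=20_000, n_genes=10)
        _, genes = simulate_genome(cfg)
        with pytest.raises(SimConfigError):
            make_true_effects(genes, cfg, spec=EffectSpec(n_antagonistic=20))
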