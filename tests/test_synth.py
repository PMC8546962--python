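"""Synthetic-study generator: design arithmetic, determinism, structure."""

import math

import numpy as np
import pytest

from terroirseq import (
    ScenarioConfig,
    ValidationError,
    generate_community_counts,
    generate_environment,
    generate_expression_timeseries,
    generate_study,
    haversine_matrix,
    mantel,
)
from terroirseq.compositional import euclidean_distance
from terroirseq.datamodel import DistanceMatrix
from terroirseq.synth import GRAPE_ORGANISM, INOCULANT_ORGANISM


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides, match",
        [
            ({"n_regions": 0}, "n_regions"),
            ({"effect_sd_site": -0.1}, "effect_sd_site"),
            ({"frac_active_taxa": 1.5}, "frac_active_taxa"),
            ({"dna_rna_r2": -0.2}, "dna_rna_r2"),
            ({"timepoints_hours": (2, 2, 6)}, "strictly increasing"),
            ({"library_size_dna": 0}, "library_size_dna"),
            ({"n_genes": 10, "n_site_genes": 20}, "n_site_genes"),
        ],
    )
    def test_invalid_configs_rejected(self, overrides, match):
        with pytest.raises(ValidationError, match=match):
            ScenarioConfig(**overrides).validate()

    def test_invalid_marker_rejected(self):
        with pytest.raises(ValidationError, match="marker"):
            generate_community_counts(ScenarioConfig.null_effect(), "mRNA")

    def test_yaml_round_trip(self):
        cfg = ScenarioConfig.study_design(seed=3)
        assert ScenarioConfig.from_dict(cfg.to_dict()) == cfg


class TestDesignArithmetic:
    def test_study_design_sample_counts(self):
        cfg = ScenarioConfig.study_design()
        assert len(cfg.sites) == 15
        assert len(cfg.sites_by_region()) == 8
        # 15 sites x 4 tanks x 3 vintages, minus the one unfermented tank
        assert len(cfg.dna_design()) == 15 * 4 * 3 - 1
        # RNA: 15 sites x 2 tanks x 2 vintages
        assert len(cfg.rna_design()) == 15 * 2 * 2

    def test_tables_match_design(self):
        cfg = ScenarioConfig.study_design(
            seed=1, n_bacterial_taxa=20, n_fungal_taxa=20, n_genes=15, n_site_genes=3
        )
        study = generate_study(cfg)
        assert study.fungal_counts.n_samples == 179
        assert study.bacterial_counts.n_features == 20 + cfg.n_organelle_asvs
        for table in study.transcript_counts.values():
            assert table.n_samples == 60
        # every sample in every table appears in metadata
        meta_ids = set(study.metadata.sample_ids)
        for table in (
            study.bacterial_counts,
            study.fungal_counts,
            *study.transcript_counts.values(),
        ):
            assert set(table.sample_ids) <= meta_ids

    def test_truth_features_subset_of_tables(self):
        study = generate_study(ScenarioConfig.large_effect(seed=2, n_genes=30, n_site_genes=5))
        genes = set(next(iter(study.transcript_counts.values())).feature_ids)
        assert set(study.truth["site_informative_genes"]) <= genes
        assert set(study.truth["active_taxa"]) <= set(study.fungal_counts.feature_ids)


class TestDeterminism:
    def test_same_seed_identical_study(self):
        a = generate_study(ScenarioConfig.null_effect(seed=5))
        b = generate_study(ScenarioConfig.null_effect(seed=5))
        assert a.fungal_counts.equals(b.fungal_counts)
        assert a.bacterial_counts.equals(b.bacterial_counts)
        assert all(
            a.transcript_counts[t].equals(b.transcript_counts[t])
            for t in a.transcript_counts
        )
        assert a.metadata.frame.equals(b.metadata.frame)
        assert a.truth == b.truth

    def test_different_seed_differs(self):
        a = generate_study(ScenarioConfig.null_effect(seed=5))
        b = generate_study(ScenarioConfig.null_effect(seed=6))
        assert not a.fungal_counts.equals(b.fungal_counts)

    def test_write_is_byte_stable(self, tmp_path):
        for d in ("a", "b"):
            generate_study(ScenarioConfig.null_effect(seed=9)).write(tmp_path / d)
        for name in ("fungal_ITS.tsv", "metadata.tsv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()


class TestCommunityStructure:
    def test_dominant_taxon_highest_mean_everywhere(self):
        # enough samples for a stable mean; dominance on taxon 0
        cfg = ScenarioConfig(
            n_regions=5,
            sites_per_region=5,
            tanks_per_site=4,
            vintages=("2017",),
            rna_vintages=("2017",),
            n_fungal_taxa=40,
            dominance_alpha=50.0,
            seed=11,
        )
        table = generate_community_counts(cfg, "ITS")
        rel = table.counts / table.counts.sum(axis=0)
        assert rel.shape[1] == 100
        means = rel.mean(axis=1)
        assert means.idxmax() == table.feature_ids[0]

    def test_zero_depth_rejected(self):
        with pytest.raises(ValidationError):
            generate_community_counts(
                ScenarioConfig.null_effect(seed=1, library_size_dna=0), "ITS"
            )


class TestExpression:
    def test_no_active_taxa_only_inoculant_and_grape(self):
        cfg = ScenarioConfig.null_effect(seed=3, frac_active_taxa=0.0, rna_only_share=0.0)
        fungal = generate_community_counts(cfg, "ITS")
        tables = generate_expression_timeseries(cfg, fungal)
        for table in tables.values():
            organisms = set(table.organism[table.counts.sum(axis=1) > 0])
            assert organisms <= {INOCULANT_ORGANISM, GRAPE_ORGANISM}

    def test_inoculant_holds_majority_share(self, large_effect_study):
        for table in large_effect_study.transcript_counts.values():
            rel = table.counts / table.counts.sum(axis=0)
            inoc = rel[table.organism == INOCULANT_ORGANISM].sum(axis=0)
            assert (inoc > 0.5).all()

    def test_perfect_linkage_recovers_r2_one(self):
        from terroirseq.concordance import concordance_table
        from terroirseq.synth import _assemble_metadata

        cfg = ScenarioConfig.large_effect(
            seed=4,
            dna_rna_r2=1.0,
            n_genes=20,
            n_site_genes=0,
            n_fungal_taxa=40,
            timepoints_hours=(2, 6),
        )
        fungal = generate_community_counts(cfg, "ITS")
        tables = generate_expression_timeseries(cfg, fungal)
        meta = _assemble_metadata(cfg, generate_environment(cfg))
        results = concordance_table(fungal, tables, meta, "Hanseniaspora uvarum")
        for r in results:
            assert r.r_squared > 0.95

    def test_no_genes_refused_downstream(self):
        from terroirseq.signatures import summarize_timeseries
        from terroirseq.synth import _assemble_metadata

        cfg = ScenarioConfig.null_effect(
            seed=5, n_genes=0, n_site_genes=0, n_grape_genes=0,
            frac_active_taxa=0.0, rna_only_share=0.0,
        )
        fungal = generate_community_counts(cfg, "ITS")
        tables = generate_expression_timeseries(cfg, fungal)
        assert all(t.n_features == 0 for t in tables.values())
        meta = _assemble_metadata(cfg, generate_environment(cfg))
        with pytest.raises(ValidationError):
            summarize_timeseries(tables, meta)


class TestEnvironment:
    def test_infinite_range_collapses_to_shared_value(self):
        cfg = ScenarioConfig.null_effect(seed=6, env_spatial_range=math.inf)
        env = generate_environment(cfg)
        for vintage, sub in env.groupby("vintage"):
            assert sub["precipitation_mm"].nunique() == 1
            assert sub["gdd"].nunique() == 1

    def test_small_range_gives_positive_geo_climate_mantel(self):
        hits = 0
        for seed in range(8):
            cfg = ScenarioConfig.large_effect(seed=100 + seed, env_spatial_range=60.0)
            env = generate_environment(cfg)
            sites = env[env.vintage == cfg.vintages[0]].set_index("site")
            geo = haversine_matrix(
                sites[["latitude_deg", "longitude_deg"]], ids=list(sites.index)
            )
            precip = euclidean_distance(sites[["precipitation_mm"]])
            res = mantel(geo, precip, n_perm=199, seed=seed)
            if res.statistic > 0 and res.p_value < 0.05:
                hits += 1
        assert hits >= 6

    def test_few_sites_warns(self, caplog):
        import logging

        cfg = ScenarioConfig.null_effect(seed=1, n_regions=2, sites_per_region=1)
        with caplog.at_level(logging.WARNING, logger="terroirseq.synth"):
            generate_environment(cfg)
        assert any("fewer than 3 sites" in r.message for r in caplog.records)
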