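"""Synthetic study generator: determinism, bands, planted effects."""

import numpy as np
import pytest
from scipy import stats

from microweb import (
    FoodWebStudy,
    PlantedEffect,
    SyntheticConfig,
    generate_catalog,
    generate_seasonal_dataset,
    plant_association,
    read_annotation,
    read_community_table,
    read_interaction_catalog,
    regress_feature,
)
from microweb.build import build_web, detected_taxa
from microweb.io import TaxonAnnotation
from microweb.metrics import complexity
from microweb.simulate import _assign_guilds


class TestCatalogGeneration:
    def test_forced_bacterivore_prey_count(self):
        cat = generate_catalog(
            {"g1": frozenset({"B"})},
            ["PhylumA", "PhylumB"],
            np.random.default_rng(0),
            prey_count_fixed={"B": 2},
        )
        b_edges = [(p, q) for p, q, _ in cat if p == "g1"]
        assert len(b_edges) == 2

    def test_no_raptors_means_no_raptor_edges(self):
        guilds = {"g1": frozenset({"B"}), "g2": frozenset({"P"})}
        cat = generate_catalog(guilds, ["PhylumA"], np.random.default_rng(1))
        assert not any(prov.endswith(":R") for _, _, prov in cat.edges)

    def test_guild_without_prey_class_rejected(self):
        # a lone raptor has no protist genus to hunt
        with pytest.raises(ValueError, match="'R'"):
            generate_catalog({"g1": frozenset({"R"})}, [], np.random.default_rng(2))
        # a lone parasite has no host genus to attach to
        with pytest.raises(ValueError, match="'H-P'"):
            generate_catalog({"g1": frozenset({"H-P"})}, [], np.random.default_rng(2))

    def test_default_connectance_band_at_65_genera(self):
        """Webs built on the full 65-genus pool stay inside the
        generator's documented connectance band across 50 seeds."""
        cfg = SyntheticConfig(pool_size=65)
        for seed in range(50):
            rng = np.random.default_rng(seed)
            genera, _primary, guilds = _assign_guilds(cfg, rng)
            cat = generate_catalog(guilds, cfg.bacterial_phyla, rng)
            ann = {g: TaxonAnnotation("protist", "X", guilds[g]) for g in genera}
            web, _ = build_web(set(genera), ann, cat)
            assert 0.10 <= complexity(web).C <= 0.22


class TestSeasonalDataset:
    def test_same_seed_byte_identical(self, tmp_path):
        generate_seasonal_dataset(3).write(tmp_path / "a")
        generate_seasonal_dataset(3).write(tmp_path / "b")
        for name in (
            "protist_counts.tsv",
            "bacteria_counts.tsv",
            "annotation.tsv",
            "catalog.tsv",
            "environment.tsv",
            "manifest.json",
        ):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_richness_targets_give_matching_genus_counts(self):
        cfg = SyntheticConfig(richness=(69, 70, 61, 59))
        ds = generate_seasonal_dataset(1, cfg)
        study = FoodWebStudy.from_dataset(ds)
        for season, target in zip(cfg.seasons, cfg.richness):
            assert study.build_reports()[season].n_genus_nodes == target

    def test_artifacts_pass_all_parsers(self, dataset, tmp_path):
        dataset.write(tmp_path)
        read_community_table(tmp_path / "protist_counts.tsv")
        read_community_table(tmp_path / "bacteria_counts.tsv")
        ann = read_annotation(tmp_path / "annotation.tsv")
        cat = read_interaction_catalog(tmp_path / "catalog.tsv")
        assert cat.pairs() == dataset.catalog.pairs()
        assert ann == dataset.annotation

    def test_webs_have_basal_nodes_and_no_self_loops(self, season_webs):
        for web in season_webs.values():
            assert web.basal_mask().any()
            assert np.diagonal(web.adjacency).sum() == 0

    def test_infeasible_richness_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            generate_seasonal_dataset(0, SyntheticConfig(richness=(99, 70, 61, 59)))


class TestPlantedAssociation:
    def test_strength_zero_is_identity(self, dataset):
        out = plant_association(
            dataset, PlantedEffect("Int", "Mod", 1, 0.0), np.random.default_rng(0)
        )
        for season in dataset.seasons:
            assert np.array_equal(
                out.protist_tables[season].counts,
                dataset.protist_tables[season].counts,
            )

    def test_unknown_feature_or_metric_rejected(self, dataset):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="feature"):
            plant_association(dataset, PlantedEffect("AD", "Mod", 1, 0.5), rng)
        with pytest.raises(ValueError, match="metric"):
            plant_association(dataset, PlantedEffect("Int", "CC", 1, 0.5), rng)

    def test_detected_richness_preserved_under_planting(self, dataset):
        out = plant_association(
            dataset, PlantedEffect("Int", "Mod", 1, 0.9), np.random.default_rng(1)
        )
        for season in dataset.seasons:
            before = detected_taxa(dataset.protist_tables[season], season)
            after = detected_taxa(out.protist_tables[season], season)
            assert after == before

    def test_positive_int_mod_plant_yields_positive_rank_correlation(self):
        hits = 0
        n_seeds = 12
        for seed in range(n_seeds):
            ds = generate_seasonal_dataset(seed)
            planted = plant_association(
                ds, PlantedEffect("Int", "Mod", 1, 0.6),
                np.random.default_rng(1000 + seed),
            )
            df = FoodWebStudy.from_dataset(planted).fit(
                seed=seed, stages=("features",), sample_qss_draws=0
            ).samples
            if stats.spearmanr(df["Int"], df["Mod"]).statistic > 0:
                hits += 1
        assert hits >= n_seeds - 1

    def test_negative_int_link_plant_reverses_slope(self):
        negatives = 0
        n_seeds = 8
        for seed in range(n_seeds):
            ds = generate_seasonal_dataset(100 + seed)
            planted = plant_association(
                ds, PlantedEffect("Int", "L", -1, 0.6),
                np.random.default_rng(2000 + seed),
            )
            df = FoodWebStudy.from_dataset(planted).fit(
                seed=seed, stages=("features",), sample_qss_draws=0
            ).samples
            if regress_feature(df["Int"], df["sub_L"]).slope < 0:
                negatives += 1
        assert negatives >= n_seeds - 2
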