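"""Degree statistics, frequent targets, category overlap, pipeline run."""

import numpy as np
import pandas as pd
import pytest

import autoqsp as aq
from autoqsp import network


def catalog_with(counts):
    records = []
    for cat, n in counts.items():
        records += [aq.DrugRecord(f"{cat}{k}", cat, cat) for k in range(n)]
    return aq.DrugCatalog(records)


def spread_edges(catalog, totals):
    """Deterministic edge list with the requested per-category edge totals."""
    pairs = []
    for cat, total in totals.items():
        drugs = [r.drug_id for r in catalog if r.category == cat]
        for k in range(total):
            pairs.append((drugs[k % len(drugs)], f"t{cat[:3]}{k}"))
    return aq.InteractionSet.from_pairs(pairs)


class TestDegrees:
    def test_printed_mean_degree_arithmetic(self):
        # 1339 known edges over 174 activators -> mean 7.7 to one decimal
        catalog = catalog_with({"activator": 174})
        edges = spread_edges(catalog, {"activator": 1339})
        degrees = aq.modulator_degrees(edges, catalog)
        assert network.mean_degrees(degrees)["activator"] == 7.7

    def test_outlier_excluded_mean(self):
        # 389 inhibitor edges, one outlier drug holding 303 of them:
        # remaining 86 edges over 30 drugs -> 2.9
        catalog = catalog_with({"inhibitor": 31})
        pairs = [("inhibitor0", f"tx{k}") for k in range(303)]
        for k in range(86):
            pairs.append((f"inhibitor{1 + k % 30}", f"ty{k}"))
        edges = aq.InteractionSet.from_pairs(pairs)
        degrees = aq.modulator_degrees(edges, catalog)
        assert degrees["known_degree"].sum() == 389
        means = network.mean_degrees(degrees, exclude=("inhibitor0",))
        assert means["inhibitor"] == 2.9

    def test_drug_without_edges_has_degree_zero(self, tiny_catalog):
        edges = aq.InteractionSet.from_pairs([("d1", "t1")])
        degrees = aq.modulator_degrees(edges, tiny_catalog)
        assert degrees.set_index("drug_id").loc["d3", "total_degree"] == 0

    def test_degree_sum_conservation(self, small_world):
        degrees = aq.modulator_degrees(small_world.interactions, small_world.catalog)
        t_degrees = network.target_degrees(small_world.interactions, small_world.targets)
        assert degrees["known_degree"].sum() == len(small_world.interactions)
        assert t_degrees["known_degree"].sum() == len(small_world.interactions)


class TestPromiscuityHistogram:
    def test_top_bin_percentages(self):
        # 31 of 174 activators at degree >= 10 -> 17.8%; 3 of 31 -> 9.7%
        rows = []
        for cat, n, high in [("activator", 174, 31), ("inhibitor", 31, 3)]:
            for k in range(n):
                rows.append((f"{cat}{k}", cat, 12 if k < high else 1, 0, 12 if k < high else 1))
        degrees = pd.DataFrame(
            rows, columns=["drug_id", "category", "known_degree", "predicted_degree", "total_degree"]
        )
        hist = aq.promiscuity_histogram(degrees)
        top = hist[(hist["bin"] == "10+")].set_index("category")["percent"]
        assert round(top["activator"], 1) == 17.8
        assert round(top["inhibitor"], 1) == 9.7

    def test_all_single_target(self):
        degrees = pd.DataFrame(
            [(f"d{k}", "dual", 1, 0, 1) for k in range(5)],
            columns=["drug_id", "category", "known_degree", "predicted_degree", "total_degree"],
        )
        hist = aq.promiscuity_histogram(degrees)
        row = hist[(hist["category"] == "dual") & (hist["bin"] == "1")]
        assert row["percent"].item() == 100.0

    def test_percentages_sum_to_100(self, small_world):
        degrees = aq.modulator_degrees(small_world.interactions, small_world.catalog)
        hist = aq.promiscuity_histogram(degrees)
        for _cat, group in hist.groupby("category"):
            if group["count"].sum():
                assert group["percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_category_zero_rows(self):
        degrees = pd.DataFrame(
            [("d0", "activator", 2, 0, 2)],
            columns=["drug_id", "category", "known_degree", "predicted_degree", "total_degree"],
        )
        hist = aq.promiscuity_histogram(degrees)
        dual = hist[hist["category"] == "dual"]
        assert (dual["count"] == 0).all()


class TestFrequentTargets:
    def test_threshold_inclusive_at_five(self):
        catalog = catalog_with({"activator": 6})
        pairs = [(f"activator{k}", "hub5") for k in range(5)]
        pairs += [(f"activator{k}", "hub4") for k in range(4)]
        edges = aq.InteractionSet.from_pairs(pairs)
        table = aq.frequent_targets(edges, catalog)
        assert list(table["target_id"]) == ["hub5"]

    def test_min_one_returns_all_targets(self, tiny_catalog, tiny_edges):
        table = aq.frequent_targets(tiny_edges, tiny_catalog, min_modulators=1)
        assert set(table["target_id"]) == {"t1", "t2", "t3"}

    def test_constructed_world_counts(self):
        catalog = catalog_with({"activator": 6, "inhibitor": 3, "dual": 2})
        pairs = []
        # 3 frequent targets with known per-category splits
        for t, (na, ni, nd) in {"f1": (4, 1, 0), "f2": (3, 2, 1), "f3": (5, 0, 0)}.items():
            pairs += [(f"activator{k}", t) for k in range(na)]
            pairs += [(f"inhibitor{k}", t) for k in range(ni)]
            pairs += [(f"dual{k}", t) for k in range(nd)]
        pairs += [("activator0", "rare")]
        edges = aq.InteractionSet.from_pairs(pairs)
        table = aq.frequent_targets(edges, catalog).set_index("target_id")
        assert len(table) == 3
        assert table.loc["f2", ["activator", "inhibitor", "dual"]].tolist() == [3, 2, 1]

    def test_predicted_counted_separately(self):
        catalog = catalog_with({"activator": 6})
        known = aq.InteractionSet.from_pairs([(f"activator{k}", "hub") for k in range(5)])
        pred = aq.InteractionSet.from_pairs([("activator5", "hub")], "predicted", 0.9)
        table = aq.frequent_targets(known.merged_with(pred), catalog)
        row = table.set_index("target_id").loc["hub"]
        assert row["n_known_modulators"] == 5 and row["n_predicted_modulators"] == 1


class TestCategoryOverlap:
    def test_disjoint_sets_have_empty_intersections(self):
        catalog = catalog_with({"activator": 1, "inhibitor": 1, "dual": 1})
        edges = aq.InteractionSet.from_pairs(
            [("activator0", "ta"), ("inhibitor0", "ti"), ("dual0", "td")]
        )
        overlap = aq.category_overlap(edges, catalog)
        assert overlap.all_three == 0 and overlap.activator_inhibitor == 0
        assert overlap.union_size == 3

    def test_shared_target_in_triple_region(self):
        catalog = catalog_with({"activator": 1, "inhibitor": 1, "dual": 1})
        edges = aq.InteractionSet.from_pairs(
            [("activator0", "hub"), ("inhibitor0", "hub"), ("dual0", "hub")]
        )
        assert aq.category_overlap(edges, catalog).all_three == 1

    def test_partition_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(7)
        catalog = catalog_with({"activator": 5, "inhibitor": 5, "dual": 5})
        targets = [f"t{j}" for j in range(50)]
        pairs = {
            (rec.drug_id, targets[rng.integers(50)])
            for rec in catalog
            for _ in range(rng.integers(1, 8))
        }
        edges = aq.InteractionSet.from_pairs(sorted(pairs))
        overlap = aq.category_overlap(edges, catalog)
        sets = {c: set() for c in aq.CATEGORIES}
        for d, t in pairs:
            sets[catalog.category_of(d)].add(t)
        a, i, d = sets["activator"], sets["inhibitor"], sets["dual"]
        assert overlap.regions() == {
            "activator_only": len(a - i - d),
            "inhibitor_only": len(i - a - d),
            "dual_only": len(d - a - i),
            "activator_inhibitor": len((a & i) - d),
            "activator_dual": len((a & d) - i),
            "inhibitor_dual": len((i & d) - a),
            "all_three": len(a & i & d),
        }
        assert overlap.union_size == len(a | i | d)
        assert sum(overlap.regions().values()) == overlap.union_size


@pytest.fixture(scope="module")
def pipeline_world(tmp_path_factory):
    config = aq.WorldConfig(
        n_drugs=60, n_targets=120, latent_dim=4, density=0.02, n_pathways=20,
        fingerprint_length=64, seed=11,
    )
    world = aq.generate_world(config)
    paths = aq.write_world(world, tmp_path_factory.mktemp("world"))
    return world, paths


class TestPipeline:
    def make_config(self, paths, outdir, **overrides):
        defaults = dict(
            drugs=paths["drugs"], edges=paths["edges"], gene_sets=paths["gene_sets"],
            universe=paths["universe"], outdir=outdir, latent_dim=4, epochs=40, seed=5,
        )
        defaults.update(overrides)
        return aq.PipelineConfig(**defaults)

    def test_bookkeeping_identity(self, pipeline_world, tmp_path):
        world, paths = pipeline_world
        result = network.run_pipeline(self.make_config(paths, tmp_path / "out"))
        degrees = aq.modulator_degrees(result.known, result.catalog)
        per_category = degrees.groupby("category")["known_degree"].sum()
        assert per_category.sum() == len(result.known)

    def test_no_predict_flag(self, pipeline_world, tmp_path):
        world, paths = pipeline_world
        result = network.run_pipeline(
            self.make_config(paths, tmp_path / "out", predict=False)
        )
        assert result.predictions is None
        assert "predictions" not in result.outputs
        assert not any("combined" in key for key in result.outputs)

    def test_predictions_exclude_known_edges(self, pipeline_world, tmp_path):
        world, paths = pipeline_world
        result = network.run_pipeline(self.make_config(paths, tmp_path / "out"))
        if result.predictions is not None and len(result.predictions):
            assert not (result.predictions.pairs() & result.known.pairs())

    def test_stage_name_in_error(self, pipeline_world, tmp_path):
        world, paths = pipeline_world
        config = self.make_config(paths, tmp_path / "out", latent_dim=0)
        with pytest.raises(RuntimeError, match="stage 'predict'"):
            network.run_pipeline(config)
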