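import json

import numpy as np
import pandas as pd
import pytest

from isoniche import (ConfigError, SimConfig, build_hex_lattice,
                      build_neighbor_graph, classify_spatial, generate_dataset,
                      plant_colocalization, plant_niches, read_counts,
                      read_positions, simulate_counts)
from isoniche.simulate import _nb_draw


def small_cfg(**overrides):
    base = dict(seed=5, n_rows=16, n_cols=32, n_niches=4, n_genes=40)
    base.update(overrides)
    return SimConfig(**base)


class TestHexLattice:
    def test_parity_rule_degenerate_row(self):
        assert build_hex_lattice(1, 2).n_spots == 1  # only c=0 matches r=0

    def test_two_rows_four_cols(self):
        lat = build_hex_lattice(2, 4)
        assert lat.n_spots == 4  # 2 valid columns per row

    def test_interior_spot_has_six_array_neighbors(self):
        lat = build_hex_lattice(20, 40)
        g = build_neighbor_graph(lat)
        ids = {(r, c): s for r, c, s in zip(lat.array_row, lat.array_col, lat.spot_id)}
        assert len(g.neighbors[ids[(10, 10)]]) == 6

    def test_unit_pitch_geometry(self):
        lat = build_hex_lattice(4, 8)
        g = build_neighbor_graph(lat)
        xy = {s: (x, y) for s, x, y in zip(lat.spot_id, lat.px_x, lat.px_y)}
        for s in lat.spot_id:
            for t in g.neighbors[s]:
                d = np.hypot(xy[s][0] - xy[t][0], xy[s][1] - xy[t][1])
                assert d == pytest.approx(1.0)


class TestPlantNiches:
    def test_single_niche_covers_all(self):
        lat = build_hex_lattice(6, 12)
        labels = plant_niches(lat, 1, seed=0)
        assert set(labels.values()) == {0}

    def test_seeded_determinism(self):
        lat = build_hex_lattice(10, 20)
        assert plant_niches(lat, 4, seed=9) == plant_niches(lat, 4, seed=9)

    def test_every_spot_its_own_label_at_k_equals_n(self):
        lat = build_hex_lattice(3, 6)
        labels = plant_niches(lat, lat.n_spots, seed=1)
        assert len(set(labels.values())) == lat.n_spots

    def test_all_labels_nonempty(self):
        lat = build_hex_lattice(12, 24)
        labels = plant_niches(lat, 5, seed=3)
        assert set(labels.values()) == set(range(5))

    def test_too_many_niches_rejected(self):
        lat = build_hex_lattice(2, 4)
        with pytest.raises(ConfigError):
            plant_niches(lat, 5, seed=0)

    def test_niches_are_spatially_contiguous(self):
        lat = build_hex_lattice(14, 28)
        labels = plant_niches(lat, 4, seed=2)
        graph = build_neighbor_graph(lat)
        for k in range(4):
            members = [s for s in lat.spot_id if labels[s] == k]
            seen = {members[0]}
            frontier = [members[0]]
            member_set = set(members)
            while frontier:
                s = frontier.pop()
                for t in graph.neighbors[s]:
                    if t in member_set and t not in seen:
                        seen.add(t)
                        frontier.append(t)
            assert seen == member_set


class TestSimulateCounts:
    def test_all_single_mix_yields_one_isoform_per_gene(self):
        cfg = small_cfg(isoforms_per_gene={1: 1.0},
                        class_mix={"single": 1.0, "multi_all": 0.0,
                                   "multi_one": 0.0, "multi_others": 0.0})
        lat = build_hex_lattice(cfg.n_rows, cfg.n_cols)
        niches = plant_niches(lat, cfg.n_niches, cfg.seed)
        _, iso_m, plan = simulate_counts(cfg, lat, niches)
        assert (plan.groupby("gene_id").size() == 1).all()
        assert (plan["class"] == "single").all()

    def test_gene_counts_conserve_isoform_sums(self):
        cfg = small_cfg()
        lat = build_hex_lattice(cfg.n_rows, cfg.n_cols)
        niches = plant_niches(lat, cfg.n_niches, cfg.seed)
        gene_m, iso_m, plan = simulate_counts(cfg, lat, niches)
        iso_dense = iso_m.counts.toarray()
        for gene in gene_m.features:
            cols = [iso_m.features.index(i)
                    for i in plan.loc[plan.gene_id == gene, "isoform_id"]]
            np.testing.assert_array_equal(
                gene_m.column(gene), iso_dense[:, cols].sum(axis=1))

    def test_counts_zero_outside_support(self):
        cfg = small_cfg()
        lat = build_hex_lattice(cfg.n_rows, cfg.n_cols)
        niches = plant_niches(lat, cfg.n_niches, cfg.seed)
        _, iso_m, plan = simulate_counts(cfg, lat, niches)
        niche_idx = np.array([niches[s] for s in iso_m.spots])
        dense = iso_m.counts.toarray()
        for j, (iso, support) in enumerate(zip(plan.isoform_id, plan.support)):
            outside = ~np.isin(niche_idx, list(support))
            assert dense[outside, j].sum() == 0

    def test_planted_classes_recovered_exactly(self):
        cfg = small_cfg(seed=17)
        lat = build_hex_lattice(cfg.n_rows, cfg.n_cols)
        niches = plant_niches(lat, cfg.n_niches, cfg.seed)
        _, iso_m, plan = simulate_counts(cfg, lat, niches)
        called = classify_spatial(iso_m, niches)["spatial_class"]
        truth = plan.set_index("isoform_id")["class"]
        assert (called.loc[truth.index] == truth).all()

    def test_nb_poisson_limit_variance_over_mean(self):
        rng = np.random.default_rng(0)
        draws = _nb_draw(rng, mean=4.0, dispersion=1e6, size=100_000)
        assert draws.var() / draws.mean() == pytest.approx(1.0, abs=0.05)

    def test_nb_overdispersion_at_finite_dispersion(self):
        rng = np.random.default_rng(0)
        draws = _nb_draw(rng, mean=4.0, dispersion=2.0, size=100_000)
        # var = mean + mean^2/dispersion = 4 + 8 = 12 -> ratio 3
        assert draws.var() / draws.mean() == pytest.approx(3.0, abs=0.2)

    def test_multi_one_with_single_niche_is_config_error(self):
        with pytest.raises(ConfigError, match="multi_one"):
            small_cfg(n_niches=1,
                      class_mix={"single": 0.5, "multi_all": 0.25,
                                 "multi_one": 0.25, "multi_others": 0.0})


class TestPlantColocalization:
    def test_zone_fraction_and_contiguity(self):
        cfg = small_cfg(ratio_zone_fraction=0.25)
        lat = build_hex_lattice(cfg.n_rows, cfg.n_cols)
        coloc = plant_colocalization(cfg, lat)
        n_zone = int(coloc.zone.sum())
        assert n_zone == round(0.25 * lat.n_spots)
        graph = build_neighbor_graph(lat)
        zone_spots = set(coloc.zone.index[coloc.zone])
        first = next(iter(zone_spots))
        seen, frontier = {first}, [first]
        while frontier:
            s = frontier.pop()
            for t in graph.neighbors[s]:
                if t in zone_spots and t not in seen:
                    seen.add(t)
                    frontier.append(t)
        assert seen == zone_spots

    def test_high_ratio_inside_zone(self):
        cfg = small_cfg(n_rows=30, n_cols=60)
        lat = build_hex_lattice(cfg.n_rows, cfg.n_cols)
        coloc = plant_colocalization(cfg, lat)
        pc = coloc.pair_counts[coloc.zone]
        ratio = pc.count_a / pc.count_b
        assert (ratio > 15).mean() >= 0.9

    def test_ratio_concentrates_low_outside_zone(self):
        cfg = small_cfg(n_rows=30, n_cols=60)
        lat = build_hex_lattice(cfg.n_rows, cfg.n_cols)
        coloc = plant_colocalization(cfg, lat)
        pc = coloc.pair_counts[~coloc.zone]
        defined = pc[pc.count_b > 0]
        assert ((defined.count_a / defined.count_b) <= 1).mean() > 0.8

    def test_markers_zero_exactly_where_type_absent(self):
        cfg = small_cfg()
        lat = build_hex_lattice(cfg.n_rows, cfg.n_cols)
        coloc = plant_colocalization(cfg, lat)
        for g in cfg.tex_markers:
            pos = coloc.marker_counts[g] > 0
            assert (pos == coloc.presence["present_a"]).all()
        for g in cfg.tam_markers:
            pos = coloc.marker_counts[g] > 0
            assert (pos == coloc.presence["present_b"]).all()

    def test_independent_presence_at_odds_one(self):
        # calibration: with coloc_odds=1 the zone must not predict joint
        # presence; chi-square on zone x joint rejects at ~nominal rate
        from isoniche import chi_square_test

        cfg = small_cfg(coloc_odds=1.0, n_rows=20, n_cols=40)
        lat = build_hex_lattice(cfg.n_rows, cfg.n_cols)
        rejections = 0
        n_sims = 200
        for seed in range(n_sims):
            rng = np.random.default_rng(1000 + seed)
            coloc = plant_colocalization(cfg, lat, rng=rng)
            joint = coloc.presence.present_a & coloc.presence.present_b
            table = pd.crosstab(coloc.zone, joint).to_numpy()
            if table.shape == (2, 2):
                rejections += chi_square_test(table).pvalue < 0.05
        assert 0.02 <= rejections / n_sims <= 0.09

    def test_boosted_joint_presence_in_zone(self):
        cfg = small_cfg(coloc_odds=8.0, n_rows=30, n_cols=60)
        lat = build_hex_lattice(cfg.n_rows, cfg.n_cols)
        coloc = plant_colocalization(cfg, lat)
        joint = coloc.presence.present_a & coloc.presence.present_b
        assert joint[coloc.zone].mean() > 2 * joint[~coloc.zone].mean()


class TestGenerateDataset:
    def test_bundle_roundtrip_equals_memory(self, tmp_path):
        cfg = small_cfg()
        truth = generate_dataset(cfg, tmp_path)
        lat = read_positions(tmp_path / "tissue_positions.csv")
        assert lat.n_spots == len(truth.presence)
        iso = read_counts(tmp_path / "iso_matrix.mtx", tmp_path / "iso_features.tsv",
                          tmp_path / "iso_barcodes.tsv", level="isoform",
                          iso2gene=tmp_path / "iso2gene.tsv")
        called = classify_spatial(iso, truth.niches)["spatial_class"]
        planted = truth.spatial_class
        assert (called.loc[planted.index] == planted).all()

    def test_same_seed_byte_identical_bundles(self, tmp_path):
        cfg = small_cfg(emit_trio=True)
        generate_dataset(cfg, tmp_path / "a")
        generate_dataset(cfg, tmp_path / "b")
        for rel in ["tissue_positions.csv", "gene_matrix.mtx", "iso_matrix.mtx",
                    "truth_isoforms.tsv", "truth_spots.tsv", "cell_fractions.tsv",
                    "sim_config.json", "before/iso_matrix.mtx", "after_ln/iso_matrix.mtx"]:
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        generate_dataset(small_cfg(seed=1), tmp_path / "a")
        generate_dataset(small_cfg(seed=2), tmp_path / "b")
        assert (tmp_path / "a" / "iso_matrix.mtx").read_bytes() != \
               (tmp_path / "b" / "iso_matrix.mtx").read_bytes()

    def test_config_echo_is_machine_readable(self, tmp_path):
        cfg = small_cfg()
        generate_dataset(cfg, tmp_path)
        echo = json.loads((tmp_path / "sim_config.json").read_text())
        assert echo["seed"] == cfg.seed
        assert echo["n_niches"] == cfg.n_niches
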