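"""Generator contracts: layout arithmetic, determinism, ground-truth fidelity."""

import numpy as np
import pytest

from mompscreen import (
    PhenotypeLabel,
    SimulationConfig,
    generate_plate_layout,
    render_colony_well,
    render_field,
    sample_field_truth,
    simulate_field,
    simulate_screen_scores,
)
from mompscreen.imaging import CHANNELS, REPORTER_CHANNELS
from mompscreen.phenotype import LABELS


class TestPlateLayout:
    def test_edge_exclusion_leaves_240_usable_wells(self, default_config):
        pm = generate_plate_layout(default_config, ["GENE1"], replicates=1)
        non_edge = pm[pm.role != "EMPTY_EDGE"]
        edge = pm[pm.role == "EMPTY_EDGE"]
        # 384-well plate minus a 2-wide edge band: (16-4) x (24-4) usable
        assert len(edge) == 16 * 24 - 240
        assert edge.row.min() >= 0 and len(non_edge) <= 240

    def test_1318_genes_fill_six_plates(self, default_config):
        genes = [f"G{i:04d}" for i in range(1318)]
        pm = generate_plate_layout(default_config, genes, replicates=1)
        assert pm.plate.nunique() == 6  # ceil(1318 / (240 - 8 controls))
        samples = pm[pm.role == "SAMPLE"]
        assert samples.gene.nunique() == 1318
        # one well per gene per plate, 232 sample wells on full plates
        assert (samples[samples.plate == 1].groupby("gene").size() == 1).all()
        assert len(samples[samples.plate == 1]) == 232

    def test_replicate_plates_share_gene_layout(self, default_config):
        genes = [f"G{i}" for i in range(20)]
        pm = generate_plate_layout(default_config, genes, replicates=3)
        by_rep = {
            rep: set(map(tuple, grp[grp.role == "SAMPLE"][["well", "gene"]].values))
            for rep, grp in pm.groupby("replicate")
        }
        assert by_rep[1] == by_rep[2] == by_rep[3]

    def test_empty_gene_list_gives_controls_and_edge_only(self, default_config):
        pm = generate_plate_layout(default_config, [], replicates=1)
        assert set(pm.role) == {
            "EMPTY_EDGE", "NEG_CONTROL", "POS_CONTROL", "TOX_MARKER", "UNTREATED",
        }
        assert (pm[pm.role == "SAMPLE"]).empty

    def test_capacity_error_names_required_and_available(self):
        cfg = SimulationConfig(plate_format=(4, 4), excluded_edge=1)
        with pytest.raises(ValueError, match="usable wells"):
            generate_plate_layout(cfg, ["G1"], replicates=1)

    def test_untreated_wells_carry_no_treatment(self, default_config):
        pm = generate_plate_layout(default_config, ["G1"], replicates=1)
        assert (pm[pm.role == "UNTREATED"].treatment == "NONE").all()
        assert (pm[pm.role == "NEG_CONTROL"].treatment == "ETOPOSIDE_QVD").all()


class TestFieldRendering:
    def test_empty_field_zero_noise_is_uniform_background(self):
        cfg = SimulationConfig(image_shape=(128, 128), noise_sigma=0.0,
                               shot_noise=False, background_level=200.0)
        img = render_field([], cfg, seed=1)
        for ch in CHANNELS:
            assert np.all(img.channels[ch] == 200)

    def test_rendering_is_bit_identical_given_seed(self, small_config):
        rng = np.random.default_rng(0)
        truth = sample_field_truth(small_config, rng, n_cells=6)
        a = render_field(truth, small_config, seed=7)
        b = render_field(truth, small_config, seed=7)
        for ch in CHANNELS:
            assert np.array_equal(a.channels[ch], b.channels[ch])

    def test_simulate_field_determinism_end_to_end(self, small_config):
        a, ta = simulate_field(small_config, seed=3)
        b, tb = simulate_field(small_config, seed=3)
        assert len(ta) == len(tb)
        for ch in CHANNELS:
            assert np.array_equal(a.channels[ch], b.channels[ch])

    def test_intact_cell_puncta_are_local_maxima(self):
        """Each rendered punctum is a local max at the generator's coordinates."""
        cfg = SimulationConfig(image_shape=(256, 256), noise_sigma=0.0,
                               shot_noise=False)
        rng = np.random.default_rng(5)
        truth = sample_field_truth(
            cfg, rng, n_cells=1, mixture={"BAX_POSITIVE": 0, "INTACT": 1,
                                          "DOUBLE_POSITIVE": 0, "NONDETERMINED": 0})
        truth[0].puncta["TexasRed"] = truth[0].puncta["TexasRed"][:0]
        from mompscreen.synthdata import _sample_puncta
        truth[0].puncta["TexasRed"] = _sample_puncta(
            rng, cfg.puncta["TexasRed"], truth[0].nucleus_centroid,
            cfg.puncta_radial_range, [], [], 0.0, n_override=12)
        assert len(truth[0].puncta["TexasRed"]) == 12
        img = render_field(truth, cfg, seed=1).channels["TexasRed"].astype(float)
        n_max = 0
        for p in truth[0].puncta["TexasRed"]:
            r, c = int(round(p.centroid[0])), int(round(p.centroid[1]))
            patch = img[r - 2:r + 3, c - 2:c + 3]
            rr, cc = np.unravel_index(np.argmax(patch), patch.shape)
            # the discrete intensity peak sits within 1 px of the true centroid
            if abs(rr - 2) <= 1 and abs(cc - 2) <= 1:
                n_max += 1
        assert n_max == 12

    def test_ground_truth_invariants(self, default_config):
        rng = np.random.default_rng(11)
        truth = sample_field_truth(default_config, rng, n_cells=60)
        h, w = default_config.image_shape
        for cell in truth:
            for ch in REPORTER_CHANNELS:
                lo, hi = default_config.puncta[ch].diameter_range
                for p in cell.puncta.get(ch, []):
                    assert lo <= p.diameter <= hi
                    assert 0 <= p.centroid[0] < h and 0 <= p.centroid[1] < w
            if cell.true_phenotype is PhenotypeLabel.DOUBLE_POSITIVE:
                assert len(cell.puncta["YFP"]) >= 1
                assert len(cell.puncta["TexasRed"]) >= 1
                for py in cell.puncta["YFP"]:
                    for pt in cell.puncta["TexasRed"]:
                        dist = np.hypot(py.centroid[0] - pt.centroid[0],
                                        py.centroid[1] - pt.centroid[1])
                        assert dist >= default_config.noncoloc_min_distance
            if cell.true_phenotype is PhenotypeLabel.NONDETERMINED:
                assert all(v == 0 for v in cell.diffuse.values())
                assert not any(cell.puncta[ch] for ch in REPORTER_CHANNELS)

    def test_mixture_realized_within_three_binomial_se(self, default_config):
        counts = {lab: 0 for lab in LABELS}
        total = 0
        for seed in range(19):
            rng = np.random.default_rng(seed)
            truth = sample_field_truth(default_config, rng, n_cells=55)
            for c in truth:
                counts[c.true_phenotype] += 1
                total += 1
        assert total >= 1000
        for lab in LABELS:
            p = default_config.phenotype_mixture[lab.value]
            se = np.sqrt(p * (1 - p) / total)
            assert abs(counts[lab] / total - p) <= 3 * se + 1e-9


class TestScoreSimulation:
    def test_zero_noise_scores_equal_baseline(self):
        df = simulate_screen_scores(100, None, replicates=3, noise_sd=0.0, seed=1)
        assert np.allclose(df.bax_fold, 1.0)
        assert np.allclose(df.dp_pct, 2.0)

    def test_spiked_genes_occupy_top_ranks(self):
        spikes = {f"G{i + 1:05d}": {"III": 5.0} for i in range(20)}
        df = simulate_screen_scores(100, spikes, replicates=3, noise_sd=0.05, seed=2)
        means = df.groupby("gene").dp_pct.mean().sort_values(ascending=False)
        assert set(means.index[:20]) == set(spikes)

    def test_score_table_determinism(self):
        a = simulate_screen_scores(50, {"G00003": {"I": 3.0}}, 3, 0.1, seed=9)
        b = simulate_screen_scores(50, {"G00003": {"I": 3.0}}, 3, 0.1, seed=9)
        assert a.equals(b)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_screen_scores(10, None, 3, noise_sd=-1.0, seed=0)


class TestColonyWells:
    def test_blank_and_full_wells(self):
        blank = render_colony_well(0.0, 0, seed=1)
        assert blank.realized_fraction == 0.0 and not blank.mask.any()
        full = render_colony_well(1.0, 0, seed=1)
        assert full.realized_fraction == 1.0

    @pytest.mark.parametrize("fraction", [0.05, 0.30, 0.60, 0.95])
    def test_realized_fraction_within_one_point(self, fraction):
        ci = render_colony_well(fraction, 50, seed=3)
        assert abs(ci.realized_fraction - fraction) <= 0.01

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            render_colony_well(1.2, 10, seed=0)
        with pytest.raises(ValueError):
            render_colony_well(-0.1, 10, seed=0)

    def test_colony_determinism(self):
        a = render_colony_well(0.3, 40, seed=5)
        b = render_colony_well(0.3, 40, seed=5)
        assert np.array_equal(a.image, b.image)
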