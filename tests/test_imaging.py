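"""Segmentation and granule-detection contracts against generator ground truth."""

import dataclasses

import numpy as np
import pytest

from mompscreen import (
    PhenotypeLabel,
    SimulationConfig,
    assign_cell_regions,
    detect_granules,
    render_field,
    sample_field_truth,
    segment_nuclei,
)
from mompscreen.synthdata import GroundTruthCell

INTACT_ONLY = {"BAX_POSITIVE": 0, "INTACT": 1, "DOUBLE_POSITIVE": 0, "NONDETERMINED": 0}


def _intact_field(n_cells, n_puncta, seed=0, shape=(512, 512), noise=True):
    cfg = SimulationConfig(image_shape=shape,
                           noise_sigma=30.0 if noise else 0.0, shot_noise=noise)
    rng = np.random.default_rng(seed)
    truth = sample_field_truth(cfg, rng, n_cells=n_cells, mixture=INTACT_ONLY)
    if n_puncta is not None:
        from mompscreen.synthdata import _sample_puncta
        for cell in truth:
            cell.puncta["TexasRed"] = _sample_puncta(
                rng, cfg.puncta["TexasRed"], cell.nucleus_centroid,
                cfg.puncta_radial_range, [], [], 0.0, n_override=n_puncta)
    return render_field(truth, cfg, seed=seed), truth, cfg


class TestSegmentNuclei:
    def test_blank_image_yields_no_nuclei(self, params):
        assert segment_nuclei(np.zeros((128, 128)), params) == []
        assert segment_nuclei(np.full((128, 128), 500.0), params) == []

    def test_pure_noise_yields_no_nuclei(self, params):
        rng = np.random.default_rng(0)
        img = 200 + 30 * rng.standard_normal((256, 256))
        assert segment_nuclei(img, params) == []

    def test_well_separated_nuclei_counted_exactly(self, params):
        field, truth, _ = _intact_field(25, None, seed=2, shape=(1024, 1024))
        nuclei = segment_nuclei(field.channels["DAPI"].astype(float), params)
        assert len(nuclei) == 25
        assert not any(n.fragmented for n in nuclei)
        assert all(n.fragment_count == 1 for n in nuclei)

    def test_fragmented_nucleus_grouped_into_one_object(self, params):
        cfg = SimulationConfig(image_shape=(256, 256))
        cell = GroundTruthCell(
            cell_id=1, well_id="A01", site_index=0, nucleus_centroid=(128.0, 128.0),
            nucleus_fragmented=True, true_phenotype=PhenotypeLabel.BAX_POSITIVE,
            puncta={"YFP": [], "TexasRed": []},
            diffuse={"YFP": 80.0, "TexasRed": 15.0},
            nucleus_fragments=[(120.0, 128.0, 3.0, 3.0, 0.0),
                               (133.0, 121.0, 3.0, 3.0, 0.0),
                               (133.0, 135.0, 3.0, 3.0, 0.0)],
        )
        field = render_field([cell], cfg, seed=4)
        nuclei = segment_nuclei(field.channels["DAPI"].astype(float), params)
        assert len(nuclei) == 1
        assert nuclei[0].fragment_count == 3
        assert nuclei[0].fragmented
        assert nuclei[0].area < params.normal_nucleus_min_area


class TestCellRegions:
    def test_zero_nuclei_zero_regions(self, params):
        assert assign_cell_regions([], (64, 64), params) == []

    def test_partition_is_disjoint_and_contains_nuclei(self, params):
        field, truth, _ = _intact_field(15, None, seed=3)
        nuclei = segment_nuclei(field.channels["DAPI"].astype(float), params)
        regions = assign_cell_regions(nuclei, field.shape, params)
        claimed = np.zeros(field.shape, dtype=int)
        for reg in regions:
            claimed[reg.coords[:, 0], reg.coords[:, 1]] += 1
        assert claimed.max() == 1  # no pixel claimed twice
        by_id = {r.cell_id: set(map(tuple, r.coords)) for r in regions}
        for nuc in nuclei:
            assert set(map(tuple, nuc.coords)) <= by_id[nuc.label]

    def test_expansion_bounded_by_radius(self, params):
        field, truth, _ = _intact_field(1, None, seed=5, shape=(256, 256))
        nuclei = segment_nuclei(field.channels["DAPI"].astype(float), params)
        regions = assign_cell_regions(nuclei, field.shape, params)
        assert len(regions) == 1
        nuc_set = nuclei[0].coords
        for (y, x) in regions[0].coords:
            d = np.hypot(nuc_set[:, 0] - y, nuc_set[:, 1] - x).min()
            assert d <= params.cell_expansion_radius + 1.5

    def test_close_nuclei_split_along_equidistant_line(self, params):
        cfg = SimulationConfig(image_shape=(128, 128))
        cells = []
        for i, cy in enumerate((54.0, 74.0)):
            cells.append(GroundTruthCell(
                cell_id=i + 1, well_id="A01", site_index=0,
                nucleus_centroid=(cy, 64.0), nucleus_fragmented=False,
                true_phenotype=PhenotypeLabel.INTACT,
                puncta={"YFP": [], "TexasRed": []},
                diffuse={"YFP": 100.0, "TexasRed": 40.0},
                nucleus_fragments=[(cy, 64.0, 7.0, 7.0, 0.0)],
            ))
        field = render_field(cells, cfg, seed=6)
        nuclei = segment_nuclei(field.channels["DAPI"].astype(float), params)
        assert len(nuclei) == 2
        regions = assign_cell_regions(nuclei, field.shape, params)
        sets = [set(map(tuple, r.coords)) for r in regions]
        assert not (sets[0] & sets[1])
        # pixels clearly nearer one nucleus belong to it
        top = min(nuclei, key=lambda n: n.centroid[0]).label
        owner = {r.cell_id: s for r, s in zip(regions, sets)}
        assert (50, 64) in owner[top]


class TestDetectGranules:
    def test_flat_image_yields_no_granules(self, params):
        field, truth, _ = _intact_field(3, None, seed=7, shape=(256, 256))
        nuclei = segment_nuclei(field.channels["DAPI"].astype(float), params)
        regions = assign_cell_regions(nuclei, field.shape, params)
        flat = np.full(field.shape, 200.0)
        assert detect_granules(flat, regions, params, "TexasRed") == []

    def test_unknown_channel_rejected(self, params):
        with pytest.raises(ValueError, match="unknown channel"):
            detect_granules(np.zeros((32, 32)), [], params, "FITC")

    def test_eight_puncta_detected_and_assigned(self, params):
        field, truth, _ = _intact_field(1, 8, seed=8, shape=(256, 256))
        nuclei = segment_nuclei(field.channels["DAPI"].astype(float), params)
        regions = assign_cell_regions(nuclei, field.shape, params)
        granules = detect_granules(field.channels["TexasRed"], regions, params,
                                   "TexasRed")
        assert len(granules) == 8
        assert {g.cell_id for g in granules} == {nuclei[0].label}

    def test_oversized_blob_excluded_by_diameter_rule(self, params):
        field, truth, cfg = _intact_field(1, 0, seed=9, shape=(256, 256))
        img = field.channels["TexasRed"].astype(float)
        cy, cx = truth[0].nucleus_centroid
        # a blob with FWHM twice the accepted maximum diameter
        sigma = 2 * params.channels["TexasRed"].max_diameter / 2.3548
        yy, xx = np.mgrid[0:256, 0:256]
        img = img + 3000.0 * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
        nuclei = segment_nuclei(field.channels["DAPI"].astype(float), params)
        regions = assign_cell_regions(nuclei, field.shape, params)
        assert detect_granules(img, regions, params, "TexasRed") == []

    def test_threshold_monotonicity(self, params):
        field, truth, _ = _intact_field(4, None, seed=10, shape=(512, 512))
        nuclei = segment_nuclei(field.channels["DAPI"].astype(float), params)
        regions = assign_cell_regions(nuclei, field.shape, params)
        img = field.channels["TexasRed"]
        base = len(detect_granules(img, regions, params, "TexasRed"))
        stricter = dataclasses.replace(params)
        stricter.channels = dict(params.channels)
        stricter.channels["TexasRed"] = dataclasses.replace(
            params.channels["TexasRed"], intensity_threshold=1e7)
        assert len(detect_granules(img, regions, stricter, "TexasRed")) <= base
        wider = dataclasses.replace(params)
        wider.channels = dict(params.channels)
        wider.channels["TexasRed"] = dataclasses.replace(
            params.channels["TexasRed"], min_diameter=1.0, max_diameter=20.0)
        assert len(detect_granules(img, regions, wider, "TexasRed")) >= base

    def test_intensity_scale_invariance(self, params):
        field, truth, _ = _intact_field(4, None, seed=11, shape=(512, 512))
        nuclei = segment_nuclei(field.channels["DAPI"].astype(float), params)
        regions = assign_cell_regions(nuclei, field.shape, params)
        img = field.channels["TexasRed"].astype(float)
        base = detect_granules(img, regions, params, "TexasRed")
        scaled = detect_granules(img * 3.0, regions, params.scaled(3.0), "TexasRed")
        assert len(scaled) == len(base)
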