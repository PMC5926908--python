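"""Tests for nucleus detection, body growth and positivity classification."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist

from blisterquant.cells import (
    CellRecord,
    classify_cells,
    density_report,
    detect_nuclei,
    grow_cell_bodies,
    split_merged_nuclei,
)
from blisterquant.config import CellConfig
from blisterquant.stains import stain_rasters
from blisterquant.synthetic import (
    OpticalModel,
    SlideSpec,
    centroid_f1,
    generate_ihc_slide,
)

PX = 0.45  # um per pixel


def _disk(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestDetectNuclei:
    def test_area_floor_is_physical(self):
        """49 px (9.92 um^2) rejected, 81 px (16.4 um^2) retained at 0.45 um/px."""
        nb = np.zeros((64, 64))
        nb[5:12, 5:12] = 0.5  # 49 px
        nb[30:39, 30:39] = 0.5  # 81 px
        tissue = np.ones((64, 64), dtype=bool)
        labels = detect_nuclei(nb, tissue, CellConfig(), PX)
        assert labels[8, 8] == 0
        assert labels[34, 34] > 0
        assert labels.max() == 1

    def test_blue_threshold_is_strict(self):
        nb = np.full((64, 64), 0.1)
        tissue = np.ones((64, 64), dtype=bool)
        labels = detect_nuclei(nb, tissue, CellConfig(), PX)
        assert labels.max() == 0

    def test_oversized_component_discarded_as_artifact(self):
        nb = np.zeros((120, 120))
        nb[_disk((120, 120), (60, 60), 20)] = 0.5  # ~1257 px = 254 um^2 > 150
        tissue = np.ones((120, 120), dtype=bool)
        labels = detect_nuclei(nb, tissue, CellConfig(), PX)
        assert labels.max() == 0

    def test_detection_restricted_to_tissue(self):
        nb = np.zeros((64, 64))
        nb[_disk((64, 64), (20, 20), 6)] = 0.5
        tissue = np.zeros((64, 64), dtype=bool)
        labels = detect_nuclei(nb, tissue, CellConfig(), PX)
        assert labels.max() == 0


class TestSplitMergedNuclei:
    def test_single_disk_is_not_split(self):
        labels = _disk((40, 40), (20, 20), 7).astype(np.int32)
        out = split_merged_nuclei(labels, pixel_size_um=PX)
        assert out.max() == 1
        assert np.array_equal(out > 0, labels > 0)

    def test_generator_merged_pair_splits_into_two(self):
        spec = SlideSpec(shape=(384, 384), n_positive=1, n_negative=1, n_merged_pairs=1)
        slide, truth = generate_ihc_slide(spec, OpticalModel(noise_sd=0.0), seed=4)
        rasters = stain_rasters(slide)
        labels = detect_nuclei(rasters["normalized_blue"], truth.tissue_mask, CellConfig(), PX)
        assert labels.max() == 2
        found = np.array(ndi.center_of_mass(labels > 0, labels, [1, 2]))
        planted = np.array([c.centroid_rc for c in truth.cells])
        d = cdist(found, planted)
        assert min(d[0, 0] + d[1, 1], d[0, 1] + d[1, 0]) / 2 <= 2.0

    def test_idempotence(self):
        spec = SlideSpec(shape=(384, 384), n_positive=1, n_negative=1, n_merged_pairs=1)
        slide, truth = generate_ihc_slide(spec, OpticalModel(noise_sd=0.0), seed=6)
        rasters = stain_rasters(slide)
        labels = detect_nuclei(rasters["normalized_blue"], truth.tissue_mask, CellConfig(), PX)
        again = split_merged_nuclei(labels, pixel_size_um=PX)
        assert again.max() == labels.max()
        assert np.array_equal(again > 0, labels > 0)


def _nearest_nucleus_oracle(nucleus_labels, candidates):
    """Per-pixel nearest-nucleus assignment by direct distance computation."""
    coords = np.column_stack(np.nonzero(nucleus_labels > 0))
    labs = nucleus_labels[nucleus_labels > 0]
    pts = np.column_stack(np.nonzero(candidates))
    owners = np.zeros(len(pts), dtype=int)
    d = cdist(pts, coords)
    for i in range(len(pts)):
        dmin = d[i].min()
        owners[i] = labs[d[i] <= dmin + 1e-9].min()
    return pts, owners


class TestGrowCellBodies:
    def test_isolated_nucleus_gets_annulus(self):
        labels = _disk((64, 64), (32, 32), 6).astype(np.int32)
        tissue = np.ones((64, 64), dtype=bool)
        bodies = grow_cell_bodies(labels, tissue, CellConfig(), PX)
        # growth proceeds in 8-connected steps: the halo is a chessboard annulus
        dist = ndi.distance_transform_cdt(labels == 0, metric="chessboard")
        expected = (dist <= 7) & (labels == 0)
        assert np.array_equal(bodies > 0, expected)

    def test_two_nuclei_partition_at_equidistance(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[_disk((64, 64), (32, 22), 4)] = 1
        labels[_disk((64, 64), (32, 32), 4)] = 2
        tissue = np.ones((64, 64), dtype=bool)
        bodies = grow_cell_bodies(labels, tissue, CellConfig(), PX)
        pts, owners = _nearest_nucleus_oracle(labels, bodies > 0)
        assert np.array_equal(bodies[pts[:, 0], pts[:, 1]], owners)

    def test_body_clipped_to_tissue(self):
        labels = _disk((64, 64), (32, 30), 6).astype(np.int32)
        tissue = np.zeros((64, 64), dtype=bool)
        tissue[:, :36] = True
        bodies = grow_cell_bodies(labels, tissue, CellConfig(), PX)
        assert not bodies[:, 36:].any()
        assert bodies.any()

    def test_bodies_and_nuclei_disjoint_with_bounded_depth(self, default_slide):
        slide, truth = default_slide
        rasters = stain_rasters(slide)
        nuclei = detect_nuclei(rasters["normalized_blue"], truth.tissue_mask, CellConfig(), PX)
        bodies = grow_cell_bodies(nuclei, truth.tissue_mask, CellConfig(), PX)
        assert not ((nuclei > 0) & (bodies > 0)).any()
        dist = ndi.distance_transform_edt(nuclei == 0)
        # chessboard-geodesic depth bounds the Euclidean distance
        assert dist[bodies > 0].max() <= 7 * np.sqrt(2) + 1e-9


def brute_force_classify(nucleus_labels, body_labels, brown_pos, config):
    """Per-pixel loop oracle for the positivity rules."""
    n = int(max(nucleus_labels.max(), body_labels.max()))
    out = []
    for lab in range(1, n + 1):
        nuc_px = dab_nuc = body_px = dab_body = 0
        for i in range(nucleus_labels.shape[0]):
            for j in range(nucleus_labels.shape[1]):
                is_dab = brown_pos[i, j] > config.dab_pixel_threshold
                if nucleus_labels[i, j] == lab:
                    nuc_px += 1
                    dab_nuc += is_dab
                if body_labels[i, j] == lab:
                    body_px += 1
                    dab_body += is_dab
        nf = dab_nuc / nuc_px if nuc_px else 0.0
        bf = dab_body / body_px if body_px else 0.0
        np_flag = nf > config.nucleus_positive_fraction
        bp_flag = bf > config.body_positive_fraction
        out.append((nf, bf, np_flag, bp_flag, np_flag or bp_flag))
    return out


class TestClassifyCells:
    def _records(self, nuc, body, brown, config=None):
        return classify_cells(nuc, body, brown, config or CellConfig())

    def test_body_coverage_rule(self):
        nuc = np.zeros((10, 10), dtype=int)
        body = np.zeros((10, 10), dtype=int)
        nuc[0, :4] = 1
        body[1, :4] = 1
        brown = np.zeros((10, 10))
        brown[1, 0] = 0.5  # body coverage 0.25 > 0.20
        (rec,) = self._records(nuc, body, brown)
        assert rec.body_positive and not rec.nucleus_positive
        assert rec.cell_positive

    def test_nucleus_coverage_exactly_forty_percent_is_negative(self):
        nuc = np.zeros((10, 10), dtype=int)
        nuc[0, :10] = 1
        body = np.zeros((10, 10), dtype=int)
        brown = np.zeros((10, 10))
        brown[0, :4] = 0.5  # coverage exactly 0.40
        (rec,) = self._records(nuc, body, brown)
        assert rec.nucleus_dab_fraction == pytest.approx(0.40)
        assert not rec.nucleus_positive
        brown[0, 4] = 0.5  # 0.50 > 0.40
        (rec,) = self._records(nuc, body, brown)
        assert rec.nucleus_positive

    def test_dab_pixel_threshold_is_strict(self):
        nuc = np.zeros((4, 4), dtype=int)
        nuc[0] = 1
        brown = np.full((4, 4), 0.1)  # exactly at threshold: no DAB pixel
        (rec,) = self._records(nuc, np.zeros_like(nuc), brown)
        assert rec.nucleus_dab_fraction == 0.0

    def test_empty_body_warns_and_counts_zero(self, caplog):
        nuc = np.zeros((4, 4), dtype=int)
        nuc[0] = 1
        (rec,) = self._records(nuc, np.zeros_like(nuc), np.ones((4, 4)))
        assert rec.body_area_px == 0
        assert rec.body_dab_fraction == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_per_pixel_oracle(self, seed):
        """Vectorized classification equals the brute-force loop, including
        planted coverage values at exactly 0.20 and 0.40."""
        rng = np.random.default_rng(seed)
        config = CellConfig()
        nuc = np.zeros((64, 64), dtype=int)
        body = np.zeros((64, 64), dtype=int)
        for lab in range(1, 6):
            r, c = rng.integers(5, 59, 2)
            nuc[_disk((64, 64), (r, c), 3) & (nuc == 0) & (body == 0)] = lab
            ring = _disk((64, 64), (r, c), 6) & (nuc == 0) & (body == 0)
            body[ring] = lab
        brown = rng.normal(0.05, 0.1, (64, 64))
        # plant exact boundary coverages on labels 1 and 2
        for lab, frac in ((1, config.body_positive_fraction), (2, config.nucleus_positive_fraction)):
            region = body == lab if lab == 1 else nuc == lab
            idx = np.argwhere(region)
            n_dab = int(round(frac * len(idx)))
            brown[tuple(idx[:n_dab].T)] = 0.5
            brown[tuple(idx[n_dab:].T)] = 0.0
        records = self._records(nuc, body, brown, config)
        oracle = brute_force_classify(nuc, body, brown, config)
        for rec, (nf, bf, np_flag, bp_flag, cp) in zip(records, oracle):
            assert rec.nucleus_dab_fraction == pytest.approx(nf)
            assert rec.body_dab_fraction == pytest.approx(bf)
            assert rec.nucleus_positive == np_flag
            assert rec.body_positive == bp_flag
            assert rec.cell_positive == cp


def _make_cell(cell_id, rc, positive):
    return CellRecord(
        cell_id=cell_id, centroid_rc=rc, nucleus_area_px=10, body_area_px=20,
        nucleus_dab_fraction=0.0, body_dab_fraction=1.0 if positive else 0.0,
        nucleus_positive=False, body_positive=positive, cell_positive=positive,
    )


class TestDensityReport:
    def test_mean_is_arithmetic_mean_of_roi_densities(self):
        tissue = np.ones((20, 20), dtype=bool)
        roi_a = np.zeros_like(tissue)
        roi_a[:, :10] = True
        roi_b = ~roi_a
        cells = [
            _make_cell(1, (5.0, 5.0), True),
            _make_cell(2, (5.0, 15.0), True),
            _make_cell(3, (15.0, 15.0), True),
            _make_cell(4, (10.0, 2.0), False),
        ]
        report = density_report(cells, [roi_a, roi_b], tissue, 1.0)
        assert report.roi_positive_counts == [1, 2]
        assert report.roi_densities == pytest.approx([1 / 200, 2 / 200])
        assert report.mean_density == pytest.approx(np.mean(report.roi_densities))

    def test_no_positive_cells_gives_zero_density(self):
        tissue = np.ones((10, 10), dtype=bool)
        cells = [_make_cell(1, (5.0, 5.0), False)]
        report = density_report(cells, [tissue.copy()], tissue, 0.45)
        assert report.mean_density == 0.0

    def test_single_roi_reduces_to_global_density(self):
        tissue = np.ones((10, 10), dtype=bool)
        cells = [_make_cell(i, (float(i), float(i)), True) for i in range(1, 4)]
        report = density_report(cells, [tissue.copy()], tissue, 1.0)
        assert report.mean_density == pytest.approx(3 / 100)

    def test_roi_permutation_invariance(self):
        tissue = np.ones((20, 20), dtype=bool)
        roi_a = np.zeros_like(tissue)
        roi_a[:10] = True
        roi_b = ~roi_a
        cells = [_make_cell(1, (2.0, 2.0), True), _make_cell(2, (15.0, 15.0), True)]
        r1 = density_report(cells, [roi_a, roi_b], tissue, 1.0)
        r2 = density_report(cells, [roi_b, roi_a], tissue, 1.0)
        assert r1.mean_density == pytest.approx(r2.mean_density)

    def test_zero_tissue_roi_excluded(self):
        tissue = np.zeros((10, 10), dtype=bool)
        tissue[:5] = True
        empty_roi = np.zeros_like(tissue)
        empty_roi[8:] = True
        full_roi = tissue.copy()
        cells = [_make_cell(1, (2.0, 2.0), True)]
        report = density_report(cells, [full_roi, empty_roi], tissue, 1.0)
        assert len(report.roi_densities) == 1


class TestEndToEndRecovery:
    def test_planted_cells_recovered(self, default_slide):
        """Centroid-matched F1 and positive fraction on the standard slide."""
        from blisterquant.pipeline import run_ihc_pipeline

        slide, truth = default_slide
        result = run_ihc_pipeline(slide)
        detected = np.array([c.centroid_rc for c in result["cells"]])
        planted = np.array([c.centroid_rc for c in truth.cells])
        assert centroid_f1(detected, planted, max_dist_px=5.0) >= 0.95
        detected_frac = np.mean([c.cell_positive for c in result["cells"]])
        assert abs(detected_frac - truth.positive_fraction) <= 0.05
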