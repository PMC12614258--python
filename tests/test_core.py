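"""Domain types, raster I/O and the box-table format."""

import numpy as np
import pytest

from ccfdgrid import (AnalysisConfig, BinaryCCFDMap, BoxObservation,
                      EnFaceImage, MaskImage, ShapeMismatchError, VisitRecord,
                      load_visit, read_box_table, read_ccfd_map, read_mask,
                      read_slab, write_box_table, write_ccfd_map, write_mask,
                      write_slab)
from ccfdgrid.core import DEFICIT, FLOW, INVALID


def _write_case_files(tmp_path, shape=(120, 120), mask_shape=None):
    rng = np.random.default_rng(0)
    paths = {}
    for role in ("cc_flow", "cc_structure", "subrpe_structure", "vasculature"):
        p = tmp_path / f"{role}.tif"
        write_slab(p, EnFaceImage(rng.integers(0, 4000, shape).astype(float),
                                  slab_name=role))
        paths[role] = p
    for role in ("exclusion_mask", "hypertd_mask"):
        p = tmp_path / f"{role}.png"
        arr = np.zeros(mask_shape or shape, dtype=bool)
        arr[:5, :5] = True
        write_mask(p, MaskImage(arr, kind="exclusion"))
        paths[role] = p
    return paths


class TestEnFaceImage:
    def test_rejects_negative_and_nonfinite_intensities(self):
        with pytest.raises(ValueError):
            EnFaceImage(np.array([[-1.0, 0.0]]))
        with pytest.raises(ValueError):
            EnFaceImage(np.array([[np.nan, 0.0]]))

    def test_rejects_bad_spacing_and_slab_name(self):
        with pytest.raises(ValueError):
            EnFaceImage(np.ones((4, 4)), spacing_um=0.0)
        with pytest.raises(ValueError):
            EnFaceImage(np.ones((4, 4)), slab_name="retina")


class TestRasterIO:
    def test_slab_roundtrip_preserves_integer_pixels(self, tmp_path):
        arr = np.arange(0, 65536, 257).reshape(16, 16).astype(float)
        img = EnFaceImage(arr, slab_name="cc_flow")
        for suffix in (".tif", ".png"):
            path = tmp_path / f"slab{suffix}"
            write_slab(path, img)
            back = read_slab(path, "cc_flow")
            np.testing.assert_array_equal(back.pixels, arr)

    def test_mask_roundtrip_and_binarization_at_nonzero(self, tmp_path):
        arr = np.zeros((8, 8), dtype=bool)
        arr[2:5, 3:6] = True
        path = tmp_path / "mask.png"
        write_mask(path, MaskImage(arr, kind="hypertd"))
        back = read_mask(path, "hypertd")
        np.testing.assert_array_equal(back.pixels, arr)

    def test_ccfd_map_roundtrip(self, tmp_path):
        state = np.array([[FLOW, DEFICIT], [INVALID, FLOW]], dtype=np.uint8)
        path = tmp_path / "map.png"
        write_ccfd_map(path, BinaryCCFDMap(state))
        back = read_ccfd_map(path)
        np.testing.assert_array_equal(back.state, state)


class TestLoadVisit:
    def test_loads_consistent_visit(self, tmp_path):
        paths = _write_case_files(tmp_path)
        rec = load_visit(paths, {"visit_index": 2, "eye_id": "OD", "patient_id": "p1"})
        assert rec.shape == (120, 120)
        assert rec.visit_index == 2
        assert rec.exclusion_mask.pixels[:5, :5].all()
        assert rec.vessel_mask is None

    def test_shape_mismatch_names_offending_file(self, tmp_path):
        paths = _write_case_files(tmp_path, mask_shape=(119, 120))
        with pytest.raises(ShapeMismatchError, match="exclusion_mask"):
            load_visit(paths, {"visit_index": 0})

    def test_unreadable_file_raises_io_error(self, tmp_path):
        paths = _write_case_files(tmp_path)
        paths["cc_flow"] = tmp_path / "nope.tif"
        with pytest.raises(IOError):
            load_visit(paths, {"visit_index": 0})


class TestVisitRecord:
    def test_rejects_inconsistent_raster_shapes(self):
        img = EnFaceImage(np.ones((10, 10)))
        bad = EnFaceImage(np.ones((10, 11)))
        mask = MaskImage(np.zeros((10, 10), dtype=bool))
        with pytest.raises(ShapeMismatchError):
            VisitRecord(visit_index=0, cc_flow=img, cc_structure=bad,
                        subrpe_structure=img, vasculature=img,
                        exclusion_mask=mask, hypertd_mask=mask)


def _observations(n_boxes=2, n_visits=4):
    obs = []
    for b in range(n_boxes):
        for v in range(n_visits):
            obs.append(BoxObservation(
                patient_id="p0", eye_id="e0", box_id=b, visit_index=v,
                category="target" if b == 0 else "adjacent_background",
                ccfd_pct=10.0 + b + 0.123456789 * v, valid_frac=0.97,
                included=True))
    return obs


class TestBoxTable:
    def test_row_count_one_per_eye_box_visit(self, tmp_path):
        path = tmp_path / "t.csv"
        write_box_table(_observations(), path)
        assert len(read_box_table(path)) == 8

    def test_roundtrip_values_identical(self, tmp_path):
        path = tmp_path / "t.csv"
        obs = _observations()
        write_box_table(obs, path)
        back = read_box_table(path)
        for o, (_, row) in zip(obs, back.iterrows()):
            assert abs(row["ccfd_pct"] - o.ccfd_pct) < 1e-9
            assert row["included"] == o.included

    def test_empty_observation_list_is_an_error(self, tmp_path):
        with pytest.raises(ValueError):
            write_box_table([], tmp_path / "t.csv")


class TestAnalysisConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = AnalysisConfig(box_px=50, mdc_pct=4.0)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert AnalysisConfig.from_yaml(path) == cfg

    @pytest.mark.parametrize("kw", [
        {"box_px": 0}, {"gamma_grid": ()}, {"gamma_grid": (1.0, 0.5)},
        {"max_invalid_frac": 1.5}, {"mdc_pct": -1.0},
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            AnalysisConfig(**kw)
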