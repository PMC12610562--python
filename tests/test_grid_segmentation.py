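"""Grid handling, the tray color rule, and per-cell statistics."""

import numpy as np
import pytest

from conftest import oracle_percentile
from kernelpheno import grid_segmentation as gs
from kernelpheno import synthetic_tray as st


def _cell_image(side=270, kernel_px=0, kernel_rgb=(150, 120, 90)):
    """One tray-colored cell with an optional uniform kernel block."""
    img = np.empty((side, side, 3), np.uint8)
    img[:] = st.TRAY_FACE_RGB
    if kernel_px:
        w = int(np.ceil(np.sqrt(kernel_px)))
        flat = np.zeros(w * w, bool)
        flat[:kernel_px] = True
        block = img[10 : 10 + w, 10 : 10 + w]
        block[flat.reshape(w, w)] = kernel_rgb
    return img


class TestLoadGrid:
    def test_default_grid_has_100_cells_of_side_270(self):
        grid = gs.default_grid()
        assert len(grid) == 100
        assert all(b.side == 270 for b in grid)

    def test_parametric_config(self):
        grid = gs.load_grid(
            {"origin_x": 4, "origin_y": 4, "pitch_x": 278, "pitch_y": 278, "side": 270}
        )
        boxes = {(b.row, b.col): b for b in grid}
        assert boxes[(0, 0)].x == 4
        assert boxes[(9, 9)].x == 4 + 9 * 278

    def test_explicit_list_round_trips(self, tmp_path):
        import json

        cells = [
            {"row": r, "col": c, "x": 4 + c * 278, "y": 4 + r * 278, "side": 270}
            for r in range(10)
            for c in range(10)
        ]
        path = tmp_path / "grid.json"
        path.write_text(json.dumps({"cells": cells}))
        assert len(gs.load_grid(path)) == 100

    def test_99_boxes_rejected(self):
        cells = [
            {"row": r, "col": c, "x": 4 + c * 278, "y": 4 + r * 278}
            for r in range(10)
            for c in range(10)
        ][:-1]
        with pytest.raises(gs.GridValidationError, match="99"):
            gs.load_grid({"cells": cells})

    def test_overlapping_boxes_rejected(self):
        cells = [
            {"row": r, "col": c, "x": c * 200, "y": r * 200, "side": 270}
            for r in range(10)
            for c in range(10)
        ]
        with pytest.raises(gs.GridValidationError, match="overlap"):
            gs.load_grid({"cells": cells})


class TestTrayRule:
    @pytest.mark.parametrize(
        "rgb,is_tray",
        [
            ((50, 100, 90), True),  # r - b = -40: boundary is tray
            ((50, 100, 89), False),  # r - b = -39: kernel
            ((200, 180, 140), False),  # warm kernel color
            (st.TRAY_FACE_RGB, True),
            (st.TRAY_WALL_RGB, True),
        ],
    )
    def test_boundary_and_typical_pixels(self, rgb, is_tray):
        assert gs.tray_mask(np.array([[rgb]], np.uint8))[0, 0] == is_tray

    def test_partition_within_cell(self):
        rng = np.random.default_rng(5)
        px = rng.integers(0, 256, (50, 50, 3), dtype=np.uint8)
        tray = gs.tray_mask(px)
        assert (tray | ~tray).all()  # every pixel classified exactly once


class TestSegmentCell:
    CELL = gs.CellBox(row=0, col=0, x=0, y=0, side=270)

    def test_uniform_kernel_statistics(self):
        img = _cell_image(kernel_px=600)
        rec = gs.segment_cell(img, self.CELL)
        assert not rec.is_empty
        assert rec.n_pixels == 600
        assert rec.stats["R_mean"] == 150.0
        for q in gs.PERCENTILES:
            assert rec.stats[f"R_p{q}"] == 150.0

    def test_sub_threshold_debris_is_empty(self):
        rec = gs.segment_cell(_cell_image(kernel_px=499), self.CELL)
        assert rec.is_empty
        assert rec.n_pixels == 499
        assert rec.stats == {}

    def test_500_pixels_is_a_kernel(self):
        assert not gs.segment_cell(_cell_image(kernel_px=500), self.CELL).is_empty

    def test_cell_outside_image_raises(self):
        with pytest.raises(ValueError):
            gs.segment_cell(_cell_image(), gs.CellBox(0, 1, 200, 0, 270))

    def test_percentiles_match_brute_force_oracle(self, small_render, small_scene):
        """Statistics equal a sort+interpolate oracle over the ground-truth
        mask pixels, exactly, for every kernel and channel."""
        img, truth = small_render
        geo = small_scene.geometry
        tray = img[
            geo.tray_y0 : geo.tray_y0 + geo.tray_side,
            geo.tray_x0 : geo.tray_x0 + geo.tray_side,
        ]
        recs = {r.cell: r for r in gs.segment_image(tray, geo.grid())}
        from kernelpheno.color_model import rgb_to_lab

        for ci, (ys, xs) in truth.masks.items():
            rec = recs[(ci // 10, ci % 10)]
            if ys.size < gs.MIN_KERNEL_PIXELS:
                assert rec.is_empty  # sub-threshold blobs never become kernels
                continue
            px = tray[ys, xs].astype(float)
            L, a, b = rgb_to_lab(px[:, 0], px[:, 1], px[:, 2])
            chans = dict(zip(gs.CHANNELS, (px[:, 0], px[:, 1], px[:, 2], L, a, b)))
            assert rec.n_pixels == ys.size
            for ch, vals in chans.items():
                assert rec.stats[f"{ch}_mean"] == pytest.approx(vals.mean(), abs=1e-9)
                for q in gs.PERCENTILES:
                    assert rec.stats[f"{ch}_p{q}"] == pytest.approx(
                        oracle_percentile(vals, q), abs=1e-9
                    )
            rec.validate()  # percentile monotonicity invariant


class TestSegmentImage:
    def test_kernel_count_matches_ground_truth(self, small_geo):
        scene = st.random_scene(seed=31, geometry=small_geo, fill_fraction=0.4)
        img, truth = st.render_tray(scene)
        tray = img[
            small_geo.tray_y0 : small_geo.tray_y0 + 1000,
            small_geo.tray_x0 : small_geo.tray_x0 + 1000,
        ]
        recs = gs.segment_image(tray, small_geo.grid())
        assert len(recs) == 100
        non_empty = [r for r in recs if not r.is_empty]
        big_enough = [
            s for s in scene.kernels if s.area_px >= gs.MIN_KERNEL_PIXELS
        ]
        assert len(non_empty) == len(big_enough)
        for rec, spec in zip(
            sorted(non_empty, key=lambda r: r.cell),
            sorted(big_enough, key=lambda s: s.cell_index),
        ):
            assert rec.cell == (spec.cell_index // 10, spec.cell_index % 10)
            assert rec.n_pixels == spec.area_px  # exact bookkeeping, noise-free

    def test_empty_tray_gives_100_empty_records(self, small_geo):
        scene = st.TrayScene(kernels=[], geometry=small_geo)
        img, truth = st.render_tray(scene)
        tray = img[
            small_geo.tray_y0 : small_geo.tray_y0 + 1000,
            small_geo.tray_x0 : small_geo.tray_x0 + 1000,
        ]
        recs = gs.segment_image(tray, small_geo.grid())
        assert all(r.is_empty for r in recs)

    def test_debris_in_empty_cells_changes_no_kernel_record(self, small_geo):
        base = st.random_scene(seed=33, geometry=small_geo, fill_fraction=0.5)
        with_debris = st.random_scene(
            seed=33, geometry=small_geo, fill_fraction=0.5, n_debris=5
        )
        assert with_debris.debris  # debris actually placed

        def records(scene):
            img, _ = st.render_tray(scene)
            tray = img[
                small_geo.tray_y0 : small_geo.tray_y0 + 1000,
                small_geo.tray_x0 : small_geo.tray_x0 + 1000,
            ]
            return [r for r in gs.segment_image(tray, small_geo.grid()) if not r.is_empty]

        r0, r1 = records(base), records(with_debris)
        assert len(r0) == len(r1)
        for a, b in zip(r0, r1):
            assert a.cell == b.cell
            assert a.stats == b.stats
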