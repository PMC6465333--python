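"""Simulator contracts: geometry invariants, spot placement, rendering, Cp model."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cotranscoloc.ripqpcr import percent_input
from cotranscoloc.synthetic import (
    CpSimParams,
    PlacementError,
    SceneParams,
    render_stacks,
    simulate_cp_table,
    simulate_scene,
)


def test_empty_scene_has_masks_only():
    p = SceneParams(shape=(6, 80, 80), n_cells=1, cell_radii_px=(15, 18),
                    nucleus_radii_px=(6, 7), spots_per_cell_ch1=0,
                    spots_per_cell_ch2=0, seed=1)
    scene = simulate_scene(p)
    assert scene.geometry.cell_ids == [1]
    assert len(scene.spots["ch1"]) == 0


def test_rho_one_zero_jitter_gives_exact_partners():
    p = SceneParams(shape=(8, 140, 140), n_cells=2, cell_radii_px=(18, 22),
                    nucleus_radii_px=(7, 8), spots_per_cell_ch1=50,
                    spots_per_cell_ch2=50, coloc_fraction=1.0,
                    coloc_jitter_nm=0.0, seed=2)
    scene = simulate_scene(p)
    t2 = scene.spots["ch2"].table
    assert (t2["partner_id"] >= 0).all()
    for cid in scene.geometry.cell_ids:
        a = scene.spots_in_cell("ch1", cid).coords_nm()
        sub = t2[t2["cell_id"] == cid]
        b = sub[["z_nm", "y_nm", "x_nm"]].to_numpy()
        partners = a[sub["partner_id"].to_numpy()]
        assert np.allclose(b, partners)


def test_partner_count_and_jitter_bound():
    jitter = 40.0
    p = SceneParams(shape=(10, 140, 140), n_cells=1, cell_radii_px=(25, 30),
                    nucleus_radii_px=(9, 11), spots_per_cell_ch1=100,
                    spots_per_cell_ch2=100, coloc_fraction=0.4,
                    coloc_jitter_nm=jitter, seed=3)
    scene = simulate_scene(p)
    t2 = scene.spots["ch2"].table
    partnered = t2[t2["partner_id"] >= 0]
    assert len(partnered) == 40  # exactly round(rho * n)
    a = scene.spots["ch1"].coords_nm()
    b = partnered[["z_nm", "y_nm", "x_nm"]].to_numpy()
    delta = np.abs(b - a[partnered["partner_id"].to_numpy()])
    assert (delta <= 3 * jitter + 1e-9).all()  # truncated jitter, per axis


def test_every_spot_inside_one_cell_cytoplasm(small_scene):
    geom = small_scene.geometry
    for chan, ss in small_scene.spots.items():
        t = ss.table
        yi = np.round(t["y_nm"] / 70.0).astype(int)
        xi = np.round(t["x_nm"] / 70.0).astype(int)
        cell_at = geom.cell_labels[yi, xi]
        nuc_at = geom.nucleus_labels[yi, xi]
        assert (cell_at == t["cell_id"]).all(), chan
        assert (nuc_at == 0).all(), chan


def test_seed_determinism():
    p = SceneParams(shape=(6, 100, 100), n_cells=1, cell_radii_px=(16, 20),
                    nucleus_radii_px=(6, 7), spots_per_cell_ch1=20,
                    spots_per_cell_ch2=10, seed=9)
    s1, s2 = simulate_scene(p), simulate_scene(p)
    pd.testing.assert_frame_equal(s1.spots["ch1"].table, s2.spots["ch1"].table)
    c1, _ = render_stacks(s1)
    c2, _ = render_stacks(s2)
    for name in c1:
        np.testing.assert_array_equal(c1[name].data, c2[name].data)
    cp = CpSimParams(cp_noise_sd=0.3, seed=4)
    pd.testing.assert_frame_equal(simulate_cp_table(cp), simulate_cp_table(cp))


def test_placement_rejects_impossible_scene():
    with pytest.raises(PlacementError):
        simulate_scene(SceneParams(shape=(4, 60, 60), n_cells=9,
                                   cell_radii_px=(20, 20), nucleus_radii_px=(5, 5)))


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SceneParams(coloc_fraction=1.2).validate()
    with pytest.raises(ValueError):
        SceneParams(nucleus_radii_px=(40.0, 40.0)).validate()


class TestRender:
    def _one_spot_scene(self, **over):
        p = SceneParams(shape=(9, 90, 90), n_cells=1, cell_radii_px=(25, 30),
                        nucleus_radii_px=(8, 9), spots_per_cell_ch1=1,
                        camera_noise_sd=0.0, fish_background=0.0, seed=5, **over)
        return simulate_scene(p), p

    def test_no_spots_no_noise_is_background_only(self):
        p = SceneParams(shape=(6, 90, 90), n_cells=1, cell_radii_px=(22, 26),
                        nucleus_radii_px=(8, 9), spots_per_cell_ch1=0,
                        camera_noise_sd=0.0, fish_background=0.0, seed=6)
        scene = simulate_scene(p)
        chans, _ = render_stacks(scene)
        assert chans["fish1"].data.max() == 0.0

    def test_gaussian_peak_equals_amplitude_at_spot_voxel(self):
        scene, p = self._one_spot_scene(spot_amplitude=100.0)
        # move the single spot onto an exact voxel centre
        t = scene.spots["ch1"].table
        t.loc[0, ["z_nm", "y_nm", "x_nm"]] = [4 * p.voxel_z_nm, 45 * p.voxel_xy_nm,
                                              45 * p.voxel_xy_nm]
        chans, _ = render_stacks(scene)
        assert chans["fish1"].data[4, 45, 45] == 100.0
        assert chans["fish1"].data.max() == 100.0

    def test_if_voxel_at_spot_is_r_times_background(self):
        scene, p = self._one_spot_scene(if_enrichment=2.0, if_background=100.0,
                                        if_background_cv=0.0, if_noise_sd=0.0)
        chans, _ = render_stacks(scene)
        c = scene.spots["ch1"].coords_nm()[0]
        zi, yi, xi = (int(round(c[0] / p.voxel_z_nm)), int(round(c[1] / p.voxel_xy_nm)),
                      int(round(c[2] / p.voxel_xy_nm)))
        assert chans["if"].data[zi, yi, xi] == 200.0

    def test_overflow_amplitude_clipped_and_reported(self):
        scene, _ = self._one_spot_scene(spot_amplitude=400.0)
        with pytest.warns(UserWarning, match="8-bit"):
            chans, report = render_stacks(scene)
        assert report.clipped_voxels["fish1"] > 0
        assert chans["fish1"].data.max() == 255.0

    def test_rendered_maxima_land_on_true_spots(self):
        """With no noise and well-separated spots, every bright local max
        lies within one voxel of a true spot."""
        from scipy import ndimage as ndi

        p = SceneParams(shape=(12, 160, 160), n_cells=1, cell_radii_px=(40, 50),
                        nucleus_radii_px=(12, 14), spots_per_cell_ch1=12,
                        camera_noise_sd=0.0, fish_background=0.0, seed=8)
        scene = simulate_scene(p)
        chans, _ = render_stacks(scene)
        img = chans["fish1"].data
        maxima = (img == ndi.maximum_filter(img, size=3)) & (img > 50)
        coords = np.argwhere(maxima).astype(float)
        true_vox = scene.spots["ch1"].coords_nm() / np.array([300.0, 70.0, 70.0])
        for c in coords:
            assert np.min(np.abs(true_vox - c).max(axis=1)) <= 1.0


class TestCpTable:
    def test_shapes_and_roles(self):
        p = CpSimParams(n_bio=3, n_tech=1, include_rt_minus=False, seed=0)
        table = simulate_cp_table(p)
        counts = table.groupby(["gene", "role", "rt"]).size()
        assert (counts == 3).all()
        assert set(table["role"]) == {"input", "ip", "mock"}

    @pytest.mark.parametrize("eff,expected", [(0.01, 1.0), (0.25, 25.0), (0.1, 10.0)])
    def test_noise_free_percent_input_roundtrip(self, eff, expected):
        p = CpSimParams(ip_efficiency=eff, cp_noise_sd=0.0, n_bio=1, n_tech=1,
                        include_rt_minus=False, seed=0)
        t = simulate_cp_table(p)
        g = t[t["gene"] == "Taf8"]
        cp_in = g.loc[g["role"] == "input", "cp"].iloc[0]
        cp_ip = g.loc[g["role"] == "ip", "cp"].iloc[0]
        assert percent_input(cp_in, cp_ip) == pytest.approx(expected, abs=1e-9)

    def test_rt_minus_rows_sit_12_cycles_up_or_undetected(self):
        t = simulate_cp_table(CpSimParams(cp_noise_sd=0.0, rt_minus_gap=15.0, seed=1))
        merged = t.pivot_table(index=["gene", "role", "bio_rep", "tech_rep"],
                               columns="rt", values="cp", dropna=False)
        detected = merged.dropna(subset=["minus"])
        assert (detected["minus"] - detected["plus"] >= 12.0 - 1e-9).all()

    def test_invalid_cp_params_rejected(self):
        with pytest.raises(ValueError):
            CpSimParams(ip_efficiency=1.5).validate()
        with pytest.raises(ValueError):
            CpSimParams(input_dilution=0.0).validate()
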