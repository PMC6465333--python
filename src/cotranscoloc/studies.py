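"""Simulation studies at fixed study conditions.

Each function runs one end-to-end validation study on synthetic scenes
with known ground truth — parameter recovery for the enrichment ratio
and the co-localized fraction, detector fidelity, KS calibration under
the null, qPCR round-trips, and segmentation accuracy — and returns the
measured quantities. They are used by the test suite and by the
reproducibility script; all randomness derives from the ``seed``
argument.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import SpotSet
from .dualcolor import (
    brute_force_match,
    coloc_fraction,
    greedy_match_cost,
    match_clouds,
    randomization_null,
)
from .enrichment import compare_ks, enrichment_ratio
from .ripqpcr import aggregate_replicates, percent_input
from .segmentation import focus_projection, segment_cells, segment_nuclei
from .spots import detect_spots
from .synthetic import SceneParams, render_stacks, simulate_scene

VOX = np.array([300.0, 70.0, 70.0])


def _seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([int(seed) % (2**31), salt]).generate_state(1)[0]
               % (2**31))


def _ratio_sample(n_cells: int, r: float, seed: int, spots_per_cell: int = 50,
                  cells_per_scene: int = 5) -> list[float]:
    """Per-cell enrichment ratios from scenes at IF enrichment factor r.

    IF noise SD is 10% of the cytoplasmic background.
    """
    ratios: list[float] = []
    n_scenes = -(-n_cells // cells_per_scene)
    for k in range(n_scenes):
        p = SceneParams(
            shape=(8, 220, 270), n_cells=cells_per_scene,
            cell_radii_px=(20.0, 25.0), nucleus_radii_px=(8.0, 10.0),
            spots_per_cell_ch1=spots_per_cell, if_enrichment=r,
            if_background=60.0, if_noise_sd=6.0, seed=_seed(seed, k),
        )
        scene = simulate_scene(p)
        chans, _ = render_stacks(scene, channels=("if",))
        for cid in scene.geometry.cell_ids:
            if len(ratios) >= n_cells:
                break
            ratios.append(
                enrichment_ratio(chans["if"], scene.spots["ch1"], scene.geometry,
                                 cid).ratio
            )
    return ratios


def enrichment_recovery(
    rs=(1.0, 1.5, 2.0, 3.0), n_cells: int = 30, seed: int = 0
) -> dict[float, float]:
    """Mean recovered enrichment ratio per simulated factor r."""
    return {
        r: float(np.mean(_ratio_sample(n_cells, r, _seed(seed, 1000 + i))))
        for i, r in enumerate(rs)
    }


def coloc_recovery(
    rhos=(0.0, 0.2, 0.5, 0.9), n_cells: int = 20, seed: int = 0,
    d_max_nm: float = 100.0, jitter_nm: float = 15.0,
) -> dict[float, float]:
    """Mean recovered co-localized fraction per simulated rho."""
    out: dict[float, float] = {}
    for i, rho in enumerate(rhos):
        fracs: list[float] = []
        k = 0
        while len(fracs) < n_cells:
            p = SceneParams(
                shape=(14, 180, 220), n_cells=4, cell_radii_px=(20.0, 25.0),
                nucleus_radii_px=(8.0, 10.0), spots_per_cell_ch1=40,
                spots_per_cell_ch2=40, coloc_fraction=rho,
                coloc_jitter_nm=jitter_nm, seed=_seed(seed, 2000 + 37 * i + k),
            )
            scene = simulate_scene(p)
            for cid in scene.geometry.cell_ids:
                if len(fracs) >= n_cells:
                    break
                a = scene.spots_in_cell("ch1", cid)
                b = scene.spots_in_cell("ch2", cid)
                fracs.append(coloc_fraction(match_clouds(a, b, d_max_nm)))
            k += 1
        out[rho] = float(np.mean(fracs))
    return out


def coloc_null_pvalues(seed: int = 0, d_max_nm: float = 100.0,
                       n_perm: int = 199) -> dict[float, float]:
    """Randomization-null p-values for one cell at rho = 0.5 and rho = 0."""
    out: dict[float, float] = {}
    for i, rho in enumerate((0.5, 0.0)):
        p = SceneParams(
            shape=(14, 180, 220), n_cells=3, cell_radii_px=(20.0, 25.0),
            nucleus_radii_px=(8.0, 10.0), spots_per_cell_ch1=40,
            spots_per_cell_ch2=40, coloc_fraction=rho, coloc_jitter_nm=15.0,
            seed=_seed(seed, 3000 + i),
        )
        scene = simulate_scene(p)
        cid = scene.geometry.cell_ids[0]
        a = scene.spots_in_cell("ch1", cid)
        b = scene.spots_in_cell("ch2", cid)
        _, pval = randomization_null(a, b, scene.geometry, cid, d_max_nm=d_max_nm,
                                     n_perm=n_perm, seed=_seed(seed, 3100 + i))
        out[rho] = pval
    return out


def _null_ratio_sample(seed: int, n_cells: int = 50, spots: int = 20) -> list[float]:
    """A compact r = 1 condition sample for null calibration (many small
    cells, modest spot count, so per-cell ratios are near-continuous)."""
    p = SceneParams(
        shape=(6, 200, 280), n_cells=n_cells, cell_radii_px=(12.0, 15.0),
        nucleus_radii_px=(5.0, 6.0), spots_per_cell_ch1=spots,
        if_enrichment=1.0, if_background=60.0, if_noise_sd=6.0, seed=seed,
    )
    scene = simulate_scene(p)
    chans, _ = render_stacks(scene, channels=("if",))
    return [
        enrichment_ratio(chans["if"], scene.spots["ch1"], scene.geometry, cid).ratio
        for cid in scene.geometry.cell_ids
    ]


def ks_null_rejection_rate(n_rep: int = 200, n_cells: int = 50, seed: int = 0,
                           alpha: float = 0.05) -> float:
    """Fraction of KS tests rejecting between two independent r = 1 samples."""
    rej = 0
    for k in range(n_rep):
        a = _null_ratio_sample(_seed(seed, 4000 + 2 * k), n_cells)
        b = _null_ratio_sample(_seed(seed, 4001 + 2 * k), n_cells)
        _, p = compare_ks(a, b)
        rej += p < alpha
    return rej / n_rep


def _min_separated_spots(scene, n_spots: int, min_sep_vox: float) -> None:
    """Thin a scene's channel-1 spots to a minimum pairwise lateral
    separation (voxel units), keeping exactly n_spots; edits in place."""
    t = scene.spots["ch1"].table
    coords = t[["z_nm", "y_nm", "x_nm"]].to_numpy() / VOX
    kept: list[int] = []
    for i in range(len(coords)):
        if all(np.linalg.norm(coords[i, 1:] - coords[j, 1:]) >= min_sep_vox
               for j in kept):
            kept.append(i)
        if len(kept) == n_spots:
            break
    if len(kept) < n_spots:
        raise RuntimeError("could not find enough separated spots; enlarge the cell")
    scene.spots["ch1"] = SpotSet(
        table=t.iloc[kept].reset_index(drop=True), channel="ch1",
        settings=scene.spots["ch1"].settings,
    )


def detection_fidelity(seed: int = 0, n_spots: int = 50,
                       amplitude_over_noise: float = 10.0,
                       sigma_xy: float = 1.3) -> dict[str, float]:
    """Recall/precision on noisy well-separated spots and noise-free RMSE.

    Spots are thinned to >= 6 sigma lateral separation; matches within 2
    voxels count as true positives.
    """
    p = SceneParams(
        shape=(16, 300, 300), n_cells=1, cell_radii_px=(130.0, 135.0),
        nucleus_radii_px=(20.0, 22.0), spots_per_cell_ch1=4 * n_spots,
        spot_amplitude=100.0, camera_noise_sd=100.0 / amplitude_over_noise,
        fish_background=0.0, sigma_xy_px=sigma_xy, seed=_seed(seed, 5000),
    )
    scene = simulate_scene(p)
    _min_separated_spots(scene, n_spots, 6 * sigma_xy)
    chans, _ = render_stacks(scene, channels=("fish1",))
    det = detect_spots(chans["fish1"], sigma_xy, 1.0, threshold=40.0)
    true = scene.spots["ch1"].coords_nm() / VOX
    got = det.coords_nm() / VOX
    d, _ = cKDTree(true).query(got) if len(got) else (np.array([]), None)
    tp = int((d <= 2.0).sum())
    recall = tp / len(true)
    precision = tp / max(len(got), 1)

    errs = []
    for k in range(3):
        pnf = SceneParams(
            shape=(14, 220, 220), n_cells=1, cell_radii_px=(95.0, 100.0),
            nucleus_radii_px=(16.0, 18.0), spots_per_cell_ch1=15,
            spot_amplitude=100.0, camera_noise_sd=0.0, fish_background=0.0,
            sigma_xy_px=sigma_xy, seed=_seed(seed, 5100 + k),
        )
        sc = simulate_scene(pnf)
        ch, _ = render_stacks(sc, channels=("fish1",))
        dd = detect_spots(ch["fish1"], sigma_xy, 1.0, threshold=30.0)
        tr = sc.spots["ch1"].coords_nm() / VOX
        gg = dd.coords_nm() / VOX
        dist, idx = cKDTree(tr).query(gg)
        keep = dist < 2.0
        errs.append(gg[keep] - tr[idx[keep]])
    errs = np.vstack(errs)
    rmse = np.sqrt((errs**2).mean(axis=0))
    return {
        "recall": recall,
        "precision": precision,
        "rmse_voxels_max_axis": float(rmse.max()),
    }


def lap_oracle_agreement(n_pairs: int = 500, max_size: int = 6,
                         seed: int = 0) -> dict[str, float]:
    """Exact agreement of the gated LAP with exhaustive enumeration, and the
    fraction of inputs where its objective beats or ties greedy matching."""
    rng = np.random.default_rng(_seed(seed, 6000))
    agree = 0
    not_worse = 0
    for _ in range(n_pairs):
        n, m = rng.integers(0, max_size + 1, 2)
        ca = rng.uniform(0, 600, (n, 3))
        cb = rng.uniform(0, 600, (m, 3))
        d_max = float(rng.uniform(100, 500))
        match = match_clouds(SpotSet.from_coords(ca), SpotSet.from_coords(cb), d_max)
        objective = match.total_cost_nm + d_max * len(match.unmatched_a)
        best_cost, best_k = brute_force_match(ca, cb, d_max)
        if abs(objective - best_cost) <= 1e-6 * max(best_cost, 1.0) and \
                match.n_pairs == best_k:
            agree += 1
        if objective <= greedy_match_cost(ca, cb, d_max) + 1e-9:
            not_worse += 1
    return {"oracle_agreement": agree / n_pairs, "not_worse_than_greedy": not_worse / n_pairs}


def qpcr_roundtrip(seed: int = 0) -> dict[str, float]:
    """Noise-free exact % input recovery and a noisy replicate aggregate."""
    from .synthetic import CpSimParams, simulate_cp_table

    exact = CpSimParams(ip_efficiency=0.10, cp_noise_sd=0.0, n_bio=1, n_tech=1,
                        include_rt_minus=False, seed=_seed(seed, 7000))
    t = simulate_cp_table(exact)
    g = t[t["gene"] == "Taf8"]
    v_exact = percent_input(g.loc[g["role"] == "input", "cp"].iloc[0],
                            g.loc[g["role"] == "ip", "cp"].iloc[0])

    noisy = CpSimParams(ip_efficiency=0.10, cp_noise_sd=0.2, n_bio=3, n_tech=2,
                        include_rt_minus=False, seed=_seed(seed, 7001))
    recs = aggregate_replicates(simulate_cp_table(noisy), "percent_input")
    v_noisy = float(np.mean([r.value for r in recs]))
    return {"percent_input_exact": float(v_exact), "percent_input_noisy_mean": v_noisy}


def segmentation_fidelity(seed: int = 0, n_cells: int = 4) -> dict[str, float]:
    """Recovered cell/nucleus counts and worst per-cell Jaccard on a scene
    with non-touching cells."""
    p = SceneParams(shape=(8, 200, 240), n_cells=n_cells, cell_radii_px=(22.0, 26.0),
                    nucleus_radii_px=(9.0, 10.0), spots_per_cell_ch1=60,
                    camera_noise_sd=2.0, seed=_seed(seed, 8000))
    scene = simulate_scene(p)
    chans, _ = render_stacks(scene)
    dapi2d, _ = focus_projection(chans["dapi"], window=9)
    fish2d, _ = focus_projection(chans["fish1"], window=9)
    nuclei = segment_nuclei(dapi2d, min_area=40)
    cells = segment_cells(fish2d, nuclei)
    jac = []
    for lab in range(1, int(cells.max()) + 1):
        rec = cells == lab
        true_lab = np.bincount(scene.geometry.cell_labels[rec].ravel()).argmax()
        tru = scene.geometry.cell_labels == true_lab
        jac.append((rec & tru).sum() / (rec | tru).sum())
    return {
        "true_cells": float(n_cells),
        "recovered_cells": float(cells.max()),
        "recovered_nuclei": float(nuclei.max()),
        "min_jaccard": float(min(jac)) if jac else 0.0,
    }
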