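"""Ground-truth scene simulation for the imaging and qPCR analyses.

The simulator emulates the data the downstream statistics assume:

* cells as non-overlapping 2D ellipses extruded over z (matching the
  2D-outline / 3D-spot hybrid analysis), each with a nucleus strictly
  inside;
* diffraction-limited FISH spots as anisotropic 3D Gaussians placed in
  the cytoplasm, with a configurable co-localized fraction ``rho``
  between the two colours and Gaussian localization jitter (truncated at
  3 SD per axis so every partner lies within the stated jitter);
* an immunofluorescence (IF) channel whose intensity in a small
  neighbourhood of each channel-1 spot is elevated by a factor ``r``
  over the cytoplasmic background, so the true per-cell enrichment
  ratio equals ``r`` by construction;
* qPCR crossing-point (Cp) tables generated from a log2-linear template
  model, so the % input formula applied to noise-free rows recovers
  100 x the simulated capture efficiency exactly.

All randomness flows through a single generator per operation, seeded
from the parameter set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import CellGeometry, SpotSet, VolumetricImage, warn

# log2(100): the dilution-correction constant of the % input formula
INPUT_CORRECTION_DEFAULT = 6.644


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap."""


@dataclass
class SceneParams:
    """Parameters of a synthetic IF-smiFISH scene.

    Geometry defaults follow confocal smiFISH practice: 70 nm lateral
    pixels, 300 nm z-spacing, 8-bit intensities.
    """

    shape: tuple[int, int, int] = (12, 256, 256)  # (z, y, x) voxels
    voxel_xy_nm: float = 70.0
    voxel_z_nm: float = 300.0
    n_cells: int = 4
    cell_radii_px: tuple[float, float] = (30.0, 38.0)  # (ry, rx) semi-axes
    nucleus_radii_px: tuple[float, float] = (13.0, 16.0)
    spots_per_cell_ch1: int = 100
    spots_per_cell_ch2: int = 0
    coloc_fraction: float = 0.5  # rho
    coloc_jitter_nm: float = 50.0  # per-axis SD of partner offset
    if_enrichment: float = 2.0  # r
    if_background: float = 60.0
    if_background_cv: float = 0.2  # cell-to-cell IF level variability (CV)
    if_noise_sd: float = 6.0
    fish_background: float = 20.0  # cell-confined autofluorescence level
    dapi_level: float = 150.0
    spot_amplitude: float = 120.0
    sigma_xy_px: float = 1.3
    sigma_z_slices: float = 1.0
    camera_noise_sd: float = 2.0
    bit_depth: int = 8
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.coloc_fraction <= 1.0):
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.if_enrichment < 0:
            raise ValueError("if_enrichment must be >= 0")
        for name in ("voxel_xy_nm", "voxel_z_nm", "sigma_xy_px", "sigma_z_slices"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.shape) < 1 or self.n_cells < 0:
            raise ValueError("shape dimensions must be >= 1 and n_cells >= 0")
        ry, rx = self.cell_radii_px
        nry, nrx = self.nucleus_radii_px
        if min(ry, rx, nry, nrx) <= 0:
            raise ValueError("cell and nucleus radii must be positive")
        if nry >= ry or nrx >= rx:
            raise ValueError("nucleus radii must be strictly smaller than cell radii")
        if self.spots_per_cell_ch1 < 0 or self.spots_per_cell_ch2 < 0:
            raise ValueError("spot counts must be >= 0")
        if self.coloc_jitter_nm < 0:
            raise ValueError("coloc_jitter_nm must be >= 0")
        if self.if_background_cv < 0:
            raise ValueError("if_background_cv must be >= 0")
        n_partnered = round(self.coloc_fraction * self.spots_per_cell_ch2)
        if n_partnered > self.spots_per_cell_ch1:
            raise ValueError(
                "round(rho * spots_per_cell_ch2) exceeds spots_per_cell_ch1; "
                "not enough channel-1 spots to serve as partners"
            )


@dataclass
class SyntheticScene:
    """A simulated scene: true masks, true spots, and true parameters.

    Spot tables carry two extra columns beyond the standard spot schema:
    ``cell_id`` and ``partner_id`` (index into the channel-1 table of the
    same cell's partner spot, or -1).
    """

    geometry: CellGeometry
    spots: dict[str, SpotSet]
    true_r: float
    true_rho: float
    params: SceneParams

    def spots_in_cell(self, channel: str, cell_id: int) -> SpotSet:
        sub = self.spots[channel].table
        sub = sub[sub["cell_id"] == cell_id].reset_index(drop=True)
        return SpotSet(table=sub, channel=channel, settings={"source": "simulated"})

    def write_ground_truth(self, path) -> None:
        frames = [s.table for s in self.spots.values()]
        cols = ["cell_id", "channel", "x_nm", "y_nm", "z_nm", "intensity", "partner_id"]
        out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=cols)
        out[cols].to_csv(path, index=False)


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  radii: tuple[float, float]) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    cy, cx = center
    ry, rx = radii
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _place_cells(params: SceneParams, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Place non-overlapping cells on a jittered grid.

    Grid pitch keeps cell bounding boxes disjoint with a 2 px margin even at
    maximal jitter, so placement either succeeds or the scene provably does
    not fit and a PlacementError names the offending parameters.
    """
    _, ny, nx = params.shape
    ry, rx = params.cell_radii_px
    margin = 2.0
    pitch_y, pitch_x = 2 * (ry + margin), 2 * (rx + margin)
    lo_y, hi_y = ry + margin, ny - 1 - ry - margin
    lo_x, hi_x = rx + margin, nx - 1 - rx - margin
    if hi_y < lo_y or hi_x < lo_x:
        raise PlacementError(
            f"cell_radii_px {params.cell_radii_px} do not fit into shape {params.shape}"
        )
    n_slots_y = int((hi_y - lo_y) // pitch_y) + 1
    n_slots_x = int((hi_x - lo_x) // pitch_x) + 1
    if n_slots_y * n_slots_x < params.n_cells:
        raise PlacementError(
            f"cannot place n_cells={params.n_cells} cells of radii "
            f"{params.cell_radii_px} in shape {params.shape}: only "
            f"{n_slots_y * n_slots_x} non-overlapping positions available"
        )
    slots = [
        (lo_y + i * pitch_y, lo_x + j * pitch_x)
        for i in range(n_slots_y)
        for j in range(n_slots_x)
    ]
    chosen = rng.choice(len(slots), size=params.n_cells, replace=False)
    jitter = margin / 2.0
    return [
        (
            slots[k][0] + rng.uniform(-jitter, jitter),
            slots[k][1] + rng.uniform(-jitter, jitter),
        )
        for k in chosen
    ]


def _sample_cytoplasm_xy(
    cyto: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform (y, x) pixel positions inside a cytoplasm mask, sub-pixel jittered."""
    ys, xs = np.nonzero(cyto)
    idx = rng.integers(0, len(ys), size=n)
    pos = np.stack([ys[idx], xs[idx]], axis=1).astype(float)
    pos += rng.uniform(-0.5, 0.5, size=pos.shape)
    return pos


def _truncated_normal(rng: np.random.Generator, sd: float, size: int) -> np.ndarray:
    """Normal(0, sd) truncated at +/- 3 sd by resampling."""
    if sd == 0:
        return np.zeros(size)
    out = rng.normal(0.0, sd, size)
    bad = np.abs(out) > 3 * sd
    while bad.any():
        out[bad] = rng.normal(0.0, sd, int(bad.sum()))
        bad = np.abs(out) > 3 * sd
    return out


def simulate_scene(params: SceneParams) -> SyntheticScene:
    """Simulate cell geometry and true spot positions.

    Deterministic given ``params.seed``. Every spot lies in the cytoplasm of
    exactly one cell; exactly ``round(rho * n_ch2)`` channel-2 spots per cell
    are placed within the jitter of a distinct channel-1 partner.
    """
    params.validate()
    rng = np.random.default_rng([int(params.seed) % (2**31), 11])
    nz, ny, nx = params.shape

    centers = _place_cells(params, rng)
    cell_labels = np.zeros((ny, nx), dtype=np.uint16)
    nucleus_labels = np.zeros((ny, nx), dtype=np.uint16)
    for i, c in enumerate(centers, start=1):
        cell_labels[_ellipse_mask((ny, nx), c, params.cell_radii_px)] = i
        nucleus_labels[_ellipse_mask((ny, nx), c, params.nucleus_radii_px)] = i
    geometry = CellGeometry(cell_labels=cell_labels, nucleus_labels=nucleus_labels)

    # z range keeping spots clear of the axial borders for clean rendering
    z_lo = min(params.sigma_z_slices, (nz - 1) / 2)
    z_hi = max(nz - 1 - params.sigma_z_slices, z_lo)

    rows1, rows2 = [], []
    for cid in geometry.cell_ids:
        cyto = geometry.cytoplasm_mask(cid)
        n1 = params.spots_per_cell_ch1
        n2 = params.spots_per_cell_ch2
        xy1 = _sample_cytoplasm_xy(cyto, n1, rng) if n1 else np.empty((0, 2))
        z1 = rng.uniform(z_lo, z_hi, n1)
        for k in range(n1):
            rows1.append(
                dict(
                    cell_id=cid,
                    z_nm=z1[k] * params.voxel_z_nm,
                    y_nm=xy1[k, 0] * params.voxel_xy_nm,
                    x_nm=xy1[k, 1] * params.voxel_xy_nm,
                    partner_id=-1,
                )
            )
        if n2 == 0:
            continue
        n_co = round(params.coloc_fraction * n2)
        partners = rng.choice(n1, size=n_co, replace=False) if n_co else np.array([], int)
        for j in range(n2):
            if j < n_co:
                p = int(partners[j])
                for _ in range(200):
                    jit = _truncated_normal(rng, params.coloc_jitter_nm, 3)
                    z = z1[p] * params.voxel_z_nm + jit[0]
                    y = xy1[p, 0] * params.voxel_xy_nm + jit[1]
                    x = xy1[p, 1] * params.voxel_xy_nm + jit[2]
                    yi = int(round(y / params.voxel_xy_nm))
                    xi = int(round(x / params.voxel_xy_nm))
                    zi = z / params.voxel_z_nm
                    if (
                        0 <= yi < ny and 0 <= xi < nx and cyto[yi, xi]
                        and z_lo - 0.5 <= zi <= z_hi + 0.5
                    ):
                        break
                else:
                    # pathological jitter vs geometry: collapse onto the partner
                    z = z1[p] * params.voxel_z_nm
                    y = xy1[p, 0] * params.voxel_xy_nm
                    x = xy1[p, 1] * params.voxel_xy_nm
                rows2.append(dict(cell_id=cid, z_nm=z, y_nm=y, x_nm=x, partner_id=p))
            else:
                xy = _sample_cytoplasm_xy(cyto, 1, rng)[0]
                z = rng.uniform(z_lo, z_hi)
                rows2.append(
                    dict(
                        cell_id=cid,
                        z_nm=z * params.voxel_z_nm,
                        y_nm=xy[0] * params.voxel_xy_nm,
                        x_nm=xy[1] * params.voxel_xy_nm,
                        partner_id=-1,
                    )
                )

    def _to_spotset(rows: list[dict], channel: str) -> SpotSet:
        cols = ["cell_id", "z_nm", "y_nm", "x_nm", "partner_id"]
        df = pd.DataFrame(rows, columns=cols)
        table = pd.DataFrame(
            {
                "channel": channel,
                "x_nm": df["x_nm"].astype(float),
                "y_nm": df["y_nm"].astype(float),
                "z_nm": df["z_nm"].astype(float),
                "intensity": float(params.spot_amplitude),
                "quality": 1.0,
                "flags": "",
                "cell_id": df["cell_id"].astype(int),
                "partner_id": df["partner_id"].astype(int),
            }
        )
        return SpotSet(table=table, channel=channel, settings={"source": "simulated"})

    spots = {"ch1": _to_spotset(rows1, "ch1")}
    if params.spots_per_cell_ch2 > 0:
        spots["ch2"] = _to_spotset(rows2, "ch2")

    return SyntheticScene(
        geometry=geometry,
        spots=spots,
        true_r=params.if_enrichment,
        true_rho=params.coloc_fraction,
        params=params,
    )


@dataclass
class RenderReport:
    clipped_voxels: dict[str, int] = field(default_factory=dict)


def _splat_gaussians(
    canvas: np.ndarray,
    coords_vox: np.ndarray,
    amplitude: float,
    sigma_xy: float,
    sigma_z: float,
) -> None:
    """Add anisotropic 3D Gaussians at sub-voxel (z, y, x) positions in place."""
    nz, ny, nx = canvas.shape
    hw_xy = max(int(math.ceil(4 * sigma_xy)), 2)
    hw_z = max(int(math.ceil(4 * sigma_z)), 2)
    for z0, y0, x0 in coords_vox:
        zc, yc, xc = int(round(z0)), int(round(y0)), int(round(x0))
        zs = slice(max(zc - hw_z, 0), min(zc + hw_z + 1, nz))
        ys = slice(max(yc - hw_xy, 0), min(yc + hw_xy + 1, ny))
        xs = slice(max(xc - hw_xy, 0), min(xc + hw_xy + 1, nx))
        dz = (np.arange(zs.start, zs.stop) - z0) / sigma_z
        dy = (np.arange(ys.start, ys.stop) - y0) / sigma_xy
        dx = (np.arange(xs.start, xs.stop) - x0) / sigma_xy
        g = np.exp(
            -0.5 * (dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2)
        )
        canvas[zs, ys, xs] += amplitude * g


def render_stacks(
    scene: SyntheticScene,
    params: SceneParams | None = None,
    channels: tuple[str, ...] | None = None,
) -> tuple[dict[str, VolumetricImage], RenderReport]:
    """Render multi-channel stacks from a simulated scene.

    Channels: ``fish1`` / ``fish2`` (Gaussian spots over a cell-confined
    background), ``if`` (cytoplasmic background, elevated by the factor r in
    a sigma_xy-radius neighbourhood of each channel-1 spot), ``dapi``
    (nucleus masks). Gaussian camera noise is added to every channel and
    values are rounded and clipped to the bit depth; the report counts
    clipped voxels per channel. Deterministic given the scene seed.
    """
    params = params or scene.params
    rng = np.random.default_rng([int(params.seed) % (2**31), 23])
    nz, ny, nx = params.shape
    vmax = float(2**params.bit_depth - 1)
    geometry = scene.geometry
    cell_fp = geometry.cell_labels > 0

    wanted = channels or (
        ("fish1", "fish2", "if", "dapi") if "ch2" in scene.spots else ("fish1", "if", "dapi")
    )
    report = RenderReport()
    out: dict[str, VolumetricImage] = {}

    def _vox(spotset: SpotSet) -> np.ndarray:
        c = spotset.coords_nm()
        return np.stack(
            [
                c[:, 0] / params.voxel_z_nm,
                c[:, 1] / params.voxel_xy_nm,
                c[:, 2] / params.voxel_xy_nm,
            ],
            axis=1,
        )

    def _finish(name: str, img: np.ndarray) -> None:
        noise_sd = params.if_noise_sd if name == "if" else params.camera_noise_sd
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        n_clip = int((img > vmax).sum())
        if n_clip:
            warn(f"channel {name}: {n_clip} voxels exceed the {params.bit_depth}-bit range")
        report.clipped_voxels[name] = n_clip
        out[name] = VolumetricImage(
            data=np.clip(np.round(img), 0.0, vmax),
            voxel_xy_nm=params.voxel_xy_nm,
            voxel_z_nm=params.voxel_z_nm,
            bit_depth=params.bit_depth,
        )

    for name, chan in (("fish1", "ch1"), ("fish2", "ch2")):
        if name not in wanted or chan not in scene.spots:
            continue
        img = np.where(cell_fp, params.fish_background, 0.0)[None].repeat(nz, axis=0)
        _splat_gaussians(img, _vox(scene.spots[chan]), params.spot_amplitude,
                         params.sigma_xy_px, params.sigma_z_slices)
        _finish(name, img)

    if "if" in wanted:
        # IF level varies between cells (the per-cell ratio normalizes it out)
        cell_ids = geometry.cell_ids
        factors = {
            cid: max(1.0 + params.if_background_cv * float(rng.standard_normal()), 0.2)
            for cid in cell_ids
        }
        base2d = np.zeros(cell_fp.shape)
        for cid in cell_ids:
            base2d[geometry.cell_labels == cid] = params.if_background * factors[cid]
        img = base2d[None].repeat(nz, axis=0)
        rad = params.sigma_xy_px
        hw = int(math.ceil(rad)) + 1
        hz = int(math.ceil(params.sigma_z_slices))
        spot_cells = scene.spots["ch1"].table["cell_id"].to_numpy()
        for (z0, y0, x0), cid in zip(_vox(scene.spots["ch1"]), spot_cells):
            lvl = params.if_background * factors[int(cid)] * params.if_enrichment
            zc, yc, xc = int(round(z0)), int(round(y0)), int(round(x0))
            ylo, yhi = max(yc - hw, 0), min(yc + hw + 1, ny)
            xlo, xhi = max(xc - hw, 0), min(xc + hw + 1, nx)
            yy = np.arange(ylo, yhi, dtype=float)[:, None]
            xx = np.arange(xlo, xhi, dtype=float)[None, :]
            near = (yy - y0) ** 2 + (xx - x0) ** 2 <= rad**2
            near[yc - ylo, xc - xlo] = True  # nearest voxel always elevated
            near &= cell_fp[ylo:yhi, xlo:xhi]
            for zi in range(max(zc - hz, 0), min(zc + hz + 1, nz)):
                img[zi, ylo:yhi, xlo:xhi][near] = lvl
        _finish("if", img)

    if "dapi" in wanted:
        img = np.where(geometry.nucleus_labels > 0, params.dapi_level, 0.0)[None].repeat(
            nz, axis=0
        )
        _finish("dapi", img)

    return out, report


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------


@dataclass
class CpSimParams:
    """Parameters of a simulated RIP-qPCR crossing-point table.

    ``ip_efficiency`` / ``mock_efficiency`` are the fractions of the input
    template captured by the specific and mock immunoprecipitations.
    ``input_dilution`` is the fraction of the input assayed in the input
    well; the default ``2**-6.644`` matches the dilution-correction
    constant of the % input formula, so that formula applied to noise-free
    rows returns exactly 100 x ip_efficiency.
    """

    abundances: dict[str, float] = field(
        default_factory=lambda: {"Taf8": 200.0, "Taf10": 800.0, "Gapdh": 5000.0}
    )
    ip_efficiency: dict[str, float] | float = 0.10
    mock_efficiency: dict[str, float] | float = 0.002
    input_dilution: float = 2.0**-INPUT_CORRECTION_DEFAULT
    cp_noise_sd: float = 0.0
    n_bio: int = 2
    n_tech: int = 2
    cp_at_unit_template: float = 24.0
    rt_minus_gap: float = 15.0
    max_cycles: float = 45.0
    include_rt_minus: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not self.abundances or any(a <= 0 for a in self.abundances.values()):
            raise ValueError("abundances must be positive")
        for eff in (self.ip_efficiency, self.mock_efficiency):
            vals = eff.values() if isinstance(eff, dict) else [eff]
            if any(not (0 < v <= 1) for v in vals):
                raise ValueError("efficiencies must lie in (0, 1]")
        if not (0 < self.input_dilution <= 1):
            raise ValueError("input_dilution must lie in (0, 1]")
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.cp_noise_sd < 0:
            raise ValueError("cp_noise_sd must be >= 0")

    def _eff(self, which: str, gene: str) -> float:
        eff = self.ip_efficiency if which == "ip" else self.mock_efficiency
        return eff[gene] if isinstance(eff, dict) else float(eff)


def simulate_cp_table(params: CpSimParams) -> pd.DataFrame:
    """Simulate a long-format Cp table (gene, role, rt, bio_rep, tech_rep, cp).

    Cp = cp_at_unit_template - log2(template amount) + Normal(0, noise SD).
    Template amounts: input wells assay ``abundance * input_dilution``, IP
    wells ``abundance * ip_efficiency``, mock wells ``abundance *
    mock_efficiency``. Minus-RT wells sit ``rt_minus_gap`` cycles above the
    matching plus-RT well (never less than 12) and are reported as
    not-detected (empty cp) beyond ``max_cycles``.
    """
    params.validate()
    rng = np.random.default_rng([int(params.seed) % (2**31), 37])
    rows = []
    for gene, abundance in params.abundances.items():
        amounts = {
            "input": abundance * params.input_dilution,
            "ip": abundance * params._eff("ip", gene),
            "mock": abundance * params._eff("mock", gene),
        }
        for role, amount in amounts.items():
            cp_true = params.cp_at_unit_template - math.log2(amount)
            for bio in range(1, params.n_bio + 1):
                for tech in range(1, params.n_tech + 1):
                    noise = rng.normal(0.0, params.cp_noise_sd) if params.cp_noise_sd else 0.0
                    cp_plus = cp_true + noise
                    rows.append(
                        dict(gene=gene, role=role, rt="plus", bio_rep=bio,
                             tech_rep=tech, cp=cp_plus)
                    )
                    if params.include_rt_minus:
                        cp_minus = max(cp_plus + params.rt_minus_gap, cp_plus + 12.0)
                        rows.append(
                            dict(
                                gene=gene, role=role, rt="minus", bio_rep=bio,
                                tech_rep=tech,
                                cp=np.nan if cp_minus > params.max_cycles else cp_minus,
                            )
                        )
    return pd.DataFrame(rows)


def scene_with(params: SceneParams | None = None, **overrides) -> SceneParams:
    """Convenience: copy default SceneParams with overrides."""
    base = params or SceneParams()
    return replace(base, **overrides)
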