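"""Synthetic 3-D multi-channel nucleus images and cohorts with known ground
truth.

The generator emulates the statistical structure the pipeline assumes so
every stage is testable without any real acquisition: ellipsoidal textured
nuclei on a dark background rendered on the anisotropic voxel grid
(0.09 x 0.09 x 0.5 um), condition-dependent multiplicative shifts of
nuclear volume, heterochromatin fraction, foci rate and boundary
irregularity, planted punctate gammaH2AX foci, a rim-weighted Lamin A/C
channel, per-sample bimodal surface-marker intensities, and patient-level
multiplicative random effects. Ground truth (masks, volumes, HC fraction,
foci count, subset label) is recorded before noise is added.

Two entry points exist at different scales: :func:`generate_nucleus_image`
and :func:`generate_cohort` render actual image stacks for the
segmentation / feature / foci stages, while :func:`simulate_feature_cohort`
samples per-cell chrometric feature tables directly from the same
hierarchical effect model, which is what the cohort-level statistics need
and is orders of magnitude faster than rendering and re-measuring images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import AcquisitionSpec, ImageStack, write_stack

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_nucleus_image",
    "generate_cohort",
    "simulate_feature_cohort",
]

DEFAULT_CHANNELS = {"DAPI": 0, "gH2AX": 1, "LaminAC": 2, "CD3": 3, "CD4": 4, "CD8": 5}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of the synthetic cohort.

    Geometry and intensity defaults describe a resting PBMC nucleus:
    lateral semi-axes ~2.8 um and axial ~2.0 um (projected area ~25 um^2
    and height ~4 um, inside the 6.48-40.5 um^2 / 2.5-10 um acceptance
    windows), ~25% heterochromatin, a handful of gammaH2AX foci, and
    CD3+/CD4+/CD8+ fractions typical of peripheral blood lymphocytes.
    Condition effects are multiplicative on volume, HC fraction, foci rate
    and boundary irregularity; patient effects are multiplicative
    log-normal with small SDs.
    """

    # field geometry
    shape_zyx: tuple[int, int, int] = (21, 150, 150)
    dx_um: float = 0.09
    dy_um: float = 0.09
    dz_um: float = 0.5
    channel_map: dict = field(default_factory=lambda: dict(DEFAULT_CHANNELS))
    # nucleus geometry (um)
    radius_xy_um: float = 2.8
    radius_xy_sd_um: float = 0.25
    radius_z_um: float = 2.0
    radius_z_sd_um: float = 0.15
    boundary_irregularity: float = 0.04  # relative radial Fourier perturbation
    # chromatin texture
    texture_sigma_px: float = 2.0
    hc_fraction: float = 0.25
    hc_level: float = 0.9
    ec_level: float = 0.45
    # foci model
    foci_rate: float = 3.0  # Poisson mean per nucleus
    focus_radius_px: float = 2.0
    focus_amplitude: float = 0.9
    gh2ax_base: float = 0.15
    # marker model (per-sample bimodal log-normal, area-normalized scale)
    positive_fraction: dict = field(
        default_factory=lambda: {"CD3": 0.70, "CD4": 0.45, "CD8": 0.25}
    )
    marker_neg_mean: float = 0.1
    marker_pos_mean: float = 0.5
    marker_log_sd: float = 0.15
    lamin_level: float = 0.6
    # hierarchy / noise
    patient_effect_sd: float = 0.05  # SD of multiplicative log-normal patient effect
    condition_effects: dict = field(default_factory=dict)
    # e.g. {"tumor": {"volume": 1.3, "hc_fraction": 1.2, "foci_rate": 1.5,
    #                 "boundary_irregularity": 1.5}}
    background: float = 0.05
    noise_sd: float = 0.02

    def acquisition(self) -> AcquisitionSpec:
        return AcquisitionSpec(self.dx_um, self.dy_um, self.dz_um, dict(self.channel_map))

    def effect(self, condition: str, key: str) -> float:
        return float(self.condition_effects.get(condition, {}).get(key, 1.0))


@dataclass
class GroundTruth:
    """Per-nucleus generative truth, recorded before noise."""

    nucleus_id: str
    sample_id: str
    patient_id: str
    condition: str
    timepoint: str
    mask: np.ndarray | None  # (z, y, x) rendered nuclear mask
    center_yx: tuple[float, float]
    volume_um3: float
    hc_fraction: float
    foci_count: int
    subset: str
    cd3: bool


def _render_nucleus_mask(spec: SyntheticSpec, rng, center_zyx, scale_vol=1.0, irregularity=None):
    """Voxelize a (possibly radially perturbed) ellipsoid on the anisotropic grid."""
    rz = max(spec.radius_z_um + rng.normal(0, spec.radius_z_sd_um), 2 * spec.dz_um)
    rxy = max(spec.radius_xy_um + rng.normal(0, spec.radius_xy_sd_um), 4 * spec.dx_um)
    s = scale_vol ** (1.0 / 3.0)  # volume effect split isotropically
    rz, rxy = rz * s, rxy * s
    amp = spec.boundary_irregularity if irregularity is None else irregularity
    modes = rng.normal(0, amp, size=4)  # Fourier modes k = 2..5 on the lateral angle
    phases = rng.uniform(0, 2 * np.pi, size=4)

    nz, ny, nx = spec.shape_zyx
    zz, yy, xx = np.meshgrid(
        (np.arange(nz) - center_zyx[0]) * spec.dz_um,
        (np.arange(ny) - center_zyx[1]) * spec.dy_um,
        (np.arange(nx) - center_zyx[2]) * spec.dx_um,
        indexing="ij",
    )
    theta = np.arctan2(yy, xx)
    r_lat = rxy * (1.0 + sum(m * np.cos((k + 2) * theta + ph) for k, (m, ph) in enumerate(zip(modes, phases))))
    mask = (xx / r_lat) ** 2 + (yy / r_lat) ** 2 + (zz / rz) ** 2 <= 1.0
    return mask


def _texture(spec: SyntheticSpec, rng, mask, hc_fraction):
    """DAPI texture: low-pass Gaussian random field thresholded so that the
    brightest ``hc_fraction`` of in-mask voxels form discrete HC blobs."""
    field_ = ndi.gaussian_filter(rng.standard_normal(mask.shape), sigma=(1.0, spec.texture_sigma_px, spec.texture_sigma_px))
    vals = field_[mask]
    if hc_fraction <= 0 or vals.size == 0:
        hc = np.zeros_like(mask)
    else:
        cut = np.quantile(vals, 1.0 - min(hc_fraction, 1.0))
        hc = mask & (field_ >= cut)
    dapi = np.where(hc, spec.hc_level, spec.ec_level) * mask
    return dapi, hc


def _place_foci(spec: SyntheticSpec, rng, mask, n_foci):
    """Plant round bright spots at well-interior in-mask positions; returns
    the gammaH2AX channel (pre-noise) and the realized count."""
    img = np.where(mask, spec.gh2ax_base, 0.0)
    eroded = ndi.binary_erosion(mask, iterations=3)
    coords = np.argwhere(eroded if eroded.any() else mask)
    if len(coords) == 0 or n_foci == 0:
        return img, 0
    placed = []
    min_sep = 4.0 * spec.focus_radius_px
    for _ in range(200):
        if len(placed) >= n_foci:
            break
        z, y, x = coords[rng.integers(len(coords))]
        if all((y - py) ** 2 + (x - px) ** 2 >= min_sep**2 for _, py, px in placed):
            placed.append((z, y, x))
    zz, yy, xx = np.indices(mask.shape)
    for z, y, x in placed:
        blob = np.exp(
            -(((yy - y) ** 2 + (xx - x) ** 2) / (2 * spec.focus_radius_px**2) + ((zz - z) ** 2) / 2.0)
        )
        img += spec.focus_amplitude * blob * mask
    return img, len(placed)


def _sample_subset(spec: SyntheticSpec, rng):
    cd3 = rng.random() < spec.positive_fraction.get("CD3", 0.7)
    cd4 = rng.random() < spec.positive_fraction.get("CD4", 0.45)
    cd8 = rng.random() < spec.positive_fraction.get("CD8", 0.25)
    return cd3, cd4, cd8


def _marker_level(spec: SyntheticSpec, rng, positive, sample_shift=1.0):
    mean = spec.marker_pos_mean if positive else spec.marker_neg_mean
    return float(mean * sample_shift * rng.lognormal(0.0, spec.marker_log_sd))


def generate_nucleus_image(
    spec: SyntheticSpec,
    seed: int | np.random.Generator = 0,
    condition: str = "control",
    n_nuclei: int = 1,
    metadata: dict | None = None,
    volume_shift: float = 1.0,
    foci_count: int | None = None,
) -> tuple[ImageStack, list[GroundTruth]]:
    """Render one field with ``n_nuclei`` non-touching nuclei and full truth.

    ``volume_shift`` multiplies the nuclear volume on top of the condition
    effect (patient effects are applied by :func:`generate_cohort`);
    ``foci_count`` overrides the Poisson draw. With zero noise and zero
    texture the rendered DAPI support equals the analytic ellipsoid
    voxelization exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    meta = metadata or {}
    nz, ny, nx = spec.shape_zyx
    n_channels = max(spec.channel_map.values()) + 1
    voxels = np.zeros((n_channels, nz, ny, nx))
    voxels[spec.channel_map["DAPI"]] = 0.0

    vol_eff = volume_shift * spec.effect(condition, "volume")
    hc_eff = min(spec.hc_fraction * spec.effect(condition, "hc_fraction"), 0.9)
    foci_eff = spec.foci_rate * spec.effect(condition, "foci_rate")
    irr_eff = spec.boundary_irregularity * spec.effect(condition, "boundary_irregularity")

    margin_px = int(np.ceil(1.4 * spec.radius_xy_um / spec.dx_um)) + 2
    centers: list[tuple[float, float]] = []
    truths: list[GroundTruth] = []
    occupied = np.zeros((nz, ny, nx), bool)
    min_sep_px = 2.3 * spec.radius_xy_um / spec.dx_um
    for i in range(n_nuclei):
        for _ in range(100):
            cy = rng.uniform(margin_px, ny - margin_px)
            cx = rng.uniform(margin_px, nx - margin_px)
            if all((cy - py) ** 2 + (cx - px) ** 2 >= min_sep_px**2 for py, px in centers):
                break
        else:
            break  # field full: stop placing
        cz = nz / 2.0 + rng.normal(0, 0.5)
        mask = _render_nucleus_mask(spec, rng, (cz, cy, cx), scale_vol=vol_eff, irregularity=irr_eff)
        if not mask.any() or (mask & occupied).any():
            continue
        occupied |= mask
        centers.append((cy, cx))

        dapi, _hc = _texture(spec, rng, mask, hc_eff)
        n_foci = int(rng.poisson(foci_eff)) if foci_count is None else int(foci_count)
        gh2ax, realized = _place_foci(spec, rng, mask, n_foci)
        rim = mask & ~ndi.binary_erosion(mask, iterations=2)
        cell = ndi.binary_dilation(mask, iterations=3)
        cd3, cd4, cd8 = _sample_subset(spec, rng)

        voxels[spec.channel_map["DAPI"]] += dapi
        if "gH2AX" in spec.channel_map:
            voxels[spec.channel_map["gH2AX"]] += gh2ax
        if "LaminAC" in spec.channel_map:
            voxels[spec.channel_map["LaminAC"]] += spec.lamin_level * rim
        for m, flag in (("CD3", cd3), ("CD4", cd4), ("CD8", cd8)):
            if m in spec.channel_map:
                voxels[spec.channel_map[m]] += _marker_level(spec, rng, flag, meta.get("marker_shift", 1.0)) * cell

        subset = f"CD4{'+' if cd4 else '-'}CD8{'+' if cd8 else '-'}"
        truths.append(
            GroundTruth(
                nucleus_id=f"{meta.get('sample_id', 'synthetic')}-t{i:03d}",
                sample_id=meta.get("sample_id", "synthetic"),
                patient_id=meta.get("patient_id", "P0"),
                condition=condition,
                timepoint=meta.get("timepoint", "T0"),
                mask=mask,
                center_yx=(cy, cx),
                volume_um3=float(mask.sum()) * spec.dx_um * spec.dy_um * spec.dz_um,
                hc_fraction=hc_eff,
                foci_count=realized,
                subset=subset,
                cd3=cd3,
            )
        )

    if spec.background > 0 or spec.noise_sd > 0:
        voxels += spec.background
        voxels += rng.normal(0, spec.noise_sd, size=voxels.shape)
        np.clip(voxels, 0.0, None, out=voxels)

    stack = ImageStack(
        voxels=voxels,
        spec=spec.acquisition(),
        sample_id=meta.get("sample_id", "synthetic"),
        patient_id=meta.get("patient_id", "P0"),
        condition=condition,
        timepoint=meta.get("timepoint", "T0"),
    )
    return stack, truths


def generate_cohort(
    spec: SyntheticSpec,
    n_patients_per_condition: int = 3,
    fields_per_patient: int = 2,
    nuclei_per_field: int = 3,
    conditions: tuple[str, ...] = ("control", "tumor"),
    timepoints: tuple[str, ...] = ("T0",),
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[ImageStack], pd.DataFrame, pd.DataFrame]:
    """Hierarchical image cohort: patient effects, then per-field nuclei.

    Returns (stacks, manifest, truth table). If ``out_dir`` is given, the
    stacks are written as TIFFs and the manifest/truth as CSV in the same
    dialects the pipeline consumes.
    """
    if n_patients_per_condition < 1 or fields_per_patient < 1:
        raise ValueError("need >= 1 patient and >= 1 field per patient")
    rng = np.random.default_rng(seed)
    stacks, manifest_rows, truth_rows = [], [], []
    pnum = 0
    for condition in conditions:
        for _ in range(n_patients_per_condition):
            patient_id = f"P{pnum:02d}"
            pnum += 1
            pat_vol = float(np.exp(rng.normal(0, spec.patient_effect_sd)))
            pat_marker = float(np.exp(rng.normal(0, spec.patient_effect_sd)))
            for tp in timepoints:
                sample_id = f"{patient_id}-{condition}-{tp}"
                for f_i in range(fields_per_patient):
                    meta = {
                        "sample_id": f"{sample_id}-f{f_i}",
                        "patient_id": patient_id,
                        "timepoint": tp,
                        "marker_shift": pat_marker,
                    }
                    stack, truths = generate_nucleus_image(
                        spec, rng, condition=condition, n_nuclei=nuclei_per_field,
                        metadata=meta, volume_shift=pat_vol,
                    )
                    stacks.append(stack)
                    row = {
                        "sample_id": meta["sample_id"],
                        "patient_id": patient_id,
                        "condition": condition,
                        "timepoint": tp,
                        "path": f"{meta['sample_id']}.tif",
                        **spec.channel_map,
                    }
                    manifest_rows.append(row)
                    for t in truths:
                        truth_rows.append(
                            {
                                "nucleus_id": t.nucleus_id,
                                "sample_id": t.sample_id,
                                "patient_id": t.patient_id,
                                "condition": t.condition,
                                "timepoint": t.timepoint,
                                "center_y": t.center_yx[0],
                                "center_x": t.center_yx[1],
                                "volume_um3": t.volume_um3,
                                "hc_fraction": t.hc_fraction,
                                "foci_count": t.foci_count,
                                "subset": t.subset,
                                "cd3": t.cd3,
                            }
                        )
    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for stack in stacks:
            write_stack(out_dir / f"{stack.sample_id}.tif", stack)
        manifest = manifest.assign(path=[str(out_dir / p) for p in manifest["path"]])
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        truth.to_csv(out_dir / "truth.csv", index=False)
    return stacks, manifest, truth


def simulate_feature_cohort(
    n_patients_per_condition: int = 5,
    cells_per_patient: int = 100,
    conditions: tuple[str, ...] = ("control", "tumor"),
    timepoints: tuple[str, ...] = ("T0",),
    condition_effects: dict | None = None,
    n_noise_features: int = 20,
    patient_effect_sd: float = 0.05,
    cell_cv: float = 0.12,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a per-cell chrometric feature table from the hierarchical
    effect model without rendering images.

    Cells carry the measured-scale features ``volume_um3``,
    ``hc_volume_fraction``, ``foci_count`` and ``curvature_sd`` drawn
    log-normally around condition- and patient-shifted means (foci are
    Poisson), plus ``n_noise_features`` pure-noise columns. Condition
    effects are the same multiplicative dials as the image generator
    (keys ``volume``, ``hc_fraction``, ``foci_rate``,
    ``boundary_irregularity``). With all effects at 1 the table carries no
    class signal, which is the null used for calibration.
    """
    effects = condition_effects or {}
    rng = np.random.default_rng(seed)
    base = {"volume_um3": 65.0, "hc_volume_fraction": 0.25, "foci_rate": 3.0, "curvature_sd": 0.12}
    rows = []
    pnum = 0
    for condition in conditions:
        eff = effects.get(condition, {})
        for _ in range(n_patients_per_condition):
            patient_id = f"P{pnum:02d}"
            pnum += 1
            shift = {k: float(np.exp(rng.normal(0, patient_effect_sd))) for k in base}
            for tp in timepoints:
                for c in range(cells_per_patient):
                    vol = base["volume_um3"] * eff.get("volume", 1.0) * shift["volume_um3"]
                    hcf = base["hc_volume_fraction"] * eff.get("hc_fraction", 1.0) * shift["hc_volume_fraction"]
                    lam = base["foci_rate"] * eff.get("foci_rate", 1.0) * shift["foci_rate"]
                    cur = base["curvature_sd"] * eff.get("boundary_irregularity", 1.0) * shift["curvature_sd"]
                    row = {
                        "nucleus_id": f"{patient_id}-{tp}-{c:04d}",
                        "sample_id": f"{patient_id}-{tp}",
                        "patient_id": patient_id,
                        "condition": condition,
                        "timepoint": tp,
                        "volume_um3": vol * rng.lognormal(0, cell_cv),
                        "hc_volume_fraction": min(hcf * rng.lognormal(0, cell_cv), 0.95),
                        "foci_count": int(rng.poisson(lam)),
                        "curvature_sd": cur * rng.lognormal(0, cell_cv),
                    }
                    for k in range(n_noise_features):
                        row[f"noise_{k:02d}"] = rng.standard_normal()
                    rows.append(row)
    return pd.DataFrame(rows)
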