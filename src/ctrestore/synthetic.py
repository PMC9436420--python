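"""Synthetic abdominal/pelvic CT phantoms with a photon-starvation dose model.

The phantom is a piecewise-ellipse axial section: a body ellipse with a
subcutaneous fat ring, interior soft tissue, a vertebral body and two
femoral heads (bone), a urine-filled bladder and a rectum with an optional
gas pocket, plus a smooth Gaussian-random-field texture (~10 HU) inside
the body.  Air background is exactly −1000 HU.

Dose simulation follows the physics of tube-current reduction: HU are
converted to linear attenuation at a single effective energy
(μ_water = 0.19 cm⁻¹ at 120 kV), forward-projected (parallel-beam Radon,
180 angles), the transmitted intensity I₀·f·exp(−line integral) is Poisson
sampled with additive Gaussian electronic noise, log-transformed and
filtered-back-projected.  f = 1 gives a mildly noisy normal-dose analog;
f = 24/233 (the low/normal tube-current ratio) gives the low-dose analog
with visible streaks.  I₀ defaults to 2·10⁷ counts/bin, calibrated so the
f = 1 reconstruction's soft-tissue noise standard deviation is ≈10 HU at
the default 256 grid (a diagnostic-quality analog).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import iradon, radon

from .io import ContourMask, HUVolume, write_volume

__all__ = ["PhantomSpec", "DoseModel", "make_phantom", "phantom_masks",
           "simulate_dose", "make_dataset", "uniform_roi",
           "LOW_DOSE_FRACTION", "MU_WATER"]

LOW_DOSE_FRACTION = 24.0 / 233.0   # low / normal tube current
MU_WATER = 0.19                    # cm^-1 at an effective 120 kV energy


@dataclass
class PhantomSpec:
    """Geometry and tissue parameters of the synthetic axial phantom."""

    side: int = 256
    n_slices: int = 1
    spacing: tuple | None = None   # default keeps a 512*0.9765 mm field of view
    # tissue HU means
    hu_air: float = -1000.0
    hu_fat: float = -100.0
    hu_soft: float = 40.0
    hu_urine: float = 10.0
    hu_bone: float = 700.0
    tissue_jitter: float = 8.0     # per-structure HU mean jitter (sd)
    texture_sigma: float = 10.0    # intra-tissue Gaussian-field sd, HU
    # geometry, as fractions of the image side
    body_axes: tuple = (0.33, 0.42)        # (y, x) semi-axes
    fat_ring: float = 0.05
    vertebra: tuple = (0.72, 0.50, 0.060)  # (cy, cx, r)
    femoral_heads: tuple = ((0.62, 0.27, 0.055), (0.62, 0.73, 0.055))
    bladder: tuple = (0.40, 0.50, 0.10, 0.13)   # (cy, cx, ay, ax)
    rectum: tuple = (0.60, 0.50, 0.045)
    gas_pocket: bool = True
    gas_radius: float = 0.025
    anatomy_drift: float = 0.05    # relative structure-size drift over slices
    seed: int = 0

    def __post_init__(self):
        if self.spacing is None:
            # keep the scanner's 512 x 0.9765 mm field of view at any grid
            dxy = 0.9765 * 512.0 / self.side
            self.spacing = (3.0, dxy, dxy)


@dataclass
class DoseModel:
    """Projection-domain noise model for a tube-current-scaled acquisition."""

    I0: float = 2e7                      # incident counts/bin, normal dose
    dose_fraction: float = LOW_DOSE_FRACTION
    sigma_e: float = 5.0                 # electronic noise floor (counts)
    n_angles: int = 180

    def __post_init__(self):
        if self.I0 <= 0:
            raise ValueError("I0 must be positive")
        if not (0 < self.dose_fraction <= 1):
            raise ValueError("dose fraction must lie in (0, 1]")


def _grids(side):
    y, x = np.mgrid[0:side, 0:side]
    return (y + 0.5) / side, (x + 0.5) / side


def _ellipse(yy, xx, cy, cx, ay, ax):
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _structure_masks(spec: PhantomSpec, scale: float = 1.0):
    """Boolean masks of each structure for one slice (scaled anatomy)."""
    yy, xx = _grids(spec.side)
    ay, ax = (a * scale for a in spec.body_axes)
    body = _ellipse(yy, xx, 0.5, 0.5, ay, ax)
    inner = _ellipse(yy, xx, 0.5, 0.5, ay - spec.fat_ring, ax - spec.fat_ring)
    masks = {"body": body, "fat": body & ~inner, "soft": inner}
    cy, cx, r = spec.vertebra
    masks["vertebra"] = _ellipse(yy, xx, cy, cx, r * scale, r * scale) & inner
    fh = np.zeros_like(body)
    for cy, cx, r in spec.femoral_heads:
        fh |= _ellipse(yy, xx, cy, cx, r * scale, r * scale)
    masks["femoral_heads"] = fh & inner
    cy, cx, by, bx = spec.bladder
    masks["bladder"] = _ellipse(yy, xx, cy, cx, by * scale, bx * scale) & inner
    cy, cx, r = spec.rectum
    masks["rectum"] = _ellipse(yy, xx, cy, cx, r * scale, r * scale) & inner
    if spec.gas_pocket:
        masks["gas"] = _ellipse(yy, xx, cy, cx, spec.gas_radius * scale,
                                spec.gas_radius * scale) & inner
    else:
        masks["gas"] = np.zeros_like(body)
    return masks


def make_phantom(spec: PhantomSpec) -> HUVolume:
    """Deterministic piecewise-smooth HU phantom stack from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    jit = {name: float(rng.normal(0.0, spec.tissue_jitter))
           for name in ("fat", "soft", "urine", "bone")}
    phase = float(rng.uniform(0, 2 * np.pi))
    slices = []
    for k in range(spec.n_slices):
        scale = 1.0 + spec.anatomy_drift * np.sin(
            2 * np.pi * k / max(spec.n_slices, 2) + phase)
        m = _structure_masks(spec, scale)
        img = np.full((spec.side, spec.side), spec.hu_air)
        img[m["fat"]] = spec.hu_fat + jit["fat"]
        img[m["soft"]] = spec.hu_soft + jit["soft"]
        img[m["bladder"]] = spec.hu_urine + jit["urine"]
        img[m["vertebra"]] = spec.hu_bone + jit["bone"]
        img[m["femoral_heads"]] = spec.hu_bone + jit["bone"]
        img[m["gas"]] = spec.hu_air
        # mild intra-tissue texture: smoothed white noise rescaled to sigma
        field = ndimage.gaussian_filter(
            rng.standard_normal((spec.side, spec.side)), 2.0)
        field *= spec.texture_sigma / field.std()
        tissue = m["body"] & ~m["gas"]
        img[tissue] += field[tissue]
        slices.append(img)
    vol = np.clip(np.stack(slices), -1000.0, 1800.0)
    return HUVolume(voxels=vol, spacing=spec.spacing)


def phantom_masks(spec: PhantomSpec) -> dict:
    """Contour masks (bladder, rectum, femoral heads, vertebra) for a stack."""
    rng = np.random.default_rng(spec.seed)
    rng.normal(0.0, spec.tissue_jitter, 4)   # keep stream aligned with phantom
    phase = float(rng.uniform(0, 2 * np.pi))
    out = {name: [] for name in ("bladder", "rectum", "femoral_heads",
                                 "vertebra")}
    for k in range(spec.n_slices):
        scale = 1.0 + spec.anatomy_drift * np.sin(
            2 * np.pi * k / max(spec.n_slices, 2) + phase)
        m = _structure_masks(spec, scale)
        for name in out:
            out[name].append(m[name])
    return {name: ContourMask(voxels=np.stack(planes).astype(np.uint8),
                              spacing=spec.spacing, label=name)
            for name, planes in out.items()}


def uniform_roi(spec: PhantomSpec) -> tuple:
    """Index slices of a homogeneous soft-tissue region (noise measurements)."""
    s = spec.side
    cy, cx, r = int(0.45 * s), int(0.28 * s), max(2, int(0.035 * s))
    return slice(cy - r, cy + r), slice(cx - r, cx + r)


# ------------------------------------------------------------ dose simulator
def hu_to_mu(hu: np.ndarray) -> np.ndarray:
    return MU_WATER * (1.0 + np.asarray(hu, dtype=np.float64) / 1000.0)


def mu_to_hu(mu: np.ndarray) -> np.ndarray:
    return 1000.0 * (np.asarray(mu, dtype=np.float64) / MU_WATER - 1.0)


def project_slice(hu_slice: np.ndarray, pixel_mm: float,
                  n_angles: int = 180) -> np.ndarray:
    """Parallel-beam line integrals (dimensionless μ·cm) of one HU slice."""
    theta = np.linspace(0.0, 180.0, n_angles, endpoint=False)
    mu = np.clip(hu_to_mu(hu_slice), 0.0, None)
    return radon(mu, theta=theta, circle=False) * (pixel_mm / 10.0)


def noisy_sinogram(sino: np.ndarray, model: DoseModel,
                   rng: np.random.Generator,
                   dose_fraction: float | None = None) -> np.ndarray:
    """Poisson photon statistics + electronic noise, then log transform."""
    f = model.dose_fraction if dose_fraction is None else dose_fraction
    mean = model.I0 * f * np.exp(-sino)
    counts = rng.poisson(mean).astype(np.float64)
    if model.sigma_e > 0:
        counts += rng.normal(0.0, model.sigma_e, counts.shape)
    starved = counts < 1.0
    if starved.any():
        import warnings
        warnings.warn(f"photon starvation: {int(starved.sum())} detector "
                      "bins clamped to one count", stacklevel=2)
    counts = np.maximum(counts, 1.0)   # photon-starvation floor
    return -np.log(counts / (model.I0 * f))


def simulate_dose(clean: HUVolume, model: DoseModel, seed: int = 0,
                  dose_fraction: float | None = None,
                  no_noise: bool = False) -> HUVolume:
    """Reconstruct a dose-degraded copy of ``clean`` through the FBP chain.

    ``no_noise=True`` skips the photon sampling, so the output differs from
    the input only by forward/back-projection discretization error.
    """
    rng = np.random.default_rng(seed)
    f = model.dose_fraction if dose_fraction is None else dose_fraction
    pixel_mm = clean.spacing[2]
    theta = np.linspace(0.0, 180.0, model.n_angles, endpoint=False)
    out = np.empty_like(clean.voxels)
    for k in range(clean.n_slices):
        sino = project_slice(clean.voxels[k], pixel_mm, model.n_angles)
        if not no_noise:
            sino = noisy_sinogram(sino, model, rng, f)
        mu = iradon(sino / (pixel_mm / 10.0), theta=theta, circle=False,
                    filter_name="ramp", output_size=clean.voxels.shape[1])
        out[k] = mu_to_hu(mu)
    return HUVolume(voxels=np.clip(out, -1000.0, 1800.0),
                    spacing=clean.spacing, origin=clean.origin,
                    orientation=clean.orientation)


# ------------------------------------------------------------------ datasets
def make_dataset(out_dir, n_patients: int = 4, slices_per_patient: int = 3,
                 model: DoseModel | None = None, master_seed: int = 0,
                 paired: bool = False, side: int = 256) -> dict:
    """Write a phantom dataset as uncompressed NIfTI plus a JSON manifest.

    Unpaired mode draws *disjoint* phantom populations for domain A
    (low-dose) and domain B (normal-dose), mirroring a two-scan unpaired
    study design; paired mode emits (clean, NDCT, LDCT) triplets per
    patient for metric evaluation.  The manifest records every seed and
    parameter, so the dataset regenerates byte-identically.
    """
    model = model or DoseModel()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(master_seed)
    manifest = {"master_seed": master_seed, "paired": paired, "side": side,
                "n_patients": n_patients,
                "slices_per_patient": slices_per_patient,
                "dose_model": dataclasses.asdict(model), "volumes": []}

    def emit(tag, anatomy_seed, noise_seed, fraction):
        spec = PhantomSpec(side=side, n_slices=slices_per_patient,
                           seed=anatomy_seed)
        clean = make_phantom(spec)
        entries = []
        if fraction is None:
            name = f"{tag}_clean.nii"
            write_volume(clean, out_dir / name)
            entries.append({"file": name, "kind": "clean",
                            "anatomy_seed": anatomy_seed})
        else:
            vol = simulate_dose(clean, model, seed=noise_seed,
                                dose_fraction=fraction)
            kind = "LDCT" if fraction < 1.0 else "NDCT"
            name = f"{tag}_{kind}.nii"
            write_volume(vol, out_dir / name)
            entries.append({"file": name, "kind": kind,
                            "anatomy_seed": anatomy_seed,
                            "noise_seed": noise_seed,
                            "dose_fraction": fraction})
        manifest["volumes"].extend(entries)

    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
             ss.spawn(4 * n_patients)]
    if paired:
        for p in range(n_patients):
            a_seed = seeds[4 * p]
            emit(f"p{p:03d}", a_seed, 0, None)
            emit(f"p{p:03d}", a_seed, seeds[4 * p + 1], 1.0)
            emit(f"p{p:03d}", a_seed, seeds[4 * p + 2], model.dose_fraction)
    else:
        for p in range(n_patients):
            emit(f"a{p:03d}", seeds[4 * p], seeds[4 * p + 1],
                 model.dose_fraction)
            emit(f"b{p:03d}", seeds[4 * p + 2], seeds[4 * p + 3], 1.0)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
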