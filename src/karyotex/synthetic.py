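"""Seeded synthetic nuclei and two-group cohorts.

No image data are distributed with the study this pipeline targets, so the
test bed is simulated: each nucleus is an oval or bilobed mask filled with a
fractional Brownian (fBm) chromatin surface, rescaled to a target gray
mean/SD on the 0-255 scale, optionally overlaid with dark heterochromatin
clumps.  fBm is used because its surface fractal dimension is known in
closed form (FD = 3 - H), which gives the fractal module an oracle.

Cohorts consist of two groups with distinct texture and survival parameters
(exponential survival, administrative censoring).  Every random draw is
funneled through per-patient streams derived by hashing (seed, patient_id),
so output is bit-reproducible and stable under patient-count changes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .datatypes import NucleusImage, PatientRecord
from .errors import ConfigurationError, ValidationError

__all__ = [
    "GroupParams",
    "SurvivalParams",
    "GeneratorConfig",
    "CohortBundle",
    "generate_mask",
    "generate_fbm_surface",
    "compose_nucleus",
    "generate_cohort",
    "write_cohort",
]


@dataclass
class GroupParams:
    """Texture, shape and clinical parameters of one patient group."""

    hurst: float = 0.75
    mean_gray: float = 130.0
    sd_gray: float = 8.7
    clump_density: float = 0.0
    grain: float = 0.0
    mask_shape: str = "oval"
    area_um2_range: tuple[float, float] = (80.0, 130.0)
    leukocyte_mean: float = 8.0
    leukocyte_sd: float = 4.0

    def validate(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ConfigurationError(f"hurst must be in (0, 1), got {self.hurst}")
        if not 0.0 <= self.mean_gray <= 255.0:
            raise ConfigurationError("mean_gray must be in [0, 255]")
        if self.sd_gray <= 0:
            raise ConfigurationError("sd_gray must be > 0")
        if self.clump_density < 0:
            raise ConfigurationError("clump_density must be >= 0")
        if self.grain < 0:
            raise ConfigurationError("grain must be >= 0")
        if self.mask_shape not in ("oval", "bilobed"):
            raise ConfigurationError(f"unknown mask shape {self.mask_shape!r}")
        if not 0 < self.area_um2_range[0] <= self.area_um2_range[1]:
            raise ConfigurationError("invalid area_um2_range")


@dataclass
class SurvivalParams:
    """Exponential hazard and administrative censoring for one group."""

    hazard_rate: float = 0.01
    censor_time: float = 36.0

    def validate(self) -> None:
        if self.hazard_rate <= 0:
            raise ConfigurationError("hazard_rate must be > 0")
        if self.censor_time <= 0:
            raise ConfigurationError("censor_time must be > 0")


def default_group_params() -> dict[str, GroupParams]:
    # Group A emulates the ITD-like contrast (smoother, darker, narrower
    # chromatin; leukocytosis); group B the classical morphology.
    return {
        "A": GroupParams(
            hurst=0.9,
            mean_gray=108.0,
            sd_gray=6.3,
            clump_density=0.5,
            grain=0.11,
            mask_shape="bilobed",
            leukocyte_mean=35.0,
            leukocyte_sd=12.0,
        ),
        "B": GroupParams(
            hurst=0.75,
            mean_gray=130.0,
            sd_gray=8.7,
            clump_density=0.3,
            grain=0.08,
            mask_shape="oval",
            leukocyte_mean=8.0,
            leukocyte_sd=4.0,
        ),
    }


def default_survival_params() -> dict[str, SurvivalParams]:
    return {
        "A": SurvivalParams(hazard_rate=0.08, censor_time=36.0),
        "B": SurvivalParams(hazard_rate=0.01, censor_time=36.0),
    }


@dataclass
class GeneratorConfig:
    seed: int = 42
    n_patients_per_group: int = 10
    nuclei_per_patient: int = 100
    group_params: dict[str, GroupParams] = field(default_factory=default_group_params)
    survival_params: dict[str, SurvivalParams] = field(default_factory=default_survival_params)
    calibration_um_per_px: float = 0.1

    def validate(self) -> None:
        if self.nuclei_per_patient < 1:
            raise ConfigurationError("nuclei_per_patient must be >= 1")
        if self.n_patients_per_group < 1:
            raise ConfigurationError("n_patients_per_group must be >= 1")
        if self.calibration_um_per_px <= 0:
            raise ConfigurationError("calibration must be > 0")
        if set(self.group_params) != set(self.survival_params):
            raise ConfigurationError("group_params and survival_params keys differ")
        for gp in self.group_params.values():
            gp.validate()
        for sp in self.survival_params.values():
            sp.validate()

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortBundle:
    """Generated nuclei, patient records and the truth config echo."""

    nuclei: list[NucleusImage]
    patients: list[PatientRecord]
    truth: GeneratorConfig


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    """Stable per-patient stream: hash (seed, patient_id) into a Generator."""
    digest = hashlib.sha256(f"{seed}:{patient_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def generate_mask(shape: str, area_px: int, rng: np.random.Generator) -> np.ndarray:
    """Binary mask of roughly ``area_px`` pixels, oval or bilobed.

    The bilobed variant is two overlapping ellipses sharing a waist.  The
    result is a single 4-connected component whose pixel count is within
    10% of the request.
    """
    if shape not in ("oval", "bilobed"):
        raise ConfigurationError(f"unknown mask shape {shape!r}")
    if area_px < 50:
        raise ValidationError(f"area_px must be >= 50, got {area_px}")
    elong = rng.uniform(1.05, 1.35)
    theta = rng.uniform(0.0, np.pi)
    sep_frac = rng.uniform(0.75, 0.95) if shape == "bilobed" else 0.0

    def render(scale: float) -> np.ndarray:
        if shape == "oval":
            b_ax = scale * np.sqrt(area_px / (np.pi * elong))
            a_ax = elong * b_ax
            off = 0.0
        else:
            b_ax = scale * np.sqrt(area_px / (1.75 * np.pi * elong))
            a_ax = elong * b_ax
            off = sep_frac * a_ax
        half = int(np.ceil(a_ax + off)) + 2
        yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
        xr = xx * np.cos(theta) + yy * np.sin(theta)
        yr = -xx * np.sin(theta) + yy * np.cos(theta)
        lobe1 = ((xr - off) / a_ax) ** 2 + (yr / b_ax) ** 2 <= 1.0
        if off == 0.0:
            return lobe1
        lobe2 = ((xr + off) / a_ax) ** 2 + (yr / b_ax) ** 2 <= 1.0
        return lobe1 | lobe2

    # digitization and lobe overlap shift the realized area; rescale to target
    scale = 1.0
    for _ in range(4):
        mask = render(scale)
        count = mask.sum()
        if abs(count - area_px) <= 0.02 * area_px:
            break
        scale *= np.sqrt(area_px / count)
    # crop to bounding box with a 1-px border
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    mask = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    return np.pad(mask, 1)


def generate_fbm_surface(
    hurst: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Fractional Brownian surface by spectral synthesis, unit variance.

    White Gaussian noise is filtered in the Fourier domain with amplitude
    proportional to f^-(hurst+1), i.e. power spectral density proportional
    to f^-(2 hurst + 2).  Synthesis runs on a doubled grid and crops the
    requested window to soften periodicity artifacts.  The surface fractal
    dimension of true fBm is 3 - hurst.
    """
    if not 0.0 < hurst < 1.0:
        raise ConfigurationError(f"hurst must be in (0, 1), got {hurst}")
    if size < 32:
        raise ConfigurationError(f"size must be >= 32, got {size}")
    big = 2 * size
    noise = rng.standard_normal((big, big))
    freq = np.fft.fftfreq(big)
    radial = np.sqrt(freq[:, None] ** 2 + freq[None, :] ** 2)
    radial[0, 0] = np.inf  # kill the DC term
    amplitude = radial ** (-(hurst + 1.0))
    spectrum = np.fft.fft2(noise) * amplitude
    surface = np.fft.ifft2(spectrum).real[:size, :size]
    surface -= surface.mean()
    sd = surface.std()
    if sd > 0:
        surface /= sd
    return surface


def _add_clumps(
    z: np.ndarray, mask: np.ndarray, clump_density: float, rng: np.random.Generator
) -> None:
    """Superimpose dark elliptical clumps (in surface-SD units), in place."""
    area = int(mask.sum())
    n_clumps = rng.poisson(clump_density * area / 1000.0)
    if n_clumps == 0:
        return
    fg = np.argwhere(mask)
    yy, xx = np.indices(z.shape)
    for _ in range(n_clumps):
        cy, cx = fg[rng.integers(len(fg))]
        ay = rng.uniform(2.0, 6.0)
        ax = rng.uniform(2.0, 6.0)
        depth = rng.uniform(1.0, 3.0)
        ell = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
        z -= depth * np.exp(-ell)


def compose_nucleus(
    mask: np.ndarray,
    surface: np.ndarray,
    mean_gray: float,
    sd_gray: float,
    clump_density: float = 0.0,
    rng: np.random.Generator | None = None,
    calibration: float = 0.1,
    patient_id: str = "",
    nucleus_id: str = "",
    grain: float = 0.0,
) -> NucleusImage:
    """Render a nucleus: rescale the surface inside the mask to the target
    gray mean/SD, clip to [0, 255], round; background is white (255).

    ``grain`` adds pixel-scale white noise (in surface-SD units) mimicking
    stain granularity before rescaling; ``clump_density`` superimposes dark
    elliptical heterochromatin clumps (expected count per 1000 mask px).
    """
    if sd_gray <= 0:
        raise ConfigurationError("sd_gray must be > 0")
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    if surface.shape[0] < h or surface.shape[1] < w:
        raise ValidationError("surface does not cover the mask bounding box")
    z = surface[:h, :w].astype(np.float64).copy()
    if (clump_density > 0 or grain > 0) and rng is None:
        raise ConfigurationError("clump_density/grain > 0 require an rng")
    if clump_density > 0:
        _add_clumps(z, mask, clump_density, rng)
    if grain > 0:
        z += grain * rng.standard_normal(z.shape)
    vals = z[mask]
    sd = vals.std()
    if sd == 0:
        scaled = np.full_like(z, mean_gray)
    else:
        scaled = (z - vals.mean()) / sd * sd_gray + mean_gray
    gray = np.where(mask, np.clip(np.rint(scaled), 0, 255), 255).astype(np.uint8)
    return NucleusImage(
        gray=gray,
        mask=mask,
        calibration=calibration,
        patient_id=patient_id,
        nucleus_id=nucleus_id,
    )


def _make_patient_nuclei(
    config: GeneratorConfig,
    group: str,
    patient_id: str,
    rng: np.random.Generator,
) -> list[NucleusImage]:
    gp = config.group_params[group]
    calib = config.calibration_um_per_px
    nuclei = []
    # patient-level offsets give between-patient spread of per-patient medians
    mean_offset = rng.normal(0.0, 1.5)
    sd_factor = rng.lognormal(0.0, 0.08)
    hurst_p = float(np.clip(gp.hurst + rng.normal(0.0, 0.015), 0.01, 0.99))
    for j in range(config.nuclei_per_patient):
        area_um2 = rng.uniform(*gp.area_um2_range)
        area_px = max(50, int(round(area_um2 / calib**2)))
        mask = generate_mask(gp.mask_shape, area_px, rng)
        size = max(32, max(mask.shape))
        surface = generate_fbm_surface(hurst_p, size, rng)
        nucleus = compose_nucleus(
            mask,
            surface,
            mean_gray=gp.mean_gray + mean_offset + rng.normal(0.0, 0.8),
            sd_gray=gp.sd_gray * sd_factor * rng.lognormal(0.0, 0.05),
            clump_density=gp.clump_density,
            rng=rng,
            calibration=calib,
            patient_id=patient_id,
            nucleus_id=f"{patient_id}_n{j:04d}",
            grain=gp.grain,
        )
        nuclei.append(nucleus)
    return nuclei


def generate_cohort(config: GeneratorConfig) -> CohortBundle:
    """Generate the full two-group cohort deterministically from the seed."""
    config.validate()
    nuclei: list[NucleusImage] = []
    patients: list[PatientRecord] = []
    for group in sorted(config.group_params):
        sp = config.survival_params[group]
        gp = config.group_params[group]
        for i in range(config.n_patients_per_group):
            patient_id = f"{group}{i:03d}"
            rng = _patient_rng(config.seed, patient_id)
            nuclei.extend(_make_patient_nuclei(config, group, patient_id, rng))
            leukocytes = max(0.5, rng.normal(gp.leukocyte_mean, gp.leukocyte_sd))
            death_time = rng.exponential(1.0 / sp.hazard_rate)
            event = int(death_time <= sp.censor_time)
            time = death_time if event else sp.censor_time
            patients.append(
                PatientRecord(
                    patient_id=patient_id,
                    covariates={
                        "group": float(group == sorted(config.group_params)[0]),
                        "leukocyte_count": float(leukocytes),
                    },
                    time=float(time),
                    event=event,
                )
            )
    return CohortBundle(nuclei=nuclei, patients=patients, truth=config)


def write_cohort(bundle: CohortBundle, outdir: str | Path) -> dict[str, Path]:
    """Write PNGs, a manifest CSV, a patients CSV and the config YAML.

    Returns the paths of the three metadata files.
    """
    import pandas as pd
    import yaml

    from .io import write_png

    outdir = Path(outdir)
    img_dir = outdir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for nucleus in bundle.nuclei:
        img_path = img_dir / f"{nucleus.nucleus_id}.png"
        mask_path = img_dir / f"{nucleus.nucleus_id}_mask.png"
        write_png(nucleus.gray, img_path)
        write_png(np.where(nucleus.mask, 255, 0).astype(np.uint8), mask_path)
        # paths relative to the manifest keep the cohort relocatable and
        # reruns byte-identical regardless of the output directory
        rows.append(
            {
                "patient_id": nucleus.patient_id,
                "nucleus_id": nucleus.nucleus_id,
                "image_path": str(img_path.relative_to(outdir)),
                "mask_path": str(mask_path.relative_to(outdir)),
            }
        )
    manifest_path = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    patients_path = outdir / "patients.csv"
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "group": p.covariates.get("group", float("nan")),
                "leukocyte_count": p.covariates.get("leukocyte_count", float("nan")),
                "time": p.time,
                "event": p.event,
            }
            for p in bundle.patients
        ]
    ).to_csv(patients_path, index=False)
    config_path = outdir / "config.yaml"
    config_path.write_text(yaml.safe_dump(bundle.truth.to_dict(), sort_keys=True))
    return {"manifest": manifest_path, "patients": patients_path, "config": config_path}
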