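"""Synthetic 3D breast-MRI phantoms with known ground truth.

A phantom emulates the structure a fat-suppressed, contrast-enhanced T1
acquisition presents to the analysis pipeline: a compact ellipsoidal
tumor of elevated mean intensity, a surrounding mixture of dark adipose
and brighter fibroglandular tissue at a controllable volumetric
fraction, an air background, and additive Gaussian (or Rician) noise.
The peritumoral adipose/fibroglandular arrangement is a smoothed random
field thresholded so that the equal-volume boundary shell realizes the
requested fibroglandular fraction — enough to reproduce the bimodal
shell histograms the tissue classifier relies on, while keeping every
ground-truth label exact.

A "delayed-acquisition" cohort models contrast washout: the tumor mean
decays linearly toward the fibroglandular mean by a washout factor
w in [0, 1] (w = 0: early-phase intensities unchanged; w = 1: tumor
indistinguishable from fibroglandular tissue in the mean), while the
fibroglandular mean may be inflated by a persistence factor to mimic
persistent background parenchymal enhancement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .contrast_metrics import michelson_contrast
from .errors import PhantomSpecError
from .region_geometry import build_boundary_shell
from .volume_io import ImageVolume, RegionMask, save_mask, save_volume

LABEL_AIR = 0
LABEL_ADIPOSE = 1
LABEL_FIBRO = 2
LABEL_TUMOR = 3


@dataclass
class PhantomSpec:
    """Specification of one synthetic case.

    Intensity means are in arbitrary scanner-like units with the
    fat-suppressed ordering tumor > fibroglandular > adipose > air.
    ``fibro_fraction`` is the fibroglandular volume fraction targeted
    inside the equal-volume boundary shell. ``texture_corr_mm`` sets the
    correlation length of the peritumoral tissue texture (0 = voxelwise
    white-noise labels). Spacing defaults to 1 x 1 x 2 mm, matching
    typical in-plane resolution and slice thickness of axial 3D
    gradient-echo breast protocols.
    """

    shape: tuple[int, int, int] = (48, 48, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    tumor_center_mm: tuple[float, float, float] | None = None
    tumor_semiaxes_mm: tuple[float, float, float] = (7.0, 6.0, 5.0)
    mean_tumor: float = 400.0
    mean_fibro: float = 150.0
    mean_adipose: float = 30.0
    mean_air: float = 2.0
    noise_sigma: float = 10.0
    noise_model: Literal["gaussian", "rician"] = "gaussian"
    fibro_fraction: float = 0.4
    texture_corr_mm: float = 1.5
    seed: int = 0


@dataclass
class PhantomCase:
    """One realized phantom: image, masks, exact labels, and provenance."""

    case_id: str
    cohort_label: str
    volume: ImageVolume
    tumor: RegionMask
    body: RegionMask
    labels: np.ndarray
    spec: PhantomSpec

    @property
    def true_shell_fibro_fraction(self) -> float:
        """Fibroglandular fraction of the boundary shell in the true labels."""
        shell = build_boundary_shell(self.tumor, body=self.body)
        lab = self.labels[shell.mask.mask]
        return float((lab == LABEL_FIBRO).sum() / lab.size)


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_mm: tuple[float, float, float],
    semiaxes_mm: tuple[float, float, float],
) -> np.ndarray:
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    cx, cy, cz = center_mm
    ax, ay, az = semiaxes_mm
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom case, deterministic given ``spec.seed``.

    The body is an ellipsoid filling most of the grid; the tumor
    ellipsoid must sit strictly inside it. Tissue labels come from a
    Gaussian random field smoothed to ``texture_corr_mm`` and thresholded
    at the quantile that makes the equal-volume boundary shell hit
    ``fibro_fraction`` exactly (to one voxel); the same threshold is
    applied to the rest of the body for spatial continuity.
    """
    shape = tuple(int(n) for n in spec.shape)
    spacing = tuple(float(s) for s in spec.spacing)
    extent_mm = tuple(n * s for n, s in zip(shape, spacing))
    center = spec.tumor_center_mm or tuple(e / 2.0 for e in extent_mm)

    body_mask = _ellipsoid_mask(
        shape, spacing, tuple(e / 2.0 for e in extent_mm), tuple(0.45 * e for e in extent_mm)
    )
    tumor_mask = _ellipsoid_mask(shape, spacing, center, spec.tumor_semiaxes_mm)
    if not tumor_mask.any():
        raise PhantomSpecError("tumor ellipsoid contains no voxels")
    if (tumor_mask & ~body_mask).any():
        raise PhantomSpecError("tumor ellipsoid extends outside the body")
    if not (body_mask & ~tumor_mask).any():
        raise PhantomSpecError("tumor fills the entire body; no boundary tissue")
    if not (0.0 <= spec.fibro_fraction <= 1.0):
        raise PhantomSpecError(f"fibro_fraction must be in [0, 1], got {spec.fibro_fraction}")

    tumor = RegionMask(mask=tumor_mask, spacing=spacing)
    body = RegionMask(mask=body_mask, spacing=spacing)

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    noise_field = rng.standard_normal(shape)
    texture = rng.standard_normal(shape)
    if spec.texture_corr_mm > 0:
        sigma_vox = [spec.texture_corr_mm / s for s in spacing]
        texture = ndi.gaussian_filter(texture, sigma=sigma_vox)

    # threshold chosen on the shell so the realized shell fraction is exact
    shell = build_boundary_shell(tumor, body=body)
    shell_texture = texture[shell.mask.mask]
    if spec.fibro_fraction <= 0.0:
        fibro_region = np.zeros(shape, dtype=bool)
    elif spec.fibro_fraction >= 1.0:
        fibro_region = np.ones(shape, dtype=bool)
    else:
        threshold = np.quantile(shell_texture, 1.0 - spec.fibro_fraction)
        fibro_region = texture > threshold

    labels = np.full(shape, LABEL_AIR, dtype=np.uint8)
    labels[body_mask] = np.where(fibro_region[body_mask], LABEL_FIBRO, LABEL_ADIPOSE)
    labels[tumor_mask] = LABEL_TUMOR

    means = np.array([spec.mean_air, spec.mean_adipose, spec.mean_fibro, spec.mean_tumor])
    signal = means[labels]
    if spec.noise_sigma > 0:
        if spec.noise_model == "rician":
            other = rng.standard_normal(shape)
            data = np.sqrt(
                (signal + spec.noise_sigma * noise_field) ** 2 + (spec.noise_sigma * other) ** 2
            )
        else:
            data = signal + spec.noise_sigma * noise_field
    else:
        data = signal.astype(np.float64)

    volume = ImageVolume(data=data, spacing=spacing)
    return PhantomCase(
        case_id="", cohort_label="", volume=volume, tumor=tumor, body=body, labels=labels, spec=spec
    )


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort with per-case variability.

    Per-case intensity means, tumor size, and shell fibroglandular
    fraction are jittered around ``base``; the washout factor ``w``
    moves every case's tumor mean toward its fibroglandular mean,
    ``persistence`` optionally inflates the fibroglandular mean by
    (1 + persistence * w). Case randomness derives only from ``seed``
    and the case index, so two cohorts with the same seed share per-case
    draws and differ solely through w and persistence (matched
    "patients" re-imaged under a delayed protocol).
    """

    label: str
    n_cases: int
    base: PhantomSpec = field(default_factory=PhantomSpec)
    jitter_mean_tumor: float = 25.0
    jitter_mean_fibro: float = 12.0
    jitter_mean_adipose: float = 4.0
    fibro_fraction_range: tuple[float, float] = (0.2, 0.6)
    semiaxes_jitter_frac: float = 0.12
    washout: float = 0.0
    persistence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise PhantomSpecError("a cohort needs at least 2 cases")
        if not (0.0 <= self.washout <= 1.0):
            raise PhantomSpecError(f"washout must be in [0, 1], got {self.washout}")


def _case_spec(cspec: CohortSpec, index: int) -> tuple[PhantomSpec, dict]:
    """Draw one case's phantom spec; the draw depends only on (seed, index)."""
    ss = np.random.SeedSequence(entropy=cspec.seed, spawn_key=(index,))
    rng = np.random.default_rng(ss)
    base = cspec.base
    mean_tumor = rng.normal(base.mean_tumor, cspec.jitter_mean_tumor)
    mean_fibro = rng.normal(base.mean_fibro, cspec.jitter_mean_fibro)
    mean_adipose = rng.normal(base.mean_adipose, cspec.jitter_mean_adipose)
    mean_adipose = max(mean_adipose, base.mean_air + 1.0)
    mean_fibro = max(mean_fibro, mean_adipose + 10.0)
    mean_tumor = max(mean_tumor, mean_fibro + 20.0)
    fibro_fraction = rng.uniform(*cspec.fibro_fraction_range)
    scale = 1.0 + cspec.semiaxes_jitter_frac * rng.uniform(-1.0, 1.0, size=3)
    semiaxes = tuple(a * s for a, s in zip(base.tumor_semiaxes_mm, scale))
    phantom_seed = int(rng.integers(0, 2**31 - 1))

    # washout: tumor decays toward the (pre-persistence) fibroglandular mean
    w = cspec.washout
    tumor_eff = mean_fibro + (mean_tumor - mean_fibro) * (1.0 - w)
    fibro_eff = mean_fibro * (1.0 + cspec.persistence * w)

    spec = replace(
        base,
        tumor_semiaxes_mm=semiaxes,
        mean_tumor=float(tumor_eff),
        mean_fibro=float(fibro_eff),
        mean_adipose=float(mean_adipose),
        fibro_fraction=float(fibro_fraction),
        seed=phantom_seed,
    )
    truth = {
        "mean_tumor_early": float(mean_tumor),
        "mean_tumor": float(tumor_eff),
        "mean_fibro": float(fibro_eff),
        "mean_adipose": float(mean_adipose),
        "fibro_fraction": float(fibro_fraction),
        "washout": float(w),
        "expected_contrast_tumor_fibro": michelson_contrast(tumor_eff, fibro_eff),
        "expected_contrast_tumor_adipose": michelson_contrast(tumor_eff, mean_adipose),
    }
    return spec, truth


def simulate_cohort(cspec: CohortSpec) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Generate all cases of a cohort in memory with a ground-truth table."""
    cases: list[PhantomCase] = []
    rows: list[dict] = []
    for i in range(cspec.n_cases):
        spec, truth = _case_spec(cspec, i)
        case = make_phantom(spec)
        case.case_id = f"{cspec.label}_{i:03d}"
        case.cohort_label = cspec.label
        cases.append(case)
        rows.append({"case_id": case.case_id, "cohort_label": cspec.label, **truth})
    return cases, pd.DataFrame(rows)


def make_cohorts(
    cohorts: list[CohortSpec], out_dir: str | Path
) -> tuple[Path, Path]:
    """Write cohorts to disk in the manifest contract the pipeline consumes.

    Emits per-case NIfTI volumes and masks under ``out_dir``, a
    ``manifest.csv`` (case_id, cohort_label, volume_path,
    tumor_mask_path, body_mask_path), and a ``ground_truth.csv`` with the
    per-case true means, shell fibroglandular fractions, and analytic
    expected contrasts. Returns (manifest_path, ground_truth_path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows: list[dict] = []
    truth_tables: list[pd.DataFrame] = []
    for cspec in cohorts:
        cases, truth = simulate_cohort(cspec)
        truth_tables.append(truth)
        for case in cases:
            vol_path = out_dir / f"{case.case_id}_volume.nii"
            tum_path = out_dir / f"{case.case_id}_tumor.nii"
            body_path = out_dir / f"{case.case_id}_body.nii"
            save_volume(case.volume, vol_path)
            save_mask(case.tumor, tum_path)
            save_mask(case.body, body_path)
            manifest_rows.append(
                {
                    "case_id": case.case_id,
                    "cohort_label": case.cohort_label,
                    "volume_path": vol_path.name,
                    "tumor_mask_path": tum_path.name,
                    "body_mask_path": body_path.name,
                }
            )
    manifest_path = out_dir / "manifest.csv"
    truth_path = out_dir / "ground_truth.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    pd.concat(truth_tables, ignore_index=True).to_csv(truth_path, index=False)
    return manifest_path, truth_path
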