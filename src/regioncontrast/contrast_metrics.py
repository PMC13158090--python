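"""Per-case contrast metrics: Michelson contrast, SNR, CNR, and ROC AUC.

The central quantity is the normalized (Michelson) contrast between two
region mean intensities,

    C = (I_a - I_b) / (I_a + I_b),

bounded in [-1, 1] and invariant under global intensity rescaling, which
makes it comparable across scanners, coils, and sequences where absolute
signal units are not. A case report carries the tumor-to-boundary,
tumor-to-adipose, and tumor-to-fibroglandular contrasts plus companion
metrics (SNR, CNR, voxelwise ROC AUC) and tumor shape descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .errors import EmptyRegionError, NoiseEstimationError, UndefinedContrastError
from .region_geometry import BoundaryShell, ShapeMetrics, shape_metrics
from .tissue_classification import BoundaryPartition
from .volume_io import ImageVolume, RegionMask

#: stable column order of the per-case report CSV
REPORT_COLUMNS = (
    "case_id",
    "cohort_label",
    "contrast_tumor_boundary",
    "contrast_tumor_fibro",
    "contrast_tumor_adipose",
    "fibro_fraction",
    "otsu_threshold",
    "snr_tumor",
    "snr_fibro",
    "snr_adipose",
    "cnr_tumor_fibro",
    "cnr_tumor_adipose",
    "auc_tumor_fibro",
    "auc_tumor_adipose",
    "volume_mm3",
    "max_extent_mm",
    "surface_area_mm2",
    "sphericity",
    "shell_volume_mm3",
    "shell_thickness_mm",
    "noise_sigma",
    "flags",
)


def michelson_contrast(mean_a: float, mean_b: float) -> float:
    """Normalized contrast (mean_a - mean_b) / (mean_a + mean_b).

    Antisymmetric in its arguments and bounded in [-1, 1] for
    nonnegative region means.

    Raises
    ------
    UndefinedContrastError
        If the denominator is zero.
    """
    denom = mean_a + mean_b
    if denom == 0:
        raise UndefinedContrastError("mean_a + mean_b is zero; Michelson contrast undefined")
    return float((mean_a - mean_b) / denom)


def voxel_auc(positives: np.ndarray, negatives: np.ndarray) -> float:
    """ROC AUC of intensity as a voxelwise tumor-vs-tissue discriminator.

    Rank-based: the probability that a random positive (tumor) voxel
    intensity exceeds a random negative (tissue) voxel intensity, ties
    counted 1/2. Identical to the Mann-Whitney U statistic divided by
    n_pos * n_neg.
    """
    positives = np.asarray(positives, dtype=np.float64).ravel()
    negatives = np.asarray(negatives, dtype=np.float64).ravel()
    if positives.size == 0 or negatives.size == 0:
        raise EmptyRegionError("AUC requires nonempty positive and negative samples")
    ranks = stats.rankdata(np.concatenate([positives, negatives]))
    n_pos, n_neg = positives.size, negatives.size
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def estimate_noise_sigma(
    volume: ImageVolume,
    background: RegionMask | None = None,
    shell: BoundaryShell | None = None,
) -> float:
    """Estimate the noise standard deviation for SNR/CNR.

    Preferred mode: the standard deviation inside a user-supplied
    background (air) region. Fallback: a robust sigma (1.4826 * MAD) of
    the lowest-decile shell intensities — a heuristic that underestimates
    sigma when the darkest shell tissue carries structure, so an air
    region should be provided whenever available.
    """
    if background is not None and background.mask.any():
        return float(volume.data[background.mask].std(ddof=1))
    if shell is not None and shell.mask.mask.any():
        values = volume.data[shell.mask.mask]
        decile = np.quantile(values, 0.1)
        low = values[values <= decile]
        if low.size >= 3:
            mad = np.median(np.abs(low - np.median(low)))
            sigma = 1.4826 * mad
            if sigma > 0:
                return float(sigma)
    raise NoiseEstimationError("no background region and no estimable shell noise")


@dataclass
class CaseContrastReport:
    """All per-case metrics; undefined quantities are None plus a flag.

    Flags: ``degenerate_partition``, ``volume_deficit``, ``no_adipose``,
    ``no_fibro``, ``no_noise_estimate``, ``undefined_contrast``.
    Undefined metrics are never silently zero — cohort statistics are
    computed on the defined subset only.
    """

    case_id: str
    cohort_label: str
    contrast_tumor_boundary: Optional[float]
    contrast_tumor_fibro: Optional[float]
    contrast_tumor_adipose: Optional[float]
    fibro_fraction: float
    otsu_threshold: float
    snr_tumor: Optional[float]
    snr_fibro: Optional[float]
    snr_adipose: Optional[float]
    cnr_tumor_fibro: Optional[float]
    cnr_tumor_adipose: Optional[float]
    auc_tumor_fibro: Optional[float]
    auc_tumor_adipose: Optional[float]
    shape: ShapeMetrics
    shell_volume_mm3: float
    shell_thickness_mm: float
    noise_sigma: Optional[float]
    flags: set[str] = field(default_factory=set)

    def to_row(self) -> dict:
        """Flatten to a dict following :data:`REPORT_COLUMNS`."""
        row = {
            "case_id": self.case_id,
            "cohort_label": self.cohort_label,
            "contrast_tumor_boundary": self.contrast_tumor_boundary,
            "contrast_tumor_fibro": self.contrast_tumor_fibro,
            "contrast_tumor_adipose": self.contrast_tumor_adipose,
            "fibro_fraction": self.fibro_fraction,
            "otsu_threshold": self.otsu_threshold,
            "snr_tumor": self.snr_tumor,
            "snr_fibro": self.snr_fibro,
            "snr_adipose": self.snr_adipose,
            "cnr_tumor_fibro": self.cnr_tumor_fibro,
            "cnr_tumor_adipose": self.cnr_tumor_adipose,
            "auc_tumor_fibro": self.auc_tumor_fibro,
            "auc_tumor_adipose": self.auc_tumor_adipose,
            "volume_mm3": self.shape.volume_mm3,
            "max_extent_mm": self.shape.max_extent_mm,
            "surface_area_mm2": self.shape.surface_area_mm2,
            "sphericity": self.shape.sphericity,
            "shell_volume_mm3": self.shell_volume_mm3,
            "shell_thickness_mm": self.shell_thickness_mm,
            "noise_sigma": self.noise_sigma,
            "flags": ";".join(sorted(self.flags)),
        }
        return row


def case_report(
    volume: ImageVolume,
    tumor: RegionMask,
    shell: BoundaryShell,
    partition: BoundaryPartition,
    noise_sigma: float | None = None,
    background: RegionMask | None = None,
    case_id: str = "",
    cohort_label: str = "",
) -> CaseContrastReport:
    """Assemble the full per-case contrast report.

    Contrasts are Michelson contrasts of region mean intensities;
    SNR_region = mean_region / sigma and CNR = (mean_tumor -
    mean_tissue) / sigma, with sigma taken from ``noise_sigma`` if
    supplied, else estimated from ``background`` (air) or, as a last
    resort, from the darkest decile of the shell. If no sigma is
    obtainable, SNR/CNR are omitted with the ``no_noise_estimate`` flag
    while contrasts and AUCs are still computed.
    """
    if not tumor.mask.any():
        raise EmptyRegionError("tumor mask is empty")
    flags: set[str] = set()
    if shell.volume_deficit:
        flags.add("volume_deficit")
    if partition.degenerate:
        flags.add("degenerate_partition")

    tumor_vals = volume.data[tumor.mask]
    shell_vals = volume.data[shell.mask.mask]
    adipose_vals = volume.data[partition.adipose.mask]
    fibro_vals = volume.data[partition.fibroglandular.mask]
    mean_tumor = float(tumor_vals.mean())
    mean_shell = float(shell_vals.mean())

    def _contrast(mean_tissue: float) -> Optional[float]:
        try:
            return michelson_contrast(mean_tumor, mean_tissue)
        except UndefinedContrastError:
            flags.add("undefined_contrast")
            return None

    contrast_boundary = _contrast(mean_shell)

    if adipose_vals.size == 0:
        flags.add("no_adipose")
        mean_adipose = None
        contrast_adipose = None
        auc_adipose = None
    else:
        mean_adipose = float(adipose_vals.mean())
        contrast_adipose = _contrast(mean_adipose)
        auc_adipose = voxel_auc(tumor_vals, adipose_vals)

    if fibro_vals.size == 0:
        flags.add("no_fibro")
        mean_fibro = None
        contrast_fibro = None
        auc_fibro = None
    else:
        mean_fibro = float(fibro_vals.mean())
        contrast_fibro = _contrast(mean_fibro)
        auc_fibro = voxel_auc(tumor_vals, fibro_vals)

    sigma: Optional[float]
    if noise_sigma is not None:
        if noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        sigma = float(noise_sigma)
    else:
        try:
            sigma = estimate_noise_sigma(volume, background=background, shell=shell)
        except NoiseEstimationError:
            sigma = None
            flags.add("no_noise_estimate")

    if sigma is not None and sigma > 0:
        snr_tumor = mean_tumor / sigma
        snr_fibro = mean_fibro / sigma if mean_fibro is not None else None
        snr_adipose = mean_adipose / sigma if mean_adipose is not None else None
        cnr_fibro = (mean_tumor - mean_fibro) / sigma if mean_fibro is not None else None
        cnr_adipose = (mean_tumor - mean_adipose) / sigma if mean_adipose is not None else None
    else:
        snr_tumor = snr_fibro = snr_adipose = cnr_fibro = cnr_adipose = None

    return CaseContrastReport(
        case_id=case_id,
        cohort_label=cohort_label,
        contrast_tumor_boundary=contrast_boundary,
        contrast_tumor_fibro=contrast_fibro,
        contrast_tumor_adipose=contrast_adipose,
        fibro_fraction=partition.fibro_fraction,
        otsu_threshold=partition.threshold,
        snr_tumor=snr_tumor,
        snr_fibro=snr_fibro,
        snr_adipose=snr_adipose,
        cnr_tumor_fibro=cnr_fibro,
        cnr_tumor_adipose=cnr_adipose,
        auc_tumor_fibro=auc_fibro,
        auc_tumor_adipose=auc_adipose,
        shape=shape_metrics(tumor),
        shell_volume_mm3=shell.shell_volume_mm3,
        shell_thickness_mm=shell.thickness_mm,
        noise_sigma=sigma,
        flags=flags,
    )
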