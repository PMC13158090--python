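"""Batch orchestration: per-case analysis from a manifest and cohort comparison.

This layer only composes module operations (load -> shell -> partition ->
metrics -> statistics) and serializes their results; every number in the
output files is produced by a library function, never computed inline
here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from . import cohort_stats as cs
from .contrast_metrics import REPORT_COLUMNS, CaseContrastReport, case_report
from .errors import ConfigError, RegionContrastError
from .region_geometry import build_boundary_shell
from .synthetic_phantom import PhantomCase
from .tissue_classification import DEFAULT_BINS, partition_shell
from .volume_io import RegionMask, load_case, read_manifest, save_label_map

logger = logging.getLogger("regioncontrast")

#: metrics subjected to the non-inferiority test (normalized contrasts only;
#: the tumor-to-boundary contrast is excluded because it confounds tissue
#: composition with enhancement and is analyzed through correlations instead)
NONINFERIORITY_METRICS = ("contrast_tumor_fibro", "contrast_tumor_adipose")

#: metrics compared pairwise across cohorts
COMPARISON_METRICS = (
    "contrast_tumor_fibro",
    "contrast_tumor_adipose",
    "fibro_fraction",
    "snr_tumor",
    "snr_fibro",
    "snr_adipose",
    "cnr_tumor_fibro",
    "cnr_tumor_adipose",
    "auc_tumor_fibro",
    "auc_tumor_adipose",
)

#: per-cohort correlations: (x, y) column pairs
CORRELATION_PAIRS = (
    ("fibro_fraction", "contrast_tumor_boundary"),
    ("volume_mm3", "contrast_tumor_boundary"),
    ("max_extent_mm", "contrast_tumor_boundary"),
    ("sphericity", "contrast_tumor_boundary"),
)


@dataclass
class RunConfig:
    """Configuration of a batch run.

    ``noise_mode`` selects the SNR/CNR noise estimate: the standard
    deviation of air voxels outside the body mask (``air_background``),
    the robust sigma of the darkest shell decile (``shell_decile``), or a
    fixed ``noise_sigma``. The non-inferiority margin is in normalized
    contrast units and must be negative.
    """

    manifest: str | Path | None = None
    out_dir: str | Path = "regioncontrast_out"
    otsu_bins: int = DEFAULT_BINS
    noise_mode: Literal["air_background", "shell_decile", "provided"] = "air_background"
    noise_sigma: float | None = None
    noninferiority_margin: float = cs.DEFAULT_NONINFERIORITY_MARGIN
    alpha_two_sided: float = cs.DEFAULT_ALPHA_TWO_SIDED
    alpha_noninf: float = cs.DEFAULT_ALPHA_NONINFERIORITY
    reference_cohort: str = "prone"
    seed: int = 0
    write_label_maps: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.noninferiority_margin >= 0:
            raise ConfigError("noninferiority_margin must be negative")
        for alpha in (self.alpha_two_sided, self.alpha_noninf):
            if not (0.0 < alpha < 1.0):
                raise ConfigError("alphas must lie strictly between 0 and 1")
        if self.noise_mode == "provided" and (self.noise_sigma is None or self.noise_sigma <= 0):
            raise ConfigError("noise_mode='provided' requires a positive noise_sigma")
        if self.otsu_bins < 2:
            raise ConfigError("otsu_bins must be >= 2")


def run_case(config: RunConfig, row: pd.Series | dict) -> CaseContrastReport:
    """Analyze one manifest row: load, build the shell, partition, report."""
    row = dict(row)
    body_path = row.get("body_mask_path")
    if isinstance(body_path, float) and np.isnan(body_path):
        body_path = None
    volume, tumor, body = load_case(row["volume_path"], row["tumor_mask_path"], body_path)
    label_map_path = None
    if config.write_label_maps:
        label_dir = Path(config.out_dir) / "label_maps"
        label_dir.mkdir(parents=True, exist_ok=True)
        label_map_path = label_dir / f"{row['case_id']}_labels.nii"
    return analyze_arrays(
        config,
        volume=volume,
        tumor=tumor,
        body=body,
        case_id=str(row["case_id"]),
        cohort_label=str(row["cohort_label"]),
        label_map_path=label_map_path,
    )


def analyze_arrays(
    config: RunConfig,
    volume,
    tumor,
    body=None,
    case_id: str = "",
    cohort_label: str = "",
    label_map_path: str | Path | None = None,
) -> CaseContrastReport:
    """Analyze one already-loaded case (volume, tumor mask, optional body).

    When ``label_map_path`` is given, the intermediate segmentation is
    exported as a NIfTI label map (0 = outside, 1 = tumor, 2 = adipose
    shell, 3 = fibroglandular shell).
    """
    shell = build_boundary_shell(tumor, volume=volume, body=body)
    partition = partition_shell(volume, shell, bins=config.otsu_bins)
    if label_map_path is not None:
        labels = np.zeros(tumor.shape, dtype=np.uint8)
        labels[tumor.mask] = 1
        labels[partition.adipose.mask] = 2
        labels[partition.fibroglandular.mask] = 3
        save_label_map(labels, tumor.spacing, label_map_path)
    sigma = None
    background = None
    if config.noise_mode == "provided":
        sigma = config.noise_sigma
    elif config.noise_mode == "air_background" and body is not None:
        background = RegionMask(mask=~body.mask, spacing=body.spacing)
    # shell_decile mode: leave both unset; case_report falls back to the shell
    return case_report(
        volume,
        tumor,
        shell,
        partition,
        noise_sigma=sigma,
        background=background,
        case_id=case_id,
        cohort_label=cohort_label,
    )


def analyze_phantom_case(config: RunConfig, case: PhantomCase) -> CaseContrastReport:
    """Analyze an in-memory synthetic case through the identical path."""
    return analyze_arrays(
        config,
        volume=case.volume,
        tumor=case.tumor,
        body=case.body,
        case_id=case.case_id,
        cohort_label=case.cohort_label,
    )


def reports_to_frame(reports: Iterable[CaseContrastReport]) -> pd.DataFrame:
    """Stack case reports into a DataFrame with the stable column order."""
    frame = pd.DataFrame([r.to_row() for r in reports])
    return frame.reindex(columns=list(REPORT_COLUMNS))


def analyze_cohort(config: RunConfig) -> pd.DataFrame:
    """Run every case in the manifest; failed cases are logged and skipped.

    Writes ``cases.csv`` (and ``failures.csv`` if any) under
    ``config.out_dir`` and returns the report table.
    """
    if config.manifest is None:
        raise ConfigError("config.manifest is required for analyze_cohort")
    manifest = read_manifest(config.manifest)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports: list[CaseContrastReport] = []
    failures: list[dict] = []
    for _, row in manifest.iterrows():
        try:
            reports.append(run_case(config, row))
        except RegionContrastError as exc:
            logger.error("case %s failed: %s", row["case_id"], exc)
            failures.append({"case_id": row["case_id"], "error": str(exc)})
    frame = reports_to_frame(reports)
    frame.to_csv(out_dir / "cases.csv", index=False)
    if failures:
        pd.DataFrame(failures).to_csv(out_dir / "failures.csv", index=False)
    return frame


def _group(frame: pd.DataFrame, cohort: str, metric: str) -> Optional[cs.GroupSample]:
    values = frame.loc[frame["cohort_label"] == cohort, metric].dropna().to_numpy()
    if values.size < 2:
        return None
    return cs.GroupSample(label=cohort, values=values)


def compare_cohorts(
    frame: pd.DataFrame,
    reference: str,
    margin: float = cs.DEFAULT_NONINFERIORITY_MARGIN,
    alpha_two_sided: float = cs.DEFAULT_ALPHA_TWO_SIDED,
    alpha_noninf: float = cs.DEFAULT_ALPHA_NONINFERIORITY,
    metrics: Sequence[str] = COMPARISON_METRICS,
    noninferiority_metrics: Sequence[str] = NONINFERIORITY_METRICS,
) -> dict[str, pd.DataFrame]:
    """Cohort comparison framework on a per-case report table.

    For every metric and unordered cohort pair: Welch t-test with 95% CI,
    Mann-Whitney U, and per-group KS normality p-values. For the
    designated contrast metrics, each non-reference cohort is additionally
    tested for non-inferiority against the reference (one-sided,
    ``alpha_noninf``) with post-hoc power; those rows feed the
    forest-plot table (difference, CI, margin). Per-cohort Pearson
    correlations of tumor-to-boundary contrast against shell composition
    and tumor size/shape are reported with Fisher 95% CIs. Cases with a
    missing value for a metric are excluded listwise for that metric.

    Returns a dict of DataFrames: ``comparisons``, ``forest``,
    ``correlations``.
    """
    cohorts = list(dict.fromkeys(frame["cohort_label"]))
    if reference not in cohorts:
        raise ConfigError(f"reference cohort '{reference}' not present in {cohorts}")

    comparison_rows: list[dict] = []
    forest_rows: list[dict] = []
    for metric in metrics:
        if metric not in frame.columns:
            continue
        for i, label_a in enumerate(cohorts):
            for label_b in cohorts[i + 1 :]:
                a = _group(frame, label_a, metric)
                b = _group(frame, label_b, metric)
                if a is None or b is None:
                    comparison_rows.append(
                        {"metric": metric, "cohort_a": label_a, "cohort_b": label_b,
                         "skipped": "insufficient defined values"}
                    )
                    continue
                welch = cs.welch_test(a, b)
                u_stat, mwu_p = cs.mwu_test(a, b)
                ks_a = cs.ks_normality(a) if a.n >= 5 else None
                ks_b = cs.ks_normality(b) if b.n >= 5 else None
                row = {
                    "metric": metric,
                    "cohort_a": label_a,
                    "cohort_b": label_b,
                    "n_a": a.n,
                    "n_b": b.n,
                    "mean_a": a.mean,
                    "mean_b": b.mean,
                    "mean_diff": welch.mean_diff,
                    "ci95_lo": welch.ci95[0],
                    "ci95_hi": welch.ci95[1],
                    "welch_t": welch.t,
                    "welch_df": welch.df,
                    "p_two_sided": welch.p_two_sided,
                    "power_posthoc_two_sided": (
                        cs.posthoc_power(a, b, alpha=alpha_two_sided) if not welch.degenerate else np.nan
                    ),
                    "mwu_U": u_stat,
                    "mwu_p": mwu_p,
                    "ks_p_a": ks_a.p if ks_a is not None else np.nan,
                    "ks_p_b": ks_b.p if ks_b is not None else np.nan,
                    "skipped": "",
                }
                is_ni_pair = metric in noninferiority_metrics and reference in (label_a, label_b)
                if is_ni_pair and not (label_a == label_b == reference):
                    new_label = label_b if label_a == reference else label_a
                    new = _group(frame, new_label, metric)
                    ref = _group(frame, reference, metric)
                    ni = cs.noninferiority_test(
                        new, ref, margin=margin, alpha=alpha_noninf, metric=metric
                    )
                    row.update(
                        {
                            "noninferiority_new": new_label,
                            "p_noninferiority": ni.p_noninferiority,
                            "power_posthoc_noninf": ni.power_posthoc,
                            "verdict": ni.verdict,
                        }
                    )
                    forest_rows.append(
                        {
                            "metric": metric,
                            "cohort": new_label,
                            "reference": reference,
                            "mean_diff": ni.mean_diff,
                            "ci95_lo": ni.ci95[0],
                            "ci95_hi": ni.ci95[1],
                            "margin": margin,
                            "p_noninferiority": ni.p_noninferiority,
                            "power_posthoc": ni.power_posthoc,
                            "verdict": ni.verdict,
                        }
                    )
                comparison_rows.append(row)

    correlation_rows: list[dict] = []
    for cohort in cohorts:
        sub = frame[frame["cohort_label"] == cohort]
        for x_col, y_col in CORRELATION_PAIRS:
            if x_col not in sub.columns or y_col not in sub.columns:
                continue
            paired = sub[[x_col, y_col]].dropna()
            if len(paired) < 4:
                continue
            try:
                res = cs.pearson_with_ci(paired[x_col], paired[y_col])
            except RegionContrastError:
                continue
            correlation_rows.append(
                {
                    "cohort": cohort,
                    "x": x_col,
                    "y": y_col,
                    "r": res.r,
                    "ci95_lo": res.ci95[0],
                    "ci95_hi": res.ci95[1],
                    "n": res.n,
                }
            )

    return {
        "comparisons": pd.DataFrame(comparison_rows),
        "forest": pd.DataFrame(forest_rows),
        "correlations": pd.DataFrame(correlation_rows),
    }


def run_cohort_comparison(config: RunConfig, cases: pd.DataFrame | str | Path) -> dict[str, pd.DataFrame]:
    """Compare cohorts from a case table (DataFrame or cases.csv path).

    Writes ``comparisons.csv``, ``forest.csv``, ``correlations.csv`` and a
    JSON mirror under ``config.out_dir`` and returns the tables.
    """
    if not isinstance(cases, pd.DataFrame):
        cases = pd.read_csv(cases)
    tables = compare_cohorts(
        cases,
        reference=config.reference_cohort,
        margin=config.noninferiority_margin,
        alpha_two_sided=config.alpha_two_sided,
        alpha_noninf=config.alpha_noninf,
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {}
    for name, table in tables.items():
        table.to_csv(out_dir / f"{name}.csv", index=False)
        payload[name] = table.to_dict(orient="records")
    with open(out_dir / "comparison.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return tables
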