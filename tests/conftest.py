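"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from regioncontrast import PhantomSpec, RegionMask, make_phantom
from regioncontrast.pipeline import RunConfig


def brute_force_shell(tumor: RegionMask, body: RegionMask | None = None):
    """Independent equal-volume shell construction by exhaustive distance sort.

    For every eligible non-tumor voxel, the distance to the tumor is the
    minimum spacing-aware Euclidean distance to any tumor voxel center.
    Voxels are admitted stratum by stratum (all voxels sharing a distance
    enter together) until the shell's physical volume first reaches the
    tumor's. Returns (shell boolean array, realized thickness, deficit flag).
    """
    spacing = np.asarray(tumor.spacing)
    voxvol = float(np.prod(spacing))
    tumor_coords = np.argwhere(tumor.mask) * spacing
    eligible = ~tumor.mask
    if body is not None:
        eligible = eligible & body.mask
    elig_idx = np.argwhere(eligible)
    elig_coords = elig_idx * spacing
    # min distance to any tumor voxel, chunked to bound memory
    dists = np.empty(len(elig_coords))
    for start in range(0, len(elig_coords), 2048):
        block = elig_coords[start : start + 2048]
        d2 = ((block[:, None, :] - tumor_coords[None, :, :]) ** 2).sum(axis=2)
        dists[start : start + 2048] = np.sqrt(d2.min(axis=1))
    tumor_volume = tumor.mask.sum() * voxvol
    strata = np.unique(dists)
    shell = np.zeros(tumor.mask.shape, dtype=bool)
    total = 0.0
    thickness = 0.0
    deficit = True
    for t in strata:
        in_stratum = dists == t
        shell[tuple(elig_idx[in_stratum].T)] = True
        total += in_stratum.sum() * voxvol
        thickness = float(t)
        if total >= tumor_volume:
            deficit = False
            break
    return shell, thickness, deficit


def brute_force_otsu(values: np.ndarray, bins: int = 256) -> float:
    """Naive between-class-variance scan over all candidate bin edges.

    Accumulates class weights and means with sequential running sums so
    that floating-point ties resolve identically to a cumulative-sum
    implementation; ties break to the lowest edge.
    """
    values = np.asarray(values, dtype=np.float64)
    counts, edges = np.histogram(values, bins=bins, range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_score, best_edge = -np.inf, None
    w0 = 0.0
    mass0 = 0.0
    total = float(counts.sum())
    total_mass = float((counts * centers).sum())
    for k in range(1, bins):
        w0 += counts[k - 1]
        mass0 += counts[k - 1] * centers[k - 1]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = mass0 / w0
        mu1 = (total_mass - mass0) / w1
        score = w0 * w1 * (mu0 - mu1) ** 2
        if score > best_score:
            best_score, best_edge = score, float(edges[k])
    return best_edge


def brute_force_auc(positives: np.ndarray, negatives: np.ndarray) -> float:
    """All-pairs AUC: P(pos > neg) + 0.5 * P(pos == neg)."""
    pos = np.asarray(positives, dtype=np.float64)[:, None]
    neg = np.asarray(negatives, dtype=np.float64)[None, :]
    wins = (pos > neg).sum() + 0.5 * (pos == neg).sum()
    return float(wins / (pos.size * neg.size))


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def small_phantom():
    """A compact noisy phantom reused by read-only tests."""
    spec = PhantomSpec(shape=(32, 32, 20), tumor_semiaxes_mm=(6.0, 5.0, 5.0), seed=7)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(
        shape=(32, 32, 20), tumor_semiaxes_mm=(6.0, 5.0, 5.0),
        mean_tumor=400.0, mean_fibro=100.0, mean_adipose=50.0, mean_air=5.0,
        noise_sigma=0.0, fibro_fraction=0.5, seed=5,
    )
    return make_phantom(spec)


def random_tumor_mask(rng: np.random.Generator, shape=(16, 16, 12), spacing=(1.0, 1.0, 2.0)) -> RegionMask:
    """A random connected blob strictly inside the grid (for shell property tests)."""
    from scipy import ndimage as ndi

    while True:
        seeds = np.zeros(shape, dtype=bool)
        n_seed = rng.integers(1, 4)
        idx = np.column_stack([rng.integers(3, s - 3, size=n_seed) for s in shape])
        seeds[tuple(idx.T)] = True
        grown = ndi.binary_dilation(seeds, iterations=int(rng.integers(1, 4)))
        grown[:2], grown[-2:] = False, False
        grown[:, :2], grown[:, -2:] = False, False
        grown[:, :, :2], grown[:, :, -2:] = False, False
        if grown.any():
            return RegionMask(mask=grown, spacing=spacing)
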