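"""Domain-divergence diagnostics: pooled pixel-intensity histograms and a
two-sample T-statistic between intensity populations.

Every pixel is treated as an observation of its domain's intensity
population; optional seeded per-image subsampling bounds the cost (and the
otherwise degenerate p-values) at scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .data_io import DomainDataset, ImageSample
from .errors import ConfigurationError

DEFAULT_BINS = 50


@dataclass(frozen=True)
class IntensityProfile:
    """Normalized pooled-intensity histogram of one dataset."""

    domain_id: str
    bin_edges: np.ndarray  # length n_bins + 1, spanning [0, 1]
    density: np.ndarray  # length n_bins, sums to 1
    n_pixels: int

    def __post_init__(self) -> None:
        if len(self.density) != len(self.bin_edges) - 1:
            raise ValueError("len(density) must equal len(bin_edges) - 1")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        if self.n_pixels > 0 and abs(float(self.density.sum()) - 1.0) > 1e-9:
            raise ValueError("density must sum to 1")


@dataclass(frozen=True)
class TTestResult:
    t_value: float
    p_value: float
    df: float
    variant: str  # "student_pooled" | "welch"


@dataclass(frozen=True)
class DomainComparison:
    profile_A: IntensityProfile
    profile_B: IntensityProfile
    per_class_profiles_A: dict[str, IntensityProfile]
    per_class_profiles_B: dict[str, IntensityProfile]
    ttest: TTestResult
    subsample_per_image: int | None = None


def _pooled_intensities(
    samples: Sequence[ImageSample],
    subsample_per_image: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    if not samples:
        raise ValueError("no samples to pool intensities from")
    chunks = []
    for s in samples:
        flat = np.asarray(s.pixels, dtype=np.float64).ravel()
        if subsample_per_image is not None and flat.size > subsample_per_image:
            assert rng is not None
            flat = rng.choice(flat, size=subsample_per_image, replace=False)
        chunks.append(flat)
    return np.concatenate(chunks)


def intensity_histogram(
    dataset: DomainDataset | Sequence[ImageSample],
    n_bins: int = DEFAULT_BINS,
    domain_id: str | None = None,
) -> IntensityProfile:
    """Pool all pixels of all samples (both splits) into fixed equal-width
    bins on [0, 1], normalized to sum 1."""
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if isinstance(dataset, DomainDataset):
        samples = dataset.train + dataset.test
        domain_id = domain_id or dataset.domain_id
    else:
        samples = list(dataset)
        domain_id = domain_id or (samples[0].domain_id if samples else "unknown")
    if not samples:
        raise ValueError("empty dataset")
    values = _pooled_intensities(samples)
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    return IntensityProfile(
        domain_id=domain_id,
        bin_edges=edges,
        density=counts / counts.sum(),
        n_pixels=int(values.size),
    )


def two_sample_tstat(
    intensities_A: Sequence[float],
    intensities_B: Sequence[float],
    variant: str = "welch",
) -> TTestResult:
    """Two-sided two-sample t-test on the difference of means.

    ``student_pooled`` uses the pooled-variance statistic with
    df = n_A + n_B - 2; ``welch`` uses the unequal-variance statistic with
    Welch-Satterthwaite df.  Both groups zero-variance with equal means
    returns t = 0, p = 1 by convention.
    """
    if variant not in ("student_pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    a = np.asarray(intensities_A, dtype=np.float64)
    b = np.asarray(intensities_B, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)

    if va == 0.0 and vb == 0.0:
        df = float(na + nb - 2)
        if ma == mb:
            return TTestResult(t_value=0.0, p_value=1.0, df=df, variant=variant)
        t = np.inf if ma > mb else -np.inf
        return TTestResult(t_value=float(t), p_value=0.0, df=df, variant=variant)

    if variant == "student_pooled":
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        se2a, se2b = va / na, vb / nb
        se = np.sqrt(se2a + se2b)
        df = float(
            (se2a + se2b) ** 2
            / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
        )
    t = (ma - mb) / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(t_value=float(t), p_value=p, df=df, variant=variant)


def compare_domains(
    dataset_A: DomainDataset,
    dataset_B: DomainDataset,
    n_bins: int = DEFAULT_BINS,
    subsample_per_image: int | None = None,
    variant: str = "welch",
    seed: int = 0,
) -> DomainComparison:
    """Pooled and per-class intensity profiles plus the pooled-intensity t-test."""
    if dataset_A.class_names != dataset_B.class_names:
        raise ConfigurationError(
            f"class name mismatch: {dataset_A.class_names} vs {dataset_B.class_names}"
        )
    rng = np.random.default_rng(seed)

    def pooled(ds: DomainDataset) -> np.ndarray:
        return _pooled_intensities(ds.train + ds.test, subsample_per_image, rng)

    def per_class(ds: DomainDataset) -> dict[str, IntensityProfile]:
        out = {}
        for label, name in enumerate(ds.class_names):
            samples = [s for s in ds.train + ds.test if s.label == label]
            if samples:
                out[name] = intensity_histogram(samples, n_bins, domain_id=ds.domain_id)
        return out

    ia, ib = pooled(dataset_A), pooled(dataset_B)
    return DomainComparison(
        profile_A=intensity_histogram(dataset_A, n_bins),
        profile_B=intensity_histogram(dataset_B, n_bins),
        per_class_profiles_A=per_class(dataset_A),
        per_class_profiles_B=per_class(dataset_B),
        ttest=two_sample_tstat(ia, ib, variant=variant),
        subsample_per_image=subsample_per_image,
    )


def histogram_distance(p: IntensityProfile, q: IntensityProfile) -> float:
    """Total-variation distance between two profiles on identical bins."""
    if not np.allclose(p.bin_edges, q.bin_edges):
        raise ValueError("profiles must share bin edges")
    return float(0.5 * np.abs(p.density - q.density).sum())
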