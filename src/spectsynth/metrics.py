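"""Image-quality metrics and the paired statistical protocol.

Synthetic projections are compared against both the noisy and the
noise-free ground truth with the structural similarity index (SSIM,
Gaussian 11x11 window, sigma 1.5, standard stabilizers) and the
normalized root-mean-squared error (NRMSE, in percent of the ground
truth stack maximum by default).  Per-dataset means are aggregated as a
mean of means; paired hypothesis tests follow a normality-gated
protocol: a Shapiro-Wilk test on the paired differences decides between
the paired two-sided t test and the Wilcoxon signed-rank test for NRMSE,
while SSIM (typically non-normal) always uses the Wilcoxon signed-rank
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .projector import ProjectionSet

__all__ = [
    "ssim_pair", "nrmse_pair", "MetricsRecord", "dataset_metrics",
    "ComparisonResult", "paired_compare", "BlandAltman", "bland_altman",
]

_SSIM_SIGMA = 1.5
_SSIM_TRUNCATE = 3.5  # 11x11 window
_K1, _K2 = 0.01, 0.03


def ssim_pair(a: np.ndarray, b: np.ndarray, data_range: float,
              sigma: float = _SSIM_SIGMA) -> float:
    """Structural similarity of two 2D images.

    Gaussian-weighted local statistics (window 11x11 for sigma 1.5),
    population covariances, stabilizers C1 = (0.01 L)^2 and
    C2 = (0.03 L)^2 with L = ``data_range``; the mean is taken over the
    window-valid interior.  Symmetric in (a, b) and 1 iff a == b.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("images must be two equal-shape 2D arrays")
    if data_range <= 0:
        raise ValueError("data_range must be positive")

    def filt(img):
        return ndimage.gaussian_filter(img, sigma, truncate=_SSIM_TRUNCATE)

    ua, ub = filt(a), filt(b)
    vara = filt(a * a) - ua * ua
    varb = filt(b * b) - ub * ub
    covab = filt(a * b) - ua * ub
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    s = ((2 * ua * ub + c1) * (2 * covab + c2)) / \
        ((ua**2 + ub**2 + c1) * (vara + varb + c2))
    pad = int(_SSIM_TRUNCATE * sigma + 0.5)
    return float(s[pad:-pad, pad:-pad].mean())


def nrmse_pair(estimate: np.ndarray, reference: np.ndarray,
               normalization: str = "max",
               norm_value: float | None = None) -> float:
    """Normalized RMSE in percent.

    ``normalization``: 'max' (default), 'mean' or 'range' of the
    reference, or pass an explicit ``norm_value`` (e.g. the maximum of
    the whole ground-truth stack).
    """
    estimate = np.asarray(estimate, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if estimate.shape != reference.shape:
        raise ValueError("shape mismatch")
    if norm_value is None:
        if normalization == "max":
            norm_value = reference.max()
        elif normalization == "mean":
            norm_value = reference.mean()
        elif normalization == "range":
            norm_value = reference.max() - reference.min()
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
    if norm_value <= 0:
        raise ValueError("normalization constant must be positive")
    rmse = np.sqrt(np.mean((estimate - reference) ** 2))
    return float(100.0 * rmse / norm_value)


@dataclass
class MetricsRecord:
    """Per-dataset mean metrics of synthetic projections against both
    ground truths."""

    dataset_id: str
    mean_ssim_vs_noisy: float
    mean_nrmse_vs_noisy: float
    mean_ssim_vs_noisefree: float
    mean_nrmse_vs_noisefree: float


def _stack_means(synth: np.ndarray, truth: np.ndarray
                 ) -> tuple[float, float]:
    data_range = float(truth.max())
    if data_range <= 0:
        raise ValueError("ground-truth stack is empty")
    ssims = [ssim_pair(s, t, data_range) for s, t in zip(synth, truth)]
    nrmses = [nrmse_pair(s, t, norm_value=data_range)
              for s, t in zip(synth, truth)]
    return float(np.mean(ssims)), float(np.mean(nrmses))


def dataset_metrics(synthetic: ProjectionSet, noisy: ProjectionSet,
                    noisefree: ProjectionSet) -> MetricsRecord:
    """Mean SSIM/NRMSE over all synthetic projections of one dataset."""
    for other in (noisy, noisefree):
        if not np.allclose(synthetic.angles_deg, other.angles_deg):
            raise ValueError("projection sets are not angle-aligned")
    s_n, n_n = _stack_means(synthetic.images, noisy.images)
    s_f, n_f = _stack_means(synthetic.images, noisefree.images)
    return MetricsRecord(synthetic.dataset_id, s_n, n_n, s_f, n_f)


@dataclass
class ComparisonResult:
    metric: str
    test: str  # 'paired t' | 'wilcoxon' | 'degenerate'
    p_value: float
    mean_difference: float
    loa_lower: float
    loa_upper: float
    shapiro_p: float | None = None


def _wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    d = d[d != 0]
    method = "exact" if len(d) <= 25 else "approx"
    try:
        res = stats.wilcoxon(d, alternative="two-sided", method=method,
                             correction=(method == "approx"))
    except ValueError:  # ties prevent the exact distribution
        res = stats.wilcoxon(d, alternative="two-sided", method="approx",
                             correction=True)
    return float(res.pvalue)


def paired_compare(a, b, metric: str, alpha: float = 0.05
                   ) -> ComparisonResult:
    """Paired two-sided comparison of two metric series.

    NRMSE: Shapiro-Wilk on the paired differences gates between the
    paired t test (normality not rejected at ``alpha``) and the Wilcoxon
    signed-rank test.  SSIM: always Wilcoxon signed-rank.  All-zero
    differences are flagged degenerate with p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1D series of length >= 3")
    d = a - b
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (mean_d - 1.96 * sd, mean_d + 1.96 * sd)
    if np.all(d == 0):
        return ComparisonResult(metric, "degenerate", 1.0, 0.0, 0.0, 0.0)
    if metric.lower() == "ssim":
        p = _wilcoxon(a, b)
        return ComparisonResult(metric, "wilcoxon", p, mean_d, *loa)
    shapiro_p = float(stats.shapiro(d).pvalue)
    if shapiro_p >= alpha:
        p = float(stats.ttest_rel(a, b).pvalue)
        return ComparisonResult(metric, "paired t", p, mean_d, *loa,
                                shapiro_p=shapiro_p)
    p = _wilcoxon(a, b)
    return ComparisonResult(metric, "wilcoxon", p, mean_d, *loa,
                            shapiro_p=shapiro_p)


@dataclass
class BlandAltman:
    mean_difference: float
    loa_lower: float
    loa_upper: float
    differences: np.ndarray
    means: np.ndarray


def bland_altman(a, b) -> BlandAltman:
    """Bland-Altman agreement data: per-pair differences and means, the
    mean difference and the 95% limits of agreement (mean +/- 1.96 SD)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need two equal-length series of length >= 2")
    d = a - b
    m = d.mean()
    sd = d.std(ddof=1)
    return BlandAltman(float(m), float(m - 1.96 * sd), float(m + 1.96 * sd),
                       d, (a + b) / 2.0)
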