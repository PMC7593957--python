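"""System suitability and in-house validation of the analytical fingerprint.

Untargeted fingerprints cannot be validated compound by compound, so the
signal itself is validated: a peak-free noise window sets a gating threshold
(mean noise + 3 SD); per-scan relative standard deviation over pooled-QC
replicates measures intra-/inter-day repeatability against the 15%/20%
benchmarks; and a PCA distance-to-model (normalized residual SD, DModX)
flags deviating replicates. Suitability checks cover per-compound
signal-to-noise (> 3) and chromatographic resolution (R >= 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .chromatograms import Chromatogram, FingerprintMatrix
from .chemometrics import autoscale_fit, autoscale_apply, pca_fit

log = logging.getLogger(__name__)


@dataclass
class NoiseEstimate:
    mean_noise: float
    sd_noise: float
    window: tuple[int, int]

    @property
    def window_len(self) -> int:
        return self.window[1] - self.window[0]

    @property
    def threshold(self) -> float:
        """Signal gate: mean noise plus three standard deviations."""
        return self.mean_noise + 3.0 * self.sd_noise


@dataclass
class SuitabilityReport:
    snr_by_compound: dict[str, float]
    resolution: float
    resolution_pair: tuple[str, str]
    pass_snr: bool = field(init=False)
    pass_resolution: bool = field(init=False)

    def __post_init__(self) -> None:
        self.pass_snr = all(v > 3.0 for v in self.snr_by_compound.values())
        self.pass_resolution = self.resolution >= 1.0


@dataclass
class RepeatabilityReport:
    mode: Literal["intra_day", "inter_day"]
    retained_mask: np.ndarray
    rsd_percent: np.ndarray     # over retained, defined points
    frac_rsd_le_15: float
    frac_rsd_le_20: float
    n_undefined: int = 0

    @property
    def retained_fraction(self) -> float:
        return float(self.retained_mask.mean())


@dataclass
class DModXReport:
    residual_sd_per_sample: np.ndarray  # normalized distance to the PCA model
    critical_value: float
    flags: np.ndarray


def estimate_noise(row: np.ndarray, window_len: int = 300) -> NoiseEstimate:
    """Mean/SD of the minimum-variance contiguous window of ``window_len`` scans.

    The minimum-variance window is an automatic proxy for a representative
    peak-free region of the TIC.
    """
    row = np.asarray(row, dtype=float)
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    if row.size <= window_len:
        raise ValueError(
            f"row length {row.size} must exceed window_len {window_len}")
    # rolling mean/variance via cumulative sums
    c1 = np.concatenate([[0.0], np.cumsum(row)])
    c2 = np.concatenate([[0.0], np.cumsum(row**2)])
    w = window_len
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    var = np.maximum(s2 / w - (s1 / w) ** 2, 0.0)
    start = int(np.argmin(var))
    seg = row[start:start + w]
    return NoiseEstimate(
        mean_noise=float(seg.mean()),
        sd_noise=float(seg.std(ddof=1)),
        window=(start, start + w),
    )


def signal_mask(replicates: np.ndarray | FingerprintMatrix,
                noise: NoiseEstimate) -> np.ndarray:
    """Retain scan points whose mean replicate intensity exceeds the gate.

    A point survives iff mean intensity > mean_noise + 3 * sd_noise (strict).
    """
    values = replicates.values if isinstance(replicates, FingerprintMatrix) else np.asarray(replicates, float)
    if values.ndim == 1:
        values = values[None, :]
    if values.size == 0:
        raise ValueError("empty replicate matrix")
    return values.mean(axis=0) > noise.threshold


def rsd_per_point(
    replicates: FingerprintMatrix | np.ndarray,
    mask: np.ndarray,
    mode: Literal["intra_day", "inter_day"] = "intra_day",
) -> RepeatabilityReport:
    """Per-scan RSD% over replicate injections, restricted to gated points.

    RSD% = 100 * SD(n-1) / mean. Retained points with zero mean are reported
    as undefined and excluded from the <=15% / <=20% fractions (logged).
    """
    values = replicates.values if isinstance(replicates, FingerprintMatrix) else np.asarray(replicates, float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 replicates")
    mask = np.asarray(mask, dtype=bool)
    if mask.size != values.shape[1]:
        raise ValueError("mask length does not match scan count")
    sub = values[:, mask]
    means = sub.mean(axis=0)
    sds = sub.std(axis=0, ddof=1)
    defined = means != 0
    n_undef = int((~defined).sum())
    if n_undef:
        log.warning("%d retained points have zero mean; RSD undefined there", n_undef)
    rsd = 100.0 * sds[defined] / means[defined]
    if rsd.size:
        frac15 = float((rsd <= 15.0).mean())
        frac20 = float((rsd <= 20.0).mean())
    else:
        frac15 = frac20 = float("nan")
    return RepeatabilityReport(
        mode=mode, retained_mask=mask, rsd_percent=rsd,
        frac_rsd_le_15=frac15, frac_rsd_le_20=frac20, n_undefined=n_undef,
    )


def _find_apex(chrom: Chromatogram, peak_rt: float, tol_min: float = 0.2) -> int:
    lo = np.searchsorted(chrom.rt, peak_rt - tol_min)
    hi = np.searchsorted(chrom.rt, peak_rt + tol_min)
    if hi <= lo:
        raise ValueError(f"no scans within {tol_min} min of rt {peak_rt}")
    return lo + int(np.argmax(chrom.intensity[lo:hi]))


def snr(chrom: Chromatogram, peak_rt: float, noise: NoiseEstimate,
        tol_min: float = 0.2) -> float:
    """Signal-to-noise ratio: (apex - mean noise) / noise SD."""
    apex = float(chrom.intensity[_find_apex(chrom, peak_rt, tol_min)])
    if noise.sd_noise == 0:
        warnings.warn("noise SD is zero; SNR reported as +inf", stacklevel=2)
        return float("inf")
    return (apex - noise.mean_noise) / noise.sd_noise


def _gaussian(t, amp, mu, sigma, base):
    return base + amp * np.exp(-((t - mu) ** 2) / (2 * sigma**2))


def _fit_peak_sigma(chrom: Chromatogram, peak_rt: float, tol_min: float = 0.2) -> tuple[float, float]:
    """Fit a local Gaussian around the apex; return (apex rt, sigma in minutes)."""
    apex = _find_apex(chrom, peak_rt, tol_min)
    mu0 = float(chrom.rt[apex])
    # initial sigma from half maximum crossing
    height = chrom.intensity[apex]
    base0 = float(np.percentile(chrom.intensity, 10))
    half = base0 + (height - base0) / 2.0
    left = apex
    while left > 0 and chrom.intensity[left] > half:
        left -= 1
    right = apex
    while right < len(chrom) - 1 and chrom.intensity[right] > half:
        right += 1
    fwhm = max(chrom.rt[right] - chrom.rt[left], 2 * (chrom.rt[1] - chrom.rt[0]))
    sigma0 = fwhm / 2.3548
    lo = np.searchsorted(chrom.rt, mu0 - 4 * sigma0)
    hi = np.searchsorted(chrom.rt, mu0 + 4 * sigma0)
    t = chrom.rt[lo:hi]
    y = chrom.intensity[lo:hi]
    try:
        popt, _ = optimize.curve_fit(
            _gaussian, t, y,
            p0=[height - base0, mu0, sigma0, base0],
            maxfev=5000,
        )
        amp, mu, sigma, _b = popt
        if amp <= 0 or not np.isfinite(sigma):
            raise RuntimeError
        return float(mu), abs(float(sigma))
    except Exception:  # fall back to the moment-style estimate
        return mu0, float(sigma0)


def resolution(chrom: Chromatogram, rt1: float, rt2: float,
               tol_min: float = 0.2) -> float:
    """Chromatographic resolution R = (t2 - t1) / mean baseline width.

    Peak widths use the baseline-width convention w = 4 sigma from a local
    Gaussian fit at each apex, so R = 2 |t2 - t1| / (w1 + w2)... identically
    the retention-time difference over the average width.
    """
    mu1, s1 = _fit_peak_sigma(chrom, rt1, tol_min)
    mu2, s2 = _fit_peak_sigma(chrom, rt2, tol_min)
    w1, w2 = 4 * s1, 4 * s2
    return abs(mu2 - mu1) / ((w1 + w2) / 2.0)


def suitability_report(
    chrom: Chromatogram,
    compound_rts: Mapping[str, float],
    resolution_pair: tuple[str, str],
    noise: NoiseEstimate | None = None,
) -> SuitabilityReport:
    """Evaluate SNR for each listed compound and R for the named pair."""
    noise = noise or estimate_noise(chrom.intensity, window_len=min(300, len(chrom) // 4))
    snrs = {name: snr(chrom, rt, noise) for name, rt in compound_rts.items()}
    a, b = resolution_pair
    r = resolution(chrom, compound_rts[a], compound_rts[b])
    return SuitabilityReport(snr_by_compound=snrs, resolution=r,
                             resolution_pair=resolution_pair)


def pca_qc(
    replicates_and_controls: FingerprintMatrix,
    n_components: int = 4,
    confidence: float = 0.95,
    critical_value: float | None = None,
) -> tuple[np.ndarray, DModXReport]:
    """PCA precision check with a distance-to-model criterion.

    Rows are unit-variance scaled and mean centred, a PCA with
    ``n_components`` is fitted, and each sample's normalized residual SD
    (DModX) is its residual SD over ``p - A`` degrees of freedom divided by
    the model's pooled residual SD. The default critical value comes from
    the F distribution at ``confidence``; pass ``critical_value`` to pin the
    flagging threshold to a fixed plotting convention instead.
    """
    X = replicates_and_controls.values
    n, p = X.shape
    A = n_components
    if n < A + 2:
        raise ValueError("need at least n_components + 2 rows")
    pre = autoscale_fit(X)
    Xs = autoscale_apply(pre, X)
    model = pca_fit(Xs, A, preprocessed=True)
    recon = model.scores @ model.loadings.T
    resid = Xs - recon
    rss = (resid**2).sum(axis=1)
    s_i = np.sqrt(rss / (p - A))
    dof_pooled = (n - A - 1) * (p - A)
    s0 = np.sqrt(rss.sum() / dof_pooled) if dof_pooled > 0 else np.nan
    if rss.sum() <= 1e-12 * (Xs**2).sum():
        # data lie (numerically) in the A-dimensional model plane
        norm_sd = np.zeros(n)
    elif s0 and np.isfinite(s0) and s0 > 0:
        norm_sd = s_i / s0
    else:
        norm_sd = np.full(n, np.nan)
    if critical_value is None:
        crit = float(np.sqrt(stats.f.ppf(confidence, p - A, dof_pooled)))
    else:
        crit = float(critical_value)
    flags = norm_sd > crit
    return model.scores, DModXReport(
        residual_sd_per_sample=norm_sd, critical_value=crit, flags=flags)
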