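"""Mixture model for read k-mer histograms: error, heterozygous, homozygous.

The histogram of distinct k-mer counts by read multiplicity x is modeled as

    total(x) = error(x) + het(x) + hom(x)
    error(x) = W * x**(-a)                      (low-multiplicity error tail)
    het(x)   = 2*h*G * NB(x; mean=lambda,   size=sigma_het)
    hom(x)   = (1-h)*G * NB(x; mean=2*lambda, size=sigma_hom)

where lambda is the haploid k-mer coverage, G the number of haploid k-mer
loci, and h = 1 - (1-r)**k converts the per-base heterozygosity r to the
fraction of k-mer loci containing at least one heterozygous site. The
negative binomial is parameterized by mean and size (variance mu + mu^2/size)
so the component means stay pinned at lambda and 2*lambda. Repeat components
are intentionally omitted: the downstream intersection uses only the three
curves above.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import InputError, ModelDegenerateError
from .kmers import KmerHistogram


@dataclass
class ModelFit:
    """Fitted mixture parameters plus fit diagnostics."""

    k: int
    lambda_hap: float
    r: float
    g_loci: float
    sigma_het: float
    sigma_hom: float
    err_weight: float
    err_exponent: float
    fit_range: tuple[int, int]
    converged: bool
    residual: float
    metadata: dict = field(default_factory=dict)

    @property
    def h(self) -> float:
        """Fraction of k-mer loci overlapping at least one heterozygous site."""
        return 1.0 - (1.0 - self.r) ** self.k

    def validate(self) -> None:
        if self.lambda_hap <= 0 or self.g_loci <= 0:
            raise InputError("lambda and G must be positive")
        if self.sigma_het <= 0 or self.sigma_hom <= 0:
            raise InputError("negative-binomial size parameters must be positive")
        if not 0.0 <= self.r < 1.0:
            raise InputError("r must lie in [0, 1)")
        if self.err_weight < 0 or self.err_exponent <= 1.0:
            raise InputError("error term requires W >= 0 and a > 1")


@dataclass
class ComponentCurves:
    """Expected distinct-k-mer counts of each model component on an x grid."""

    x: np.ndarray
    error: np.ndarray
    het: np.ndarray
    hom: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.error + self.het + self.hom

    def component(self, name: str) -> np.ndarray:
        return {"error": self.error, "het": self.het, "hom": self.hom}[name]


def nb_pmf(x: np.ndarray, mean: float, size: float) -> np.ndarray:
    """Negative binomial pmf with mean/size parameterization."""
    p = size / (size + mean)
    return stats.nbinom.pmf(x, size, p)


def model_expected_counts(fit: ModelFit, x_grid: np.ndarray | None = None) -> ComponentCurves:
    """Evaluate the three component curves on an integer x grid."""
    fit.validate()
    if x_grid is None:
        x_grid = np.arange(fit.fit_range[0], fit.fit_range[1] + 1)
    x = np.asarray(x_grid, dtype=np.int64)
    h = fit.h
    err = fit.err_weight * np.power(x.astype(float), -fit.err_exponent)
    het = 2.0 * h * fit.g_loci * nb_pmf(x, fit.lambda_hap, fit.sigma_het)
    hom = (1.0 - h) * fit.g_loci * nb_pmf(x, 2.0 * fit.lambda_hap, fit.sigma_hom)
    return ComponentCurves(x=x, error=err, het=het, hom=hom)


def find_trough(dense: np.ndarray, smooth: int = 3) -> int | None:
    """First local minimum of the histogram (multiplicity, 1-based).

    The histogram is lightly smoothed with a centered moving average before
    scanning so that single-bin sampling noise does not produce a spurious
    trough in the error tail.
    """
    if dense.size < 3:
        return None
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        y = np.convolve(dense.astype(float), kernel, mode="same")
    else:
        y = dense.astype(float)
    # a genuine trough separates the error tail from a genomic peak, so the
    # curve must rise substantially after it; this rejects plateaus and
    # count-level noise in the far right tail
    right_max = np.maximum.accumulate(y[::-1])[::-1]
    for i in range(1, y.size - 1):
        if y[i - 1] > y[i] <= y[i + 1] and right_max[i + 1] > max(2.0 * y[i], y[i] + 2.0):
            return i + 1
    return None


def _model_total(params: np.ndarray, x: np.ndarray, k: int) -> np.ndarray:
    lam, r, g, s_het, s_hom, w, a = params
    h = 1.0 - (1.0 - r) ** k
    err = w * np.power(x.astype(float), -a)
    het = 2.0 * h * g * nb_pmf(x, lam, s_het)
    hom = (1.0 - h) * g * nb_pmf(x, 2.0 * lam, s_hom)
    return err + het + hom


def fit_spectrum(hist: KmerHistogram, k: int | None = None,
                 init_overrides: dict | None = None) -> ModelFit:
    """Fit the mixture model to a read k-mer histogram by weighted least squares.

    Minimizes sum_x w(x) * (hist[x] - total(x))^2 with w(x) = 1/(hist[x]+1)
    over x in [1, ceil(8*lambda0)]. Two starts are tried for the haploid
    coverage (the post-trough histogram peak, and half of it, covering the
    cases where the global peak is the homozygous or the heterozygous
    component); the start with the smaller residual wins, ties broken by the
    smaller fitted lambda. The fit is deterministic given the histogram.
    """
    if k is None:
        k = hist.k
    elif k != hist.k:
        raise InputError(f"k mismatch: histogram k={hist.k}, requested {k}")
    if hist.total_distinct == 0:
        raise ModelDegenerateError("empty histogram")
    if sum(1 for _, n in hist.items() if n > 0) < 2:
        raise ModelDegenerateError("histogram has a single nonzero bin")

    x_top = hist.max_multiplicity
    dense_full = hist.dense(x_top)
    trough = find_trough(dense_full)
    trough_x = trough if trough is not None else 1
    post = dense_full[trough_x - 1:]
    peak = trough_x + int(np.argmax(post))
    lam_candidates = [float(peak), max(float(peak) / 2.0, 2.0)]

    overrides = dict(init_overrides or {})
    if "lambda_hap" in overrides:
        lam_candidates = [float(overrides["lambda_hap"])]

    g0 = float(dense_full[trough_x - 1:].sum())
    g0 = max(g0, 1.0)
    r0 = overrides.get("r", 0.005)
    w0 = max(float(dense_full[0]), 1.0)
    a0 = 3.0

    best: tuple[float, float, optimize.OptimizeResult, tuple[int, int]] | None = None
    for lam0 in lam_candidates:
        x_max = int(math.ceil(8.0 * lam0))
        x_max = min(max(x_max, trough_x + 3), x_top)
        x = np.arange(1, x_max + 1)
        y = dense_full[:x_max].astype(float)
        wts = np.sqrt(1.0 / (y + 1.0))

        p0 = np.array([lam0, r0, overrides.get("g_loci", g0),
                       overrides.get("sigma_het", 15.0),
                       overrides.get("sigma_hom", 15.0),
                       overrides.get("err_weight", w0),
                       overrides.get("err_exponent", a0)])
        lo = np.array([1.0, 0.0, 1.0, 0.5, 0.5, 0.0, 1.01])
        hi = np.array([float(x_max), 0.3, 1e12, 1e4, 1e4, 1e12, 8.0])
        p0 = np.clip(p0, lo, hi)

        def resid(p: np.ndarray) -> np.ndarray:
            return wts * (y - _model_total(p, x, k))

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sol = optimize.least_squares(
                resid, p0, bounds=(lo, hi), method="trf",
                x_scale=np.array([lam0, 0.01, g0, 10.0, 10.0, w0, 1.0]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=4000,
            )
        sse = float(np.sum(sol.fun ** 2))
        key = (sse, float(sol.x[0]))
        if best is None or key < (best[0], best[1]):
            best = (sse, float(sol.x[0]), sol, (1, x_max))

    assert best is not None
    sse, _, sol, fit_range = best
    lam, r, g, s_het, s_hom, w, a = (float(v) for v in sol.x)
    fit = ModelFit(
        k=k, lambda_hap=lam, r=r, g_loci=g, sigma_het=s_het, sigma_hom=s_hom,
        err_weight=w, err_exponent=a, fit_range=fit_range,
        converged=bool(sol.success), residual=sse,
        metadata={"trough": trough, "peak": peak, "optimizer_status": int(sol.status)},
    )
    return fit


def estimate_heterozygosity(fit: ModelFit) -> float:
    """Per-base heterozygosity as a percentage (100 * r)."""
    if not fit.converged:
        warnings.warn("heterozygosity estimated from an unconverged fit", stacklevel=2)
        fit.metadata.setdefault("warnings", []).append("unconverged fit")
    return 100.0 * fit.r


@dataclass
class GenomeSizeEstimate:
    bases: float
    fitted_g: float
    trough_used: int
    trough_found: bool


def estimate_genome_size(fit: ModelFit, hist: KmerHistogram) -> GenomeSizeEstimate:
    """Haploid genome size from the genomic part of the histogram.

    Returns sum_{x >= trough} x * hist[x] / (2 * lambda), where the trough is
    the first local minimum of the histogram (separating the error tail from
    genomic k-mers); with no detectable trough the sum starts at the fit
    range minimum and that fallback is recorded.
    """
    if not fit.converged:
        warnings.warn("genome size estimated from an unconverged fit", stacklevel=2)
    dense = hist.dense()
    trough = find_trough(dense)
    found = trough is not None
    start = trough if found else fit.fit_range[0]
    x = np.arange(1, dense.size + 1)
    mass = float(np.sum(x[start - 1:] * dense[start - 1:]))
    return GenomeSizeEstimate(
        bases=mass / (2.0 * fit.lambda_hap),
        fitted_g=fit.g_loci,
        trough_used=start,
        trough_found=found,
    )
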