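"""Quantitative assay statistics as scikit-learn style estimators.

Four fitters cover the quantitative experiments around the structural
work, each with ``fit`` / fitted ``_``-suffixed attributes and
``get_params``/``set_params`` so they compose with sklearn tooling:

* ``MichaelisMentenEstimator`` — MT-stimulated ATPase, v = kcat*S/(Km+S);
* ``GaussianMixture1D`` — 1-2 component velocity/intensity mixtures with
  BIC model selection (EM on raw samples, not histogram bins);
* ``CensoredExponentialFitter`` — right-censored exponential run lengths
  (closed-form MLE: mean = total observed length / number of uncensored
  runs, half-length = mean * ln 2);
* ``OverlapForceRegressor`` — plateau force per micron of MT overlap,
  with a pair-resampling bootstrap CI.

Module-level ``fit_*`` functions are thin wrappers returning fitted
estimators. ``roi_intensity_ratio`` computes the background-subtracted
spindle:cytoplasm localization metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

__all__ = [
    "MichaelisMentenEstimator",
    "GaussianMixture1D",
    "CensoredExponentialFitter",
    "OverlapForceRegressor",
    "fit_michaelis_menten",
    "fit_gaussian_mixture",
    "fit_runlength",
    "fit_force_per_overlap",
    "RoiRatioResult",
    "roi_intensity_ratio",
]


def _mm(s, kcat, km):
    return kcat * s / (km + s)


class MichaelisMentenEstimator(BaseEstimator):
    """Nonlinear least squares Michaelis-Menten fit.

    Initialized from the Hanes-Woolf linearization (S/v vs S), then
    refined with Levenberg-Marquardt; standard errors come from the
    local curvature (covariance of the converged fit).
    """

    def __init__(self, max_nfev: int = 10000):
        self.max_nfev = max_nfev

    def fit(self, conc_nM, rate_per_s):
        s = np.asarray(conc_nM, dtype=float)
        v = np.asarray(rate_per_s, dtype=float)
        if s.size < 3:
            raise ValueError("need at least 3 concentration points")
        if np.all(v == 0):
            raise ValueError("all rates are zero")
        order = np.argsort(s)
        s, v = s[order], v[order]
        # saturated-only data cannot constrain Km
        if v.std() < 1e-9 * max(abs(v.mean()), 1e-30):
            self.kcat_ = float(v.mean())
            self.km_ = np.nan
            self.kcat_se_ = float(v.std() / np.sqrt(v.size))
            self.km_se_ = np.nan
            self.converged_ = False
            self.km_identifiable_ = False
            self.residual_rms_ = 0.0
            return self
        pos = v > 0
        a, b = np.polyfit(s[pos], s[pos] / v[pos], 1)  # S/v = S/kcat + Km/kcat
        kcat0 = 1.0 / a if a > 0 else v.max()
        km0 = b * kcat0 if b * kcat0 > 0 else np.median(s)
        try:
            popt, pcov = curve_fit(
                _mm, s, v, p0=[kcat0, km0], maxfev=self.max_nfev,
                bounds=([0.0, 0.0], [np.inf, np.inf]),
            )
            self.converged_ = True
        except RuntimeError:
            popt, pcov = np.array([kcat0, km0]), np.full((2, 2), np.nan)
            self.converged_ = False
        self.kcat_, self.km_ = float(popt[0]), float(popt[1])
        ses = np.sqrt(np.diag(pcov))
        self.kcat_se_, self.km_se_ = float(ses[0]), float(ses[1])
        self.km_identifiable_ = True
        self.residual_rms_ = float(np.sqrt(np.mean((v - _mm(s, *popt)) ** 2)))
        return self

    def predict(self, conc_nM):
        return _mm(np.asarray(conc_nM, dtype=float), self.kcat_, self.km_)


class GaussianMixture1D(BaseEstimator):
    """1D Gaussian mixture by EM on raw samples, k in {1, 2} (or BIC-chosen).

    Components are reported sorted by mean. A variance floor guards the
    degenerate collapse of one component onto a single point; hitting the
    floor sets ``degenerate_``. With ``n_components=None`` both k=1 and
    k=2 are fit and the lower BIC wins.
    """

    def __init__(
        self,
        n_components: int | None = None,
        max_iter: int = 500,
        tol: float = 1e-10,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _em(self, x: np.ndarray, k: int):
        n = x.size
        sd_all = x.std()
        floor = max(1e-6 * max(sd_all, 1e-12), 1e-12)
        if k == 1:
            mu = np.array([x.mean()])
            sd = np.array([max(x.std(), floor)])
            w = np.array([1.0])
            ll = float(np.sum(_log_normal(x, mu[0], sd[0])))
            return mu, sd, w, ll, [ll], False
        # deterministic quantile init (order-invariant)
        qs = np.quantile(x, np.linspace(0.15, 0.85, k))
        mu = qs.astype(float)
        sd = np.full(k, max(sd_all / k, floor))
        w = np.full(k, 1.0 / k)
        ll_old = -np.inf
        trace = []
        degenerate = False
        for _ in range(self.max_iter):
            logp = np.stack([np.log(w[j]) + _log_normal(x, mu[j], sd[j]) for j in range(k)])
            m = logp.max(axis=0)
            lse = m + np.log(np.exp(logp - m).sum(axis=0))
            ll = float(lse.sum())
            trace.append(ll)
            r = np.exp(logp - lse)  # responsibilities (k, n)
            nk = r.sum(axis=1)
            nk = np.maximum(nk, 1e-12)
            w = nk / n
            mu = (r * x).sum(axis=1) / nk
            var = (r * (x - mu[:, None]) ** 2).sum(axis=1) / nk
            sd_new = np.sqrt(np.maximum(var, floor**2))
            if np.any(var < floor**2):
                degenerate = True
            sd = sd_new
            if ll - ll_old < self.tol and np.isfinite(ll_old):
                break
            ll_old = ll
        return mu, sd, w, trace[-1], trace, degenerate

    def fit(self, samples, y=None):
        x = np.asarray(samples, dtype=float)
        ks = [self.n_components] if self.n_components is not None else [1, 2]
        for k in ks:
            if x.size < 10 * k:
                raise ValueError(f"need at least {10 * k} samples for k={k}")
        fits = {}
        for k in ks:
            mu, sd, w, ll, trace, degen = self._em(x, k)
            p = 3 * k - 1
            bic = -2.0 * ll + p * np.log(x.size)
            fits[k] = (mu, sd, w, ll, trace, degen, bic)
        best_k = min(fits, key=lambda k: fits[k][6])
        mu, sd, w, ll, trace, degen, bic = fits[best_k]
        order = np.argsort(mu)
        self.means_ = mu[order]
        self.sds_ = sd[order]
        self.weights_ = w[order]
        self.log_likelihood_ = ll
        self.ll_trace_ = list(trace)
        self.degenerate_ = bool(degen)
        self.bic_ = {k: fits[k][6] for k in ks}
        self.k_ = int(best_k)
        # collapse indistinguishable components
        if best_k == 2 and abs(self.means_[1] - self.means_[0]) < 1e-8 * max(1.0, abs(self.means_[0])):
            self.k_ = 1
        return self


def _log_normal(x, mu, sd):
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


class CensoredExponentialFitter(BaseEstimator):
    """Right-censored exponential MLE for run lengths.

    The censored-likelihood maximizer is mean = (sum of all observed
    lengths, censored included) / (number of uncensored events); the
    half-length is mean * ln 2. The naive uncensored sample mean is
    biased low whenever runs hit the observation window.
    """

    def fit(self, lengths_um, censored=None):
        x = np.asarray(lengths_um, dtype=float)
        if censored is None:
            censored = np.zeros(x.size, dtype=bool)
        c = np.asarray(censored, dtype=bool)
        if np.any(x <= 0):
            raise ValueError("run lengths must be > 0")
        n_unc = int((~c).sum())
        if n_unc == 0:
            raise ValueError("all records censored; mean run length is unbounded")
        self.mean_um_ = float(x.sum() / n_unc)
        self.half_length_um_ = float(self.mean_um_ * np.log(2.0))
        self.n_observed_ = n_unc
        self.n_censored_ = int(c.sum())
        self.mean_se_um_ = float(self.mean_um_ / np.sqrt(n_unc))
        return self


class OverlapForceRegressor(BaseEstimator):
    """Least-squares plateau-force-per-overlap slope with bootstrap CI.

    By default the intercept is free (plateau-force plots show nonzero
    intercepts); ``through_origin=True`` constrains the line through 0.
    The CI is a seeded nonparametric percentile bootstrap over pairs.
    """

    def __init__(
        self,
        through_origin: bool = False,
        n_boot: int = 1000,
        ci: float = 0.95,
        random_state: int = 0,
    ):
        self.through_origin = through_origin
        self.n_boot = n_boot
        self.ci = ci
        self.random_state = random_state

    def _slope(self, x, y):
        if self.through_origin:
            return float(np.dot(x, y) / np.dot(x, x)), 0.0
        a, b = np.polyfit(x, y, 1)
        return float(a), float(b)

    def fit(self, overlap_um, force_pN):
        x = np.asarray(overlap_um, dtype=float)
        y = np.asarray(force_pN, dtype=float)
        if x.size < 2 or np.unique(x).size < 2:
            raise ValueError("need at least 2 distinct overlap lengths")
        self.slope_, self.intercept_ = self._slope(x, y)
        rng = np.random.default_rng(self.random_state)
        slopes = np.empty(self.n_boot)
        for b in range(self.n_boot):
            idx = rng.integers(0, x.size, size=x.size)
            xs = x[idx]
            if np.unique(xs).size < 2:
                slopes[b] = self.slope_
                continue
            slopes[b], _ = self._slope(xs, y[idx])
        alpha = (1.0 - self.ci) / 2.0
        self.ci_low_, self.ci_high_ = (
            float(np.quantile(slopes, alpha)),
            float(np.quantile(slopes, 1.0 - alpha)),
        )
        self.bootstrap_slopes_ = slopes
        return self

    def predict(self, overlap_um):
        return self.intercept_ + self.slope_ * np.asarray(overlap_um, dtype=float)


@dataclass
class RoiRatioResult:
    ratio: float
    spindle_mean: float
    cyto_mean: float
    bg_mean: float
    undefined: bool = False


def roi_intensity_ratio(image, spindle_mask, cell_mask, background_rois) -> RoiRatioResult:
    """Background-subtracted spindle:cytoplasm mean-intensity ratio.

    Cytoplasm is the cell mask minus the spindle mask; the averaged
    background-ROI intensity is subtracted from both compartments. A
    cytoplasm signal at or below background is flagged undefined.
    """
    img = np.asarray(image, dtype=float)
    sp = np.asarray(spindle_mask, dtype=bool)
    cell = np.asarray(cell_mask, dtype=bool)
    bg = np.asarray(background_rois, dtype=bool)
    if not sp.any() or not cell.any() or not bg.any():
        raise ValueError("empty mask")
    if np.any(sp & ~cell):
        raise ValueError("spindle mask must lie inside the cell mask")
    if np.any(bg & cell):
        raise ValueError("background ROIs must be disjoint from the cell")
    cyto = cell & ~sp
    if not cyto.any():
        raise ValueError("cytoplasm region is empty")
    ms, mc, mb = img[sp].mean(), img[cyto].mean(), img[bg].mean()
    if mc <= mb:
        return RoiRatioResult(np.nan, ms, mc, mb, undefined=True)
    return RoiRatioResult(float((ms - mb) / (mc - mb)), ms, mc, mb)


# ---------------------------------------------------------------- wrappers


def fit_michaelis_menten(conc_nM, rate_per_s) -> MichaelisMentenEstimator:
    return MichaelisMentenEstimator().fit(conc_nM, rate_per_s)


def fit_gaussian_mixture(samples, k: int | None = None, seed: int = 0) -> GaussianMixture1D:
    return GaussianMixture1D(n_components=k, random_state=seed).fit(samples)


def fit_runlength(lengths_um, censored_flags=None, censor_limit_um=None) -> CensoredExponentialFitter:
    est = CensoredExponentialFitter().fit(lengths_um, censored_flags)
    est.censor_limit_um_ = censor_limit_um
    return est


def fit_force_per_overlap(
    overlap_um, force_pN, through_origin: bool = False, seed: int = 0, n_boot: int = 1000
) -> OverlapForceRegressor:
    return OverlapForceRegressor(
        through_origin=through_origin, random_state=seed, n_boot=n_boot
    ).fit(overlap_um, force_pN)
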