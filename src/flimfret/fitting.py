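"""Per-pixel TCSPC decay estimation.

Mono- and bi-exponential fits against the IRF-convolved periodic decay model,
with the conventions of commercial FLIM fitting software: a photon-count
threshold below which a pixel is masked rather than fitted, a spatial binning
factor ``b`` that aggregates the (2b+1) x (2b+1) neighborhood decay before
fitting, and a Pearson reduced chi-square goodness of fit.

The default objective is the Poisson maximum likelihood (C-statistic), which
is unbiased at the low counts typical of TCSPC; Neyman-weighted least squares
is available for cross-checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, optimize

from .io import TcspcCube
from .models import AcquisitionConfig, BiDecayParams, Irf

__all__ = [
    "FitConfig",
    "DecayFit",
    "BiDecayFit",
    "LifetimeMap",
    "BiFitImage",
    "fit_mono",
    "fit_bi",
    "fit_image",
    "estimate_tau0_donor_only",
]

logger = logging.getLogger(__name__)

_TAU_BOUNDS = (0.15, 10.0)  # ns; generous bracket for nanosecond-scale dyes
_COLLAPSE_RATIO = 0.95


@dataclass(frozen=True)
class FitConfig:
    """Fitting options.

    ``threshold_counts`` applies to the binned decay (total counts by default,
    peak-bin counts with ``threshold_on="peak"``).  ``binning_factor`` b
    aggregates the (2b+1) x (2b+1) neighborhood; b=1 means 3x3.
    ``background`` is a known constant counts-per-bin offset included in the
    model (not fitted).
    """

    model: str = "mono"
    threshold_counts: float = 30.0
    threshold_on: str = "total"
    binning_factor: int = 1
    objective: str = "poisson_mle"
    fix_tau0: Optional[float] = None
    background: float = 0.0
    max_iterations: int = 2000
    convergence_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.model not in ("mono", "bi"):
            raise ValueError("model must be 'mono' or 'bi'")
        if self.threshold_counts < 0:
            raise ValueError("threshold_counts must be >= 0")
        if self.threshold_on not in ("total", "peak"):
            raise ValueError("threshold_on must be 'total' or 'peak'")
        if self.binning_factor < 0:
            raise ValueError("binning_factor must be >= 0")
        if self.objective not in ("poisson_mle", "weighted_least_squares"):
            raise ValueError(
                "objective must be 'poisson_mle' or 'weighted_least_squares'"
            )
        if self.fix_tau0 is not None and self.fix_tau0 <= 0:
            raise ValueError("fix_tau0 must be positive")
        if self.background < 0:
            raise ValueError("background must be >= 0")


@dataclass
class DecayFit:
    """Result of a single-pixel mono-exponential fit."""

    tau: float
    amplitude: float
    background: float
    chi2_reduced: float
    n_photons: int
    converged: bool
    fitted: bool = True

    @classmethod
    def masked(cls, n_photons: int = 0) -> "DecayFit":
        return cls(
            tau=np.nan,
            amplitude=np.nan,
            background=np.nan,
            chi2_reduced=np.nan,
            n_photons=n_photons,
            converged=False,
            fitted=False,
        )


@dataclass
class BiDecayFit:
    """Result of a single-pixel two-component fit.

    ``delta_nll`` is the objective improvement of the two-component model
    over the best single-exponential fit; small values mean the second
    component is not supported by the data.
    """

    params: Optional[BiDecayParams]
    chi2_reduced: float
    n_photons: int
    converged: bool
    collapsed: bool = False
    delta_nll: float = np.nan
    fitted: bool = True

    @classmethod
    def masked(cls, n_photons: int = 0) -> "BiDecayFit":
        return cls(
            params=None,
            chi2_reduced=np.nan,
            n_photons=n_photons,
            converged=False,
            collapsed=False,
            fitted=False,
        )


@dataclass
class LifetimeMap:
    """Per-pixel lifetime image: tau is defined exactly where mask is true."""

    tau_map: np.ndarray
    mask: np.ndarray
    chi2_map: np.ndarray
    intensity_map: np.ndarray

    def __post_init__(self) -> None:
        defined = np.isfinite(self.tau_map)
        if not np.array_equal(defined, self.mask):
            raise ValueError("tau_map must be finite exactly on masked-in pixels")


@dataclass
class BiFitImage:
    """Per-pixel two-component fit maps (NaN where masked)."""

    a1_map: np.ndarray
    a2_map: np.ndarray
    tau_fret_map: np.ndarray
    tau0_map: np.ndarray
    chi2_map: np.ndarray
    mask: np.ndarray
    collapsed: np.ndarray
    intensity_map: np.ndarray
    delta_nll_map: Optional[np.ndarray] = None

    def a1_fraction_map(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.a1_map / (self.a1_map + self.a2_map)

    def amplitude_weighted_tau_map(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return (
                self.a1_map * self.tau_fret_map + self.a2_map * self.tau0_map
            ) / (self.a1_map + self.a2_map)


class _Forward:
    """Cached forward model: normalized IRF-convolved periodic decay shapes."""

    def __init__(self, irf: Irf, acq: AcquisitionConfig) -> None:
        if abs(irf.bin_width - acq.bin_width) > 1e-9 * max(
            irf.bin_width, acq.bin_width
        ):
            raise ValueError("IRF bin width does not match acquisition bin width")
        self.acq = acq
        self.m = acq.n_period_bins
        h = np.zeros(self.m)
        h[: irf.weights.size] = irf.weights
        self._H = np.fft.rfft(h)
        self._k = np.arange(self.m)

    def shape(self, tau: float) -> np.ndarray:
        """Expected decay shape for lifetime ``tau``, normalized to sum 1."""
        e = np.exp(-self.acq.bin_width / tau)
        d = (1.0 - e) * e**self._k
        d /= d.sum()
        s = np.fft.irfft(np.fft.rfft(d) * self._H, self.m)[: self.acq.n_bins]
        np.maximum(s, 1e-300, out=s)
        return s / s.sum()


def _profile_scale(y: np.ndarray, s: np.ndarray, bg: float, n_total: float) -> float:
    """Optimal model scale for shape ``s`` and fixed background (Poisson MLE)."""
    if bg == 0.0:
        return n_total
    scale = max(n_total - bg * y.size, 1e-6)
    for _ in range(4):  # Newton on the profile-likelihood score
        mu = scale * s + bg
        g = float(np.sum(y * s / mu)) - 1.0
        hmat = float(np.sum(y * s**2 / mu**2))
        if hmat <= 0:
            break
        scale = max(scale + g / hmat, 1e-6)
    return scale


def _objective(
    y: np.ndarray,
    s: np.ndarray,
    bg: float,
    n_total: float,
    kind: str,
    wls_weights: Optional[np.ndarray] = None,
):
    """Objective value and fitted scale for a given shape.

    For weighted least squares, ``wls_weights`` supplies the (fixed) inverse
    variances; the default is the Neyman choice ``1/max(y, 1)``.
    """
    if kind == "poisson_mle":
        scale = _profile_scale(y, s, bg, n_total)
        mu = scale * s + bg
        val = float(np.sum(mu) - np.sum(y * np.log(mu)))
        return val, scale
    wts = wls_weights if wls_weights is not None else 1.0 / np.maximum(y, 1.0)
    num = float(np.sum(wts * (y - bg) * s))
    den = float(np.sum(wts * s**2))
    scale = max(num / den, 1e-6) if den > 0 else n_total
    mu = scale * s + bg
    val = float(np.sum(wts * (y - mu) ** 2))
    return val, scale


def _pearson_chi2(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Reduced Pearson chi-square over bins with expected counts >= 1."""
    use = mu >= 1.0
    n_used = int(use.sum())
    dof = max(n_used - n_params, 1)
    return float(np.sum((y[use] - mu[use]) ** 2 / mu[use]) / dof)


def _totals(decay: np.ndarray) -> float:
    return float(np.asarray(decay).sum())


def fit_mono(
    decay: np.ndarray,
    irf: Irf,
    acq: AcquisitionConfig,
    cfg: FitConfig | None = None,
    _fw: Optional[_Forward] = None,
) -> DecayFit:
    """Fit a single-exponential decay to one (possibly binned) pixel decay.

    Pixels whose counts fall below ``cfg.threshold_counts`` are returned as
    masked, unfitted results rather than raising.
    """
    cfg = cfg or FitConfig()
    y = np.asarray(decay, dtype=float)
    if y.size != acq.n_bins:
        raise ValueError(f"decay length {y.size} != acq.n_bins {acq.n_bins}")
    n_total = _totals(y)
    crit = n_total if cfg.threshold_on == "total" else float(y.max(initial=0))
    if crit < cfg.threshold_counts or n_total <= 0:
        return DecayFit.masked(n_photons=int(round(n_total)))

    fw = _fw or _Forward(irf, acq)
    bg = cfg.background
    wls_w: Optional[np.ndarray] = None

    def nll(log_tau: float) -> float:
        val, _ = _objective(
            y, fw.shape(float(np.exp(log_tau))), bg, n_total, cfg.objective,
            wls_weights=wls_w,
        )
        return val

    def minimize() -> optimize.OptimizeResult:
        return optimize.minimize_scalar(
            nll,
            bounds=(np.log(_TAU_BOUNDS[0]), np.log(_TAU_BOUNDS[1])),
            method="bounded",
            options={"xatol": 1e-7, "maxiter": cfg.max_iterations},
        )

    res = minimize()
    if cfg.objective == "weighted_least_squares":
        # one reweighting pass (IRLS): variances from the fitted model curb
        # the low-count bias of the raw Neyman weights
        tau1 = float(np.exp(res.x))
        s1 = fw.shape(tau1)
        _, scale1 = _objective(y, s1, bg, n_total, cfg.objective)
        wls_w = 1.0 / np.maximum(scale1 * s1 + bg, 1.0)
        res = minimize()
    tau = float(np.exp(res.x))
    s = fw.shape(tau)
    _, scale = _objective(y, s, bg, n_total, cfg.objective, wls_weights=wls_w)
    mu = scale * s + bg
    chi2 = _pearson_chi2(y, mu, n_params=3)
    at_bound = (
        tau <= _TAU_BOUNDS[0] * 1.001 or tau >= _TAU_BOUNDS[1] * 0.999
    )
    return DecayFit(
        tau=tau,
        amplitude=scale / tau,  # t=0 intensity equivalent (counts per ns)
        background=bg,
        chi2_reduced=chi2,
        n_photons=int(round(n_total)),
        converged=bool(res.success and not at_bound),
    )


def _bi_shape(fw: _Forward, tau_f: float, tau0: float, q: float) -> np.ndarray:
    return q * fw.shape(tau_f) + (1.0 - q) * fw.shape(tau0)


def _sigmoid(u: float) -> float:
    return 1.0 / (1.0 + np.exp(-u))


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def fit_bi(
    decay: np.ndarray,
    irf: Irf,
    acq: AcquisitionConfig,
    cfg: FitConfig | None = None,
    _fw: Optional[_Forward] = None,
) -> BiDecayFit:
    """Fit a two-component decay; ``tau_fret <= tau0`` is enforced by construction.

    The fast lifetime is parameterized as a fraction of the slow one and the
    mixture by the photon fraction of the fast component, both through
    sigmoids, so the optimizer works on an unconstrained domain.  With
    ``cfg.fix_tau0`` set the slow lifetime is held at the donor-only
    reference.  Near-degenerate solutions (tau_fret/tau0 > 0.95) are flagged
    as collapsed.
    """
    cfg = cfg or FitConfig(model="bi")
    y = np.asarray(decay, dtype=float)
    if y.size != acq.n_bins:
        raise ValueError(f"decay length {y.size} != acq.n_bins {acq.n_bins}")
    n_total = _totals(y)
    crit = n_total if cfg.threshold_on == "total" else float(y.max(initial=0))
    if crit < cfg.threshold_counts or n_total <= 0:
        return BiDecayFit.masked(n_photons=int(round(n_total)))

    fw = _fw or _Forward(irf, acq)
    bg = cfg.background
    fixed_tau0 = cfg.fix_tau0

    mono = fit_mono(y, irf, acq, FitConfig(threshold_counts=0, background=bg,
                                           objective=cfg.objective), _fw=fw)
    tau_m = mono.tau if mono.converged else 2.5
    mono_val, _ = _objective(y, fw.shape(tau_m), bg, n_total, cfg.objective)

    def unpack(x: np.ndarray) -> tuple[float, float, float]:
        if fixed_tau0 is not None:
            tau0 = fixed_tau0
            r = _sigmoid(x[0])
            q = _sigmoid(x[1])
        else:
            tau0 = float(np.clip(np.exp(x[0]), *_TAU_BOUNDS))
            r = _sigmoid(x[1])
            q = _sigmoid(x[2])
        tau_f = max(r * tau0, 1e-3)
        return tau_f, tau0, q

    wls_w: Optional[np.ndarray] = None

    def objective(x: np.ndarray) -> float:
        tau_f, tau0, q = unpack(x)
        val, _ = _objective(y, _bi_shape(fw, tau_f, tau0, q), bg, n_total,
                            cfg.objective, wls_weights=wls_w)
        return val

    if fixed_tau0 is not None:
        x0 = np.array([_logit(min(tau_m / fixed_tau0, 0.9)), _logit(0.5)])
    else:
        x0 = np.array([np.log(min(tau_m * 1.3, _TAU_BOUNDS[1] * 0.9)),
                       _logit(0.6), _logit(0.5)])
    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": cfg.convergence_tol,
            "fatol": cfg.convergence_tol,
            "maxiter": cfg.max_iterations,
            "maxfev": cfg.max_iterations,
        },
    )
    if cfg.objective == "weighted_least_squares":
        # IRLS pass as in fit_mono: reweight from the fitted model
        tau_f, tau0, q = unpack(res.x)
        s1 = _bi_shape(fw, tau_f, tau0, q)
        _, scale1 = _objective(y, s1, bg, n_total, cfg.objective)
        wls_w = 1.0 / np.maximum(scale1 * s1 + bg, 1.0)
        res = optimize.minimize(
            objective, res.x, method="Nelder-Mead",
            options={"xatol": cfg.convergence_tol, "fatol": cfg.convergence_tol,
                     "maxiter": cfg.max_iterations, "maxfev": cfg.max_iterations},
        )
    tau_f, tau0, q = unpack(res.x)
    s = _bi_shape(fw, tau_f, tau0, q)
    _, scale = _objective(y, s, bg, n_total, cfg.objective, wls_weights=wls_w)
    mu = scale * s + bg
    n_params = 4 if fixed_tau0 is not None else 5
    chi2 = _pearson_chi2(y, mu, n_params=n_params)
    # back out t=0 amplitudes from the photon split: N_i = a_i * tau_i
    a1 = q * scale / tau_f
    a2 = (1.0 - q) * scale / tau0
    params = BiDecayParams(
        a1=a1, a2=a2, tau_fret=min(tau_f, tau0), tau0=tau0, background=bg
    )
    bi_val, _ = _objective(y, s, bg, n_total, cfg.objective, wls_weights=wls_w)
    return BiDecayFit(
        params=params,
        chi2_reduced=chi2,
        n_photons=int(round(n_total)),
        converged=bool(res.success),
        collapsed=bool(tau_f / tau0 > _COLLAPSE_RATIO),
        delta_nll=max(mono_val - bi_val, 0.0),
    )


def _binned_counts(counts: np.ndarray, b: int) -> np.ndarray:
    """Neighborhood-summed cube: each pixel gets its (2b+1)^2 aggregate decay."""
    if b == 0:
        return counts.astype(np.float64)
    k = 2 * b + 1
    out = ndimage.uniform_filter(
        counts.astype(np.float64), size=(1, k, k), mode="constant"
    )
    return np.rint(out * (k * k))


def fit_image(
    cube: TcspcCube,
    irf: Irf,
    cfg: FitConfig | None = None,
):
    """Fit every above-threshold pixel of a cube.

    Returns a :class:`LifetimeMap` for ``cfg.model == "mono"`` or a
    :class:`BiFitImage` for ``"bi"``.  The threshold is applied to the binned
    (neighborhood-aggregated) decay; ``intensity_map`` always reports the raw
    per-pixel photon totals.
    """
    cfg = cfg or FitConfig()
    acq = cube.acq
    fw = _Forward(irf, acq)
    binned = _binned_counts(cube.counts, cfg.binning_factor)
    totals = binned.sum(axis=0)
    crit = totals if cfg.threshold_on == "total" else binned.max(axis=0)
    candidates = crit >= cfg.threshold_counts
    intensity = cube.pixel_totals().astype(np.float64)

    h, w = candidates.shape
    shape2d = (h, w)
    if cfg.model == "mono":
        tau_map = np.full(shape2d, np.nan)
        chi2_map = np.full(shape2d, np.nan)
        mask = np.zeros(shape2d, dtype=bool)
        n_fitted = n_failed = 0
        for y, x in np.argwhere(candidates):
            fit = fit_mono(binned[:, y, x], irf, acq, cfg, _fw=fw)
            if fit.fitted and fit.converged:
                tau_map[y, x] = fit.tau
                chi2_map[y, x] = fit.chi2_reduced
                mask[y, x] = True
                n_fitted += 1
            else:
                n_failed += 1
        if not mask.any():
            logger.warning("fit_image: no pixel above threshold/converged; "
                           "returning an all-masked map")
        logger.info(
            "fit_image(mono): %d fitted, %d masked, %d failed",
            n_fitted, int((~candidates).sum()), n_failed,
        )
        return LifetimeMap(
            tau_map=tau_map, mask=mask, chi2_map=chi2_map, intensity_map=intensity
        )

    a1_map = np.full(shape2d, np.nan)
    a2_map = np.full(shape2d, np.nan)
    tauf_map = np.full(shape2d, np.nan)
    tau0_map = np.full(shape2d, np.nan)
    chi2_map = np.full(shape2d, np.nan)
    mask = np.zeros(shape2d, dtype=bool)
    collapsed = np.zeros(shape2d, dtype=bool)
    delta_nll = np.full(shape2d, np.nan)
    n_fitted = n_failed = 0
    for y, x in np.argwhere(candidates):
        fit = fit_bi(binned[:, y, x], irf, acq, cfg, _fw=fw)
        if fit.fitted and fit.converged and fit.params is not None:
            p = fit.params
            a1_map[y, x] = p.a1
            a2_map[y, x] = p.a2
            tauf_map[y, x] = p.tau_fret
            tau0_map[y, x] = p.tau0
            chi2_map[y, x] = fit.chi2_reduced
            collapsed[y, x] = fit.collapsed
            delta_nll[y, x] = fit.delta_nll
            mask[y, x] = True
            n_fitted += 1
        else:
            n_failed += 1
    if not mask.any():
        logger.warning("fit_image: no pixel above threshold/converged; "
                       "returning an all-masked result")
    logger.info(
        "fit_image(bi): %d fitted, %d masked, %d failed",
        n_fitted, int((~candidates).sum()), n_failed,
    )
    return BiFitImage(
        a1_map=a1_map,
        a2_map=a2_map,
        tau_fret_map=tauf_map,
        tau0_map=tau0_map,
        chi2_map=chi2_map,
        mask=mask,
        collapsed=collapsed,
        intensity_map=intensity,
        delta_nll_map=delta_nll,
    )


def estimate_tau0_donor_only(lifetime_map: LifetimeMap) -> float:
    """Intensity-weighted mean lifetime of a donor-only specimen.

    Used as the fixed slow-lifetime reference (``tau0``) for FRET analysis.
    """
    mask = lifetime_map.mask
    if not mask.any():
        raise ValueError("cannot estimate tau0 from an all-masked lifetime map")
    tau = lifetime_map.tau_map[mask]
    wts = lifetime_map.intensity_map[mask].astype(float)
    if wts.sum() <= 0:
        wts = np.ones_like(tau)
    return float(np.average(tau, weights=wts))
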