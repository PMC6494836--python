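"""Michaelis-Menten characterization of bifunctional DHPAAS variants.

The aldehyde-synthase activity of DHPAAS is assayed through its H2O2
co-product, giving substrate-velocity data that are fit to the irreversible
Michaelis-Menten law v = Vmax*S/(Km+S) by nonlinear least squares with
iterative outlier elimination.  Confidence intervals are profile-likelihood
based (the printed intervals of such fits are visibly asymmetric, which the
asymptotic normal approximation cannot produce).  The decarboxylase activity
is measured as an initial dopamine-production rate, and the two maximal
velocities define the bifunctional partition: the percent of flux through
the aldehyde branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


class FitError(RuntimeError):
    """Nonlinear fit failed; carries the last iterate when available."""

    def __init__(self, message: str, last: dict | None = None):
        super().__init__(message)
        self.last = last or {}


@dataclass
class RateDataset:
    """Substrate-velocity data for one enzyme variant.

    ``substrate`` in µM, ``rate`` in any velocity unit (e.g. nmol min^-1
    mg^-1).  ``enzyme_conc`` is the enzyme amount per rate-normalisation
    unit -- for specific activities in nmol min^-1 mg^-1 this is nmol enzyme
    per mg protein (1e6 / MW in Da) -- so that kcat = Vmax / enzyme_conc.
    """

    substrate: np.ndarray
    rate: np.ndarray
    enzyme_conc: float | None = None
    replicate_id: np.ndarray | None = None

    def __post_init__(self):
        self.substrate = np.asarray(self.substrate, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.substrate.shape != self.rate.shape:
            raise ValueError("substrate and rate must have equal length")
        if np.any(self.substrate < 0):
            raise ValueError("substrate concentrations must be >= 0")
        if len(np.unique(self.substrate)) < 4:
            raise ValueError("need >= 4 distinct substrate levels to fit")
        if self.replicate_id is None:
            self.replicate_id = np.zeros(len(self.rate), dtype=int)
        else:
            self.replicate_id = np.asarray(self.replicate_id)


@dataclass
class MMFitResult:
    km: float
    vmax: float
    km_ci: tuple[float, float]
    vmax_ci: tuple[float, float]
    kcat: float | None = None
    kcat_ci: tuple[float, float] | None = None
    outlier_flags: np.ndarray = field(default_factory=lambda: np.array([], bool))
    ssr: float = np.nan
    n_iterations: int = 0
    converged: bool = False
    unbounded_ci: bool = False


@dataclass
class PartitionResult:
    v_aas: float
    v_ddc: float
    pct_aas: float


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (presentation helper)."""
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"{x:.{sig}g}")


def initial_rate(times, product, window: tuple[float, float] | None = None) -> float:
    """Initial velocity as the least-squares slope of product vs. time.

    ``window`` restricts the regression to an early-time span (inclusive);
    the intercept is free, so a constant background offset does not bias the
    slope.
    """
    t = np.asarray(times, dtype=float)
    p = np.asarray(product, dtype=float)
    if t.shape != p.shape:
        raise ValueError("times and product must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, p = t[sel], p[sel]
    if len(t) < 2 or np.ptp(t) == 0:
        raise ValueError("need >= 2 points spanning a nonzero time window")
    slope, _ = np.polyfit(t, p, 1)
    return float(slope)


def _mm(S, vmax, km):
    return vmax * S / (km + S)


def _fit_once(S: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    """Single NLS fit; returns (vmax, km, ssr)."""
    vmax0 = max(float(np.max(v)), 1e-12)
    km0 = max(float(np.median(S)), 1e-9)
    try:
        popt, _ = optimize.curve_fit(
            _mm, S, v, p0=(vmax0, km0),
            bounds=((0.0, 1e-12), (np.inf, np.inf)), maxfev=10_000)
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}",
                       {"p0": (vmax0, km0)}) from exc
    vmax, km = float(popt[0]), float(popt[1])
    ssr = float(np.sum((v - _mm(S, vmax, km)) ** 2))
    return vmax, km, ssr


def _studentized_residuals(S, v, vmax, km):
    """Internally studentized residuals using the Jacobian-based hat matrix."""
    resid = v - _mm(S, vmax, km)
    n = len(v)
    J = np.column_stack([S / (km + S), -vmax * S / (km + S) ** 2])
    # hat diagonal from the linearized model; guard rank deficiency
    try:
        JtJ_inv = np.linalg.pinv(J.T @ J)
        h = np.einsum("ij,jk,ik->i", J, JtJ_inv, J)
    except np.linalg.LinAlgError:
        h = np.zeros(n)
    dof = max(n - 2, 1)
    s2 = np.sum(resid ** 2) / dof
    denom = np.sqrt(np.maximum(s2 * (1.0 - np.clip(h, 0, 0.999)), 1e-300))
    return resid / denom


def fit_mm(data: RateDataset, outlier_threshold: float = 3.0,
           max_outlier_frac: float = 0.2, ci_level: float = 0.95) -> MMFitResult:
    """Fit the MM law with iterative studentized-residual outlier elimination.

    At most one point is removed per refit (the largest |studentized
    residual| exceeding ``outlier_threshold``) and no more than
    ``max_outlier_frac`` of the data may be flagged in total.  Profile
    likelihood confidence intervals at ``ci_level`` are computed on the
    cleaned data.
    """
    S_all = data.substrate
    v_all = data.rate
    keep = np.ones(len(v_all), dtype=bool)
    max_remove = int(max_outlier_frac * len(v_all))

    vmax, km, ssr = _fit_once(S_all, v_all)
    n_iter = 1
    for _ in range(max_remove):
        r = _studentized_residuals(S_all[keep], v_all[keep], vmax, km)
        worst = np.argmax(np.abs(r))
        if np.abs(r[worst]) <= outlier_threshold:
            break
        keep_idx = np.flatnonzero(keep)
        keep[keep_idx[worst]] = False
        if keep.sum() < 4:
            raise FitError("outlier elimination left too few points",
                           {"flags": ~keep})
        vmax, km, ssr = _fit_once(S_all[keep], v_all[keep])
        n_iter += 1

    S, v = S_all[keep], v_all[keep]
    km_ci, vmax_ci, unbounded = _profile_intervals(S, v, vmax, km, ssr, ci_level)
    kcat = kcat_ci = None
    if data.enzyme_conc:
        kcat = vmax / data.enzyme_conc
        kcat_ci = (vmax_ci[0] / data.enzyme_conc, vmax_ci[1] / data.enzyme_conc)
    return MMFitResult(km=km, vmax=vmax, km_ci=km_ci, vmax_ci=vmax_ci,
                       kcat=kcat, kcat_ci=kcat_ci, outlier_flags=~keep,
                       ssr=ssr, n_iterations=n_iter, converged=True,
                       unbounded_ci=unbounded)


def _profile_ssr_km(S, v, km):
    """SSR profiled over Vmax at fixed Km (Vmax enters linearly)."""
    g = S / (km + S)
    denom = float(g @ g)
    vmax = float(g @ v) / denom if denom > 0 else 0.0
    vmax = max(vmax, 0.0)
    return float(np.sum((v - vmax * g) ** 2))


def _profile_ssr_vmax(S, v, vmax, km_hat):
    """SSR profiled over Km at fixed Vmax (1-D bounded minimisation)."""
    def obj(log_km):
        return float(np.sum((v - _mm(S, vmax, np.exp(log_km))) ** 2))
    lo, hi = np.log(km_hat) - 12, np.log(km_hat) + 12
    res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.fun)


def _profile_intervals(S, v, vmax, km, ssr_min, level):
    """Profile-likelihood intervals from the SSR F-test threshold.

    The bound solves SSR(theta) = SSR_min * (1 + F(1, n-p; level)/(n-p)).
    Search expands geometrically from the estimate; if the profile never
    crosses the threshold within a wide factor the interval is flagged
    unbounded instead of reporting a silent number.
    """
    n, p = len(v), 2
    dof = n - p
    if dof <= 0:
        return (np.nan, np.nan), (np.nan, np.nan), True
    fcrit = stats.f.ppf(level, 1, dof)
    thresh = ssr_min * (1.0 + fcrit / dof)
    if ssr_min <= 1e-14 * float(np.sum(v ** 2)):
        # numerically perfect fit: the profile is a spike, interval collapses
        return (km, km), (vmax, vmax), False

    unbounded = False

    def bound(profile, hat, direction):
        nonlocal unbounded
        f = lambda x: profile(x) - thresh
        if f(hat) >= 0:  # round-off: profiled SSR at the MLE is at threshold
            return hat
        step, x = 1.25, hat
        for _ in range(80):
            x = x * step if direction > 0 else x / step
            if f(x) > 0:
                lo, hi = (hat, x) if direction > 0 else (x, hat)
                return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-10))
        unbounded = True
        return math.inf if direction > 0 else 0.0

    km_prof = lambda x: _profile_ssr_km(S, v, x)
    vmax_prof = lambda x: _profile_ssr_vmax(S, v, x, km)
    km_ci = (bound(km_prof, km, -1), bound(km_prof, km, +1))
    vmax_ci = (bound(vmax_prof, vmax, -1), bound(vmax_prof, vmax, +1))
    return km_ci, vmax_ci, unbounded


def confidence_intervals(data: RateDataset, fit: MMFitResult,
                         level: float = 0.95):
    """Recompute profile-likelihood intervals for a converged fit."""
    if not fit.converged:
        raise FitError("confidence intervals require a converged fit")
    keep = ~fit.outlier_flags if fit.outlier_flags.size else slice(None)
    S, v = data.substrate[keep], data.rate[keep]
    km_ci, vmax_ci, unbounded = _profile_intervals(
        S, v, fit.vmax, fit.km, fit.ssr, level)
    return {"km": km_ci, "vmax": vmax_ci, "unbounded": unbounded}


def percent_aas(v_aas: float, v_ddc: float) -> float:
    """Percent of bifunctional flux through the aldehyde-synthase branch.

    Compares the H2O2-derived aldehyde-branch Vmax with the initial-rate
    dopamine (decarboxylase) Vmax; reported to two significant figures, the
    convention used for the printed partition percentages.
    """
    if v_aas < 0 or v_ddc < 0:
        raise ValueError("velocities must be >= 0")
    if v_aas == 0 and v_ddc == 0:
        raise ValueError("both velocities zero; partition undefined")
    return round_sig(100.0 * v_aas / (v_aas + v_ddc), 2)


def partition(v_aas: float, v_ddc: float) -> PartitionResult:
    return PartitionResult(v_aas=v_aas, v_ddc=v_ddc,
                           pct_aas=percent_aas(v_aas, v_ddc))
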