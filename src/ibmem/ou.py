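"""Reduced Ornstein--Uhlenbeck models of receptor-site membrane motion.

A single ghost-tethered membrane's receptor displacement is
well-approximated by a one-component OU process

    dZ = -(Z/tau) dt + sigma sqrt(2/tau) dW,

whose stationary law is N(0, sigma^2) and whose autocorrelation is
alpha(dt) = exp(-dt/tau).  The interface (two membranes coupled through
the thin fluid layer) needs two timescales: two independent hidden OU
components X, Y of common variance sigma^2 combine as

    Z = c X + sqrt(1 - c^2) Y,        alpha(dt) = c^2 e^{-dt/tau_slow}
                                               + (1 - c^2) e^{-dt/tau_fast},

so the slow process carries a fraction c^2 of the variance.  Reference
fitted values from the full fluid simulations: single membrane
sigma = 3.12 nm, tau = 1.05e-6 s; interface sigma = 4.6 nm,
tau_slow = 8.2e-5 s, tau_fast = 5.3e-7 s, c^2 = 0.48.

Simulation uses the exact discretization (stationary variance correct at
any step size).  Fitting utilities recover (sigma, tau) or
(c^2, tau_slow, tau_fast) from traces, with effective-sample-size-aware
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import Trace


@dataclass
class OUParams1:
    """One-component OU: relaxation time tau [s], stationary SD sigma [nm]."""

    tau: float = 1.05e-6
    sigma: float = 3.12

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.sigma <= 0:
            raise ValueError("tau and sigma must be positive")


@dataclass
class OUParams2:
    """Two-component OU: Z = c X + sqrt(1-c^2) Y, common component SD sigma.

    tau_slow > tau_fast [s]; c in [0, 1] (slow variance fraction = c^2);
    sigma [nm] is the stationary SD of Z (and of each hidden component).
    """

    tau_slow: float = 8.2e-5
    tau_fast: float = 5.3e-7
    sigma: float = 4.6
    c: float = np.sqrt(0.48)

    def __post_init__(self) -> None:
        if not (self.tau_slow > self.tau_fast > 0):
            raise ValueError("need tau_slow > tau_fast > 0")
        if not (0.0 <= self.c <= 1.0):
            raise ValueError("need 0 <= c <= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _exact_update_coeffs(tau: float, sigma: float, dt: float) -> tuple[float, float]:
    a = np.exp(-dt / tau)
    return a, sigma * np.sqrt(1.0 - a * a)


def _ar1(a: float, shocks: np.ndarray, z0: float) -> np.ndarray:
    """z_n = a z_{n-1} + shocks_n, returned for n = 1..len(shocks)."""
    from scipy.signal import lfilter

    out, _ = lfilter([1.0], [1.0, -a], shocks, zi=np.array([a * z0]))
    return out


def simulate_ou1(
    params: OUParams1, dt: float, n_steps: int, seed, *, z0: float | None = None
) -> Trace:
    """Exact-discretization OU path sampled at interval dt [s].

    z0=None starts from the stationary distribution.  The update
    z' = a z + sigma sqrt(1-a^2) xi (a = exp(-dt/tau)) has the exact
    transition law, so the stationary variance is sigma^2 at any dt.
    """
    if dt >= params.tau:
        import warnings

        warnings.warn("dt >= tau: the path is sampled coarser than it decorrelates")
    rng = np.random.default_rng(seed)
    z = np.empty(n_steps + 1)
    z[0] = params.sigma * rng.standard_normal() if z0 is None else z0
    a, s = _exact_update_coeffs(params.tau, params.sigma, dt)
    z[1:] = _ar1(a, s * rng.standard_normal(n_steps), z[0])
    t = dt * np.arange(n_steps + 1)
    return Trace(t, z, {"model": "ou1", "tau": params.tau, "sigma": params.sigma, "dt": dt})


def simulate_ou2(
    params: OUParams2, dt: float, n_steps: int, seed, *, stationary_start: bool = True
) -> Trace:
    """Two-component OU path Z = c X + sqrt(1-c^2) Y at interval dt [s]."""
    if dt >= params.tau_fast:
        import warnings

        warnings.warn("dt >= tau_fast: the fast component is under-resolved")
    rng = np.random.default_rng(seed)
    a1, s1 = _exact_update_coeffs(params.tau_slow, params.sigma, dt)
    a2, s2 = _exact_update_coeffs(params.tau_fast, params.sigma, dt)
    if stationary_start:
        x = params.sigma * rng.standard_normal()
        y = params.sigma * rng.standard_normal()
    else:
        x = y = 0.0
    cs = np.sqrt(1.0 - params.c**2)
    z = np.empty(n_steps + 1)
    z[0] = params.c * x + cs * y
    xs = _ar1(a1, s1 * rng.standard_normal(n_steps), x)
    ys = _ar1(a2, s2 * rng.standard_normal(n_steps), y)
    z[1:] = params.c * xs + cs * ys
    t = dt * np.arange(n_steps + 1)
    return Trace(
        t, z,
        {"model": "ou2", "tau_slow": params.tau_slow, "tau_fast": params.tau_fast,
         "sigma": params.sigma, "c": params.c, "dt": dt},
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass
class GaussianFit:
    mean: float
    sigma: float
    mean_ci: tuple[float, float]
    sigma_ci: tuple[float, float]
    n_effective: float


def autocorrelation(trace: Trace, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Empirical normalized autocorrelation alpha(dt) via FFT.

    Returns (lags [s], alpha); alpha[0] = 1 by construction.
    """
    if max_lag >= len(trace):
        raise ValueError("max_lag must be smaller than the trace length")
    from statsmodels.tsa.stattools import acf

    alpha = acf(trace.values, nlags=max_lag, fft=True)
    lags = trace.dt * np.arange(max_lag + 1)
    return lags, alpha


def integrated_autocorr_time(trace: Trace) -> float:
    """Integrated autocorrelation time [s] (self-truncating window sum)."""
    n = len(trace)
    lags, alpha = autocorrelation(trace, min(n - 2, max(10, n // 10)))
    # sum until alpha first dips below zero (standard truncation)
    neg = np.flatnonzero(alpha < 0)
    stop = int(neg[0]) if len(neg) else len(alpha)
    return float(trace.dt * (1.0 + 2.0 * np.sum(alpha[1:stop])))


def fit_gaussian(trace: Trace) -> GaussianFit:
    """Sample mean/SD with autocorrelation-corrected confidence intervals.

    The effective sample size is N dt / (2 tau_int); CIs use the normal
    approximation for the mean and the chi-square-free large-sample
    approximation SE(sigma) = sigma / sqrt(2 (N_eff - 1)).
    """
    v = trace.values
    n = len(v)
    mean = float(v.mean())
    sigma = float(v.std(ddof=1)) if n > 1 else 0.0
    if sigma == 0.0:
        return GaussianFit(mean, 0.0, (mean, mean), (0.0, 0.0), float(n))
    tau_int = max(integrated_autocorr_time(trace), trace.dt)
    n_eff = max(2.0, n * trace.dt / (2.0 * tau_int))
    if n_eff < 20:
        import warnings

        warnings.warn("trace much shorter than its correlation time: wide CIs")
    se_mean = sigma / np.sqrt(n_eff)
    se_sig = sigma / np.sqrt(2.0 * (n_eff - 1.0))
    return GaussianFit(
        mean, sigma,
        (mean - 1.96 * se_mean, mean + 1.96 * se_mean),
        (sigma - 1.96 * se_sig, sigma + 1.96 * se_sig),
        float(n_eff),
    )


# ---------------------------------------------------------------------------
# exponential fits to the autocorrelation
# ---------------------------------------------------------------------------

@dataclass
class ExpFit:
    tau: float
    sse: float
    window: int        # number of lags fitted
    ci: tuple[float, float] | None = None


@dataclass
class DoubleExpFit:
    c2: float          # slow variance fraction (weight of tau_slow)
    tau_slow: float
    tau_fast: float
    sse: float
    window: int
    fallback_single: bool = False
    c2_ci: tuple[float, float] | None = None

    @property
    def c(self) -> float:
        """Amplitude convention: Z = c X + sqrt(1-c^2) Y."""
        return float(np.sqrt(self.c2))


def _fit_window(alpha: np.ndarray, floor: float = 0.02) -> int:
    """Lags from 0 until alpha first drops below ``floor`` (noise-floor bias guard)."""
    below = np.flatnonzero(alpha < floor)
    stop = int(below[0]) if len(below) else len(alpha)
    return max(stop, 5)


def fit_single_exp(lags: np.ndarray, alpha: np.ndarray, *, floor: float = 0.02) -> ExpFit:
    """Least-squares exp(-t/tau) over the default window."""
    from scipy.optimize import curve_fit

    w = min(_fit_window(alpha, floor), len(alpha))
    t, a = lags[:w], alpha[:w]
    # log-linear seed
    pos = a > 0
    slope = np.polyfit(t[pos], np.log(a[pos]), 1)[0]
    tau0 = -1.0 / slope if slope < 0 else (t[-1] if t[-1] > 0 else 1.0)
    popt, _ = curve_fit(lambda tt, tau: np.exp(-tt / tau), t, a, p0=[abs(tau0)],
                        bounds=(1e-300, np.inf), maxfev=10000)
    tau = float(popt[0])
    sse = float(np.sum((np.exp(-t / tau) - a) ** 2))
    return ExpFit(tau=tau, sse=sse, window=w)


def _double_exp(t, c2, log_ts, log_tf):
    return c2 * np.exp(-t / np.exp(log_ts)) + (1.0 - c2) * np.exp(-t / np.exp(log_tf))


def fit_double_exp(
    lags: np.ndarray, alpha: np.ndarray, *, floor: float = 0.02,
    min_separation: float = 3.0,
) -> DoubleExpFit:
    """Nonlinear least squares for c^2 e^{-t/ts} + (1-c^2) e^{-t/tf}.

    Multistart over log-spaced timescale seed pairs; if the optimum has
    tau_slow/tau_fast < ``min_separation`` the two timescales are not
    identifiable and a single-exponential fallback is reported.
    """
    from scipy.optimize import curve_fit

    w = min(_fit_window(alpha, floor), len(alpha))
    t, a = lags[:w], alpha[:w]
    tmax = t[-1] if t[-1] > 0 else 1.0
    tmin = max(t[1], tmax * 1e-6) if len(t) > 1 else tmax * 1e-3
    seeds = np.log(np.geomspace(tmin / 3.0, 3.0 * tmax, 6))
    best = None
    for i, ls in enumerate(seeds):
        for lf in seeds[:i]:
            try:
                popt, _ = curve_fit(
                    _double_exp, t, a, p0=[0.5, ls, lf],
                    bounds=([0.0, np.log(tmin) - 14, np.log(tmin) - 14],
                            [1.0, np.log(tmax) + 7, np.log(tmax) + 7]),
                    maxfev=5000,
                )
            except RuntimeError:
                continue
            sse = float(np.sum((_double_exp(t, *popt) - a) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt)
    if best is None:
        raise RuntimeError("double-exponential fit did not converge from any start")
    sse, (c2, ls, lf) = best
    ts, tf = float(np.exp(ls)), float(np.exp(lf))
    if ts < tf:
        ts, tf = tf, ts
        c2 = 1.0 - c2
    if ts / tf < min_separation:
        single = fit_single_exp(lags, alpha, floor=floor)
        return DoubleExpFit(c2=1.0, tau_slow=single.tau, tau_fast=single.tau,
                            sse=single.sse, window=w, fallback_single=True)
    return DoubleExpFit(c2=float(c2), tau_slow=ts, tau_fast=tf, sse=sse, window=w)


def fit_trace_ou1(trace: Trace, *, max_lag: int | None = None) -> tuple[OUParams1, ExpFit]:
    """Recover (tau, sigma) from a trace: Gaussian SD + single-exp autocorr."""
    g = fit_gaussian(trace)
    ml = max_lag if max_lag is not None else min(len(trace) - 2, len(trace) // 4)
    lags, alpha = autocorrelation(trace, ml)
    f = fit_single_exp(lags, alpha)
    return OUParams1(tau=f.tau, sigma=g.sigma), f


def fit_trace_ou2(trace: Trace, *, max_lag: int | None = None) -> tuple[OUParams2, DoubleExpFit]:
    """Recover (c^2, tau_slow, tau_fast, sigma) from an interface trace."""
    g = fit_gaussian(trace)
    ml = max_lag if max_lag is not None else min(len(trace) - 2, len(trace) // 4)
    lags, alpha = autocorrelation(trace, ml)
    f = fit_double_exp(lags, alpha)
    if f.fallback_single:
        raise RuntimeError("two timescales not identifiable in this trace")
    params = OUParams2(tau_slow=f.tau_slow, tau_fast=f.tau_fast, sigma=g.sigma,
                       c=float(np.sqrt(np.clip(f.c2, 0.0, 1.0))))
    return params, f


def block_bootstrap_c2(
    trace: Trace, n_boot: int = 50, seed: int = 0, *, max_lag: int | None = None
) -> tuple[float, float]:
    """Moving-block-bootstrap 95% CI for the slow variance fraction c^2.

    Block length = 10 fitted slow timescales.
    """
    rng = np.random.default_rng(seed)
    _, base = fit_trace_ou2(trace, max_lag=max_lag)
    block = max(10, int(round(10.0 * base.tau_slow / trace.dt)))
    n = len(trace)
    n_blocks = max(2, int(np.ceil(n / block)))
    vals = []
    for _ in range(n_boot):
        starts = rng.integers(0, max(1, n - block), size=n_blocks)
        sample = np.concatenate([trace.values[s:s + block] for s in starts])[:n]
        tb = Trace(trace.times[: len(sample)], sample)
        try:
            _, f = fit_trace_ou2(tb, max_lag=max_lag)
            vals.append(f.c2)
        except RuntimeError:
            continue
    if len(vals) < max(5, n_boot // 4):
        raise RuntimeError("bootstrap fits mostly failed; trace too short")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)
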