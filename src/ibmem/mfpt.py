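"""Mean first-passage times for the reduced OU processes.

Three routes to the same quantity, used to cross-validate each other:

* :func:`analytic_mfpt_ou1` -- the classical double-integral (quadrature)
  form of the mean exit time for a one-component OU process with an
  absorbing boundary above the start (the process is confining below, so
  no lower boundary is needed).
* :func:`brute_force_mfpt` -- direct seeded Monte Carlo of first hitting
  times; feasible up to ~2.5 sigma thresholds.
* :func:`run_weighted_ensemble` -- Weighted Ensemble (WE) splitting /
  merging along the displacement coordinate, estimating the MFPT from
  the steady-state flux into the absorbing threshold (Hill relation
  MFPT = 1/flux with absorbed walkers recycled at the start).  This is
  the only feasible route for the rare thresholds (>= 4 sigma) where
  membrane proximity lives.

Displacement is measured from the stationary mean toward contact, so a
threshold b means "separation reduced by b nm".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ou import OUParams1, OUParams2, _exact_update_coeffs


# ---------------------------------------------------------------------------
# analytic reference (one-component OU)
# ---------------------------------------------------------------------------

def analytic_mfpt_ou1(params: OUParams1, start: float, threshold: float) -> float:
    """Mean first time [s] for dZ = -Z/tau dt + sigma sqrt(2/tau) dW to
    reach ``threshold`` from ``start`` (both in nm; threshold > start).

    T(x -> b) = tau sqrt(2 pi) * int_{x/sigma}^{b/sigma} e^{u^2/2} Phi(u) du,
    evaluated by adaptive quadrature to ~1e-10 relative accuracy.  For
    deep thresholds the integrand is exp-rescaled to avoid overflow.
    """
    if threshold < start:
        raise ValueError("threshold must be >= start")
    if threshold == start:
        return 0.0
    from scipy.integrate import quad
    from scipy.special import log_ndtr

    lo, hi = start / params.sigma, threshold / params.sigma
    # integrand e^{u^2/2} Phi(u) spans many orders; integrate in log space
    # by factoring out its value at the upper limit.
    log_peak = 0.5 * hi * hi + log_ndtr(hi)

    def f(u):
        return np.exp(0.5 * u * u + log_ndtr(u) - log_peak)

    val, err = quad(f, lo, hi, epsabs=0.0, epsrel=1e-10, limit=200)
    if not np.isfinite(val):
        raise FloatingPointError("quadrature failed for this threshold")
    return float(params.tau * np.sqrt(2.0 * np.pi) * val * np.exp(log_peak))


# ---------------------------------------------------------------------------
# brute-force Monte Carlo oracle
# ---------------------------------------------------------------------------

def _propagate_displacement(process, dt: float):
    """Return (weights, step, inc_std) for vectorized exact OU propagation.

    state is (n, d); displacement toward contact is z = state @ weights;
    inc_std is the one-step shock SD of z, used for the Brownian-bridge
    crossing correction between samples.
    """
    if isinstance(process, OUParams1):
        a, s = _exact_update_coeffs(process.tau, process.sigma, dt)

        def step(state, rng):
            state *= a
            state += s * rng.standard_normal(state.shape)
            return state

        weights = np.array([1.0])
        inc_std = s
    elif isinstance(process, OUParams2):
        a1, s1 = _exact_update_coeffs(process.tau_slow, process.sigma, dt)
        a2, s2 = _exact_update_coeffs(process.tau_fast, process.sigma, dt)
        avec = np.array([a1, a2])
        svec = np.array([s1, s2])

        def step(state, rng):
            state *= avec
            state += svec * rng.standard_normal(state.shape)
            return state

        weights = np.array([process.c, np.sqrt(1.0 - process.c**2)])
        inc_std = float(np.sqrt((process.c * s1) ** 2 + (1.0 - process.c**2) * s2**2))
    else:
        raise TypeError(f"unsupported process type {type(process).__name__}")
    return weights, step, inc_std


@dataclass
class MFPTEstimate:
    mfpt: float      # [s]
    se: float        # standard error [s]
    n: int           # trials (or WE runs)


def brute_force_mfpt(
    process, start: float, threshold: float, n_trials: int, dt: float, seed,
    *, t_max_factor: float = 50.0, two_sided: bool = False,
) -> MFPTEstimate:
    """Monte-Carlo mean first time [s] for the displacement to reach
    ``threshold`` from ``start`` (one-sided by default).

    Each trial propagates the exact discrete process from displacement
    ``start`` until crossing; a trial exceeding t_max_factor * (rough
    analytic scale) raises, since the estimate would be censored.
    """
    if threshold <= start:
        return MFPTEstimate(0.0, 0.0, n_trials)
    rng = np.random.default_rng(seed)
    weights, step, inc_std = _propagate_displacement(process, dt)
    d = len(weights)
    # start at displacement `start` distributed across components by variance share
    state = np.zeros((n_trials, d))
    state += start * weights / np.sum(weights**2)
    times = np.full(n_trials, np.nan)
    alive = np.ones(n_trials, dtype=bool)
    sigma = process.sigma
    guess = _mfpt_scale(process, threshold / sigma)
    max_steps = int(np.ceil(t_max_factor * guess / dt))
    t = 0.0
    z_prev = state @ weights
    for k in range(1, max_steps + 1):
        sub = state[alive]
        zp = z_prev[alive]
        sub = step(sub, rng)
        state[alive] = sub
        z = sub @ weights
        if two_sided:
            hit = np.abs(z) >= threshold
            hit |= rng.random(len(z)) < _bridge_prob(np.abs(zp), np.abs(z), threshold, inc_std)
        else:
            hit = z >= threshold
            hit |= rng.random(len(z)) < _bridge_prob(zp, z, threshold, inc_std)
        z_prev[alive] = z
        t = k * dt
        if hit.any():
            idx = np.flatnonzero(alive)[hit]
            times[idx] = t
            alive[idx] = False
        if not alive.any():
            break
    if alive.any():
        raise RuntimeError(
            f"{alive.sum()}/{n_trials} trials did not reach the threshold within "
            f"{max_steps} steps; estimate would be censored"
        )
    return MFPTEstimate(float(times.mean()), float(times.std(ddof=1) / np.sqrt(n_trials)),
                        n_trials)


def _bridge_prob(z0, z1, threshold, inc_std):
    """P(path crossed the threshold between samples | endpoints below it).

    Brownian-bridge approximation: exp(-2 (b-z0)(b-z1) / inc_std^2).
    """
    a = np.maximum(threshold - z0, 0.0)
    b = np.maximum(threshold - z1, 0.0)
    return np.exp(-2.0 * a * b / inc_std**2)


def _mfpt_scale(process, b_over_sigma: float) -> float:
    """Crude Arrhenius-style scale used only to cap brute-force runtimes."""
    tau = process.tau if isinstance(process, OUParams1) else process.tau_slow
    return float(tau * (1.0 + np.sqrt(2 * np.pi) * np.exp(0.5 * b_over_sigma**2)))


# ---------------------------------------------------------------------------
# Weighted Ensemble
# ---------------------------------------------------------------------------

@dataclass
class WEConfig:
    """Weighted Ensemble configuration.

    n_bins uniform bins over [start, threshold] along the displacement
    coordinate; walkers_per_bin targets per occupied bin; resample_every
    [s] between split/merge steps (defaults to tau_fast); t_total [s]
    simulated per run; n_runs independent replicates; burn_in fraction
    of each flux record discarded.
    """

    n_bins: int = 30
    walkers_per_bin: int = 4
    resample_every: float | None = None
    dt: float | None = None
    t_total: float = 1.0e-2
    n_runs: int = 10
    burn_in: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.walkers_per_bin < 2:
            raise ValueError("walkers_per_bin must be >= 2")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass
class WEEstimate:
    mfpt: float                  # [s] (1 / mean flux, averaged over runs)
    per_run: np.ndarray          # per-run MFPT estimates [s]
    std: float                   # SD across runs [s]
    flux_trace: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    n_resamples: int = 0


def _fastest_tau(process) -> float:
    return process.tau if isinstance(process, OUParams1) else process.tau_fast


def run_weighted_ensemble(
    process, start: float, threshold: float, config: WEConfig
) -> WEEstimate:
    """Weighted Ensemble MFPT [s] to the absorbing threshold.

    Standard split/merge resampling: walkers are binned along the
    displacement coordinate; each occupied bin is brought to the target
    walker count by splitting the heaviest walkers and merging the
    lightest pairs (victim chosen with probability proportional to
    weight), conserving total weight to machine precision.  Absorbed
    weight is recycled at the start, and MFPT = 1 / (steady-state flux).
    """
    if threshold <= start:
        raise ValueError("threshold must exceed start")
    tau_f = _fastest_tau(process)
    dt = config.dt if config.dt is not None else tau_f / 20.0
    resample = config.resample_every if config.resample_every is not None else tau_f
    m_steps = max(1, int(round(resample / dt)))
    edges = np.linspace(start, threshold, config.n_bins + 1)
    n_cycles = max(10, int(round(config.t_total / (m_steps * dt))))
    burn = int(config.burn_in * n_cycles)
    ss = np.random.SeedSequence(config.seed)
    run_seeds = ss.spawn(config.n_runs)

    per_run = np.empty(config.n_runs)
    fluxes_all = []
    for r in range(config.n_runs):
        rng = np.random.default_rng(run_seeds[r])
        flux = _we_single_run(process, start, threshold, edges, config.walkers_per_bin,
                              dt, m_steps, n_cycles, rng)
        fluxes_all.append(flux)
        mean_flux = flux[burn:].sum() / ((n_cycles - burn) * m_steps * dt)
        per_run[r] = 1.0 / mean_flux if mean_flux > 0 else np.inf
    finite = np.isfinite(per_run)
    if not finite.any():
        raise RuntimeError("threshold unreachable at this budget: zero flux after burn-in")
    # average rates, not times: flux is the unbiased WE observable
    rates = 1.0 / per_run[finite]
    mfpt = float(1.0 / rates.mean())
    std = float(np.std(per_run[finite], ddof=1)) if finite.sum() > 1 else 0.0
    return WEEstimate(mfpt=mfpt, per_run=per_run, std=std,
                      flux_trace=np.asarray(fluxes_all), n_resamples=n_cycles)


def _we_single_run(process, start, threshold, edges, target, dt, m_steps, n_cycles, rng):
    weights_vec, step, inc_std = _propagate_displacement(process, dt)
    start_state = start * weights_vec / np.sum(weights_vec**2)

    n0 = (len(edges) - 1) * target
    state = np.tile(start_state, (n0, 1))
    w = np.full(n0, 1.0 / n0)
    flux = np.zeros(n_cycles)

    for cycle in range(n_cycles):
        z_prev = state @ weights_vec
        for _ in range(m_steps):
            state = step(state, rng)
            z = state @ weights_vec
            hit = z >= threshold
            hit |= rng.random(len(z)) < _bridge_prob(z_prev, z, threshold, inc_std)
            if hit.any():
                flux[cycle] += w[hit].sum()
                state[hit] = start_state
                z[hit] = z_prev[0] * 0.0 + start
            z_prev = z
        # --- resample ---
        z = state @ weights_vec
        bins = np.clip(np.digitize(z, edges) - 1, 0, len(edges) - 2)
        new_state = []
        new_w = []
        for b in np.unique(bins):
            sel = np.flatnonzero(bins == b)
            bw = w[sel]
            bs = state[sel]
            order = np.argsort(bw)
            bw = bw[order]
            bs = bs[order]
            # merge lightest pairs while over target
            while len(bw) > target:
                total = bw[0] + bw[1]
                keep = 0 if rng.random() < bw[0] / total else 1
                bs = np.concatenate([bs[keep:keep + 1], bs[2:]])
                bw = np.concatenate([[total], bw[2:]])
                order = np.argsort(bw)
                bw = bw[order]
                bs = bs[order]
            # split heaviest while under target
            while len(bw) < target:
                i = len(bw) - 1
                bw = np.concatenate([bw[:i], [bw[i] / 2, bw[i] / 2]])
                bs = np.concatenate([bs, bs[i:i + 1]])
                order = np.argsort(bw)
                bw = bw[order]
                bs = bs[order]
            new_state.append(bs)
            new_w.append(bw)
        state = np.concatenate(new_state)
        w = np.concatenate(new_w)
        # weight conservation guard (absorbed weight was recycled, so sum == 1)
        total = w.sum()
        if not np.isclose(total, 1.0, rtol=1e-9, atol=1e-12):
            raise RuntimeError(f"WE weight leak: sum(w) = {total!r}")
    return flux
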