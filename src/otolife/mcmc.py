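"""Bayesian estimation of the growth/selectivity/mortality model.

All eight parameters are sampled on the log scale with independent normal
priors on ln(theta) (equivalently log-normal priors on the natural scale),
specified as a natural-scale median and a log-space SD. Posterior draws come
from a componentwise random-walk Metropolis–Hastings sampler whose per-
parameter proposal scales are adapted during burn-in toward a 20–40%
acceptance rate and then frozen, so the post-burn-in chain is a standard
time-homogeneous Metropolis chain.

Convergence is assessed with the Gelman–Rubin potential scale reduction
factor (multiple chains), the Geweke first-10%/last-50% mean comparison, and
a Heidelberger–Welch-style Cramér–von Mises stationarity test on each chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .growth import (
    PARAM_NAMES,
    GridSpec,
    _compute_probs,
    observed_cell_counts,
)

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PriorSpec:
    """Independent log-normal priors: natural-scale medians and log-space SDs."""

    medians: dict
    log_sds: dict

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if name not in self.medians or name not in self.log_sds:
                raise ValueError(f"prior missing for parameter {name!r}")
            if self.medians[name] <= 0:
                raise ValueError(f"prior median for {name!r} must be > 0")
            if self.log_sds[name] <= 0:
                raise ValueError(f"prior log-SD for {name!r} must be > 0")

    def mu_vector(self) -> np.ndarray:
        return np.array([np.log(self.medians[n]) for n in PARAM_NAMES])

    def sd_vector(self) -> np.ndarray:
        return np.array([self.log_sds[n] for n in PARAM_NAMES])

    def with_median(self, name: str, value: float) -> "PriorSpec":
        med = dict(self.medians)
        med[name] = value
        return PriorSpec(medians=med, log_sds=dict(self.log_sds))


def default_priors() -> PriorSpec:
    """Priors used for the Gulf of Mexico Warsaw grouper fit.

    Weak (log-SD 2-5) priors on growth, length CV and selectivity; an
    informative prior (log-SD 0.1) on M centred on the Hewitt-Hoenig
    longevity estimate 0.069/y.
    """
    return PriorSpec(
        medians={
            "linf": 1618.0,
            "k": 0.13,
            "t0": 0.2,
            "cv_len": 0.12,
            "l50": 880.0,
            "sel_steepness": 5.0,
            "m_nat": 0.069,
            "f_mort": 0.2,
        },
        log_sds={
            "linf": 5.0,
            "k": 2.0,
            "t0": 2.0,
            "cv_len": 2.0,
            "l50": 5.0,
            "sel_steepness": 2.0,
            "m_nat": 0.1,
            "f_mort": 2.0,
        },
    )


def log_prior(log_params, priors: PriorSpec) -> float:
    """Sum of normal log-densities of ln(theta); -inf if any theta <= 0.

    ``log_params`` may also be a GrowthParams, in which case its natural-scale
    values are logged first.
    """
    if hasattr(log_params, "to_array"):
        arr = log_params.to_array()
        if np.any(arr <= 0):
            return -np.inf
        x = np.log(arr)
    else:
        x = np.asarray(log_params, dtype=float)
    if not np.all(np.isfinite(x)):
        return -np.inf
    mu = priors.mu_vector()
    sd = priors.sd_vector()
    z = (x - mu) / sd
    return float(np.sum(-0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI))


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings. Defaults follow the published fit."""

    n_chains: int = 4
    burn_in: int = 5_000
    n_samples: int = 200_000
    thin: int = 1
    initial_scale: float = 0.1  # log-space RW proposal SD before adaptation
    adapt_interval: int = 50
    target_low: float = 0.20
    target_high: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.burn_in < 0 or self.n_samples < 1 or self.thin < 1:
            raise ValueError("invalid chain lengths")


@dataclass
class McmcResult:
    """Posterior draws (log scale) and natural-scale summaries."""

    draws: np.ndarray  # (n_chains, n_kept, 8) log-parameter draws, post burn-in
    acceptance: np.ndarray  # (n_chains,) post-burn-in joint acceptance rates
    scales: np.ndarray  # (n_chains, 8) marginal SDs of the frozen proposal
    config: McmcConfig
    param_names: tuple = PARAM_NAMES

    pooled_: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.pooled_ = self.draws.reshape(-1, self.draws.shape[-1])

    def posterior_mean(self) -> dict:
        """Natural-scale posterior means E[theta]."""
        means = np.exp(self.pooled_).mean(axis=0)
        return dict(zip(self.param_names, means))

    def posterior_median(self) -> dict:
        med = np.exp(np.median(self.pooled_, axis=0))
        return dict(zip(self.param_names, med))

    def posterior_log_sd(self) -> dict:
        """SD of the log-scale draws (the 'SD in log space' of the summary table)."""
        sds = self.pooled_.std(axis=0, ddof=1)
        return dict(zip(self.param_names, sds))

    def summary_table(self):
        """Posterior summary as a pandas DataFrame (value, SD in log space)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "posterior_mean": [self.posterior_mean()[n] for n in self.param_names],
                "posterior_log_sd": [self.posterior_log_sd()[n] for n in self.param_names],
            }
        )


class _Posterior:
    """Log-posterior over the 8 log-parameters, with optional empty-data mode."""

    def __init__(self, observations, priors: PriorSpec, spec: GridSpec):
        self.priors = priors
        self.spec = spec
        self.zq = spec.group_quantiles()
        if observations is None or len(observations) == 0:
            self.cells = None
            self.counts = None
        else:
            self.cells, self.counts = observed_cell_counts(observations, spec)

    def log_lik(self, x: np.ndarray) -> float:
        if self.cells is None:
            return 0.0
        theta = np.exp(x)
        probs = _compute_probs(theta, self.zq, self.spec)
        return float(self.counts @ np.log(probs.ravel()[self.cells]))

    def __call__(self, x: np.ndarray) -> float:
        lp = log_prior(x, self.priors)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.log_lik(x)


def _run_chain(post, x0, cfg: McmcConfig, seed: int):
    """One random-walk Metropolis chain with burn-in-only adaptation.

    Burn-in proceeds in two phases: componentwise updates with per-parameter
    scale tuning (robust mode finding), then joint proposals whose covariance
    is estimated from the accumulated burn-in draws (2.38^2/d scaling, with a
    scalar multiplier nudged toward 20-40% acceptance). After burn-in the
    proposal is frozen, so the sampling phase is a standard Metropolis chain.
    """
    rng = np.random.default_rng(seed)
    ndim = x0.size
    x = x0.copy()
    lp = post(x)
    if not np.isfinite(lp):
        raise RuntimeError(f"non-finite log-posterior at initial point {x0.tolist()}")
    scales = np.full(ndim, cfg.initial_scale)
    phase1 = min(cfg.burn_in, max(cfg.burn_in // 2, 200)) if cfg.burn_in else 0
    history = np.empty((cfg.burn_in, ndim))
    acc_window = np.zeros(ndim)
    n_window = 0

    # --- phase 1: componentwise with scale adaptation ---------------------
    for it in range(phase1):
        for j in range(ndim):
            x_new = x.copy()
            x_new[j] = x[j] + scales[j] * rng.standard_normal()
            lp_new = post(x_new)
            if np.log(rng.uniform()) < lp_new - lp:
                x, lp = x_new, lp_new
                acc_window[j] += 1
        history[it] = x
        n_window += 1
        if n_window == cfg.adapt_interval:
            rates = acc_window / n_window
            scales = np.where(rates < cfg.target_low, scales * 0.7, scales)
            scales = np.where(rates > cfg.target_high, scales * 1.4, scales)
            acc_window[:] = 0.0
            n_window = 0

    # --- phase 2: joint proposals, covariance from the running history ----
    def chol_from(draws):
        cov = np.cov(draws.T) if draws.shape[0] > 2 * ndim else np.diag(scales**2)
        cov = cov + 1e-10 * np.eye(ndim)
        return np.linalg.cholesky(cov)

    mult = 2.38 / np.sqrt(ndim)
    chol = chol_from(history[: max(phase1, 1)])
    acc_j = 0
    n_j = 0
    for it in range(phase1, cfg.burn_in):
        x_new = x + mult * (chol @ rng.standard_normal(ndim))
        lp_new = post(x_new)
        if np.log(rng.uniform()) < lp_new - lp:
            x, lp = x_new, lp_new
            acc_j += 1
        n_j += 1
        history[it] = x
        if n_j == 4 * cfg.adapt_interval:
            rate = acc_j / n_j
            if rate < cfg.target_low:
                mult *= 0.7
            elif rate > cfg.target_high:
                mult *= 1.4
            chol = chol_from(history[max(phase1 - 2000, 0): it + 1])
            acc_j = 0
            n_j = 0

    # --- sampling phase: frozen joint proposal ----------------------------
    n_kept = cfg.n_samples // cfg.thin
    kept = np.empty((n_kept, ndim))
    kept_i = 0
    acc_post = 0
    prop_chol = mult * chol
    for k in range(cfg.n_samples):
        x_new = x + prop_chol @ rng.standard_normal(ndim)
        lp_new = post(x_new)
        if np.log(rng.uniform()) < lp_new - lp:
            x, lp = x_new, lp_new
            acc_post += 1
        if k % cfg.thin == 0 and kept_i < n_kept:
            kept[kept_i] = x
            kept_i += 1
    return kept[:kept_i], acc_post / cfg.n_samples, np.diag(prop_chol @ prop_chol.T) ** 0.5


def run_mcmc(
    observations,
    priors: PriorSpec | None = None,
    config: McmcConfig | None = None,
    spec: GridSpec | None = None,
    init: np.ndarray | None = None,
) -> McmcResult:
    """Sample the posterior of the 8 growth/mortality parameters.

    ``observations`` is an (n, 2) array of (age, length) or None/empty for
    prior-only sampling (constant likelihood). Chain c uses seed
    ``config.seed + c`` so multi-chain runs are reproducible yet distinct.
    """
    priors = priors or default_priors()
    config = config or McmcConfig()
    spec = spec or GridSpec()
    if observations is not None and len(observations) > 0 and len(observations) < 50:
        raise ValueError("need >= 50 observations (or none, for prior-only sampling)")
    post = _Posterior(observations, priors, spec)
    x0 = priors.mu_vector() if init is None else np.asarray(init, dtype=float)
    draws, accs, scales = [], [], []
    for c in range(config.n_chains):
        # mildly overdispersed starts so multi-chain diagnostics have teeth
        jitter = np.random.default_rng(config.seed + 1000 + c).normal(0.0, 0.05, x0.size)
        kept, acc, sc = _run_chain(post, x0 + jitter, config, config.seed + c)
        draws.append(kept)
        accs.append(acc)
        scales.append(sc)
    return McmcResult(
        draws=np.array(draws),
        acceptance=np.array(accs),
        scales=np.array(scales),
        config=config,
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------


def gelman_rubin_psrf(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor for one scalar parameter.

    ``chains`` has shape (n_chains, n_draws). Requires >= 2 chains.
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    if m < 2:
        raise ValueError("PSRF requires >= 2 chains")
    chain_means = chains.mean(axis=1)
    b = n * chain_means.var(ddof=1)
    w = chains.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _spectral_se(x: np.ndarray) -> float:
    """Standard error of the mean allowing for autocorrelation (batch means)."""
    n = x.size
    nb = max(int(np.sqrt(n)), 2)
    bs = n // nb
    if bs < 1:
        return float(x.std(ddof=1) / np.sqrt(n))
    means = x[: nb * bs].reshape(nb, bs).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(nb))


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain means."""
    x = np.asarray(chain, dtype=float)
    n = x.size
    a = x[: max(int(first * n), 2)]
    b = x[n - max(int(last * n), 2):]
    se = np.sqrt(_spectral_se(a) ** 2 + _spectral_se(b) ** 2)
    if se == 0:
        return 0.0
    return float((a.mean() - b.mean()) / se)


def heidelberger_welch_stationary(chain: np.ndarray, alpha: float = 0.05) -> bool:
    """Cramér–von Mises stationarity test on the standardized cumulative sum.

    Returns True when stationarity is NOT rejected at the given level
    (critical values 0.347 / 0.461 / 0.743 for alpha 0.10 / 0.05 / 0.01).
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("need >= 100 draws")
    s0 = n * _spectral_se(x) ** 2  # spectral density at zero estimate
    if s0 == 0:
        return True
    csum = np.cumsum(x - x.mean())
    t = np.arange(1, n + 1) / n
    bridge = csum / np.sqrt(n * s0)
    cvm = float(np.sum(bridge**2) / n)
    crit = {0.10: 0.347, 0.05: 0.461, 0.01: 0.743}[alpha]
    _ = t
    return cvm < crit


@dataclass
class ConvergenceReport:
    psrf: dict
    geweke: dict
    heidelberger: dict  # parameter -> list of per-chain booleans
    passed: bool

    def failures(self) -> list:
        out = []
        for name, v in self.psrf.items():
            if v >= 1.1:
                out.append(f"PSRF[{name}]={v:.3f}")
        for name, v in self.geweke.items():
            if abs(v) >= 2:
                out.append(f"Geweke[{name}]={v:.2f}")
        for name, oks in self.heidelberger.items():
            if not all(oks):
                out.append(f"HW[{name}] nonstationary")
        return out


def convergence_diagnostics(result: McmcResult) -> ConvergenceReport:
    """PSRF, Geweke z and Heidelberger–Welch stationarity per parameter.

    Overall pass requires PSRF < 1.1, |Geweke z| < 2 (pooled within-chain
    mean of z, assessed per chain then averaged) and every chain stationary.
    """
    draws = result.draws
    if draws.shape[0] < 2:
        raise ValueError("diagnostics require >= 2 chains")
    if draws.shape[1] < 100:
        raise ValueError("diagnostics require >= 100 post-burn-in draws")
    psrf, gew, hw = {}, {}, {}
    for j, name in enumerate(result.param_names):
        chains = draws[:, :, j]
        psrf[name] = gelman_rubin_psrf(chains)
        gew[name] = float(np.mean([geweke_z(c) for c in chains]))
        hw[name] = [heidelberger_welch_stationary(c) for c in chains]
    passed = (
        all(v < 1.1 for v in psrf.values())
        and all(abs(v) < 2 for v in gew.values())
        and all(all(v) for v in hw.values())
    )
    return ConvergenceReport(psrf=psrf, geweke=gew, heidelberger=hw, passed=passed)
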