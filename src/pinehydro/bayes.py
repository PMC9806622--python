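"""Bayesian calibration of response curves with a DE-MCzs sampler.

The calibration engine pairs a Gaussian likelihood (residual sd σ is
itself a calibrated parameter unless fixed) with broad uniform priors
and samples the posterior with differential-evolution Markov chain
Monte Carlo with memory and snooker updates (DE-MCzs, ter Braak &
Vrugt 2008).  Proposals are difference vectors between rows of a
growing memory matrix ``Z`` of past states, scaled by 2.38/√(2d)
(occasionally γ = 1 to allow mode jumps); with small probability a
snooker move proposes along the line from the current state to a random
memory point, with the |x*−z|/|x−z| ^(d−1) volume correction in the
Metropolis ratio.  The scheme needs only a handful of parallel chains
(3 by default) because the memory matrix supplies the population.

Response models shipped here:

* :class:`VpdModel` — Oren-type conductance response
  gc(VPD) = gc_ref − m·ln(VPD/VPD_ref), so gc_ref is gc at the
  reference VPD (1 kPa).
* :class:`ClosureModel` — logistic relative conductance under falling
  water potential, gc_rel(Ψ) = 1/(1 + exp(s(Ψ50 − Ψ))); the water
  potential at stomatal closure is the Ψ where gc_rel drops to 5%.
* :class:`AbaModel` — linear ABA accumulation with tension,
  ABA(Ψ) = ABA₀ + r·(−Ψ).
* :class:`WeibullPlcModel` — the vulnerability curve of
  :mod:`pinehydro.hydraulics`.

Convergence is assessed per parameter with the Gelman–Rubin diagnostic
(threshold 1.1); per-unit (tree/branch) posteriors can be merged with
equal weight into treatment-level posteriors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# priors and configuration
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Independent uniform priors: one (name, lower, upper) per parameter."""

    names: list[str]
    lows: np.ndarray
    highs: np.ndarray

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, float, float]]) -> "PriorSpec":
        names = [p[0] for p in pairs]
        lows = np.array([p[1] for p in pairs], dtype=float)
        highs = np.array([p[2] for p in pairs], dtype=float)
        if np.any(lows >= highs):
            raise ValueError("PriorSpec: require lower < upper for every parameter")
        return cls(names, lows, highs)

    def __len__(self) -> int:
        return len(self.names)

    @property
    def log_density(self) -> float:
        return float(-np.sum(np.log(self.highs - self.lows)))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lows, self.highs, size=(n, len(self)))

    def contains(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        return np.all((theta >= self.lows) & (theta <= self.highs), axis=1)

    def append(self, name: str, low: float, high: float) -> "PriorSpec":
        return PriorSpec.from_pairs(
            list(zip(self.names, self.lows, self.highs)) + [(name, low, high)]
        )


@dataclass
class CalibrationConfig:
    """Sampler settings (defaults follow the study protocol)."""

    iterations: int = 30_000
    burn_in: int = 10_000
    n_chains: int = 3
    seed: int = 0
    rhat_threshold: float = 1.1
    snooker_probability: float = 0.1
    gamma_jump_probability: float = 0.1
    predictive_draws: int = 5_000
    ci_level: float = 0.95
    memory_thin: int = 10  # append chain states to Z every this many generations

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("require 0 <= burn_in < iterations")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for the Gelman-Rubin diagnostic")


# ---------------------------------------------------------------------------
# response models
# ---------------------------------------------------------------------------

class ResponseModel:
    """Contract: ``param_names`` and a broadcastable ``predict``.

    ``predict(theta, x)`` accepts ``theta`` of shape (d,) or (N, d) and
    predictor ``x`` of shape (n,) and returns (n,) or (N, n).
    """

    name: str = "response"
    param_names: list[str] = []

    def predict(self, theta: np.ndarray, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class VpdModel(ResponseModel):
    """gc(VPD) = gc_ref − m·ln(VPD/VPD_ref); gc_ref is gc at VPD_ref."""

    name = "gc_vpd"
    param_names = ["gc_ref", "m"]

    def __init__(self, reference_vpd: float = 1.0):
        if reference_vpd <= 0:
            raise ValueError("reference_vpd must be > 0")
        self.reference_vpd = reference_vpd

    def predict(self, theta, x):
        theta = np.asarray(theta, dtype=float)
        logv = np.log(np.asarray(x, dtype=float) / self.reference_vpd)
        return theta[..., 0, None] - theta[..., 1, None] * logv if theta.ndim > 1 \
            else theta[0] - theta[1] * logv


class ClosureModel(ResponseModel):
    """Relative conductance gc_rel(Ψ) = 1/(1 + exp(s(Ψ50 − Ψ))), Ψ in MPa (< 0)."""

    name = "gc_closure"
    param_names = ["psi50", "s"]
    closure_fraction = 0.05

    def predict(self, theta, x):
        theta = np.asarray(theta, dtype=float)
        psi = np.asarray(x, dtype=float)
        if theta.ndim > 1:
            z = theta[..., 1, None] * (theta[..., 0, None] - psi)
        else:
            z = theta[1] * (theta[0] - psi)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(z))

    def psi_close(self, theta) -> np.ndarray:
        """Ψ at which gc_rel falls to the closure fraction (5%)."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        f = self.closure_fraction
        out = theta[:, 0] - np.log((1.0 - f) / f) / theta[:, 1]
        return out if out.size > 1 else float(out[0])


class AbaModel(ResponseModel):
    """ABA(Ψ) = ABA₀ + r·(−Ψ): linear accumulation with tension."""

    name = "aba_psi"
    param_names = ["aba0", "r"]

    def predict(self, theta, x):
        theta = np.asarray(theta, dtype=float)
        tension = -np.asarray(x, dtype=float)
        return theta[..., 0, None] + theta[..., 1, None] * tension if theta.ndim > 1 \
            else theta[0] + theta[1] * tension


class WeibullPlcModel(ResponseModel):
    """PLC(Ψ) = 100(1 − exp(−(|Ψ|/scale)^shape))."""

    name = "weibull_plc"
    param_names = ["scale", "shape"]

    def predict(self, theta, x):
        theta = np.asarray(theta, dtype=float)
        tension = np.abs(np.asarray(x, dtype=float))
        if theta.ndim > 1:
            ratio = tension / theta[..., 0, None]
            expo = theta[..., 1, None]
        else:
            ratio = tension / theta[0]
            expo = theta[1]
        with np.errstate(over="ignore"):
            return 100.0 * (1.0 - np.exp(-(ratio**expo)))


def default_vpd_priors() -> PriorSpec:
    return PriorSpec.from_pairs(
        [("gc_ref", 1e-3, 2.0), ("m", -0.5, 2.0), ("sigma", 1e-5, 0.5)]
    )


def default_weibull_priors() -> PriorSpec:
    return PriorSpec.from_pairs(
        [("scale", 0.5, 15.0), ("shape", 0.2, 30.0), ("sigma", 0.1, 30.0)]
    )


def default_closure_priors() -> PriorSpec:
    return PriorSpec.from_pairs(
        [("psi50", -5.0, -0.05), ("s", 0.1, 20.0), ("sigma", 1e-3, 0.5)]
    )


def default_aba_priors() -> PriorSpec:
    return PriorSpec.from_pairs(
        [("aba0", 0.0, 2000.0), ("r", 0.0, 2000.0), ("sigma", 0.5, 500.0)]
    )


# ---------------------------------------------------------------------------
# posterior containers
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSet:
    """Posterior samples with convergence metadata.

    For a single calibration ``chains`` holds the post-burn-in samples
    (n_chains, n_kept, d) and ``rhat`` the per-parameter Gelman–Rubin
    diagnostic.  A merged (treatment-level) posterior stores flat
    ``samples`` instead; per-unit R̂ values are recorded before merging
    and summarized in ``unit_converged``.
    """

    param_names: list[str]
    chains: np.ndarray | None = None
    rhat: np.ndarray | None = None
    rhat_threshold: float = 1.1
    merged: bool = False
    provenance: list[str] = field(default_factory=list)
    samples: np.ndarray | None = None
    unit_converged: bool | None = None
    acceptance_rate: float | None = None

    def flat_samples(self) -> np.ndarray:
        if self.samples is not None:
            return self.samples
        m, n, d = self.chains.shape
        return self.chains.reshape(m * n, d)

    @property
    def converged(self) -> bool:
        if self.merged:
            return bool(self.unit_converged)
        return bool(np.all(self.rhat <= self.rhat_threshold))

    def _col(self, param: str) -> np.ndarray:
        return self.flat_samples()[:, self.param_names.index(param)]

    def median(self, param: str) -> float:
        return float(np.median(self._col(param)))

    def credible_interval(self, param: str, level: float = 0.95) -> tuple[float, float]:
        return credible_interval(self._col(param), level)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def make_log_posterior(
    model: ResponseModel,
    x: np.ndarray,
    y: np.ndarray,
    priors: PriorSpec,
    sigma: float | None = None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Batched log-posterior: Gaussian likelihood + uniform log-prior.

    If ``sigma`` is None the residual sd is the last calibrated
    parameter.  Rows outside the prior support, or producing non-finite
    predictions, evaluate to −inf (non-finite predictions are counted
    on ``logp.n_nonfinite``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    log_prior = priors.log_density

    def logp(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        inb = priors.contains(theta)
        safe = np.where(inb[:, None], theta, 0.5 * (priors.lows + priors.highs))
        if sigma is None:
            sig = safe[:, -1]
            pars = safe[:, :-1]
        else:
            sig = np.full(safe.shape[0], float(sigma))
            pars = safe
        pred = model.predict(pars, x)
        finite = np.isfinite(pred).all(axis=-1)
        pred = np.where(finite[:, None], pred, 0.0)
        resid = y[None, :] - pred
        ll = (
            -0.5 * np.sum((resid / sig[:, None]) ** 2, axis=1)
            - n * np.log(sig)
            - 0.5 * n * LOG_2PI
        )
        logp.n_nonfinite += int(np.sum(inb & ~finite))
        out = np.where(inb & finite, ll + log_prior, -np.inf)
        return out

    logp.n_nonfinite = 0
    return logp


def log_posterior(
    model: ResponseModel,
    theta: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    priors: PriorSpec,
    sigma: float | None = None,
) -> float:
    """Scalar log-posterior of one parameter vector (σ last unless fixed)."""
    return float(make_log_posterior(model, x, y, priors, sigma)(np.asarray(theta))[0])


# ---------------------------------------------------------------------------
# DE-MCzs sampler
# ---------------------------------------------------------------------------

def _distinct_rows(rng: np.random.Generator, m: int, k: int, n: int) -> np.ndarray:
    """(n, k) index array, each row k distinct integers from range(m)."""
    idx = rng.integers(0, m, size=(n, k))
    for _ in range(100):
        if k == 3:
            c0, c1, c2 = idx[:, 0], idx[:, 1], idx[:, 2]
            dup = (c0 == c1) | (c0 == c2) | (c1 == c2)
        else:  # pragma: no cover - generic fallback
            dup = (idx[:, :, None] == idx[:, None, :]).sum(axis=(1, 2)) > k
        if not dup.any():
            return idx
        idx[dup] = rng.integers(0, m, size=(int(dup.sum()), k))
    raise RuntimeError("could not draw distinct memory rows")  # pragma: no cover


def demczs_sample(
    log_post: Callable[[np.ndarray], np.ndarray],
    priors: PriorSpec,
    config: CalibrationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Run DE-MCzs; return (chains, acceptance_rate).

    ``chains`` has shape (n_chains, iterations, d) — the caller discards
    burn-in.  Fully reproducible from ``config.seed`` when ``rng`` is
    not supplied.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    d = len(priors)
    n_chains = config.n_chains
    iters = config.iterations
    k_thin = config.memory_thin

    m0 = max(10 * d, 3 * n_chains)
    z_cap = m0 + n_chains * (iters // k_thin + 1)
    z = np.empty((z_cap, d))
    z[:m0] = priors.sample(rng, m0)
    z_len = m0

    x = priors.sample(rng, n_chains)
    lp_x = log_post(x)
    # reseed any chain starting at -inf (e.g. non-finite model prediction)
    for _ in range(100):
        bad = ~np.isfinite(lp_x)
        if not bad.any():
            break
        x[bad] = priors.sample(rng, int(bad.sum()))
        lp_x = np.where(bad, log_post(x), lp_x)

    gamma_par = 2.38 / np.sqrt(2.0 * d)
    eps_scale = 1e-6 * (priors.highs - priors.lows)
    chains = np.empty((n_chains, iters, d))
    n_accept = 0
    accept_window = 0
    window = 1000

    for it in range(iters):
        idx = _distinct_rows(rng, z_len, 3, n_chains)
        z1, z2, zp = z[idx[:, 0]], z[idx[:, 1]], z[idx[:, 2]]

        # parallel-direction proposal
        gam = np.where(
            rng.random(n_chains) < config.gamma_jump_probability, 1.0, gamma_par
        )
        eps = rng.normal(0.0, 1.0, size=(n_chains, d)) * eps_scale
        prop = x + gam[:, None] * (z1 - z2) + eps
        log_corr = np.zeros(n_chains)

        # snooker proposal along the line x - z
        snooker = rng.random(n_chains) < config.snooker_probability
        dvec = x - zp
        norm2 = np.einsum("ij,ij->i", dvec, dvec)
        can_snk = snooker & (norm2 > 0)
        if can_snk.any():
            gam_s = rng.uniform(1.2, 2.2, n_chains)
            safe_norm2 = np.where(norm2 > 0, norm2, 1.0)
            s_proj = np.einsum("ij,ij->i", z1 - z2, dvec) / safe_norm2
            prop_snk = x + (gam_s * s_proj)[:, None] * dvec
            num2 = np.einsum(
                "ij,ij->i", prop_snk - zp, prop_snk - zp
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = 0.5 * (d - 1) * (np.log(num2) - np.log(safe_norm2))
            prop = np.where(can_snk[:, None], prop_snk, prop)
            log_corr = np.where(can_snk, corr, log_corr)

        lp_prop = log_post(prop)
        with np.errstate(invalid="ignore"):
            log_alpha = lp_prop - lp_x + log_corr
        accept = np.log(rng.random(n_chains)) < log_alpha
        x = np.where(accept[:, None], prop, x)
        lp_x = np.where(accept, lp_prop, lp_x)
        n_accept += int(accept.sum())
        accept_window += int(accept.sum())
        chains[:, it, :] = x

        if (it + 1) % k_thin == 0:
            z[z_len : z_len + n_chains] = x
            z_len += n_chains
        if (it + 1) % window == 0:
            if accept_window == 0:
                warnings.warn(
                    "DE-MCzs: zero acceptances over the last "
                    f"{window} generations; consider widening priors, "
                    "rescaling the data, or increasing iterations",
                    RuntimeWarning,
                    stacklevel=2,
                )
            accept_window = 0

    return chains, n_accept / (iters * n_chains)


def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Per-parameter Gelman–Rubin R̂ from (n_chains, n, d) samples.

    R̂ = sqrt(((n−1)/n·W + B/n)/W) with W the mean within-chain variance
    and B = n·var(chain means).  Parameters with zero within-chain
    variance come back NaN (undefined).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 3 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("gelman_rubin: need (>=2 chains, >=2 samples, d) array")
    n = chains.shape[1]
    w = np.mean(np.var(chains, axis=1, ddof=1), axis=0)
    b_over_n = np.var(np.mean(chains, axis=1), axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(((n - 1) / n * w + b_over_n) / w)
    return np.where(w > 0, rhat, np.nan)


def calibrate(
    model: ResponseModel,
    x: np.ndarray,
    y: np.ndarray,
    priors: PriorSpec,
    config: CalibrationConfig | None = None,
    sigma: float | None = None,
    provenance: list[str] | None = None,
) -> PosteriorSet:
    """Calibrate a response model on (x, y) data; returns the posterior.

    ``priors`` must cover the model parameters plus ``sigma`` last
    (unless ``sigma`` is fixed).  Non-convergence (any R̂ above the
    threshold) is flagged on the result and logged, never silently
    accepted.
    """
    if config is None:
        config = CalibrationConfig()
    expected = len(model.param_names) + (0 if sigma is not None else 1)
    if len(priors) != expected:
        raise ValueError(
            f"calibrate: prior has {len(priors)} parameters, model needs {expected}"
        )
    logp = make_log_posterior(model, x, y, priors, sigma)
    chains, acc = demczs_sample(logp, priors, config)
    kept = chains[:, config.burn_in :, :]
    rhat = gelman_rubin(kept)
    post = PosteriorSet(
        param_names=list(priors.names),
        chains=kept,
        rhat=rhat,
        rhat_threshold=config.rhat_threshold,
        provenance=provenance or [],
        acceptance_rate=acc,
    )
    if not post.converged:
        logger.warning(
            "calibration of %s not converged: R-hat = %s (threshold %.2f)",
            model.name, np.round(rhat, 3), config.rhat_threshold,
        )
    return post


# ---------------------------------------------------------------------------
# posterior operations
# ---------------------------------------------------------------------------

def merge_posteriors(units: Sequence[PosteriorSet]) -> PosteriorSet:
    """Equal-weight merge of per-unit posteriors (e.g. per tree -> treatment).

    Each unit's flat posterior is subsampled (evenly spaced, hence
    deterministic) to the minimum unit length and the pieces are
    concatenated.  Units that failed convergence are merged anyway but
    with a warning, and the merged set records the overall flag.
    """
    if not units:
        raise ValueError("merge_posteriors: no posteriors given")
    names = units[0].param_names
    for u in units[1:]:
        if u.param_names != names:
            raise ValueError("merge_posteriors: mismatched parameter sets")
    not_conv = [u.provenance for u in units if not u.converged]
    if not_conv:
        warnings.warn(
            f"merging non-converged posteriors (units {not_conv})",
            RuntimeWarning,
            stacklevel=2,
        )
    flats = [u.flat_samples() for u in units]
    n_min = min(f.shape[0] for f in flats)
    pieces = []
    for f in flats:
        take = np.linspace(0, f.shape[0] - 1, n_min).round().astype(int)
        pieces.append(f[take])
    merged = np.concatenate(pieces, axis=0)
    return PosteriorSet(
        param_names=list(names),
        samples=merged,
        merged=True,
        provenance=[p for u in units for p in u.provenance],
        unit_converged=all(u.converged for u in units),
    )


def credible_interval(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval from posterior samples."""
    samples = np.asarray(samples, dtype=float)
    if not 0 < level < 1:
        raise ValueError("credible_interval: level must lie in (0, 1)")
    if samples.size < 100:
        raise ValueError("credible_interval: need >= 100 samples")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def ci_overlap_decision(ci_a: tuple[float, float], ci_b: tuple[float, float]) -> bool:
    """True iff the two intervals are disjoint (a meaningful difference)."""
    (lo_a, hi_a), (lo_b, hi_b) = ci_a, ci_b
    if lo_a > hi_a or lo_b > hi_b:
        raise ValueError("ci_overlap_decision: malformed interval")
    return hi_a < lo_b or hi_b < lo_a


def posterior_predictive(
    model: ResponseModel,
    posterior: PosteriorSet,
    predictor_grid: np.ndarray,
    draws: int = 5_000,
    ci_level: float = 0.95,
    rng: np.random.Generator | None = None,
):
    """Median and equal-tailed CI band of the model over a predictor grid.

    Parameter vectors are drawn from the posterior with replacement and
    pushed through ``model.predict``; measurement noise is not added
    (the band reflects parameter uncertainty, as in the study's posterior
    predictive plots).  Grid points yielding non-finite predictions come
    back NaN.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    flat = posterior.flat_samples()
    if flat.shape[0] == 0:
        raise ValueError("posterior_predictive: empty posterior")
    idx = rng.integers(0, flat.shape[0], size=draws)
    theta = flat[idx, : len(model.param_names)]
    pred = model.predict(theta, np.asarray(predictor_grid, dtype=float))
    pred = np.where(np.isfinite(pred), pred, np.nan)
    alpha = (1.0 - ci_level) / 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        median = np.nanmedian(pred, axis=0)
        lo = np.nanquantile(pred, alpha, axis=0)
        hi = np.nanquantile(pred, 1.0 - alpha, axis=0)
    return median, lo, hi
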