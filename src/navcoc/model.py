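"""Hierarchical Bayes state-space model of navigation ability.

For animal j with signed daily cross-track deviations y_{j,t} (km) the model
is

    y_{j,t} = x_{j,t} + eps_{j,t},            eps ~ N(0, sigma_eps^2)
    x_{j,t} = gamma_j x_{j,t-1} + sigma_j e_t, e_t ~ t_nu

with the latent x the animal's best guess of its position relative to its
intended great-circle route. The circle of confusion — the radius within
which the animal cannot resolve its own position — is the stationary scale
of this AR(1):

    CoC_j = sigma_j / sqrt(1 - gamma_j^2).

Individual (gamma_j, sigma_j) are exchangeable across animals: gamma_j =
2 v_j - 1 with v_j ~ Beta(a, b), sigma_j ~ N(theta, tau^2) truncated to
sigma > 0, with uniform hyper-priors; nu has a uniform prior and sigma_eps
an informative normal prior (default mean 2 km, SD 0.02 km, reflecting
Argos-class measurement error after robust daily regularization). Note that
sigma_j is the *scale* of the t shock, not its standard deviation — the
fitted nu is routinely small enough (< 2) that the t variance does not
exist, so the CoC is defined on the scale; a variance-corrected variant is
available when nu > 2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln, log_ndtr
from sklearn.base import BaseEstimator

from . import _sampler
from .geometry import DeviationSeries

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "CircleOfConfusionModel",
    "coc_radius",
    "coc_interval",
    "predictive_coc",
    "summarize",
    "log_joint",
]

QUANTILES = (2.5, 50.0, 97.5)


@dataclass(frozen=True)
class PriorSpec:
    """Prior and hyper-prior specification (km units throughout).

    ``sigma_eps_prior`` is (mean, sd) of a normal truncated at 0; the
    remaining fields are uniform bounds for the hyper-parameters and nu.
    """

    sigma_eps_prior: tuple[float, float] = (2.0, 0.02)
    # a up to 500: the beta prior for v = (gamma+1)/2 must be able to
    # concentrate near v ~ 0.99 (gamma ~ 0.98), which needs a + b in the
    # hundreds; a cap of ~20 would exclude the high-autocorrelation regime
    # the model exists to measure. b >= 1 keeps the density bounded at
    # gamma = 1, where the near-unit-root likelihood is otherwise flat.
    a_range: tuple[float, float] = (1.0, 500.0)
    b_range: tuple[float, float] = (1.0, 20.0)
    theta_range: tuple[float, float] = (0.0, 50.0)
    tau_range: tuple[float, float] = (0.01, 50.0)
    nu_range: tuple[float, float] = (1.5, 50.0)

    def __post_init__(self) -> None:
        if self.sigma_eps_prior[1] <= 0:
            raise ValueError("sigma_eps prior sd must be positive")
        for name in ("a_range", "b_range", "theta_range", "tau_range", "nu_range"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"{name} must be finite with lower < upper")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain protocol: default 2 chains of 40,000, burn-in 20,000, thin 5."""

    n_chains: int = 2
    n_iter: int = 40_000
    n_burnin: int = 20_000
    thin: int = 5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return self.n_chains * ((self.n_iter - self.n_burnin) // self.thin)


def coc_radius(sigma_j, gamma_j):
    """Circle-of-confusion radius sigma / sqrt(1 - gamma^2), km."""
    sigma_j = np.asarray(sigma_j, dtype=float)
    gamma_j = np.asarray(gamma_j, dtype=float)
    if np.any(np.abs(gamma_j) >= 1.0):
        raise ValueError("|gamma| must be < 1 (stationarity)")
    if np.any(sigma_j <= 0):
        raise ValueError("sigma must be positive")
    out = sigma_j / np.sqrt(1.0 - gamma_j**2)
    return float(out) if out.ndim == 0 else out


def coc_interval(coc: float, level: float = 0.95) -> float:
    """Half-width of the level-% positional interval: z_{(1+level)/2} * CoC."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if coc <= 0:
        raise ValueError("coc must be positive")
    return float(stats.norm.ppf((1.0 + level) / 2.0) * coc)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws (chain-major) plus derived CoC quantities.

    Individual-level arrays have shape (chains, draws, J); hyper-parameters
    (chains, draws, G) with one column per group; nu and sigma_eps
    (chains, draws). Latent paths, when stored, are a list of
    (chains, draws, T_j) arrays.
    """

    gamma: np.ndarray
    sigma: np.ndarray
    a: np.ndarray
    b: np.ndarray
    theta: np.ndarray
    tau: np.ndarray
    nu: np.ndarray
    sigma_eps: np.ndarray
    animal_ids: list[str]
    groups: np.ndarray
    group_names: list[str]
    hierarchical: bool = True
    x: Optional[list[np.ndarray]] = None

    @property
    def n_chains(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_draws(self) -> int:
        """Total retained draws over all chains."""
        return self.gamma.shape[0] * self.gamma.shape[1]

    @property
    def n_animals(self) -> int:
        return self.gamma.shape[2]

    @property
    def coc(self) -> np.ndarray:
        """Per-animal CoC draws, shape (chains, draws, J)."""
        return self.sigma / np.sqrt(1.0 - self.gamma**2)

    def coc_corrected(self) -> np.ndarray:
        """Variance-corrected CoC sqrt(nu/(nu-2)) * CoC (NaN where nu <= 2)."""
        fac = np.sqrt(np.where(self.nu > 2.0, self.nu / (self.nu - 2.0), np.nan))
        return fac[..., None] * self.coc

    def coc_mean(self, group: Optional[int] = None) -> np.ndarray:
        """Per-draw mean CoC over animals (optionally within one group)."""
        coc = self.coc
        if group is None:
            return coc.mean(axis=2)
        return coc[..., self.groups == group].mean(axis=2)

    def flat(self, arr: np.ndarray) -> np.ndarray:
        """Collapse the chain axis: (C, D, ...) -> (C*D, ...)."""
        return arr.reshape(-1, *arr.shape[2:]) if arr.ndim > 2 else arr.reshape(-1)


def predictive_coc(samples: PosteriorSamples, seed=None, group: int = 0) -> np.ndarray:
    """Posterior predictive CoC draws for an unobserved individual.

    For each retained draw a new animal's gamma* = 2 Beta(a, b) - 1 and
    sigma* ~ N(theta, tau^2) truncated at 0 are sampled from that draw's
    hyper-parameters; the result is the induced distribution of CoC for an
    animal exchangeable with those observed.
    """
    if not samples.hierarchical:
        raise ValueError("predictive CoC requires a hierarchical fit")
    rng = np.random.default_rng(seed)
    a = samples.flat(samples.a)[:, group]
    b = samples.flat(samples.b)[:, group]
    theta = samples.flat(samples.theta)[:, group]
    tau = samples.flat(samples.tau)[:, group]
    gamma_star = 2.0 * rng.beta(a, b) - 1.0
    alpha = -theta / tau  # lower tail bound in standard units
    u = rng.uniform(stats.norm.cdf(alpha), 1.0)
    sigma_star = theta + tau * stats.norm.ppf(u)
    sigma_star = np.clip(sigma_star, 1e-12, None)
    return sigma_star / np.sqrt(1.0 - gamma_star**2)


def summarize(samples: PosteriorSamples, seed: int = 0) -> pd.DataFrame:
    """Posterior 2.5/50/97.5% quantile table for all key parameters.

    Rows cover, per group: hierarchical mean CoC, the predictive ("new
    animal") CoC and gamma, hyper-parameters; shared sigma_eps and nu; and
    each animal's CoC, gamma and sigma.
    """
    rows: dict[str, np.ndarray] = {}
    G = samples.a.shape[2]
    for g in range(G):
        tag = f"[{samples.group_names[g]}]" if G > 1 else ""
        rows[f"coc_mean{tag}"] = samples.coc_mean(g if G > 1 else None).reshape(-1)
        if samples.hierarchical:
            rows[f"coc_pred*{tag}"] = predictive_coc(samples, seed=seed, group=g)
            for name, arr in (("a", samples.a), ("b", samples.b),
                              ("theta", samples.theta), ("tau", samples.tau)):
                rows[f"{name}{tag}"] = samples.flat(arr)[:, g]
    rows["sigma_eps"] = samples.flat(samples.sigma_eps)
    nu_flat = samples.flat(samples.nu)
    if np.all(np.isfinite(nu_flat)):
        rows["nu"] = nu_flat
    coc = samples.flat(samples.coc)
    gam = samples.flat(samples.gamma)
    sig = samples.flat(samples.sigma)
    for j, aid in enumerate(samples.animal_ids):
        rows[f"coc[{aid}]"] = coc[:, j]
        rows[f"gamma[{aid}]"] = gam[:, j]
        rows[f"sigma[{aid}]"] = sig[:, j]
    table = pd.DataFrame(
        {
            "parameter": list(rows),
            "2.5%": [np.percentile(v, QUANTILES[0]) for v in rows.values()],
            "50%": [np.percentile(v, QUANTILES[1]) for v in rows.values()],
            "97.5%": [np.percentile(v, QUANTILES[2]) for v in rows.values()],
        }
    )
    return table.set_index("parameter")


def _t_logpdf(e, scale, nu):
    if math.isinf(nu):
        return stats.norm.logpdf(e, scale=scale)
    return stats.t.logpdf(e, df=nu, scale=scale)


def log_joint(
    params: dict,
    data: Sequence[DeviationSeries | np.ndarray],
    priors: PriorSpec,
    groups: Optional[np.ndarray] = None,
    init_state: tuple = ("data", 10.0),
) -> float:
    """Log joint density of states, parameters and data under the model.

    ``params`` holds per-animal arrays ``gamma``, ``sigma`` and latent paths
    ``x`` (list of arrays), hyper-parameters ``a b theta tau`` (scalars or
    per-group arrays), ``nu`` and ``sigma_eps``. Returns -inf outside the
    support. The process terms use the marginal scaled-t density (the sampler
    uses the equivalent normal scale-mixture representation).
    """
    ys = [np.asarray(getattr(d, "values_km", d), dtype=float) for d in data]
    J = len(ys)
    groups = np.zeros(J, dtype=int) if groups is None else np.asarray(groups)
    gamma = np.atleast_1d(np.asarray(params["gamma"], dtype=float))
    sigma = np.atleast_1d(np.asarray(params["sigma"], dtype=float))
    xlist = [np.asarray(x, dtype=float) for x in params["x"]]
    if len(xlist) != J or any(len(x) != len(y) for x, y in zip(xlist, ys)):
        raise ValueError("state series must match data series lengths")
    nu = float(params["nu"])
    sigma_eps = float(params["sigma_eps"])
    G = int(groups.max()) + 1
    a = np.broadcast_to(np.atleast_1d(params["a"]), (G,)).astype(float)
    b = np.broadcast_to(np.atleast_1d(params["b"]), (G,)).astype(float)
    theta = np.broadcast_to(np.atleast_1d(params["theta"]), (G,)).astype(float)
    tau = np.broadcast_to(np.atleast_1d(params["tau"]), (G,)).astype(float)

    def _in(v, lo, hi):
        return lo <= v <= hi

    if (
        np.any(np.abs(gamma) >= 1.0)
        or np.any(sigma <= 0)
        or sigma_eps <= 0
        or not all(_in(a[g], *priors.a_range) for g in range(G))
        or not all(_in(b[g], *priors.b_range) for g in range(G))
        or not all(_in(theta[g], *priors.theta_range) for g in range(G))
        or not all(_in(tau[g], *priors.tau_range) for g in range(G))
        or not (_in(nu, *priors.nu_range) or math.isinf(nu))
    ):
        return -math.inf

    lp = 0.0
    mu_eps, sd_eps = priors.sigma_eps_prior
    sigma_eps_f = max(sigma_eps, 1e-12)
    for j in range(J):
        y, x = ys[j], xlist[j]
        mask = np.isfinite(y)
        # observation terms
        lp += float(np.sum(stats.norm.logpdf(y[mask], loc=x[mask], scale=sigma_eps_f)))
        # initial state
        if init_state[0] == "stationary":
            fac = nu / (nu - 2.0) if (math.isfinite(nu) and nu > 2.0) else 1.0
            m0 = 0.0
            sd0 = sigma[j] * math.sqrt(fac / (1.0 - gamma[j] ** 2))
        elif init_state[0] == "data":
            first = np.flatnonzero(mask)
            m0 = y[first[0]] if len(first) else 0.0
            sd0 = init_state[1] * mu_eps
        else:
            m0, sd0 = init_state[1], init_state[2]
        lp += float(stats.norm.logpdf(x[0], loc=m0, scale=sd0))
        # process terms
        e = x[1:] - gamma[j] * x[:-1]
        lp += float(np.sum(_t_logpdf(e, sigma[j], nu)))
        # individual-level priors
        g = groups[j]
        v = (gamma[j] + 1.0) / 2.0
        lp += (a[g] - 1.0) * math.log(v) + (b[g] - 1.0) * math.log(1.0 - v)
        lp += -betaln(a[g], b[g]) - math.log(2.0)  # Jacobian of gamma = 2v - 1
        lp += (
            -0.5 * math.log(2.0 * math.pi)
            - math.log(tau[g])
            - 0.5 * ((sigma[j] - theta[g]) / tau[g]) ** 2
            - log_ndtr(theta[g] / tau[g])
        )
    # sigma_eps prior (truncated normal) and uniform hyper-priors
    lp += float(
        stats.norm.logpdf(sigma_eps, mu_eps, sd_eps) - log_ndtr(mu_eps / sd_eps)
    )
    for lo, hi in (priors.a_range, priors.b_range, priors.theta_range, priors.tau_range):
        lp -= G * math.log(hi - lo)
    if not math.isinf(nu):
        lp -= math.log(priors.nu_range[1] - priors.nu_range[0])
    return lp


class CircleOfConfusionModel(BaseEstimator):
    """Hierarchical Bayes AR(1) state-space estimator of navigation ability.

    Fit to a collection of signed cross-track deviation series (one per
    animal); yields posterior draws of every individual parameter, the
    hyper-parameters and the derived circle-of-confusion radii.

    Parameters
    ----------
    grouping : {"common", "by_sex"}
        Pool all animals under one hyper-distribution, or give each sex its
        own (a, b, theta, tau) with nu and sigma_eps shared.
    priors : PriorSpec or None
        Prior specification; None uses the defaults.
    n_chains, n_iter, n_burnin, thin : int
        MCMC protocol; defaults reproduce 2 x (40,000 - 20,000) / 5 = 8,000
        retained draws.
    seed : int or None
        Master seed; fans out deterministically to per-chain streams.
    nu : float or None
        None estimates the t degrees of freedom; ``np.inf`` fixes Gaussian
        process errors; a finite value fixes nu.
    hierarchical : bool
        False replaces the hyper-parameter layer with fixed values
        (``fixed_hypers``) — used for single-animal fits and validation.
    fixed_gamma, fixed_sigma_eps : float or None
        Optionally pin gamma (all animals) or the measurement SD.
    init_state : tuple
        ("stationary",): x_1 ~ N(0, sigma_j^2 (nu/(nu-2)) / (1 - gamma_j^2)),
        the stationary Gaussian approximation (default; ties the initial
        state to the AR parameters and penalizes the near-unit-root
        likelihood plateau); ("data", c): x_1 ~ N(y_1, (c * prior-mean
        sigma_eps)^2); ("fixed", m, sd): x_1 ~ N(m, sd^2).
    store_states : bool
        Keep latent-path draws (needed for posterior predictive loss).

    Attributes
    ----------
    samples_ : PosteriorSamples
    summary_ : pandas.DataFrame of 2.5/50/97.5% quantiles
    rhat_ : dict of split-chain R-hat per parameter block
    coc_median_ : per-animal posterior median CoC (km)
    """

    def __init__(
        self,
        grouping: str = "common",
        priors: Optional[PriorSpec] = None,
        n_chains: int = 2,
        n_iter: int = 40_000,
        n_burnin: int = 20_000,
        thin: int = 5,
        seed: Optional[int] = None,
        nu: Optional[float] = None,
        hierarchical: bool = True,
        fixed_hypers: Optional[dict] = None,
        fixed_gamma: Optional[float] = None,
        fixed_sigma_eps: Optional[float] = None,
        init_state: tuple = ("stationary",),
        store_states: bool = True,
        rhat_threshold: float = 1.1,
    ):
        self.grouping = grouping
        self.priors = priors
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.n_burnin = n_burnin
        self.thin = thin
        self.seed = seed
        self.nu = nu
        self.hierarchical = hierarchical
        self.fixed_hypers = fixed_hypers
        self.fixed_gamma = fixed_gamma
        self.fixed_sigma_eps = fixed_sigma_eps
        self.init_state = init_state
        self.store_states = store_states
        self.rhat_threshold = rhat_threshold

    # -- helpers -----------------------------------------------------------
    def _coerce(self, X) -> tuple[list[np.ndarray], list[np.ndarray], list[str], list[str]]:
        ys, masks, ids, sexes = [], [], [], []
        for i, d in enumerate(X):
            y = np.asarray(getattr(d, "values_km", d), dtype=float)
            if y.ndim != 1:
                raise ValueError("each deviation series must be 1-D")
            if len(y) < 5:
                raise ValueError("each series must have length >= 5")
            ys.append(y)
            masks.append(np.isfinite(y))
            ids.append(str(getattr(d, "animal_id", "") or f"animal{i}"))
            sexes.append(str(getattr(d, "sex", "unknown")))
        return ys, masks, ids, sexes

    def fit(self, X: Sequence[DeviationSeries | np.ndarray], y=None):
        """Run the MCMC on a list of deviation series; returns self."""
        if len(X) < 1:
            raise ValueError("need at least one deviation series")
        ys, masks, ids, sexes = self._coerce(X)
        if self.grouping == "by_sex":
            group_names = sorted(set(sexes))
            groups = np.array([group_names.index(s) for s in sexes])
        elif self.grouping == "common":
            group_names = ["all"]
            groups = np.zeros(len(ys), dtype=int)
        else:
            raise ValueError("grouping must be 'common' or 'by_sex'")
        priors = self.priors or PriorSpec()
        cfg = MCMCConfig(self.n_chains, self.n_iter, self.n_burnin, self.thin, self.seed)

        seed_seq = np.random.SeedSequence(self.seed)
        chain_seeds = seed_seq.spawn(cfg.n_chains)
        chains = [
            _sampler.run_chain(
                ys,
                masks,
                groups,
                len(group_names),
                priors,
                cfg.n_iter,
                cfg.n_burnin,
                cfg.thin,
                chain_seeds[c],
                hierarchical=self.hierarchical,
                fixed_hypers=self.fixed_hypers,
                fixed_gamma=self.fixed_gamma,
                fixed_sigma_eps=self.fixed_sigma_eps,
                nu=self.nu,
                init_state=self.init_state,
                store_states=self.store_states,
            )
            for c in range(cfg.n_chains)
        ]
        stack = lambda key: np.stack([ch[key] for ch in chains])
        xs = None
        if self.store_states:
            xs = [
                np.stack([ch["x"][j] for ch in chains]) for j in range(len(ys))
            ]
        self.samples_ = PosteriorSamples(
            gamma=stack("gamma"),
            sigma=stack("sigma"),
            a=stack("a"),
            b=stack("b"),
            theta=stack("theta"),
            tau=stack("tau"),
            nu=stack("nu"),
            sigma_eps=stack("sigma_eps"),
            animal_ids=ids,
            groups=groups,
            group_names=group_names,
            hierarchical=self.hierarchical,
            x=xs,
        )
        self.priors_ = priors
        self.config_ = cfg
        self.data_ = ys
        self.obs_masks_ = masks
        self.rhat_ = self._compute_rhat()
        bad = {k: v for k, v in self.rhat_.items() if np.any(np.asarray(v) > self.rhat_threshold)}
        if bad and cfg.n_chains > 1:
            warnings.warn(
                "split-chain R-hat above "
                f"{self.rhat_threshold} for: "
                + ", ".join(f"{k}={np.max(v):.3f}" for k, v in bad.items()),
                stacklevel=2,
            )
        self.summary_ = summarize(
            self.samples_, seed=int(seed_seq.generate_state(1)[0] % 2**31)
        )
        self.coc_median_ = np.median(self.samples_.flat(self.samples_.coc), axis=0)
        return self

    def _compute_rhat(self) -> dict:
        import arviz as az

        s = self.samples_
        out = {}
        if s.n_chains < 2:  # split-chain diagnostic needs >= 2 chains
            return out
        blocks = {"gamma": s.gamma, "sigma": s.sigma, "sigma_eps": s.sigma_eps}
        if self.hierarchical:
            blocks.update(a=s.a, b=s.b, theta=s.theta, tau=s.tau)
        if self.nu is None:
            blocks["nu"] = s.nu
        for name, arr in blocks.items():
            if not np.all(np.isfinite(arr)):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = az.rhat(az.convert_to_dataset(arr[:, :, None] if arr.ndim == 2 else arr))
            out[name] = np.asarray(r.to_array()).ravel()
        return out

    # -- derived quantities -------------------------------------------------
    def predictive_coc(self, seed=None, group: int = 0) -> np.ndarray:
        return predictive_coc(self.samples_, seed=seed, group=group)

    def coc_summary(self) -> pd.DataFrame:
        """Per-animal CoC posterior quantiles."""
        coc = self.samples_.flat(self.samples_.coc)
        return pd.DataFrame(
            {
                "animal_id": self.samples_.animal_ids,
                "2.5%": np.percentile(coc, 2.5, axis=0),
                "50%": np.percentile(coc, 50.0, axis=0),
                "97.5%": np.percentile(coc, 97.5, axis=0),
            }
        )
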