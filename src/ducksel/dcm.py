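"""Bayesian mixed (random-effects) conditional logit for discrete choice.

Each animal i carries its own coefficient vector beta_i over the unit-level
covariates; the probability that it picks unit j from choice set C_n is

    P(j | C_n, beta_i) = exp(x_j' beta_i) / sum_{l in C_n} exp(x_l' beta_i).

The hierarchy is beta_{i,k} ~ Normal(mu_k, sigma_k^2) with weakly
informative hyperpriors mu_k ~ Normal(0, 2.786) (variance) and sigma_k ~
half-t(scale 2, df 3). Population inference is on mu_k: a variable is
*important* when the 95% credible interval of mu_k excludes zero.
Candidate models are ranked by DIC with differences of at most 5 treated
as competitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .catalog import RESOURCE_CLASSES, RISK_TIERS, VariableCatalog
from .choiceset import ChoiceSetCollection

MODEL_NAMES = ("random", "risk", "resource", "full")

DELTA_DIC_COMPETITIVE = 5.0
RHAT_THRESHOLD = 1.1


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------


@dataclass
class ChoiceData:
    """Stacked, padded choice sets ready for likelihood evaluation.

    ``X`` is (n_sets, max_alternatives, n_vars) with the used alternative at
    index 0; ``mask`` flags real alternatives; ``animal`` maps each set to an
    animal index.
    """

    X: np.ndarray
    mask: np.ndarray
    animal: np.ndarray
    animal_ids: list
    var_names: list[str]

    def __post_init__(self) -> None:
        if self.X.ndim != 3 or self.mask.shape != self.X.shape[:2]:
            raise ValueError("X must be (sets, alternatives, vars) with matching mask")
        if not self.mask[:, 0].all():
            raise ValueError("every set needs its used alternative at index 0")

    @property
    def n_sets(self) -> int:
        return self.X.shape[0]

    @property
    def n_vars(self) -> int:
        return self.X.shape[2]

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def set_sizes(self) -> np.ndarray:
        return self.mask.sum(axis=1)

    def fingerprint(self) -> tuple:
        return (self.n_sets, int(self.mask.sum()), tuple(self.animal.tolist()))

    @classmethod
    def from_frames(
        cls, sets: pd.DataFrame, units: pd.DataFrame, var_names: list[str]
    ) -> "ChoiceData":
        """Build from long-format frames (one unit row per alternative)."""
        animal_ids = sorted(sets["animal_id"].unique().tolist())
        a_index = {a: i for i, a in enumerate(animal_ids)}
        sizes = units.groupby("set_id").size()
        set_order = sets["set_id"].to_numpy()
        jmax = int(sizes.max())
        n = len(set_order)
        X = np.zeros((n, jmax, len(var_names)))
        mask = np.zeros((n, jmax), dtype=bool)
        grouped = dict(tuple(units.groupby("set_id")))
        for row, sid in enumerate(set_order):
            g = grouped[sid]
            # used unit first
            order = np.argsort(1 - g["used"].to_numpy(), kind="stable")
            vals = g[var_names].to_numpy(dtype=float)[order]
            X[row, : len(g)] = vals
            mask[row, : len(g)] = True
            if g["used"].sum() != 1:
                raise ValueError(f"set {sid} must have exactly one used unit")
        animal = np.array([a_index[a] for a in sets["animal_id"]])
        return cls(X, mask, animal, animal_ids, list(var_names))

    @classmethod
    def from_collection(cls, coll: ChoiceSetCollection, var_names: list[str] | None = None) -> "ChoiceData":
        return cls.from_frames(coll.sets, coll.units, var_names or coll.var_names)


# ---------------------------------------------------------------------------
# Candidate model designs
# ---------------------------------------------------------------------------


def candidate_columns(
    units: pd.DataFrame,
    catalog: VariableCatalog,
    model: str,
    retained: list[str] | None = None,
) -> pd.DataFrame:
    """Unit-level covariate columns (raw ha) for one candidate model.

    random: none; resource: the five foraging-class area totals; risk: the
    hunting-risk tier totals; full: each retained catalog variable.
    """
    retained = retained if retained is not None else catalog.abbreviations
    if model == "random":
        return pd.DataFrame(index=units.index)
    if model == "full":
        return units[retained].copy()
    if model == "resource":
        cols = {}
        for rc in RESOURCE_CLASSES:
            if rc == "other":
                continue
            members = [v.abbreviation for v in catalog if v.resource_class == rc]
            if members:
                cols[rc.replace(" ", "_")] = units[members].sum(axis=1)
        return pd.DataFrame(cols)
    if model == "risk":
        cols = {}
        for tier in RISK_TIERS:
            members = [v.abbreviation for v in catalog if v.risk_tier == tier]
            if members:
                cols[f"risk_{tier}"] = units[members].sum(axis=1)
        return pd.DataFrame(cols)
    raise ValueError(f"unknown candidate model {model!r} (choose from {MODEL_NAMES})")


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _eta(data: ChoiceData, beta_rows: np.ndarray) -> np.ndarray:
    eta = np.einsum("njk,nk->nj", data.X, beta_rows)
    if not data.mask.all():
        eta = np.where(data.mask, eta, -np.inf)
    return eta


def _set_ll_from_eta(eta: np.ndarray) -> np.ndarray:
    # stable log-sum-exp along the last axis; the used slot (index 0 along
    # that axis) is always real so the max is finite
    m = eta.max(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        lse = m[..., 0] + np.log(np.exp(eta - m).sum(axis=-1))
    return eta[..., 0] - lse


def set_logliks(data: ChoiceData, beta: np.ndarray) -> np.ndarray:
    """Per-set log-likelihood for animal-level coefficients beta (A, K)."""
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    if beta.shape != (data.n_animals, data.n_vars):
        raise ValueError(
            f"beta must have shape ({data.n_animals}, {data.n_vars}), got {beta.shape}"
        )
    if data.n_vars == 0:
        return -np.log(data.set_sizes.astype(float))
    return _set_ll_from_eta(_eta(data, beta[data.animal]))


def loglik(data: ChoiceData, beta: np.ndarray) -> float:
    """Total conditional-logit log-likelihood (used unit at index 0), using
    a log-sum-exp evaluation that is stable for |x'beta| up to ~700."""
    return float(set_logliks(data, beta).sum())


def animal_logliks(data: ChoiceData, beta: np.ndarray) -> np.ndarray:
    return np.bincount(data.animal, weights=set_logliks(data, beta), minlength=data.n_animals)


def choice_probabilities(data: ChoiceData, beta: np.ndarray) -> np.ndarray:
    """(n_sets, max_alternatives) probabilities; padded slots are zero."""
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    eta = _eta(data, beta[data.animal])
    p = np.exp(eta - logsumexp(eta, axis=1, keepdims=True))
    return np.where(data.mask, p, 0.0)


# ---------------------------------------------------------------------------
# Priors and MCMC configuration
# ---------------------------------------------------------------------------


@dataclass
class Priors:
    """mu_k ~ Normal(mu_mean, mu_var); sigma_k ~ half-t(scale, df).

    ``mu_var_is_variance`` records whether 2.786 parameterises a variance
    (default) rather than a precision.
    """

    mu_mean: float = 0.0
    mu_var: float = 2.786
    sigma_scale: float = 2.0
    sigma_df: float = 3.0
    mu_var_is_variance: bool = True

    @property
    def mu_variance(self) -> float:
        return self.mu_var if self.mu_var_is_variance else 1.0 / self.mu_var

    def log_half_t(self, sigma: np.ndarray) -> np.ndarray:
        z2 = (sigma / self.sigma_scale) ** 2
        return -0.5 * (self.sigma_df + 1.0) * np.log1p(z2 / self.sigma_df)


@dataclass
class McmcConfig:
    chains: int = 3
    iterations: int = 4000
    burn_in: int = 1500
    thin: int = 1
    seed: int = 0
    target_accept: float = 0.3
    adapt_interval: int = 50
    max_doublings: int = 2  # adaptive run-length doubling until converged

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("R-hat needs at least two chains")
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn-in")


@dataclass
class Posterior:
    """Post-burn-in draws: mu/sigma (chains, draws, K), beta (chains, draws, A, K)."""

    mu: np.ndarray
    sigma: np.ndarray
    beta: np.ndarray
    var_names: list[str]
    animal_ids: list
    accept_beta: float = np.nan
    accept_sigma: float = np.nan

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    def pooled(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------


def sample_posterior(data: ChoiceData, priors: Priors, cfg: McmcConfig) -> Posterior:
    """Adaptive random-walk Metropolis within Gibbs over (beta, mu, sigma).

    beta blocks (one per animal) and log sigma_k move by random-walk
    proposals whose scales adapt toward 20-40% acceptance during burn-in;
    mu_k is drawn from its conditional normal. Deterministic under
    ``cfg.seed`` (per-chain generators are derived from it).
    """
    A, K = data.n_animals, data.n_vars
    n_keep = (cfg.iterations - cfg.burn_in) // cfg.thin
    mu_out = np.empty((cfg.chains, n_keep, K))
    sig_out = np.empty((cfg.chains, n_keep, K))
    beta_out = np.empty((cfg.chains, n_keep, A, K))
    acc_beta_total = acc_sig_total = 0.0

    for chain in range(cfg.chains):
        rng = np.random.default_rng([cfg.seed % (2**31), chain])
        mu = np.zeros(K)
        sigma = np.ones(K)
        beta = mu + 0.1 * rng.standard_normal((A, K))
        ll = animal_logliks(data, beta) if K else np.zeros(A)
        step_beta = np.full(A, 0.3)
        step_lsig = np.full(K, 0.4)
        acc_beta = np.zeros(A)
        acc_sig = np.zeros(K)
        n_acc_windows = 0
        kept = 0
        for it in range(cfg.iterations):
            if K:
                # --- beta: per-animal random-walk block update
                prop = beta + step_beta[:, None] * rng.standard_normal((A, K))
                ll_prop = animal_logliks(data, prop)
                lp_cur = -0.5 * (((beta - mu) / sigma) ** 2).sum(axis=1)
                lp_prop = -0.5 * (((prop - mu) / sigma) ** 2).sum(axis=1)
                accept = np.log(rng.uniform(size=A)) < (ll_prop - ll + lp_prop - lp_cur)
                beta[accept] = prop[accept]
                ll[accept] = ll_prop[accept]
                acc_beta += accept

                # --- mu: conjugate normal conditional
                prec = 1.0 / priors.mu_variance + A / sigma**2
                mean = (beta.sum(axis=0) / sigma**2 + priors.mu_mean / priors.mu_variance) / prec
                mu = mean + rng.standard_normal(K) / np.sqrt(prec)

                # --- sigma: random walk on log sigma
                ss = ((beta - mu) ** 2).sum(axis=0)
                lsig = np.log(sigma)
                lsig_prop = lsig + step_lsig * rng.standard_normal(K)
                sig_prop = np.exp(lsig_prop)

                def logpost_sigma(s: np.ndarray) -> np.ndarray:
                    # includes the log|Jacobian| of the log transform
                    return -A * np.log(s) - ss / (2 * s**2) + priors.log_half_t(s) + np.log(s)

                accept_s = np.log(rng.uniform(size=K)) < logpost_sigma(sig_prop) - logpost_sigma(sigma)
                sigma = np.where(accept_s, sig_prop, sigma)
                acc_sig += accept_s

                # --- adaptation (burn-in only)
                if it < cfg.burn_in and (it + 1) % cfg.adapt_interval == 0:
                    rate_b = acc_beta / cfg.adapt_interval
                    step_beta *= np.exp(np.clip(rate_b - cfg.target_accept, -0.5, 0.5))
                    rate_s = acc_sig / cfg.adapt_interval
                    step_lsig *= np.exp(np.clip(rate_s - cfg.target_accept, -0.5, 0.5))
                    acc_beta[:] = 0
                    acc_sig[:] = 0
                elif it == cfg.burn_in:
                    acc_beta[:] = 0
                    acc_sig[:] = 0
                    n_acc_windows = 0
                if it >= cfg.burn_in:
                    n_acc_windows += 1

            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and kept < n_keep:
                mu_out[chain, kept] = mu
                sig_out[chain, kept] = sigma
                beta_out[chain, kept] = beta
                kept += 1
        if K and n_acc_windows:
            acc_beta_total += acc_beta.mean() / n_acc_windows
            acc_sig_total += acc_sig.mean() / n_acc_windows

    return Posterior(
        mu_out,
        sig_out,
        beta_out,
        list(data.var_names),
        list(data.animal_ids),
        accept_beta=acc_beta_total / cfg.chains,
        accept_sigma=acc_sig_total / cfg.chains,
    )


# ---------------------------------------------------------------------------
# Convergence
# ---------------------------------------------------------------------------


def gelman_rubin(chains: np.ndarray) -> np.ndarray | float:
    """Potential scale reduction factor sqrt(V_hat / W).

    ``chains`` is (n_chains, n_draws) or (n_chains, n_draws, n_params);
    V_hat = (n-1)/n W + B/n with W the mean within-chain variance and B/n the
    variance of chain means. Degenerate (zero within-variance) chains are
    rejected.
    """
    arr = np.asarray(chains, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[..., None]
    m, n = arr.shape[:2]
    if m < 2 or n < 10:
        raise ValueError("need >= 2 chains of length >= 10")
    w = arr.var(axis=1, ddof=1).mean(axis=0)
    if np.any(w == 0):
        raise ValueError("zero within-chain variance (degenerate chains)")
    b_over_n = arr.mean(axis=1).var(axis=0, ddof=1)
    v_hat = (n - 1) / n * w + b_over_n
    rhat = np.sqrt(v_hat / w)
    return float(rhat[0]) if squeeze else rhat


def convergence_rhats(post: Posterior) -> dict[str, np.ndarray]:
    out = {}
    if post.mu.shape[2]:
        out["mu"] = gelman_rubin(post.mu)
        out["sigma"] = gelman_rubin(post.sigma)
    return out


def converged(post: Posterior, threshold: float = RHAT_THRESHOLD) -> bool:
    rhats = convergence_rhats(post)
    return all(np.all(v < threshold) for v in rhats.values()) if rhats else True


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------


def null_dic(data: ChoiceData) -> float:
    """Closed-form DIC of the no-covariate (random choice) model:
    deviance is constant at 2 sum_n ln|C_n| and pD = 0."""
    return float(2.0 * np.log(data.set_sizes.astype(float)).sum())


def dic(post: Posterior, data: ChoiceData) -> dict[str, float]:
    """Deviance information criterion from individual-level coefficients.

    D = -2 log L(beta); Dbar averages D over draws; the plug-in deviance uses
    the posterior means of each animal's beta_i; pD = Dbar - D(beta_bar).
    """
    if data.n_vars == 0:
        d = 2.0 * np.log(data.set_sizes.astype(float)).sum()
        return {"Dbar": float(d), "pD": 0.0, "DIC": float(d)}
    betas = post.pooled("beta")  # (draws, A, K)
    if betas.shape[0] == 0:
        raise ValueError("empty chains")
    use = betas
    if len(betas) > 1500:  # Dbar needs only a representative thinning
        use = betas[np.linspace(0, len(betas) - 1, 1500).astype(int)]
    devs = []
    for d0 in range(0, len(use), 64):
        block = use[d0 : d0 + 64][:, data.animal]  # (b, N, K)
        eta = np.einsum("njk,bnk->bnj", data.X, block)
        if not data.mask.all():
            eta = np.where(data.mask[None], eta, -np.inf)
        devs.append(-2.0 * _set_ll_from_eta(eta).sum(axis=1))
    devs = np.concatenate(devs)
    dbar = float(devs.mean())
    dhat = float(-2.0 * loglik(data, betas.mean(axis=0)))
    pd_ = dbar - dhat
    return {"Dbar": dbar, "pD": pd_, "DIC": dbar + pd_}


def rank_models(results: dict[str, dict], delta_competitive: float = DELTA_DIC_COMPETITIVE) -> pd.DataFrame:
    """Rank candidate models by DIC; competitive iff DIC - min(DIC) <= 5.

    ``results`` maps model name -> {"DIC": float, "fingerprint": hashable};
    all models must have been fitted on identical choice sets.
    """
    if len(results) < 2:
        raise ValueError("need at least two models to rank")
    fps = {r.get("fingerprint") for r in results.values()}
    if len(fps) > 1:
        raise ValueError("models were fitted on different choice sets")
    df = pd.DataFrame(
        [(name, r["DIC"]) for name, r in results.items()], columns=["model", "DIC"]
    ).sort_values("DIC", kind="stable", ignore_index=True)
    df["delta_DIC"] = df["DIC"] - df["DIC"].min()
    df["competitive"] = df["delta_DIC"] <= delta_competitive
    return df


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------


def summarize(post: Posterior, rhats: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Per-variable population summary: posterior mean of mu_k, 95% credible
    interval (2.5/97.5 percentiles of pooled draws), posterior mean sigma_k,
    R-hat, and the importance flag (CrI excludes zero). This is the
    caterpillar-plot table."""
    rhats = rhats if rhats is not None else convergence_rhats(post)
    mu = post.pooled("mu")
    sigma = post.pooled("sigma")
    lo, hi = np.percentile(mu, [2.5, 97.5], axis=0) if mu.size else (np.array([]), np.array([]))
    rows = []
    for k, name in enumerate(post.var_names):
        rows.append(
            {
                "variable": name,
                "mean": mu[:, k].mean(),
                "cri_lo": lo[k],
                "cri_hi": hi[k],
                "sigma_mean": sigma[:, k].mean(),
                "rhat": float(rhats["mu"][k]) if "mu" in rhats else np.nan,
                "important": bool(lo[k] > 0 or hi[k] < 0),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# High-level fit with adaptive run length
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    model: str
    posterior: Posterior
    rhats: dict[str, np.ndarray]
    converged: bool
    dic: dict[str, float]
    summary: pd.DataFrame
    fingerprint: tuple = field(default=())


def fit_model(
    data: ChoiceData,
    model_name: str = "full",
    priors: Priors | None = None,
    cfg: McmcConfig | None = None,
) -> ModelFit:
    """Sample the posterior, doubling the run length until every monitored
    R-hat is below 1.1 or the doubling cap is hit; a non-converged result is
    returned flagged, never silently."""
    priors = priors or Priors()
    cfg = cfg or McmcConfig()
    current = cfg
    post = sample_posterior(data, priors, current)
    rounds = 0
    while not converged(post) and rounds < cfg.max_doublings:
        rounds += 1
        current = McmcConfig(
            chains=cfg.chains,
            iterations=cfg.iterations * 2**rounds,
            burn_in=cfg.burn_in * 2**rounds,
            thin=cfg.thin,
            seed=cfg.seed,
            target_accept=cfg.target_accept,
            adapt_interval=cfg.adapt_interval,
            max_doublings=cfg.max_doublings,
        )
        post = sample_posterior(data, priors, current)
    rhats = convergence_rhats(post)
    return ModelFit(
        model=model_name,
        posterior=post,
        rhats=rhats,
        converged=converged(post),
        dic=dic(post, data),
        summary=summarize(post, rhats),
        fingerprint=data.fingerprint(),
    )
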