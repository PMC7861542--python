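"""Latitudinal migration progression: a Gaussian mixed model of median dates.

Median migration date (day of year, 1 Jan = 1) of each species in each zone
is modelled on zone (numeric 1-4, south to north), the species' seasonal
mean median across zones (to let early and late migrants progress at
different speeds), and their interaction, with species as a random
intercept:

    d50_{s,z} = b0 + b1 * zone_z + b2 * mm_s + b3 * zone_z * mm_s + u_s + e

Spring and autumn are analysed separately.  A positive zone slope in spring
means migration reaches northern zones later; a negative autumn slope means
southbound migration leaves the north earlier.  The response and the
mean-median covariate are centred before fitting, so the intercept is the
grand mean date.

Two fitters are provided: a deterministic REML fit (default) and an MCMC
posterior sampler with the hierarchical Gaussian likelihood, for use when
credible intervals are preferred.  An optional species covariance matrix
(e.g. derived from a phylogeny) can structure the random effects; the
identity is used by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.regression.mixed_linear_model import MixedLM

logger = logging.getLogger(__name__)

TERMS = ("intercept", "zone", "mean_median", "zone:mean_median")


@dataclass
class ProgressionData:
    """Design table for one season's progression analysis."""

    table: pd.DataFrame  # columns: species, zone, median_day, mean_median
    season: str
    species_cov: np.ndarray | None = None  # optional PSD species matrix


@dataclass
class ProgressionFit:
    """Fixed-effect estimates with uncertainty, and variance components."""

    season: str
    method: str
    params: pd.Series  # indexed by TERMS
    conf_int: pd.DataFrame  # columns lower, upper
    pvalues: pd.Series
    sigma2_species: float
    sigma2_resid: float
    n_obs: int
    n_species: int

    def summary_frame(self) -> pd.DataFrame:
        out = self.conf_int.copy()
        out.insert(0, "estimate", self.params)
        out["p"] = self.pvalues
        return out


def build_progression_data(
    summaries, season: str, species_cov: np.ndarray | None = None
) -> ProgressionData:
    """Assemble the design table from phenology summaries of one season.

    Species present in fewer than two zones carry no information about
    progression and are dropped with a warning.
    """
    rows = [
        {"species": s.species, "zone": s.zone, "median_day": s.d50}
        for s in summaries
        if s.season == season
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError(f"no {season} summaries supplied")
    nz = df.groupby("species")["zone"].nunique()
    single = nz[nz < 2].index
    if len(single):
        logger.warning(
            "dropping %d species present in <2 zones: %s",
            len(single), list(single)[:8],
        )
        df = df[~df["species"].isin(single)]
    df["mean_median"] = df.groupby("species")["median_day"].transform("mean")
    return ProgressionData(table=df.reset_index(drop=True), season=season,
                           species_cov=species_cov)


def _design(data: ProgressionData, interaction: bool = True):
    df = data.table
    if df["zone"].nunique() < 2:
        raise ValueError("singular design: all observations are from one zone")
    if df["species"].nunique() < 10:
        logger.warning(
            "only %d species; random-effect variance may be unstable",
            df["species"].nunique(),
        )
    y = df["median_day"].to_numpy(float)
    yc = y - y.mean()
    zc = df["zone"].to_numpy(float) - df["zone"].to_numpy(float).mean()
    mm = df["mean_median"].to_numpy(float)
    mmc = mm - mm.mean()
    cols = [np.ones_like(yc), zc, mmc]
    if interaction:
        cols.append(zc * mmc)
    X = np.column_stack(cols)
    species, sp_idx = np.unique(df["species"], return_inverse=True)
    Z = np.zeros((len(df), len(species)))
    Z[np.arange(len(df)), sp_idx] = 1.0
    return yc, X, Z, species, y.mean()


def _reml_general(y, X, Z, C):
    """Profiled REML for  y ~ N(Xb, s2_u Z C Z' + s2_e I).

    The single variance ratio lam = s2_u / s2_e is profiled out through the
    eigendecomposition of K = Z C Z', leaving a 1-D bounded optimisation.
    Supports any positive semi-definite species matrix C.
    """
    n, p = X.shape
    K = Z @ C @ Z.T
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    yt, Xt = U.T @ y, U.T @ X

    def neg_reml(log_lam):
        lam = np.exp(log_lam)
        d = lam * w + 1.0
        Xd = Xt / d[:, None]
        XtVX = Xt.T @ Xd
        XtVy = Xd.T @ yt
        beta = np.linalg.solve(XtVX, XtVy)
        r = yt - Xt @ beta
        quad = float(r @ (r / d))
        s2 = quad / (n - p)
        ll = -0.5 * (
            np.sum(np.log(d)) + (n - p) * np.log(s2)
            + np.linalg.slogdet(XtVX)[1] + (n - p)
        )
        return -ll

    res = optimize.minimize_scalar(neg_reml, bounds=(-12, 12), method="bounded")
    lam = float(np.exp(res.x))
    d = lam * w + 1.0
    Xd = Xt / d[:, None]
    XtVX = Xt.T @ Xd
    beta = np.linalg.solve(XtVX, Xd.T @ yt)
    r = yt - Xt @ beta
    s2_e = float(r @ (r / d)) / (n - p)
    cov_beta = s2_e * np.linalg.inv(XtVX)
    return beta, cov_beta, lam * s2_e, s2_e


def fit_progression(
    data: ProgressionData,
    method: str = "reml",
    seed: int | None = None,
    interaction: bool = True,
    mcmc_iterations: int = 13000,
    mcmc_burn: int = 3000,
    mcmc_thin: int = 10,
) -> ProgressionFit:
    """Fit the progression mixed model.

    Parameters
    ----------
    data
        Output of :func:`build_progression_data`.
    method
        ``"reml"`` (deterministic, default) or ``"mcmc"`` (ensemble sampler
        on the marginal Gaussian likelihood; intervals are 95% credible
        intervals and p-values are two-sided posterior tail probabilities).
    seed
        Random seed for the MCMC fitter; ignored for REML.
    mcmc_iterations, mcmc_burn, mcmc_thin
        Total retained+discarded posterior draws, burn-in draws, and
        thinning factor.
    """
    yc, X, Z, species, _ = _design(data, interaction=interaction)
    n, p = X.shape
    terms = TERMS[:p]

    if method == "mcmc":
        return _fit_mcmc(data, yc, X, Z, species, seed,
                         mcmc_iterations, mcmc_burn, mcmc_thin)
    if method != "reml":
        raise ValueError(f"unknown method {method!r}")

    if data.species_cov is None:
        # standard random-intercept model: statsmodels REML.  The species
        # mean-median covariate often absorbs nearly all between-species
        # variance, pushing the random-effect variance to its zero boundary;
        # the optimizer's boundary warnings are expected there, not failures.
        import warnings as _warnings

        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        groups = data.table["species"].to_numpy()
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            res = MixedLM(yc, X, groups=groups).fit(reml=True)
        beta = np.asarray(res.fe_params)
        cov = np.asarray(res.cov_params())[:p, :p]
        s2_u = float(np.asarray(res.cov_re)[0, 0])
        s2_e = float(res.scale)
    else:
        C = np.asarray(data.species_cov, float)
        if C.shape != (len(species), len(species)):
            raise ValueError(
                f"species covariance must be {len(species)}x{len(species)}, got {C.shape}"
            )
        beta, cov, s2_u, s2_e = _reml_general(yc, X, Z, C)

    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    ci = np.column_stack([beta - 1.96 * se, beta + 1.96 * se])
    return ProgressionFit(
        season=data.season,
        method="reml",
        params=pd.Series(beta, index=terms),
        conf_int=pd.DataFrame(ci, index=terms, columns=["lower", "upper"]),
        pvalues=pd.Series(pvals, index=terms),
        sigma2_species=s2_u,
        sigma2_resid=s2_e,
        n_obs=n,
        n_species=len(species),
    )


def _fit_mcmc(data, yc, X, Z, species, seed, iterations, burn, thin):
    """Ensemble MCMC on the marginal likelihood N(Xb, s2_u Z C Z' + s2_e I)."""
    import emcee

    n, p = X.shape
    terms = TERMS[:p]
    C = (np.eye(len(species)) if data.species_cov is None
         else np.asarray(data.species_cov, float))
    K = Z @ C @ Z.T
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    yt, Xt = U.T @ yc, U.T @ X
    scale = max(yc.std(), 1.0)

    def log_post(theta):
        beta, log_su, log_se = theta[:p], theta[p], theta[p + 1]
        if not (-12 < log_su < 12 and -12 < log_se < 12):
            return -np.inf
        s2_u, s2_e = np.exp(2 * log_su), np.exp(2 * log_se)
        d = s2_u * w + s2_e
        r = yt - Xt @ beta
        ll = -0.5 * (np.sum(np.log(d)) + np.sum(r**2 / d))
        # weak N(0, (100*scale)^2) prior on fixed effects, flat on log-sd
        lp = -0.5 * np.sum((beta / (100.0 * scale)) ** 2)
        return ll + lp

    ndim = p + 2
    nwalkers = 2 * ndim + 2
    rng = np.random.default_rng(seed)
    beta0, _, s2_u0, s2_e0 = _reml_general(yc, X, Z, C)
    center = np.concatenate([
        beta0, [0.5 * np.log(max(s2_u0, 1e-6)), 0.5 * np.log(max(s2_e0, 1e-6))]
    ])
    p0 = center + 0.01 * scale * rng.standard_normal((nwalkers, ndim))
    nsteps = max(int(np.ceil(iterations / nwalkers)), 50)
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_post,
                                    moves=emcee.moves.StretchMove())
    sampler.random_state = np.random.RandomState(seed)
    sampler.run_mcmc(p0, nsteps, progress=False)
    burn_steps = min(int(np.ceil(burn / nwalkers)), nsteps - 1)
    chain = sampler.get_chain(discard=burn_steps, thin=max(thin // nwalkers, 1),
                              flat=True)
    beta_draws = chain[:, :p]
    post_mean = beta_draws.mean(axis=0)
    lo = np.percentile(beta_draws, 2.5, axis=0)
    hi = np.percentile(beta_draws, 97.5, axis=0)
    tail = np.minimum((beta_draws > 0).mean(axis=0), (beta_draws < 0).mean(axis=0))
    pvals = np.clip(2 * tail, 1.0 / len(beta_draws), 1.0)
    s2_u = float(np.exp(2 * chain[:, p]).mean())
    s2_e = float(np.exp(2 * chain[:, p + 1]).mean())
    return ProgressionFit(
        season=data.season,
        method="mcmc",
        params=pd.Series(post_mean, index=terms),
        conf_int=pd.DataFrame(
            np.column_stack([lo, hi]), index=terms, columns=["lower", "upper"]
        ),
        pvalues=pd.Series(pvals, index=terms),
        sigma2_species=s2_u,
        sigma2_resid=s2_e,
        n_obs=n,
        n_species=len(species),
    )
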