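"""Statistical layer: paired nonparametric comparisons, beta regressions on
bounded inbreeding proportions (optionally with a year random intercept via
Laplace-approximate ML), temporal natural-spline models, pre/post-rescue
contrasts, and the pedigree-depth (CGE) analysis.

Responses are inbreeding coefficients in [0, 1); a beta likelihood with
logit-linked mean mu and precision phi is natural for proportions that are
probabilities of identity by descent.  Exact zeros are nudged to a small
constant (< 0.001) before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

ERA_CUT_DEFAULT = 2002


# ---------------------------------------------------------------------------
# analysis join


def build_inbreeding_table(
    ped_table: pd.DataFrame,
    froh: pd.DataFrame | None = None,
    het: pd.DataFrame | None = None,
    era_cut: int = ERA_CUT_DEFAULT,
) -> pd.DataFrame:
    """Join per-individual pedigree, F_ROH and homozygosity statistics.

    ``year`` is the birth year, or the introduction year for translocated
    individuals.  Era: born in or before ``era_cut`` -> pre; born later, or
    translocated (regardless of birth year) -> post.
    """
    df = ped_table.rename(columns={"id": "individual"}).copy()
    year = df["birth_year"].astype(float)
    if "intro_year" in df.columns:
        iy = pd.to_numeric(df["intro_year"], errors="coerce")
        year = year.where(~df["translocated"].astype(bool), iy)
    df["year"] = year
    df["era"] = np.where(
        df["translocated"].astype(bool) | (df["year"] > era_cut), "post", "pre"
    )
    if froh is not None:
        df = df.merge(froh, on="individual", how="left")
    if het is not None:
        df = df.merge(
            het.rename(columns={"o_hom": "o_hom", "f_is": "f_is"}), on="individual", how="left"
        )
    return df


# ---------------------------------------------------------------------------
# paired comparison


@dataclass
class PairedComparison:
    n: int
    wilcoxon_v: float
    wilcoxon_p: float
    kendall_tau: float
    kendall_p: float
    all_zero: bool = False


def paired_comparison(fped: np.ndarray, froh: np.ndarray) -> PairedComparison:
    """Wilcoxon signed-rank on F_PED - F_ROH plus Kendall tau-b.

    V is the sum of ranks of positive differences after dropping exact
    zeros (mid-ranks for ties); the p-value is exact for n <= 25 nonzero
    pairs, otherwise a normal approximation with continuity correction.
    """
    fped = np.asarray(fped, dtype=float)
    froh = np.asarray(froh, dtype=float)
    if len(fped) != len(froh) or len(fped) < 2:
        raise ValueError("need >= 2 paired observations")
    d = fped - froh
    nz = d[d != 0]
    if len(nz) == 0:
        tau, tp = stats.kendalltau(fped, froh)
        return PairedComparison(len(fped), np.nan, np.nan, tau, tp, all_zero=True)
    ranks = stats.rankdata(np.abs(nz))
    v = float(ranks[nz > 0].sum())
    if len(nz) <= 25:
        p = _wilcoxon_exact_p(ranks, v)
    else:
        p = float(
            stats.wilcoxon(nz, alternative="two-sided", method="approx",
                           correction=True).pvalue
        )
    tau, tp = stats.kendalltau(fped, froh)  # tau-b (tie-corrected) by default
    return PairedComparison(len(fped), v, p, float(tau), float(tp))


def _wilcoxon_exact_p(ranks: np.ndarray, v: float) -> float:
    """Exact two-sided signed-rank p under random signs, honouring mid-ranks.

    The null distribution of V (sum of positive-sign ranks) is built by
    dynamic programming over the tie-adjusted ranks (doubled so they are
    integers); it is symmetric about sum(ranks)/2, and the p-value is the
    probability of a V at least as far from the centre as observed.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    v2 = int(round(2 * v))
    dev = abs(v2 - total / 2)
    support = np.arange(total + 1)
    return float(dist[np.abs(support - total / 2) >= dev - 1e-9].sum())


# ---------------------------------------------------------------------------
# boundary adjustment


def adjust_boundaries(y, replacement: float = 0.0005) -> np.ndarray:
    """Replace exact zeros with a small constant (< 0.001) so a beta
    likelihood is defined; no individual is expected to be entirely devoid
    of autozygosity."""
    if not 0.0 < replacement < 0.001:
        raise ValueError("replacement must be in (0, 0.001)")
    y = np.asarray(y, dtype=float)
    if np.any(y >= 1.0) or np.any(y < 0.0):
        raise ValueError("proportions must lie in [0, 1)")
    out = y.copy()
    out[out == 0.0] = replacement
    return out


# ---------------------------------------------------------------------------
# natural cubic spline basis


@dataclass
class SplineBasis:
    """Natural cubic spline basis (truncated-power form) with df columns.

    Internal knots at equally spaced quantiles of the fitting data,
    boundary knots at min/max; linear beyond the boundary knots.
    """

    knots: np.ndarray  # all knots, boundary first/last

    @classmethod
    def from_data(cls, x, df: int = 3) -> "SplineBasis":
        x = np.asarray(x, dtype=float)
        if df < 2:
            raise ValueError("df must be >= 2")
        n_internal = df - 1
        qs = np.linspace(0, 1, n_internal + 2)[1:-1]
        internal = np.quantile(x, qs)
        knots = np.concatenate(([x.min()], internal, [x.max()]))
        if len(np.unique(knots)) != len(knots):
            raise ValueError("fewer distinct covariate values than knots")
        return cls(knots=knots)

    @property
    def df(self) -> int:
        return len(self.knots) - 1

    def transform(self, x) -> np.ndarray:
        """Basis matrix (n, df), no intercept column."""
        x = np.asarray(x, dtype=float)
        k = self.knots
        K = len(k)

        def d(j):
            return (
                np.clip(x - k[j], 0, None) ** 3 - np.clip(x - k[K - 1], 0, None) ** 3
            ) / (k[K - 1] - k[j])

        cols = [x]
        for j in range(K - 2):
            cols.append(d(j) - d(K - 2))
        return np.column_stack(cols)


# ---------------------------------------------------------------------------
# beta regression


def _beta_loglik(y, mu, phi):
    a = mu * phi
    b = (1 - mu) * phi
    return (
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1) * np.log(y)
        + (b - 1) * np.log1p(-y)
    )


@dataclass
class BetaFit:
    """Logit-link beta regression fit (fixed effects; optionally a scalar
    random intercept per group, integrated by Laplace approximation)."""

    params: np.ndarray  # beta coefficients
    bse: np.ndarray
    phi: float
    loglik: float
    names: list[str]
    sigma_re: float | None = None  # random-intercept SD, if fitted
    cov: np.ndarray | None = None  # covariance of beta

    def predict(self, X) -> np.ndarray:
        """Mean response at the fixed effects (random intercept at 0)."""
        return special.expit(np.asarray(X) @ self.params)

    def predict_ci(self, X, alpha: float = 0.05) -> pd.DataFrame:
        X = np.asarray(X)
        eta = X @ self.params
        if self.cov is not None:
            se = np.sqrt(np.einsum("ij,jk,ik->i", X, self.cov, X))
        else:
            se = np.zeros(len(X))
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "mean": special.expit(eta),
                "lo": special.expit(eta - z * se),
                "hi": special.expit(eta + z * se),
            }
        )

    def summary(self) -> pd.DataFrame:
        z = self.params / self.bse
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.params,
                "se": self.bse,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )


def _check_y(y):
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError(
            "responses must lie strictly in (0, 1); apply adjust_boundaries first"
        )
    return y


def fit_beta(
    y,
    X,
    random_intercept_group=None,
    names: list[str] | None = None,
) -> BetaFit:
    """ML beta regression with logit mean link and constant precision.

    Without a grouping factor this delegates to statsmodels' BetaModel.
    With one, per-group intercepts u_g ~ Normal(0, sigma^2) are integrated
    out with a one-dimensional Laplace approximation per group and the
    marginal likelihood is maximized over (beta, log phi, log sigma).
    """
    y = _check_y(y)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    names = names or [f"x{j}" for j in range(X.shape[1])]
    if random_intercept_group is None:
        return _fit_beta_fixed(y, X, names)
    return _fit_beta_laplace(y, X, np.asarray(random_intercept_group), names)


def _fit_beta_fixed(y, X, names) -> BetaFit:
    from statsmodels.othermod.betareg import BetaModel

    # scale columns to unit spread for conditioning; coefficients are
    # transformed back afterwards
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale
    model = BetaModel(y, Xs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0)
        if not res.mle_retvals.get("converged", True):
            res = model.fit(start_params=res.params, method="nm",
                            maxiter=5000, disp=0)
    grad = np.max(np.abs(model.score(res.params)))
    if not res.mle_retvals.get("converged", True) and grad > 1e-2:
        raise RuntimeError(
            f"beta regression did not converge (max |score| = {grad:.3g})"
        )
    k = X.shape[1]
    return BetaFit(
        params=res.params[:k] / scale,
        bse=res.bse[:k] / scale,
        phi=float(np.exp(res.params[k])),
        loglik=float(res.llf),
        names=list(names),
        cov=np.asarray(res.cov_params())[:k, :k] / np.outer(scale, scale),
    )


def _laplace_marginal_loglik(y, eta0, phi, sigma, codes, n_groups, logit_y):
    """Laplace-approximate marginal loglik over all groups, vectorized.

    The per-group posterior mode in u is found by simultaneous Newton steps
    (the problem is separable across groups), then each 1-D integral is
    replaced by its Laplace approximation.
    """
    u = np.zeros(n_groups)
    for _ in range(60):
        eta = eta0 + u[codes]
        mu = np.clip(special.expit(eta), 1e-10, 1 - 1e-10)
        a, b = mu * phi, (1 - mu) * phi
        dl_dmu = phi * (-special.digamma(a) + special.digamma(b) + logit_y)
        dmu = mu * (1 - mu)
        g = np.bincount(codes, weights=dl_dmu * dmu, minlength=n_groups) - u / sigma**2
        d2l_dmu2 = -(phi**2) * (special.polygamma(1, a) + special.polygamma(1, b))
        h_obs = d2l_dmu2 * dmu**2 + dl_dmu * dmu * (1 - 2 * mu)
        h = np.bincount(codes, weights=h_obs, minlength=n_groups) - 1 / sigma**2
        h = np.minimum(h, -1e-8)
        step = np.clip(-g / h, -5, 5)
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta0 + u[codes]
    mu = np.clip(special.expit(eta), 1e-10, 1 - 1e-10)
    ll_obs = _beta_loglik(y, mu, phi).sum()
    # recompute curvature at the mode
    a, b = mu * phi, (1 - mu) * phi
    dl_dmu = phi * (-special.digamma(a) + special.digamma(b) + logit_y)
    dmu = mu * (1 - mu)
    d2l_dmu2 = -(phi**2) * (special.polygamma(1, a) + special.polygamma(1, b))
    h_obs = d2l_dmu2 * dmu**2 + dl_dmu * dmu * (1 - 2 * mu)
    h = np.bincount(codes, weights=h_obs, minlength=n_groups) - 1 / sigma**2
    h = np.minimum(h, -1e-12)
    return (
        ll_obs
        - 0.5 * (u**2).sum() / sigma**2
        - 0.5 * n_groups * np.log(sigma**2)
        - 0.5 * np.log(-h).sum()
    )


def _fit_beta_laplace(y, X, groups, names) -> BetaFit:
    codes, _ = pd.factorize(groups)
    n_groups = int(codes.max()) + 1
    logit_y = special.logit(y)
    start = _fit_beta_fixed(y, X, names)
    theta0 = np.concatenate([start.params, [np.log(start.phi)], [np.log(0.2)]])
    k = X.shape[1]

    def negll(theta):
        beta = theta[:k]
        phi = np.exp(theta[k])
        sigma = np.exp(theta[k + 1])
        if phi > 1e6 or sigma > 50 or sigma < 1e-8:
            return 1e10
        return -_laplace_marginal_loglik(y, X @ beta, phi, sigma, codes, n_groups, logit_y)

    res = optimize.minimize(negll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
    if not res.success:  # pragma: no cover
        res2 = optimize.minimize(negll, res.x, method="Nelder-Mead",
                                 options={"maxiter": 4000})
        if res2.fun <= res.fun:
            res = res2
    sigma_hat = float(np.exp(res.x[k + 1]))
    if sigma_hat < 1e-3:
        # variance estimated at the zero boundary: the model reduces to the
        # fixed-effects fit, whose information-based SEs are well defined
        fixed = _fit_beta_fixed(y, X, names)
        fixed.sigma_re = 0.0
        return fixed
    from statsmodels.tools.numdiff import approx_hess1

    H = approx_hess1(res.x, negll)
    try:
        cov_all = np.linalg.inv(H)
        bse = np.sqrt(np.clip(np.diag(cov_all)[:k], 0, None))
        cov = cov_all[:k, :k]
    except np.linalg.LinAlgError:  # pragma: no cover
        bse = np.full(k, np.nan)
        cov = None
    return BetaFit(
        params=res.x[:k],
        bse=bse,
        phi=float(np.exp(res.x[k])),
        sigma_re=sigma_hat,
        loglik=float(-res.fun),
        names=list(names),
        cov=cov,
    )


# ---------------------------------------------------------------------------
# the analyses


TEMPORAL_RESPONSES = (
    "fped", "froh_total", "froh_1to5", "froh_5to20", "froh_gt20", "o_hom",
)


def temporal_models(
    table: pd.DataFrame,
    responses=TEMPORAL_RESPONSES,
    df: int = 3,
    n_grid: int = 100,
) -> dict[str, dict]:
    """Beta regression of each response on a natural cubic spline of year.

    No random effect; returns per response the fit, the spline basis and a
    prediction curve (with 95% CI) over the observed year range.
    """
    out: dict[str, dict] = {}
    for resp in responses:
        if resp not in table.columns:
            continue
        sub = table[["year", resp]].dropna()
        if sub.empty:
            continue
        basis = SplineBasis.from_data(sub["year"], df=df)
        Xs = basis.transform(sub["year"])
        X = np.column_stack([np.ones(len(sub)), Xs])
        yv = adjust_boundaries(sub[resp].to_numpy())
        fit = fit_beta(yv, X, names=["intercept"] + [f"ns{j+1}" for j in range(Xs.shape[1])])
        grid = np.linspace(sub["year"].min(), sub["year"].max(), n_grid)
        Xg = np.column_stack([np.ones(n_grid), basis.transform(grid)])
        curve = fit.predict_ci(Xg)
        curve.insert(0, "year", grid)
        out[resp] = {"fit": fit, "basis": basis, "curve": curve, "n": len(sub)}
    return out


@dataclass
class PrePostResult:
    fit: BetaFit
    mean_pre: float
    mean_post: float
    percent_change: float
    n: int

    def to_dict(self) -> dict:
        s = self.fit.summary()
        return {
            "n": self.n,
            "beta_group": float(s["estimate"][1]),
            "se": float(s["se"][1]),
            "z": float(s["z"][1]),
            "p": float(s["p"][1]),
            "mean_pre": self.mean_pre,
            "mean_post": self.mean_post,
            "percent_change": self.percent_change,
            "sigma_year": self.fit.sigma_re,
        }


def prepost_models(
    table: pd.DataFrame, responses=("fped", "froh_total")
) -> dict[str, PrePostResult]:
    """Beta mixed model per response: era fixed effect + year random intercept.

    Reports the group coefficient (logit scale), model-predicted group means
    (random intercept at zero) and the percent change 100*(post-pre)/pre.
    """
    out: dict[str, PrePostResult] = {}
    for resp in responses:
        if resp not in table.columns:
            continue
        sub = table[["year", "era", resp]].dropna()
        eras = set(sub["era"])
        if eras != {"pre", "post"}:
            raise ValueError(f"both eras must be represented; got {sorted(eras)}")
        yv = adjust_boundaries(sub[resp].to_numpy())
        post = (sub["era"] == "post").to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(sub)), post])
        fit = fit_beta(
            yv, X, random_intercept_group=sub["year"].to_numpy(),
            names=["intercept", "post"],
        )
        m_pre = float(special.expit(fit.params[0]))
        m_post = float(special.expit(fit.params[0] + fit.params[1]))
        out[resp] = PrePostResult(
            fit=fit,
            mean_pre=m_pre,
            mean_post=m_post,
            percent_change=100.0 * (m_post - m_pre) / m_pre,
            n=len(sub),
        )
    return out


@dataclass
class DepthBiasResult:
    welch_t: float
    welch_df: float
    welch_p: float
    ci_low: float
    ci_high: float
    mean_cge_pre: float
    mean_cge_post: float
    cge_fit: BetaFit
    n_regression: int

    def to_dict(self) -> dict:
        s = self.cge_fit.summary()
        return {
            "welch_t": self.welch_t,
            "welch_df": self.welch_df,
            "welch_p": self.welch_p,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "mean_cge_pre": self.mean_cge_pre,
            "mean_cge_post": self.mean_cge_post,
            "beta_cge": float(s["estimate"][1]),
            "beta_cge_se": float(s["se"][1]),
            "beta_cge_p": float(s["p"][1]),
            "n_regression": self.n_regression,
        }


def depth_bias_analysis(table: pd.DataFrame, min_cge: float = 1.0) -> DepthBiasResult:
    """Welch's t on CGE by era, then beta mixed regression of F_PED on CGE.

    The regression is restricted to individuals with CGE > min_cge, whose
    pedigrees are deep enough that F_PED is not structurally pinned at 0.
    """
    sub = table[["era", "cge", "fped", "year"]].dropna(subset=["cge", "fped"])
    pre = sub.loc[sub["era"] == "pre", "cge"].to_numpy()
    post = sub.loc[sub["era"] == "post", "cge"].to_numpy()
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("both eras must contain individuals with CGE")
    t_res = stats.ttest_ind(pre, post, equal_var=False)
    dof = t_res.df
    se = np.sqrt(pre.var(ddof=1) / len(pre) + post.var(ddof=1) / len(post))
    diff = pre.mean() - post.mean()
    tcrit = stats.t.ppf(0.975, dof)
    reg = sub[sub["cge"] > min_cge]
    yv = adjust_boundaries(reg["fped"].to_numpy())
    X = np.column_stack([np.ones(len(reg)), reg["cge"].to_numpy()])
    fit = fit_beta(
        yv, X, random_intercept_group=reg["year"].to_numpy(), names=["intercept", "cge"]
    )
    return DepthBiasResult(
        welch_t=float(t_res.statistic),
        welch_df=float(dof),
        welch_p=float(t_res.pvalue),
        ci_low=float(diff - tcrit * se),
        ci_high=float(diff + tcrit * se),
        mean_cge_pre=float(pre.mean()),
        mean_cge_post=float(post.mean()),
        cge_fit=fit,
        n_regression=len(reg),
    )
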