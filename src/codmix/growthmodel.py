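"""Linear mixed model for juvenile body length, with two-step AIC selection.

The response is the natural log of fork length (cm). Fixed effects are drawn
from sampling year (factor, first year as reference), log wave exposure
(linear), vegetation type (factor, eelgrass reference), vegetation cover
(linear, 1-5) and ecotype (fjord reference), plus ecotype interactions with
the three habitat covariates; sampling region enters as a random intercept.

The fit maximizes the profiled (restricted) Gaussian log-likelihood of the
single-random-intercept model over the variance ratio lambda =
sigma^2_region / sigma^2_residual. For fixed lambda the marginal covariance
is block diagonal, V_g = I + lambda 1 1', so Woodbury algebra gives the GLS
coefficients and the profiled variance in closed form; a bounded scalar
search (tolerance 1e-8 on lambda) completes the fit. At lambda = 0 the fit
reduces exactly to ordinary least squares.

Model selection follows the two-step protocol: first the random structure is
chosen by REML AIC under the full fixed structure, then nine nested fixed
structures are compared by ML AIC, and the winner is refit by REML for
inference. AIC counts fixed coefficients plus variance parameters
(residual always, region variance when the random intercept is present).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "LmmFit",
    "FIXED_TERMS",
    "CANDIDATE_STRUCTURES",
    "build_design",
    "fit_lmm",
    "select_model",
    "predict_lengths",
]

FIXED_TERMS = ("Y", "WE", "VT", "VC", "CO", "WE:CO", "VT:CO", "VC:CO")

#: The nine candidate fixed structures for step 2 of model selection, from
#: the full interaction model down to year alone.
CANDIDATE_STRUCTURES: tuple[tuple[str, ...], ...] = (
    ("Y", "WE", "VT", "VC", "CO", "WE:CO", "VT:CO", "VC:CO"),
    ("Y", "WE", "VT", "VC", "CO", "WE:CO", "VT:CO"),
    ("Y", "WE", "VT", "VC", "CO", "WE:CO"),
    ("Y", "WE", "VT", "VC", "CO", "VT:CO"),
    ("Y", "WE", "VT", "VC", "CO"),
    ("Y", "WE", "VT", "CO"),
    ("Y", "WE", "CO"),
    ("Y", "CO"),
    ("Y",),
)


def _check_hierarchy(terms: tuple[str, ...]) -> None:
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            if a not in terms or b not in terms:
                raise ValueError(f"interaction {t} requires both main effects")


def build_design(
    survey: pd.DataFrame,
    terms: tuple[str, ...] = FIXED_TERMS,
    year_levels: list | None = None,
) -> tuple[np.ndarray, pd.DataFrame, pd.Series]:
    """Response, fixed design matrix and region index from a survey table.

    ``survey`` needs columns length_cm, year, wave_exposure, veg_type,
    veg_cover, ecotype, region. Fish length and wave exposure are
    natural-log transformed; factors use treatment coding with the first
    sampling year, eelgrass and the fjord type as reference levels. Rows
    with any missing required value are dropped.
    """
    _check_hierarchy(tuple(terms))
    need = ["length_cm", "year", "wave_exposure", "veg_type", "veg_cover",
            "ecotype", "region"]
    missing = [c for c in need if c not in survey.columns]
    if missing:
        raise ValueError(f"survey table missing columns: {missing}")
    df = survey[need].dropna()
    if (df["length_cm"] <= 0).any() or (df["wave_exposure"] <= 0).any():
        raise ValueError("lengths and wave exposures must be positive for log transform")
    bad_vt = set(df["veg_type"]) - {"eelgrass", "macroalgae"}
    if bad_vt:
        raise ValueError(f"unknown vegetation type(s): {sorted(bad_vt)}")
    bad_co = set(df["ecotype"]) - {"fjord", "northsea"}
    if bad_co:
        raise ValueError(f"unknown ecotype label(s): {sorted(bad_co)}")

    y = np.log(df["length_cm"].to_numpy(float))
    we = np.log(df["wave_exposure"].to_numpy(float))
    vt = (df["veg_type"] == "macroalgae").to_numpy(float)
    vc = df["veg_cover"].to_numpy(float)
    co = (df["ecotype"] == "northsea").to_numpy(float)

    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(df))}
    if "Y" in terms:
        levels = year_levels if year_levels is not None else sorted(df["year"].unique())
        for lev in levels[1:]:
            cols[f"Y[{lev}]"] = (df["year"] == lev).to_numpy(float)
    if "WE" in terms:
        cols["WE"] = we
    if "VT" in terms:
        cols["VT[macroalgae]"] = vt
    if "VC" in terms:
        cols["VC"] = vc
    if "CO" in terms:
        cols["CO[northsea]"] = co
    if "WE:CO" in terms:
        cols["WE:CO[northsea]"] = we * co
    if "VT:CO" in terms:
        cols["VT[macroalgae]:CO[northsea]"] = vt * co
    if "VC:CO" in terms:
        cols["VC:CO[northsea]"] = vc * co
    X = pd.DataFrame(cols, index=df.index)
    return y, X, df["region"].reset_index(drop=True)


@dataclass
class LmmFit:
    """A fitted single-random-intercept Gaussian mixed model."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    sigma2_region: float
    sigma2_resid: float
    loglik: float
    aic: float
    n: int
    method: str  # 'REML' | 'ML'
    has_random: bool
    terms: tuple[str, ...] = ()
    year_levels: tuple = ()
    cov_params: np.ndarray = field(default=None, repr=False)

    @property
    def variance_share_region(self) -> float:
        tot = self.sigma2_region + self.sigma2_resid
        return self.sigma2_region / tot if tot > 0 else 0.0


def _profile(lam: float, y, X, sizes, idx_groups, reml: bool):
    """Profiled negative log-likelihood pieces for a given variance ratio."""
    n, p = X.shape
    xtx = X.T @ X
    xty = X.T @ y
    yty = float(y @ y)
    logdet_v = 0.0
    for m, rows in zip(sizes, idx_groups):
        c = lam / (1.0 + lam * m)
        sx = X[rows].sum(axis=0)
        sy = float(y[rows].sum())
        xtx = xtx - c * np.outer(sx, sx)
        xty = xty - c * sx * sy
        yty = yty - c * sy * sy
        logdet_v += np.log1p(lam * m)
    try:
        cho = np.linalg.cholesky(xtx)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular fixed-effects design (rank deficient)")
    beta = np.linalg.solve(xtx, xty)
    rss = max(yty - float(beta @ xty), 1e-300)
    logdet_xvx = 2.0 * float(np.log(np.diag(cho)).sum())
    if reml:
        df = n - p
        sigma2 = rss / df
        ll = -0.5 * (df * np.log(2 * np.pi * sigma2) + logdet_v + logdet_xvx + df)
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet_v + n)
    return ll, beta, sigma2, xtx


def fit_lmm(
    y: np.ndarray,
    X: pd.DataFrame,
    groups: pd.Series | None,
    method: str = "REML",
    terms: tuple[str, ...] = (),
    lam_max: float = 1e4,
    tol: float = 1e-8,
) -> LmmFit:
    """Fit the random-intercept LMM (or OLS when ``groups`` is None).

    Maximizes the profiled (restricted) log-likelihood over the variance
    ratio by bounded scalar search with absolute tolerance ``tol``; fixed
    effects and the residual variance are profiled out in closed form.
    Coefficient p-values use the Wald normal approximation.
    """
    method = method.upper()
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    reml = method == "REML"
    names = list(X.columns)
    Xa = X.to_numpy(float)
    y = np.asarray(y, float)
    n, p = Xa.shape
    if n <= p:
        raise ValueError(f"need n > number of parameters ({n} <= {p})")

    has_random = groups is not None
    if has_random:
        codes, _ = pd.factorize(pd.Series(groups).reset_index(drop=True))
        if codes.max() < 1:
            raise ValueError("random intercept requires >= 2 groups")
        idx_groups = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]
        sizes = [len(r) for r in idx_groups]
    else:
        idx_groups, sizes = [], []

    def nll(lam):
        return -_profile(lam, y, Xa, sizes, idx_groups, reml)[0]

    if has_random:
        res = optimize.minimize_scalar(
            nll, bounds=(0.0, lam_max), method="bounded",
            options={"xatol": tol},
        )
        lam = float(res.x)
        # the boundary is a genuine candidate the bounded search can miss
        if nll(0.0) <= res.fun:
            lam = 0.0
    else:
        lam = 0.0

    ll, beta, sigma2, xtx = _profile(lam, y, Xa, sizes, idx_groups, reml)
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    k = p + (2 if has_random else 1)
    year_levels = tuple(
        c[2:-1] for c in names if c.startswith("Y[")
    )
    return LmmFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma2_region=lam * sigma2 if has_random else 0.0,
        sigma2_resid=sigma2,
        loglik=float(ll),
        aic=float(-2.0 * ll + 2.0 * k),
        n=n,
        method=method,
        has_random=has_random,
        terms=tuple(terms),
        year_levels=year_levels,
        cov_params=cov,
    )


def fit_survey(
    survey: pd.DataFrame,
    terms: tuple[str, ...] = FIXED_TERMS,
    method: str = "REML",
    random_intercept: bool = True,
) -> LmmFit:
    """Convenience wrapper: build the design from a survey table and fit."""
    y, X, region = build_design(survey, terms)
    groups = region if random_intercept else None
    return fit_lmm(y, X, groups, method=method, terms=terms)


def select_model(survey: pd.DataFrame) -> tuple[pd.DataFrame, LmmFit]:
    """Two-step AIC model selection for the length model.

    Step 1 fits the full fixed structure by REML with and without the region
    random intercept and keeps the lower-AIC random structure. Step 2 fits
    the nine candidate fixed structures by ML (with the chosen random
    structure) and keeps the lowest AIC. The winner is refit by REML for
    inference. Returns the trace of every fit and the final REML fit.
    """
    rows = []
    step1 = {}
    for has_rand in (True, False):
        f = fit_survey(survey, FIXED_TERMS, "REML", random_intercept=has_rand)
        step1[has_rand] = f
        rows.append({"step": 1, "structure": "+".join(FIXED_TERMS),
                     "random_intercept": has_rand, "method": "REML",
                     "aic": f.aic, "loglik": f.loglik})
    use_random = step1[True].aic <= step1[False].aic

    best = None
    for terms in CANDIDATE_STRUCTURES:
        f = fit_survey(survey, terms, "ML", random_intercept=use_random)
        rows.append({"step": 2, "structure": "+".join(terms),
                     "random_intercept": use_random, "method": "ML",
                     "aic": f.aic, "loglik": f.loglik})
        if best is None or f.aic < best[1]:
            best = (terms, f.aic)

    final = fit_survey(survey, best[0], "REML", random_intercept=use_random)
    rows.append({"step": 3, "structure": "+".join(best[0]),
                 "random_intercept": use_random, "method": "REML",
                 "aic": final.aic, "loglik": final.loglik})
    return pd.DataFrame(rows), final


def predict_lengths(
    fit: LmmFit,
    grid: pd.DataFrame,
    year=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fixed-effects length predictions (cm) over a covariate grid.

    ``grid`` needs wave_exposure, veg_type, veg_cover, ecotype columns; the
    random region effect is set to 0 (marginal prediction) and year fixed to
    ``year`` (default: the reference year). Wald intervals on the linear
    predictor are exp back-transformed along with the point prediction.
    """
    g = grid.copy()
    g["length_cm"] = 1.0  # placeholder response, unused
    g["region"] = 0
    g["year"] = 0
    no_year_terms = tuple(t for t in fit.terms if t != "Y")
    _, X, _ = build_design(g, no_year_terms)
    # align to the fitted coefficient order, zero-filling year dummies
    X = X.reindex(columns=fit.params.index, fill_value=0.0)
    if year is not None:
        col = f"Y[{year}]"
        if col in X.columns:
            X[col] = 1.0
        # a year with no dummy column is the reference level: nothing to set
    eta = X.to_numpy(float) @ fit.params.to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", X.to_numpy(float), fit.cov_params,
                           X.to_numpy(float)))
    zq = sps.norm.ppf(1 - alpha / 2)
    out = grid.copy()
    out["log_length"] = eta
    out["length_cm"] = np.exp(eta)
    out["length_cm_lo"] = np.exp(eta - zq * se)
    out["length_cm_hi"] = np.exp(eta + zq * se)
    return out
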