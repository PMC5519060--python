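"""Random-intercept Gaussian linear mixed model, fit by profiled (restricted)
likelihood.

Model:  y_ij = x_ij' beta + u_i + e_ij,  u_i ~ N(0, s2_u),  e_ij ~ N(0, s2_e),
for observation j in group (community) i.  Writing theta = s2_u / s2_e, the
marginal covariance of group i is s2_e * (I + theta * J).  For fixed theta the
GLS solution and the profiled error variance are closed-form via the Woodbury
identity, so fitting reduces to a one-dimensional optimization over theta >= 0
(log-parameterized, with the theta = 0 boundary checked explicitly).

Inference mirrors the nlme reporting convention: Wald t statistics with
inner-outer containment denominator degrees of freedom — terms constant
within every group ("between" terms, the intercept included) are tested
against n_groups - 1 - #between-terms; terms varying within groups against
n_obs - n_groups - #within-terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

_LOG2PI = float(np.log(2.0 * np.pi))


def build_design(data: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix for a term list with ':' interactions.

    Categorical columns expand to treatment dummies against their first
    category (order categoricals so the reference level comes first).
    An intercept column is always prepended.
    """
    def expand(term: str) -> tuple[np.ndarray, list[str]]:
        col = data[term]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            cat = col.astype("category")
            levels = list(cat.cat.categories)
            cols = [(cat == lv).to_numpy(dtype=float) for lv in levels[1:]]
            return np.column_stack(cols) if cols else np.empty((len(data), 0)), \
                [f"{term}[{lv}]" for lv in levels[1:]]
        return col.to_numpy(dtype=float)[:, None], [term]

    mats = [np.ones((len(data), 1))]
    names = ["(Intercept)"]
    for term in terms:
        parts = [p.strip() for p in term.split(":")]
        m, nm = expand(parts[0])
        for p in parts[1:]:
            m2, nm2 = expand(p)
            m = np.einsum("ni,nj->nij", m, m2).reshape(len(data), -1)
            nm = [f"{a}:{b}" for a in nm for b in nm2]
        mats.append(m)
        names.extend(nm)
    return np.column_stack(mats), names


@dataclass
class LMMFit:
    terms: list
    beta: np.ndarray
    se: np.ndarray
    df: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    sigma2_group: float
    sigma2_resid: float
    loglik: float
    aic: float
    method: str
    n_obs: int
    n_groups: int
    # refit handles
    _data_key: int = 0
    _refit: tuple | None = None

    @property
    def n_params(self) -> int:
        return len(self.beta) + 2  # fixed effects + two variance components

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.terms, "beta": self.beta, "se": self.se,
                             "df": self.df, "t": self.t_values, "p": self.p_values})


def _profile(theta: float, X: np.ndarray, y: np.ndarray, starts: np.ndarray,
             counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """GLS pieces at variance ratio theta, working with V* = I + theta*J per
    group (residual variance profiled out).

    Returns (A, b, q, logdetVstar) with A = X'V*^-1 X, b = X'V*^-1 y,
    q = y'V*^-1 y.
    """
    p = X.shape[1]
    A = np.zeros((p, p))
    b = np.zeros(p)
    q = 0.0
    logdet = 0.0
    for s, n_g in zip(starts, counts):
        Xg = X[s:s + n_g]
        yg = y[s:s + n_g]
        c = theta / (1.0 + n_g * theta)
        xs = Xg.sum(axis=0)
        ys = yg.sum()
        A += Xg.T @ Xg - c * np.outer(xs, xs)
        b += Xg.T @ yg - c * xs * ys
        q += yg @ yg - c * ys * ys
        logdet += np.log1p(n_g * theta)
    return A, b, q, logdet


def _neg2ll(theta: float, X, y, starts, counts, reml: bool) -> float:
    n, p = X.shape
    A, b, q, logdet = _profile(theta, X, y, starts, counts)
    beta = np.linalg.solve(A, b)
    rss = max(q - b @ beta, 1e-300)
    if reml:
        # -2 restricted ll at the profiled variance: the n*log(s2) from |V| and
        # the -p*log(s2) from |X'V^-1 X| combine into the (n-p)*log(s2) term
        s2 = rss / (n - p)
        _, logdetA = np.linalg.slogdet(A)
        return (n - p) * (_LOG2PI + np.log(s2)) + logdet + logdetA + (n - p)
    s2 = rss / n
    return n * (_LOG2PI + np.log(s2)) + logdet + n


def fit_lmm(data: pd.DataFrame, response: str, fixed: list[str], group: str,
            method: str = "REML") -> LMMFit:
    """Fit the random-intercept model.

    fixed : term names from ``data``; ':' builds interactions; categorical
    columns use their first category as the reference level.
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    groups = data[group].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    order = np.argsort(groups, kind="stable")
    data_s = data.iloc[order].reset_index(drop=True)
    X, names = build_design(data_s, fixed)
    y = data_s[response].to_numpy(dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(f"singular design matrix; check collinearity among {names}")
    g_sorted = data_s[group].to_numpy()
    uniq, starts, counts = np.unique(g_sorted, return_index=True, return_counts=True)
    n_groups = len(uniq)
    reml = method == "REML"

    obj = lambda log_th: _neg2ll(np.exp(log_th), X, y, starts, counts, reml)
    res = optimize.minimize_scalar(obj, bounds=(-12.0, 8.0), method="bounded",
                                   options={"xatol": 1e-10})
    cand = [(float(res.fun), float(np.exp(res.x)))]
    cand.append((_neg2ll(0.0, X, y, starts, counts, reml), 0.0))
    f_opt, theta = min(cand)

    A, b, q, _ = _profile(theta, X, y, starts, counts)
    beta = np.linalg.solve(A, b)
    rss = max(q - b @ beta, 1e-300)
    s2e = rss / (n - p) if reml else rss / n
    s2u = theta * s2e
    cov = s2e * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))

    # containment df: a column is "between" iff constant within every group
    between = np.ones(p, dtype=bool)
    for s, n_g in zip(starts, counts):
        blk = X[s:s + n_g]
        between &= np.all(np.abs(blk - blk[0]) < 1e-12, axis=0)
    n_between = int(between.sum())
    n_within = p - n_between
    df = np.where(between, max(n_groups - 1 - n_between, 1),
                  max(n - n_groups - n_within, 1)).astype(float)

    t = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(t), df)
    ll = -0.5 * f_opt
    k = p + 2
    fit = LMMFit(names, beta, se, df, t, pvals, float(s2u), float(s2e),
                 float(ll), float(2 * k - 2 * ll), method, n, n_groups,
                 _data_key=id(data), _refit=(data, response, list(fixed), group))
    return fit


def select_model(candidates: list[LMMFit]) -> LMMFit:
    """AIC selection among ML fits of the same data, ties broken toward the
    most parsimonious model; the winner is refit by REML for final estimates."""
    if not candidates:
        raise ValueError("no candidate models")
    if any(c.method != "ML" for c in candidates):
        raise ValueError("candidates must be fit by ML for AIC comparison")
    keys = {c._data_key for c in candidates}
    ns = {c.n_obs for c in candidates}
    if len(keys) > 1 or len(ns) > 1:
        raise ValueError("candidates were fit to differing data")
    best = min(candidates, key=lambda c: (round(c.aic, 10), c.n_params))
    data, response, fixed, group = best._refit
    return fit_lmm(data, response, fixed, group, method="REML")
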