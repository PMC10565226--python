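"""Linear mixed-effects engine for the threat-difference responses.

Model
-----
For observation i of participant p(i):

    y_i = x_i' beta + b_{p(i)} + e_i,
    b_p  ~ N(0, sigma_b^2)                        (random participant intercept)
    e_i  ~ N(0, sigma^2 * exp(2 * delta * g_i) / w_i)

where ``g_i`` indicates the non-reference level of the variance-grouping
factor (nationality; the reference level's residual scale is ``sigma^2``) and
``w_i`` is the known observation weight (2 for a full mirror-pair average,
1 for a lone survivor).  This is the "constant variance by group x fixed
variance by weight" residual structure.

Likelihoods (ML and REML) are evaluated exactly per participant block via the
rank-one (Sherman-Morrison) structure of each block's covariance — no dense
n x n inversion.  ``beta`` and ``sigma^2`` are profiled out; the optimiser
runs over ``(gamma, delta)`` with ``lambda = gamma^2 = sigma_b^2 / sigma^2``
from a fixed multi-start grid, so fits are deterministic.

The public surface follows the Model/Results idiom: build a
:class:`ThreatBiasLMM` from an observation table, ``fit()`` it, and read
estimates, tests, marginal means and contrasts off the returned
:class:`LMMResults`.

Denominator degrees of freedom use a two-level inner-outer rule: terms
constant within participants (nationality, gender, age and their
interactions) are tested against between-participant df
``M - p_between``; terms varying within participants (morphotype and its
interactions) against within-participant df ``n - M - p_within``, where
``p_between`` / ``p_within`` count the non-intercept parameters at each
level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve

__all__ = [
    "ThreatBiasLMM",
    "LMMResults",
    "build_design",
    "lrt",
    "lrt_pvalue",
    "backward_reduce",
    "ReductionResult",
    "FULL_TERMS",
]

#: fixed-effect structure of the study's full models
FULL_TERMS = (
    "intercept",
    "morphotype",
    "nationality",
    "gender",
    "age",
    "morphotype:nationality",
    "gender:nationality",
)


# ---------------------------------------------------------------------------
# design construction

@dataclass(frozen=True)
class Design:
    X: np.ndarray
    columns: tuple[str, ...]
    term_slices: dict[str, list[int]]
    y: np.ndarray
    group_codes: np.ndarray
    group_labels: tuple[str, ...]
    var_codes: np.ndarray          # 0 = reference variance group
    var_levels: tuple[str, ...]
    weights: np.ndarray
    meta: dict                     # var -> ("cat", levels) | ("num", mean)
    varies_within: dict[str, bool]
    response: str

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)


def _var_meta(df: pd.DataFrame, var: str):
    col = df[var]
    if col.isna().any():
        raise ValueError(f"missing values in column {var!r}")
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        return ("cat", tuple(sorted(map(str, col.unique()))))
    return ("num", float(col.mean()))


def _encode_factor(df: pd.DataFrame, var: str, meta) -> tuple[np.ndarray, list[str]]:
    kind, info = meta
    if kind == "num":
        return df[var].to_numpy(float)[:, None], [var]
    levels = info
    cols = []
    names = []
    vals = df[var].astype(str).to_numpy()
    for lev in levels[1:]:  # treatment coding, first level is the reference
        cols.append((vals == lev).astype(float))
        names.append(f"{var}[{lev}]")
    if not cols:
        return np.empty((len(df), 0)), []
    return np.column_stack(cols), names


def _encode_term(df: pd.DataFrame, term: str, meta: dict):
    if term == "intercept":
        return np.ones((len(df), 1)), ["intercept"]
    parts = term.split(":")
    mats, name_lists = [], []
    for v in parts:
        m, names = _encode_factor(df, v, meta[v])
        mats.append(m)
        name_lists.append(names)
    mat = mats[0]
    names = name_lists[0]
    for m2, n2 in zip(mats[1:], name_lists[1:]):
        mat = np.concatenate(
            [mat[:, [i]] * m2 for i in range(mat.shape[1])], axis=1
        ) if mat.shape[1] else mat
        names = [f"{a}:{b}" for a in names for b in n2]
    return mat, names


def _term_row(values: dict, term: str, meta: dict) -> np.ndarray:
    """Design row fragment for one term at explicit factor/covariate values."""
    if term == "intercept":
        return np.ones(1)
    parts = term.split(":")
    frag = np.ones(1)
    for v in parts:
        kind, info = meta[v]
        if kind == "num":
            piece = np.array([float(values[v])])
        else:
            piece = np.array(
                [1.0 if str(values[v]) == lev else 0.0 for lev in info[1:]]
            )
        frag = np.concatenate([frag[i] * piece for i in range(frag.size)])
    return frag


def build_design(
    df: pd.DataFrame,
    terms=FULL_TERMS,
    response: str = "diff_fix",
    group_col: str = "participant_id",
    var_group_col: str | None = "nationality",
    weight_col: str | None = "weight",
) -> Design:
    """Assemble treatment-coded design matrices from an observation table.

    Rows are sorted by participant (stable within participant).  Interaction
    terms must be accompanied by their main effects.
    """
    terms = tuple(terms)
    if "intercept" not in terms:
        terms = ("intercept",) + terms
    for t in terms:
        for part in t.split(":"):
            if part != "intercept" and ":" in t and part not in terms:
                raise ValueError(
                    f"interaction {t!r} requires main effect {part!r} in terms"
                )
    for col in (response, group_col):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
        if df[col].isna().any():
            raise ValueError(f"missing values in column {col!r}")

    order = np.argsort(df[group_col].to_numpy(), kind="stable")
    df = df.iloc[order].reset_index(drop=True)

    varnames = sorted({v for t in terms if t != "intercept" for v in t.split(":")})
    meta = {v: _var_meta(df, v) for v in varnames}

    mats, columns = [], []
    term_slices: dict[str, list[int]] = {}
    for t in terms:
        m, names = _encode_term(df, t, meta)
        term_slices[t] = list(range(len(columns), len(columns) + len(names)))
        mats.append(m)
        columns.extend(names)
    X = np.column_stack(mats)

    groups_raw = df[group_col].astype(str).to_numpy()
    group_labels, group_codes = np.unique(groups_raw, return_inverse=True)

    if var_group_col is not None and var_group_col in df.columns:
        var_raw = df[var_group_col].astype(str).to_numpy()
        var_levels, var_codes = np.unique(var_raw, return_inverse=True)
        if len(var_levels) > 2:
            raise ValueError(
                "variance grouping with more than two levels is not supported"
            )
    else:
        var_levels = np.array(["_all"])
        var_codes = np.zeros(len(df), dtype=int)

    if weight_col is not None and weight_col in df.columns:
        w = df[weight_col].to_numpy(float)
        if np.any(w <= 0):
            raise ValueError("observation weights must be positive")
    else:
        w = np.ones(len(df))

    varies_within = {}
    for t in terms:
        if t == "intercept":
            varies_within[t] = False
            continue
        cols = X[:, term_slices[t]]
        vw = False
        for gc in range(len(group_labels)):
            block = cols[group_codes == gc]
            if block.shape[0] > 1 and np.ptp(block, axis=0).max() > 0:
                vw = True
                break
        varies_within[t] = vw

    return Design(
        X=X,
        columns=tuple(columns),
        term_slices=term_slices,
        y=df[response].to_numpy(float),
        group_codes=group_codes,
        group_labels=tuple(map(str, group_labels)),
        var_codes=var_codes.astype(int),
        var_levels=tuple(map(str, var_levels)),
        weights=w,
        meta=meta,
        varies_within=varies_within,
        response=response,
    )


# ---------------------------------------------------------------------------
# model

class ThreatBiasLMM:
    """Random-intercept LMM with group-scaled, weight-scaled residual variance.

    Parameters
    ----------
    design
        A :class:`Design` from :func:`build_design`.

    Use :meth:`from_dataframe` for the common path.
    """

    def __init__(self, design: Design):
        if design.n_groups < 2:
            raise ValueError("need at least two participants")
        self.design = design
        d = design
        # pre-sort by group for reduceat block sums
        order = np.argsort(d.group_codes, kind="stable")
        self._X = d.X[order]
        self._y = d.y[order]
        self._g = d.var_codes[order].astype(float)
        self._w = d.weights[order]
        gc = d.group_codes[order]
        self._starts = np.flatnonzero(np.r_[True, np.diff(gc) != 0])
        self._delta_active = len(d.var_levels) == 2
        if self._delta_active:
            for lev in range(2):
                if np.sum(d.var_codes == lev) < 2:
                    raise ValueError(
                        "need at least two observations in each variance group"
                    )

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        response: str = "diff_fix",
        terms=FULL_TERMS,
        group_col: str = "participant_id",
        var_group_col: str | None = "nationality",
        weight_col: str | None = "weight",
    ) -> "ThreatBiasLMM":
        return cls(
            build_design(df, terms=terms, response=response, group_col=group_col,
                         var_group_col=var_group_col, weight_col=weight_col)
        )

    # -- likelihood --------------------------------------------------------
    def _components(self, lam: float, delta: float):
        X, y, starts = self._X, self._y, self._starts
        v = np.exp(2.0 * delta * self._g) / self._w
        a = 1.0 / v
        s = np.add.reduceat(a, starts)
        aX = X * a[:, None]
        U = np.add.reduceat(aX, starts, axis=0)
        ay = a * y
        tvec = np.add.reduceat(ay, starts)
        c = lam / (1.0 + lam * s)
        XtVX = X.T @ aX - (U * c[:, None]).T @ U
        XtVy = X.T @ ay - U.T @ (c * tvec)
        yVy = float(y @ ay - c @ (tvec * tvec))
        logdetV = float(np.sum(np.log(v)) + np.sum(np.log1p(lam * s)))
        return XtVX, XtVy, yVy, logdetV

    def loglik(self, lam: float, delta: float, method: str = "REML"):
        """Profiled log-likelihood at relative variance ``lam`` and log
        variance-ratio ``delta``; beta and sigma^2 at their closed-form
        optima.  Returns ``(loglik, beta, sigma2)``."""
        if not (np.isfinite(lam) and np.isfinite(delta)) or lam < 0:
            raise ValueError("variance parameters must be finite and lam >= 0")
        XtVX, XtVy, yVy, logdetV = self._components(lam, delta)
        n, p = self._X.shape
        beta = solve(XtVX, XtVy, assume_a="pos")
        q = max(yVy - float(beta @ XtVy), 1e-300)
        if method.upper() == "ML":
            sigma2 = q / n
            ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdetV + n)
        elif method.upper() == "REML":
            sigma2 = q / (n - p)
            sign, logdet_xtvx = np.linalg.slogdet(XtVX)
            if sign <= 0:
                raise np.linalg.LinAlgError("X'V^-1X not positive definite")
            ll = -0.5 * (
                (n - p) * np.log(2 * np.pi * sigma2)
                + logdetV
                + logdet_xtvx
                + (n - p)
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        return float(ll), beta, float(sigma2)

    # -- fitting -----------------------------------------------------------
    def fit(self, method: str = "REML") -> "LMMResults":
        """Maximise the (restricted) likelihood over the variance parameters.

        Deterministic: L-BFGS-B from a fixed multi-start grid over
        ``(gamma, delta)`` with ``lambda = gamma^2``.
        """
        method = method.upper()

        def neg(z):
            gamma = z[0]
            delta = z[1] if self._delta_active else 0.0
            try:
                ll, _, _ = self.loglik(gamma * gamma, delta, method)
            except np.linalg.LinAlgError:
                return 1e12
            return -ll

        gammas = (0.0, 0.3, 1.0, 3.0)
        deltas = (-0.3, 0.0, 0.3) if self._delta_active else (0.0,)
        if self._delta_active:
            bounds = [(0.0, 1e4), (-5.0, 5.0)]
            starts = [np.array([g, d]) for g in gammas for d in deltas]
        else:
            bounds = [(0.0, 1e4)]
            starts = [np.array([g]) for g in gammas]

        best = None
        for z0 in starts:
            res = optimize.minimize(
                neg, z0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
            raise RuntimeError(f"LMM optimisation failed: {best}")
        # simplex polish: L-BFGS-B's numerical gradient limits its precision
        polish = optimize.minimize(
            neg, best.x, method="Nelder-Mead", bounds=bounds,
            options={"fatol": 1e-13, "xatol": 1e-10, "maxiter": 2000},
        )
        if np.isfinite(polish.fun) and polish.fun <= best.fun:
            best = polish

        gamma = float(best.x[0])
        delta = float(best.x[1]) if self._delta_active else 0.0
        lam = gamma * gamma
        ll, beta, sigma2 = self.loglik(lam, delta, method)
        XtVX, _, _, _ = self._components(lam, delta)
        cov = sigma2 * np.linalg.inv(XtVX)
        n, p = self._X.shape
        k_var = 2 + (1 if self._delta_active else 0)
        aic = -2.0 * ll + 2.0 * (p + k_var)
        return LMMResults(
            model=self,
            method=method,
            params=pd.Series(beta, index=list(self.design.columns)),
            cov_params_=pd.DataFrame(
                cov, index=list(self.design.columns),
                columns=list(self.design.columns),
            ),
            sigma2=sigma2,
            sigma_b2=lam * sigma2,
            delta=delta,
            llf=float(ll),
            aic=float(aic),
            n_obs=n,
            n_groups=self.design.n_groups,
        )


# ---------------------------------------------------------------------------
# results

@dataclass
class LMMResults:
    """Fitted mixed-model state: estimates, uncertainties and tests."""

    model: ThreatBiasLMM
    method: str
    params: pd.Series
    cov_params_: pd.DataFrame
    sigma2: float
    sigma_b2: float
    delta: float
    llf: float
    aic: float
    n_obs: int
    n_groups: int
    _df_cache: dict = field(default_factory=dict, repr=False)

    def cov_params(self) -> pd.DataFrame:
        return self.cov_params_

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params_.to_numpy())), index=self.params.index
        )

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.model.design.term_slices)

    @property
    def residual_sd_by_level(self) -> dict[str, float]:
        """Residual sd at weight 1 for each variance-group level."""
        d = self.model.design
        out = {d.var_levels[0]: float(np.sqrt(self.sigma2))}
        if len(d.var_levels) == 2:
            out[d.var_levels[1]] = float(
                np.sqrt(self.sigma2) * np.exp(self.delta)
            )
        return out

    # -- degrees of freedom ------------------------------------------------
    def _df_split(self):
        if "split" not in self._df_cache:
            d = self.model.design
            p_within = sum(
                len(d.term_slices[t])
                for t in d.term_slices
                if t != "intercept" and d.varies_within[t]
            )
            p_between = sum(
                len(d.term_slices[t])
                for t in d.term_slices
                if t != "intercept" and not d.varies_within[t]
            )
            df_within = d.n_obs - d.n_groups - p_within
            df_between = d.n_groups - (p_between if p_between > 0 else 1)
            if df_within < 1 or df_between < 1:
                raise ValueError(
                    "not enough observations/participants for the inner-outer "
                    "df rule"
                )
            self._df_cache["split"] = (df_within, df_between)
        return self._df_cache["split"]

    def denominator_df(self, term: str) -> int:
        """Inner-outer denominator df for a fixed-effect term."""
        d = self.model.design
        if term not in d.term_slices:
            raise ValueError(f"term {term!r} not in the fitted model")
        df_within, df_between = self._df_split()
        if term == "intercept":
            has_within = any(
                d.varies_within[t] for t in d.term_slices if t != "intercept"
            )
            return df_within if has_within else df_between
        return df_within if d.varies_within[term] else df_between

    # -- tests -------------------------------------------------------------
    def wald_f(self, term: str) -> tuple[float, int, int, float]:
        """Marginal Wald F-test of a term; returns ``(F, df_num, df_den, p)``."""
        d = self.model.design
        if term not in d.term_slices:
            raise ValueError(f"term {term!r} not in the fitted model")
        idx = d.term_slices[term]
        b = self.params.to_numpy()[idx]
        C = self.cov_params_.to_numpy()[np.ix_(idx, idx)]
        fstat = float(b @ solve(C, b, assume_a="pos") / len(idx))
        dfd = self.denominator_df(term)
        p = float(stats.f.sf(fstat, len(idx), dfd))
        return fstat, len(idx), dfd, p

    # -- marginal means ----------------------------------------------------
    def _factor_names(self) -> list[str]:
        d = self.model.design
        return [v for v, (kind, _) in sorted(d.meta.items()) if kind == "cat"]

    def _grid_row(self, values: dict) -> np.ndarray:
        d = self.model.design
        frags = [
            _term_row(values, t, d.meta) for t in d.term_slices
        ]
        return np.concatenate(frags)

    def _emm_lvector(self, focal_values: dict) -> np.ndarray:
        """L-vector for one marginal-mean cell: average the design row equally
        over the levels of all non-focal factors, covariates at their mean."""
        d = self.model.design
        covs = {v: info for v, (kind, info) in d.meta.items() if kind == "num"}
        others = [f for f in self._factor_names() if f not in focal_values]
        rows = []
        level_sets = [d.meta[f][1] for f in others]
        for combo in itertools.product(*level_sets) if others else [()]:
            values = dict(focal_values)
            values.update(dict(zip(others, combo)))
            values.update(covs)
            rows.append(self._grid_row(values))
        return np.mean(rows, axis=0)

    def _emm_df(self, factors: list[str]) -> int:
        d = self.model.design
        has_within = any(
            d.varies_within[t] for t in d.term_slices if t != "intercept"
        )
        df_within, df_between = self._df_split()
        return df_within if has_within else df_between

    def emmeans(self, by: list[str] | str) -> pd.DataFrame:
        """Estimated marginal means of the cells of ``by`` factors, each
        tested against zero with the inner-outer df of the model."""
        if isinstance(by, str):
            by = [by]
        d = self.model.design
        for f in by:
            if f not in d.meta or d.meta[f][0] != "cat":
                raise ValueError(f"factor {f!r} not in the fitted model")
        beta = self.params.to_numpy()
        C = self.cov_params_.to_numpy()
        df = self._emm_df(by)
        tcrit = stats.t.ppf(0.975, df)
        rows = []
        for combo in itertools.product(*[d.meta[f][1] for f in by]):
            L = self._emm_lvector(dict(zip(by, combo)))
            est = float(L @ beta)
            se = float(np.sqrt(L @ C @ L))
            tval = est / se if se > 0 else np.inf
            rows.append(
                {
                    **dict(zip(by, combo)),
                    "estimate": est,
                    "se": se,
                    "ci_lo": est - tcrit * se,
                    "ci_hi": est + tcrit * se,
                    "df": df,
                    "t": tval,
                    "p": float(2 * stats.t.sf(abs(tval), df)),
                }
            )
        return pd.DataFrame(rows)

    def contrasts(self, factor: str, by: list[str] | str = ()) -> pd.DataFrame:
        """Pairwise differences of marginal means between levels of ``factor``
        within each cell of ``by``.

        The df follows the level at which ``factor`` varies: contrasts of a
        participant-constant factor (nationality) use between-participant df.
        """
        if isinstance(by, str):
            by = [by]
        d = self.model.design
        if factor not in d.meta or d.meta[factor][0] != "cat":
            raise ValueError(f"factor {factor!r} not in the fitted model")
        df_within, df_between = self._df_split()
        if factor in d.term_slices:
            df = df_within if d.varies_within[factor] else df_between
        else:
            df = df_within
        beta = self.params.to_numpy()
        C = self.cov_params_.to_numpy()
        tcrit = stats.t.ppf(0.975, df)
        levels = d.meta[factor][1]
        rows = []
        by_levels = [d.meta[f][1] for f in by]
        for cell in itertools.product(*by_levels) if by else [()]:
            cell_values = dict(zip(by, cell))
            for la, lb in itertools.combinations(levels, 2):
                La = self._emm_lvector({**cell_values, factor: la})
                Lb = self._emm_lvector({**cell_values, factor: lb})
                L = La - Lb
                est = float(L @ beta)
                se = float(np.sqrt(L @ C @ L))
                tval = est / se if se > 0 else 0.0
                rows.append(
                    {
                        **cell_values,
                        "contrast": f"{la} - {lb}",
                        "estimate": est,
                        "se": se,
                        "ci_lo": est - tcrit * se,
                        "ci_hi": est + tcrit * se,
                        "df": df,
                        "t": tval,
                        "p": float(2 * stats.t.sf(abs(tval), df)),
                    }
                )
        return pd.DataFrame(rows)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        d = self.model.design
        lines = [
            "Random-intercept LMM with heteroscedastic weighted residuals",
            f"  response: {d.response}   method: {self.method}",
            f"  n_obs: {self.n_obs}   participants: {self.n_groups}",
            f"  logLik: {self.llf:.4f}   AIC: {self.aic:.4f}",
            f"  sigma_b^2 (participant): {self.sigma_b2:.6g}",
            f"  sigma^2 (residual, ref level, weight 1): {self.sigma2:.6g}",
        ]
        if len(d.var_levels) == 2:
            lines.append(
                f"  variance ratio {d.var_levels[1]}/{d.var_levels[0]}: "
                f"{np.exp(2 * self.delta):.4f} (delta = {self.delta:.4f})"
            )
        lines.append("")
        lines.append(f"  {'term':32s} {'est':>10s} {'se':>9s} {'df':>6s} "
                     f"{'t':>8s} {'p':>8s}")
        bse = self.bse
        for term, idx in d.term_slices.items():
            dfd = self.denominator_df(term)
            for i in idx:
                name = d.columns[i]
                est = self.params.iloc[i]
                se = bse.iloc[i]
                tval = est / se if se > 0 else np.inf
                p = 2 * stats.t.sf(abs(tval), dfd)
                lines.append(
                    f"  {name:32s} {est:10.4f} {se:9.4f} {dfd:6d} "
                    f"{tval:8.3f} {p:8.4f}"
                )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model comparison and reduction

def lrt_pvalue(stat: float, df: int) -> float:
    """Upper-tail chi-square p-value for a likelihood-ratio statistic."""
    if df < 0:
        raise ValueError("df must be non-negative")
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(max(stat, 0.0), df))


def lrt(fit_full: LMMResults, fit_reduced: LMMResults) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML fits on the same data."""
    if fit_full.method != "ML" or fit_reduced.method != "ML":
        raise ValueError("LRT requires ML fits")
    if not np.array_equal(fit_full.model._y, fit_reduced.model._y):
        raise ValueError("LRT requires fits on the same data")
    full_cols = set(fit_full.params.index)
    red_cols = set(fit_reduced.params.index)
    if not red_cols <= full_cols:
        raise ValueError("models are not nested")
    df = len(full_cols) - len(red_cols)
    stat = max(0.0, 2.0 * (fit_full.llf - fit_reduced.llf))
    return stat, df, lrt_pvalue(stat, df)


def _eliminable(terms: tuple[str, ...]) -> list[str]:
    out = []
    for t in terms:
        if t == "intercept":
            continue
        if ":" in t:
            out.append(t)
            continue
        in_interaction = any(
            ":" in other and t in other.split(":") for other in terms
        )
        if not in_interaction:
            out.append(t)
    return out


@dataclass
class ReductionResult:
    final: LMMResults
    trace: pd.DataFrame
    full_ml: LMMResults
    final_ml: LMMResults
    lrt_stat: float
    lrt_df: int
    lrt_p: float

    @property
    def aic_full(self) -> float:
        return self.full_ml.aic

    @property
    def aic_final(self) -> float:
        return self.final_ml.aic


def backward_reduce(
    df: pd.DataFrame,
    response: str,
    full_terms=FULL_TERMS,
    alpha: float = 0.05,
    group_col: str = "participant_id",
    var_group_col: str | None = "nationality",
    weight_col: str | None = "weight",
) -> ReductionResult:
    """Backward elimination of non-significant fixed effects.

    Repeatedly refit by REML, Wald-F test every eliminable term (interactions
    before their main effects; a main effect is eliminable only when no
    retained interaction contains it), and drop the term with the largest
    p >= alpha.  The trace records every test at every step.  The full and
    final fixed structures are then refit by ML for the likelihood-ratio and
    AIC comparison.
    """

    def refit(terms, method="REML"):
        return ThreatBiasLMM.from_dataframe(
            df, response=response, terms=terms, group_col=group_col,
            var_group_col=var_group_col, weight_col=weight_col,
        ).fit(method)

    terms = tuple(full_terms)
    trace_rows = []
    step = 0
    current = refit(terms)
    while True:
        candidates = _eliminable(terms)
        if not candidates:
            break
        tests = {t: current.wald_f(t) for t in candidates}
        worst = max(candidates, key=lambda t: tests[t][3])
        fstat, dfn, dfd, p = tests[worst]
        for t in candidates:
            f_, n_, d_, p_ = tests[t]
            trace_rows.append(
                {"step": step, "term": t, "F": f_, "df_num": n_, "df_den": d_,
                 "p": p_, "action": "dropped" if (t == worst and p >= alpha)
                 else "kept"}
            )
        if p < alpha:
            break
        terms = tuple(t for t in terms if t != worst)
        current = refit(terms)
        step += 1

    full_ml = refit(tuple(full_terms), "ML")
    final_ml = refit(terms, "ML")
    stat, dof, p = lrt(full_ml, final_ml)
    return ReductionResult(
        final=current,
        trace=pd.DataFrame(
            trace_rows,
            columns=["step", "term", "F", "df_num", "df_den", "p", "action"],
        ),
        full_ml=full_ml,
        final_ml=final_ml,
        lrt_stat=stat,
        lrt_df=dof,
        lrt_p=p,
    )
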