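"""Phylogenetic generalized least squares with AICc model ranking.

The comparative analysis asks whether body mass and trophic level
predict the proportion of range a species has lost, while species
residuals are correlated through shared ancestry.  The model is

    y = X beta + eps,   eps ~ N(0, sigma^2 V(lambda)),

with V(lambda) the lambda-scaled Brownian covariance from the phylogeny.
beta is the GLS estimator, sigma^2 is profiled by maximum likelihood,
and lambda is either fixed or ML-profiled per model.  Candidate models
are ranked by small-sample AICc; models within 2 units of the best are
"well supported" (a threshold of 6 is also reported).

The four-candidate trait suite is: {mass}, {mass + trophic},
{mass + trophic + interaction}, {trophic}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_core import TraitTable
from .phylo import scale_lambda, tree_covariance

TRAIT_MODEL_SET = ("mass", "mass + trophic", "mass + trophic + interaction", "trophic")


def aicc(ll: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion.

    AICc = -2 LL + 2k + 2k(k+1)/(n-k-1); undefined when n <= k+1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aic(ll: float, k: int) -> float:
    return -2.0 * ll + 2.0 * k


def trait_design_matrix(
    traits: TraitTable,
    formula: str,
    log10_mass: bool = True,
    trophic_categorical: bool = True,
) -> pd.DataFrame:
    """Design matrix for one of the trait-model formulas.

    Body mass enters as log10(kg) by default (it spans four orders of
    magnitude); trophic level as an unordered categorical with herbivore
    (level 1) the reference, or numerically when
    ``trophic_categorical=False``.
    """
    if formula not in TRAIT_MODEL_SET:
        raise ValueError(f"unknown formula {formula!r}; expected one of {TRAIT_MODEL_SET}")
    t = traits.table
    mass = np.log10(t["body_mass_kg"]) if log10_mass else t["body_mass_kg"]
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(t))}
    troph: dict[str, np.ndarray] = {}
    if trophic_categorical:
        # unused levels are dropped, as for factors in R model matrices
        troph = {
            name: col
            for name, col in (
                ("trophic_omnivore", (t["trophic"] == 2).to_numpy(float)),
                ("trophic_carnivore", (t["trophic"] == 3).to_numpy(float)),
            )
            if col.any()
        }
    else:
        troph["trophic"] = t["trophic"].to_numpy(float)
    if "mass" in formula:
        cols["log10_mass" if log10_mass else "mass"] = mass.to_numpy(float)
    if "trophic" in formula:
        cols.update(troph)
    if "interaction" in formula:
        mname = "log10_mass" if log10_mass else "mass"
        for name, col in troph.items():
            cols[f"{mname}:{name}"] = cols[mname] * col
    X = pd.DataFrame(cols, index=t.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"design matrix for {formula!r} is rank-deficient: {list(X)}")
    return X


def _chol(V: np.ndarray) -> np.ndarray:
    """Cholesky factor, with escalating relative jitter for near-singular V.

    Trees with very short terminal branches give nearly identical
    covariance rows; a tiny diagonal inflation keeps the factorization
    stable without perturbing the fit at working precision.
    """
    scale = float(np.trace(V)) / len(V)
    for jitter in (0.0, 1e-12, 1e-10, 1e-8):
        try:
            return np.linalg.cholesky(V + jitter * scale * np.eye(len(V)))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance not positive-definite after jitter")


def _gls_profile(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """GLS beta, ML sigma^2 and log-likelihood for fixed covariance V."""
    n = len(y)
    L = _chol(V)
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    # exact fits (zero residual) would send the profile likelihood to
    # +inf; floor the variance so degenerate inputs stay finite
    sigma2_ml = max(rss / n, 1e-300)
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * math.log(2 * math.pi * sigma2_ml) + logdet_V + n)
    return beta, sigma2_ml, rss, ll, XtX, yw, Xw


@dataclass
class PGLSResults:
    """Fitted PGLS estimates, uncertainties and information criteria."""

    model: "PGLS"
    params: pd.Series
    bse: pd.Series
    llf: float
    lambda_: float
    sigma2_ml: float
    rss_gls: float
    k: int
    n: int
    df_resid: int
    rsquared: float
    rsquared_adj: float

    @property
    def aicc(self) -> float:
        return aicc(self.llf, self.k, self.n)

    @property
    def aic(self) -> float:
        return aic(self.llf, self.k)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), self.df_resid), index=self.params.index
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"PGLS results: {self.model.name or 'model'}",
            f"  n = {self.n}, k = {self.k}, lambda = {self.lambda_:.4f} "
            f"({self.model.lambda_mode})",
            f"  logLik = {self.llf:.3f}, AICc = {self.aicc:.3f}, "
            f"adj r^2 = {self.rsquared_adj:.3f}",
            f"  {'term':<28}{'coef':>10}{'se':>10}{'t':>8}{'p':>9}"
            f"{'[0.025':>10}{'0.975]':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<28}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.tvalues[name]:>8.2f}{self.pvalues[name]:>9.4f}"
                f"{ci.loc[name, 'lower']:>10.4f}{ci.loc[name, 'upper']:>10.4f}"
            )
        return "\n".join(lines)


class PGLS:
    """Phylogenetic GLS regression model.

    Parameters
    ----------
    y : response vector aligned with ``X`` rows.
    X : design matrix (include the intercept column explicitly, or use
        :func:`trait_design_matrix`).
    C : unscaled Brownian covariance matrix aligned with the rows.
    lambda_mode : "ml" profiles Pagel's lambda per model (default);
        "fixed" uses ``lambda_fixed``.
    count_lambda_param : whether an ML-estimated lambda adds 1 to the
        AICc parameter count k (k always counts the coefficients plus
        the residual variance).
    """

    def __init__(
        self,
        y,
        X: pd.DataFrame,
        C,
        lambda_mode: str = "ml",
        lambda_fixed: float = 1.0,
        count_lambda_param: bool = True,
        name: str = "",
    ):
        self.y = np.asarray(y, dtype=float)
        self.X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        self.C = np.asarray(C, dtype=float)
        n = len(self.y)
        if self.X.shape[0] != n or self.C.shape != (n, n):
            raise ValueError("y, X and C dimensions are not aligned")
        if np.linalg.matrix_rank(self.X.to_numpy()) < self.X.shape[1]:
            raise ValueError("design matrix is rank-deficient")
        if lambda_mode not in ("ml", "fixed"):
            raise ValueError("lambda_mode must be 'ml' or 'fixed'")
        self.lambda_mode = lambda_mode
        self.lambda_fixed = lambda_fixed
        self.count_lambda_param = count_lambda_param
        self.name = name

    @classmethod
    def from_traits(
        cls,
        traits: TraitTable,
        tree,
        response: str,
        formula: str = "mass + trophic",
        log10_mass: bool = True,
        trophic_categorical: bool = True,
        **kwargs,
    ) -> "PGLS":
        """Build a trait-suite model from a trait table and a phylogeny."""
        X = trait_design_matrix(traits, formula, log10_mass, trophic_categorical)
        order = list(X.index)
        C = tree_covariance(tree, taxa=order)
        y = traits.table.loc[order, response].to_numpy(float)
        kwargs.setdefault("name", formula)
        return cls(y, X, C.to_numpy(), **kwargs)

    def _loglik_at(self, lam: float) -> float:
        V = scale_lambda(self.C, lam)
        return _gls_profile(self.y, self.X.to_numpy(), V)[3]

    def fit(self) -> PGLSResults:
        n, p = self.X.shape
        if self.lambda_mode == "fixed":
            lam = self.lambda_fixed
        else:
            res = optimize.minimize_scalar(
                lambda t: -self._loglik_at(t), bounds=(0.0, 1.0), method="bounded",
                options={"xatol": 1e-8},
            )
            lam = float(res.x)
            # the optimum may sit at a boundary the bounded search skirts
            for edge in (0.0, 1.0):
                if self._loglik_at(edge) > self._loglik_at(lam):
                    lam = edge
        V = scale_lambda(self.C, lam)
        Xa = self.X.to_numpy()
        beta, sigma2_ml, rss, ll, XtX, yw, Xw = _gls_profile(self.y, Xa, V)
        df_resid = n - p
        sigma2_u = rss / df_resid if df_resid > 0 else np.nan
        cov_beta = sigma2_u * np.linalg.inv(XtX)
        bse = np.sqrt(np.diag(cov_beta))
        # GLS R^2 against the intercept-only GLS fit on the same V
        ones = np.ones((n, 1))
        _, _, tss, _, _, _, _ = _gls_profile(self.y, ones, V)
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid if df_resid > 0 else np.nan
        k = p + 1 + (1 if self.lambda_mode == "ml" and self.count_lambda_param else 0)
        return PGLSResults(
            model=self,
            params=pd.Series(beta, index=self.X.columns),
            bse=pd.Series(bse, index=self.X.columns),
            llf=ll,
            lambda_=lam,
            sigma2_ml=sigma2_ml,
            rss_gls=rss,
            k=k,
            n=n,
            df_resid=df_resid,
            rsquared=r2,
            rsquared_adj=r2_adj,
        )


@dataclass
class ModelRanking:
    """AICc-ranked model comparison with support flags."""

    table: pd.DataFrame  # index model name; LL, k, AICc, dAICc, supported flags
    fits: dict[str, object] = field(default_factory=dict)
    threshold: float = 2.0
    secondary_threshold: float = 6.0

    @property
    def best(self) -> str:
        return self.table.index[0]

    @property
    def supported(self) -> list[str]:
        return list(self.table.index[self.table["supported"]])


def rank_models(
    fits: dict[str, PGLSResults],
    threshold: float = 2.0,
    secondary_threshold: float = 6.0,
    criterion: str = "aicc",
) -> ModelRanking:
    """Rank fitted models by (A)ICc and flag the well-supported set.

    A model is well supported when its criterion lies within
    ``threshold`` (default 2) of the best model; a looser
    ``secondary_threshold`` (default 6) column is reported alongside.
    """
    if not fits:
        raise ValueError("no fits to rank")
    rows = {}
    for name, res in fits.items():
        ic = res.aicc if criterion == "aicc" else res.aic
        rows[name] = {
            "LL": res.llf,
            "k": res.k,
            criterion.upper(): ic,
            "adj_r2": getattr(res, "rsquared_adj", np.nan),
            "lambda": getattr(res, "lambda_", np.nan),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    col = criterion.upper()
    table[f"d{col}"] = table[col] - table[col].min()
    table = table.sort_values(f"d{col}", kind="stable")
    table["supported"] = table[f"d{col}"] < threshold
    table[f"supported_{int(secondary_threshold)}"] = table[f"d{col}"] < secondary_threshold
    return ModelRanking(
        table=table, fits=dict(fits), threshold=threshold,
        secondary_threshold=secondary_threshold,
    )


def run_trait_suite(
    traits: TraitTable,
    tree,
    response: str,
    lambda_mode: str = "ml",
    log10_mass: bool = True,
    trophic_categorical: bool = True,
    threshold: float = 2.0,
) -> ModelRanking:
    """Fit and rank the four-candidate trait model set for one response."""
    fits = {
        formula: PGLS.from_traits(
            traits, tree, response, formula,
            log10_mass=log10_mass, trophic_categorical=trophic_categorical,
            lambda_mode=lambda_mode,
        ).fit()
        for formula in TRAIT_MODEL_SET
    }
    return rank_models(fits, threshold=threshold)
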