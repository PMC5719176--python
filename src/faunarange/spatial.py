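"""Binomial GLMs of per-cell species loss on environmental predictors.

Each analysed grid cell contributes a count pair (species lost, species
retained) out of its older-period occupants, modelled with a logit-link
binomial GLM against six environmental surfaces: elevation (Elev, m),
Human Footprint Index (HFI), annual precipitation (Rain, mm/yr), annual
temperature (Temp, degC), actual and potential evapotranspiration
(AET/PET, mm/yr).  Ten a-priori predictor combinations (models a-j)
encode hypotheses about climatic, anthropogenic and physical drivers;
they are ranked by AICc and judged by the proportion of null deviance
explained.  An empirical-logit linear-model response is available as a
sensitivity mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grids import CellLossTable, GridSpec, empirical_logit
from .pgls import ModelRanking, aic as _aic, aicc as _aicc
from .projection import EqualAreaProjection
from .rasters import Raster

logger = logging.getLogger(__name__)

PREDICTORS = ("AET", "Elev", "HFI", "PET", "Rain", "Temp")

#: The ten a-priori model formulas, keyed by their conventional letters.
MODEL_SUITE: dict[str, tuple[str, ...]] = {
    "a": ("AET", "Elev", "HFI", "PET", "Rain", "Temp"),
    "b": ("AET", "HFI", "PET", "Rain", "Temp"),
    "c": ("AET", "PET", "Rain", "Temp"),
    "d": ("Elev", "HFI", "PET", "Rain", "Temp"),
    "e": ("Elev", "HFI", "PET", "Rain"),
    "f": ("HFI", "PET", "Rain"),
    "g": ("Elev", "PET", "Rain"),
    "h": ("Elev",),
    "i": ("HFI",),
    "j": ("PET", "Rain"),
}


@dataclass
class CellPredictorTable:
    """Per-cell predictor means and loss counts for one interval."""

    table: pd.DataFrame  # index cell_id; PREDICTORS + n_lost, n_retained
    dropped: list[str] = field(default_factory=list)  # cells lost to missing data

    @property
    def n_cells(self) -> int:
        return len(self.table)


def aggregate_predictors(
    rasters: dict[str, Raster],
    grid: GridSpec,
    loss: CellLossTable,
    projection: EqualAreaProjection | None = None,
    subsample: int = 5,
    min_coverage: float = 0.5,
) -> CellPredictorTable:
    """Aggregate predictor rasters to grid-cell means for analysed cells.

    Each cell is sampled on a ``subsample x subsample`` lattice of
    points (inverse-projected to the rasters' geographic coordinates);
    the cell value is the mean of non-missing samples.  Cells where any
    predictor has < ``min_coverage`` valid samples are dropped and
    logged.  Only cells flagged analysed in ``loss`` are returned.
    """
    missing = [p for p in PREDICTORS if p not in rasters]
    if missing:
        raise ValueError(f"missing predictor rasters: {missing}")
    proj = projection or EqualAreaProjection()
    offs = (np.arange(subsample) + 0.5) / subsample
    rows: dict[str, dict[str, float]] = {}
    dropped: list[str] = []
    analysed = loss.analysed
    for cid in analysed.index:
        x0, y0 = grid.cell_origin(cid)
        xs = x0 + offs * grid.cell_size
        ys = y0 + offs * grid.cell_size
        gx, gy = np.meshgrid(xs, ys)
        lon, lat = proj.inverse(gx.ravel(), gy.ravel())
        vals: dict[str, float] = {}
        ok = True
        for name in PREDICTORS:
            sample = rasters[name].sample(lon, lat)
            valid = np.isfinite(sample)
            if valid.mean() < min_coverage:
                ok = False
                break
            vals[name] = float(sample[valid].mean())
        if not ok:
            dropped.append(cid)
            continue
        vals["n_lost"] = int(analysed.loc[cid, "n_lost"])
        vals["n_retained"] = int(analysed.loc[cid, "n_old"] - analysed.loc[cid, "n_lost"])
        rows[cid] = vals
    if dropped:
        logger.warning("%d cells dropped for predictor coverage < %.0f%%: %s",
                       len(dropped), 100 * min_coverage, dropped[:10])
    table = pd.DataFrame.from_dict(rows, orient="index").rename_axis("cell_id")
    return CellPredictorTable(table=table, dropped=dropped)


@dataclass
class CellLossGLMResults:
    """One fitted suite member: coefficients, AICc and deviance explained."""

    model: "CellLossGLM"
    formula_id: str
    terms: tuple[str, ...]
    params: pd.Series  # on the standardized predictor scale
    bse: pd.Series
    params_raw: pd.Series  # back-transformed to native predictor units
    llf: float
    k: int
    n: int
    deviance: float
    null_deviance: float
    converged: bool

    @property
    def deviance_explained(self) -> float:
        """Proportion of null deviance explained, in [0, 1]."""
        if self.null_deviance <= 0:
            return 0.0
        return max(0.0, 1.0 - self.deviance / self.null_deviance)

    @property
    def aicc(self) -> float:
        return _aicc(self.llf, self.k, self.n)

    @property
    def aic(self) -> float:
        return _aic(self.llf, self.k)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy import stats

        q = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )

    def summary(self) -> str:
        lines = [
            f"Binomial GLM (model {self.formula_id}): "
            f"{' + '.join(self.terms) if self.terms else 'intercept only'}",
            f"  n cells = {self.n}, k = {self.k}, logLik = {self.llf:.3f}, "
            f"AICc = {self.aicc:.3f}",
            f"  deviance explained = {self.deviance_explained:.3f}",
            f"  {'term':<12}{'coef(z)':>10}{'se':>10}{'coef(raw)':>12}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<12}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.params_raw[name]:>12.6f}"
            )
        return "\n".join(lines)


class CellLossGLM:
    """Logit-link binomial GLM for the cell-loss count pairs.

    Predictors are z-standardized internally (coefficients are reported
    on both scales).  ``response="binomial"`` (default) fits the
    (n_lost, n_retained) pair; ``response="empirical_logit"`` fits an
    ordinary linear model to the empirical logit of the cell proportion.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        terms: tuple[str, ...] | list[str],
        formula_id: str = "",
        response: str = "binomial",
        standardize: bool = True,
    ):
        needed = set(terms) | {"n_lost", "n_retained"}
        missing = needed - set(table.columns)
        if missing:
            raise ValueError(f"cell table missing columns {sorted(missing)}")
        if (table["n_lost"] + table["n_retained"] < 1).any():
            raise ValueError("every analysed cell needs n_old >= 1")
        if response not in ("binomial", "empirical_logit"):
            raise ValueError("response must be 'binomial' or 'empirical_logit'")
        self.table = table
        self.terms = tuple(terms)
        self.formula_id = formula_id
        self.response = response
        self.standardize = standardize
        if len(table) < len(self.terms) + 2:
            raise ValueError(
                f"only {len(table)} cells for {len(self.terms)} predictors"
            )

    def fit(self, maxiter: int = 100, tol: float = 1e-8) -> CellLossGLMResults:
        tab = self.table
        X_raw = tab.loc[:, list(self.terms)].to_numpy(float) if self.terms else np.empty((len(tab), 0))
        mu = X_raw.mean(axis=0) if self.terms else np.array([])
        sd = X_raw.std(axis=0, ddof=0) if self.terms else np.array([])
        if self.standardize and self.terms:
            if np.any(sd == 0):
                bad = [t for t, s in zip(self.terms, sd) if s == 0]
                raise ValueError(f"constant predictors cannot be standardized: {bad}")
            Xz = (X_raw - mu) / sd
        else:
            Xz = X_raw
        X = sm.add_constant(Xz, has_constant="add")
        names = ["intercept", *self.terms]

        if self.response == "binomial":
            import warnings as _warnings

            from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

            endog = tab.loc[:, ["n_lost", "n_retained"]].to_numpy(float)
            glm = sm.GLM(endog, X, family=sm.families.Binomial())
            with _warnings.catch_warnings(record=True) as caught:
                _warnings.simplefilter("always", PerfectSeparationWarning)
                res = glm.fit(maxiter=maxiter, tol=tol)
                null = sm.GLM(
                    endog, np.ones((len(tab), 1)), family=sm.families.Binomial()
                ).fit()
            if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
                logger.warning(
                    "model %s: complete (quasi-)separation detected; "
                    "coefficients may not be identified",
                    self.formula_id or self.terms,
                )
            llf, dev, null_dev = float(res.llf), float(res.deviance), float(null.deviance)
            converged = bool(res.converged)
        else:
            n_old = (tab["n_lost"] + tab["n_retained"]).to_numpy(float)
            y = empirical_logit(tab["n_lost"].to_numpy(float) / n_old, n_old)
            res = sm.OLS(y, X).fit()
            llf = float(res.llf)
            dev = float(res.ssr)
            null_dev = float(res.centered_tss)
            converged = True

        params = pd.Series(res.params, index=names)
        bse = pd.Series(res.bse, index=names)
        if self.standardize and self.terms:
            raw = params.copy()
            raw[list(self.terms)] = params[list(self.terms)].to_numpy() / sd
            raw["intercept"] = params["intercept"] - float(
                (params[list(self.terms)].to_numpy() * mu / sd).sum()
            )
        else:
            raw = params.copy()
        k = X.shape[1] + (1 if self.response == "empirical_logit" else 0)
        if not converged:
            raise RuntimeError(
                f"model {self.formula_id or self.terms}: IRLS did not converge "
                f"in {maxiter} iterations"
            )
        return CellLossGLMResults(
            model=self,
            formula_id=self.formula_id,
            terms=self.terms,
            params=params,
            bse=bse,
            params_raw=raw,
            llf=llf,
            k=k,
            n=len(tab),
            deviance=dev,
            null_deviance=null_dev,
            converged=converged,
        )


def run_model_suite(
    cells: CellPredictorTable,
    suite: dict[str, tuple[str, ...]] | None = None,
    response: str = "binomial",
    criterion: str = "aicc",
    threshold: float = 2.0,
) -> ModelRanking:
    """Fit and rank the ten-model suite on one interval's cell table.

    A single failing fit is recorded and the suite continues; the
    ranking table carries LL, k, the information criterion, its delta to
    the best model, support flags and the deviance explained.
    """
    suite = suite or MODEL_SUITE
    fits: dict[str, CellLossGLMResults] = {}
    failures: dict[str, str] = {}
    for fid, terms in suite.items():
        try:
            fits[fid] = CellLossGLM(
                cells.table, terms, formula_id=fid, response=response
            ).fit()
        except Exception as exc:  # noqa: BLE001 - suite must survive one bad fit
            failures[fid] = str(exc)
            logger.warning("model %s failed: %s", fid, exc)
    if not fits:
        raise RuntimeError(f"every suite model failed: {failures}")
    rows = {}
    for fid, res in fits.items():
        ic = res.aicc if criterion == "aicc" else res.aic
        rows[fid] = {
            "formula": " + ".join(res.terms),
            "LL": res.llf,
            "k": res.k,
            criterion.upper(): ic,
            "pct_deviance_explained": res.deviance_explained,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    col = criterion.upper()
    table[f"d{col}"] = table[col] - table[col].min()
    table = table.sort_values(f"d{col}", kind="stable")
    table["supported"] = table[f"d{col}"] < threshold
    ranking = ModelRanking(table=table, fits=dict(fits), threshold=threshold)
    if failures:
        ranking.table.attrs["failures"] = failures
    return ranking
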