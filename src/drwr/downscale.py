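"""Surrogate construction: statistical and direct downscaling of RWR.

Statistical downscaling (SDC) fits rarity-weighted richness of coarse cells
as a function of environmental predictors measured on those cells, then
applies the fitted model to the same predictors measured on fine cells.  The
regressor is an ensemble of regression trees, each grown on a subsample of
about 66% of the coarse sites drawn without replacement; fit quality and
permutation importances are estimated out-of-bag (OOB), i.e. for each site
only from trees that did not train on it.

Predictors are chosen by varimax-rotated factor analysis (VrFA) of the
coarse environmental table: principal factors of the correlation matrix are
retained under the Kaiser criterion (eigenvalue > 1), varimax-rotated, and
the variable loading most heavily on each retained factor is selected.
Because the factors are orthogonal, the selected variables have low
multicollinearity.

Direct downscaling (DDC) skips modelling entirely: range maps are rasterized
onto the fine grid and RWR is computed from the overlap pattern.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor
from statsmodels.multivariate.factor_rotation import rotate_factors

from .complementarity import ComplementarityVector, rwr
from .grids import (
    EnvTable,
    GridSpec,
    OccurrenceMatrix,
    RangeMapSet,
    ValidationError,
    rasterize_ranges,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FactorModel",
    "DownscaleModel",
    "varimax",
    "vrfa_select",
    "fit_downscale_model",
    "predict_fine",
    "direct_downscale",
]


@dataclass
class FactorModel:
    """Varimax-rotated factor solution with one selected variable per factor."""

    variables: list[str]
    loadings: np.ndarray          # variable x retained factor, rotated
    eigenvalues: np.ndarray       # of the retained factors, before rotation
    selected: list[str]           # per-factor top-loading variable
    selected_unique: list[str]    # duplicates collapsed, order preserved
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def communalities(self) -> np.ndarray:
        return (self.loadings**2).sum(axis=1)


def varimax(loadings: np.ndarray, kaiser_normalize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Varimax-rotate a loading matrix; returns (rotated loadings, rotation).

    With ``kaiser_normalize`` each row is scaled to unit communality before
    rotation and scaled back afterwards, so variables contribute equally to
    the rotation criterion.  The rotation matrix is orthogonal, so per-row
    communalities are preserved.
    """
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2 or L.shape[1] < 1:
        raise ValidationError("loadings must be a 2-d matrix")
    if L.shape[1] == 1:
        return L.copy(), np.eye(1)
    # deterministic non-identity start: the identity is a stationary point of
    # the rotation criterion for symmetric loading patterns
    k = L.shape[1]
    T0, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(k, k)))
    if kaiser_normalize:
        h = np.sqrt((L**2).sum(axis=1))
        h = np.where(h > 0, h, 1.0)
        rotated, T = rotate_factors(L / h[:, None], "varimax", T=T0, tol=1e-10)
        rotated = rotated * h[:, None]
    else:
        rotated, T = rotate_factors(L, "varimax", T=T0, tol=1e-10)
    # canonical column order: match each rotated factor to the unrotated
    # factor it most resembles (rotation and start leave the order arbitrary)
    from scipy.optimize import linear_sum_assignment

    rows, cols = linear_sum_assignment(-np.abs(T))
    perm = cols[np.argsort(rows)]
    rotated, T = rotated[:, perm], T[:, perm]
    # sign convention: each factor's largest-magnitude loading is positive
    signs = np.sign(rotated[np.abs(rotated).argmax(axis=0), np.arange(L.shape[1])])
    signs[signs == 0] = 1.0
    return rotated * signs, T * signs


def vrfa_select(env: EnvTable, eigenvalue_threshold: float = 1.0) -> FactorModel:
    """Select low-multicollinearity predictors via varimax-rotated factors.

    Standardizes the non-constant variables over complete sites, extracts
    principal factors of their correlation matrix, retains factors with
    eigenvalue above the Kaiser threshold, varimax-rotates them, and picks
    the variable with maximal absolute rotated loading on each factor.
    """
    constant = env.constant_variables()
    if constant:
        warnings.warn(
            f"dropping {len(constant)} constant variable(s) from factor "
            f"analysis: {constant}",
            stacklevel=2,
        )
    variables = [v for v in env.variables if v not in constant]
    if len(variables) < 3:
        raise ValidationError(
            f"factor analysis needs >= 3 non-constant variables, have {len(variables)}"
        )
    sub = env.subset(variables)
    complete = sub.complete_rows()
    X = sub.values[complete]
    if X.shape[0] < len(variables) + 1:
        raise ValidationError(
            f"factor analysis needs more complete sites ({X.shape[0]}) than "
            f"variables ({len(variables)})"
        )
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    corr = (Z.T @ Z) / (Z.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # strict Kaiser cut with a numerical guard for exactly-degenerate spectra
    retained = eigval > eigenvalue_threshold + 1e-9
    n_factors = int(retained.sum())
    if n_factors == 0:
        raise ValidationError(
            "no factor passes the Kaiser criterion (all eigenvalues <= "
            f"{eigenvalue_threshold}); supply an explicit predictor list instead"
        )
    loadings = eigvec[:, :n_factors] * np.sqrt(eigval[:n_factors])
    rotated, _ = varimax(loadings)
    selected = [variables[int(np.abs(rotated[:, f]).argmax())] for f in range(n_factors)]
    selected_unique = list(dict.fromkeys(selected))
    if len(selected_unique) < len(selected):
        logger.info(
            "duplicate factor picks collapsed: %d factors -> %d unique variables",
            len(selected), len(selected_unique),
        )
    logger.info(
        "VrFA retained %d factor(s) (eigenvalues %s); selected: %s",
        n_factors, np.round(eigval[:n_factors], 3).tolist(), selected_unique,
    )
    return FactorModel(
        variables, rotated, eigval[:n_factors], selected, selected_unique, constant
    )


@dataclass
class DownscaleModel:
    """Fitted environment -> RWR tree ensemble with OOB diagnostics.

    ``importances`` holds, per predictor, the mean increase in a tree's OOB
    mean-squared error when that predictor's values are permuted among the
    tree's OOB sites — the permutation importance on the raw MSE scale.
    """

    predictors: list[str]
    trees: list[DecisionTreeRegressor]
    inbag: np.ndarray             # n_trees x n_sites boolean
    training_sites: list[str]
    y_train: np.ndarray
    oob_mse: float
    oob_r2: float
    importances: pd.Series
    n_trees: int
    sample_fraction: float
    seed: int
    source_tag: str = "SDC_a"
    dropped_sites: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Ensemble mean prediction for rows of predictor values."""
        acc = np.zeros(X.shape[0])
        for tree in self.trees:
            acc += tree.predict(X)
        return acc / len(self.trees)

    def fitted_values(self) -> np.ndarray:
        """In-sample ensemble predictions on the training sites."""
        X = np.asarray(self._X_train)
        return self.predict(X)

    def write_manifest(self, directory: str | Path) -> None:
        """Persist a plain-text manifest (parameters, OOB stats, importances)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        lines = [
            f"method_tag={self.source_tag}",
            f"predictors={','.join(self.predictors)}",
            f"n_trees={self.n_trees}",
            f"sample_fraction={self.sample_fraction}",
            f"seed={self.seed}",
            f"n_training_sites={len(self.training_sites)}",
            f"oob_mse={self.oob_mse:.10g}",
            f"oob_r2={self.oob_r2:.10g}",
        ]
        (directory / "model_manifest.txt").write_text("\n".join(lines) + "\n")
        self.importances.rename("oob_mse_increase").to_csv(
            directory / "importances.csv", index_label="predictor"
        )


def fit_downscale_model(
    occ_coarse: OccurrenceMatrix,
    env_coarse: EnvTable,
    predictors: list[str],
    n_trees: int = 500,
    seed: int = 0,
    sample_fraction: float = 0.66,
    source_tag: str = "SDC_a",
    max_features: str | float = "third",
) -> DownscaleModel:
    """Fit the coarse-scale RWR ~ environment tree ensemble.

    The dependent variable is the rarity-weighted richness of each coarse
    site.  Each of ``n_trees`` regression trees is grown on a subsample of
    ``sample_fraction`` of the sites drawn without replacement, splitting on
    a random third of the predictors at each node; the held-out ~34% of
    sites per tree supply the OOB error, OOB R2 and permutation importances.
    Sites with any missing predictor value are dropped (and recorded), not
    imputed.
    """
    bad = [p for p in predictors if p not in env_coarse.variables]
    if bad:
        raise ValidationError(f"predictor(s) not in environmental table: {bad}")
    if not predictors:
        raise ValidationError("empty predictor list")
    if set(occ_coarse.sites) != set(env_coarse.sites):
        raise ValidationError(
            "coarse occurrence and environmental tables cover different sites"
        )
    if n_trees < 200:
        warnings.warn(
            f"n_trees={n_trees} is below the ~200-tree error plateau for this "
            "kind of ensemble; results may be noisy",
            stacklevel=2,
        )
    y_all = rwr(occ_coarse)
    env_sub = env_coarse.subset(predictors)
    pos = {s: i for i, s in enumerate(env_sub.sites)}
    X_all = env_sub.values[[pos[s] for s in occ_coarse.sites]]
    complete = np.isfinite(X_all).all(axis=1)
    dropped = [s for s, ok in zip(occ_coarse.sites, complete) if not ok]
    if dropped:
        logger.warning("dropping %d site(s) with missing predictors", len(dropped))
    X = X_all[complete]
    y = y_all.scores[complete]
    sites = [s for s, ok in zip(occ_coarse.sites, complete) if ok]
    n = X.shape[0]
    if n < 10:
        raise ValidationError(f"only {n} complete sites; refusing an unstable fit")

    if max_features == "third":
        mf: int | float = max(1, round(len(predictors) / 3))
    else:
        mf = max_features
    rng = np.random.default_rng(seed)
    n_inbag = max(2, int(round(sample_fraction * n)))
    trees: list[DecisionTreeRegressor] = []
    inbag = np.zeros((n_trees, n), dtype=bool)
    for t in range(n_trees):
        idx = rng.choice(n, size=n_inbag, replace=False)
        inbag[t, idx] = True
        tree = DecisionTreeRegressor(
            max_features=mf, random_state=int(rng.integers(2**31))
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)

    # OOB predictions: average over trees for which the site was held out
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n)
    imp = np.zeros((n_trees, len(predictors)))
    for t, tree in enumerate(trees):
        oob_idx = np.flatnonzero(~inbag[t])
        if oob_idx.size == 0:
            continue
        X_oob = X[oob_idx]
        pred = tree.predict(X_oob)
        oob_sum[oob_idx] += pred
        oob_cnt[oob_idx] += 1
        base_mse = float(np.mean((pred - y[oob_idx]) ** 2))
        for j in range(len(predictors)):
            X_perm = X_oob.copy()
            X_perm[:, j] = X_perm[rng.permutation(oob_idx.size), j]
            perm_mse = float(np.mean((tree.predict(X_perm) - y[oob_idx]) ** 2))
            imp[t, j] = perm_mse - base_mse
    seen = oob_cnt > 0
    oob_pred = np.where(seen, oob_sum / np.maximum(oob_cnt, 1), np.nan)
    oob_mse = float(np.mean((oob_pred[seen] - y[seen]) ** 2))
    var_y = float(np.var(y[seen]))
    oob_r2 = 1.0 - oob_mse / var_y if var_y > 0 else 0.0

    model = DownscaleModel(
        predictors=list(predictors),
        trees=trees,
        inbag=inbag,
        training_sites=sites,
        y_train=y,
        oob_mse=oob_mse,
        oob_r2=oob_r2,
        importances=pd.Series(imp.mean(axis=0), index=predictors),
        n_trees=n_trees,
        sample_fraction=sample_fraction,
        seed=seed,
        source_tag=source_tag,
        dropped_sites=dropped,
    )
    model._X_train = X  # kept for in-sample fitted values
    logger.info(
        "fitted %d-tree downscale model on %d sites: OOB MSE %.4g, OOB R2 %.3f",
        n_trees, n, oob_mse, oob_r2,
    )
    return model


def predict_fine(model: DownscaleModel, env_fine: EnvTable) -> ComplementarityVector:
    """Apply a fitted coarse-scale model to fine-grain predictors.

    Fine sites with a missing predictor value are excluded from the output
    (and logged); predictions are clamped at 0 to respect the nonnegativity
    of RWR (tree averages cannot normally go below the training minimum, but
    the clamp makes the contract explicit).
    """
    missing = [p for p in model.predictors if p not in env_fine.variables]
    if missing:
        raise ValidationError(f"fine environmental table lacks predictor(s): {missing}")
    sub = env_fine.subset(model.predictors)
    complete = sub.complete_rows()
    if not complete.all():
        logger.warning(
            "excluding %d fine site(s) with missing predictor values",
            int((~complete).sum()),
        )
    X = sub.values[complete]
    pred = model.predict(X)
    n_clamped = int((pred < 0).sum())
    if n_clamped:
        logger.info("clamped %d negative prediction(s) to 0", n_clamped)
    pred = np.maximum(pred, 0.0)
    sites = [s for s, ok in zip(env_fine.sites, complete) if ok]
    return ComplementarityVector(sites, pred, model.source_tag)


def direct_downscale(ranges: RangeMapSet, grid: GridSpec) -> ComplementarityVector:
    """RWR computed directly from range-map overlap with the fine grid.

    Counts the ranges overlapping each fine cell and the fine cells covered
    by each range, then scores each cell by summed inverse coverage — i.e.
    RWR of the rasterized range maps.  Summed over cells, each species with a
    nonempty mask contributes exactly 1.
    """
    occ_fine = rasterize_ranges(ranges, grid, "fine")
    vec = rwr(occ_fine)
    return ComplementarityVector(vec.sites, vec.scores, "DDC_r")
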