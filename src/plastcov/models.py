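"""Multivariate models: ordinary least squares and CART regression trees.

Both model families regress a coverage outcome (normalized WRSD count or
E-score) on categorical predictors (structural partition, coding status,
sequencing platform) and quantitative quality scores, optionally with two
covariates (partition length, average read length) whose inclusion probes
confounding: when a covariate carries the signal, adding it demotes the
categorical predictor's explanatory share.

Linear models report the adjusted R-squared; trees use RMSE loss with
cost-complexity pruning selected by seeded 10-fold cross-validation, and
report variable importance as the total SSE reduction per variable rescaled
so the maximum is 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

#: reference-level orders for treatment coding (first level = reference)
CANONICAL_ORDERS = {
    "partition": ["LSC", "IRb", "SSC", "IRa"],
    "coding_status": ["coding", "noncoding"],
}


@dataclass
class ModelSpec:
    outcome: str
    predictors: list[str]
    covariates: list[str] = field(default_factory=list)
    seed: int = 0
    folds: int = 10
    min_node: int = 7
    max_depth: int = 5

    def __post_init__(self) -> None:
        if "software" in self.predictors or "software" in self.covariates:
            # high missingness makes 'missing' the dominant level
            raise ValueError("assembly software is excluded from multivariate models")

    @property
    def terms(self) -> list[str]:
        return list(self.predictors) + list(self.covariates)


@dataclass
class ModelResult:
    kind: str                                  # 'linear' | 'tree'
    n: int
    coef_table: pd.DataFrame | None = None     # linear only
    r2_adj: float | None = None                # linear only
    rmse: float | None = None                  # tree: training RMSE
    r2_train: float | None = None              # tree: training R^2
    cv_rmse: float | None = None               # tree: CV RMSE at chosen alpha
    ccp_alpha: float | None = None
    importance: dict[str, float] = field(default_factory=dict)
    tree_dump: dict | None = None
    feature_map: dict[str, str] = field(default_factory=dict)


def _level_order(col: str, values: pd.Series) -> list[str]:
    if col in CANONICAL_ORDERS:
        known = [lv for lv in CANONICAL_ORDERS[col] if lv in set(values)]
        extra = sorted(set(values) - set(known))
        return known + extra
    return sorted(values.unique())


def _design(table: pd.DataFrame, spec: ModelSpec, drop_first: bool
            ) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    """Complete-case design matrix; categoricals one-hot with canonical level
    order.  ``feature_map`` maps each design column to its source variable."""
    cols = [spec.outcome] + spec.terms
    df = table[cols].copy()
    for c in spec.terms:
        if df[c].dtype == object or isinstance(df[c].dtype, pd.CategoricalDtype):
            df = df[df[c].astype(str) != "missing"]
    df = df.dropna()
    y = df[spec.outcome].astype(float)
    parts, fmap = [], {}
    for c in spec.terms:
        if df[c].dtype == object or isinstance(df[c].dtype, pd.CategoricalDtype):
            order = _level_order(c, df[c])
            if len(order) < 2:
                raise ValueError(f"categorical predictor {c!r} has < 2 levels")
            cat = pd.Categorical(df[c], categories=order)
            dum = pd.get_dummies(cat, prefix=c, drop_first=drop_first).astype(float)
            dum.index = df.index
            parts.append(dum)
            fmap.update({col: c for col in dum.columns})
        else:
            parts.append(df[[c]].astype(float))
            fmap[c] = c
    X = pd.concat(parts, axis=1)
    return X, y, fmap


def fit_linear(table: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """OLS with treatment coding; reports the coefficient table and the
    adjusted R-squared."""
    X, y, fmap = _design(table, spec, drop_first=True)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        aliased = _aliased_columns(Xc)
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    fit = sm.OLS(y, Xc).fit()
    coef = pd.DataFrame({
        "term": Xc.columns,
        "estimate": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "t": fit.tvalues.to_numpy(),
        "p": fit.pvalues.to_numpy(),
    })
    return ModelResult("linear", n=len(y), coef_table=coef,
                       r2_adj=float(fit.rsquared_adj), feature_map=fmap)


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    cols, out = [], []
    M = X.to_numpy()
    rank = 0
    for j, name in enumerate(X.columns):
        r = np.linalg.matrix_rank(M[:, : j + 1])
        if r == rank:
            out.append(name)
        rank = r
    return out


def fit_tree(table: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """CART regression tree (squared-error loss) with cost-complexity pruning
    chosen by seeded K-fold cross-validated RMSE."""
    X, y, fmap = _design(table, spec, drop_first=False)
    if len(y) < 30:
        raise ValueError("need >= 30 complete cases for a regression tree")

    def make_tree(alpha: float) -> DecisionTreeRegressor:
        return DecisionTreeRegressor(
            max_depth=spec.max_depth, min_samples_leaf=spec.min_node,
            ccp_alpha=alpha, random_state=spec.seed)

    if np.ptp(y.to_numpy()) == 0:
        # constant outcome: degenerate single-node tree
        tree = make_tree(0.0).fit(X, y)
        return ModelResult("tree", n=len(y), rmse=0.0, r2_train=1.0,
                           cv_rmse=0.0, ccp_alpha=0.0,
                           importance={v: 0.0 for v in spec.terms},
                           tree_dump=_dump_tree(tree, list(X.columns)),
                           feature_map=fmap)

    path = make_tree(0.0).cost_complexity_pruning_path(X, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))

    kf = KFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    folds = list(kf.split(X))
    cv_rmse = np.zeros(len(alphas))
    Xv, yv = X.to_numpy(), y.to_numpy()
    for ai, alpha in enumerate(alphas):
        se = 0.0
        for tr, te in folds:
            t = make_tree(alpha).fit(Xv[tr], yv[tr])
            pred = t.predict(Xv[te])
            se += float(np.sum((pred - yv[te]) ** 2))
        cv_rmse[ai] = np.sqrt(se / len(yv))
    best = int(np.argmin(cv_rmse))
    tree = make_tree(float(alphas[best])).fit(X, y)

    pred = tree.predict(X)
    sse = float(np.sum((pred - yv) ** 2))
    sst = float(np.sum((yv - yv.mean()) ** 2))
    importance = _aggregate_importance(tree, list(X.columns), fmap, spec.terms)
    return ModelResult(
        "tree", n=len(y),
        rmse=float(np.sqrt(sse / len(yv))),
        r2_train=1.0 - sse / sst,
        cv_rmse=float(cv_rmse[best]),
        ccp_alpha=float(alphas[best]),
        importance=importance,
        tree_dump=_dump_tree(tree, list(X.columns)),
        feature_map=fmap,
    )


def _aggregate_importance(tree: DecisionTreeRegressor, columns: list[str],
                          fmap: dict[str, str], terms: list[str]) -> dict[str, float]:
    """Per-variable SSE-reduction importance, dummies summed per source
    variable, rescaled so the maximum is 100."""
    raw = tree.tree_.compute_feature_importances(normalize=False)
    agg = {v: 0.0 for v in terms}
    for col, imp in zip(columns, raw):
        agg[fmap[col]] += float(imp)
    mx = max(agg.values())
    if mx > 0:
        agg = {k: v / mx * 100.0 for k, v in agg.items()}
    return agg


def variable_importance(result: ModelResult) -> pd.DataFrame:
    """Importance scores ordered descending (tree models)."""
    if result.kind != "tree":
        raise ValueError("variable importance is defined for tree models")
    df = pd.DataFrame(sorted(result.importance.items(),
                             key=lambda kv: -kv[1]),
                      columns=["variable", "importance"])
    return df


def _dump_tree(tree: DecisionTreeRegressor, columns: list[str]) -> dict:
    t = tree.tree_

    def node(i: int) -> dict:
        if t.children_left[i] == -1:
            return {"leaf": True, "n": int(t.n_node_samples[i]),
                    "mean": float(t.value[i].ravel()[0])}
        return {"leaf": False,
                "split": columns[t.feature[i]],
                "threshold": float(t.threshold[i]),
                "n": int(t.n_node_samples[i]),
                "mean": float(t.value[i].ravel()[0]),
                "left": node(int(t.children_left[i])),
                "right": node(int(t.children_right[i]))}

    return node(0)
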