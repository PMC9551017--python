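"""From association to causation: lagged multivariate Granger regression.

Each target gene y is regressed on the lagged values of every candidate
regulator (lags 1..d), one of four regressors fits the design, and a
per-regulator importance is read off the fit:

* ``rf``       — random-forest variance-reduction (impurity) importances,
* ``xgboost``  — gradient-boosting total split gain per column,
* ``lasso``    — |coefficient| of an L1-penalised standardized fit,
* ``ridge``    — |coefficient| of an L2-penalised standardized fit.

Lag columns of the same gene are summed, self-lags are dropped from the
scores, each target's weights are normalised to sum to 1, and the weight
matrix is combined with the dynamic grey association (element-wise
product by default) into the final edge ranking.  A direction-resolution
rule in the style of lasso-Granger turns weights into a binary directed
network when one is requested: x -> y iff x carries weight for y but y
carries none for x; mutual weight means mutual regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grey_dynamics import AssociationMatrix, DgaParams, dynamic_grey_association
from .io_formats import ExpressionTable, RankedEdgeList, ValidationError

__all__ = [
    "LaggedDesign",
    "RegressorConfig",
    "WeightMatrix",
    "ScoredNetwork",
    "build_lagged_design",
    "fit_importances",
    "aggregate_lags",
    "assemble_weight_matrix",
    "combine_scores",
    "resolve_direction",
    "infer_network",
]

REGRESSOR_KINDS = ("rf", "xgboost", "lasso", "ridge")


@dataclass
class LaggedDesign:
    response: np.ndarray                 # (rows,)
    predictors: np.ndarray               # (rows, n_regulators * d)
    column_index: list[tuple[str, int]]  # (gene_id, lag) per column
    d: int
    target_id: str


@dataclass
class RegressorConfig:
    """Regressor choice and hyper-parameters.

    ``lam=None`` for lasso/ridge selects the penalty by 5-fold
    cross-validation over a logarithmic grid.  Stochastic regressors
    (rf, xgboost) are averaged over ``n_repeats`` reseeded fits.
    """

    kind: str = "lasso"
    lam: float | None = None
    n_trees: int = 100
    max_depth: int | None = None
    max_features: float | str = "sqrt"  # rf per-split feature subsample
    subsample: float = 1.0              # xgboost row subsample
    colsample: float = 1.0              # xgboost per-tree column subsample
    xgb_gamma: float = 0.0
    seed: int = 0
    n_repeats: int = 10

    def __post_init__(self):
        if self.kind not in REGRESSOR_KINDS:
            raise ValidationError(
                f"regressor kind must be one of {REGRESSOR_KINDS}, got {self.kind!r}"
            )
        if self.lam is not None and self.lam < 0:
            raise ValidationError("lambda must be >= 0")
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")


@dataclass
class WeightMatrix:
    """regulators x targets importance matrix; diagonal entries
    (self-regulation) are held at 0."""

    weights: np.ndarray
    regulator_ids: list[str]
    target_ids: list[str]
    normalized: bool = True

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.regulator_ids), len(self.target_ids)):
            raise ValidationError("weight matrix shape mismatch")
        if (self.weights < 0).any():
            raise ValidationError("importances must be non-negative")

    def get(self, regulator: str, target: str) -> float:
        """Weight of regulator -> target; 0 when regulator is not a row."""
        if regulator not in self.regulator_ids or target not in self.target_ids:
            return 0.0
        return float(
            self.weights[
                self.regulator_ids.index(regulator), self.target_ids.index(target)
            ]
        )


@dataclass
class ScoredNetwork:
    scores: np.ndarray
    regulator_ids: list[str]
    target_ids: list[str]
    combine_mode: str = "product"

    def to_ranked_edges(self) -> RankedEdgeList:
        rows = []
        for i, reg in enumerate(self.regulator_ids):
            for j, tgt in enumerate(self.target_ids):
                if reg == tgt:
                    continue
                rows.append((reg, tgt, float(self.scores[i, j])))
        return RankedEdgeList(rows=rows)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def build_lagged_design(
    table: ExpressionTable,
    target_id: str,
    d: int,
    regulator_ids: Sequence[str] | None = None,
) -> LaggedDesign:
    """Stack the lagged regression problem for one target gene.

    For every replicate block and every usable timepoint t in [d, n) the
    response is ``target[t]`` and the predictor row concatenates
    ``regulator_k[t - l]`` for each regulator k and lag l in 1..d.
    Rows never span a block boundary.
    """
    if d < 1:
        raise ValidationError("lag order d must be >= 1")
    regs = list(regulator_ids) if regulator_ids is not None else list(table.gene_ids)
    tgt_row = table.gene_index(target_id)
    reg_rows = [table.gene_index(g) for g in regs]
    ys, Xs = [], []
    for bi, block in enumerate(table.blocks):
        n = block.shape[1]
        if n <= d:
            raise ValidationError(
                f"block {bi} has {n} timepoints, need more than d={d}"
            )
        for t in range(d, n):
            ys.append(block[tgt_row, t])
            Xs.append(
                [block[r, t - lag] for r in reg_rows for lag in range(1, d + 1)]
            )
    column_index = [(g, lag) for g in regs for lag in range(1, d + 1)]
    return LaggedDesign(
        response=np.array(ys, dtype=float),
        predictors=np.array(Xs, dtype=float),
        column_index=column_index,
        d=d,
        target_id=target_id,
    )


# ---------------------------------------------------------------------------
# regressor fits
# ---------------------------------------------------------------------------


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _fit_linear(design: LaggedDesign, config: RegressorConfig) -> np.ndarray:
    from sklearn.linear_model import Lasso, LassoCV, Ridge, RidgeCV

    X = _standardize(design.predictors)
    y = design.response
    if np.allclose(y, y[0]):
        return np.zeros(X.shape[1])
    grid = np.logspace(-4, 1, 30)
    if config.kind == "lasso":
        if config.lam is None:
            model = LassoCV(alphas=grid, cv=5, max_iter=50_000)
        else:
            model = Lasso(alpha=max(config.lam, 1e-12), max_iter=50_000)
    else:
        if config.lam is None:
            model = RidgeCV(alphas=grid, cv=5)
        else:
            model = Ridge(alpha=config.lam)
    model.fit(X, y)
    return np.abs(model.coef_)


def _fit_rf(design: LaggedDesign, config: RegressorConfig) -> np.ndarray:
    from sklearn.ensemble import RandomForestRegressor

    X, y = design.predictors, design.response
    total = np.zeros(X.shape[1])
    for r in range(config.n_repeats):
        model = RandomForestRegressor(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            max_features=config.max_features,
            random_state=(config.seed + r) % 2**31,
            n_jobs=1,
        )
        model.fit(X, y)
        total += model.feature_importances_
    return total / config.n_repeats


def _fit_xgboost(design: LaggedDesign, config: RegressorConfig) -> np.ndarray:
    import xgboost as xgb

    X, y = design.predictors, design.response
    p = X.shape[1]
    total = np.zeros(p)
    names = [f"f{i}" for i in range(p)]
    for r in range(config.n_repeats):
        model = xgb.XGBRegressor(
            n_estimators=config.n_trees,
            max_depth=config.max_depth or 6,
            reg_lambda=config.lam if config.lam is not None else 1.0,
            gamma=config.xgb_gamma,
            subsample=config.subsample,
            colsample_bytree=config.colsample,
            random_state=(config.seed + r) % 2**31,
            n_jobs=1,
            verbosity=0,
        )
        model.fit(X, y)
        gains = model.get_booster().get_score(importance_type="total_gain")
        total += np.array([gains.get(nm, 0.0) for nm in names])
    return total / config.n_repeats


def fit_importances(design: LaggedDesign, config: RegressorConfig) -> np.ndarray:
    """Per-(gene, lag) non-negative importance vector for one target.

    Constant response or predictor columns are tolerated and simply
    receive zero importance.
    """
    if design.predictors.size == 0 or design.response.size == 0:
        raise ValidationError("empty design")
    if config.kind in ("lasso", "ridge"):
        return _fit_linear(design, config)
    if np.allclose(design.response, design.response[0]):
        return np.zeros(design.predictors.shape[1])
    if config.kind == "rf":
        return _fit_rf(design, config)
    return _fit_xgboost(design, config)


def aggregate_lags(
    importances: np.ndarray,
    column_index: Sequence[tuple[str, int]],
    target_id: str,
) -> dict[str, float]:
    """Sum lag-column importances per gene; the target's own
    autoregressive columns are dropped."""
    weights: dict[str, float] = {}
    for (gene, _lag), imp in zip(column_index, importances):
        if gene == target_id:
            continue
        weights[gene] = weights.get(gene, 0.0) + float(imp)
    return weights


# ---------------------------------------------------------------------------
# weight matrix and score combination
# ---------------------------------------------------------------------------


def assemble_weight_matrix(
    table: ExpressionTable,
    config: RegressorConfig,
    d: int = 2,
    regulator_ids: Sequence[str] | None = None,
    include_self_lags: bool = True,
    candidate_regulators: dict[str, list[str]] | None = None,
) -> WeightMatrix:
    """Fit one lagged regression per target and collect the importances.

    ``regulator_ids`` restricts rows to a TF list; ``candidate_regulators``
    optionally narrows each target's design to a per-target candidate
    set (used for DGA-top-k pre-filtering).  Each nonzero column is
    rescaled to sum to 1 so rankings are comparable across targets.
    """
    regs = list(regulator_ids) if regulator_ids is not None else list(table.gene_ids)
    targets = list(table.gene_ids)
    W = np.zeros((len(regs), len(targets)))
    reg_pos = {g: i for i, g in enumerate(regs)}
    for j, target in enumerate(targets):
        design_regs = [g for g in regs if g != target]
        if candidate_regulators is not None:
            allowed = set(candidate_regulators.get(target, design_regs))
            design_regs = [g for g in design_regs if g in allowed]
        if include_self_lags:
            design_regs = design_regs + [target]
        if not design_regs:
            continue
        design = build_lagged_design(table, target, d, design_regs)
        imp = fit_importances(design, config)
        for gene, w in aggregate_lags(imp, design.column_index, target).items():
            if gene in reg_pos:
                W[reg_pos[gene], j] = w
    col_sums = W.sum(axis=0)
    nz = col_sums > 0
    W[:, nz] /= col_sums[nz]
    return WeightMatrix(
        weights=W, regulator_ids=regs, target_ids=targets, normalized=True
    )


def combine_scores(
    dga: AssociationMatrix, w: WeightMatrix, mode: str = "product"
) -> ScoredNetwork:
    """Join association and regression evidence into final edge scores.

    ``product`` multiplies the two matrices element-wise;
    ``regression_only`` and ``dga_only`` keep a single factor (the two
    arms of the with/without-DGA ablation).
    """
    if mode not in ("product", "regression_only", "dga_only"):
        raise ValidationError(f"unknown combine mode {mode!r}")
    gene_pos = {g: i for i, g in enumerate(dga.gene_ids)}
    reg_idx = [gene_pos[g] for g in w.regulator_ids]
    tgt_idx = [gene_pos[g] for g in w.target_ids]
    dga_sub = dga.scores[np.ix_(reg_idx, tgt_idx)]
    if mode == "product":
        scores = dga_sub * w.weights
    elif mode == "regression_only":
        scores = w.weights.copy()
    else:
        scores = dga_sub.copy()
    for i, reg in enumerate(w.regulator_ids):
        for j, tgt in enumerate(w.target_ids):
            if reg == tgt:
                scores[i, j] = 0.0
    return ScoredNetwork(
        scores=scores,
        regulator_ids=list(w.regulator_ids),
        target_ids=list(w.target_ids),
        combine_mode=mode,
    )


def resolve_direction(
    w: WeightMatrix, threshold: float = 0.0
) -> set[tuple[str, str]]:
    """Binary directed edges from the weight matrix.

    ``x -> y`` is emitted iff w[x, y] > threshold while w[y, x] does not
    exceed it; when both exceed the threshold the genes regulate each
    other and both directions are emitted.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    edges: set[tuple[str, str]] = set()
    for i, x in enumerate(w.regulator_ids):
        for j, y in enumerate(w.target_ids):
            if x == y:
                continue
            if w.weights[i, j] > threshold:
                edges.add((x, y))
    return edges


# ---------------------------------------------------------------------------
# end-to-end inference
# ---------------------------------------------------------------------------


@dataclass
class InferenceParams:
    """Everything that determines one inference run."""

    dga: DgaParams = field(default_factory=DgaParams)
    regressor: RegressorConfig = field(default_factory=RegressorConfig)
    d: int = 2
    combine_mode: str = "product"
    regulator_ids: list[str] | None = None
    include_self_lags: bool = True
    dga_topk: int | None = None


def infer_network(
    table: ExpressionTable, params: InferenceParams | None = None
) -> tuple[RankedEdgeList, ScoredNetwork, AssociationMatrix, WeightMatrix]:
    """Run the full pipeline: DGA, Granger regression, combination.

    Returns the ranked edge list consumed by evaluation plus the three
    intermediate matrices for inspection.
    """
    params = params or InferenceParams()
    dga = dynamic_grey_association(table, params.dga)
    candidates = None
    if params.dga_topk is not None:
        gene_pos = {g: i for i, g in enumerate(dga.gene_ids)}
        regs = params.regulator_ids or list(table.gene_ids)
        candidates = {}
        for tgt in table.gene_ids:
            j = gene_pos[tgt]
            pool = [g for g in regs if g != tgt]
            ranked = sorted(pool, key=lambda g: (-dga.scores[gene_pos[g], j], g))
            candidates[tgt] = ranked[: params.dga_topk]
    w = assemble_weight_matrix(
        table,
        params.regressor,
        d=params.d,
        regulator_ids=params.regulator_ids,
        include_self_lags=params.include_self_lags,
        candidate_regulators=candidates,
    )
    network = combine_scores(dga, w, params.combine_mode)
    return network.to_ranked_edges(), network, dga, w
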