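"""Model/Results front end over the inference pipeline.

``GreyNet`` holds the data and configuration; ``fit()`` runs the two
stages (dynamic grey association, lagged Granger regression) and
returns a ``GreyNetResults`` carrying the association matrix, the
regression weight matrix, the combined edge scores, the ranked edge
list, and evaluation / export helpers.

Example
-------
>>> from greynet import GreyNet
>>> from greynet.synthetic_data import NetworkSpec, DynamicsSpec, \\
...     sample_network, simulate_timeseries
>>> gold, S = sample_network(NetworkSpec(m=10, seed=3))
>>> table = simulate_timeseries((gold, S), DynamicsSpec(seed=3))
>>> res = GreyNet(table, regressor="lasso", seed=3).fit()
>>> res.evaluate(gold).auroc > 0.5
True
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grey_dynamics import DgaParams
from .granger_regression import (
    InferenceParams,
    RegressorConfig,
    infer_network,
    resolve_direction,
)
from .io_formats import (
    ExpressionTable,
    GoldStandard,
    RankedEdgeList,
    read_timeseries_tsv,
    write_edge_ranking,
)
from .evaluation import EvaluationResult, evaluate_ranking

__all__ = ["GreyNet", "GreyNetResults"]


class GreyNet:
    """Gene regulatory network inference model for one time-course
    expression dataset.

    Parameters
    ----------
    table : ExpressionTable
        Genes x timepoints expression data, possibly several replicate
        blocks.
    regressor : {"rf", "xgboost", "lasso", "ridge"}
        Granger-regression back end.
    lags : int
        Lag order d of the lagged design.
    rho : float
        Distinguished coefficient of the grey relational coefficient.
    combine : {"product", "regression_only", "dga_only"}
        How association and regression evidence are joined.
    tf_list : sequence of str, optional
        Restrict candidate regulators to these genes.
    dga_topk : int, optional
        Pre-filter each target's candidate regulators to its K
        highest-association genes before regression.
    """

    def __init__(
        self,
        table: ExpressionTable,
        regressor: str = "lasso",
        lags: int = 2,
        rho: float = 0.5,
        lam: float | None = None,
        n_trees: int = 100,
        n_repeats: int = 10,
        combine: str = "product",
        normalization: str = "zscore",
        window_init: int | None = None,
        window_bounds: tuple[int | None, int | None] = (None, None),
        pool_extrema: str = "window",
        tf_list: Sequence[str] | None = None,
        dga_topk: int | None = None,
        include_self_lags: bool = True,
        seed: int = 0,
    ) -> None:
        self.table = table
        self.params = InferenceParams(
            dga=DgaParams(
                rho=rho,
                L_init=window_init,
                bounds=window_bounds,
                normalization=normalization,
                pool_extrema=pool_extrema,
            ),
            regressor=RegressorConfig(
                kind=regressor,
                lam=lam,
                n_trees=n_trees,
                n_repeats=n_repeats,
                seed=seed,
            ),
            d=lags,
            combine_mode=combine,
            regulator_ids=list(tf_list) if tf_list is not None else None,
            include_self_lags=include_self_lags,
            dga_topk=dga_topk,
        )

    @classmethod
    def from_tsv(cls, path: str | Path, dialect: str = "dream4", **kwargs) -> "GreyNet":
        """Build the model straight from a time-series TSV file."""
        return cls(read_timeseries_tsv(path, dialect), **kwargs)

    def fit(self) -> "GreyNetResults":
        """Run both stages and return the fitted results."""
        ranked, network, dga, weights = infer_network(self.table, self.params)
        return GreyNetResults(self, ranked, network, dga, weights)


class GreyNetResults:
    """Fitted edge scores and diagnostics of a :class:`GreyNet` run."""

    def __init__(self, model, ranked, network, dga, weights):
        self.model = model
        self.ranked_edges: RankedEdgeList = ranked
        self.network = network
        self.association = dga
        self.weights = weights

    @property
    def scores(self) -> np.ndarray:
        return self.network.scores

    def association_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.association.scores,
            index=self.association.gene_ids,
            columns=self.association.gene_ids,
        )

    def weight_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights.weights,
            index=self.weights.regulator_ids,
            columns=self.weights.target_ids,
        )

    def edges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.ranked_edges.rows, columns=["regulator", "target", "score"]
        )

    def directed_edges(self, threshold: float = 0.0) -> set[tuple[str, str]]:
        """Binary directed network via the direction-resolution rule."""
        return resolve_direction(self.weights, threshold)

    def evaluate(self, gold: GoldStandard) -> EvaluationResult:
        """AUROC/AUPRC of the ranking against a gold standard."""
        return evaluate_ranking(self.ranked_edges, gold)

    def save_ranking(self, path: str | Path) -> None:
        write_edge_ranking(self.ranked_edges, path)

    def summary(self, top: int = 10) -> str:
        """Human-readable run summary with the top-ranked edges."""
        p = self.model.params
        lines = [
            "GreyNet inference results",
            "=" * 41,
            f"genes:            {self.model.table.n_genes}",
            f"replicate blocks: {self.model.table.n_blocks}",
            f"regressor:        {p.regressor.kind}",
            f"lag order d:      {p.d}",
            f"rho:              {p.dga.rho}",
            f"normalization:    {p.dga.normalization}",
            f"combine mode:     {p.combine_mode}",
            f"ranked edges:     {len(self.ranked_edges)}",
            "-" * 41,
            f"top {min(top, len(self.ranked_edges))} edges (regulator -> target, score):",
        ]
        for reg, tgt, s in self.ranked_edges.rows[:top]:
            lines.append(f"  {reg:>8s} -> {tgt:<8s} {s:.4f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<GreyNetResults: {self.model.table.n_genes} genes, "
            f"{len(self.ranked_edges)} ranked edges>"
        )
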