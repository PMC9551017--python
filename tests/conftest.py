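import numpy as np
import pytest

from greynet.io_formats import ExpressionTable
from greynet.synthetic_data import (
    DynamicsSpec,
    NetworkSpec,
    sample_network,
    simulate_timeseries,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def toy_table():
    """3 genes x 10 timepoints, one block, deterministic values."""
    rng = np.random.default_rng(7)
    return ExpressionTable(
        gene_ids=["g1", "g2", "g3"],
        blocks=[rng.uniform(1.0, 10.0, size=(3, 10))],
    )


@pytest.fixture
def dream4_like():
    """10-gene, 5-block, 21-timepoint synthetic benchmark instance."""
    gold, strengths = sample_network(NetworkSpec(m=10, density=0.15, seed=42))
    table = simulate_timeseries(
        (gold, strengths),
        DynamicsSpec(model="var1", n_timepoints=21, n_blocks=5, noise_sd=0.1, seed=42),
    )
    return table, gold


@pytest.fixture
def dream4_file(tmp_path, dream4_like):
    from greynet.io_formats import write_gold_standard, write_timeseries_tsv

    table, gold = dream4_like
    expr = tmp_path / "expr.tsv"
    goldp = tmp_path / "gold.tsv"
    write_timeseries_tsv(table, expr, dialect="dream4")
    write_gold_standard(gold, goldp)
    return expr, goldp
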