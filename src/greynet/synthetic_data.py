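"""Synthetic regulatory networks and time-series with known causal
structure.

The generator emulates the shape of the DREAM4 in-silico time-series
benchmark: small directed networks (10-100 genes, no self-loops) and
several replicate series of ~21 timepoints each.  Two dynamics are
available:

* ``var1`` — a stable first-order vector autoregression
  ``x_t = A x_{t-1} + eps``; Granger-style inference is provably
  consistent here, so the causal half of the pipeline must recover the
  support of A.  A is rescaled to spectral radius 0.9 (strong but
  stationary signal).
* ``hill_ode`` — saturating Hill-kinetics ODEs
  ``dx_i/dt = sum_parents beta * hill(x_p) - gamma * x_i`` integrated
  by fixed-step RK4 with observation noise, a harder nonlinear surface
  for the tree regressors.

Defaults (10 genes, edge density 0.15, 21 timepoints, 5 replicate
blocks, noise sd 0.1) mirror the size-10 benchmark shape with lag-1
signal-to-noise around 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import (
    ExpressionTable,
    GoldStandard,
    ValidationError,
    write_gold_standard,
    write_timeseries_tsv,
)

__all__ = [
    "NetworkSpec",
    "DynamicsSpec",
    "sample_network",
    "simulate_timeseries",
    "make_fixture",
]


@dataclass
class NetworkSpec:
    m: int = 10
    density: float = 0.15
    topology: str = "erdos_renyi"   # erdos_renyi | scale_free_out
    coef_range: tuple[float, float] = (0.5, 1.0)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.density < 1:
            raise ValidationError("density must be in [0, 1)")
        if self.topology not in ("erdos_renyi", "scale_free_out"):
            raise ValidationError(f"unknown topology {self.topology!r}")
        if self.m < 2:
            raise ValidationError("need at least 2 genes")


@dataclass
class DynamicsSpec:
    model: str = "var1"             # var1 | hill_ode
    noise_sd: float = 0.1
    n_timepoints: int = 21
    n_blocks: int = 5
    dt: float = 0.1                 # hill_ode integration step
    spectral_radius: float = 0.9    # var1 stability target
    self_decay: float = 0.5         # autoregressive diagonal before rescale
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("var1", "hill_ode"):
            raise ValidationError(f"unknown dynamics model {self.model!r}")
        if self.n_timepoints < 5:
            raise ValidationError("need at least 5 timepoints")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def _gene_ids(m: int) -> list[str]:
    return [f"G{i + 1}" for i in range(m)]


def sample_network(spec: NetworkSpec) -> tuple[GoldStandard, np.ndarray]:
    """Draw a directed network and signed edge strengths.

    Returns the gold standard (positive edge set) and an (m, m) signed
    strength matrix S with S[i, j] != 0 iff gene i regulates gene j;
    strengths are uniform on +/-[coef_lo, coef_hi].
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.m
    genes = _gene_ids(m)
    adj = np.zeros((m, m), dtype=bool)
    if spec.topology == "erdos_renyi":
        mask = rng.random((m, m)) < spec.density
        np.fill_diagonal(mask, False)
        adj = mask
    else:
        # out-hub preferential attachment: few regulators own most edges
        n_edges = max(1, round(spec.density * m * (m - 1)))
        out_w = 1.0 / (np.arange(m) + 1)  # Zipf-ish out-degree propensity
        out_w /= out_w.sum()
        placed = 0
        while placed < n_edges:
            i = rng.choice(m, p=out_w)
            j = rng.integers(m)
            if i != j and not adj[i, j]:
                adj[i, j] = True
                placed += 1
    lo, hi = spec.coef_range
    signs = rng.choice([-1.0, 1.0], size=(m, m))
    mags = rng.uniform(lo, hi, size=(m, m))
    strengths = np.where(adj, signs * mags, 0.0)
    edges = {(genes[i], genes[j]) for i, j in zip(*np.nonzero(adj))}
    return GoldStandard(edges=edges, gene_ids=genes), strengths


def _stabilize(strengths: np.ndarray, dyn: DynamicsSpec) -> np.ndarray:
    """VAR(1) transition matrix: edge strengths plus a self-decay
    diagonal, rescaled to the target spectral radius.  Note the
    transition acts as x_t = A x_{t-1} with A[j, i] carrying edge
    i -> j, i.e. A is the transpose of the strength matrix."""
    A = strengths.T.copy()
    np.fill_diagonal(A, dyn.self_decay)
    radius = np.max(np.abs(np.linalg.eigvals(A)))
    if radius > 0:
        A *= dyn.spectral_radius / radius
    return A


def simulate_timeseries(
    network: tuple[GoldStandard, np.ndarray] | np.ndarray,
    dyn: DynamicsSpec,
) -> ExpressionTable:
    """Simulate replicate expression time series from a known network.

    Accepts either the (gold, strengths) pair from :func:`sample_network`
    or a bare strength matrix.  Output values are shifted to be
    positive, expression-like.
    """
    strengths = network[1] if isinstance(network, tuple) else np.asarray(network)
    m = strengths.shape[0]
    rng = np.random.default_rng(dyn.seed)
    blocks = []
    if dyn.model == "var1":
        A = _stabilize(strengths, dyn)
        for _ in range(dyn.n_blocks):
            x = rng.standard_normal(m)
            traj = [x]
            for _ in range(dyn.n_timepoints - 1):
                x = A @ x + rng.normal(0.0, dyn.noise_sd, size=m)
                traj.append(x)
            blocks.append(np.array(traj).T)
    else:
        blocks = _simulate_hill(strengths, dyn, rng)
    # shift to positive, expression-like values (one global offset so
    # replicate blocks stay comparable)
    lo = min(b.min() for b in blocks)
    offset = 0.5 - lo
    blocks = [b + offset for b in blocks]
    return ExpressionTable(gene_ids=_gene_ids(m), blocks=blocks)


def _hill(x: np.ndarray, K: float = 1.0, h: float = 2.0) -> np.ndarray:
    xp = np.clip(x, 0.0, None)
    return xp**h / (K**h + xp**h)


def _simulate_hill(strengths: np.ndarray, dyn: DynamicsSpec, rng) -> list[np.ndarray]:
    m = strengths.shape[0]
    gamma = 0.5
    steps_per_obs = 5

    def deriv(x):
        act = _hill(x)
        rep = 1.0 - act
        drive = np.zeros(m)
        for i, j in zip(*np.nonzero(strengths)):
            s = strengths[i, j]
            drive[j] += abs(s) * (act[i] if s > 0 else rep[i])
        return drive - gamma * x + 0.1

    blocks = []
    for _ in range(dyn.n_blocks):
        x = rng.uniform(0.2, 1.5, size=m)
        obs = [x.copy()]
        for _ in range(dyn.n_timepoints - 1):
            for _ in range(steps_per_obs):
                k1 = deriv(x)
                k2 = deriv(x + 0.5 * dyn.dt * k1)
                k3 = deriv(x + 0.5 * dyn.dt * k2)
                k4 = deriv(x + dyn.dt * k3)
                x = x + dyn.dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            obs.append(x + rng.normal(0.0, dyn.noise_sd, size=m))
        blocks.append(np.array(obs).T)
    return blocks


def make_fixture(
    spec: NetworkSpec, dyn: DynamicsSpec, out_dir: str | Path
) -> dict[str, Path]:
    """Write a DREAM4-dialect time-series TSV and its gold standard.

    Returns the paths of the two files; both round-trip through
    io_formats unchanged.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gold, strengths = sample_network(spec)
    table = simulate_timeseries((gold, strengths), dyn)
    expr_path = out_dir / "timeseries.tsv"
    gold_path = out_dir / "goldstandard.tsv"
    write_timeseries_tsv(table, expr_path, dialect="dream4")
    write_gold_standard(gold, gold_path)
    return {"expression": expr_path, "gold": gold_path}
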