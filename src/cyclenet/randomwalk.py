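"""Random walk with restart on the augmented gene network.

The walker at a node follows each outgoing edge with equal probability,
so row u of the transition matrix M puts 1/outdeg(u) on every
out-neighbour.  Iterating P_{t+1} = P_t M from the uniform-over-genes
start vector (0, 1/n, ..., 1/n, 0) gives the trajectory of visiting
probabilities; because the augmented graph is strongly connected and
aperiodic the trajectory converges to the unique stationary distribution
P with PM = P — equivalently the eigenvector of M^T at eigenvalue 1.
The stationary probability of a gene measures how strongly the network
as a whole influences it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .interactions import GeneNetwork

__all__ = [
    "TransitionMatrix",
    "StateTrajectory",
    "StationaryDistribution",
    "GeneSeries",
    "NonErgodicError",
    "transition_matrix",
    "initial_distribution",
    "walk",
    "stationary",
    "extract_gene_series",
]


class NonErgodicError(RuntimeError):
    """The chain has no unique stationary limit reachable by the solver."""


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition matrix with its node ordering."""

    values: np.ndarray
    node_order: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.values, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("transition matrix must be square")
        if m.shape[0] != len(self.node_order):
            raise ValueError("node order length does not match matrix dimension")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12, rtol=0):
            raise ValueError("every row of a transition matrix must sum to 1")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class StateTrajectory:
    """A sequence of state vectors indexed by time.

    For a random walk the states are probability vectors over the graph
    nodes and ``times`` are integer step counts; for the ODE model the
    states are gene expression levels and ``times`` are real.
    """

    times: np.ndarray
    states: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.times) != self.states.shape[0] or len(self.times) == 0:
            raise ValueError("times and states must be non-empty and aligned")
        if self.states.shape[1] != len(self.labels):
            raise ValueError("state dimension does not match labels")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.labels))
        df.insert(0, "t", self.times)
        return df

    def to_csv(self) -> str:
        return self.to_frame().to_csv(index=False)


@dataclass(frozen=True)
class StationaryDistribution:
    """Stationary probability vector and the residual max|PM - P|."""

    probabilities: np.ndarray
    residual: float
    node_order: tuple[str, ...]
    method: str
    iterations: int = 0

    def to_series(self) -> pd.Series:
        return pd.Series(self.probabilities, index=list(self.node_order))


@dataclass(frozen=True)
class GeneSeries:
    """Per-gene scalar sample sequences extracted from a walk trajectory."""

    labels: tuple[str, ...]
    values: np.ndarray  # shape (n_steps, n_genes)
    step_size: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.labels))
        df.insert(0, "t", np.arange(len(df)) * self.step_size)
        return df


def transition_matrix(network: GeneNetwork) -> TransitionMatrix:
    """Uniform-out-edge transition matrix of the network, rows in node order."""
    nodes = network.nodes
    index = {node: k for k, node in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for u in nodes:
        succ = list(network.graph.successors(u))
        if not succ:
            raise ValueError(f"node {u!r} has out-degree 0; the walk cannot leave it")
        p = 1.0 / len(succ)
        for v in succ:
            m[index[u], index[v]] = p
    return TransitionMatrix(values=m, node_order=nodes)


def initial_distribution(network: GeneNetwork) -> np.ndarray:
    """Start vector (0, 1/n, ..., 1/n, 0): uniform over genes, zero on S and T."""
    n = network.n_genes
    p0 = np.full(network.n_nodes, 1.0 / n)
    p0[0] = 0.0
    p0[-1] = 0.0
    return p0


def walk(matrix: TransitionMatrix, p0: np.ndarray, steps: int) -> StateTrajectory:
    """Iterate P_{t+1} = P_t M for ``steps`` steps, recording every state."""
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (matrix.n,):
        raise ValueError(f"initial vector has dimension {p0.shape}, expected ({matrix.n},)")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if not np.isclose(p0.sum(), 1.0, atol=1e-12):
        raise ValueError("initial vector must be a probability distribution")
    states = np.empty((steps + 1, matrix.n))
    states[0] = p0
    for t in range(steps):
        states[t + 1] = states[t] @ matrix.values
    return StateTrajectory(
        times=np.arange(steps + 1), states=states, labels=matrix.node_order
    )


def stationary(
    matrix: TransitionMatrix,
    method: str = "eigen",
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> StationaryDistribution:
    """Solve PM = P for the stationary distribution.

    ``method='eigen'`` takes the eigenvector of M^T at the eigenvalue
    closest to 1 (it must be within 1e-8 of 1); ``method='power'``
    iterates from the uniform vector until the L1 change drops below
    ``tol``.  Tiny negative components are clipped and the vector is
    renormalized to sum 1.
    """
    m = matrix.values
    iterations = 0
    if method == "eigen":
        eigvals, eigvecs = scipy.linalg.eig(m.T)
        k = int(np.argmin(np.abs(eigvals - 1.0)))
        if abs(eigvals[k] - 1.0) > 1e-8:
            raise NonErgodicError(
                f"no eigenvalue within 1e-8 of 1 (closest: {eigvals[k]:.6g}); "
                "the chain is not ergodic"
            )
        p = np.real(eigvecs[:, k])
        p = p / p.sum()
    elif method == "power":
        p = np.full(matrix.n, 1.0 / matrix.n)
        for iterations in range(1, max_iter + 1):
            nxt = p @ m
            if np.abs(nxt - p).sum() < tol:
                p = nxt
                break
            p = nxt
        else:
            raise NonErgodicError(
                f"power iteration did not converge within {max_iter} iterations; "
                "the chain may not be ergodic"
            )
    else:
        raise ValueError(f"unknown method {method!r} (expected 'eigen' or 'power')")

    p[(p < 0) & (p > -1e-12)] = 0.0  # floating-point noise from the eigensolver
    if np.any(p < 0):
        raise NonErgodicError("stationary solve produced a genuinely negative component")
    p = p / p.sum()
    residual = float(np.max(np.abs(p @ m - p)))
    return StationaryDistribution(
        probabilities=p,
        residual=residual,
        node_order=matrix.node_order,
        method=method,
        iterations=iterations,
    )


def extract_gene_series(
    trajectory: StateTrajectory, network: GeneNetwork, genes: list[str] | tuple[str, ...]
) -> GeneSeries:
    """Pull out the per-step probabilities of the named gene nodes."""
    nodes = list(trajectory.labels)
    cols = []
    for lab in genes:
        if lab not in nodes:
            raise KeyError(f"unknown gene label {lab!r}")
        cols.append(nodes.index(lab))
    return GeneSeries(labels=tuple(genes), values=trajectory.states[:, cols])
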