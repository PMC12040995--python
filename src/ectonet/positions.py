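"""Per-host position indices in an individual-based bipartite network.

Four indices characterize each host individual:

* **strength** -- the summed dependencies of all parasite species on the
  host, ``s_i = sum_j a_ij / A_j``; host strengths sum to the number of
  parasite species.
* **nested rank** -- the host's rank once the matrix is re-arranged for
  maximal nestedness, normalized to [0, 1] (0 = most generalist).
* **d'** -- Kullback-Leibler divergence of the host's interaction
  frequencies from the parasite marginal distribution, normalized to [0, 1].
* **eigenvector centrality** -- principal-eigenvector centrality of the
  host in the unipartite (host x host) projection of the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ectonet.netcore import InteractionMatrix, NetworkBundle, to_binary


@dataclass
class PositionTable:
    """Per-host position indices for one network."""

    table: pd.DataFrame  # columns: host_id, sex, strength, nested_rank, dprime, evcent

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def individual_strength(matrix: InteractionMatrix) -> np.ndarray:
    """Sum over parasite species of the share of that species found on the host.

    Conservation: strengths sum to the number of parasite columns.
    """
    a = matrix.counts.astype(float)
    return (a / a.sum(axis=0, keepdims=True)).sum(axis=1)


def nested_rank(matrix: InteractionMatrix, method: str = "degree_sort") -> np.ndarray:
    """Normalized rank of each host in the maximally nested row ordering.

    Rows are ordered by decreasing binary degree, ties broken by decreasing
    row total, then by input order (stable).  Rank ``r`` in {1..S} maps to
    ``(r - 1) / (S - 1)``: 0 = most generalist, 1 = most specialized.
    """
    if method != "degree_sort":
        raise ValueError(f"unknown nested-rank method {method!r}")
    a = matrix.counts
    n = a.shape[0]
    if n < 2:
        raise ValueError("nested rank undefined for a single host")
    degree = (a > 0).sum(axis=1)
    abundance = a.sum(axis=1)
    # lexsort: last key is primary; negate for decreasing order
    order = np.lexsort((np.arange(n), -abundance, -degree))
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    return (ranks - 1) / (n - 1)


def specialization_dprime(matrix: InteractionMatrix) -> np.ndarray:
    """Standardized Kullback-Leibler specialization d' per host.

    For host i with interaction frequencies ``p_ij = a_ij / A_i`` and
    parasite availability ``q_j = A_j / m``:
    ``d_i = sum_{a_ij>0} p_ij * ln(p_ij / q_j)``, normalized by the
    real-valued bounds ``d_min = 0`` and ``d_max = ln(m / A_i)`` and clamped
    to [0, 1].  A host holding every interaction in the network (d_max = 0)
    gets d' = 0.
    """
    a = matrix.counts.astype(float)
    A_i = a.sum(axis=1)
    m = a.sum()
    q = a.sum(axis=0) / m
    p = a / A_i[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(a > 0, p * np.log(p / q[None, :]), 0.0)
    d = terms.sum(axis=1)
    d_max = np.log(m / A_i)
    out = np.zeros_like(d)
    pos = d_max > 0
    out[pos] = d[pos] / d_max[pos]
    return np.clip(out, 0.0, 1.0)


def project_unipartite(matrix: InteractionMatrix, method: str = "sum") -> np.ndarray:
    """One-mode (host x host) projection of the bipartite count matrix.

    ``sum``    -- w_gh = sum over shared parasite species of (a_gj + a_hj)
    ``binary`` -- number of shared parasite species
    ``newman`` -- shared species weighted by 1/(n_j - 1) where n_j is the
                  number of hosts carrying species j (singleton species
                  contribute nothing)
    """
    a = matrix.counts.astype(float)
    b = (a > 0).astype(float)
    if method == "sum":
        # sum over shared j of (a_gj + a_hj) = a B^T + B a^T restricted to shared cells
        w = a @ b.T + b @ a.T
    elif method == "binary":
        w = b @ b.T
    elif method == "newman":
        n_j = b.sum(axis=0)
        inv = np.where(n_j > 1, 1.0 / np.maximum(n_j - 1, 1), 0.0)
        w = (b * inv[None, :]) @ b.T
    else:
        raise ValueError(f"unknown projection method {method!r}")
    np.fill_diagonal(w, 0.0)
    return w


def eigenvector_centrality(
    projection: np.ndarray, tol: float = 1e-12, max_iter: int = 10_000
) -> np.ndarray:
    """Principal-eigenvector centrality of a weighted undirected graph.

    Power iteration from a uniform start vector; entries are rescaled so the
    maximum equals 1.  On a disconnected graph, components not carrying the
    principal eigenvalue decay to 0.
    """
    w = np.asarray(projection, dtype=float)
    if w.shape[0] != w.shape[1] or not np.allclose(w, w.T):
        raise ValueError("projection must be a symmetric square matrix")
    if (w < 0).any():
        raise ValueError("projection weights must be non-negative")
    if not w.any():
        raise ValueError(
            "all-zero projection: no two hosts share a parasite species; "
            "eigenvector centrality is undefined on an empty graph"
        )
    n = w.shape[0]
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        # iterate on I + W: same eigenvectors, but strictly dominant top
        # eigenvalue even when the graph is bipartite (spectrum symmetric)
        y = x + w @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            break
        y /= norm
        if np.abs(y - x).max() < tol:
            x = y
            break
        x = y
    x = np.abs(x)
    return x / x.max()


def position_table(bundle: NetworkBundle, projection_method: str = "sum") -> PositionTable:
    """Assemble the four position indices for every host of a bundle."""
    m = bundle.matrix
    table = pd.DataFrame(
        {
            "host_id": m.host_ids,
            "sex": bundle.sexes,
            "strength": individual_strength(m),
            "nested_rank": nested_rank(m),
            "dprime": specialization_dprime(m),
            "evcent": eigenvector_centrality(project_unipartite(m, projection_method)),
        }
    )
    return PositionTable(table=table)
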