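"""Bipartite module detection and Guimera-Amaral network roles.

Modules are groups of host individuals and parasite species that interact
mostly with each other.  They are found by maximizing Barber's bipartite
modularity

    Q = (1/m) * sum_ij (a_ij - A_i * A_j / m) * delta(g_i, h_j)

with a weighted label-propagation hill climber (multi-restart, plus a
greedy module-merge phase).  Each host is then placed in the
(within-module degree z, participation coefficient c) plane and classified
as peripheral, connector, module hub or network hub using per-network 95th
percentile critical values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ectonet.netcore import InteractionMatrix, NetworkBundle

ROLES = ("peripheral", "connector", "module_hub", "network_hub")


@dataclass
class ModulePartition:
    """A joint partition of hosts and parasites into modules."""

    host_module: np.ndarray  # module id per host row
    parasite_module: np.ndarray  # module id per parasite column
    Q: float
    n_modules: int


@dataclass
class RoleTable:
    """Per-host z, c, role label and the network's critical values."""

    table: pd.DataFrame  # columns: host_id, sex, z, c, role
    z_crit: float
    c_crit: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _barber_B(a: np.ndarray) -> tuple[np.ndarray, float]:
    a = a.astype(float)
    m = a.sum()
    return a - np.outer(a.sum(axis=1), a.sum(axis=0)) / m, m


def _partition_Q(B: np.ndarray, m: float, row_lab: np.ndarray, col_lab: np.ndarray) -> float:
    return float(B[row_lab[:, None] == col_lab[None, :]].sum() / m)


def _propagate(B: np.ndarray, m: float, rng: np.random.Generator,
               max_sweeps: int = 200) -> tuple[np.ndarray, np.ndarray, float]:
    """One label-propagation run from a random unique-label start."""
    n, s = B.shape
    row_lab = rng.permutation(n)
    # each parasite joins the host label that benefits it most
    col_lab = row_lab[np.argmax(B, axis=0)]
    best_q = _partition_Q(B, m, row_lab, col_lab)
    for _ in range(max_sweeps):
        prev = (row_lab.copy(), col_lab.copy())
        labels = np.unique(np.concatenate([row_lab, col_lab]))
        C = (col_lab[:, None] == labels[None, :]).astype(float)
        row_lab = labels[np.argmax(B @ C, axis=1)]
        labels = np.unique(np.concatenate([row_lab, col_lab]))
        R = (row_lab[:, None] == labels[None, :]).astype(float)
        col_lab = labels[np.argmax(B.T @ R, axis=1)]
        q = _partition_Q(B, m, row_lab, col_lab)
        if q <= best_q + 1e-12:
            row_lab, col_lab = prev
            break
        best_q = q
    return row_lab, col_lab, best_q


def _merge_modules(B: np.ndarray, m: float, row_lab: np.ndarray,
                   col_lab: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Greedily merge module pairs while any merge increases Q."""
    while True:
        labels = np.unique(np.concatenate([row_lab, col_lab]))
        if labels.size < 2:
            break
        R = (row_lab[:, None] == labels[None, :]).astype(float)
        C = (col_lab[:, None] == labels[None, :]).astype(float)
        M = R.T @ B @ C
        gain = M + M.T
        np.fill_diagonal(gain, -np.inf)
        i, j = np.unravel_index(np.argmax(gain), gain.shape)
        # zero-gain merges are taken too, so a structureless network
        # collapses to a single module rather than to arbitrary labels
        if gain[i, j] < -1e-12:
            break
        row_lab = np.where(row_lab == labels[j], labels[i], row_lab)
        col_lab = np.where(col_lab == labels[j], labels[i], col_lab)
    return row_lab, col_lab, _partition_Q(B, m, row_lab, col_lab)


def detect_modules(
    matrix: InteractionMatrix | np.ndarray,
    seed: int | None = None,
    n_restarts: int = 10,
) -> ModulePartition:
    """Best Barber-modularity partition over ``n_restarts`` seeded runs."""
    a = matrix.counts if isinstance(matrix, InteractionMatrix) else np.asarray(matrix)
    B, m = _barber_B(a)
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_restarts):
        rl, cl, _ = _propagate(B, m, rng)
        rl, cl, q = _merge_modules(B, m, rl, cl)
        if best is None or q > best[2]:
            best = (rl, cl, q)
    rl, cl, q = best
    # consecutive module ids, ordered by first appearance over rows then cols
    labels, inv = np.unique(np.concatenate([rl, cl]), return_inverse=True)
    order = {}
    for lab in np.concatenate([rl, cl]):
        if lab not in order:
            order[lab] = len(order)
    remap = np.array([order[lab] for lab in labels])
    ids = remap[inv]
    return ModulePartition(
        host_module=ids[: len(rl)],
        parasite_module=ids[len(rl):],
        Q=q,
        n_modules=len(labels),
    )


def cz_values(
    matrix: InteractionMatrix | np.ndarray,
    partition: ModulePartition,
    weighted: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Within-module degree z and participation coefficient c for hosts.

    With binary degrees (default): ``k_it`` is the number of parasite
    species of module t on host i; ``z_i`` standardizes the within-own-
    module degree over the hosts of that module (0 when the module's sd is
    0); ``c_i = 1 - sum_t (k_it / k_i)^2``.
    """
    a = matrix.counts if isinstance(matrix, InteractionMatrix) else np.asarray(matrix)
    x = a.astype(float) if weighted else (a > 0).astype(float)
    modules = np.unique(
        np.concatenate([partition.host_module, partition.parasite_module])
    )
    C = (partition.parasite_module[:, None] == modules[None, :]).astype(float)
    k = x @ C  # hosts x modules link counts
    k_tot = k.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = 1.0 - ((k / k_tot[:, None]) ** 2).sum(axis=1)
    own_col = np.searchsorted(modules, partition.host_module)
    k_own = k[np.arange(len(own_col)), own_col]
    z = np.zeros_like(k_own)
    for t, mod in enumerate(modules):
        members = partition.host_module == mod
        if not members.any():
            continue
        vals = k[members, t]
        sd = vals.std(ddof=0)
        if sd > 0:
            z[members] = (k_own[members] - vals.mean()) / sd
    return z, c


def classify_roles(
    z: np.ndarray,
    c: np.ndarray,
    percentile: float = 95.0,
    host_ids: list[str] | None = None,
    sexes: np.ndarray | None = None,
    fixed_thresholds: tuple[float, float] | None = None,
) -> RoleTable:
    """Classify hosts into the four z/c roles.

    Critical values are the per-network empirical percentiles of z and c
    (linear interpolation between order statistics); "high" means strictly
    greater than the critical value.  ``fixed_thresholds=(z_crit, c_crit)``
    substitutes the classic universal cutoffs if desired.
    """
    z = np.asarray(z, dtype=float)
    c = np.asarray(c, dtype=float)
    if fixed_thresholds is not None:
        z_crit, c_crit = fixed_thresholds
    else:
        z_crit = float(np.percentile(z, percentile))
        c_crit = float(np.percentile(c, percentile))
    high_z = z > z_crit
    high_c = c > c_crit
    role = np.where(
        high_z,
        np.where(high_c, "network_hub", "module_hub"),
        np.where(high_c, "connector", "peripheral"),
    )
    table = pd.DataFrame(
        {
            "host_id": host_ids if host_ids is not None else np.arange(len(z)),
            "sex": sexes if sexes is not None else [""] * len(z),
            "z": z,
            "c": c,
            "role": role,
        }
    )
    return RoleTable(table=table, z_crit=z_crit, c_crit=c_crit)


def host_roles(
    bundle: NetworkBundle,
    seed: int | None = None,
    n_restarts: int = 10,
    percentile: float = 95.0,
    weighted: bool = False,
) -> tuple[RoleTable, ModulePartition]:
    """Module detection + z/c + role classification for one bundle."""
    part = detect_modules(bundle.matrix, seed=seed, n_restarts=n_restarts)
    z, c = cz_values(bundle.matrix, part, weighted=weighted)
    roles = classify_roles(
        z, c, percentile=percentile, host_ids=bundle.matrix.host_ids,
        sexes=bundle.sexes,
    )
    return roles, part


def role_proportions_by_sex(role_table: RoleTable, network_id: str = "") -> pd.DataFrame:
    """Proportion of each sex's hosts playing each role.

    One row per (network, sex, role); proportions sum to 1 within each
    (network, sex).
    """
    t = role_table.table
    rows = []
    for sex, grp in t.groupby("sex"):
        n = len(grp)
        counts = grp["role"].value_counts()
        for role in ROLES:
            rows.append(
                {
                    "network": network_id,
                    "sex": sex,
                    "role": role,
                    "count": int(counts.get(role, 0)),
                    "n": n,
                    "proportion": counts.get(role, 0) / n,
                }
            )
    return pd.DataFrame(rows)
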