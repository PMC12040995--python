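"""Network-level structure and null-model standardization.

Two indices describe each network: NODF (nestedness based on paired overlap
and decreasing fill, 0-100, computed on presences) and H2' (network-level
specialization, 0-1, computed on counts).  Because networks differ in size,
fill and totals, both indices are standardized as Z-scores against an
ensemble of constrained random matrices that preserve connectance and
approximately proportional marginals (the "vaznull" scheme: cells selected
with probability proportional to the product of marginal totals until every
row and column is covered, then the remaining interaction events distributed
over the selected cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ectonet.netcore import InteractionMatrix, NetworkBundle, to_binary

logger = logging.getLogger(__name__)


@dataclass
class StructureResult:
    """Raw and null-standardized structure indices for one network."""

    id: str
    nodf_raw: float
    h2_raw: float
    n_null: int
    seed: int | None = None
    nodf_null_mean: float = float("nan")
    nodf_null_sd: float = float("nan")
    z_nodf: float = float("nan")
    h2_null_mean: float = float("nan")
    h2_null_sd: float = float("nan")
    z_h2: float = float("nan")

    def as_row(self) -> dict:
        return {
            "id": self.id,
            "nodf_raw": self.nodf_raw,
            "z_nodf": self.z_nodf,
            "h2_raw": self.h2_raw,
            "z_h2": self.z_h2,
            "n_null": self.n_null,
            "seed": self.seed,
        }


def nodf(binary_matrix: np.ndarray) -> float:
    """NODF nestedness of a presence/absence matrix, in [0, 100].

    For every ordered row pair (i, k) with fill_i > fill_k the pair scores
    100 * |shared| / fill_k, otherwise 0; likewise over columns; NODF is the
    mean over all row pairs and column pairs.  Invariant to row/column
    permutation.
    """
    b = (np.asarray(binary_matrix) > 0).astype(float)
    n, s = b.shape
    if n < 2 and s < 2:
        raise ValueError("NODF undefined for a single row and single column")
    scores: list[np.ndarray] = []
    for mat in (b, b.T):
        k = mat.shape[0]
        if k < 2:
            continue
        fill = mat.sum(axis=1)
        shared = mat @ mat.T
        fi = fill[:, None]
        fk = fill[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            paired = np.where(fi > fk, 100.0 * shared / fk, 0.0)
        iu = np.triu_indices(k, 1)
        # unordered pair (i,k): exactly one of the two ordered directions can
        # satisfy the decreasing-fill condition
        scores.append(paired[iu] + paired.T[iu])
    return float(np.concatenate(scores).mean())


def h2prime(matrix: InteractionMatrix | np.ndarray) -> tuple[float, float, float, float]:
    """Network-level specialization H2' with its entropy components.

    Returns ``(h2_prime, H2, H2min, H2max)``.  H2 is the Shannon entropy of
    the interaction frequencies; H2max the independence (outer-product)
    entropy given the marginals; H2min a greedy-packing lower bound that
    concentrates interactions in as few cells as the marginals allow.
    ``H2' = (H2max - H2) / (H2max - H2min)``, clamped to [0, 1]; 0 when the
    bounds coincide.
    """
    a = matrix.counts if isinstance(matrix, InteractionMatrix) else np.asarray(matrix)
    a = a.astype(float)
    m = a.sum()
    p = a[a > 0] / m
    H2 = float(-(p * np.log(p)).sum())
    ri = a.sum(axis=1) / m
    cj = a.sum(axis=0) / m
    H2max = float(-(ri * np.log(ri)).sum() - (cj * np.log(cj)).sum())
    H2min = _h2min_greedy(a.sum(axis=1).copy(), a.sum(axis=0).copy(), m)
    if H2max - H2min <= 0:
        return 0.0, H2, H2min, H2max
    val = (H2max - H2) / (H2max - H2min)
    return float(np.clip(val, 0.0, 1.0)), H2, H2min, H2max


def _h2min_greedy(row_rem: np.ndarray, col_rem: np.ndarray, m: float) -> float:
    """Entropy of the greedy marginal packing: repeatedly put
    min(largest remaining row, largest remaining column) into one cell."""
    cells = []
    while row_rem.max() > 0 and col_rem.max() > 0:
        i = int(np.argmax(row_rem))
        j = int(np.argmax(col_rem))
        q = min(row_rem[i], col_rem[j])
        cells.append(q)
        row_rem[i] -= q
        col_rem[j] -= q
    p = np.asarray(cells) / m
    return float(-(p * np.log(p)).sum())


def vaznull_sample(
    matrix: InteractionMatrix, rng: np.random.Generator
) -> np.ndarray:
    """One constrained null draw preserving total m and fill L.

    Cell probabilities are proportional to the product of the observed row
    and column totals.  Phase 1 first guarantees coverage: cells are drawn
    by P and accepted only while they cover a still-empty row or column
    (at most rows + cols - 1 acceptances), then the remaining ``L - |sel|``
    cells are drawn by P without replacement from the unselected cells.
    Phase 2 distributes the remaining ``m - L`` interaction events over the
    selected cells with replacement and adds the guaranteed 1 to each.
    """
    a = matrix.counts
    n, s = a.shape
    A_i = a.sum(axis=1).astype(float)
    A_j = a.sum(axis=0).astype(float)
    m = int(a.sum())
    L = int((a > 0).sum())
    if L < max(n, s):
        raise ValueError(
            f"cannot cover {n} rows and {s} columns with L={L} cells"
        )
    P = np.outer(A_i, A_j).ravel()
    P /= P.sum()
    for _ in range(1000):
        selected = np.zeros(n * s, dtype=bool)
        row_covered = np.zeros(n, dtype=bool)
        col_covered = np.zeros(s, dtype=bool)
        n_sel = 0
        while not (row_covered.all() and col_covered.all()):
            batch = rng.choice(n * s, size=4 * (n + s), replace=True, p=P)
            for cell in batch:
                r, c = divmod(int(cell), s)
                if selected[cell] or (row_covered[r] and col_covered[c]):
                    continue
                selected[cell] = True
                n_sel += 1
                row_covered[r] = True
                col_covered[c] = True
                if row_covered.all() and col_covered.all():
                    break
        if n_sel <= L:
            break
        # a tightly-filled matrix (L < rows + cols - 1) can make the greedy
        # coverage overshoot the available cells; redraw in that case
    else:
        raise RuntimeError(
            f"vaznull: could not cover a {n}x{s} matrix within L={L} cells"
        )
    if n_sel < L:
        free = np.flatnonzero(~selected)
        pf = P[free] / P[free].sum()
        extra_cells = rng.choice(free, size=L - n_sel, replace=False, p=pf)
        selected[extra_cells] = True
    chosen = np.flatnonzero(selected)
    null = np.zeros(n * s, dtype=np.int64)
    null[chosen] = 1
    rest = m - L
    if rest > 0:
        pc = P[chosen] / P[chosen].sum()
        null[chosen] += rng.multinomial(rest, pc)
    return null.reshape(n, s)


def zscore(observed: float, nulls: np.ndarray | list[float]) -> float:
    """(observed - null mean) / null sample sd; 0 with a warning if sd = 0."""
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size < 2:
        raise ValueError("need at least 2 null values for a Z-score")
    sd = nulls.std(ddof=1)
    if sd == 0:
        logger.warning("null ensemble has zero variance; Z set to 0")
        return 0.0
    return float((observed - nulls.mean()) / sd)


def structure_with_nulls(
    bundle: NetworkBundle, n_null: int = 1000, seed: int | None = None
) -> StructureResult:
    """NODF and H2' with null-ensemble means, sds and Z-scores.

    NODF is evaluated on binarized null draws, H2' on the count draws.
    With ``n_null = 0`` only the raw indices are reported.
    """
    obs_nodf = nodf(to_binary(bundle.matrix))
    obs_h2 = h2prime(bundle.matrix)[0]
    result = StructureResult(
        id=bundle.id, nodf_raw=obs_nodf, h2_raw=obs_h2, n_null=n_null, seed=seed
    )
    if n_null == 0:
        return result
    rng = np.random.default_rng(seed)
    null_nodf = np.empty(n_null)
    null_h2 = np.empty(n_null)
    for k in range(n_null):
        draw = vaznull_sample(bundle.matrix, rng)
        null_nodf[k] = nodf(draw > 0)
        null_h2[k] = h2prime(draw)[0]
    result.nodf_null_mean = float(null_nodf.mean())
    result.nodf_null_sd = float(null_nodf.std(ddof=1))
    result.z_nodf = zscore(obs_nodf, null_nodf)
    result.h2_null_mean = float(null_h2.mean())
    result.h2_null_sd = float(null_h2.std(ddof=1))
    result.z_h2 = zscore(obs_h2, null_h2)
    logger.info("structure %s: seed=%s n_null=%d", bundle.id, seed, n_null)
    return result
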