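"""Key-set construction by statistical-leverage selection.

For each training slide, the rows of its bag matrix with the highest
leverage scores (diagonal of the projection onto the top-r singular
subspace) are taken as representatives; the selections from every
training slide — both classes — are concatenated into a single joint
key set supplied as external guidance to cross-attention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from damil.bags import EmbeddingBag


@dataclass
class CrlConfig:
    """Rank rule and per-slide selection count for key extraction."""

    rank_energy: float = 0.90  # fraction of squared spectral mass retained
    max_rank: int = 32
    keys_per_slide: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.rank_energy <= 1.0):
            raise ValueError("rank_energy must be in (0, 1]")
        if self.max_rank < 1:
            raise ValueError("max_rank must be >= 1")
        if self.keys_per_slide < 1:
            raise ValueError("keys_per_slide must be >= 1")


@dataclass
class KeySet:
    """tau selected embeddings as columns of K, with per-key provenance."""

    K: np.ndarray  # (D, tau)
    provenance: list[tuple[str, int]]  # (slide_id, row index in that bag)

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K)
        if self.K.ndim != 2:
            raise ValueError("K must be a (D, tau) matrix")
        if self.K.shape[1] != len(self.provenance):
            raise ValueError("provenance length must equal tau")
        if self.K.shape[1] < 1:
            raise ValueError("key set must contain at least one key")

    @property
    def tau(self) -> int:
        return self.K.shape[1]

    @property
    def dim(self) -> int:
        return self.K.shape[0]

    def slide_ids(self) -> set[str]:
        return {sid for sid, _ in self.provenance}


def leverage_scores(E: np.ndarray, r: int) -> np.ndarray:
    """Leverage of each row of E w.r.t. its top-r singular subspace.

    score_i = sum_{j<=r} U[i, j]^2 for the left singular vectors U of E;
    scores lie in [0, 1] and sum exactly to r (trace identity).
    """
    E = np.asarray(E, dtype=np.float64)
    n, d = E.shape
    if not (1 <= r <= min(n, d)):
        raise ValueError(f"rank r={r} out of range [1, {min(n, d)}]")
    U, _, _ = np.linalg.svd(E, full_matrices=False)
    return (U[:, :r] ** 2).sum(axis=1)


def _energy_rank(singular_values: np.ndarray, rank_energy: float, cap: int) -> int:
    energy = singular_values**2
    total = energy.sum()
    if total == 0:
        return 1
    frac = np.cumsum(energy) / total
    r = int(np.searchsorted(frac, rank_energy - 1e-12) + 1)
    return max(1, min(r, cap))


def select_keys(E: np.ndarray, config: CrlConfig) -> np.ndarray:
    """Indices of the m highest-leverage rows of a bag matrix.

    The rank is the smallest one capturing ``rank_energy`` of the squared
    spectral mass, capped at ``max_rank`` and min(n, D). Ties break
    toward the lower row index; a bag with fewer than m rows contributes
    all of them.
    """
    E = np.asarray(E, dtype=np.float64)
    if E.ndim != 2 or E.shape[0] == 0:
        raise ValueError("bag matrix must be non-empty and 2-D")
    n, d = E.shape
    m = config.keys_per_slide
    if n <= m:
        return np.arange(n)
    s = np.linalg.svd(E, compute_uv=False)
    r = _energy_rank(s, config.rank_energy, min(config.max_rank, n, d))
    scores = leverage_scores(E, r)
    # snap float noise so exact symmetries tie, then break ties by index
    order = np.lexsort((np.arange(n), -np.round(scores, 9)))
    return np.sort(order[:m])


def build_keyset(training_bags: list[EmbeddingBag], config: CrlConfig) -> KeySet:
    """Concatenate per-slide selections from all training bags into K."""
    if not training_bags:
        raise ValueError("need at least one training bag")
    dims = {bag.dim for bag in training_bags}
    if len(dims) != 1:
        raise ValueError(f"bags have mixed embedding dimensions: {sorted(dims)}")
    columns = []
    provenance: list[tuple[str, int]] = []
    for bag in training_bags:
        idx = select_keys(bag.embeddings, config)
        columns.append(bag.embeddings[idx].T)
        provenance.extend((bag.slide_id, int(i)) for i in idx)
    return KeySet(K=np.concatenate(columns, axis=1), provenance=provenance)


def save_keyset(keyset: KeySet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("K", data=keyset.K)
        sids = np.array([s for s, _ in keyset.provenance], dtype=h5py.string_dtype())
        rows = np.array([r for _, r in keyset.provenance], dtype=np.int64)
        f.create_dataset("provenance_slide", data=sids)
        f.create_dataset("provenance_row", data=rows)


def load_keyset(path: str | Path) -> KeySet:
    with h5py.File(path, "r") as f:
        K = f["K"][...]
        sids = [s.decode() for s in f["provenance_slide"][...]]
        rows = f["provenance_row"][...]
    return KeySet(K=K, provenance=list(zip(sids, (int(r) for r in rows))))
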