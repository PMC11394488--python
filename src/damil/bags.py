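"""Embedding bags: the MIL unit of computation, plus HDF5/CSV containers.

One bag holds the instance-embedding matrix of a single slide together
with its slide/patient identity and bag-level label. Cohort-level
survival metadata (time, event) lives in the cohort table, not on the
bag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

RC = "RC"
NRC = "NRC"
LABELS = (RC, NRC)

COHORT_COLUMNS = ["patient_id", "slide_id", "label", "time_months", "event"]


@dataclass
class EmbeddingBag:
    """All instance embeddings of one slide (rows = instances)."""

    embeddings: np.ndarray  # (n, D) float32
    slide_id: str
    patient_id: str
    label: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=np.float32)
        if self.embeddings.ndim != 2:
            raise ValueError("embeddings must be a 2-D (n, D) matrix")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def n_instances(self) -> int:
        return self.embeddings.shape[0]

    @property
    def dim(self) -> int:
        return self.embeddings.shape[1]

    def subset(self, rows: np.ndarray) -> "EmbeddingBag":
        """Row-subset preserving order and metadata."""
        return EmbeddingBag(
            embeddings=self.embeddings[np.asarray(rows)],
            slide_id=self.slide_id,
            patient_id=self.patient_id,
            label=self.label,
            meta=dict(self.meta),
        )


def save_bags(bags: list[EmbeddingBag], path: str | Path) -> None:
    """Write bags to an HDF5 file, one group per slide."""
    with h5py.File(path, "w") as f:
        for bag in bags:
            grp = f.create_group(bag.slide_id)
            grp.create_dataset("embeddings", data=bag.embeddings.astype(np.float32))
            grp.attrs["patient_id"] = bag.patient_id
            grp.attrs["label"] = bag.label


def load_bags(path: str | Path) -> list[EmbeddingBag]:
    """Load bags from HDF5, sorted by slide id for determinism."""
    bags = []
    with h5py.File(path, "r") as f:
        for slide_id in sorted(f.keys()):
            grp = f[slide_id]
            bags.append(
                EmbeddingBag(
                    embeddings=grp["embeddings"][...],
                    slide_id=slide_id,
                    patient_id=str(grp.attrs["patient_id"]),
                    label=str(grp.attrs["label"]),
                )
            )
    return bags


def save_cohort(table: pd.DataFrame, path: str | Path) -> None:
    table[COHORT_COLUMNS].to_csv(path, index=False)


def load_cohort(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"patient_id": str, "slide_id": str})
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return table
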