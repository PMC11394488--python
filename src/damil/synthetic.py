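"""Synthetic fixtures: embedding bags, survival outcomes, toy slides.

Everything downstream (key-set construction, the aggregator, training,
survival evaluation) is exercisable against these generators with known
ground truth, so no external data is required.

Instance model: background instances are isotropic Gaussian at mean 0;
signal instances are isotropic Gaussian shifted by ``effect_size`` along
a fixed random unit direction shared by the whole cohort. RC bags carry
``ceil(witness_rate * n)`` signal instances; NRC bags carry none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from damil.bags import LABELS, NRC, RC, EmbeddingBag

#: Baseline exponential rate for the NRC arm, chosen so that ~35% of NRC
#: patients have events before 60 months: 1 - exp(-60 * rate) = 0.35.
NRC_EVENT_RATE = -math.log(0.65) / 60.0


@dataclass
class SyntheticCohortSpec:
    """Parameters of a synthetic MIL cohort with survival outcomes."""

    n_rc: int = 50
    n_nrc: int = 50
    slides_per_patient: tuple[int, int] = (1, 1)
    n_instances: tuple[int, int] = (30, 60)
    dim: int = 64
    witness_rate: float = 0.2
    effect_size: float = 4.0
    true_hr: float = 2.3
    censor_horizon: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.witness_rate <= 1.0):
            raise ValueError("witness_rate must be in [0, 1]")
        if self.true_hr <= 0:
            raise ValueError("true_hr must be > 0")
        if self.n_rc < 1 or self.n_nrc < 1:
            raise ValueError("n_rc and n_nrc must be >= 1")
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        for name in ("slides_per_patient", "n_instances"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must be a range 1 <= lo <= hi")
        if self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be > 0")


@dataclass
class ToySlideSpec:
    """A toy RGB slide: colored tissue with circular tumor blobs."""

    width: int = 256
    height: int = 256
    background_color: tuple[int, int, int] = (255, 255, 255)
    tumor_blobs: list[tuple[tuple[int, int], int, tuple[int, int, int]]] = field(
        default_factory=list
    )  # ((cx, cy), radius, color)
    normal_texture_color: tuple[int, int, int] = (220, 150, 180)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("slide dimensions must be positive")
        for (cx, cy), radius, _ in self.tumor_blobs:
            if radius <= 0:
                raise ValueError("blob radius must be positive")
            if not (
                radius <= cx <= self.width - 1 - radius
                and radius <= cy <= self.height - 1 - radius
            ):
                raise ValueError("blob must lie within image bounds")


def signal_direction(spec: SyntheticCohortSpec) -> np.ndarray:
    """Fixed unit direction of the signal mean, shared across the cohort."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xD1]))
    v = rng.standard_normal(spec.dim)
    return v / np.linalg.norm(v)


def gen_bag(label: str, spec: SyntheticCohortSpec, seed: int) -> EmbeddingBag:
    """Generate a single bag; RC bags contain a witness minority of signal.

    Deterministic given (label, spec, seed). The signal mean has
    Euclidean norm ``effect_size`` along the cohort direction.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    rng = np.random.default_rng(seed)
    lo, hi = spec.n_instances
    n = int(rng.integers(lo, hi + 1))
    emb = rng.standard_normal((n, spec.dim))
    n_signal = math.ceil(spec.witness_rate * n) if label == RC else 0
    if n_signal:
        emb[:n_signal] += spec.effect_size * signal_direction(spec)
        rng.shuffle(emb, axis=0)
    return EmbeddingBag(
        embeddings=emb.astype(np.float32),
        slide_id="",
        patient_id="",
        label=label,
        meta={"n_signal": n_signal},
    )


def gen_survival(
    labels: list[str], spec: SyntheticCohortSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Exponential survival per patient, administratively censored.

    NRC patients have rate ``NRC_EVENT_RATE``; RC patients have rate
    ``NRC_EVENT_RATE * true_hr``.
    """
    rates = np.where(
        np.asarray(labels) == RC, NRC_EVENT_RATE * spec.true_hr, NRC_EVENT_RATE
    )
    raw = rng.exponential(1.0 / rates)
    event = (raw < spec.censor_horizon).astype(int)
    time = np.minimum(raw, spec.censor_horizon)
    return pd.DataFrame({"time_months": time, "event": event})


def gen_cohort(spec: SyntheticCohortSpec) -> tuple[list[EmbeddingBag], pd.DataFrame]:
    """Generate all bags and the cohort table for a synthetic cohort.

    Returns one bag per slide and one cohort row per slide
    (patient_id, slide_id, label, time_months, event); every slide of a
    patient carries the patient's label and survival outcome.
    """
    root = np.random.SeedSequence(spec.seed)
    surv_ss, slide_ss, bag_ss = root.spawn(3)
    labels = [RC] * spec.n_rc + [NRC] * spec.n_nrc
    patient_ids = [f"P{i:04d}" for i in range(len(labels))]

    survival = gen_survival(labels, spec, np.random.default_rng(surv_ss))
    slide_rng = np.random.default_rng(slide_ss)
    lo, hi = spec.slides_per_patient
    bag_seeds = bag_ss.generate_state(len(labels) * hi, dtype=np.uint64)

    bags: list[EmbeddingBag] = []
    rows = []
    k = 0
    for pid, label, (_, srow) in zip(patient_ids, labels, survival.iterrows()):
        n_slides = int(slide_rng.integers(lo, hi + 1))
        for s in range(n_slides):
            slide_id = f"{pid}_S{s}"
            bag = gen_bag(label, spec, int(bag_seeds[k]))
            k += 1
            bag.slide_id = slide_id
            bag.patient_id = pid
            bags.append(bag)
            rows.append(
                {
                    "patient_id": pid,
                    "slide_id": slide_id,
                    "label": label,
                    "time_months": srow["time_months"],
                    "event": int(srow["event"]),
                }
            )
    return bags, pd.DataFrame(rows)


def gen_toy_slide(
    spec: ToySlideSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a toy slide with known tumor and tissue masks.

    The tissue is a centered ellipse of ``normal_texture_color`` (with
    mild seeded color jitter) plus the tumor blobs; everything else is
    background. Returns (image HxWx3 uint8, tumor mask, tissue mask).
    """
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:h, 0:w]

    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    ax, ay = 0.4 * w, 0.4 * h
    tissue = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0

    tumor = np.zeros((h, w), dtype=bool)
    image = np.empty((h, w, 3), dtype=np.uint8)
    image[:] = np.asarray(spec.background_color, dtype=np.uint8)

    jitter = rng.integers(-10, 11, size=(h, w, 3))
    normal = np.clip(
        np.asarray(spec.normal_texture_color, dtype=np.int64) + jitter, 0, 255
    ).astype(np.uint8)
    image[tissue] = normal[tissue]

    for (bx, by), radius, color in spec.tumor_blobs:
        disc = (xx - bx) ** 2 + (yy - by) ** 2 <= radius**2
        tumor |= disc
        image[disc] = np.asarray(color, dtype=np.uint8)

    tissue |= tumor
    return image, tumor, tissue
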