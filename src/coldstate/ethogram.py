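"""Behaviour vocabulary and ethogram data model.

An ethogram is a time-binned sequence of categorical behaviour labels for a
single animal, annotated at a fixed bin width (1 s by default).  The default
vocabulary is the 15-action set used for cold-exposure home-cage recordings:
postural/thermoregulatory actions (sitting, shivering, pushing bedding,
bedding retrieval ...), feeding-related actions (moving out, eating, moving
back, drinking) and exploratory/grooming actions.  Integer codes follow the
fixed vocabulary order so that encodings are stable across runs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ACTIONS",
    "BehaviorVocabulary",
    "Ethogram",
    "ObservationSequence",
    "read_ethogram",
    "write_ethogram",
    "encode_observations",
    "decode_observations",
]

#: Canonical 15-action vocabulary, in fixed order (codes 0..14).
DEFAULT_ACTIONS: tuple[str, ...] = (
    "sitting",
    "shivering",
    "head grooming",
    "turning",
    "lower body grooming",
    "moving out",
    "eating",
    "moving back",
    "pushing bedding",
    "standing up",
    "bedding retrieval",
    "drinking",
    "digging",
    "grooming tail",
    "walking",
)


@dataclass(frozen=True)
class BehaviorVocabulary:
    """Ordered action vocabulary with a stable name -> integer code map."""

    actions: tuple[str, ...] = DEFAULT_ACTIONS

    def __post_init__(self) -> None:
        if len(set(self.actions)) != len(self.actions):
            raise ValueError("vocabulary actions must be unique")
        if len(self.actions) == 0:
            raise ValueError("vocabulary must not be empty")

    @property
    def size(self) -> int:
        return len(self.actions)

    @property
    def index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.actions)}

    def code(self, action: str) -> int:
        try:
            return self.actions.index(action)
        except ValueError:
            raise KeyError(f"unknown behaviour label: {action!r}") from None

    @classmethod
    def default(cls) -> "BehaviorVocabulary":
        return cls(DEFAULT_ACTIONS)


@dataclass
class Ethogram:
    """1-s-binned (by default) behaviour labels for one animal.

    Parameters
    ----------
    labels
        One action name per bin, contiguous fixed-width bins starting at
        ``t0`` seconds.
    """

    labels: list[str]
    animal_id: str = ""
    condition: str = ""
    t0: float = 0.0
    bin_s: float = 1.0

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if len(self.labels) == 0:
            raise ValueError("ethogram must contain at least one bin")
        if self.bin_s <= 0:
            raise ValueError("bin_s must be positive")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def times(self) -> np.ndarray:
        """Start time (s) of each bin."""
        return self.t0 + self.bin_s * np.arange(len(self.labels))

    def validate(self, vocab: BehaviorVocabulary) -> None:
        for i, lab in enumerate(self.labels):
            if lab not in vocab.index:
                raise ValueError(
                    f"unknown behaviour label {lab!r} at bin {i}"
                )


@dataclass
class ObservationSequence:
    """Integer-encoded ethogram, the HMM observation input."""

    codes: np.ndarray
    V: int
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 1:
            raise ValueError("codes must be one-dimensional")
        if len(self.codes) and (self.codes.min() < 0 or self.codes.max() >= self.V):
            raise ValueError(f"codes must lie in [0, {self.V - 1}]")

    def __len__(self) -> int:
        return len(self.codes)


def read_ethogram(path, vocab: BehaviorVocabulary | None = None) -> Ethogram:
    """Read a `time_s,behavior` CSV (optional ``# key=value`` comments).

    Bins must be sorted, contiguous and of constant width; every label must
    belong to ``vocab``.
    """
    vocab = vocab or BehaviorVocabulary.default()
    meta: dict[str, str] = {}
    body = io.StringIO()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    k, v = stripped.split("=", 1)
                    meta[k.strip()] = v.strip()
            else:
                body.write(line)
    body.seek(0)
    df = pd.read_csv(body, float_precision="round_trip")
    if not {"time_s", "behavior"} <= set(df.columns):
        raise ValueError("ethogram file must have columns time_s,behavior")
    if len(df) == 0:
        raise ValueError("ethogram file contains no bins")
    df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("duplicated time bins in ethogram file")
        if not np.allclose(dt, np.median(dt), rtol=0, atol=1e-9):
            raise ValueError("non-contiguous or variable-width bins")
        bin_s = float(np.median(dt))
    else:
        bin_s = 1.0
    if "bin_s" in meta:  # declared width wins over (ulp-fuzzy) inference
        declared = float(meta["bin_s"])
        if len(t) > 1 and abs(declared - bin_s) > 1e-9:
            raise ValueError("declared bin_s disagrees with sample spacing")
        bin_s = declared
    labels = df["behavior"].astype(str).str.strip().tolist()
    index = vocab.index
    for row, lab in enumerate(labels):
        if lab not in index:
            raise ValueError(
                f"unknown behaviour label {lab!r} at row {row} of {path}"
            )
    return Ethogram(
        labels=labels,
        animal_id=meta.get("animal_id", ""),
        condition=meta.get("condition", ""),
        t0=float(t[0]),
        bin_s=bin_s,
    )


def write_ethogram(e: Ethogram, path) -> None:
    """Write an ethogram as `time_s,behavior` CSV, re-readable losslessly."""
    if len(e) == 0:  # defensive; the constructor forbids this already
        raise ValueError("refusing to write an empty ethogram")
    with open(path, "w", encoding="utf-8") as fh:
        if e.animal_id:
            fh.write(f"# animal_id={e.animal_id}\n")
        if e.condition:
            fh.write(f"# condition={e.condition}\n")
        fh.write(f"# bin_s={float(e.bin_s)!r}\n")
        fh.write("time_s,behavior\n")
        for t, lab in zip(e.times, e.labels):
            fh.write(f"{float(t)!r},{lab}\n")  # repr => exact float round trip


def encode_observations(
    e: Ethogram, vocab: BehaviorVocabulary | None = None
) -> ObservationSequence:
    """Map labels to integer codes in vocabulary order."""
    vocab = vocab or BehaviorVocabulary.default()
    index = vocab.index
    codes = np.empty(len(e), dtype=np.int64)
    for i, lab in enumerate(e.labels):
        if lab not in index:
            raise ValueError(f"unknown behaviour label {lab!r} at bin {i}")
        codes[i] = index[lab]
    return ObservationSequence(codes=codes, V=vocab.size, animal_id=e.animal_id)


def decode_observations(
    obs: ObservationSequence, vocab: BehaviorVocabulary | None = None
) -> list[str]:
    """Inverse of :func:`encode_observations`."""
    vocab = vocab or BehaviorVocabulary.default()
    if obs.V != vocab.size:
        raise ValueError("observation V does not match vocabulary size")
    return [vocab.actions[c] for c in obs.codes]
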