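"""Shared dataset containers used across the pipeline.

A :class:`LabelledDataset` couples a feature matrix with binary MVI labels
(1 = MVI+, 0 = MVI-).  Rows carry a ``real`` flag so that oversampled
(simulated) instances remain distinguishable from measured nodules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: reserved (non-feature) column names in the on-disk CSV representation
RESERVED_COLUMNS = ("subject_id", "label", "real")


@dataclass
class LabelledDataset:
    """Feature matrix plus MVI labels for a set of nodules."""

    X: pd.DataFrame
    y: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    real: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y have different lengths")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary (1 = MVI+, 0 = MVI-)")
        if not self.subject_ids:
            self.subject_ids = [f"case-{i:03d}" for i in range(len(self.y))]
        if self.real is None:
            self.real = np.ones(len(self.y), dtype=bool)
        self.real = np.asarray(self.real, dtype=bool)
        if len(self.real) != len(self.y):
            raise ValueError("real flags and y have different lengths")

    # -- basic queries ----------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_pos(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def n_neg(self) -> int:
        return int(np.sum(self.y == 0))

    def __len__(self) -> int:
        return len(self.y)

    # -- manipulation -----------------------------------------------------
    def select_features(self, names: list[str]) -> "LabelledDataset":
        missing = [n for n in names if n not in self.X.columns]
        if missing:
            raise KeyError(f"features not in dataset: {missing}")
        return LabelledDataset(
            self.X[list(names)].copy(), self.y.copy(),
            list(self.subject_ids), self.real.copy(),
        )

    def subset(self, idx: np.ndarray) -> "LabelledDataset":
        idx = np.asarray(idx)
        return LabelledDataset(
            self.X.iloc[idx].reset_index(drop=True),
            self.y[idx],
            [self.subject_ids[i] for i in idx],
            self.real[idx],
        )

    # -- round-trip -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        frame = self.X.copy()
        frame.insert(0, "subject_id", self.subject_ids)
        frame.insert(1, "label", self.y)
        frame.insert(2, "real", self.real.astype(int))
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LabelledDataset":
        feats = [c for c in frame.columns if c not in RESERVED_COLUMNS]
        real = (
            frame["real"].to_numpy().astype(bool)
            if "real" in frame.columns
            else None
        )
        return cls(
            frame[feats].reset_index(drop=True),
            frame["label"].to_numpy(),
            [str(s) for s in frame["subject_id"]],
            real,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LabelledDataset":
        return cls.from_frame(pd.read_csv(path))
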