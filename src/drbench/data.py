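"""Tabular data containers shared by the learners and estimators.

The estimators only ever need three pieces: a covariate matrix ``W``, a
binary treatment vector ``A`` and an endpoint vector ``Y``.  Simulated
datasets additionally carry the generating truth (true propensity score and
both conditional-mean vectors) for oracle checks; observational data read
from CSV carry only the observed triple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["ObservedData", "SimulatedDataset"]

_W_COLS = [f"W{i}" for i in range(1, 9)]


@dataclass
class ObservedData:
    """An observational dataset: covariates, binary treatment, endpoint."""

    W: np.ndarray
    A: np.ndarray
    Y: np.ndarray
    covariate_names: list[str] = field(default_factory=lambda: list(_W_COLS))

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be a 2-d matrix")
        n = self.W.shape[0]
        if self.A.shape != (n,) or self.Y.shape != (n,):
            raise ValueError("A and Y must be vectors matching the rows of W")
        if not np.isin(self.A, (0.0, 1.0)).all():
            raise ValueError("treatment A must be binary in {0, 1}")
        if len(self.covariate_names) != self.W.shape[1]:
            self.covariate_names = [f"W{i+1}" for i in range(self.W.shape[1])]

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.W, columns=self.covariate_names)
        df["A"] = self.A
        df["Y"] = self.Y
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, covariates: list[str] | None = None) -> "ObservedData":
        if covariates is None:
            covariates = [c for c in df.columns if c.startswith("W")]
        missing = [c for c in [*covariates, "A", "Y"] if c not in df.columns]
        if missing:
            raise ConfigurationError(f"data is missing required columns: {missing}")
        return cls(
            W=df[covariates].to_numpy(float),
            A=df["A"].to_numpy(float),
            Y=df["Y"].to_numpy(float),
            covariate_names=list(covariates),
        )

    @classmethod
    def read_csv(cls, path, covariates: list[str] | None = None) -> "ObservedData":
        return cls.from_frame(pd.read_csv(path, comment="#"), covariates)

    def resample(self, rng: np.random.Generator) -> "ObservedData":
        """Row resample with replacement (for the nonparametric bootstrap)."""
        idx = rng.integers(0, self.n, size=self.n)
        return ObservedData(self.W[idx], self.A[idx], self.Y[idx], list(self.covariate_names))


@dataclass
class SimulatedDataset(ObservedData):
    """One simulated draw plus the generating truth.

    ``true_ps`` is the propensity used to draw ``A``; ``mu0``/``mu1`` are the
    conditional endpoint means under control and treatment for every row.
    """

    true_ps: np.ndarray = None  # type: ignore[assignment]
    mu0: np.ndarray = None  # type: ignore[assignment]
    mu1: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        for name in ("true_ps", "mu0", "mu1"):
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"SimulatedDataset requires {name}")
            setattr(self, name, np.asarray(v, dtype=float))
        if not ((self.true_ps > 0) & (self.true_ps < 1)).all():
            raise ValueError("true_ps must lie strictly inside (0, 1)")

    def to_frame(self) -> pd.DataFrame:
        df = super().to_frame()
        df["true_ps"] = self.true_ps
        df["mu0"] = self.mu0
        df["mu1"] = self.mu1
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, covariates: list[str] | None = None) -> "SimulatedDataset":
        if covariates is None:
            covariates = [c for c in df.columns if c.startswith("W")]
        return cls(
            W=df[covariates].to_numpy(float),
            A=df["A"].to_numpy(float),
            Y=df["Y"].to_numpy(float),
            covariate_names=list(covariates),
            true_ps=df["true_ps"].to_numpy(float),
            mu0=df["mu0"].to_numpy(float),
            mu1=df["mu1"].to_numpy(float),
        )
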