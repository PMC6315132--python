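"""Symmetric distance matrices with labels, plus delimited-text I/O."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KINDS = ("phylogenetic", "trait-euclidean", "dendrogram-cophenetic")


@dataclass(frozen=True)
class DistanceMatrix:
    """A labelled symmetric nonnegative matrix with zero diagonal.

    ``kind`` records the provenance of the distances: patristic distances on
    a phylogeny, Euclidean distances in standardized trait space, or
    cophenetic distances on a trait dendrogram (the last are additionally
    ultrametric).
    """

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown distance kind {self.kind!r}; expected one of {KINDS}")
        d = np.asarray(self.values, dtype=float)
        labels = tuple(self.labels)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in distance matrix")
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(labels):
            raise ValueError("distance matrix must be square and match its labels")
        if not np.allclose(d, d.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < -1e-12):
            raise ValueError("distances must be nonnegative")
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        object.__setattr__(self, "values", d)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, labels) -> np.ndarray:
        pos = {lab: k for k, lab in enumerate(self.labels)}
        missing = [l for l in labels if l not in pos]
        if missing:
            raise KeyError(f"labels absent from distance matrix: {missing}")
        return np.asarray([pos[l] for l in labels], dtype=np.intp)

    def submatrix(self, labels) -> np.ndarray:
        idx = self.index_of(labels)
        return self.values[np.ix_(idx, idx)]

    def is_ultrametric(self, rtol: float = 1e-8) -> bool:
        """Three-point condition: d(i,j) <= max(d(i,k), d(j,k)) for all triples."""
        d = self.values
        scale = d.max() if d.size else 0.0
        tol = rtol * max(scale, 1.0)
        # d[i,j] must not exceed max(d[i,k], d[k,j]) for any k
        m = np.minimum.reduce(np.maximum(d[:, None, :], d[None, :, :]), axis=2)
        return bool(np.all(d <= m + tol))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index_label="species")


def read_distance_matrix(path, kind: str, sep: str = "\t") -> DistanceMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return DistanceMatrix(labels=tuple(df.index.astype(str)), values=df.to_numpy(float), kind=kind)
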