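"""Pairwise percent-identity matrices for a protein set and their summaries.

Entries are global (Needleman-Wunsch) percent identities under BLOSUM62
with the package's default gap penalties, reported to two decimals;
identity is counted over gap-free aligned columns.  A loader is provided
for the packaged matrix of agmatine-deiminase (AgD) identities across the
12 cluster-Ia *Frankia* strains.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .align import AlignmentParams, SubstitutionMatrix, global_percent_identity
from .records import ProteinRecord


@dataclass(frozen=True)
class IdentityMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # symmetric, percent, 100.0 diagonal

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 100.0):
            raise ValueError("diagonal must be 100.0")
        if self.values.min() < 0 or self.values.max() > 100:
            raise ValueError("percent identities must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids),
                            columns=list(self.ids))

    def offdiagonal(self) -> np.ndarray:
        """The n(n-1)/2 distinct off-diagonal entries, row-major."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]


@dataclass(frozen=True)
class MatrixSummary:
    mean_offdiag: float  # two decimals
    min_offdiag: float
    max_offdiag: float
    argmin_pair: tuple[str, str]
    argmax_pair: tuple[str, str]


def build_identity_matrix(records: list[ProteinRecord],
                          matrix: SubstitutionMatrix,
                          params: AlignmentParams,
                          include_gaps: bool = False) -> IdentityMatrix:
    """All-pairs global percent identity; symmetric by construction."""
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    ids = [r.locus_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    n = len(records)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = global_percent_identity(records[i], records[j], matrix,
                                          params, include_gaps=include_gaps)
            values[i, j] = values[j, i] = pid
    return IdentityMatrix(ids=tuple(ids), values=values)


def matrix_summary(m: IdentityMatrix) -> MatrixSummary:
    """Statistics over the distinct off-diagonal pairs."""
    if len(m.ids) < 2:
        raise ValueError("summary needs at least a 2x2 matrix")
    iu = np.triu_indices(len(m.ids), k=1)
    vals = m.values[iu]
    kmin = int(np.argmin(vals))
    kmax = int(np.argmax(vals))
    return MatrixSummary(
        mean_offdiag=round(float(vals.mean()), 2),
        min_offdiag=float(vals[kmin]),
        max_offdiag=float(vals[kmax]),
        argmin_pair=(m.ids[iu[0][kmin]], m.ids[iu[1][kmin]]),
        argmax_pair=(m.ids[iu[0][kmax]], m.ids[iu[1][kmax]]),
    )


def read_identity_matrix(path: str | Path) -> IdentityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return IdentityMatrix(ids=tuple(df.index), values=df.to_numpy(float))


def write_identity_matrix(m: IdentityMatrix, path: str | Path) -> None:
    df = m.to_frame().round(2)
    df.index.name = "strain"
    df.to_csv(path, sep="\t", float_format="%.2f")


def load_agd_identity_matrix() -> IdentityMatrix:
    """The packaged AgD percent-identity matrix over the 12 cluster-Ia
    strains (values as printed, mirrored to a full symmetric matrix)."""
    ref = resources.files("sympan.data") / "agd_identity_matrix.tsv"
    with resources.as_file(ref) as path:
        return read_identity_matrix(path)
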