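"""Pairwise species turnover between grid cells (Simpson's beta).

Simpson dissimilarity,

    beta_sim(i, j) = min(b, c) / (min(b, c) + a),

with a the species shared by cells i and j, b those only in i and c those
only in j, measures compositional turnover while discounting richness
differences: a species-poor cell nested inside a rich one scores 0, and
only genuine replacement of species drives the index toward 1.  Pairs
sharing no species score exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occurrence_grid import DegenerateCellError, SiteBySpeciesMatrix

__all__ = ["TurnoverMatrix", "simpson_beta", "turnover_matrix",
           "write_square", "write_pairs"]


@dataclass
class TurnoverMatrix:
    """Symmetric beta_sim dissimilarities plus the per-pair a/b/c audit counts."""

    cells: list
    beta: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        n = len(self.cells)
        if self.beta.shape != (n, n):
            raise ValueError("beta must be square over the cell list")
        if not np.allclose(self.beta, self.beta.T) or np.any(np.diag(self.beta) != 0):
            raise ValueError("beta must be symmetric with zero diagonal")
        if np.any(self.beta < 0) or np.any(self.beta > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def simpson_beta(species_i, species_j) -> float:
    """Simpson dissimilarity between two species sets.

    Raises :class:`DegenerateCellError` on an empty set (empty cells must
    have been excluded upstream).
    """
    si, sj = set(species_i), set(species_j)
    if not si or not sj:
        raise DegenerateCellError("simpson_beta is undefined for an empty species set")
    a = len(si & sj)
    if a == 0:
        return 1.0
    b = len(si - sj)
    c = len(sj - si)
    m = min(b, c)
    return m / (m + a)


def turnover_matrix(matrix: SiteBySpeciesMatrix, chunk_size: int = 256) -> TurnoverMatrix:
    """All-pairs beta_sim over the cells of an incidence matrix.

    Shared counts come from a boolean Gram product computed in row chunks,
    so peak memory stays linear in ``chunk_size``; the result is identical
    for any chunking.  The matrix must contain no empty cells (enforced by
    :class:`SiteBySpeciesMatrix` itself).
    """
    P = matrix.presence.astype(np.int32)
    n = matrix.n_cells
    rich = P.sum(axis=1)
    a = np.empty((n, n), dtype=np.int64)
    for start in range(0, n, max(chunk_size, 1)):
        stop = min(start + max(chunk_size, 1), n)
        a[start:stop] = P[start:stop] @ P.T
    b = rich[:, None] - a
    c = rich[None, :] - a
    m = np.minimum(b, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(a == 0, 1.0, m / (m + a))
    np.fill_diagonal(beta, 0.0)
    return TurnoverMatrix(cells=list(matrix.cells), beta=beta, a=a, b=b, c=c)


def _cell_label(cell) -> str:
    if isinstance(cell, tuple):
        return f"{cell[0]}_{cell[1]}"
    return str(cell)


def write_square(tm: TurnoverMatrix, path) -> None:
    """Square delimited-text dissimilarity matrix with labelled rows/columns."""
    labels = [_cell_label(c) for c in tm.cells]
    pd.DataFrame(tm.beta, index=labels, columns=labels).to_csv(path, index_label="cell")


def write_pairs(tm: TurnoverMatrix, path) -> None:
    """Long-form pair table: cell_i, cell_j, a, b, c, beta for each unordered pair."""
    n = tm.n_cells
    iu, ju = np.triu_indices(n, k=1)
    labels = [_cell_label(c) for c in tm.cells]
    pd.DataFrame({
        "cell_i": [labels[i] for i in iu],
        "cell_j": [labels[j] for j in ju],
        "a": tm.a[iu, ju],
        "b": tm.b[iu, ju],
        "c": tm.c[iu, ju],
        "beta": tm.beta[iu, ju],
    }).to_csv(path, index=False)
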