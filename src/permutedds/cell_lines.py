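"""Cell-line feature construction.

A cell line enters the model as two vectors: a real-valued expression
profile over a fixed gene panel (z-scored per gene on the training set) and
a 0/1 mutation profile over a second panel. Panels are built by
intersecting the available matrix columns with a landmark gene list and
fixing a sorted column order so feature positions are stable across runs.

The module also provides the one-hot descriptor baseline (unseen cell lines
map to the all-zero vector) and the Gaussian noise operators used by the
robustness study: multiplicative ``x * N(1, sigma)`` and additive
``x + N(0, sigma)`` noise, seeded per cell line via spawned substreams so
that extending the panel never perturbs existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyIntersectionError


@dataclass(frozen=True)
class GenePanel:
    """Ordered gene symbols defining the expression and mutation feature axes."""

    expression_genes: tuple[str, ...]
    mutation_genes: tuple[str, ...]

    def __post_init__(self):
        for name in ("expression_genes", "mutation_genes"):
            genes = tuple(getattr(self, name))
            if len(set(genes)) != len(genes):
                raise ValueError(f"{name} contains duplicate symbols")
            object.__setattr__(self, name, genes)

    @property
    def g_expr(self) -> int:
        return len(self.expression_genes)

    @property
    def g_mut(self) -> int:
        return len(self.mutation_genes)


@dataclass(frozen=True)
class CellLineProfile:
    """Expression and mutation feature vectors for one cell line."""

    cell_id: str
    expression: np.ndarray
    mutation: np.ndarray

    def __post_init__(self):
        expr = np.asarray(self.expression, dtype=float)
        mut = np.asarray(self.mutation, dtype=float)
        if np.isnan(expr).any() or np.isnan(mut).any():
            raise ValueError(f"profile {self.cell_id}: missing values after preprocessing")
        object.__setattr__(self, "expression", expr)
        object.__setattr__(self, "mutation", mut)


def select_landmark_genes(
    matrix: pd.DataFrame, landmark: list[str]
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Restrict a cell x gene matrix to its intersection with a landmark list.

    Columns are ordered by sorted gene symbol so that feature positions are a
    pure function of the resulting panel.

    Raises
    ------
    EmptyIntersectionError
        If no matrix column appears in the landmark list.
    """
    if len(landmark) == 0:
        raise EmptyIntersectionError("landmark gene list is empty")
    keep = sorted(set(matrix.columns) & set(landmark))
    if not keep:
        raise EmptyIntersectionError("no overlap between matrix genes and landmark set")
    return matrix.loc[:, keep], tuple(keep)


def normalize_expression(
    train_matrix: pd.DataFrame, apply_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene z-score of ``apply_matrix`` using train-set mean/sd only.

    Genes constant on the training set (sd = 0) map to 0, avoiding division
    blow-ups while keeping the column.
    """
    if list(train_matrix.columns) != list(apply_matrix.columns):
        raise ValueError("train and apply matrices must share the same gene panel")
    mean = train_matrix.mean(axis=0)
    sd = train_matrix.std(axis=0, ddof=0)
    z = (apply_matrix - mean).div(sd.where(sd > 0, 1.0), axis=1)
    z.loc[:, sd == 0] = 0.0
    return z


def _check_sigma(sigma: float) -> None:
    if sigma < 0:
        raise DomainError(f"noise sd must be >= 0, got {sigma}")


def inject_multiplicative_noise(x: np.ndarray, sigma_mul: float, seed) -> np.ndarray:
    """Return ``x * eps`` with ``eps ~ N(1, sigma_mul)`` i.i.d. per entry.

    ``sigma_mul = 0`` is the exact identity. ``seed`` may be an int or a
    ``numpy.random.SeedSequence`` (used for per-cell substreams).
    """
    _check_sigma(sigma_mul)
    x = np.asarray(x, dtype=float)
    if sigma_mul == 0:
        return x.copy()
    rng = np.random.Generator(np.random.PCG64(seed))
    return x * rng.normal(loc=1.0, scale=sigma_mul, size=x.shape)


def inject_additive_noise(x: np.ndarray, sigma_add: float, seed) -> np.ndarray:
    """Return ``x + eps`` with ``eps ~ N(0, sigma_add)`` i.i.d. per entry."""
    _check_sigma(sigma_add)
    x = np.asarray(x, dtype=float)
    if sigma_add == 0:
        return x.copy()
    rng = np.random.Generator(np.random.PCG64(seed))
    return x + rng.normal(loc=0.0, scale=sigma_add, size=x.shape)


def noise_matrix(
    matrix: np.ndarray, sigma: float, mode: str, seed: int
) -> np.ndarray:
    """Noise every row (cell line) of a feature matrix independently.

    One master seed spawns one substream per row index, so appending cell
    lines leaves the draws of existing rows unchanged. ``mode`` is ``"mul"``
    or ``"add"``; mutation matrices are noised as real vectors (binariness is
    deliberately not restored — the robustness study perturbs both profiles).
    """
    if mode not in ("mul", "add"):
        raise ValueError(f"mode must be 'mul' or 'add', got {mode!r}")
    _check_sigma(sigma)
    matrix = np.asarray(matrix, dtype=float)
    if sigma == 0:
        return matrix.copy()
    op = inject_multiplicative_noise if mode == "mul" else inject_additive_noise
    children = np.random.SeedSequence(seed).spawn(matrix.shape[0])
    return np.stack([op(row, sigma, child) for row, child in zip(matrix, children)])


def onehot_descriptors(train_cells: list[str], query_cells: list[str]) -> np.ndarray:
    """One-hot cell-line descriptors over the training cell set.

    Each known query cell maps to its unit basis vector (positions follow
    ``train_cells`` order); cells unseen during training map to the all-zero
    vector, mirroring how the one-hot baseline handles held-out cell lines.
    """
    if len(train_cells) == 0:
        raise ValueError("train_cells must be non-empty")
    if len(set(train_cells)) != len(train_cells):
        raise ValueError("train_cells must be unique")
    index = {c: i for i, c in enumerate(train_cells)}
    out = np.zeros((len(query_cells), len(train_cells)))
    for row, cell in enumerate(query_cells):
        if cell in index:
            out[row, index[cell]] = 1.0
    return out
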