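"""Correspondence analysis (factorial analysis of correspondence).

An eigenvector ordination of a non-negative table under the chi-square
metric.  With correspondence matrix ``P = N / n`` (``n`` the grand total),
row masses ``r`` and column masses ``c``, the standardized residuals

    S_ij = (P_ij - r_i c_j) / sqrt(r_i c_j)

are decomposed by SVD, ``S = U diag(sigma) V'``.  Principal inertias are
``sigma_k**2``; their sum (the total inertia) equals the Pearson
chi-square statistic of the table divided by the grand total.  Row
principal coordinates are ``diag(1/sqrt(r)) U diag(sigma)`` (columns
symmetrically), and standard coordinates drop the ``diag(sigma)`` factor.
The trivial axis of the uncentered problem is removed by the centering,
and axes are reported in decreasing inertia order as F1, F2, ...
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: singular values below this multiple of the largest are treated as zero
_RELATIVE_RANK_TOL = 1e-12


@dataclass(frozen=True)
class CAResult:
    """Fitted correspondence analysis.

    Coordinates have one column per retained axis (F1, F2, ...).  Rank-0
    tables (perfect independence) are valid fits with ``n_axes == 0`` and
    empty coordinate matrices.
    """

    row_labels: tuple[str, ...]
    column_labels: tuple[str, ...]
    singular_values: np.ndarray
    principal_inertias: np.ndarray
    inertia_fractions: np.ndarray
    row_coordinates: np.ndarray
    column_coordinates: np.ndarray
    row_standard_coordinates: np.ndarray
    column_standard_coordinates: np.ndarray
    row_masses: np.ndarray
    column_masses: np.ndarray
    total_inertia: float

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)


def _as_labelled_array(table) -> tuple[np.ndarray, list[str], list[str]]:
    # IndicatorTable without importing classify (avoids a module cycle)
    if hasattr(table, "row_labels") and hasattr(table, "values"):
        return (
            np.asarray(table.values, dtype=float),
            list(table.row_labels),
            list(table.column_labels),
        )
    if isinstance(table, pd.DataFrame):
        return (
            table.to_numpy(dtype=float),
            [str(i) for i in table.index],
            [str(c) for c in table.columns],
        )
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("table must be two-dimensional")
    return (
        arr,
        [f"row{i}" for i in range(arr.shape[0])],
        [f"col{j}" for j in range(arr.shape[1])],
    )


def fit_ca(table) -> CAResult:
    """Fit correspondence analysis to a non-negative table.

    Accepts an ``IndicatorTable``, a pandas ``DataFrame`` or a plain
    array.  All-zero rows or columns are rejected (their chi-square
    profile is undefined) with the offending label named.  Axis signs are
    fixed by forcing the largest-magnitude row coordinate on each axis to
    be positive, so fits are reproducible across platforms.
    """
    N, row_labels, col_labels = _as_labelled_array(table)
    if np.any(N < 0) or not np.all(np.isfinite(N)):
        raise ValueError("table entries must be finite and non-negative")
    grand = N.sum()
    if grand <= 0:
        raise ValueError("table grand total must be positive")
    zero_rows = [row_labels[i] for i in np.flatnonzero(N.sum(axis=1) == 0)]
    if zero_rows:
        raise ValueError(f"all-zero row(s): {zero_rows}")
    zero_cols = [col_labels[j] for j in np.flatnonzero(N.sum(axis=0) == 0)]
    if zero_cols:
        raise ValueError(f"all-zero column(s): {zero_cols}")

    P = N / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    expected = np.outer(r, c)
    S = (P - expected) / np.sqrt(expected)
    total_inertia = float((S**2).sum())

    U, sigma, Vt = np.linalg.svd(S, full_matrices=False)
    max_axes = min(len(row_labels), len(col_labels)) - 1
    sigma = sigma[:max_axes]
    U = U[:, :max_axes]
    V = Vt.T[:, :max_axes]
    if sigma.size and sigma[0] > 0:
        keep = sigma >= _RELATIVE_RANK_TOL * sigma[0]
        # numerical zero inertia: treat as rank 0 (perfect independence)
        if total_inertia < _RELATIVE_RANK_TOL:
            keep &= False
    else:
        keep = np.zeros(sigma.shape, dtype=bool)
    sigma, U, V = sigma[keep], U[:, keep], V[:, keep]

    inv_sqrt_r = 1.0 / np.sqrt(r)
    inv_sqrt_c = 1.0 / np.sqrt(c)
    row_standard = inv_sqrt_r[:, None] * U
    col_standard = inv_sqrt_c[:, None] * V

    # reproducible sign convention
    for k in range(sigma.size):
        i = int(np.argmax(np.abs(row_standard[:, k])))
        if row_standard[i, k] < 0:
            row_standard[:, k] *= -1
            col_standard[:, k] *= -1

    row_coords = row_standard * sigma
    col_coords = col_standard * sigma
    inertias = sigma**2
    fractions = (
        inertias / total_inertia if total_inertia > 0 else np.zeros_like(inertias)
    )

    return CAResult(
        row_labels=tuple(row_labels),
        column_labels=tuple(col_labels),
        singular_values=sigma,
        principal_inertias=inertias,
        inertia_fractions=fractions,
        row_coordinates=row_coords,
        column_coordinates=col_coords,
        row_standard_coordinates=row_standard,
        column_standard_coordinates=col_standard,
        row_masses=r,
        column_masses=c,
        total_inertia=total_inertia,
    )


def project_supplementary(result: CAResult, new_rows) -> np.ndarray:
    """Project supplementary rows onto fitted axes.

    Uses the CA transition formula: a row profile (row divided by its
    sum) times the column standard coordinates.  Re-projecting a fitted
    row reproduces its own principal coordinates; a row proportional to
    the column-mass profile lands at the origin.
    """
    if isinstance(new_rows, pd.DataFrame):
        missing = [c for c in result.column_labels if c not in new_rows.columns]
        extra = [c for c in new_rows.columns if c not in result.column_labels]
        if missing or extra:
            raise ValueError(
                f"column mismatch: missing {missing}, unexpected {extra}"
            )
        arr = new_rows.loc[:, list(result.column_labels)].to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(new_rows, dtype=float))
        if arr.shape[1] != len(result.column_labels):
            raise ValueError(
                f"expected {len(result.column_labels)} columns, got {arr.shape[1]}"
            )
    row_sums = arr.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValueError("every supplementary row must have a positive sum")
    profiles = arr / row_sums[:, None]
    return profiles @ result.column_standard_coordinates


def plane_summary(result: CAResult, axes: tuple[int, ...] = (1, 2)) -> float:
    """Fraction of total inertia carried by the requested axes (1-based)."""
    total = 0.0
    for axis in axes:
        if not 1 <= axis <= result.n_axes:
            raise IndexError(
                f"axis {axis} out of range; fit has {result.n_axes} axes"
            )
        total += float(result.inertia_fractions[axis - 1])
    return total
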