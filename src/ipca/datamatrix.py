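"""Sample-by-variable data matrix container and column centering.

The whole package works on the ``n x p`` convention of omics expression
matrices: rows are biological samples, columns are measured variables
(genes, transcripts, metabolites).  ``DataMatrix`` is a thin validated
wrapper around a float ndarray that keeps sample/variable labels together
with the data and records whether columns have been mean-centered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputDataError

__all__ = ["DataMatrix", "center"]


def _default_labels(prefix: str, k: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i + 1}" for i in range(k))


@dataclass(frozen=True)
class DataMatrix:
    """An ``n x p`` numeric matrix with sample and variable labels.

    Parameters
    ----------
    values
        Matrix of shape ``(n, p)`` with ``n >= 2`` samples in rows and
        ``p >= 2`` variables in columns.  Must be finite; missing values
        are rejected (impute upstream if needed).
    sample_ids, variable_names
        Optional labels; generated as ``s1..sn`` / ``x1..xp`` when omitted.
    centered
        Set when every column mean is (numerically) zero.  Constructors
        that center data set this; user-constructed matrices default to
        ``False``.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...] = field(default=())
    variable_names: tuple[str, ...] = field(default=())
    centered: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise InputDataError(f"expected a 2-d matrix, got ndim={values.ndim}")
        n, p = values.shape
        if n < 2 or p < 2:
            raise InputDataError(f"need at least 2 samples and 2 variables, got {n} x {p}")
        sample_ids = tuple(self.sample_ids) or _default_labels("s", n)
        variable_names = tuple(self.variable_names) or _default_labels("x", p)
        bad = ~np.isfinite(values)
        if bad.any():
            j = int(np.argwhere(bad.any(axis=0)).ravel()[0])
            name = variable_names[j] if j < len(variable_names) else f"column {j + 1}"
            raise InputDataError(f"non-finite value in variable {name!r}")
        object.__setattr__(self, "values", values)
        if len(sample_ids) != n:
            raise InputDataError(f"{len(sample_ids)} sample ids for {n} rows")
        if len(variable_names) != p:
            raise InputDataError(f"{len(variable_names)} variable names for {p} columns")
        if len(set(variable_names)) != p:
            raise InputDataError("duplicate variable names")
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "variable_names", variable_names)
        if self.centered:
            scale = max(float(np.abs(values).max()), 1.0)
            if float(np.abs(values.mean(axis=0)).max()) > 1e-10 * scale:
                raise InputDataError("centered=True but column means are not zero")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def center(data: DataMatrix) -> DataMatrix:
    """Subtract the mean of each column.

    Idempotent: centering an already-centered matrix returns an equal
    matrix.  The input object is never modified.
    """
    values = data.values - data.values.mean(axis=0, keepdims=True)
    return DataMatrix(
        values=values,
        sample_ids=data.sample_ids,
        variable_names=data.variable_names,
        centered=True,
    )
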