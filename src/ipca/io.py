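"""Reading expression matrices and writing fit results.

Input is a rectangular delimited table (CSV or TSV) with a header row of
variable names and a first column of sample identifiers -- the standard
layout of an exported expression or abundance matrix.  Outputs are plain
CSV/JSON: ``scores.csv`` (samples x components), ``loadings.csv``
(variables x components), ``kurtosis.json`` (per-component kurtosis,
ordering and any sparsity plan) and ``run_log.json`` (full configuration
including the seed, for bit-for-bit reruns of deterministic paths).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import IcaResult, SpcaResult
from .datamatrix import DataMatrix
from .decomposition import IpcaResult
from .exceptions import InputDataError
from .pca import PcaResult
from .simulate import EvaluationReport

__all__ = ["read_matrix", "write_results"]


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_matrix(
    path,
    delimiter: str | None = None,
    labels_column: str | None = None,
) -> tuple[DataMatrix, np.ndarray | None]:
    """Load a samples-x-variables table.

    The first column is taken as sample identifiers.  ``labels_column``
    optionally names a (non-numeric or numeric) column of class labels to
    split off, e.g. for Davies-Bouldin evaluation.  Returns
    ``(DataMatrix, labels-or-None)``.  Non-numeric cells, ragged rows and
    duplicate variable names raise :class:`InputDataError` naming the
    offending location.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise InputDataError(f"duplicate variable name {name!r}")
        seen.add(name)
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise InputDataError(f"malformed table {path}: {exc}") from exc
    labels = None
    if labels_column is not None:
        if labels_column not in frame.columns:
            raise InputDataError(f"label column {labels_column!r} not in header")
        labels = frame[labels_column].to_numpy()
        frame = frame.drop(columns=[labels_column])
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        raise InputDataError(f"non-numeric cell at row {row!r}, column {col!r}")
    if numeric.isna().any().any():
        col = numeric.isna().any(axis=0).idxmax()
        raise InputDataError(f"missing value in column {col!r}")
    data = DataMatrix(
        values=numeric.to_numpy(dtype=float),
        sample_ids=tuple(str(i) for i in frame.index),
        variable_names=tuple(str(c) for c in frame.columns),
    )
    return data, labels


def _components_frame(matrix: np.ndarray, index, prefix: str = "IPC") -> pd.DataFrame:
    cols = [f"{prefix}{j + 1}" for j in range(matrix.shape[1])]
    return pd.DataFrame(matrix, index=index, columns=cols)


def write_results(result, outdir, data: DataMatrix | None = None, config: dict | None = None):
    """Write a fit result (or an evaluation report) as CSV + JSON files.

    Returns the list of paths written.  Scores/loadings round-trip
    through :func:`read_matrix` within 1e-12.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample_ids = data.sample_ids if data is not None else None
    variable_names = data.variable_names if data is not None else None
    written: list[Path] = []

    def _dump_json(name: str, payload: dict) -> None:
        path = outdir / name
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(path)

    def _dump_csv(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        frame.to_csv(path, float_format="%.17g")
        written.append(path)

    if isinstance(result, EvaluationReport):
        _dump_csv("replicates.csv", pd.DataFrame(result.to_tidy_records()).set_index("replicate"))
        _dump_json("summary.json", result.summary())
    elif isinstance(result, (IpcaResult, IcaResult, SpcaResult, PcaResult)):
        if isinstance(result, IpcaResult):
            loadings = result.independent_loadings.T
            scores = result.scores
            kurt = {
                "loading_kurtosis": [float(x) for x in result.loading_kurtosis],
                "order": [int(x) for x in result.order],
            }
            if result.sparsity is not None:
                kurt["keepX"] = list(result.sparsity.keepX)
                kurt["gamma"] = [float(g) for g in result.sparsity.gamma]
        elif isinstance(result, IcaResult):
            loadings = result.sources.T
            scores = result.scores
            kurt = {
                "component_kurtosis": [float(x) for x in result.component_kurtosis],
                "order": [int(x) for x in result.order],
            }
        elif isinstance(result, SpcaResult):
            loadings = result.sparse_loadings
            scores = result.scores
            kurt = {"keepX": list(result.keepX), "converged": bool(result.converged)}
        else:
            loadings = result.V
            scores = result.U * result.D
            kurt = {
                "explained_variance_ratio": [
                    float(x) for x in result.explained_variance_ratio
                ]
            }
        n, m = scores.shape
        sidx = sample_ids or [f"s{i + 1}" for i in range(n)]
        vidx = variable_names or [f"x{i + 1}" for i in range(loadings.shape[0])]
        _dump_csv("scores.csv", _components_frame(scores, pd.Index(sidx, name="sample")))
        _dump_csv(
            "loadings.csv", _components_frame(loadings, pd.Index(vidx, name="variable"))
        )
        _dump_json("kurtosis.json", kurt)
    else:
        raise TypeError(f"don't know how to serialize {type(result).__name__}")
    _dump_json("run_log.json", config or {})
    return written
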