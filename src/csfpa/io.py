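"""Readers and writers for expression data, networks and reports.

All tabular artifacts are tab-separated text.  Expression data comes in two
dialects: one file per replicate series (header row of gene names, one row
per time point), or a single file whose first column, named ``series``,
labels the replicate.  Gene indices in edge lists are 1-based.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .benchmark import ExpressionDataset, SignedNetwork

__all__ = [
    "read_expression",
    "write_expression",
    "read_adjacency",
    "write_adjacency",
    "read_edge_list",
    "write_edge_list",
    "preprocess_sos",
    "load_config",
    "write_report",
]

SERIES_COLUMN = "series"


def _read_table(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV ({exc})") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def _to_numeric(df: pd.DataFrame, path: Path) -> np.ndarray:
    coerced = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(coerced) & df.notna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-numeric cell at line {r + 2}, column {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    if df.isna().to_numpy().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing cell at line {r + 2}, column {df.columns[c]!r}")
    # convert from the raw strings (correctly rounded) so round trips are exact
    return df.to_numpy(dtype=object).astype(float)


def read_expression(paths: str | Path | Sequence[str | Path]) -> ExpressionDataset:
    """Read time-series expression data (either TSV dialect).

    A single path whose table contains a ``series`` column is split into
    replicates by that column; otherwise each file is one replicate series.
    Gene names must agree across files.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    series: list[np.ndarray] = []
    gene_names: list[str] | None = None
    for p in map(Path, paths):
        df = _read_table(p)
        if df.columns[0] == SERIES_COLUMN:
            labels = df[SERIES_COLUMN]
            names = list(df.columns[1:])
            for _, group in df.groupby(labels, sort=False):
                series.append(_to_numeric(group[names], p))
        else:
            names = list(df.columns)
            series.append(_to_numeric(df, p))
        if gene_names is None:
            gene_names = names
        elif names != gene_names:
            raise ValueError(f"{p}: gene names differ from earlier files")
    return ExpressionDataset(series, gene_names or [])


def write_expression(
    dataset: ExpressionDataset,
    path: str | Path,
    combined: bool = False,
    float_format: str = "%.6g",
) -> list[Path]:
    """Write a dataset as TSV: one file per series, or one combined file.

    With ``combined=True`` writes a single file at ``path`` with a leading
    ``series`` column; otherwise writes ``<stem>_s<k>.tsv`` files beside
    ``path`` and returns their paths.
    """
    path = Path(path)
    if combined:
        frames = []
        for k, s in enumerate(dataset.series, start=1):
            df = pd.DataFrame(s, columns=dataset.gene_names)
            df.insert(0, SERIES_COLUMN, k)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(
            path, sep="\t", index=False, float_format=float_format
        )
        return [path]
    out = []
    for k, s in enumerate(dataset.series, start=1):
        f = path.with_name(f"{path.stem}_s{k}{path.suffix or '.tsv'}")
        pd.DataFrame(s, columns=dataset.gene_names).to_csv(
            f, sep="\t", index=False, float_format=float_format
        )
        out.append(f)
    return out


def read_adjacency(path: str | Path) -> SignedNetwork:
    """Read a signed adjacency matrix TSV (header = gene names)."""
    p = Path(path)
    df = _read_table(p)
    values = _to_numeric(df, p)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{p}: adjacency must be square, got {values.shape}")
    return SignedNetwork(values)


def write_adjacency(
    network: SignedNetwork | np.ndarray,
    path: str | Path,
    gene_names: Iterable[str] | None = None,
    float_format: str = "%.6g",
) -> Path:
    adj = network.adjacency if isinstance(network, SignedNetwork) else np.asarray(network)
    names = list(gene_names) if gene_names else [f"G{i + 1}" for i in range(adj.shape[0])]
    pd.DataFrame(adj, columns=names).to_csv(
        Path(path), sep="\t", index=False, float_format=float_format
    )
    return Path(path)


def write_edge_list(network: SignedNetwork, path: str | Path) -> Path:
    """Write edges as TSV columns (regulator, target, sign), 1-based, sign in {+,-}."""
    rows = [
        {"regulator": reg, "target": tgt, "sign": "+" if s > 0 else "-"}
        for reg, tgt, s in network.edges()
    ]
    pd.DataFrame(rows, columns=["regulator", "target", "sign"]).to_csv(
        Path(path), sep="\t", index=False
    )
    return Path(path)


def read_edge_list(path: str | Path, n_genes: int) -> SignedNetwork:
    """Read a (regulator, target, sign) edge list into an N x N signed network."""
    p = Path(path)
    df = pd.read_csv(p, sep="\t", dtype=str)
    required = ["regulator", "target", "sign"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{p}: edge list needs columns {required}")
    adj = np.zeros((n_genes, n_genes))
    for line, row in enumerate(df.itertuples(index=False), start=2):
        try:
            reg, tgt = int(row.regulator), int(row.target)
        except ValueError:
            raise ValueError(f"{p}: non-integer gene index at line {line}") from None
        if not (1 <= reg <= n_genes and 1 <= tgt <= n_genes):
            raise ValueError(f"{p}: gene index out of range at line {line}")
        if row.sign not in ("+", "-", "+1", "-1", "1"):
            raise ValueError(f"{p}: sign must be + or - at line {line}")
        adj[tgt - 1, reg - 1] = 1.0 if row.sign in ("+", "+1", "1") else -1.0
    return SignedNetwork(adj)


def preprocess_sos(raw: ExpressionDataset) -> ExpressionDataset:
    """Standard preprocessing for the E. coli SOS response series.

    Drops the first time point of each series (the zero measurement) and
    min-max rescales each gene to [0, 1] within each series.  A gene that is
    constant after dropping has zero range and is set to 0.5 with a warning.
    """
    out = []
    for k, s in enumerate(raw.series):
        if s.shape[0] < 3:
            raise ValueError(f"series {k}: need at least 3 time points to drop one")
        trimmed = s[1:].copy()
        lo = trimmed.min(axis=0)
        hi = trimmed.max(axis=0)
        span = hi - lo
        flat = span == 0
        if np.any(flat):
            names = [raw.gene_names[i] for i in np.nonzero(flat)[0]]
            warnings.warn(
                f"series {k + 1}: constant gene(s) {names} set to 0.5 after rescaling",
                stacklevel=2,
            )
        span = np.where(flat, 1.0, span)
        scaled = (trimmed - lo) / span
        scaled[:, flat] = 0.5
        out.append(scaled)
    return ExpressionDataset(out, list(raw.gene_names))


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration; returns a plain dict of sections."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_report(report: dict, path: str | Path) -> Path:
    """Write a report as JSON plus a flat key-value text sidecar."""
    p = Path(path)
    p.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    flat = p.with_suffix(".txt")
    with open(flat, "w") as fh:
        for key, value in sorted(report.items()):
            fh.write(f"{key}\t{value}\n")
    return p
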