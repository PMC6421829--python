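"""Readers and writers for the pipeline's external formats.

TSV (tab-delimited, UTF-8, '.' decimal separator) for count / environment /
function tables; Newick for trees; JSON for structured results.  Lines
starting with '#' are treated as comments in every TSV dialect, which is
where the writers embed run metadata.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .tables import CountTable, DistanceMatrix, EnvTable, FunctionTable
from .tree import PhyloTree

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_env_table",
    "write_env_table",
    "read_function_table",
    "write_function_table",
    "read_tree",
    "write_results",
]

log = logging.getLogger("benthodiv.io")

_NA_TOKENS = ["NA", "NaN", "nan", ""]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        comment="#",
        na_values=_NA_TOKENS,
        keep_default_na=False,
        encoding="utf-8",
    )


def read_count_table(
    path: str | Path,
    transpose: bool = False,
    fraction: Mapping[str, str] | None = None,
) -> CountTable:
    """Read a samples x zOTUs integer count table.

    The first column holds sample labels; pass ``transpose=True`` for the
    zOTUs-in-rows dialect (some QIIME-style exports).  Cells must be
    non-negative integers; the first offending cell is named on error.
    """
    df = _read_tsv(path)
    if transpose:
        df = df.T
    arr = df.to_numpy()
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (np.mod(vals.fillna(0), 1) != 0)
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"non-integer count {df.iloc[i, j]!r} at sample "
                f"{df.index[i]!r}, zOTU {col!r} in {path}"
            )
        neg = vals < 0
        if neg.any():
            i = int(np.argmax(neg.to_numpy()))
            raise ValueError(
                f"negative count {df.iloc[i, j]!r} at sample "
                f"{df.index[i]!r}, zOTU {col!r} in {path}"
            )
    table = CountTable.from_dataframe(df.astype(np.int64), fraction=fraction)
    depths = table.depths()
    log.info(
        "read count table %s: %d samples, %d zOTUs, depths %d-%d",
        path, table.n_samples, table.n_otus, depths.min(), depths.max(),
    )
    return table


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="sample")


def read_env_table(
    path: str | Path, companion: CountTable | None = None
) -> EnvTable:
    """Read per-sample environmental covariates.

    Numeric columns only, except an optional ``fraction`` column carrying
    DNA/RNA labels.  NA tokens stay missing (pairwise-complete handling is
    downstream's job).  If a companion count table is given, samples present
    here but absent there are reported as orphans (warning only).
    """
    df = _read_tsv(path)
    frac = None
    if "fraction" in df.columns:
        frac = df.pop("fraction").astype(str)
    for col in df.columns:
        df[col] = pd.to_numeric(df[col], errors="raise")
    env = EnvTable(df, fraction=frac)
    na_cols = [c for c in df.columns if df[c].isna().any()]
    if na_cols:
        log.info("environment table %s has missing values in: %s", path, na_cols)
    if companion is not None:
        orphans = [s for s in env.sample_ids if s not in companion.sample_ids]
        if orphans:
            log.warning(
                "environment samples absent from count table: %s", orphans
            )
    return env


def write_env_table(env: EnvTable, path: str | Path) -> None:
    df = env.data.copy()
    if env.fraction is not None:
        df.insert(0, "fraction", env.fraction)
    df.to_csv(path, sep="\t", index_label="sample", na_rep="NA")


def read_function_table(path: str | Path) -> FunctionTable:
    df = _read_tsv(path)
    for col in df.columns:
        df[col] = pd.to_numeric(df[col], errors="raise")
    return FunctionTable(df)


def write_function_table(table: FunctionTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample")


def read_tree(path: str | Path) -> PhyloTree:
    """Read a rooted Newick tree with branch lengths."""
    return PhyloTree.from_newick(Path(path))


def _meta_header(metadata: Mapping[str, Any] | None) -> str:
    if not metadata:
        return ""
    items = "\t".join(f"{k}={v}" for k, v in sorted(metadata.items()))
    return f"# benthodiv\t{items}\n"


def write_results(
    obj: Any, path: str | Path, metadata: Mapping[str, Any] | None = None
) -> Path:
    """Write a result object to disk.

    Tabular results (distance matrices, alpha profiles, screen tables,
    DataFrames) become TSV with metadata in '#' header lines; structured
    results (PERMANOVA results, dicts, dataclasses) become JSON with the
    metadata under a ``meta`` key.  Column order is deterministic.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _tsv(df: pd.DataFrame, index_label: str = "id") -> Path:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_meta_header(metadata))
            df.to_csv(fh, sep="\t", index_label=index_label, na_rep="NA")
        return path

    if isinstance(obj, DistanceMatrix):
        return _tsv(obj.to_dataframe(), index_label="sample")
    if isinstance(obj, CountTable):
        return _tsv(obj.to_dataframe(), index_label="sample")
    if isinstance(obj, EnvTable):
        df = obj.data.copy()
        if obj.fraction is not None:
            df.insert(0, "fraction", obj.fraction)
        return _tsv(df, index_label="sample")
    if isinstance(obj, FunctionTable):
        return _tsv(obj.data, index_label="sample")
    if isinstance(obj, pd.DataFrame):
        return _tsv(obj, index_label=obj.index.name or "id")
    if hasattr(obj, "data") and isinstance(getattr(obj, "data"), pd.DataFrame):
        return _tsv(obj.data, index_label=obj.data.index.name or "id")
    # structured results -> JSON
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        payload = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if isinstance(v, pd.DataFrame):
                continue  # per-rarefaction traces are written separately
            if isinstance(v, (np.floating, np.integer)):
                v = v.item()
            elif isinstance(v, np.ndarray):
                v = v.tolist()
            elif dataclasses.is_dataclass(v):
                v = dataclasses.asdict(v)
            payload[f.name] = v
    elif isinstance(obj, Mapping):
        payload = dict(obj)
    else:
        raise TypeError(f"do not know how to write a {type(obj).__name__}")
    if metadata:
        payload = {"meta": dict(metadata), **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n",
                    encoding="utf-8")
    return path
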