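"""Plain-text readers/writers for the pipeline's tabular formats.

Everything is TSV or JSON: expression matrices (rows = genes, columns =
samples), sample metadata, proportion matrices, marker panels, edge
lists, gene lists, and ground-truth exports of the simulator.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_proportions",
    "write_proportions",
    "read_marker_panel",
    "write_marker_panel",
    "read_probe_map",
    "read_edge_list",
    "write_edge_list",
    "read_gene_list",
    "write_ground_truth",
]


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.rename_axis("gene").to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype={"status": str, "gender": str})
    required = {"study", "status"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata lacks required columns: {sorted(missing)}")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("sample_id").to_csv(path, sep="\t")


def read_proportions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_proportions(props: pd.DataFrame, path) -> None:
    props.rename_axis("sample_id").to_csv(path, sep="\t")


def read_marker_panel(path) -> dict[str, list[str]]:
    with open(path) as fh:
        panel = json.load(fh)
    return {str(t): [str(g) for g in genes] for t, genes in panel.items()}


def write_marker_panel(markers: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        json.dump(markers, fh, indent=1)


def read_probe_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("probe map needs two columns: probe_id, gene_id")
    dup = df.iloc[:, 0].duplicated()
    if dup.any():
        multi = df.loc[dup, df.columns[0]].unique()
        raise ValueError(f"probes mapping to more than one gene: {list(multi[:5])}")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_edge_list(path, source: str | None = None) -> tuple[str, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return source or Path(path).stem, df


def write_edge_list(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_ground_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
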