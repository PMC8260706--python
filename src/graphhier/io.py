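"""Edge-list / GraphML readers and writers, result tables and run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .graph_core import GraphValidationError, WeightedDigraph, build_graph, from_networkx

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "write_graphml",
    "RunManifest",
    "write_results",
]

_FLOAT_FMT = "%.12g"


def _sniff(first_line: str) -> tuple[str, bool]:
    """Return (separator, has_header) from the first line of an edge list."""
    sep = "\t" if "\t" in first_line else ","
    fields = [f.strip() for f in first_line.split(sep)]

    def numeric(x: str) -> bool:
        try:
            float(x)
            return True
        except ValueError:
            return False

    # a header row is one whose trailing (weight) / all columns are non-numeric
    has_header = bool(fields) and not all(numeric(f) for f in fields)
    return sep, has_header


def read_edge_list(path, undirected: bool = False) -> WeightedDigraph:
    """Read a CSV/TSV edge list into a :class:`WeightedDigraph`.

    Accepts a ``tail,head[,weight]`` header or a headerless 2-3 column
    layout; a missing weight column defaults to 1.0.  Malformed rows raise
    with their line number; simple-graph violations raise
    :class:`GraphValidationError`.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    if not first.strip():
        raise GraphValidationError(f"{path}: empty edge list")
    sep, has_header = _sniff(first.rstrip("\n"))
    table = pd.read_csv(
        path, sep=sep, header=0 if has_header else None, dtype=str
    )
    if table.shape[1] not in (2, 3):
        raise GraphValidationError(
            f"{path}: expected 2 or 3 columns, found {table.shape[1]}"
        )
    records = []
    offset = 2 if has_header else 1  # 1-based line number of the first record
    for pos, row in enumerate(table.itertuples(index=False)):
        vals = list(row)
        try:
            w = float(vals[2]) if len(vals) == 3 and pd.notna(vals[2]) else 1.0
        except (TypeError, ValueError):
            raise GraphValidationError(
                f"{path}, line {pos + offset}: non-numeric weight {vals[2]!r}"
            ) from None
        if pd.isna(vals[0]) or pd.isna(vals[1]):
            raise GraphValidationError(
                f"{path}, line {pos + offset}: missing endpoint"
            )
        records.append((vals[0].strip(), vals[1].strip(), w))
    try:
        return build_graph(records, undirected=undirected)
    except GraphValidationError as err:
        raise GraphValidationError(f"{path}: {err}") from None


def write_edge_list(graph: WeightedDigraph, path) -> None:
    """Write ``tail,head,weight`` CSV; re-reading reproduces the graph."""
    frame = pd.DataFrame(
        graph.edge_records(), columns=["tail", "head", "weight"]
    )
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_graphml(path, undirected: bool = False) -> WeightedDigraph:
    """Read GraphML with a ``weight`` edge attribute (default 1.0)."""
    g = nx.read_graphml(path)
    if undirected or not g.is_directed():
        records = [
            (u, v, data.get("weight", 1.0)) for u, v, data in g.edges(data=True)
        ]
        return build_graph(records, vertices=list(g.nodes), undirected=True)
    return from_networkx(g)


def write_graphml(graph: WeightedDigraph, path) -> None:
    nx.write_graphml(graph.to_networkx(), path)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a CLI run bit-for-bit."""

    command: str
    parameters: dict
    seed: int | None = None
    package_version: str = __version__
    python_version: str = field(default_factory=platform.python_version)
    input_checksums: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def add_input(self, path) -> None:
        self.input_checksums[str(path)] = _sha256(path)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def write_results(tables: dict, manifest: RunManifest, out_dir) -> list[Path]:
    """Write each named table as CSV plus ``manifest.json``; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False, float_format=_FLOAT_FMT)
        written.append(path)
    mpath = out_dir / "manifest.json"
    mpath.write_text(manifest.to_json())
    written.append(mpath)
    return written
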