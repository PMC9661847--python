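"""Plain-text readers and writers: TSV count tables, metadata, network files.

All formats are desk-scale text: tab-separated tables for counts and edge
lists, GraphML for network topology.  BIOM and binary formats are deliberately
unsupported.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import CountTable, CountTableError, SampleMetadata

log = logging.getLogger("pneumotyper")

ORIENTATIONS = ("samples-in-rows", "taxa-in-rows")


def read_count_table(
    path: str | Path,
    orientation: str = "samples-in-rows",
    site_of: dict[str, str] | None = None,
) -> CountTable:
    """Read a TSV count table; the first column holds row identifiers.

    ``orientation='taxa-in-rows'`` transposes on read so the in-memory object
    is always samples-in-rows.  Samples with zero total reads are dropped
    with a warning.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}, got {orientation!r}")
    frame = pd.read_csv(path, sep="\t", index_col=0)
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            raise CountTableError(
                f"non-numeric cell at row '{bad[0]}', column '{col}' in {path}"
            )
        frame[col] = coerced
    if orientation == "taxa-in-rows":
        frame = frame.T
    totals = frame.sum(axis=1)
    if (totals == 0).any():
        log.warning(
            "dropping %d zero-total samples from %s", int((totals == 0).sum()), path
        )
    return CountTable(frame, site_of=site_of, drop_empty=True)


def write_count_table(
    table: CountTable, path: str | Path, orientation: str = "samples-in-rows"
) -> None:
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}, got {orientation!r}")
    frame = table.counts if orientation == "samples-in-rows" else table.counts.T
    frame.to_csv(path, sep="\t", index_label="id")


def read_metadata(path: str | Path, *, allow_replicates: bool = False) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return SampleMetadata(frame, allow_replicates=allow_replicates)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- network

EDGE_COLUMNS = ("source", "target", "rho", "p", "sign")


def write_network(net, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write an edge-list TSV and a GraphML file.

    Every edge must carry a significance value: networks are written only
    after the permutation test has run.

    Returns the two paths written: ``(<prefix>.edges.tsv, <prefix>.graphml)``.
    """
    graph = net.graph
    rows = []
    for u, v, data in graph.edges(data=True):
        if "p" not in data or data["p"] is None:
            raise ValueError(f"edge ({u}, {v}) has no p value; run significance first")
        rows.append(
            {
                "source": u,
                "target": v,
                "rho": data["rho"],
                "p": data["p"],
                "sign": data["sign"],
            }
        )
    edges = pd.DataFrame(rows, columns=list(EDGE_COLUMNS))
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    edge_path = prefix.with_suffix(".edges.tsv")
    graphml_path = prefix.with_suffix(".graphml")
    edges.to_csv(edge_path, sep="\t", index=False)
    clean = nx.Graph()
    for node, data in graph.nodes(data=True):
        clean.add_node(node, **{k: v for k, v in data.items() if v is not None})
    for u, v, data in graph.edges(data=True):
        clean.add_edge(u, v, **{k: v for k, v in data.items() if v is not None})
    nx.write_graphml(clean, graphml_path)
    return edge_path, graphml_path


def read_network(graphml_path: str | Path):
    """Round-trip partner of :func:`write_network` (topology + attributes)."""
    from .networks import MicrobialNetwork

    graph = nx.read_graphml(graphml_path)
    graph = nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes})
    return MicrobialNetwork(graph)
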