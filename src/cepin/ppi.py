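"""Reading, cleaning and validating the protein-interaction network (PIN).

The PIN is the scaffold onto which every co-expressed network is built: an
undirected simple graph over gene symbols.  Input edge lists are cleaned by
dropping self-loops and collapsing duplicate pairs in either orientation.
Gene identity is the exact symbol string after whitespace trimming (case is
preserved); inputs are expected to be pre-harmonized to one symbol namespace.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["load_network", "subgraph_on", "write_network", "NetworkParseError"]


class NetworkParseError(ValueError):
    """Raised when an edge-list file is empty or contains a malformed line."""


_DELIMS = ("\t", ",", None)  # None -> any whitespace run


def _split_line(line: str, delim: str | None) -> list[str]:
    if delim is None:
        return line.split()
    return [f.strip() for f in line.split(delim)]


def _detect_delimiter(first_line: str) -> str | None:
    """Pick among tab / comma / whitespace, preferring tab."""
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return None


def load_network(path: str | Path) -> nx.Graph:
    """Load an edge list into a simple undirected :class:`networkx.Graph`.

    Accepts two-column edge lists (tab, comma or whitespace delimited) and
    three-column SIF lines (``node relation node``; the relation is ignored).
    An optional single header line is tolerated when its fields repeat as
    gene symbols nowhere else -- in practice, a header is detected as a first
    line whose fields contain common header words.

    Self-loops are dropped, duplicate pairs (either orientation) collapsed,
    and the counts of dropped records are logged.

    Raises
    ------
    NetworkParseError
        For an empty file, or any line that does not have 2 (edge list) or
        3 (SIF) non-empty fields; the error names the 1-based line number.
    """
    path = Path(path)
    raw = path.read_text()
    lines = raw.splitlines()
    graph: nx.Graph = nx.Graph()
    n_self, n_dup, n_records = 0, 0, 0
    delim: str | None = None
    header_re = re.compile(
        r"^(gene|node|protein|source|target|symbol|interactor|from|to)[_a-z0-9]*$",
        re.IGNORECASE,
    )
    started = False
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if delim is None:
            delim = _detect_delimiter(line)
        fields = [f for f in _split_line(line.strip(), delim) if f]
        if not started and len(fields) in (2, 3) and all(header_re.match(f) for f in fields):
            started = True  # header line
            continue
        started = True
        if len(fields) == 3:
            a, b = fields[0], fields[2]  # SIF: node relation node
        elif len(fields) == 2:
            a, b = fields
        else:
            raise NetworkParseError(
                f"{path}:{lineno}: expected 2 fields (edge list) or 3 (SIF), "
                f"got {len(fields)}: {line!r}"
            )
        n_records += 1
        if a == b:
            n_self += 1
            continue
        if graph.has_edge(a, b):
            n_dup += 1
            continue
        graph.add_edge(a, b)
    if n_records == 0:
        raise NetworkParseError(f"{path}: no interaction records found")
    logger.info(
        "loaded %s: %d records -> %d nodes, %d edges (%d self-loops, %d duplicates dropped)",
        path.name, n_records, graph.number_of_nodes(), graph.number_of_edges(), n_self, n_dup,
    )
    return graph


def subgraph_on(genes: Iterable[str], net: nx.Graph) -> nx.Graph:
    """Induced subgraph on ``genes ∩ net.nodes`` (a detached copy).

    An empty intersection yields an empty network; no error is raised.
    """
    keep = set(genes) & set(net.nodes)
    return nx.Graph(net.subgraph(keep))


def write_network(net: nx.Graph, path: str | Path) -> None:
    """Write the cleaned network as a two-column tab-separated edge list.

    Edges are emitted in sorted order with each pair's endpoints sorted, so
    the output is deterministic and reload-stable (isolated nodes are not
    representable in an edge list and are omitted).
    """
    path = Path(path)
    with path.open("w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\n")
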