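"""Signed protein–protein interaction network: data model, I/O, distance queries.

The network mixes physical (symmetric) and regulatory (directed) relations.
Undirected edges are stored once and traversed in both directions; directed
edges only source→target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx

from .errors import ParseError, ValidationError

EDGE_LIST_HEADER = ("source", "target", "sign", "directed")

_TRUE_TOKENS = {"true", "1", "yes", "t"}
_FALSE_TOKENS = {"false", "0", "no", "f"}


@dataclass(frozen=True)
class Protein:
    id: str
    gene_symbol: str = ""
    uniprot: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ValidationError("protein id must be non-empty")


@dataclass(frozen=True)
class Interaction:
    source: str
    target: str
    sign: int = +1
    directed: bool = False
    kind: str = ""

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise ValidationError(f"interaction sign must be +1 or -1, got {self.sign}")

    def endpoints(self) -> frozenset[str] | tuple[str, str]:
        """Canonical key: ordered tuple if directed, frozen pair otherwise."""
        if self.directed:
            return (self.source, self.target)
        return frozenset((self.source, self.target))


@dataclass
class InteractomeGraph:
    """Signed interaction network over uniquely-identified proteins."""

    proteins: dict[str, Protein] = field(default_factory=dict)
    interactions: list[Interaction] = field(default_factory=list)

    def __post_init__(self):
        self._digraph: nx.DiGraph | None = None

    # -- construction -------------------------------------------------

    def add_protein(self, protein: Protein) -> None:
        if protein.id not in self.proteins:
            self.proteins[protein.id] = protein
            self._digraph = None

    def add_interaction(self, interaction: Interaction) -> bool:
        """Add an edge, creating endpoints as bare proteins if needed.

        Duplicate edges (same endpoints under the directedness convention)
        collapse to the first occurrence with a warning. Returns True if the
        edge was added.
        """
        for pid in (interaction.source, interaction.target):
            self.add_protein(Protein(id=pid, gene_symbol=pid))
        key = interaction.endpoints()
        if not hasattr(self, "_edge_keys"):
            self._edge_keys = {e.endpoints() for e in self.interactions}
        if key in self._edge_keys:
            warnings.warn(
                f"duplicate edge {interaction.source}-{interaction.target} ignored "
                "(first sign kept)",
                stacklevel=2,
            )
            return False
        self._edge_keys.add(key)
        self.interactions.append(interaction)
        self._digraph = None
        return True

    # -- queries -------------------------------------------------------

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_interactions(self) -> int:
        return len(self.interactions)

    def protein_ids(self) -> list[str]:
        return list(self.proteins)

    def as_digraph(self) -> nx.DiGraph:
        """Directed view: undirected edges contribute both arcs."""
        if self._digraph is None:
            g = nx.DiGraph()
            g.add_nodes_from(self.proteins)
            for e in self.interactions:
                g.add_edge(e.source, e.target, sign=e.sign)
                if not e.directed:
                    g.add_edge(e.target, e.source, sign=e.sign)
            self._digraph = g
        return self._digraph


def distances_from(
    graph: InteractomeGraph, source: str, max_depth: int
) -> dict[str, int]:
    """Hop distances from `source` up to `max_depth`, source excluded.

    Respects edge directedness: undirected edges are walkable both ways.
    """
    if source not in graph.proteins:
        raise KeyError(f"unknown source protein {source!r}")
    if max_depth < 1:
        raise ValidationError("max_depth must be >= 1")
    lengths = nx.single_source_shortest_path_length(
        graph.as_digraph(), source, cutoff=max_depth
    )
    lengths.pop(source, None)
    return lengths


def read_network(path, dialect: str = "tsv-edge-list") -> InteractomeGraph:
    """Read a signed edge list.

    ``tsv-edge-list``: header ``source\\ttarget\\tsign\\tdirected``.
    ``sif``: whitespace-separated ``source relation target [target...]``,
    read-only, sign defaults to +1, undirected.
    """
    if dialect == "tsv-edge-list":
        return _read_tsv_edge_list(path)
    if dialect == "sif":
        return _read_sif(path)
    raise ValidationError(f"unknown dialect {dialect!r}")


def _parse_sign(token: str, line: int) -> int:
    token = token.strip()
    if token in ("+1", "1", "+"):
        return +1
    if token in ("-1", "-", "−1"):  # ASCII or unicode minus
        return -1
    raise ValidationError(f"line {line}: unknown sign token {token!r}")


def _parse_bool(token: str, line: int) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise ParseError(f"unparseable directed flag {token!r}", line=line)


def _read_tsv_edge_list(path) -> InteractomeGraph:
    graph = InteractomeGraph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() == "source":
                continue
            if len(fields) < 4:
                raise ParseError(
                    f"expected 4 tab-separated columns, got {len(fields)}", line=lineno
                )
            src, tgt, sign_tok, dir_tok = fields[:4]
            kind = fields[4] if len(fields) > 4 else ""
            if not src or not tgt:
                raise ParseError("empty endpoint id", line=lineno)
            graph.add_interaction(
                Interaction(
                    source=src,
                    target=tgt,
                    sign=_parse_sign(sign_tok, lineno),
                    directed=_parse_bool(dir_tok, lineno),
                    kind=kind,
                )
            )
    return graph


def _read_sif(path) -> InteractomeGraph:
    graph = InteractomeGraph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) == 1:
                graph.add_protein(Protein(id=fields[0], gene_symbol=fields[0]))
                continue
            if len(fields) < 3:
                raise ParseError("SIF line needs source, relation, target", line=lineno)
            src, relation = fields[0], fields[1]
            for tgt in fields[2:]:
                graph.add_interaction(
                    Interaction(source=src, target=tgt, sign=+1, directed=False, kind=relation)
                )
    return graph


def write_network(graph: InteractomeGraph, path) -> None:
    """Write the 4-column TSV dialect (kind appended when present)."""
    with open(path, "w") as fh:
        fh.write("\t".join(EDGE_LIST_HEADER) + "\n")
        for e in graph.interactions:
            row = [e.source, e.target, f"{e.sign:+d}", str(e.directed).lower()]
            if e.kind:
                row.append(e.kind)
            fh.write("\t".join(row) + "\n")


def write_node_table(graph: InteractomeGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tgene_symbol\tuniprot\n")
        for p in graph.proteins.values():
            fh.write(f"{p.id}\t{p.gene_symbol}\t{p.uniprot or ''}\n")
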