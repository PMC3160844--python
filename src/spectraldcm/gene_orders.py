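"""Gene-order data types and file formats.

A genome is modelled as a *signed permutation* of the integers ``1..g``: the
order of entries gives the order of the shared genes along the (single,
linear) chromosome and the sign gives the strand.  An inversion reverses a
contiguous block of genes and flips every sign in the block; it is the only
mutation type modelled here.

The module also provides the labeled-tree container used throughout the
package (leaves carry observed genomes, internal vertices carry reconstructed
ancestral genomes) and readers/writers for the two external formats the tool
touches: GRAPPA-style gene-order files and Newick trees.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence, Union

import networkx as nx
import numpy as np

__all__ = [
    "GeneOrderError",
    "FormatError",
    "SignedGeneOrder",
    "GenomeSet",
    "LabeledTree",
    "apply_inversion",
    "read_gene_orders",
    "write_gene_orders",
    "read_newick",
    "write_newick",
]


class GeneOrderError(ValueError):
    """A gene order violates the signed-permutation contract."""


class FormatError(ValueError):
    """A gene-order or tree file could not be parsed."""


@dataclass(frozen=True)
class SignedGeneOrder:
    """A named genome as a signed permutation of ``1..g``.

    ``genes`` is stored as an immutable int32 array.  Two gene orders are
    equal iff their signed sequences are elementwise equal (names are
    metadata and do not participate in equality).
    """

    name: str
    genes: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.genes, dtype=np.int32)
        arr.setflags(write=False)
        object.__setattr__(self, "genes", arr)
        validate_permutation(arr, self.name)

    @property
    def g(self) -> int:
        return int(self.genes.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedGeneOrder):
            return NotImplemented
        return self.genes.size == other.genes.size and bool(
            np.array_equal(self.genes, other.genes)
        )

    def __hash__(self) -> int:
        return hash(self.genes.tobytes())

    def rename(self, name: str) -> "SignedGeneOrder":
        return SignedGeneOrder(name, self.genes)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SignedGeneOrder({self.name!r}, {self.genes.tolist()})"


def validate_permutation(arr: np.ndarray, name: str = "?") -> None:
    """Raise :class:`GeneOrderError` unless ``arr`` is a signed permutation."""
    if arr.ndim != 1 or arr.size == 0:
        raise GeneOrderError(f"genome {name}: empty or non-1D gene sequence")
    if np.any(arr == 0):
        raise GeneOrderError(f"genome {name}: zero gene entry")
    mag = np.abs(arr)
    seen = np.zeros(arr.size + 1, dtype=bool)
    for x in mag:
        if x > arr.size:
            raise GeneOrderError(
                f"genome {name}: gene {int(x)} out of range 1..{arr.size}"
            )
        if seen[x]:
            raise GeneOrderError(f"duplicate gene {int(x)} in {name}")
        seen[x] = True


@dataclass
class GenomeSet:
    """An ordered collection of genomes over one shared gene set."""

    genomes: list[SignedGeneOrder]

    def __post_init__(self) -> None:
        if not self.genomes:
            raise GeneOrderError("empty genome set")
        g = self.genomes[0].g
        names = set()
        for sg in self.genomes:
            if sg.g != g:
                raise GeneOrderError(
                    f"genome {sg.name}: gene count {sg.g} != {g} of {self.genomes[0].name}"
                )
            if sg.name in names:
                raise GeneOrderError(f"duplicate genome name {sg.name!r}")
            names.add(sg.name)

    @property
    def g(self) -> int:
        return self.genomes[0].g

    @property
    def n(self) -> int:
        return len(self.genomes)

    @property
    def names(self) -> list[str]:
        return [sg.name for sg in self.genomes]

    def __iter__(self) -> Iterator[SignedGeneOrder]:
        return iter(self.genomes)

    def __getitem__(self, i: int) -> SignedGeneOrder:
        return self.genomes[i]


def apply_inversion(genome: SignedGeneOrder, i: int, j: int) -> SignedGeneOrder:
    """Invert the gene block between 1-based positions ``i`` and ``j`` inclusive.

    The block appears in reversed order with all signs flipped; positions
    outside ``i..j`` are unchanged.  Applying the same inversion twice is the
    identity.
    """
    g = genome.g
    if not (1 <= i <= j <= g):
        raise IndexError(f"inversion positions ({i},{j}) out of range 1..{g}")
    genes = genome.genes.copy()
    genes[i - 1 : j] = -genes[i - 1 : j][::-1]
    return SignedGeneOrder(genome.name, genes)


# ---------------------------------------------------------------------------
# GRAPPA-style gene-order files
#
# ">name" header lines, each followed by one or more lines of whitespace-
# separated signed integers until the next header.  The writer emits one
# line of genes per genome.
# ---------------------------------------------------------------------------


def read_gene_orders(source: Union[str, io.TextIOBase]) -> GenomeSet:
    """Read a GRAPPA-style gene-order file into a :class:`GenomeSet`.

    ``source`` may be a filesystem path or an open text stream.  Each genome
    is validated as a signed permutation and all genomes must share the same
    gene count; violations raise :class:`FormatError` naming the offending
    genome.
    """
    if isinstance(source, (str,)):
        with open(source, "rt", encoding="utf-8") as fh:
            return read_gene_orders(fh)
    name: Optional[str] = None
    buf: list[int] = []
    genomes: list[SignedGeneOrder] = []

    def flush() -> None:
        if name is None:
            return
        if not buf:
            raise FormatError(f"genome {name}: no genes")
        try:
            genomes.append(SignedGeneOrder(name, np.array(buf, dtype=np.int32)))
        except GeneOrderError as exc:
            raise FormatError(str(exc)) from exc

    for lineno, raw in enumerate(source, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip()
            buf = []
            if not name:
                raise FormatError(f"line {lineno}: empty genome name")
        else:
            if name is None:
                raise FormatError(f"line {lineno}: gene data before any '>' header")
            try:
                buf.extend(int(tok) for tok in line.split())
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer gene entry") from exc
    flush()
    if not genomes:
        raise FormatError("no genomes in input")
    try:
        return GenomeSet(genomes)
    except GeneOrderError as exc:
        raise FormatError(str(exc)) from exc


def write_gene_orders(genome_set: GenomeSet, dest: Union[str, io.TextIOBase]) -> None:
    """Inverse of :func:`read_gene_orders`; one gene line per genome."""
    if isinstance(dest, str):
        with open(dest, "wt", encoding="utf-8") as fh:
            write_gene_orders(genome_set, fh)
        return
    for sg in genome_set:
        dest.write(f">{sg.name}\n")
        dest.write(" ".join(str(int(x)) for x in sg.genes) + "\n")


# ---------------------------------------------------------------------------
# Labeled trees
# ---------------------------------------------------------------------------


class LabeledTree:
    """An unrooted tree whose vertices may carry genome labels.

    Thin wrapper around an undirected :class:`networkx.Graph`.  Vertices are
    opaque integer ids; the node attribute ``genome`` holds an optional
    :class:`SignedGeneOrder`, the edge attribute ``length`` an optional
    nonnegative branch length.  Leaves (degree <= 1 vertices) of fully built
    trees always carry labels; internal vertices of a binary tree have degree
    exactly 3.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()
        self._next_id = 0

    # -- construction ------------------------------------------------------

    def add_vertex(self, genome: Optional[SignedGeneOrder] = None) -> int:
        v = self._next_id
        self._next_id += 1
        self.graph.add_node(v, genome=genome)
        return v

    def add_edge(self, u: int, v: int, length: Optional[float] = None) -> None:
        self.graph.add_edge(u, v, length=length)

    def copy(self) -> "LabeledTree":
        t = LabeledTree()
        t.graph = self.graph.copy()
        t._next_id = self._next_id
        return t

    @classmethod
    def from_star(cls, genomes: Sequence[SignedGeneOrder],
                  center: Optional[SignedGeneOrder] = None) -> "LabeledTree":
        """A star tree: one central vertex joined to every genome."""
        t = cls()
        c = t.add_vertex(center)
        for sg in genomes:
            t.add_edge(c, t.add_vertex(sg))
        return t

    # -- queries -----------------------------------------------------------

    def vertices(self) -> list[int]:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple[int, int]]:
        return list(self.graph.edges)

    def label(self, v: int) -> Optional[SignedGeneOrder]:
        return self.graph.nodes[v]["genome"]

    def set_label(self, v: int, genome: Optional[SignedGeneOrder]) -> None:
        self.graph.nodes[v]["genome"] = genome

    def length(self, u: int, v: int) -> Optional[float]:
        return self.graph.edges[u, v].get("length")

    def set_length(self, u: int, v: int, length: Optional[float]) -> None:
        self.graph.edges[u, v]["length"] = length

    def degree(self, v: int) -> int:
        return self.graph.degree[v]

    def neighbors(self, v: int) -> list[int]:
        return list(self.graph.neighbors(v))

    def is_leaf(self, v: int) -> bool:
        return self.graph.degree[v] <= 1

    def leaves(self) -> list[int]:
        return [v for v in self.graph.nodes if self.is_leaf(v)]

    def leaf_names(self) -> set[str]:
        out = set()
        for v in self.leaves():
            sg = self.label(v)
            if sg is not None:
                out.add(sg.name)
        return out

    def internal_vertices(self) -> list[int]:
        return [v for v in self.graph.nodes if self.graph.degree[v] >= 2]

    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    def validate(self) -> None:
        if self.graph.number_of_nodes() == 0:
            raise ValueError("empty tree")
        if not nx.is_tree(self.graph):
            raise ValueError("graph is not a tree (cycle or disconnected)")

    def is_binary(self) -> bool:
        return all(
            self.graph.degree[v] in (1, 3) or self.graph.number_of_nodes() <= 2
            for v in self.graph.nodes
        )

    # -- editing helpers used by the merging step --------------------------

    def subdivide_edge(self, u: int, v: int,
                       genome: Optional[SignedGeneOrder] = None) -> int:
        """Replace edge (u,v) by u-x-v and return the new vertex x."""
        if not self.graph.has_edge(u, v):
            raise KeyError(f"no edge ({u},{v})")
        self.graph.remove_edge(u, v)
        x = self.add_vertex(genome)
        self.add_edge(u, x)
        self.add_edge(x, v)
        return x

    def contract_edge(self, u: int, v: int) -> int:
        """Contract edge (u,v), merging v into u (u keeps its label)."""
        if not self.graph.has_edge(u, v):
            raise KeyError(f"no edge ({u},{v})")
        for w in list(self.graph.neighbors(v)):
            if w != u:
                self.graph.add_edge(u, w, **self.graph.edges[v, w])
        self.graph.remove_node(v)
        return u

    def suppress_degree_two(self) -> None:
        """Remove all unlabeled-or-not degree-2 vertices, joining their neighbors.

        Branch lengths of the two incident edges are summed when both are
        present.
        """
        changed = True
        while changed:
            changed = False
            for v in list(self.graph.nodes):
                if self.graph.degree[v] == 2:
                    a, b = self.graph.neighbors(v)
                    la = self.graph.edges[v, a].get("length")
                    lb = self.graph.edges[v, b].get("length")
                    length = (la + lb) if (la is not None and lb is not None) else None
                    self.graph.remove_node(v)
                    self.graph.add_edge(a, b, length=length)
                    changed = True
                    break

    def restricted_to(self, names: Iterable[str]) -> "LabeledTree":
        """The induced subtree spanning the named leaves, degree-2 suppressed."""
        want = set(names)
        keep = [v for v in self.leaves()
                if self.label(v) is not None and self.label(v).name in want]
        if len(keep) != len(want):
            raise KeyError(f"missing leaves: {want - self.leaf_names()}")
        t = self.copy()
        # iteratively strip leaves outside the wanted set
        changed = True
        while changed:
            changed = False
            for v in list(t.graph.nodes):
                if t.graph.degree[v] <= 1:
                    sg = t.label(v)
                    if sg is None or sg.name not in want:
                        t.graph.remove_node(v)
                        changed = True
        t.suppress_degree_two()
        return t

    # -- splits ------------------------------------------------------------

    def edge_split(self, u: int, v: int) -> frozenset[frozenset[str]]:
        """The bipartition of leaf names induced by removing edge (u,v)."""
        g = self.graph.copy()
        g.remove_edge(u, v)
        side_u = nx.node_connected_component(g, u)
        names_u, names_v = set(), set()
        for w in self.leaves():
            sg = self.label(w)
            if sg is None:
                continue
            (names_u if w in side_u else names_v).add(sg.name)
        return frozenset({frozenset(names_u), frozenset(names_v)})

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"LabeledTree({self.graph.number_of_nodes()} vertices, "
                f"{len(self.leaves())} leaves)")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick(source: Union[str, io.TextIOBase]) -> LabeledTree:
    """Parse a Newick tree (path, stream, or literal string) into a LabeledTree.

    Leaf names are preserved as labels holding no genome data; use
    :func:`attach_genomes` to bind a :class:`GenomeSet` afterwards.  Rooted
    serializations are read as unrooted trees (the root is suppressed when of
    degree 2).
    """
    import dendropy

    if isinstance(source, io.TextIOBase):
        text = source.read()
    elif isinstance(source, str) and "(" in source:
        text = source
    else:
        with open(source, "rt", encoding="utf-8") as fh:
            text = fh.read()
    try:
        dt = dendropy.Tree.get(data=text, schema="newick",
                               suppress_internal_node_taxa=True)
    except Exception as exc:
        raise FormatError(f"newick parse error: {exc}") from exc

    t = LabeledTree()
    mapping: dict = {}
    names_seen: set[str] = set()
    for node in dt.preorder_node_iter():
        label = None
        if node.taxon is not None:
            name = node.taxon.label
            if name in names_seen:
                raise FormatError(f"duplicate leaf name {name!r}")
            names_seen.add(name)
            label = _NamePlaceholder(name)
        mapping[node] = t.add_vertex(label)
        if node.parent_node is not None:
            t.add_edge(mapping[node.parent_node], mapping[node],
                       length=node.edge.length)
    t.suppress_degree_two()
    return t


class _NamePlaceholder:
    """Stands in for a genome label when only the leaf name is known."""

    __slots__ = ("name",)

    def __init__(self, name: str) -> None:
        self.name = name

    def __repr__(self) -> str:  # pragma: no cover
        return f"<leaf {self.name}>"


def attach_genomes(tree: LabeledTree, genome_set: GenomeSet) -> None:
    """Replace name placeholders on leaves with the matching genomes."""
    by_name = {sg.name: sg for sg in genome_set}
    for v in tree.leaves():
        lab = tree.label(v)
        if lab is not None and lab.name in by_name:
            tree.set_label(v, by_name[lab.name])


def write_newick(tree: LabeledTree, dest: Union[str, io.TextIOBase, None] = None,
                 *, internal_labels: bool = False) -> str:
    """Serialize a LabeledTree to Newick text (trifurcating root when unrooted).

    Returns the Newick string; when ``dest`` is given, also writes it there.
    With ``internal_labels=True`` internal vertices that carry genomes emit
    their names as internal node labels.
    """
    tree.validate()
    verts = tree.vertices()
    if len(verts) == 1:
        name = tree.label(verts[0]).name if tree.label(verts[0]) else ""
        text = f"({name});"
    elif len(verts) == 2:
        u, v = verts
        lu = tree.label(u).name if tree.label(u) else ""
        lv = tree.label(v).name if tree.label(v) else ""
        ln = tree.length(u, v)
        suffix = "" if ln is None else f":{_fmt_len(ln)}"
        text = f"({lu},{lv}{suffix});"
    else:
        # root at an internal vertex (binary trees always have one)
        internal = [v for v in verts if tree.degree(v) >= 3]
        root = internal[0] if internal else max(verts, key=tree.degree)
        text = _newick_recurse(tree, root, None, internal_labels) + ";"
    if dest is not None:
        if isinstance(dest, str):
            with open(dest, "wt", encoding="utf-8") as fh:
                fh.write(text + "\n")
        else:
            dest.write(text + "\n")
    return text


def _newick_recurse(tree: LabeledTree, v: int, parent: Optional[int],
                    internal_labels: bool) -> str:
    children = [w for w in tree.neighbors(v) if w != parent]
    lab = tree.label(v)
    name = lab.name if lab is not None else ""
    if not children:
        body = name
    else:
        inner = ",".join(
            _newick_recurse(tree, c, v, internal_labels)
            + ("" if tree.length(v, c) is None else f":{_fmt_len(tree.length(v, c))}")
            for c in children
        )
        body = f"({inner})" + (name if internal_labels else "")
    return body


def _fmt_len(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))
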