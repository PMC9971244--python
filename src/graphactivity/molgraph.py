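"""Hydrogen-suppressed molecular graphs.

A molecule is modelled as a simple undirected connected graph: one vertex per
heavy (non-hydrogen) atom, one edge per bond between heavy atoms.  Bond order,
aromaticity, charges, isotopes and stereochemistry are deliberately discarded —
the activity descriptors computed downstream are purely topological, and the
hydrogen-suppressed convention is what makes the reference values of the
bundled flavonoid set come out right (taxifolin has 22 heavy atoms, and its
descriptors are quoted over n = 22).

Graphs can come from chemistry (SMILES strings, SDF/MOL files, parsed with
RDKit) or be given directly as abstract edge lists.  Internally vertices are
always relabelled to contiguous 0-based integers; the original labels are kept
for reporting.
"""

from __future__ import annotations

import logging
from typing import Hashable, Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "MolecularGraph",
    "GraphError",
    "InvalidStructureError",
    "InvalidGraphError",
    "DisconnectedGraphError",
    "DegenerateInputError",
    "from_smiles",
    "from_edge_list",
    "from_sdf",
    "read_smiles_file",
]


class GraphError(ValueError):
    """Base class for molecular-graph construction errors."""


class InvalidStructureError(GraphError):
    """The chemical input could not be parsed into a molecule."""


class InvalidGraphError(GraphError):
    """The abstract graph input violates simplicity (self-loop / duplicate edge)."""


class DisconnectedGraphError(GraphError):
    """The graph has more than one connected component.

    The descriptors assume a connected graph, so multi-fragment inputs
    (e.g. salts) are a hard error rather than silently reduced to the
    largest fragment.
    """

    def __init__(self, message: str, fragment_sizes: Sequence[int] = ()):  # noqa: D107
        super().__init__(message)
        self.fragment_sizes = tuple(sorted(fragment_sizes, reverse=True))


class DegenerateInputError(GraphError):
    """Fewer than two heavy atoms / vertices."""


class MolecularGraph:
    """Simple, undirected, connected graph of heavy atoms.

    Parameters
    ----------
    edges:
        Iterable of vertex pairs.  Labels may be arbitrary hashables; they are
        remapped to ``0 .. n-1`` (sorted label order for sortable labels,
        insertion order otherwise).
    name:
        Text label carried through to result tables.

    Raises
    ------
    InvalidGraphError
        on self-loops or duplicate edges.
    DisconnectedGraphError
        if the edge set does not span a single component.
    DegenerateInputError
        if fewer than two vertices result.
    """

    def __init__(self, edges: Iterable[tuple[Hashable, Hashable]], name: str = ""):
        edge_list = list(edges)
        seen: set[frozenset] = set()
        for u, v in edge_list:
            if u == v:
                raise InvalidGraphError(f"self-loop at vertex {u!r}")
            key = frozenset((u, v))
            if key in seen:
                raise InvalidGraphError(f"duplicate edge ({u!r}, {v!r})")
            seen.add(key)

        labels = set()
        for u, v in edge_list:
            labels.add(u)
            labels.add(v)
        if len(labels) < 2:
            raise DegenerateInputError("a molecular graph needs at least 2 vertices")
        try:
            ordered = sorted(labels)
        except TypeError:
            ordered = list(labels)
        self._labels: tuple = tuple(ordered)
        index = {lab: i for i, lab in enumerate(ordered)}

        g = nx.Graph()
        g.add_nodes_from(range(len(ordered)))
        g.add_edges_from((index[u], index[v]) for u, v in edge_list)
        if not nx.is_connected(g):
            sizes = [len(c) for c in nx.connected_components(g)]
            raise DisconnectedGraphError(
                f"graph {name!r} is disconnected "
                f"(fragment sizes {sorted(sizes, reverse=True)})",
                fragment_sizes=sizes,
            )
        self._g = g
        self.name = name

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        """Number of vertices (heavy atoms)."""
        return self._g.number_of_nodes()

    @property
    def vertices(self) -> range:
        return range(self.n)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(e)) for e in self._g.edges())

    @property
    def labels(self) -> tuple:
        """Original vertex labels, position i labelling internal vertex i."""
        return self._labels

    def degree(self, v: int) -> int:
        return self._g.degree(v)

    def neighbors(self, v: int) -> list[int]:
        return sorted(self._g.neighbors(v))

    def to_networkx(self) -> nx.Graph:
        """A copy of the underlying :class:`networkx.Graph`."""
        return self._g.copy()

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MolecularGraph(name={self.name!r}, n={self.n}, "
            f"m={self._g.number_of_edges()})"
        )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_smiles(cls, smiles: str, name: str = "") -> "MolecularGraph":
        """Build the hydrogen-suppressed graph of a SMILES string.

        Every heavy atom becomes a vertex and every bond between heavy atoms
        becomes one edge, regardless of bond order or aromaticity.  Explicit
        hydrogens are removed first.
        """
        from rdkit import Chem
        from rdkit import RDLogger

        RDLogger.DisableLog("rdApp.error")
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise InvalidStructureError(f"could not parse SMILES {smiles!r}")
        mol = Chem.RemoveHs(mol)
        frags = Chem.GetMolFrags(mol)
        if len(frags) > 1:
            raise DisconnectedGraphError(
                f"{name or smiles!r} has {len(frags)} fragments "
                f"(sizes {sorted((len(f) for f in frags), reverse=True)}); "
                "salts/mixtures are not supported",
                fragment_sizes=[len(f) for f in frags],
            )
        if mol.GetNumAtoms() < 2:
            raise DegenerateInputError(
                f"{name or smiles!r} has fewer than 2 heavy atoms"
            )
        edges = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
        ]
        return cls(edges, name=name or smiles)

    @classmethod
    def from_edge_list(
        cls, edges: Iterable[tuple[Hashable, Hashable]], name: str = ""
    ) -> "MolecularGraph":
        """Build a graph directly from an abstract edge list."""
        return cls(edges, name=name)

    @classmethod
    def from_sdf(cls, path) -> list["MolecularGraph"]:
        """Read an SDF/MOL file; one graph per readable record.

        Unreadable records are skipped with a logged warning naming the record
        index.  An empty file yields an empty list.
        """
        from rdkit import Chem
        from rdkit import RDLogger

        RDLogger.DisableLog("rdApp.error")
        graphs: list[MolecularGraph] = []
        with open(path) as fh:
            text = fh.read()
        if not text.strip():
            return graphs
        supplier = Chem.SDMolSupplier()
        supplier.SetData(text, sanitize=True, removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("skipping unreadable SDF record %d in %s", i, path)
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record-{i}"
            frags = Chem.GetMolFrags(mol)
            if len(frags) > 1:
                raise DisconnectedGraphError(
                    f"SDF record {i} ({name!r}) has {len(frags)} fragments",
                    fragment_sizes=[len(f) for f in frags],
                )
            if mol.GetNumAtoms() < 2:
                raise DegenerateInputError(
                    f"SDF record {i} ({name!r}) has fewer than 2 heavy atoms"
                )
            edges = [
                (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
            ]
            graphs.append(cls(edges, name=name))
        return graphs


def from_smiles(smiles: str, name: str = "") -> MolecularGraph:
    return MolecularGraph.from_smiles(smiles, name)


def from_edge_list(
    edges: Iterable[tuple[Hashable, Hashable]], name: str = ""
) -> MolecularGraph:
    return MolecularGraph.from_edge_list(edges, name)


def from_sdf(path) -> list[MolecularGraph]:
    return MolecularGraph.from_sdf(path)


def read_smiles_file(path) -> list[MolecularGraph]:
    """Read a ``.smi`` file: one ``SMILES<TAB>name`` per line, ``#`` comments.

    Lines that fail to parse raise; callers that want per-line error recovery
    (the CLI does) should iterate themselves.
    """
    graphs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else smiles
            graphs.append(MolecularGraph.from_smiles(smiles, name))
    return graphs
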