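"""Signature molecular descriptors.

A *signature* of height ``h`` rooted at an atom is a canonical string
encoding of the induced subgraph containing all heavy atoms within graph
distance ``h`` of the root.  Counting occurrences of each distinct
signature over all (root atom, height) pairs yields a sparse,
interpretable substructure-count vector that works well with linear
models for structure-activity modelling.

Canonical form
--------------
Each rooted subgraph is serialized by depth-first traversal:

* atom label: element symbol (lower-cased when aromatic) plus the formal
  charge when nonzero (e.g. ``N+``, ``O-``);
* a back edge to an already visited atom is written ``@k`` where ``k``
  is the DFS visit index of that atom (ring closures);
* each child branch is wrapped in parentheses and prefixed with its bond
  symbol (``-``, ``=``, ``#``, ``:``).

The canonical string is the lexicographic minimum over every possible
DFS serialization of the subgraph.  For acyclic subgraphs this minimum
is computed by a fast bottom-up recursion (sort child serializations);
for cyclic subgraphs a pruned exhaustive search over child orderings is
used.  The same minimum is recovered by the brute-force enumeration used
as an oracle in the test-suite.

Signatures are tagged with their height (``h2:...``) so that identical
subgraph strings arising at different heights remain distinct features.
"""

from __future__ import annotations

import io
import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from rdkit import Chem

logger = logging.getLogger(__name__)

__all__ = [
    "MolecularGraph",
    "SignatureConfig",
    "SignatureVector",
    "SignatureDictionary",
    "SmilesParseError",
    "parse_smiles",
    "atom_signature",
    "featurize",
    "build_dictionary",
    "vectorize",
    "vectorize_many",
    "write_sparse_dataset",
    "read_sparse_dataset",
]

_BOND_SYMBOL = {1.0: "-", 2.0: "=", 3.0: "#", 1.5: ":"}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed.

    Carries the offending string so pipeline callers can skip-and-log.
    """

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom molecular graph (hydrogens implicit).

    ``atoms[i]`` is ``(element, aromatic, formal_charge)``; ``bonds`` are
    ``(i, j, order)`` with order 1.5 denoting an aromatic bond.
    """

    atoms: tuple[tuple[str, bool, int], ...]
    bonds: tuple[tuple[int, int, float], ...]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> list[list[tuple[int, float]]]:
        adj: list[list[tuple[int, float]]] = [[] for _ in self.atoms]
        for i, j, order in self.bonds:
            adj[i].append((j, order))
            adj[j].append((i, order))
        return adj

    def permuted(self, perm: Sequence[int]) -> "MolecularGraph":
        """Graph with atom ``i`` relabelled to ``perm[i]`` (test helper)."""
        inv = [0] * len(perm)
        for old, new in enumerate(perm):
            inv[new] = old
        atoms = tuple(self.atoms[inv[k]] for k in range(self.n_atoms))
        bonds = tuple(
            (min(perm[i], perm[j]), max(perm[i], perm[j]), order)
            for i, j, order in self.bonds
        )
        return MolecularGraph(atoms=atoms, bonds=tuple(sorted(bonds)))


@dataclass(frozen=True)
class SignatureConfig:
    """Which signature heights to generate (default heights 1-3)."""

    heights: frozenset[int] = frozenset({1, 2, 3})

    def __post_init__(self):
        object.__setattr__(self, "heights", frozenset(self.heights))
        if not self.heights:
            raise ValueError("heights must be non-empty")
        if any(h < 0 for h in self.heights):
            raise ValueError("heights must be non-negative")


@dataclass
class SignatureVector:
    """Sparse signature-count representation of one molecule."""

    counts: dict[str, int]
    n_heavy_atoms: int


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom graph with perceived aromaticity."""
    if not smiles:
        raise SmilesParseError(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    atoms = tuple(
        (a.GetSymbol(), a.GetIsAromatic(), a.GetFormalCharge())
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        sorted(
            (
                min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                1.5 if b.GetIsAromatic() else float(b.GetBondTypeAsDouble()),
            )
            for b in mol.GetBonds()
        )
    )
    return MolecularGraph(atoms=atoms, bonds=bonds)


def _atom_label(atom: tuple[str, bool, int]) -> str:
    symbol, aromatic, charge = atom
    label = symbol.lower() if aromatic else symbol
    if charge > 0:
        label += "+" * charge
    elif charge < 0:
        label += "-" * (-charge)
    return label


def _ball(adj: list[list[tuple[int, float]]], root: int, height: int) -> set[int]:
    """Atom indices at graph distance <= height from root (BFS)."""
    seen = {root}
    frontier = deque([(root, 0)])
    while frontier:
        v, d = frontier.popleft()
        if d == height:
            continue
        for u, _ in adj[v]:
            if u not in seen:
                seen.add(u)
                frontier.append((u, d + 1))
    return seen


def _concat_min_sort(branches: list[str]) -> list[str]:
    """Order wrapped branch strings so their concatenation is lexicographically minimal.

    Plain ``sorted`` is wrong when one branch string is a prefix of
    another; the classic pairwise concatenation comparator handles that.
    """
    import functools

    def cmp(a: str, b: str) -> int:
        ab, ba = a + b, b + a
        return -1 if ab < ba else (1 if ab > ba else 0)

    return sorted(branches, key=functools.cmp_to_key(cmp))


def _serialize_tree(
    labels: Mapping[int, str],
    adj: Mapping[int, list[tuple[int, float]]],
    v: int,
    parent: int | None,
) -> str:
    """Canonical serialization of an acyclic rooted subgraph (fast path).

    Every DFS serialization of a fixed subtree has the same length, so
    the minimum is reached by minimizing each branch independently and
    then ordering branches with the concatenation comparator.
    """
    branches = [
        "(" + _BOND_SYMBOL[order] + _serialize_tree(labels, adj, u, v) + ")"
        for u, order in adj[v]
        if u != parent
    ]
    return labels[v] + "".join(_concat_min_sort(branches))


def _min_dfs_cyclic(
    labels: Mapping[int, str],
    adj: Mapping[int, list[tuple[int, float]]],
    root: int,
) -> str:
    """Lexicographically minimal DFS serialization of a cyclic subgraph.

    Exhaustive search over DFS child orderings with prefix pruning.
    Subgraphs are height-limited, so the search space stays small.
    """
    best: str | None = None
    n = len(labels)
    visit: dict[int, int] = {}
    out: list[str] = []

    def finish() -> None:
        nonlocal best
        if len(visit) == n:
            s = "".join(out)
            if best is None or s < best:
                best = s

    def enter(v: int, parent: int | None, cont) -> None:
        nonlocal best
        visit[v] = len(visit)
        back = sorted(visit[u] for u, _ in adj[v] if u != parent and u in visit and u != v)
        out.append(labels[v] + "".join(f"@{k}" for k in back))
        prefix = "".join(out)
        if best is None or prefix <= best[: len(prefix)]:
            expand(v, parent, cont)
        out.pop()
        del visit[v]

    def expand(v: int, parent: int | None, cont) -> None:
        # try every still-unvisited neighbor as the next branch; a sibling
        # absorbed through an earlier branch's ring closure is skipped
        unvisited = [(u, o) for u, o in adj[v] if u != parent and u not in visit]
        if not unvisited:
            cont()
            return
        for u, order in unvisited:
            if u in visit:
                continue
            out.append("(" + _BOND_SYMBOL[order])

            def after_child(v=v, parent=parent, cont=cont):
                out.append(")")
                expand(v, parent, cont)
                out.pop()

            enter(u, v, after_child)
            out.pop()

    enter(root, None, finish)
    assert best is not None
    return best


def _subgraph_is_tree(atom_set: set[int], adj: list[list[tuple[int, float]]]) -> bool:
    n_edges = sum(
        1
        for v in atom_set
        for u, _ in adj[v]
        if u in atom_set and u > v
    )
    return n_edges == len(atom_set) - 1


def atom_signature(
    mol: MolecularGraph, root: int, height: int,
    _adj: list[list[tuple[int, float]]] | None = None,
) -> str:
    """Canonical signature string of the height-limited ball around ``root``.

    The returned string is identical for symmetry-equivalent roots and
    invariant under atom-index permutation.  The height tag is *not*
    included here; :func:`featurize` adds it.
    """
    if not (0 <= root < mol.n_atoms):
        raise IndexError(f"root atom {root} out of range")
    if height < 0:
        raise ValueError("height must be >= 0")
    adj = _adj if _adj is not None else mol.adjacency()
    ball = _ball(adj, root, height)
    labels = {v: _atom_label(mol.atoms[v]) for v in ball}
    sub_adj = {
        v: sorted((u, o) for u, o in adj[v] if u in ball) for v in ball
    }
    if _subgraph_is_tree(ball, adj):
        return _serialize_tree(labels, sub_adj, root, None)
    return _min_dfs_cyclic(labels, sub_adj, root)


def signature_with_height(height: int, body: str) -> str:
    return f"h{height}:{body}"


def featurize(mol: MolecularGraph, config: SignatureConfig = SignatureConfig()) -> SignatureVector:
    """Signature count vector over all (root, height) pairs.

    For every configured height each heavy atom roots exactly one
    signature, so per-height counts always sum to the heavy-atom count.
    """
    adj = mol.adjacency()
    counts: dict[str, int] = {}
    for h in sorted(config.heights):
        for root in range(mol.n_atoms):
            sig = signature_with_height(h, atom_signature(mol, root, h, _adj=adj))
            counts[sig] = counts.get(sig, 0) + 1
    return SignatureVector(counts=counts, n_heavy_atoms=mol.n_atoms)


@dataclass
class SignatureDictionary:
    """Frozen signature-string -> column index mapping.

    Guarantees a stable, contiguous 0-based column layout shared between
    training and prediction time.
    """

    index: dict[str, int] = field(default_factory=dict)
    frozen: bool = False

    def __len__(self) -> int:
        return len(self.index)

    def add(self, signature: str) -> int:
        if self.frozen:
            raise RuntimeError("dictionary is frozen")
        if signature not in self.index:
            self.index[signature] = len(self.index)
        return self.index[signature]

    def freeze(self) -> "SignatureDictionary":
        self.frozen = True
        return self

    def to_tsv(self) -> str:
        lines = []
        for sig, col in sorted(self.index.items(), key=lambda kv: kv[1]):
            tag, _, body = sig.partition(":")
            lines.append(f"{col}\t{tag[1:]}\t{body}")
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_tsv(cls, text: str) -> "SignatureDictionary":
        index: dict[str, int] = {}
        for line in text.splitlines():
            if not line.strip():
                continue
            col_s, height_s, body = line.split("\t")
            index[signature_with_height(int(height_s), body)] = int(col_s)
        cols = sorted(index.values())
        if cols != list(range(len(cols))):
            raise ValueError("dictionary columns are not contiguous")
        return cls(index=index, frozen=True)


def build_dictionary(vectors: Iterable[SignatureVector]) -> SignatureDictionary:
    """Assign a column to every signature seen in ``vectors`` and freeze."""
    vectors = list(vectors)
    if not vectors:
        raise ValueError("cannot build a dictionary from zero vectors")
    d = SignatureDictionary()
    for vec in vectors:
        for sig in vec.counts:
            d.add(sig)
    return d.freeze()


def vectorize(vector: SignatureVector, dictionary: SignatureDictionary) -> sparse.csr_matrix:
    """Map one signature vector onto the dictionary's column space (1 x D row).

    Signatures absent from the dictionary are dropped (the linear model
    has no weight for them); the drop count is logged at debug level.
    """
    return vectorize_many([vector], dictionary)


def vectorize_many(
    vectors: Sequence[SignatureVector], dictionary: SignatureDictionary
) -> sparse.csr_matrix:
    """Stack many signature vectors into an (n x D) CSR matrix."""
    if not dictionary.frozen:
        raise RuntimeError("dictionary must be frozen before vectorizing")
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    dropped = 0
    for vec in vectors:
        row = []
        for sig, cnt in vec.counts.items():
            col = dictionary.index.get(sig)
            if col is None:
                dropped += 1
            else:
                row.append((col, cnt))
        row.sort()
        indices.extend(c for c, _ in row)
        data.extend(v for _, v in row)
        indptr.append(len(indices))
    if dropped:
        logger.debug("dropped %d signatures absent from dictionary", dropped)
    return sparse.csr_matrix(
        (np.asarray(data, dtype=np.float64), np.asarray(indices, dtype=np.int32),
         np.asarray(indptr, dtype=np.int32)),
        shape=(len(vectors), len(dictionary)),
    )


def write_sparse_dataset(
    path, X: sparse.csr_matrix, labels: Sequence[str], dictionary: SignatureDictionary
) -> None:
    """Write a LIBSVM-style sparse text file plus a sidecar dictionary file.

    Row format: ``label col:value ...`` with 1-based column indices.  The
    sidecar (``<path>.dict.tsv``) has one signature per line:
    ``column<TAB>height<TAB>string``.
    """
    path = str(path)
    buf = io.StringIO()
    X = X.tocsr()
    for i, label in enumerate(labels):
        row = X.getrow(i)
        pairs = " ".join(
            f"{col + 1}:{val:g}" for col, val in zip(row.indices, row.data)
        )
        buf.write(f"{label} {pairs}".rstrip() + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
    with open(path + ".dict.tsv", "w") as fh:
        fh.write(dictionary.to_tsv())


def read_sparse_dataset(path) -> tuple[sparse.csr_matrix, list[str], SignatureDictionary]:
    """Round-trip reader for :func:`write_sparse_dataset`."""
    path = str(path)
    with open(path + ".dict.tsv") as fh:
        dictionary = SignatureDictionary.from_tsv(fh.read())
    labels: list[str] = []
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            labels.append(parts[0])
            for pair in parts[1:]:
                col_s, val_s = pair.split(":")
                indices.append(int(col_s) - 1)
                data.append(float(val_s))
            indptr.append(len(indices))
    X = sparse.csr_matrix(
        (np.asarray(data), np.asarray(indices, dtype=np.int32),
         np.asarray(indptr, dtype=np.int32)),
        shape=(len(labels), len(dictionary)),
    )
    return X, labels, dictionary
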