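"""Codon alignments and phylogenies: reading, validation, transformation.

Alignments are in-frame codon matrices (rows = taxa, columns = codon
sites).  Trees are rooted, possibly multifurcating, with stable post-order
branch identifiers and optional foreground marks written in Newick as a
``#k`` suffix on the node bearing the branch (the convention used for
branch labels in codon-model software).
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .genetic_code import is_sense_codon, translate_codon

GAP_CODON = "---"
_DNA = set("ACGT")


class AlignmentError(ValueError):
    """Malformed sequence input (ragged rows, frame, labels, emptiness)."""


class TreeError(ValueError):
    """Malformed tree input or tree/alignment mismatch."""


# ---------------------------------------------------------------------------
# CodonAlignment
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """Aligned in-frame coding sequences over a genetic code.

    ``codons`` is a (n_taxa, n_sites) array of 3-letter strings; cells that
    are not sense codons (gaps, ambiguity codes, stops) are permitted until
    :func:`complete_deletion` is applied.
    """

    taxa: list[str]
    codons: np.ndarray  # dtype <U3, shape (n_taxa, n_sites)
    code: str = "standard"

    def __post_init__(self) -> None:
        self.codons = np.asarray(self.codons, dtype="<U3")
        if self.codons.ndim != 2:
            raise AlignmentError("codon matrix must be 2-D")
        if len(self.taxa) != self.codons.shape[0]:
            raise AlignmentError("taxa count does not match codon matrix rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def site_count(self) -> int:
        return self.codons.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codons[self.taxa.index(taxon)]

    def sequence(self, taxon: str) -> str:
        return "".join(self.row(taxon))

    def nucleotide_rows(self) -> list[str]:
        return ["".join(r) for r in self.codons]

    def is_gap_free(self) -> bool:
        return all(is_sense_codon(c) for c in self.codons.flat)

    def translate(self) -> list[str]:
        """Amino-acid strings per taxon; gaps stay '-', stops '*'."""
        out = []
        for r in self.codons:
            out.append(
                "".join(
                    "-" if set(c) == {"-"} else translate_codon(c) for c in r
                )
            )
        return out

    def subset(self, taxa: list[str]) -> "CodonAlignment":
        idx = [self.taxa.index(t) for t in taxa]
        return CodonAlignment(list(taxa), self.codons[idx].copy(), self.code)


def _split_codons(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def read_codon_fasta(path, frame_check: bool = True) -> CodonAlignment:
    """Read an aligned FASTA of coding sequences as a codon alignment.

    Input order is preserved and lowercase is normalised to uppercase.
    Raises :class:`AlignmentError` on ragged rows, duplicate labels, or
    (with ``frame_check``) a length not divisible by 3.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    taxa = [r.id for r in records]
    if len(set(taxa)) != len(taxa):
        raise AlignmentError("duplicate labels in FASTA input")
    seqs = [str(r.seq).upper() for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
    (length,) = lengths
    if frame_check and length % 3 != 0:
        raise AlignmentError(f"sequence length {length} is not a multiple of 3")
    n_sites = length // 3
    mat = np.array([_split_codons(s[: n_sites * 3]) for s in seqs], dtype="<U3")
    return CodonAlignment(taxa, mat)


def write_codon_fasta(aln: CodonAlignment, path) -> None:
    with open(path, "w") as fh:
        for t, row in zip(aln.taxa, aln.codons):
            fh.write(f">{t}\n{''.join(row)}\n")


def backtranslate(
    protein_alignment: dict[str, str] | list[tuple[str, str]],
    cds: dict[str, str],
) -> CodonAlignment:
    """Thread unaligned coding sequences onto an amino-acid alignment.

    Each amino-acid column becomes one codon column; protein gaps become
    ``---``.  The ungapped translation of each CDS must equal the ungapped
    protein row, otherwise an :class:`AlignmentError` names the taxon and
    1-based residue position of the first mismatch.
    """
    items = (
        list(protein_alignment.items())
        if isinstance(protein_alignment, dict)
        else list(protein_alignment)
    )
    taxa = [t for t, _ in items]
    rows = []
    for taxon, prot in items:
        seq = cds[taxon].upper()
        codons = _split_codons(seq)
        out, k = [], 0
        for col, aa in enumerate(prot.upper()):
            if aa == "-":
                out.append(GAP_CODON)
                continue
            if k >= len(codons):
                raise AlignmentError(
                    f"back-translation error: {taxon} CDS exhausted at residue {col + 1}"
                )
            codon = codons[k]
            if translate_codon(codon) != aa:
                raise AlignmentError(
                    f"back-translation error: {taxon} residue {col + 1} "
                    f"({aa}) does not match codon {codon}"
                )
            out.append(codon)
            k += 1
        if k != len(codons):
            raise AlignmentError(
                f"back-translation error: {taxon} has {len(codons) - k} unused codons"
            )
        rows.append(out)
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise AlignmentError("protein alignment rows have unequal lengths")
    return CodonAlignment(taxa, np.array(rows, dtype="<U3"))


def complete_deletion(aln: CodonAlignment) -> CodonAlignment:
    """Drop every codon column containing a gap, ambiguity code, or stop.

    Ambiguity codes are treated like gaps; stop codons have no state in the
    codon model so columns containing one are removed too.  Idempotent.
    Raises :class:`AlignmentError` when nothing survives.
    """
    keep = np.ones(aln.site_count, dtype=bool)
    for j in range(aln.site_count):
        col = aln.codons[:, j]
        if any(not is_sense_codon(c) for c in col):
            keep[j] = False
    out = aln.codons[:, keep]
    if out.shape[1] == 0:
        raise AlignmentError("complete deletion removed every column")
    return CodonAlignment(list(aln.taxa), out.copy(), aln.code)


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    mark: int = 0  # omega-class mark; 0 = background
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = field(default=None, repr=False)
    branch_id: int = -1  # assigned post-order over non-root nodes

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted phylogeny with stable post-order branch identifiers.

    Every non-root node owns the branch to its parent; branch ids are the
    node's index in a post-order traversal of non-root nodes, so they are
    reproducible for a fixed topology regardless of labels or lengths.
    ``foreground`` is the set of branch ids with a non-zero mark.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._index()

    def _index(self) -> None:
        self._branches: list[TreeNode] = []
        for node in self.postorder():
            node.branch_id = -1
            if node is not self.root:
                node.branch_id = len(self._branches)
                self._branches.append(node)

    # -- traversal ---------------------------------------------------------

    def postorder(self):
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        for node in out:
            for ch in node.children:
                ch.parent = node
        return list(reversed(out))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def taxa(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def branches(self) -> list[TreeNode]:
        return list(self._branches)

    @property
    def n_branches(self) -> int:
        return len(self._branches)

    def branch(self, branch_id: int) -> TreeNode:
        return self._branches[branch_id]

    @property
    def branch_lengths(self) -> np.ndarray:
        return np.array([b.length for b in self._branches])

    def set_branch_lengths(self, lengths) -> None:
        for b, t in zip(self._branches, lengths):
            b.length = float(t)

    @property
    def foreground(self) -> set[int]:
        return {b.branch_id for b in self._branches if b.mark}

    def set_foreground(self, branch_ids, mark: int = 1) -> None:
        for b in self._branches:
            b.mark = mark if b.branch_id in set(branch_ids) else 0

    def subtended_leaves(self, branch_id: int) -> frozenset[str]:
        node = self.branch(branch_id)
        stack, out = [node], []
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.name)
            stack.extend(n.children)
        return frozenset(out)

    def mrca(self, taxa) -> TreeNode:
        want = set(taxa)
        unknown = want - set(self.taxa)
        if unknown:
            raise TreeError(f"taxa not in tree: {sorted(unknown)}")
        below: dict[int, set[str]] = {}
        best = self.root
        for node in self.postorder():
            s = (
                {node.name}
                if node.is_leaf
                else set().union(*(below[id(ch)] for ch in node.children))
            )
            below[id(node)] = s
        # smallest node containing all wanted taxa
        candidates = [
            n for n in self.postorder() if want <= below[id(n)]
        ]
        best = min(candidates, key=lambda n: len(below[id(n)]))
        return best

    def copy(self) -> "PhyloTree":
        def rec(node: TreeNode) -> TreeNode:
            c = TreeNode(node.name, node.length, node.mark)
            c.children = [rec(ch) for ch in node.children]
            return c

        return PhyloTree(rec(self.root))

    # -- Newick ------------------------------------------------------------

    _MARK_RE = re.compile(r"^(.*?)#(\d+)$")

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse types
            raise TreeError(f"Newick parse error: {exc}") from exc

        def convert(dnode) -> TreeNode:
            label = (
                dnode.taxon.label
                if dnode.taxon is not None
                else dnode.label
            )
            mark = 0
            name = label
            if label:
                m = cls._MARK_RE.match(label)
                if m:
                    name, mark = m.group(1) or None, int(m.group(2))
            node = TreeNode(
                name=name,
                length=float(dnode.edge.length or 0.0),
                mark=mark,
            )
            node.children = [convert(ch) for ch in dnode.child_nodes()]
            return node

        tree = cls(convert(dtree.seed_node))
        names = [n.name for n in tree.leaves()]
        if any(n is None for n in names) or len(set(names)) != len(names):
            raise TreeError("leaf labels must be present and unique")
        return tree

    def to_newick(self, lengths: bool = True, precision: int = 10) -> str:
        def rec(node: TreeNode) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(rec(ch) for ch in node.children) + ")"
                if node.name:
                    s += node.name
            if node.mark:
                s += f"#{node.mark}"
            if lengths and node is not self.root:
                s += f":{node.length:.{precision}g}"
            return s

        return rec(self.root) + ";"


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def pair_check(aln: CodonAlignment, tree: PhyloTree) -> None:
    """Require a bijection between tree leaves and alignment taxa."""
    if set(tree.taxa) != set(aln.taxa):
        raise TreeError(
            "tree leaves and alignment taxa differ: "
            f"{sorted(set(tree.taxa) ^ set(aln.taxa))}"
        )


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------


def _pairwise_distance(a: str, b: str, model: str) -> float:
    pairs = [
        (x, y) for x, y in zip(a, b) if x in _DNA and y in _DNA
    ]
    if not pairs:
        raise AlignmentError("no comparable sites between sequences")
    p = sum(x != y for x, y in pairs) / len(pairs)
    if model == "p-distance":
        return p
    if model == "jc":
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0.0:
            raise AlignmentError(
                f"saturated distance (p = {p:.3f}): Jukes-Cantor undefined"
            )
        return -0.75 * math.log(arg)
    raise ValueError(f"unknown distance model {model!r}")


def neighbor_joining(aln: CodonAlignment, distance: str = "p-distance") -> PhyloTree:
    """Neighbor-joining tree from pairwise nucleotide distances.

    Distances are p-distance (default) or Jukes-Cantor corrected; the
    agglomeration is the canonical Q-matrix NJ.  Negative branch lengths
    are clamped to zero.  The result is unrooted in the usual NJ sense,
    represented with a trifurcating (or, for 3 taxa, star) root.
    """
    if aln.n_taxa < 3:
        raise AlignmentError("neighbor joining needs at least 3 taxa")
    rows = aln.nucleotide_rows()
    n = aln.n_taxa
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _pairwise_distance(rows[i], rows[j], distance)
    sk_tree = _skbio_nj(DistanceMatrix(dm, ids=aln.taxa))
    newick = io.StringIO()
    sk_tree.write(newick, format="newick")
    tree = PhyloTree.from_newick(newick.getvalue())
    for b in tree.branches:
        if b.length < 0:
            b.length = 0.0
    return tree
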