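"""Progressive multiple alignment, identity distances and NJ dendrogram.

The promoter comparison runs in the classic Clustal-W style: a fast k-tuple
distance seeds a neighbor-joining guide tree, profiles are merged
progressively up the tree with an affine-gap Gotoh aligner, and the final
alignment yields a percent-identity distance matrix and an NJ dendrogram.

The guide-tree stage only has to be roughly right — the reproducible object
downstream is the profile-HMM refinement, which realigns everything — so
k-tuple word counting (k=4 by default) is used instead of full pairwise DP.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path


import dendropy
import numpy as np
import pandas as pd
from numba import njit

from .errors import InputError

DNA_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
CODE_DNA = "ACGTN-"


def encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    table = np.full(256, 4, dtype=np.int8)  # unknown -> N
    for ch, code in DNA_CODE.items():
        table[ord(ch)] = code
    return table[arr]


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """A rectangular multiple alignment of gapped DNA strings."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise InputError("labels and rows differ in count")
        if len({len(r) for r in self.rows}) > 1:
            raise InputError("alignment rows have unequal lengths")

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def nrow(self) -> int:
        return len(self.rows)

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def to_matrix(self) -> np.ndarray:
        return np.vstack([encode(r) for r in self.rows])

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for lab, row in zip(self.labels, self.rows):
                fh.write(f">{lab}\n")
                for i in range(0, len(row), 70):
                    fh.write(row[i : i + 70] + "\n")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "Alignment":
        from Bio import AlignIO

        aln = AlignIO.read(str(path), "fasta")
        return cls([rec.id for rec in aln], [str(rec.seq).upper() for rec in aln])

    def write_stockholm(self, path: str | Path) -> None:
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import AlignIO

        msa = MultipleSeqAlignment(
            [SeqRecord(Seq(row), id=lab, description="") for lab, row in zip(self.labels, self.rows)]
        )
        AlignIO.write(msa, str(path), "stockholm")

    @classmethod
    def read_stockholm(cls, path: str | Path) -> "Alignment":
        from Bio import AlignIO

        aln = AlignIO.read(str(path), "stockholm")
        return cls([rec.id for rec in aln], [str(rec.seq).upper() for rec in aln])


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def ktuple_distance(a: str, b: str, k: int = 4) -> float:
    """Word-count distance: 1 - shared k-words / min word count.

    Shared counts are multiset intersections, the quick Clustal-W-style
    proxy used only to seed the guide tree.
    """
    if len(a) < k or len(b) < k:
        raise InputError(f"sequences must be at least k={k} long")
    wa = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    wb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    shared = sum((wa & wb).values())
    denom = min(sum(wa.values()), sum(wb.values()))
    return 1.0 - shared / denom


def identity_distance(row_a: str, row_b: str) -> float:
    """1 - fractional identity over mutually ungapped columns.

    Columns where either row has a gap are excluded; if no column is
    comparable the distance is 1.
    """
    if len(row_a) != len(row_b):
        raise InputError("aligned rows differ in length")
    a, b = encode(row_a), encode(row_b)
    both = (a != 5) & (b != 5)
    n = int(both.sum())
    if n == 0:
        return 1.0
    ident = int(((a == b) & both).sum())
    return 1.0 - ident / n


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with labels, values in [0, 1]."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InputError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise InputError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise InputError("distance matrix diagonal must be zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        df.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = [str(x) for x in df.index]
        if [str(c) for c in df.columns] != labels:
            raise InputError("distance TSV must be square with matching row/column labels")
        return cls(labels, df.values.astype(float))


def distance_matrix(aln: Alignment) -> DistanceMatrix:
    """All-pairs identity distance over the alignment."""
    mat = aln.to_matrix()
    n = aln.nrow
    nongap = mat != 5
    values = np.zeros((n, n))
    for i in range(n):
        both = nongap[i] & nongap[i + 1 :]
        comp = both.sum(axis=1)
        ident = ((mat[i] == mat[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(comp > 0, 1.0 - ident / np.maximum(comp, 1), 1.0)
        values[i, i + 1 :] = d
        values[i + 1 :, i] = d
    return DistanceMatrix(list(aln.labels), values)


def count_within(D: DistanceMatrix, reference: str, cutoff_taxon: str) -> int:
    """Number of taxa at distance from ``reference`` <= the distance of
    ``cutoff_taxon`` (the cutoff taxon itself counts)."""
    for lab in (reference, cutoff_taxon):
        if lab not in D.labels:
            raise InputError(f"unknown label {lab!r}")
    cutoff = D[reference, cutoff_taxon]
    i = D.labels.index(reference)
    row = D.values[i]
    return int(sum(1 for j, d in enumerate(row) if j != i and d <= cutoff))


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Standard NJ agglomeration.

    Deterministic: at equal Q the lowest (row, col) index pair is joined.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch so the pair's summed length is preserved.
    """
    n = len(D.labels)
    if n < 3:
        raise InputError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(D.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in D.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)
    d = D.values.astype(float).copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = (np.inf, -1, -1)
        for ai in range(m):
            for aj in range(ai + 1, m):
                if q[ai, aj] < best[0] - 1e-12:
                    best = (q[ai, aj], ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_index = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for ak in active:
            if ak in (i, j):
                continue
            nd = 0.5 * (d[i, ak] + d[j, ak] - dij)
            d[new_index, ak] = d[ak, new_index] = max(nd, 0.0)
        active = [x for x in active if x not in (i, j)] + [new_index]

    # final three-point join
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    root = tree.seed_node
    for node, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.edge.length = max(ln, 0.0)
        root.add_child(node)
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignParams:
    """Clustal-W-like DNA defaults; penalties are positive costs."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = 10.0
    gap_extend: float = 0.2


@njit(cache=True)
def _gotoh_profile(S, gap_open, gap_extend):  # pragma: no cover - jit
    """Global affine-gap DP over a column-pair score matrix S (L1 x L2).

    Returns a traceback matrix: 0 diagonal, 1 up (gap in profile B),
    2 left (gap in profile A).  Ties prefer diagonal, then up, then left.
    """
    L1, L2 = S.shape
    NEG = -1e30
    H = np.full((L1 + 1, L2 + 1), NEG)
    E = np.full((L1 + 1, L2 + 1), NEG)  # gap in A (consume B column)
    F = np.full((L1 + 1, L2 + 1), NEG)  # gap in B (consume A column)
    ptrH = np.zeros((L1 + 1, L2 + 1), dtype=np.int8)
    ptrE = np.zeros((L1 + 1, L2 + 1), dtype=np.int8)  # 1 = from H, 0 = extend
    ptrF = np.zeros((L1 + 1, L2 + 1), dtype=np.int8)
    H[0, 0] = 0.0
    for j in range(1, L2 + 1):
        E[0, j] = -(gap_open + gap_extend * j)
        ptrE[0, j] = 1 if j == 1 else 0
        H[0, j] = E[0, j]
        ptrH[0, j] = 2
    for i in range(1, L1 + 1):
        F[i, 0] = -(gap_open + gap_extend * i)
        ptrF[i, 0] = 1 if i == 1 else 0
        H[i, 0] = F[i, 0]
        ptrH[i, 0] = 1
    for i in range(1, L1 + 1):
        for j in range(1, L2 + 1):
            # E: gap in A ending at (i,j)
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 0
            # F: gap in B ending at (i,j)
            f_open = H[i - 1, j] - gap_open - gap_extend
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 0
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            best = diag
            ptr = 0
            if F[i, j] > best:
                best = F[i, j]
                ptr = 1
            if E[i, j] > best:
                best = E[i, j]
                ptr = 2
            H[i, j] = best
            ptrH[i, j] = ptr
    return H, E, F, ptrH, ptrE, ptrF


def _traceback(S_shape, H, E, F, ptrH, ptrE, ptrF) -> list[tuple[bool, bool]]:
    """Recover the merged column order; each step says whether a column of
    profile A and/or B is consumed."""
    i, j = S_shape
    steps: list[tuple[bool, bool]] = []
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            p = ptrH[i, j]
            if i == 0:
                p = 2
            elif j == 0:
                p = 1
            if p == 0:
                steps.append((True, True))
                i -= 1
                j -= 1
            elif p == 1:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            opened = ptrF[i, j] == 1
            steps.append((True, False))
            i -= 1
            if opened:
                state = "H"
        else:
            opened = ptrE[i, j] == 1
            steps.append((False, True))
            j -= 1
            if opened:
                state = "H"
    steps.reverse()
    return steps


_SUBST = None


def _subst_matrix(params: AlignParams) -> np.ndarray:
    """4x5 substitution table (A,C,G,T) x (A,C,G,T,N); N scores 0."""
    m = np.full((5, 5), params.mismatch)
    np.fill_diagonal(m, params.match)
    m[4, :] = 0.0
    m[:, 4] = 0.0
    return m


class _Profile:
    """Column base-frequency profile of a growing sub-alignment."""

    def __init__(self, labels: list[str], rows: np.ndarray):
        self.labels = labels
        self.rows = rows  # (n, L) int8 codes incl. gap=5

    @classmethod
    def from_seq(cls, label: str, seq: str) -> "_Profile":
        return cls([label], encode(seq)[None, :])

    def freqs(self) -> np.ndarray:
        """(L, 5) frequencies of A,C,G,T,N per column, normalized by row
        count (gaps contribute zero weight)."""
        L = self.rows.shape[1]
        out = np.zeros((L, 5))
        for code in range(5):
            out[:, code] = (self.rows == code).sum(axis=0)
        return out / self.rows.shape[0]


def _merge(pa: _Profile, pb: _Profile, params: AlignParams) -> _Profile:
    subst = _subst_matrix(params)
    fa, fb = pa.freqs(), pb.freqs()
    S = np.ascontiguousarray(fa @ subst @ fb.T)
    H, E, F, ptrH, ptrE, ptrF = _gotoh_profile(S, params.gap_open, params.gap_extend)
    steps = _traceback(S.shape, H, E, F, ptrH, ptrE, ptrF)
    na, nb = pa.rows.shape[0], pb.rows.shape[0]
    L = len(steps)
    merged = np.full((na + nb, L), 5, dtype=np.int8)
    ia = ib = 0
    for col, (use_a, use_b) in enumerate(steps):
        if use_a:
            merged[:na, col] = pa.rows[:, ia]
            ia += 1
        if use_b:
            merged[na:, col] = pb.rows[:, ib]
            ib += 1
    return _Profile(pa.labels + pb.labels, merged)


def guide_tree(seqs: dict[str, str], k: int = 4) -> dendropy.Tree:
    """NJ guide tree from k-tuple distances."""
    labels = list(seqs)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = ktuple_distance(seqs[labels[i]], seqs[labels[j]], k)
    if n == 2:
        tree = dendropy.Tree(taxon_namespace=dendropy.TaxonNamespace(labels))
        for lab in labels:
            node = dendropy.Node(taxon=tree.taxon_namespace.get_taxon(lab))
            node.edge.length = values[0, 1] / 2
            tree.seed_node.add_child(node)
        return tree
    return neighbor_joining(DistanceMatrix(labels, values))


def progressive_align(
    seqs: dict[str, str],
    guide: dendropy.Tree | None = None,
    params: AlignParams | None = None,
) -> Alignment:
    """Profile-profile progressive alignment following guide-tree postorder.

    With exactly two sequences this reduces to a plain global affine-gap
    pairwise alignment under the same scoring.
    """
    if len(seqs) < 2:
        raise InputError("progressive alignment needs at least 2 sequences")
    params = params or AlignParams()
    if guide is None:
        guide = guide_tree(seqs)
    leaf_labels = {leaf.taxon.label for leaf in guide.leaf_node_iter()}
    if leaf_labels != set(seqs):
        raise InputError("guide tree leaf set does not match sequence labels")

    def build(node) -> _Profile:
        if node.is_leaf():
            lab = node.taxon.label
            return _Profile.from_seq(lab, seqs[lab])
        children = node.child_nodes()
        prof = build(children[0])
        for child in children[1:]:
            prof = _merge(prof, build(child), params)
        return prof

    prof = build(guide.seed_node)
    rows = ["".join(CODE_DNA[c] for c in row) for row in prof.rows]
    # restore input ordering
    order = {lab: i for i, lab in enumerate(prof.labels)}
    labels = list(seqs)
    return Alignment(labels, [rows[order[lab]] for lab in labels])
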