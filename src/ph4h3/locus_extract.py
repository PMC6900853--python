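"""Extraction of the bidirectional histone h4.1-h3 intergenic promoter.

In most filamentous fungi the core histone genes *h4.1* and *h3* sit next to
each other on opposite strands, transcribed away from a shared intergenic
region that acts as a bidirectional promoter (Ph4h3).  This module locates
the two genes in an annotated genome by protein homology, verifies the
divergent arrangement, and cuts out the intergenic region between the two
start codons.

Coordinates follow GFF3 conventions (1-based, inclusive) in all public
records; slicing converts to 0-based half-open internally.  The extracted
promoter is always reported in *canonical orientation*: the stored string is
the h3 coding strand of the gap, so position 1 abuts the h4 ATG (the Ph4'
end) and the last position abuts the h3 ATG (the Ph3' end).
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import (
    DegenerateLocusError,
    DifferentContigError,
    HomologNotFoundError,
    InputError,
    InputIOError,
    InterveningGeneError,
    OrientationError,
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene model (CDS span) on a contig."""

    gene_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str
    protein: str | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise InputError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise InputError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class DivergentPair:
    """A verified h4/h3 divergent gene pair sharing an intergenic gap.

    ``gap_start``/``gap_end`` are the 1-based inclusive bounds of the
    intergenic region (exclusive of both CDSs, hence of both ATGs).
    """

    h4: GeneRecord
    h3: GeneRecord
    contig: str
    gap_start: int
    gap_end: int


@dataclass(frozen=True)
class PromoterRegion:
    """An extracted Ph4h3 sequence in canonical orientation."""

    species: str
    sequence: str
    h4_gene_id: str
    h3_gene_id: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self):
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise InputError(f"{self.species}: non-DNA characters in promoter: {sorted(bad)}")


@dataclass(frozen=True)
class HomologHit:
    """Best local alignment of a query protein against a target protein."""

    query_id: str
    target_id: str
    score: float
    aligned_span_query: tuple[int, int]   # 0-based half-open
    aligned_span_target: tuple[int, int]  # 0-based half-open


@dataclass
class HomologSearchResult:
    """Best hit for one query plus any genes tying it above threshold."""

    query_id: str
    best: GeneRecord
    best_hit: HomologHit
    ties: list[GeneRecord] = field(default_factory=list)
    above_threshold: list[GeneRecord] = field(default_factory=list)

    @property
    def multiplicity(self) -> int:
        return len(self.above_threshold)


# ---------------------------------------------------------------------------
# Protein homology search (Smith-Waterman)
# ---------------------------------------------------------------------------

def _blosum62_x_neutral():
    """BLOSUM62 with the X row/column zeroed so unknown residues are
    score-neutral."""
    mat = substitution_matrices.load("BLOSUM62")
    mat = mat.copy()
    alphabet = mat.alphabet
    ix = alphabet.index("X")
    for j in range(len(alphabet)):
        mat[ix, j] = 0.0
        mat[j, ix] = 0.0
    return mat


_BLOSUM62_X0 = _blosum62_x_neutral()


def _make_aligner(matrix=None, gap_open: float = 11.0, gap_extend: float = 1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix if matrix is not None else _BLOSUM62_X0
    # a gap of length g costs gap_open + g * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align_proteins(
    query: str,
    target: str,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    query_id: str = "query",
    target_id: str = "target",
) -> HomologHit:
    """Smith-Waterman local alignment of two protein sequences.

    Scores use BLOSUM62 by default with affine gaps (a gap of length g costs
    ``gap_open + g * gap_extend``).  ``X`` is score-neutral against every
    residue; any other non-standard residue is rejected.
    """
    for name, seq in (("query", query), ("target", target)):
        if not seq:
            raise InputError(f"{name} sequence is empty")
        bad = set(seq.upper()) - AA_ALPHABET - {"X"}
        if bad:
            raise InputError(f"{name} contains unknown residues: {sorted(bad)}")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alns = aligner.align(query.upper(), target.upper())
    best = alns[0]
    qblocks, tblocks = best.aligned
    qspan = (int(qblocks[0][0]), int(qblocks[-1][1]))
    tspan = (int(tblocks[0][0]), int(tblocks[-1][1]))
    return HomologHit(query_id, target_id, float(best.score), qspan, tspan)


def self_score(seq: str, matrix=None, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    return local_align_proteins(seq, seq, matrix, gap_open, gap_extend).score


def find_histone_genes(
    proteome: Iterable[GeneRecord],
    h4_query: str,
    h3_query: str,
    min_score_fraction: float = 0.5,
) -> tuple[HomologSearchResult, HomologSearchResult]:
    """Locate the best h4.1 and h3 homologs in a proteome.

    A gene qualifies when its Smith-Waterman score against the query reaches
    ``min_score_fraction`` of the query self-score.  All qualifying genes are
    reported (histone genes are usually single-copy, but ties and extra
    copies are surfaced to the caller rather than silently broken).
    """
    genes = [g for g in proteome if g.protein]
    if not genes:
        raise InputError("proteome is empty (no gene records with protein sequences)")
    results = []
    for qname, query in (("h4", h4_query), ("h3", h3_query)):
        threshold = min_score_fraction * self_score(query)
        scored: list[tuple[float, GeneRecord, HomologHit]] = []
        for gene in genes:
            hit = local_align_proteins(query, gene.protein, query_id=qname, target_id=gene.gene_id)
            scored.append((hit.score, gene, hit))
        scored.sort(key=lambda t: (-t[0], t[1].gene_id))
        qualifying = [(s, g, h) for s, g, h in scored if s >= threshold]
        if not qualifying:
            raise HomologNotFoundError(
                f"no proteome entry scored >= {threshold:.1f} "
                f"({min_score_fraction:.2f} x self-score) for query {qname!r}"
            )
        best_score, best_gene, best_hit = qualifying[0]
        ties = [g for s, g, _ in qualifying[1:] if s == best_score]
        results.append(
            HomologSearchResult(
                query_id=qname,
                best=best_gene,
                best_hit=best_hit,
                ties=ties,
                above_threshold=[g for _, g, _ in qualifying],
            )
        )
    return results[0], results[1]


# ---------------------------------------------------------------------------
# Divergent-pair verification and promoter extraction
# ---------------------------------------------------------------------------

def verify_divergent(
    h4: GeneRecord,
    h3: GeneRecord,
    all_genes: Iterable[GeneRecord] = (),
) -> DivergentPair:
    """Check that h4 and h3 form a divergent pair around a shared gap.

    Divergent means: same contig, opposite strands, and both genes
    transcribed *away* from the intergenic gap (left gene on '-', right gene
    on '+').  Any third gene overlapping the gap disqualifies the pair.
    """
    if h4.contig != h3.contig:
        raise DifferentContigError(
            f"{h4.gene_id} on {h4.contig} but {h3.gene_id} on {h3.contig}"
        )
    if h4.strand == h3.strand:
        raise OrientationError(
            f"{h4.gene_id} and {h3.gene_id} are on the same strand ({h4.strand})"
        )
    left, right = (h4, h3) if h4.start <= h3.start else (h3, h4)
    if left.strand != "-" or right.strand != "+":
        raise OrientationError(
            f"{left.gene_id}/{right.gene_id} are convergent, not divergent "
            f"(left strand {left.strand}, right strand {right.strand})"
        )
    gap_start, gap_end = left.end + 1, right.start - 1
    for gene in all_genes:
        if gene.gene_id in {h4.gene_id, h3.gene_id} or gene.contig != h4.contig:
            continue
        if gene.start <= gap_end and gene.end >= gap_start:
            raise InterveningGeneError(
                f"gene {gene.gene_id} [{gene.start},{gene.end}] lies inside the "
                f"{left.gene_id}/{right.gene_id} intergenic gap [{gap_start},{gap_end}]"
            )
    return DivergentPair(h4=h4, h3=h3, contig=h4.contig, gap_start=gap_start, gap_end=gap_end)


def extract_promoter(
    pair: DivergentPair,
    genome: Mapping[str, str],
    species: str = "unknown",
) -> PromoterRegion:
    """Extract the intergenic Ph4h3 region in canonical orientation.

    The promoter is the gap between the two CDSs, so both ATGs are excluded.
    The stored string is the h3 coding strand: if h3 is the right-hand
    ('+' strand) gene the genomic slice is kept as-is, otherwise it is
    reverse-complemented so the Ph4' end always comes first.
    """
    if pair.gap_end < pair.gap_start:
        raise DegenerateLocusError(
            f"{pair.h4.gene_id}/{pair.h3.gene_id}: empty intergenic gap "
            f"(start codons overlap or abut)"
        )
    try:
        contig_seq = genome[pair.contig]
    except KeyError:
        raise InputIOError(f"contig {pair.contig!r} not found in genome") from None
    if pair.gap_end > len(contig_seq):
        raise InputError(
            f"gap end {pair.gap_end} beyond contig {pair.contig} length {len(contig_seq)}"
        )
    raw = str(contig_seq[pair.gap_start - 1 : pair.gap_end]).upper()
    if pair.h3.strand == "-":
        raw = reverse_complement(raw)
    return PromoterRegion(
        species=species,
        sequence=raw,
        h4_gene_id=pair.h4.gene_id,
        h3_gene_id=pair.h3.gene_id,
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into a contig -> sequence dict."""
    path = Path(path)
    if not path.exists():
        raise InputIOError(f"genome FASTA not found: {path}")
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_proteome(path: str | Path) -> dict[str, str]:
    """Read a proteome FASTA keyed by gene ID."""
    path = Path(path)
    if not path.exists():
        raise InputIOError(f"proteome FASTA not found: {path}")
    return {rec.id: str(rec.seq).upper().rstrip("*") for rec in SeqIO.parse(str(path), "fasta")}


def read_gff(path: str | Path, proteome: Mapping[str, str] | None = None) -> list[GeneRecord]:
    """Parse gene models from a GFF3 file.

    Each ``gene`` feature becomes one :class:`GeneRecord` whose span is the
    CDS span in translation order (the promoter is defined between ATGs, so
    the CDS start, not the mRNA start, is the anchor).  Genes without CDS
    children fall back to the gene bounds.  Proteins are attached by gene ID
    when a proteome mapping is supplied.
    """
    path = Path(path)
    if not path.exists():
        raise InputIOError(f"GFF3 file not found: {path}")
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    records: list[GeneRecord] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        cds = list(db.children(gene, featuretype="CDS", order_by="start"))
        if cds:
            start = min(c.start for c in cds)
            end = max(c.end for c in cds)
        else:
            start, end = gene.start, gene.end
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        protein = proteome.get(gene_id) if proteome else None
        records.append(
            GeneRecord(
                gene_id=gene_id,
                contig=gene.seqid,
                start=start,
                end=end,
                strand=gene.strand,
                protein=protein,
            )
        )
    return records


def write_promoters_fasta(promoters: Sequence[PromoterRegion], path: str | Path) -> None:
    """Write promoters as FASTA with ``species|h4_id|h3_id|length`` headers."""
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(f">{p.species}|{p.h4_gene_id}|{p.h3_gene_id}|{p.length}\n")
            for i in range(0, p.length, 70):
                fh.write(p.sequence[i : i + 70] + "\n")


def read_promoters_fasta(path: str | Path) -> list[PromoterRegion]:
    """Read a promoter set written by :func:`write_promoters_fasta` (or any
    promoter table FASTA whose headers start with the species name)."""
    path = Path(path)
    if not path.exists():
        raise InputIOError(f"promoter FASTA not found: {path}")
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        species = parts[0]
        h4_id = parts[1] if len(parts) > 2 else "h4"
        h3_id = parts[2] if len(parts) > 2 else "h3"
        region = PromoterRegion(
            species=species,
            sequence=str(rec.seq).upper(),
            h4_gene_id=h4_id,
            h3_gene_id=h3_id,
        )
        if len(parts) > 3 and parts[3].isdigit() and int(parts[3]) != region.length:
            raise InputError(
                f"{species}: header length {parts[3]} != sequence length {region.length}"
            )
        out.append(region)
    return out


def write_manifest(
    promoters: Sequence[PromoterRegion],
    path: str | Path,
    multiplicity: Mapping[str, tuple[int, int]] | None = None,
) -> None:
    """Write a TSV manifest (one row per promoter, with homolog multiplicity
    warnings when available)."""
    with open(path, "w") as fh:
        fh.write("species\th4_gene_id\th3_gene_id\tlength\th4_multiplicity\th3_multiplicity\n")
        for p in promoters:
            m4, m3 = (multiplicity or {}).get(p.species, (1, 1))
            fh.write(f"{p.species}\t{p.h4_gene_id}\t{p.h3_gene_id}\t{p.length}\t{m4}\t{m3}\n")
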