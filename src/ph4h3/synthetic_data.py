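"""Synthetic study-scale inputs: an evolved promoter family with planted
motif architecture, flanking divergent histone-like gene models, and
machine-readable truth tables.

The generator emulates the structure of the real promoter family: ~85
sequences of roughly 800 bp descending from a common ancestor along a Yule
tree, Jukes-Cantor substitutions plus geometric-length indels, elevated
conservation in the windows 100-200 nt in from each promoter end, and
mirror-paired motif occurrences near both ends (two Spt10-style sites per
end, opposite orientations, the outermost 51 and 58 nt from the respective
end, pair gaps of 63 and 59 nt).  Indels are redrawn if they would touch a
planted motif or a conserved block, so motif truth coordinates stay exact
up to shifts, which are tracked.

Everything is deterministic under a fixed seed, down to the emitted bytes.
All protein and motif fixtures are synthetic look-alikes constructed for
testing; no real database records are shipped.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .architecture import PH3, PH4
from .errors import InputError
from .motif_scan import PFM, load_bundled_motifs
from .locus_extract import reverse_complement

BASES = "ACGT"

# Synthetic histone-like protein seeds (look-alikes, not database records).
H4_SEED = (
    "MSGRGKGGKGLGKGGAKRHRKILRDNIQGITKPAIRRLARRGGVKRISGLIYEETRGVLK"
    "SFLESVIRDSVTYTEHAKRKTVTSLDVVYALKRQGRTLYGFGG"
)
H3_SEED = (
    "MARTKQTARKSTGGKAPRKQLASKAARKSAPSTGGVKKPHRYKPGTVALREIRRFQKSTE"
    "LLIRKLPFQRLVREIAQDFKSDLRFQSSAIGALQESVEAYLVSLFEDTNLAAIHAKRVTI"
    "QKKDIKLARRLRGERS"
)
AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ConservedBlock:
    """End-relative window with a reduced substitution rate."""

    end: str            # PH4 or PH3
    offset_start: int   # nt in from the end (inclusive)
    offset_end: int     # nt in from the end (exclusive)
    rate_multiplier: float = 0.1


@dataclass(frozen=True)
class PlantedMotif:
    """A PWM-sampled occurrence anchored a fixed distance from one end.

    ``end_offset`` is the number of nucleotides between the promoter
    terminus and the motif's outer edge.
    """

    pfm: PFM
    end: str
    end_offset: int
    strand: str


def default_planted_motifs() -> list[PlantedMotif]:
    """The mirror quartet: two Spt10-style sites per end in opposite
    orientations; outermost sites 51 and 58 nt from the ends, pair gaps of
    63 and 59 nt."""
    spt10 = next(m for m in load_bundled_motifs() if m.motif_id == "spt10_like")
    w = spt10.width
    return [
        PlantedMotif(spt10, PH4, 51, "-"),
        PlantedMotif(spt10, PH4, 51 + w + 63, "+"),
        PlantedMotif(spt10, PH3, 58, "+"),
        PlantedMotif(spt10, PH3, 58 + w + 59, "-"),
    ]


@dataclass
class SimulationConfig:
    n_species: int = 85
    root_length: int = 800
    conserved_blocks: list[ConservedBlock] = field(
        default_factory=lambda: [
            ConservedBlock(PH4, 100, 200, 0.1),
            ConservedBlock(PH3, 100, 200, 0.1),
        ]
    )
    planted_motifs: list[PlantedMotif] = field(default_factory=default_planted_motifs)
    tree_birth_rate: float = 1.0
    tree_height: float = 0.15       # expected substitutions/site, root to leaf
    indel_rate: float = 0.005       # events per site per unit branch length
    indel_mean_len: float = 3.0     # geometric mean indel length
    seed: int = 0

    def block_spans(self) -> list[tuple[int, int, float]]:
        """Absolute 0-based half-open spans of the conserved blocks."""
        spans = []
        for b in self.conserved_blocks:
            if b.end == PH4:
                spans.append((b.offset_start, b.offset_end, b.rate_multiplier))
            else:
                spans.append(
                    (self.root_length - b.offset_end, self.root_length - b.offset_start, b.rate_multiplier)
                )
        spans.sort()
        for (s1, e1, _), (s2, e2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise InputError("conserved blocks overlap")
        return spans

    def motif_spans(self) -> list[tuple[int, int, PlantedMotif]]:
        """Absolute 0-based half-open spans of the planted motifs."""
        spans = []
        for m in self.planted_motifs:
            w = m.pfm.width
            if m.end == PH4:
                start = m.end_offset
            else:
                start = self.root_length - m.end_offset - w
            if start < 0 or start + w > self.root_length:
                raise InputError(f"planted motif at offset {m.end_offset} outside root sequence")
            spans.append((start, start + w, m))
        return sorted(spans, key=lambda t: t[0])

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Read scalar parameters from a plain key: value (YAML) file;
        blocks and motifs keep their defaults."""
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        scalars = {
            k: v
            for k, v in data.items()
            if k in {"n_species", "root_length", "tree_birth_rate", "tree_height",
                     "indel_rate", "indel_mean_len", "seed"}
        }
        return cls(**scalars)


# ---------------------------------------------------------------------------
# Truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class MotifTruth:
    motif_id: str
    start: int   # 1-based on the canonical promoter strand
    strand: str
    width: int


@dataclass
class SpeciesTruth:
    promoter: str
    motifs: list[MotifTruth]
    contig: str = ""
    gap_start: int = 0  # 1-based inclusive genome coordinates of the promoter
    gap_end: int = 0


@dataclass
class TruthTable:
    tree_newick: str
    root_sequence: str
    species: dict[str, SpeciesTruth]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("species\tkind\tvalue\tstart\tstrand\twidth\n")
            for sp in sorted(self.species):
                t = self.species[sp]
                fh.write(f"{sp}\tpromoter_coords\t{t.contig}\t{t.gap_start}\t+\t{len(t.promoter)}\n")
                for m in t.motifs:
                    fh.write(f"{sp}\tmotif\t{m.motif_id}\t{m.start}\t{m.strand}\t{m.width}\n")


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(n: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree with n leaves labelled sp001..spNNN."""
    if n < 2:
        raise InputError("need at least 2 species")
    labels = [f"sp{i + 1:03d}" for i in range(n)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n,
        taxon_namespace=taxa,
        rng=random.Random(seed),
    )
    return tree


def scale_tree_height(tree: dendropy.Tree, height: float) -> dendropy.Tree:
    """Scale branch lengths so the maximum root-to-leaf path equals
    ``height`` (expected substitutions per site)."""
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    top = max(depths)
    if top <= 0:
        raise InputError("tree has zero height")
    factor = height / top
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _sample_motif(pfm: PFM, strand: str, rng: np.random.Generator) -> str:
    probs = pfm.counts / pfm.counts.sum(axis=0, keepdims=True)
    site = "".join(BASES[rng.choice(4, p=probs[:, j])] for j in range(pfm.width))
    return reverse_complement(site) if strand == "-" else site


@dataclass
class _NodeState:
    seq: list[str]
    motif_spans: list[tuple[int, int, PlantedMotif]]   # 0-based half-open
    block_spans: list[tuple[int, int, float]]


def _protected(state: _NodeState, pos: int, span: int = 0) -> bool:
    for s, e, _ in state.motif_spans:
        if pos < e and pos + max(span, 1) > s:
            return True
    for s, e, _ in state.block_spans:
        if pos < e and pos + max(span, 1) > s:
            return True
    return False


def _shift(spans, pos, delta):
    out = []
    for s, e, payload in spans:
        if s >= pos:
            out.append((s + delta, e + delta, payload))
        else:
            out.append((s, e, payload))
    return out


def _evolve_branch(state: _NodeState, length: float, cfg: SimulationConfig,
                   rng: np.random.Generator) -> _NodeState:
    seq = list(state.seq)
    motif_spans = list(state.motif_spans)
    block_spans = list(state.block_spans)
    L = len(seq)
    if length > 0:
        p_sub = 0.75 * (1.0 - np.exp(-4.0 * length / 3.0))
        mult = np.ones(L)
        for s, e, m in block_spans:
            mult[s:e] = m
        for s, e, _ in motif_spans:
            mult[s:e] = 0.0  # motifs are re-sampled from their PFMs instead
        hit = rng.random(L) < p_sub * mult
        for i in np.flatnonzero(hit):
            alternatives = [b for b in BASES if b != seq[i]]
            seq[i] = alternatives[rng.integers(3)]
        # indels
        n_events = rng.poisson(cfg.indel_rate * length * L)
        for _ in range(n_events):
            for _attempt in range(200):
                size = int(rng.geometric(1.0 / cfg.indel_mean_len))
                insertion = bool(rng.integers(2))
                pos = int(rng.integers(1, len(seq)))  # never at the very ends
                span = 0 if insertion else size
                probe = _NodeState(seq, motif_spans, block_spans)
                if pos + span <= len(seq) and not _protected(probe, pos, span):
                    break
            else:
                continue
            if insertion:
                fragment = [BASES[b] for b in rng.integers(0, 4, size)]
                seq[pos:pos] = fragment
                motif_spans = _shift(motif_spans, pos, size)
                block_spans = _shift(block_spans, pos, size)
            else:
                del seq[pos : pos + span]
                motif_spans = _shift(motif_spans, pos + span, -span)
                block_spans = _shift(block_spans, pos + span, -span)
    return _NodeState(seq, motif_spans, block_spans)


def evolve_promoters(
    root: str,
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], TruthTable]:
    """Evolve the root promoter down the tree; returns leaf sequences and
    the truth table (leaf motif coordinates after indel shifts)."""
    rng = rng or np.random.default_rng(config.seed)
    config.block_spans()  # validates overlap
    root_state = _NodeState(list(root), config.motif_spans(), config.block_spans())
    leaf_states: dict[str, _NodeState] = {}

    def recurse(node, state: _NodeState):
        for child in node.child_nodes():
            child_state = _evolve_branch(state, child.edge.length or 0.0, config, rng)
            if child.is_leaf():
                leaf_states[child.taxon.label] = child_state
            else:
                recurse(child, child_state)

    recurse(tree.seed_node, root_state)
    promoters: dict[str, str] = {}
    species: dict[str, SpeciesTruth] = {}
    for label in sorted(leaf_states):
        state = leaf_states[label]
        seq = list(state.seq)
        motifs = []
        for s, e, planted in state.motif_spans:
            site = _sample_motif(planted.pfm, planted.strand, rng)
            seq[s:e] = list(site)
            motifs.append(
                MotifTruth(planted.pfm.motif_id, s + 1, planted.strand, planted.pfm.width)
            )
        promoters[label] = "".join(seq)
        species[label] = SpeciesTruth(promoter=promoters[label], motifs=motifs)
    truth = TruthTable(
        tree_newick=tree.as_string(schema="newick").strip(),
        root_sequence=root,
        species=species,
    )
    return promoters, truth


def random_root(config: SimulationConfig, rng: np.random.Generator) -> str:
    seq = [BASES[b] for b in rng.integers(0, 4, config.root_length)]
    for s, e, planted in config.motif_spans():
        seq[s:e] = list(_sample_motif(planted.pfm, planted.strand, rng))
    return "".join(seq)


# ---------------------------------------------------------------------------
# Genome emission
# ---------------------------------------------------------------------------

def _mutate_protein(protein: str, n_subs: int, rng: np.random.Generator) -> str:
    prot = list(protein)
    positions = rng.choice(len(prot) - 1, size=n_subs, replace=False) + 1  # keep Met1
    for p in positions:
        alternatives = [a for a in AA if a != prot[p]]
        prot[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(prot)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(BASES[b] for b in rng.integers(0, 4, n))


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    tree: dendropy.Tree
    promoters: dict[str, str]
    truth: TruthTable
    genomes: dict[str, str]                   # contig -> sequence
    gff_lines: list[str]
    proteome: dict[str, str]                  # gene_id -> protein
    h4_query: str = H4_SEED
    h3_query: str = H3_SEED


def emit_genomes(
    promoters: dict[str, str],
    truth: TruthTable,
    rng: np.random.Generator,
    flank: int = 500,
) -> tuple[dict[str, str], list[str], dict[str, str]]:
    """Embed each promoter between a leftward h4-like and rightward h3-like
    gene with random flanks and decoy genes; returns (genomes, GFF3 lines,
    proteome)."""
    genomes: dict[str, str] = {}
    proteome: dict[str, str] = {}
    gff = ["##gff-version 3"]
    for sp in sorted(promoters):
        prom = promoters[sp]
        contig = f"{sp}_contig"
        h4_prot = _mutate_protein(H4_SEED, 2, rng)
        h3_prot = _mutate_protein(H3_SEED, 2, rng)
        decoy_prot = "M" + "".join(AA[i] for i in rng.integers(0, len(AA), 149))
        h4_len = 3 * len(h4_prot)
        h3_len = 3 * len(h3_prot)
        left = _random_dna(flank, rng)
        right = _random_dna(flank, rng)
        h4_cds = _random_dna(h4_len - 3, rng) + "CAT"  # '-' strand gene ends ...CAT = revcomp ATG
        h3_cds = "ATG" + _random_dna(h3_len - 3, rng)
        genome = left + h4_cds + prom + h3_cds + right
        genomes[contig] = genome
        h4_start, h4_end = flank + 1, flank + h4_len
        gap_start, gap_end = h4_end + 1, h4_end + len(prom)
        h3_start, h3_end = gap_end + 1, gap_end + h3_len
        decoy_start = 50
        decoy_end = decoy_start + 3 * 150 - 1
        entries = [
            (f"{sp}_h4", h4_start, h4_end, "-", h4_prot),
            (f"{sp}_h3", h3_start, h3_end, "+", h3_prot),
            (f"{sp}_decoy1", decoy_start, decoy_end, "+", decoy_prot),
        ]
        for gene_id, start, end, strand, prot in entries:
            gff.append(f"{contig}\tsynth\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene_id}")
            gff.append(
                f"{contig}\tsynth\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gene_id}.t1;Parent={gene_id}"
            )
            gff.append(
                f"{contig}\tsynth\tCDS\t{start}\t{end}\t.\t{strand}\t0\t"
                f"ID={gene_id}.cds;Parent={gene_id}.t1"
            )
            proteome[gene_id] = prot
        t = truth.species[sp]
        t.contig = contig
        t.gap_start = gap_start
        t.gap_end = gap_end
    return genomes, gff, proteome


def generate(config: SimulationConfig) -> SyntheticBundle:
    """Full deterministic bundle: tree, promoters, genomes, truth."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_species, config.tree_birth_rate, config.seed)
    scale_tree_height(tree, config.tree_height)
    root = random_root(config, rng)
    promoters, truth = evolve_promoters(root, tree, config, rng)
    genomes, gff, proteome = emit_genomes(promoters, truth, rng)
    return SyntheticBundle(
        config=config,
        tree=tree,
        promoters=promoters,
        truth=truth,
        genomes=genomes,
        gff_lines=gff,
        proteome=proteome,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fasta", "w") as fh:
        for contig in sorted(bundle.genomes):
            fh.write(f">{contig}\n")
            seq = bundle.genomes[contig]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    (outdir / "annotation.gff3").write_text("\n".join(bundle.gff_lines) + "\n")
    with open(outdir / "proteome.faa", "w") as fh:
        for gene_id in sorted(bundle.proteome):
            fh.write(f">{gene_id}\n{bundle.proteome[gene_id]}\n")
    with open(outdir / "promoters.fasta", "w") as fh:
        for sp in sorted(bundle.promoters):
            fh.write(f">{sp}|{sp}_h4|{sp}_h3|{len(bundle.promoters[sp])}\n")
            seq = bundle.promoters[sp]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    (outdir / "tree.nwk").write_text(bundle.truth.tree_newick + "\n")
    bundle.truth.write_tsv(outdir / "truth.tsv")
    with open(outdir / "queries.faa", "w") as fh:
        fh.write(f">h4_query\n{bundle.h4_query}\n>h3_query\n{bundle.h3_query}\n")
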