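"""Command-line pipeline: simulate / extract / align / refine / scan /
architecture / full.

Each stage reads the previous stage's standard files so stages are
independently testable; ``full`` chains them in-process.  Every run writes
its resolved configuration (YAML) next to its outputs and logs to stderr
plus ``run.log``.  Exit codes: 0 ok, 2 validation, 3 I/O, 4 non-convergence
escalated by ``--strict``.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import warnings
from dataclasses import dataclass
from pathlib import Path

import click
import numpy as np
import yaml

from . import architecture as arch
from . import locus_extract as lx
from . import motif_scan as ms
from . import msa_phylo as mp
from . import profile_hmm as ph
from . import synthetic_data as sd
from .errors import (
    ConvergenceWarning,
    InputError,
    InputIOError,
    Ph4h3Error,
    ValidationError,
)

logger = logging.getLogger("ph4h3")


@dataclass
class PipelineConfig:
    """Resolved parameters of a pipeline run; written alongside outputs."""

    ktuple_k: int = 4
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = 10.0
    gap_extend: float = 0.2
    gap_threshold: float = 0.5
    pseudocount: float = 1.0
    transition_pseudocount: float = 0.1
    minl: float = 0.25
    minu: float = 0.5
    scan_threshold: float = 9.0
    conserved_window: int = 25
    conserved_min_ic: float = 1.25
    background: tuple = (0.25, 0.25, 0.25, 0.25)
    pwm_pseudo: float = 0.8
    max_iter: int = 50
    seed: int = 0
    min_score_fraction: float = 0.5
    take_best: bool = False

    def dump(self, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _setup_logging(outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(outdir / "run.log")):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def load_promoter_table(path: str | Path) -> list[lx.PromoterRegion]:
    """Load a ready-made promoter table (FASTA dialect of the extraction
    output); lengths in headers are validated against the sequences."""
    return lx.read_promoters_fasta(path)


# ---------------------------------------------------------------------------
# Stage implementations (plain functions, CLI wraps them)
# ---------------------------------------------------------------------------

def run_extract(
    genome_path: str | Path,
    gff_path: str | Path,
    proteome_path: str | Path,
    queries_path: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> list[lx.PromoterRegion]:
    """Per-contig homolog search, divergence check and promoter extraction."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = lx.read_genome(genome_path)
    proteome = lx.read_proteome(proteome_path)
    queries = lx.read_proteome(queries_path)
    try:
        h4_query = next(v for k, v in queries.items() if "h4" in k.lower())
        h3_query = next(v for k, v in queries.items() if "h3" in k.lower())
    except StopIteration:
        raise InputError("query FASTA must contain records with 'h4' and 'h3' in their ids")
    genes = lx.read_gff(gff_path, proteome)
    by_contig: dict[str, list[lx.GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    promoters = []
    multiplicity = {}
    for contig in sorted(by_contig):
        species = contig.removesuffix("_contig")
        contig_genes = by_contig[contig]
        r4, r3 = lx.find_histone_genes(
            contig_genes, h4_query, h3_query, config.min_score_fraction
        )
        for r in (r4, r3):
            if r.multiplicity > 1 and not config.take_best:
                raise ValidationError(
                    f"{species}: {r.multiplicity} candidate {r.query_id} genes above "
                    f"threshold; rerun with --take-best to accept the top scorer"
                )
        pair = lx.verify_divergent(r4.best, r3.best, contig_genes)
        region = lx.extract_promoter(pair, genome, species=species)
        promoters.append(region)
        multiplicity[species] = (r4.multiplicity, r3.multiplicity)
        logger.info("extracted %s: %d nt (%s/%s)", species, region.length,
                    r4.best.gene_id, r3.best.gene_id)
    lx.write_promoters_fasta(promoters, outdir / "promoters.fasta")
    lx.write_manifest(promoters, outdir / "manifest.tsv", multiplicity)
    config.dump(outdir)
    return promoters


def run_align(promoters: list[lx.PromoterRegion], outdir: str | Path,
              config: PipelineConfig | None = None) -> tuple[mp.Alignment, mp.DistanceMatrix]:
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqs = {p.species: p.sequence for p in promoters}
    if len(seqs) < 2:
        raise InputError("alignment needs at least 2 promoter sequences")
    params = mp.AlignParams(config.match, config.mismatch, config.gap_open, config.gap_extend)
    guide = mp.guide_tree(seqs, k=config.ktuple_k)
    aln = mp.progressive_align(seqs, guide, params)
    aln.write_fasta(outdir / "msa.fasta")
    D = mp.distance_matrix(aln)
    D.to_tsv(outdir / "distances.tsv")
    if len(seqs) >= 3:
        tree = mp.neighbor_joining(D)
        mp.write_newick(tree, outdir / "dendrogram.nwk")
    config.dump(outdir)
    logger.info("aligned %d sequences, %d columns", aln.nrow, aln.ncol)
    return aln, D


def run_refine(promoters: list[lx.PromoterRegion], initial_aln: mp.Alignment | None,
               outdir: str | Path, config: PipelineConfig | None = None) -> ph.RefineResult:
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqs = {p.species: p.sequence for p in promoters}
    result = ph.refine(
        seqs,
        initial_aln=initial_aln,
        max_iter=config.max_iter,
        gap_threshold=config.gap_threshold,
        pseudocount=config.pseudocount,
        transition_pseudocount=config.transition_pseudocount,
        minl=config.minl,
        minu=config.minu,
    )
    for it, m in result.history:
        logger.info("refine iteration %d: %d match states", it, m)
    logger.info(
        "consensus %s after %d iterations (%d positions)",
        "converged" if result.converged else "NOT converged",
        result.iterations,
        result.hmm.M,
    )
    ph.write_model(result.hmm, outdir / "model.txt")
    ph.write_consensus_fasta(result.consensus, outdir / "consensus.fasta")
    ph.write_ic_tsv(result.hmm, outdir / "ic.tsv")
    config.dump(outdir)
    return result


def run_scan(sequence: str, pfms: list[ms.PFM], outdir: str | Path,
             config: PipelineConfig | None = None) -> list[ms.MotifHit]:
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pwms = [ms.pfm_to_pwm(p, config.background, config.pwm_pseudo) for p in pfms]
    hits = ms.scan_many(sequence.upper(), pwms, config.scan_threshold)
    ms.write_hits_tsv(hits, outdir / "hits.tsv")
    ms.write_hits_bed(hits, outdir / "hits.bed")
    config.dump(outdir)
    logger.info("%d motif hits above %.1f bits", len(hits), config.scan_threshold)
    return hits


def run_architecture(sequence: str, hits: list[ms.MotifHit], ic: np.ndarray | None,
                     outdir: str | Path, config: PipelineConfig | None = None) -> dict:
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotated = arch.annotate_ends(hits, len(sequence))
    pairs = arch.find_mirror_pairs(annotated)
    overlaps = arch.find_overlaps(hits)
    arch.write_architecture_tsv(annotated, pairs, overlaps, outdir / "architecture.tsv")
    summary = arch.summarize(annotated, pairs, len(sequence))
    regions = []
    if ic is not None and len(ic) >= config.conserved_window:
        regions = arch.conserved_regions(ic, config.conserved_window, config.conserved_min_ic)
        summary += "Conserved IC regions (end-relative):\n"
        for r in regions:
            summary += (
                f"  [{r.start},{r.end}] mean {r.mean_ic:.2f} bits; "
                f"Ph4' {r.ph4_relative}, Ph3' {r.ph3_relative}\n"
            )
    (outdir / "summary.txt").write_text(summary)
    return {"annotated": annotated, "pairs": pairs, "overlaps": overlaps, "regions": regions}


def run_full(promoters: list[lx.PromoterRegion], pfms: list[ms.PFM],
             outdir: str | Path, config: PipelineConfig | None = None) -> dict:
    """MSA + distances + dendrogram + refined HMM consensus + motif scan +
    architecture report, all from a promoter set."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    aln, D = run_align(promoters, outdir, config)
    result = run_refine(promoters, aln, outdir, config)
    consensus_upper = result.consensus.upper().replace("N", "N")
    hits = run_scan(consensus_upper, pfms, outdir, config)
    report = run_architecture(consensus_upper, hits, ph.information_content(result.hmm),
                              outdir, config)
    return {
        "alignment": aln,
        "distances": D,
        "refine": result,
        "hits": hits,
        **report,
    }


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _common(func):
    func = click.option("--out", "outdir", required=True, type=click.Path())(func)
    func = click.option("--seed", default=0, show_default=True)(func)
    return func


@click.group()
def cli():
    """Bidirectional histone-promoter comparative analysis."""


@cli.command()
@_common
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--n-species", default=None, type=int)
@click.option("--root-length", default=None, type=int)
def simulate(outdir, seed, config_path, n_species, root_length):
    """Generate a synthetic genome/annotation/proteome bundle with truth."""
    cfg = sd.SimulationConfig.from_file(config_path) if config_path else sd.SimulationConfig()
    cfg.seed = seed
    if n_species:
        cfg.n_species = n_species
    if root_length:
        cfg.root_length = root_length
    bundle = sd.generate(cfg)
    sd.write_bundle(bundle, outdir)
    click.echo(f"wrote synthetic bundle for {cfg.n_species} species to {outdir}")


@cli.command()
@_common
@click.option("--genome", type=click.Path())
@click.option("--gff", type=click.Path())
@click.option("--proteome", type=click.Path())
@click.option("--queries", type=click.Path())
@click.option("--promoter-table", type=click.Path(),
              help="Ready-made promoter FASTA; skips extraction.")
@click.option("--take-best", is_flag=True)
def extract(outdir, seed, genome, gff, proteome, queries, promoter_table, take_best):
    """Extract promoters from genome+GFF3+proteome, or validate a table."""
    outdir = Path(outdir)
    _setup_logging(outdir)
    config = PipelineConfig(seed=seed, take_best=take_best)
    if promoter_table:
        promoters = load_promoter_table(promoter_table)
        lx.write_promoters_fasta(promoters, outdir / "promoters.fasta")
        lx.write_manifest(promoters, outdir / "manifest.tsv")
        config.dump(outdir)
        click.echo(f"validated and passed through {len(promoters)} promoters")
        return
    if not (genome and gff and proteome and queries):
        raise InputIOError("--genome, --gff, --proteome and --queries are all required")
    promoters = run_extract(genome, gff, proteome, queries, outdir, config)
    click.echo(f"extracted {len(promoters)} promoters")


@cli.command()
@_common
@click.option("--promoters", "promoters_path", required=True, type=click.Path())
def align(outdir, seed, promoters_path):
    """Progressive MSA, distance matrix and NJ dendrogram."""
    _setup_logging(Path(outdir))
    promoters = load_promoter_table(promoters_path)
    run_align(promoters, outdir, PipelineConfig(seed=seed))


@cli.command()
@_common
@click.option("--promoters", "promoters_path", required=True, type=click.Path())
@click.option("--msa", "msa_path", type=click.Path())
@click.option("--strict", is_flag=True)
def refine(outdir, seed, promoters_path, msa_path, strict):
    """Iterative profile-HMM refinement to a converged consensus."""
    _setup_logging(Path(outdir))
    promoters = load_promoter_table(promoters_path)
    initial = mp.Alignment.read_fasta(msa_path) if msa_path else None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        result = run_refine(promoters, initial, outdir, PipelineConfig(seed=seed))
    if strict and any(issubclass(w.category, ConvergenceWarning) for w in caught):
        raise click.exceptions.Exit(4)
    click.echo(f"consensus of {result.hmm.M} positions after {result.iterations} iterations")


@cli.command()
@_common
@click.option("--sequence", "seq_path", required=True, type=click.Path())
@click.option("--motifs", "motif_paths", multiple=True, type=click.Path())
@click.option("--threshold", default=9.0, show_default=True)
def scan(outdir, seed, seq_path, motif_paths, threshold):
    """PWM scan of a consensus or promoter sequence, both strands."""
    _setup_logging(Path(outdir))
    seq = _read_single_fasta(seq_path)
    pfms = _load_motifs(motif_paths)
    config = PipelineConfig(seed=seed, scan_threshold=threshold)
    hits = run_scan(seq, pfms, outdir, config)
    click.echo(f"{len(hits)} hits")


@cli.command()
@_common
@click.option("--sequence", "seq_path", required=True, type=click.Path())
@click.option("--motifs", "motif_paths", multiple=True, type=click.Path())
@click.option("--threshold", default=9.0, show_default=True)
@click.option("--ic", "ic_path", type=click.Path())
def architecture(outdir, seed, seq_path, motif_paths, threshold, ic_path):
    """End-relative motif architecture report."""
    _setup_logging(Path(outdir))
    seq = _read_single_fasta(seq_path)
    pfms = _load_motifs(motif_paths)
    config = PipelineConfig(seed=seed, scan_threshold=threshold)
    hits = run_scan(seq, pfms, outdir, config)
    ic = None
    if ic_path:
        import pandas as pd

        ic = pd.read_csv(ic_path, sep="\t")["ic_bits"].to_numpy()
    run_architecture(seq, hits, ic, outdir)
    click.echo("architecture report written")


@cli.command()
@_common
@click.option("--promoters", "promoters_path", required=True, type=click.Path())
@click.option("--motifs", "motif_paths", multiple=True, type=click.Path())
@click.option("--threshold", default=9.0, show_default=True)
@click.option("--strict", is_flag=True)
def full(outdir, seed, promoters_path, motif_paths, threshold, strict):
    """Whole analysis: align, refine, scan, architecture."""
    _setup_logging(Path(outdir))
    promoters = load_promoter_table(promoters_path)
    pfms = _load_motifs(motif_paths)
    config = PipelineConfig(seed=seed, scan_threshold=threshold)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        out = run_full(promoters, pfms, outdir, config)
    if strict and any(issubclass(w.category, ConvergenceWarning) for w in caught):
        raise click.exceptions.Exit(4)
    click.echo(
        f"consensus {out['refine'].hmm.M} nt, {len(out['hits'])} motif hits, "
        f"{len(out['pairs'])} motif pairs"
    )


def _read_single_fasta(path) -> str:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputIOError(f"no sequences in {path}")
    return str(records[0].seq).upper()


def _load_motifs(paths) -> list[ms.PFM]:
    if not paths:
        return ms.load_bundled_motifs()
    pfms: list[ms.PFM] = []
    for p in paths:
        pfms.extend(ms.read_pfm_file(p))
    return pfms


def main():
    try:
        cli.main(standalone_mode=False)
    except click.exceptions.Exit as exc:
        sys.exit(exc.exit_code)
    except click.ClickException as exc:
        exc.show()
        sys.exit(2)
    except (InputIOError, OSError) as exc:
        print(f"I/O error: {exc}", file=sys.stderr)
        sys.exit(3)
    except (ValidationError, InputError, Ph4h3Error) as exc:
        print(f"validation error: {exc}", file=sys.stderr)
        sys.exit(2)


if __name__ == "__main__":
    main()
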