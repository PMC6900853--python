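"""PFM/PWM handling and strand-aware motif scanning.

Count matrices come in as JASPAR-format PFMs (">ID name" plus four
bracketed count rows) or as the plain 4-column table dialect used by
YeTFaSCo-style models.  Counts are turned into log2-odds weights against a
background model and every window on both strands is scored; windows above
a bit-score threshold become hits reported in canonical-promoter-strand
coordinates (1-based, inclusive).

``N`` positions are background-neutral: they contribute 0 bits and never
disqualify a window.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .errors import InputError, ParseError
from .msa_phylo import encode

BASES = "ACGT"


@dataclass(frozen=True)
class PFM:
    """Position frequency (count) matrix, rows in A,C,G,T order."""

    motif_id: str
    name: str
    counts: np.ndarray  # (4, W)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise InputError(f"{self.motif_id}: counts must be a 4 x W matrix with W >= 1")
        if np.any(counts < 0):
            raise InputError(f"{self.motif_id}: negative counts")
        if np.any(counts.sum(axis=0) == 0):
            raise InputError(f"{self.motif_id}: all-zero column")

    @property
    def width(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class PWM:
    """Log2-odds weight matrix derived from a PFM."""

    motif_id: str
    name: str
    weights: np.ndarray  # (4, W) bits
    background: np.ndarray

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=0).sum())


@dataclass(frozen=True)
class MotifHit:
    """A scored motif occurrence on the canonical promoter strand."""

    motif_id: str
    name: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str
    score: float

    @property
    def width(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def read_pfm(text: str) -> list[PFM]:
    """Parse motif matrices from JASPAR PFM text or a 4-column table.

    The dialect is auto-detected: text containing '>' headers is handed to
    the Biopython JASPAR parser; otherwise each whitespace-separated row of
    four numbers is one motif position (A C G T).
    """
    stripped = text.strip()
    if not stripped:
        raise ParseError("empty motif file")
    if stripped.startswith(">"):
        return _read_jaspar(text)
    return [_read_columns(text)]


def _read_jaspar(text: str) -> list[PFM]:
    try:
        records = bio_motifs.parse(io.StringIO(text), "jaspar")
    except Exception as exc:  # Biopython raises bare ValueError
        raise ParseError(f"JASPAR parse failure: {exc}") from exc
    out = []
    for m in records:
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        out.append(PFM(motif_id=m.matrix_id or m.name, name=m.name or m.matrix_id, counts=counts))
    if not out:
        raise ParseError("no motifs found in JASPAR input")
    return out


def _read_columns(text: str, motif_id: str = "motif", name: str = "motif") -> PFM:
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(f"expected 4 columns (A C G T), got {len(parts)}", line=lineno)
        try:
            rows.append([float(x) for x in parts])
        except ValueError:
            raise ParseError(f"non-numeric count in {line!r}", line=lineno) from None
    if not rows:
        raise ParseError("no matrix rows found")
    return PFM(motif_id=motif_id, name=name, counts=np.array(rows).T)


def load_bundled_motifs() -> list[PFM]:
    """Synthetic look-alike TF motif matrices shipped with the package.

    These are stand-ins constructed for testing the scanning and
    architecture machinery (Spt10-, HAP/CCAAT-, CreA- and NEG-style); real
    JASPAR or YeTFaSCo matrices can be supplied instead via ``read_pfm``.
    """
    from importlib import resources

    text = (resources.files("ph4h3") / "matrices" / "synthetic_tf_motifs.pfm").read_text()
    return read_pfm(text)


def read_pfm_file(path: str | Path) -> list[PFM]:
    path = Path(path)
    pfms = read_pfm(path.read_text())
    if len(pfms) == 1 and pfms[0].motif_id == "motif":
        stem = path.stem
        pfms = [PFM(motif_id=stem, name=stem, counts=pfms[0].counts)]
    return pfms


def write_pfm(pfms: Sequence[PFM], path: str | Path) -> None:
    """Write motifs in JASPAR PFM format."""
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.motif_id} {pfm.name}\n")
            for b, row in zip(BASES, pfm.counts):
                fh.write(f"{b} [ " + " ".join(f"{v:g}" for v in row) + " ]\n")


# ---------------------------------------------------------------------------
# PWM construction and scanning
# ---------------------------------------------------------------------------

def pfm_to_pwm(
    pfm: PFM,
    background: Sequence[float] | None = None,
    pseudo: float = 0.8,
) -> PWM:
    """Log2-odds transform with background-proportional pseudocounts:

    w[r,j] = log2( (c[r,j] + pseudo*bg[r]) / (colsum_j + pseudo) / bg[r] )
    """
    bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0):
        raise InputError("background must be 4 strictly positive probabilities")
    bg = bg / bg.sum()
    colsum = pfm.counts.sum(axis=0)
    probs = (pfm.counts + pseudo * bg[:, None]) / (colsum + pseudo)[None, :]
    if np.any(probs <= 0):
        raise InputError(f"{pfm.motif_id}: zero probability cell; increase pseudo")
    weights = np.log2(probs / bg[:, None])
    return PWM(motif_id=pfm.motif_id, name=pfm.name, weights=weights, background=bg)


def _revcomp_pwm_weights(weights: np.ndarray) -> np.ndarray:
    # complement = reverse row order (A<->T, C<->G), then reverse columns
    return weights[::-1, ::-1]


def scan(
    seq: str,
    pwm: PWM,
    threshold: float = 9.0,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All windows with summed log2-odds strictly above ``threshold``.

    Reverse-strand windows are scored with the reverse-complemented weight
    matrix and reported in canonical-strand coordinates.  Hits are sorted by
    start, then '+' before '-'.
    """
    W = pwm.width
    L = len(seq)
    if L < W:
        warnings.warn(f"sequence shorter than motif width {W}; no windows to scan")
        return []
    codes = encode(seq)
    codes = np.where(codes == 5, 4, codes)
    ext = np.vstack([pwm.weights, np.zeros((1, W))])  # N row scores 0
    windows = np.lib.stride_tricks.sliding_window_view(codes, W)
    pos_scores = ext[windows, np.arange(W)].sum(axis=1)
    hits = [
        MotifHit(pwm.motif_id, pwm.name, i + 1, i + W, "+", float(s))
        for i, s in enumerate(pos_scores)
        if s > threshold
    ]
    if both_strands:
        rc = np.vstack([_revcomp_pwm_weights(pwm.weights), np.zeros((1, W))])
        neg_scores = rc[windows, np.arange(W)].sum(axis=1)
        hits += [
            MotifHit(pwm.motif_id, pwm.name, i + 1, i + W, "-", float(s))
            for i, s in enumerate(neg_scores)
            if s > threshold
        ]
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_many(
    seq: str,
    pwms: Sequence[PWM],
    threshold: float = 9.0,
    both_strands: bool = True,
) -> list[MotifHit]:
    out: list[MotifHit] = []
    for pwm in pwms:
        out.extend(scan(seq, pwm, threshold, both_strands))
    out.sort(key=lambda h: (h.start, h.strand, h.motif_id))
    return out


# ---------------------------------------------------------------------------
# Hit output
# ---------------------------------------------------------------------------

def write_hits_tsv(hits: Sequence[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\tname\tstart\tend\tstrand\tscore_bits\n")
        for h in hits:
            fh.write(f"{h.motif_id}\t{h.name}\t{h.start}\t{h.end}\t{h.strand}\t{h.score:.4f}\n")


def write_hits_bed(
    hits: Sequence[MotifHit],
    path: str | Path,
    chrom: str = "promoter",
    max_bits: float | None = None,
) -> None:
    """BED6 output: 0-based half-open, scores scaled to 0-1000."""
    scores = [h.score for h in hits] or [1.0]
    top = max_bits if max_bits is not None else max(max(scores), 1e-9)
    with open(path, "w") as fh:
        for h in hits:
            scaled = int(round(min(max(h.score / top, 0.0), 1.0) * 1000))
            fh.write(f"{chrom}\t{h.start - 1}\t{h.end}\t{h.motif_id}\t{scaled}\t{h.strand}\n")
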