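"""Bidirectional promoter architecture analysis.

The hallmark arrangement in the h4.1-h3 intergenic promoter is symmetry:
the same transcription-factor motif occurring near both promoter ends, on
opposite strands, with the motif's 5'->3' direction pointing at the nearer
ATG.  This module annotates motif hits relative to the two promoter ends
(Ph4' = position 1, Ph3' = last position), pairs them into mirror pairs
across ends and tandem pairs within an end, measures pair spacings and
overlaps, and locates conserved windows of the information-content profile
in end-relative coordinates.

End-relative coordinates are negative offsets from the respective ATG:
-1 is the nucleotide abutting the start codon.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InputError
from .motif_scan import MotifHit

PH4 = "Ph4'"
PH3 = "Ph3'"


@dataclass(frozen=True)
class EndAnnotatedHit:
    hit: MotifHit
    nearer_end: str               # PH4 or PH3
    distance_to_end: int          # nt between outer edge and promoter terminus
    orientation_vs_end: str       # 'toward' or 'away'

    @property
    def end_relative_start(self) -> int:
        """Negative offset of the hit's outer edge from its nearer ATG."""
        return -(self.distance_to_end + self.hit.width)


@dataclass(frozen=True)
class MotifPair:
    member_a: EndAnnotatedHit
    member_b: EndAnnotatedHit
    relationship: str  # 'mirror_across_ends' or 'tandem_within_end'
    separation: int    # inner-edge to inner-edge exclusive gap; 0 if overlapping
    overlapping: bool = False


@dataclass(frozen=True)
class OverlapRecord:
    hit_a: MotifHit
    hit_b: MotifHit
    overlap_len: int


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def annotate_ends(hits: Sequence[MotifHit], promoter_len: int) -> list[EndAnnotatedHit]:
    """Assign each hit to its nearer promoter end (midpoint rule, ties to
    Ph4') and record distance and orientation.

    Orientation 'toward' means the motif's 5'->3' arrow points at the nearer
    end: '-' strand points left (Ph4'), '+' strand points right (Ph3').
    """
    out = []
    for h in hits:
        if h.start < 1 or h.end > promoter_len:
            raise InputError(
                f"hit {h.motif_id} [{h.start},{h.end}] outside promoter of length {promoter_len}"
            )
        midpoint = (h.start + h.end) / 2
        nearer = PH4 if midpoint <= (promoter_len + 1) / 2 else PH3
        distance = h.start - 1 if nearer == PH4 else promoter_len - h.end
        points_at = PH4 if h.strand == "-" else PH3
        out.append(
            EndAnnotatedHit(
                hit=h,
                nearer_end=nearer,
                distance_to_end=distance,
                orientation_vs_end="toward" if points_at == nearer else "away",
            )
        )
    return out


def _pair(a: EndAnnotatedHit, b: EndAnnotatedHit, relationship: str) -> MotifPair:
    first, second = (a, b) if a.hit.start <= b.hit.start else (b, a)
    gap = second.hit.start - first.hit.end - 1
    return MotifPair(
        member_a=a,
        member_b=b,
        relationship=relationship,
        separation=max(gap, 0),
        overlapping=gap < 0,
    )


def find_mirror_pairs(hits: Sequence[EndAnnotatedHit]) -> list[MotifPair]:
    """Pair same-motif hits into mirror pairs (opposite strands, opposite
    ends) and tandem pairs (opposite strands, same end).

    When more than two candidates exist, matching is greedy outermost-first
    (smallest distance_to_end); unmatched hits are simply left unpaired.
    """
    by_motif: dict[str, list[EndAnnotatedHit]] = defaultdict(list)
    for h in hits:
        by_motif[h.hit.motif_id].append(h)
    pairs: list[MotifPair] = []
    for motif_id in sorted(by_motif):
        group = by_motif[motif_id]
        # mirror pairs across ends
        left = sorted((h for h in group if h.nearer_end == PH4), key=lambda h: (h.distance_to_end, h.hit.start))
        right = sorted((h for h in group if h.nearer_end == PH3), key=lambda h: (h.distance_to_end, h.hit.start))
        used_right: set[int] = set()
        for lh in left:
            for idx, rh in enumerate(right):
                if idx in used_right or rh.hit.strand == lh.hit.strand:
                    continue
                pairs.append(_pair(lh, rh, "mirror_across_ends"))
                used_right.add(idx)
                break
        # tandem pairs within each end
        for side in (left, right):
            used: set[int] = set()
            for i, a in enumerate(side):
                if i in used:
                    continue
                for j in range(i + 1, len(side)):
                    if j in used or side[j].hit.strand == a.hit.strand:
                        continue
                    pairs.append(_pair(a, side[j], "tandem_within_end"))
                    used.update((i, j))
                    break
    return pairs


def pair_spacings(pairs: Sequence[MotifPair]) -> list[dict]:
    """Tabulate pair separations (inner edge to inner edge, exclusive);
    overlapping members report separation 0 with an overlap flag."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "motif_id": p.member_a.hit.motif_id,
                "relationship": p.relationship,
                "start_a": p.member_a.hit.start,
                "start_b": p.member_b.hit.start,
                "separation": p.separation,
                "overlapping": p.overlapping,
            }
        )
    return rows


def find_overlaps(hits: Sequence[MotifHit]) -> list[OverlapRecord]:
    """All pairs of hits whose intervals genuinely intersect."""
    out = []
    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            a, b = hits[i], hits[j]
            lo = max(a.start, b.start)
            hi = min(a.end, b.end)
            if hi >= lo:
                out.append(OverlapRecord(a, b, hi - lo + 1))
    return out


@dataclass(frozen=True)
class ConservedRegion:
    start: int  # 1-based inclusive, model coordinates
    end: int
    mean_ic: float
    ph4_relative: tuple[int, int]  # negative offsets from the Ph4' ATG
    ph3_relative: tuple[int, int]  # negative offsets from the Ph3' ATG


def conserved_regions(
    ic: np.ndarray,
    window: int = 25,
    min_mean_ic: float = 1.0,
) -> list[ConservedRegion]:
    """Maximal runs of positions covered by a sliding window whose mean IC
    reaches ``min_mean_ic``, in absolute and end-relative coordinates."""
    ic = np.asarray(ic, dtype=float)
    L = len(ic)
    if window < 1:
        raise InputError("window must be >= 1")
    if window > L:
        raise InputError(f"window {window} longer than profile ({L})")
    means = np.convolve(ic, np.ones(window) / window, mode="valid")
    covered = np.zeros(L, dtype=bool)
    for j in np.flatnonzero(means >= min_mean_ic):
        covered[j : j + window] = True
    out = []
    j = 0
    while j < L:
        if covered[j]:
            k = j
            while k + 1 < L and covered[k + 1]:
                k += 1
            seg = ic[j : k + 1]
            out.append(
                ConservedRegion(
                    start=j + 1,
                    end=k + 1,
                    mean_ic=float(seg.mean()),
                    ph4_relative=(-(k + 1), -(j + 1)),
                    ph3_relative=(-(L - j), -(L - k)),
                )
            )
            j = k + 1
        else:
            j += 1
    return out


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def write_architecture_tsv(
    annotated: Sequence[EndAnnotatedHit],
    pairs: Sequence[MotifPair],
    overlaps: Sequence[OverlapRecord],
    path: str | Path,
) -> None:
    pair_of: dict[tuple, tuple[int, str, int]] = {}
    for pid, p in enumerate(pairs, start=1):
        for member in (p.member_a, p.member_b):
            key = (member.hit.motif_id, member.hit.start, member.hit.strand)
            pair_of.setdefault(key, (pid, p.relationship, p.separation))
    overlap_nt: dict[tuple, int] = defaultdict(int)
    for rec in overlaps:
        for h in (rec.hit_a, rec.hit_b):
            overlap_nt[(h.motif_id, h.start, h.strand)] += rec.overlap_len
    with open(path, "w") as fh:
        fh.write(
            "motif_id\tname\tstart\tend\tstrand\tscore_bits\tnearer_end\t"
            "distance_to_end\torientation\tpair_id\trelationship\tseparation\toverlap_nt\n"
        )
        for a in annotated:
            h = a.hit
            key = (h.motif_id, h.start, h.strand)
            pid, rel, sep = pair_of.get(key, ("", "", ""))
            fh.write(
                f"{h.motif_id}\t{h.name}\t{h.start}\t{h.end}\t{h.strand}\t{h.score:.3f}\t"
                f"{a.nearer_end}\t{a.distance_to_end}\t{a.orientation_vs_end}\t"
                f"{pid}\t{rel}\t{sep}\t{overlap_nt.get(key, 0)}\n"
            )


def summarize(
    annotated: Sequence[EndAnnotatedHit],
    pairs: Sequence[MotifPair],
    promoter_len: int,
) -> str:
    """Plain-text overview of the bidirectional architecture."""
    lines = [f"Promoter length: {promoter_len} nt (Ph4' left, Ph3' right)"]
    for end in (PH4, PH3):
        side = [a for a in annotated if a.nearer_end == end]
        lines.append(f"{end} end: {len(side)} hit(s)")
        for a in sorted(side, key=lambda x: x.distance_to_end):
            h = a.hit
            lines.append(
                f"  {h.motif_id} [{h.start},{h.end}] strand {h.strand} "
                f"{a.distance_to_end} nt from end, {a.orientation_vs_end} "
                f"({h.score:.2f} bits)"
            )
    mirrors = [p for p in pairs if p.relationship == "mirror_across_ends"]
    tandems = [p for p in pairs if p.relationship == "tandem_within_end"]
    lines.append(f"Mirror pairs across ends: {len(mirrors)}")
    for p in mirrors:
        lines.append(
            f"  {p.member_a.hit.motif_id}: {p.member_a.hit.start}({p.member_a.hit.strand})"
            f" <-> {p.member_b.hit.start}({p.member_b.hit.strand})"
        )
    lines.append(f"Tandem pairs within ends: {len(tandems)}")
    for p in tandems:
        lines.append(
            f"  {p.member_a.hit.motif_id}: {p.member_a.hit.start}({p.member_a.hit.strand})"
            f" .. {p.member_b.hit.start}({p.member_b.hit.strand}), separated by {p.separation} nt"
            + (" (overlapping)" if p.overlapping else "")
        )
    return "\n".join(lines) + "\n"
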