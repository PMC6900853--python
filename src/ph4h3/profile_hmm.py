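"""Profile HMM construction, glocal Viterbi alignment and iterative
refinement to a converged consensus.

The promoter consensus is defined by a DNA profile HMM in the classic
match/insert/delete architecture.  Because the raw promoter set has poorly
conserved 5'/3' extremities, the model is *glocal*: the full match chain
must be traversed (via matches or deletions) but sequences may carry
unpenalised N-/C-terminal flanks that are trimmed away after alignment.
Refinement repeatedly re-estimates the model from the trimmed re-alignment
until the emitted consensus string stops changing; the match length M
shrinks as unconserved end columns fall below the match-column gap rule.

Scoring is log2-odds against a uniform background.  Flanking states emit at
background with no transition cost (log-odds zero), so adding junk flanks
never lowers an optimal score and trimming is driven purely by what the
core model gains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .errors import ConvergenceWarning, DegenerateModelError, InputError
from .msa_phylo import Alignment, encode, progressive_align

NEG = -1.0e30
BASES = "ACGT"


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class ProfileHMM:
    """Match/insert/delete profile HMM over DNA.

    ``tm``/``ti``/``td`` hold per-node transition probabilities from
    M_k/I_k/D_k to ``[M_{k+1}, I_k, D_{k+1}]`` for k = 0..M, where node 0 is
    the begin state and the to-M slot at node M is the end transition.
    Impossible slots (to-D at node M, the entire D_0 row) are zero.
    """

    match_emissions: np.ndarray   # (M+1, 4), row 0 unused
    insert_emissions: np.ndarray  # (M+1, 4)
    tm: np.ndarray                # (M+1, 3)
    ti: np.ndarray                # (M+1, 3)
    td: np.ndarray                # (M+1, 3)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0] - 1

    def validate(self, tol: float = 1e-9) -> None:
        if self.M < 1:
            raise InputError("profile HMM needs at least one match state")
        em = self.match_emissions[1:]
        if np.any(np.abs(em.sum(axis=1) - 1) > tol):
            raise InputError("match emission rows must sum to 1")
        if np.any(np.abs(self.insert_emissions.sum(axis=1) - 1) > tol):
            raise InputError("insert emission rows must sum to 1")
        for name, t in (("tm", self.tm), ("ti", self.ti)):
            if np.any(np.abs(t.sum(axis=1) - 1) > tol):
                raise InputError(f"{name} transition rows must sum to 1")
        if self.M > 1 and np.any(np.abs(self.td[1:].sum(axis=1) - 1) > tol):
            raise InputError("td transition rows must sum to 1")


@dataclass
class AlignedPath:
    """Viterbi state path for one sequence.

    ``states`` is a list of (kind, node) pairs in path order with kind in
    {'N','M','I','D','C'}; node is 0 for flanks.  Non-emitting D states are
    included; the number of emitting states equals the sequence length.
    """

    label: str
    states: list[tuple[str, int]]
    score: float

    def emitted_count(self) -> int:
        return sum(1 for kind, _ in self.states if kind in "NMIC")


# ---------------------------------------------------------------------------
# Match-column assignment and estimation
# ---------------------------------------------------------------------------

def assign_match_columns(aln: Alignment, gap_threshold: float = 0.5) -> np.ndarray:
    """Boolean mask: a column is a match column iff its gap fraction is
    strictly below ``gap_threshold``."""
    mat = aln.to_matrix()
    gap_frac = (mat == 5).mean(axis=0)
    return gap_frac < gap_threshold


def _row_states(row_codes: np.ndarray, mask: np.ndarray) -> list[tuple[str, int, int]]:
    """(kind, node, residue_code) events for one alignment row; D events
    carry residue -1; insert-column gaps produce nothing."""
    events = []
    node = 0
    for c in range(len(mask)):
        code = row_codes[c]
        if mask[c]:
            node += 1
            if code == 5:
                events.append(("D", node, -1))
            else:
                events.append(("M", node, int(code)))
        elif code != 5:
            events.append(("I", node, int(code)))
    return events


def estimate_hmm(
    aln: Alignment,
    mask: np.ndarray | None = None,
    pseudocount: float = 1.0,
    transition_pseudocount: float = 0.1,
    gap_threshold: float = 0.5,
) -> ProfileHMM:
    """Count-based estimation with Laplace pseudocounts.

    Defaults add 1.0 per residue to every emission cell and 0.1 to every
    legal transition.  Rows that receive no counts and no pseudocount fall
    back to uniform over their legal slots so the model stays normalised.
    """
    if mask is None:
        mask = assign_match_columns(aln, gap_threshold)
    mask = np.asarray(mask, dtype=bool)
    M = int(mask.sum())
    if M == 0:
        raise DegenerateModelError("no match columns under the gap-fraction rule")
    cm = np.zeros((M + 1, 4))
    ci = np.zeros((M + 1, 4))
    ctm = np.zeros((M + 1, 3))
    cti = np.zeros((M + 1, 3))
    ctd = np.zeros((M + 1, 3))
    counts = {"M": ctm, "I": cti, "D": ctd}
    slot = {"M": 0, "I": 1, "D": 2}
    mat = aln.to_matrix()
    for r in range(aln.nrow):
        events = _row_states(mat[r], mask)
        prev = ("M", 0)  # begin
        for kind, node, code in events:
            counts[prev[0]][prev[1], slot[kind]] += 1
            if kind == "M" and 0 <= code < 4:
                cm[node, code] += 1
            elif kind == "I" and 0 <= code < 4:
                ci[node, code] += 1
            prev = (kind, node)
        counts[prev[0]][prev[1], slot["M"]] += 1  # -> end

    legal_m = np.ones((M + 1, 3), dtype=bool)
    legal_m[M, 2] = False
    legal_i = legal_m.copy()
    legal_d = legal_m.copy()
    legal_d[0, :] = False

    def normalize(c, legal, pseudo):
        c = c + pseudo * legal
        c[~legal] = 0.0
        sums = c.sum(axis=1, keepdims=True)
        for k in range(c.shape[0]):
            if legal[k].any() and sums[k, 0] == 0:
                c[k, legal[k]] = 1.0 / legal[k].sum()
                sums[k, 0] = 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, c / np.maximum(sums, 1e-300), 0.0)
        return out

    match_em = cm + pseudocount
    match_em[0] = 0.0
    row_sums = match_em[1:].sum(axis=1, keepdims=True)
    zero = row_sums[:, 0] == 0
    match_em[1:][zero] = 0.25
    row_sums[zero] = 1.0
    match_em[1:] = match_em[1:] / np.maximum(match_em[1:].sum(axis=1, keepdims=True), 1e-300)
    ins_em = ci + pseudocount
    zi = ins_em.sum(axis=1) == 0
    ins_em[zi] = 0.25
    ins_em = ins_em / ins_em.sum(axis=1, keepdims=True)
    return ProfileHMM(
        match_emissions=match_em,
        insert_emissions=ins_em,
        tm=normalize(ctm, legal_m, transition_pseudocount),
        ti=normalize(cti, legal_i, transition_pseudocount),
        td=normalize(ctd, legal_d, transition_pseudocount),
    )


# ---------------------------------------------------------------------------
# Viterbi alignment (glocal, free flanks)
# ---------------------------------------------------------------------------

def _log2(p: np.ndarray) -> np.ndarray:
    out = np.full(p.shape, NEG)
    nz = p > 0
    out[nz] = np.log2(p[nz])
    return out


@njit(cache=True)
def _viterbi(x, lm, li, ltm, lti, ltd):  # pragma: no cover - jit
    L = x.shape[0]
    M = lm.shape[0] - 1
    VM = np.full((L + 1, M + 1), NEG)
    VI = np.full((L + 1, M + 1), NEG)
    VD = np.full((L + 1, M + 1), NEG)
    pM = np.zeros((L + 1, M + 1), dtype=np.int8)
    pI = np.zeros((L + 1, M + 1), dtype=np.int8)
    pD = np.zeros((L + 1, M + 1), dtype=np.int8)
    for i in range(L + 1):
        VM[i, 0] = 0.0  # begin reachable after a free N-flank of length i
    # row i = 0: deletions reachable without emitting
    for k in range(1, M + 1):
        cm0 = VM[0, k - 1] + ltm[k - 1, 2]
        cd0 = VD[0, k - 1] + ltd[k - 1, 2]
        best0 = cm0
        ptr0 = 0
        if cd0 > best0:
            best0 = cd0
            ptr0 = 1
        VD[0, k] = best0
        pD[0, k] = ptr0
    for i in range(1, L + 1):
        xi = x[i - 1]
        for k in range(M + 1):
            if k >= 1:
                cm_ = VM[i - 1, k - 1] + ltm[k - 1, 0]
                cd = VD[i - 1, k - 1] + ltd[k - 1, 0]
                ci_ = VI[i - 1, k - 1] + lti[k - 1, 0]
                best = cm_
                ptr = 0
                if cd > best:
                    best = cd
                    ptr = 1
                if ci_ > best:
                    best = ci_
                    ptr = 2
                VM[i, k] = lm[k, xi] + best
                pM[i, k] = ptr
            cm_ = VM[i - 1, k] + ltm[k, 1]
            cd = VD[i - 1, k] + ltd[k, 1]
            ci_ = VI[i - 1, k] + lti[k, 1]
            best = cm_
            ptr = 0
            if cd > best:
                best = cd
                ptr = 1
            if ci_ > best:
                best = ci_
                ptr = 2
            VI[i, k] = li[k, xi] + best
            pI[i, k] = ptr
            if k >= 1:
                cm_ = VM[i, k - 1] + ltm[k - 1, 2]
                cd = VD[i, k - 1] + ltd[k - 1, 2]
                ci_ = VI[i, k - 1] + lti[k - 1, 2]
                best = cm_
                ptr = 0
                if cd > best:
                    best = cd
                    ptr = 1
                if ci_ > best:
                    best = ci_
                    ptr = 2
                VD[i, k] = best
                pD[i, k] = ptr
    return VM, VI, VD, pM, pI, pD


def _log_odds_tables(hmm: ProfileHMM):
    bg = hmm.background
    lm = np.zeros((hmm.M + 1, 5))
    lm[:, :4] = _log2(hmm.match_emissions) - _log2(bg[None, :])
    lm[0, :] = NEG
    lm[:, 4] = 0.0  # N scores as background
    lm[0, 4] = NEG
    li = np.zeros((hmm.M + 1, 5))
    li[:, :4] = _log2(hmm.insert_emissions) - _log2(bg[None, :])
    li[:, 4] = 0.0
    return lm, li, _log2(hmm.tm), _log2(hmm.ti), _log2(hmm.td)


def viterbi_align(hmm: ProfileHMM, seq: str, label: str = "seq") -> AlignedPath:
    """Maximum log2-odds glocal state path for one sequence.

    Ties between state kinds break M > D > I; at equal exit score the path
    keeping more residues inside the core model wins.
    """
    if not seq:
        raise InputError("cannot align an empty sequence")
    x = encode(seq).astype(np.int8)
    x[x == 5] = 4  # treat stray gaps as N
    lm, li, ltm, lti, ltd = _log_odds_tables(hmm)
    VM, VI, VD, pM, pI, pD = _viterbi(x, lm, li, ltm, lti, ltd)
    L, M = len(seq), hmm.M
    best_score, best_i, best_kind = NEG, 0, "M"
    for i in range(L + 1):
        for kind, V, t in (("M", VM, ltm), ("D", VD, ltd), ("I", VI, lti)):
            s = V[i, M] + t[M, 0]
            if s > best_score or (s == best_score and i > best_i):
                best_score, best_i, best_kind = s, i, kind
    # trace back through the core
    states: list[tuple[str, int]] = []
    i, k, kind = best_i, M, best_kind
    ptr_from = {0: "M", 1: "D", 2: "I"}
    while not (kind == "M" and k == 0):
        states.append((kind, k))
        if kind == "M":
            prev = ptr_from[pM[i, k]]
            i, k = i - 1, k - 1
        elif kind == "I":
            prev = ptr_from[pI[i, k]]
            i = i - 1
        else:
            prev = ptr_from[pD[i, k]]
            k = k - 1
        kind = prev
    n_prefix = i
    states.extend(("N", 0) for _ in range(n_prefix))
    states.reverse()
    states.extend(("C", 0) for _ in range(L - best_i))
    return AlignedPath(label=label, states=states, score=float(best_score))


def trim_flanks(path: AlignedPath, seq: str) -> str:
    """Drop residues assigned to the N-/C-flank states; keep everything
    emitted inside the core (matches and internal inserts)."""
    kinds = [k for k, _ in path.states if k in "NMIC"]
    if len(kinds) != len(seq):
        raise InputError("path emission count does not match sequence length")
    return "".join(ch for ch, kind in zip(seq, kinds) if kind in "MI")


# ---------------------------------------------------------------------------
# Consensus, information content
# ---------------------------------------------------------------------------

def emit_consensus(hmm: ProfileHMM, minl: float = 0.25, minu: float = 0.5) -> str:
    """Per match state: argmax residue, uppercase if p >= minu, lowercase if
    minl <= p < minu, 'n' below minl.  Ties break alphabetically."""
    if not (0 <= minl <= minu <= 1):
        raise InputError("need 0 <= minl <= minu <= 1")
    out = []
    for k in range(1, hmm.M + 1):
        probs = hmm.match_emissions[k]
        r = int(np.argmax(probs))
        p = float(probs[r])
        if p >= minu:
            out.append(BASES[r])
        elif p >= minl:
            out.append(BASES[r].lower())
        else:
            out.append("n")
    return "".join(out)


def information_content(hmm: ProfileHMM) -> np.ndarray:
    """Per-match-position information content in bits (0..2 for DNA):
    IC_j = 2 + sum_r p_j(r) log2 p_j(r)."""
    p = hmm.match_emissions[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return np.clip(2.0 + plogp.sum(axis=1), 0.0, 2.0)


# ---------------------------------------------------------------------------
# Iterative refinement
# ---------------------------------------------------------------------------

@dataclass
class RefineResult:
    hmm: ProfileHMM
    consensus: str
    iterations: int
    converged: bool
    history: list[tuple[int, int]] = field(default_factory=list)  # (iteration, M)
    alignment: Alignment | None = None  # match-column alignment the converged model was fit to


def rebuild_alignment(paths: Sequence[AlignedPath], seqs: Sequence[str], M: int) -> Alignment:
    """Alignment whose columns are the M match states; insert-state and
    flank residues are excluded."""
    rows = []
    for path, seq in zip(paths, seqs):
        row = ["-"] * M
        pos = 0
        for kind, node in path.states:
            if kind == "M":
                row[node - 1] = seq[pos]
                pos += 1
            elif kind in "NIC":
                pos += 1
        rows.append("".join(row))
    return Alignment([p.label for p in paths], rows)


def refine(
    seqs: dict[str, str],
    initial_aln: Alignment | None = None,
    max_iter: int = 50,
    gap_threshold: float = 0.5,
    pseudocount: float = 1.0,
    transition_pseudocount: float = 0.1,
    minl: float = 0.25,
    minu: float = 0.5,
) -> RefineResult:
    """Iterate model estimation / re-alignment / trimming until the emitted
    consensus string (including case) is identical between iterations.

    Each round re-aligns the *original* sequences to the current model, so
    residues trimmed in one round can re-enter later if the model grows to
    explain them.
    """
    if len(seqs) < 2:
        raise InputError("refinement needs at least 2 sequences")
    if initial_aln is None:
        initial_aln = progressive_align(seqs)
    labels = list(seqs)
    aln = initial_aln
    mask = assign_match_columns(aln, gap_threshold)
    prev_consensus: str | None = None
    history: list[tuple[int, int]] = []
    hmm = None
    consensus = ""
    for it in range(1, max_iter + 1):
        hmm = estimate_hmm(aln, mask, pseudocount, transition_pseudocount)
        consensus = emit_consensus(hmm, minl, minu)
        history.append((it, hmm.M))
        if consensus == prev_consensus:
            return RefineResult(hmm, consensus, it, True, history, aln)
        prev_consensus = consensus
        paths = [viterbi_align(hmm, seqs[lab], label=lab) for lab in labels]
        aln = rebuild_alignment(paths, [seqs[lab] for lab in labels], hmm.M)
        mask = assign_match_columns(aln, gap_threshold)
        if not mask.any():
            raise DegenerateModelError("refinement collapsed to zero match columns")
    warnings.warn(
        f"consensus did not converge within {max_iter} iterations",
        ConvergenceWarning,
    )
    return RefineResult(hmm, consensus, max_iter, False, history, aln)


# ---------------------------------------------------------------------------
# Sampling (used by simulations and parameter-recovery checks)
# ---------------------------------------------------------------------------

def sample_sequence(hmm: ProfileHMM, rng: np.random.Generator) -> str:
    """Draw one sequence from the model (begin -> core -> end; flanks are
    alignment-time devices and are not sampled)."""
    out = []
    kind, k = "M", 0
    trans = {"M": hmm.tm, "I": hmm.ti, "D": hmm.td}
    while True:
        row = trans[kind][k]
        choice = rng.choice(3, p=row / row.sum())
        if choice == 0:  # to M_{k+1} or end
            if k == hmm.M:
                return "".join(out)
            k += 1
            kind = "M"
            out.append(BASES[rng.choice(4, p=hmm.match_emissions[k])])
        elif choice == 1:
            kind = "I"
            out.append(BASES[rng.choice(4, p=hmm.insert_emissions[k])])
        else:
            k += 1
            kind = "D"


# ---------------------------------------------------------------------------
# Plain-text model I/O
# ---------------------------------------------------------------------------

def write_model(hmm: ProfileHMM, path: str | Path) -> None:
    """Documented plain-text profile format: one line per state table row."""
    with open(path, "w") as fh:
        fh.write("PH4H3-HMM 1\n")
        fh.write(f"M {hmm.M}\n")
        fh.write("BACKGROUND " + " ".join(f"{b:.12g}" for b in hmm.background) + "\n")
        for k in range(1, hmm.M + 1):
            fh.write(f"MATCH {k} " + " ".join(f"{p:.12g}" for p in hmm.match_emissions[k]) + "\n")
        for k in range(hmm.M + 1):
            fh.write(f"INSERT {k} " + " ".join(f"{p:.12g}" for p in hmm.insert_emissions[k]) + "\n")
        for name, t in (("TRANS_M", hmm.tm), ("TRANS_I", hmm.ti), ("TRANS_D", hmm.td)):
            for k in range(hmm.M + 1):
                fh.write(f"{name} {k} " + " ".join(f"{p:.12g}" for p in t[k]) + "\n")


def read_model(path: str | Path) -> ProfileHMM:
    with open(path) as fh:
        header = fh.readline().split()
        if not header or header[0] != "PH4H3-HMM":
            raise InputError(f"{path}: not a PH4H3-HMM model file")
        M = None
        background = np.full(4, 0.25)
        tables = {}
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "M":
                M = int(parts[1])
                tables = {
                    "MATCH": np.zeros((M + 1, 4)),
                    "INSERT": np.zeros((M + 1, 4)),
                    "TRANS_M": np.zeros((M + 1, 3)),
                    "TRANS_I": np.zeros((M + 1, 3)),
                    "TRANS_D": np.zeros((M + 1, 3)),
                }
            elif parts[0] == "BACKGROUND":
                background = np.array([float(x) for x in parts[1:5]])
            elif parts[0] in tables:
                k = int(parts[1])
                tables[parts[0]][k] = [float(x) for x in parts[2:]]
    if M is None:
        raise InputError(f"{path}: missing M line")
    return ProfileHMM(
        match_emissions=tables["MATCH"],
        insert_emissions=tables["INSERT"],
        tm=tables["TRANS_M"],
        ti=tables["TRANS_I"],
        td=tables["TRANS_D"],
        background=background,
    )


def write_consensus_fasta(consensus: str, path: str | Path, name: str = "consensus") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(consensus), 70):
            fh.write(consensus[i : i + 70] + "\n")


def write_ic_tsv(hmm: ProfileHMM, path: str | Path) -> None:
    """Per-position emission probabilities and information content, in a
    layout a logo renderer can consume directly."""
    ic = information_content(hmm)
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\tic_bits\n")
        for k in range(1, hmm.M + 1):
            p = hmm.match_emissions[k]
            fh.write(
                f"{k}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\t{p[3]:.6f}\t{ic[k - 1]:.6f}\n"
            )
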