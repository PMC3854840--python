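"""Two-pass local alignment of short reads against a circular reference.

Reads are first aligned at low stringency (>=80% identity over >=50% of the
read) against the reference to collect mtDNA-like reads, a per-sample
consensus is built from that pass, and reads are then re-aligned at high
stringency (>=90% identity over >=95% of the read) against the consensus.
Reads that pass the low- but not the high-stringency cutoff are the split-read
candidates routed to rearrangement breakpoint detection.

The engine is seed-and-extend on a doubled copy of the circular reference
(so windows crossing the origin are ordinary slices; all reported reference
coordinates are reduced mod L):

1. a fully vectorised stage places each read by exact seed words and scores
   the full-length ungapped placement — this resolves almost every read of a
   high-coverage library in a handful of array operations;
2. unresolved reads get a per-read multi-diagonal scan in which the best
   scoring ungapped window (match +1, mismatch -2) on each candidate
   diagonal is found and judged against the cutoffs;
3. anything still undecided (no usable seed) falls back to an exhaustive
   ungapped scan over every diagonal of the circle.

Decisions come from the best-scoring local window (match +1, mismatch -2),
ties broken toward more matches, which makes accept/reject choices
co-optimal-consistent with a full local-DP oracle for substitution-divergent
reads -- the assay's error model.  Reads whose best placement would need
gapped alignment fail the high-stringency cutoff and are routed to
split-read breakpoint analysis, which is where reference-discordant reads
belong.  "Similarity" is matches / aligned columns and "length" is aligned
read bases / read length.  N bases never match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import CircularGenome, decode_seq, revcomp_codes

#: identity and aligned-fraction cutoffs per stringency level
STRINGENCY: dict[str, tuple[float, float]] = {
    "low": (0.80, 0.50),
    "high": (0.90, 0.95),
}


@dataclass
class AlignerConfig:
    """Tunable alignment parameters.

    Scores follow the BLAST-style settings used for breakpoint detection
    (match +1, mismatch -2, gap open 5, gap extend 2) so that all stages of
    the pipeline rank alignments consistently.  ``word`` is the exact seed
    length for the read-placement index.  ``insert_bounds`` is the closed
    range of implied inserts accepted for a concordant pair; anything
    outside (or a lone/same-strand mate) marks the pair broken.
    """

    word: int = 12
    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    max_hits: int = 8
    max_diagonals: int = 24
    insert_bounds: tuple[int, int] = (50, 1200)
    #: exhaustive all-diagonal scan for reads without usable seeds; costly
    #: per read, so pipelines over seeded libraries can disable it
    full_scan_fallback: bool = True


def _kmer_values(codes: np.ndarray, word: int) -> np.ndarray:
    """Packed integer value of every ``word``-mer start; -1 where N occurs."""
    n = len(codes) - word + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for i in range(word):
        c = codes[i : i + n]
        vals = vals * 4 + np.where(c < 4, c, 0)
        bad |= c >= 4
    vals[bad] = -1
    return vals


def _kmer_at(seqs: np.ndarray, off: int, word: int) -> np.ndarray:
    """Packed ``word``-mer at column ``off`` of a read matrix; -1 if N."""
    vals = np.zeros(len(seqs), dtype=np.int64)
    bad = np.zeros(len(seqs), dtype=bool)
    for i in range(word):
        c = seqs[:, off + i]
        vals = vals * 4 + np.where(c < 4, c, 0)
        bad |= c >= 4
    vals[bad] = -1
    return vals


class ReferenceIndex:
    """Exact-word seed index over the doubled circular reference."""

    def __init__(self, genome: CircularGenome, word: int = 12):
        self.genome = genome
        self.word = word
        self.L = genome.L
        self.doubled = np.concatenate([genome.codes, genome.codes])
        vals = _kmer_values(self.doubled[: self.L + word - 1], word)
        valid = vals >= 0
        pos = np.flatnonzero(valid).astype(np.int64)
        vals = vals[valid]
        order = np.argsort(vals, kind="stable")
        self._kmers = vals[order]
        self._pos = pos[order]

    def lookup_first(self, queries: np.ndarray) -> np.ndarray:
        """First reference position of each query word; -1 when absent."""
        lo = np.searchsorted(self._kmers, queries, "left")
        hi = np.searchsorted(self._kmers, queries, "right")
        out = np.full(len(queries), -1, dtype=np.int64)
        found = (hi > lo) & (queries >= 0)
        out[found] = self._pos[lo[found]]
        return out

    def lookup_all(self, query: int, cap: int) -> np.ndarray:
        """Up to ``cap`` reference positions of one query word."""
        if query < 0:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self._kmers, query, "left")
        hi = np.searchsorted(self._kmers, query, "right")
        return self._pos[lo : min(hi, lo + cap)]


@dataclass
class AlignmentSet:
    """Per-read local alignments from one stringency pass.

    ``ref_start`` is the 0-based reference offset of the first aligned read
    base; for strand 1 the coordinates (and ``read_start``) refer to the
    reverse-complemented read.  ``length`` is the aligned column count
    (ungapped for the vectorised stages).
    """

    stringency: str
    accepted: np.ndarray  # bool (n,)
    strand: np.ndarray  # uint8, 0 = forward, 1 = reverse
    ref_start: np.ndarray  # int64, 0-based, in [0, L)
    read_start: np.ndarray  # int32
    length: np.ndarray  # int32 aligned read bases
    matches: np.ndarray  # int32
    columns: np.ndarray  # int32 aligned columns incl. gap columns
    L: int

    @property
    def n_reads(self) -> int:
        return len(self.accepted)

    @property
    def identity(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.columns > 0, self.matches / np.maximum(self.columns, 1), 0.0)

    @property
    def aligned_fraction(self) -> np.ndarray:
        return self.length / max(1, self._read_length)

    @property
    def _read_length(self) -> int:
        return getattr(self, "read_length", 100)

    def rejected_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.accepted)

    def to_dataframe(self) -> pd.DataFrame:
        sel = np.flatnonzero(self.accepted)
        return pd.DataFrame(
            {
                "read_index": sel,
                "strand": self.strand[sel],
                "ref_start": self.ref_start[sel] % self.L,
                "read_start": self.read_start[sel],
                "length": self.length[sel],
                "matches": self.matches[sel],
                "identity": self.identity[sel],
            }
        )


def _best_windows_exact(match: np.ndarray) -> tuple[int, int, int, int, int]:
    """Best ungapped window over a (D, rl) match matrix, exactly.

    Scores match +1 / mismatch -2 and picks the maximum-score window; ties
    are broken toward more matches (equivalently more columns), then the
    smaller diagonal index, then the leftmost start, which makes the choice
    deterministic and co-optimal-consistent with a local-DP oracle.
    Returns (diagonal_index, score, start, end, matches).
    """
    D, rl = match.shape
    P = np.zeros((D, rl + 1), dtype=np.int32)
    np.cumsum(match, axis=1, out=P[:, 1:])
    e = np.arange(rl + 1, dtype=np.int32)
    # windows (i, j): score = 3*(P[j]-P[i]) - 2*(j-i)
    best = None
    for d in range(D):
        diff = P[d][None, :] - P[d][:, None]  # (i, j) matches, j axis last
        span = e[None, :] - e[:, None]
        score = 3 * diff - 2 * span
        iu = np.triu_indices(rl + 1, k=1)
        sc = score[iu]
        k = int(np.argmax(sc))
        top = sc[k]
        ties = np.flatnonzero(sc == top)
        mt = diff[iu][ties]
        order = np.lexsort((iu[0][ties], -mt))
        pick = ties[order[0]]
        i, j = int(iu[0][pick]), int(iu[1][pick])
        cand = (int(top), int(diff[i, j]), -d, -i)
        if best is None or cand > (best[1], best[4], -best[0], -best[2]):
            best = (d, int(top), i, j, int(diff[i, j]))
    d, score, i, j, m = best
    if score <= 0:
        return d, 0, 0, 0, 0
    return d, score, i, j, m


def _scan_matchmat(codes, diags, doubled, rl):
    win = doubled[diags[:, None] + np.arange(rl)[None, :]]
    return (win == codes[None, :]) & (codes[None, :] < 4)


def _decide(score, matches, cols, rl, id_cut, len_cut):
    if cols == 0:
        return False
    return matches / cols >= id_cut and cols / rl >= len_cut


def _align_single(
    read_codes: np.ndarray,
    index: ReferenceIndex,
    id_cut: float,
    len_cut: float,
    config: AlignerConfig,
) -> tuple[bool, int, int, int, int, int, int]:
    """Stage-2/3 alignment of one read.

    Returns (accepted, strand, ref_start, read_start, length, matches,
    columns) for the best-scoring ungapped window over the candidate (or,
    in the fallback, all) diagonals of both strands.
    """
    rl = len(read_codes)
    L = index.L
    w = index.word
    best = None  # (score, matches, strand, diag, start, end)
    for strand, codes in ((0, read_codes), (1, revcomp_codes(read_codes))):
        kq = _kmer_values(codes, w)
        diag_parts = []
        for off in range(0, rl - w + 1):
            hits = index.lookup_all(int(kq[off]), config.max_hits)
            if len(hits):
                diag_parts.append((hits - off) % L)
        if not diag_parts:
            continue
        diags = np.concatenate(diag_parts)
        uniq, support = np.unique(diags, return_counts=True)
        if len(uniq) > config.max_diagonals:
            keep = np.argsort(-support, kind="stable")[: config.max_diagonals]
            uniq = np.sort(uniq[keep])
        match = _scan_matchmat(codes, uniq, index.doubled, rl)
        d, score, i, j, m = _best_windows_exact(match)
        if j > i:
            cand = (score, m, strand, int(uniq[d]), i, j)
            if best is None or cand[:2] > best[:2]:
                best = cand
    if best is None and config.full_scan_fallback:
        all_diags = np.arange(L)
        for strand, codes in ((0, read_codes), (1, revcomp_codes(read_codes))):
            for beg in range(0, L, 2048):
                chunk = all_diags[beg : beg + 2048]
                match = _scan_matchmat(codes, chunk, index.doubled, rl)
                d, score, i, j, m = _best_windows_exact(match)
                if j > i:
                    cand = (score, m, strand, int(chunk[d]), i, j)
                    if best is None or cand[:2] > best[:2]:
                        best = cand
    if best is None:
        return False, 0, 0, 0, 0, 0, 0
    score, m, strand, diag, i, j = best
    cols = j - i
    acc = _decide(score, m, cols, rl, id_cut, len_cut)
    return acc, strand, (diag + i) % L, i, cols, m, cols


def align_reads(
    seqs: np.ndarray,
    index: ReferenceIndex,
    stringency: str,
    config: AlignerConfig | None = None,
    seqs_rc: np.ndarray | None = None,
) -> AlignmentSet:
    """Align a read matrix (n, read_length) against an indexed circle.

    Returns an :class:`AlignmentSet` whose ``accepted`` mask implements the
    stringency contract: identity >= cutoff over aligned-fraction >= cutoff
    for the best local alignment found.
    """
    config = config or AlignerConfig()
    id_cut, len_cut = STRINGENCY[stringency]
    n, rl = seqs.shape
    L = index.L
    w = index.word
    if rl < w:
        out = AlignmentSet(
            stringency,
            np.zeros(n, bool),
            np.zeros(n, np.uint8),
            np.zeros(n, np.int64),
            np.zeros(n, np.int32),
            np.zeros(n, np.int32),
            np.zeros(n, np.int32),
            np.zeros(n, np.int32),
            L,
        )
        out.read_length = rl
        return out

    if seqs_rc is None:
        seqs_rc = revcomp_codes(seqs)

    accepted = np.zeros(n, bool)
    strand = np.zeros(n, np.uint8)
    ref_start = np.zeros(n, np.int64)
    read_start = np.zeros(n, np.int32)
    length = np.zeros(n, np.int32)
    matches = np.zeros(n, np.int32)
    columns = np.zeros(n, np.int32)

    unresolved = np.arange(n)
    offsets = sorted({0, (rl - w) // 2, rl - w})
    arange_rl = np.arange(rl)
    # a full-length placement decides acceptance only when trimming cannot
    # change the verdict: with nmm mismatches the best-scoring window keeps
    # at least rl - nmm read bases, so the aligned fraction stays above the
    # cutoff whenever nmm <= (1 - len_cut) * rl (identity can only improve)
    mm_cut = int(min((1.0 - id_cut), (1.0 - len_cut)) * rl)
    for st, mat in ((0, seqs), (1, seqs_rc)):
        for off in offsets:
            if not len(unresolved):
                break
            sub = mat[unresolved]
            first = index.lookup_first(_kmer_at(sub, off, w))
            ok = first >= 0
            place = (first - off) % L
            win = index.doubled[place[:, None] + arange_rl[None, :]]
            good = (win == sub) & (sub < 4)
            nmatch = good.sum(1)
            accept = ok & (rl - nmatch <= mm_cut)
            sel = unresolved[accept]
            accepted[sel] = True
            strand[sel] = st
            ref_start[sel] = place[accept]
            read_start[sel] = 0
            length[sel] = rl
            matches[sel] = nmatch[accept]
            columns[sel] = rl
            unresolved = unresolved[~accept]

    if len(unresolved):
        for i in unresolved:
            acc, st, rs, qs, ln, m, cols = _align_single(
                seqs[i], index, id_cut, len_cut, config
            )
            accepted[i] = acc
            strand[i] = st
            ref_start[i] = rs % L
            read_start[i] = qs
            length[i] = ln
            matches[i] = m
            columns[i] = cols

    out = AlignmentSet(
        stringency, accepted, strand, ref_start, read_start, length, matches, columns, L
    )
    out.read_length = rl
    return out


def flag_broken_pairs(aln: AlignmentSet, config: AlignerConfig | None = None) -> np.ndarray:
    """Boolean mask over reads marking members of broken pairs.

    Reads are mate-interleaved (read 2i and 2i+1 form pair i).  A pair is
    broken when either mate is unaligned, both mates map to the same strand,
    or the implied insert falls outside ``config.insert_bounds``.
    """
    config = config or AlignerConfig()
    n = aln.n_reads
    rl = aln._read_length
    L = aln.L
    if n % 2:
        raise ValueError("read count is odd; expected mate-interleaved pairs")
    a = aln.accepted.reshape(-1, 2)
    st = aln.strand.reshape(-1, 2)
    place = ((aln.ref_start - aln.read_start) % L).reshape(-1, 2)
    broken = ~(a[:, 0] & a[:, 1])
    broken |= st[:, 0] == st[:, 1]
    p_plus = np.where(st[:, 0] == 0, place[:, 0], place[:, 1])
    p_minus = np.where(st[:, 0] == 0, place[:, 1], place[:, 0])
    insert = (p_minus + rl - p_plus) % L
    lo, hi = config.insert_bounds
    broken |= (insert < lo) | (insert > hi)
    return np.repeat(broken, 2)


@dataclass
class ConsensusSequence:
    """Sample consensus: per-position plurality base over an alignment pass.

    Ties and zero-coverage positions fall back to the reference base, and no
    insertions or deletions relative to the reference are emitted, so the
    consensus has exactly the reference length and preserves its numbering.
    """

    genome: CircularGenome
    depth: np.ndarray
    n_substituted: int


def base_count_matrix(
    aln: AlignmentSet, seqs: np.ndarray, seqs_rc: np.ndarray, chunk: int = 200_000
) -> np.ndarray:
    """(L, 4) matrix of aligned base counts per reference position."""
    L = aln.L
    counts = np.zeros(4 * L, dtype=np.int64)
    sel = np.flatnonzero(aln.accepted)
    rl = seqs.shape[1]
    full = sel[(aln.read_start[sel] == 0) & (aln.length[sel] == rl)]
    part = sel[(aln.read_start[sel] != 0) | (aln.length[sel] != rl)]
    arange_rl = np.arange(rl)
    for beg in range(0, len(full), chunk):
        idx = full[beg : beg + chunk]
        bases = np.where((aln.strand[idx] == 0)[:, None], seqs[idx], seqs_rc[idx])
        pos = (aln.ref_start[idx][:, None] + arange_rl[None, :]) % L
        flat = (pos * 4 + bases).ravel()
        keep = bases.ravel() < 4
        counts += np.bincount(flat[keep], minlength=4 * L)
    for i in part:
        codes = seqs_rc[i] if aln.strand[i] else seqs[i]
        s, ln = int(aln.read_start[i]), int(aln.length[i])
        bases = codes[s : s + ln]
        pos = (aln.ref_start[i] + np.arange(ln)) % L
        keep = bases < 4
        counts += np.bincount(pos[keep] * 4 + bases[keep], minlength=4 * L)
    return counts.reshape(L, 4)


def build_consensus(
    aln: AlignmentSet,
    seqs: np.ndarray,
    reference: CircularGenome,
    seqs_rc: np.ndarray | None = None,
) -> ConsensusSequence:
    """Per-position plurality consensus from (low-stringency) alignments."""
    if seqs_rc is None:
        seqs_rc = revcomp_codes(seqs)
    counts = base_count_matrix(aln, seqs, seqs_rc)
    depth = counts.sum(1)
    ref_codes = reference.codes
    best = counts.argmax(1).astype(np.uint8)
    ref_count = counts[np.arange(reference.L), np.minimum(ref_codes, 3)]
    top = counts.max(1)
    cons = np.where((depth == 0) | (ref_count == top), ref_codes, best)
    n_sub = int((cons != ref_codes).sum())
    genome = CircularGenome(
        name=f"{reference.name}_consensus",
        sequence=decode_seq(cons.astype(np.uint8)),
        numbering=reference.numbering,
    )
    return ConsensusSequence(genome=genome, depth=depth, n_substituted=n_sub)


@dataclass
class CoverageProfile:
    """Per-position read depth and its summary statistics."""

    depth: np.ndarray
    average: float
    sd_pct: float


def compute_coverage(aln: AlignmentSet) -> CoverageProfile:
    """Depth profile counting each aligned reference base once per read."""
    L = aln.L
    diff = np.zeros(L + 1, dtype=np.int64)
    sel = np.flatnonzero(aln.accepted)
    s = aln.ref_start[sel] % L
    e = s + aln.length[sel]
    nowrap = e <= L
    np.add.at(diff, s[nowrap], 1)
    np.add.at(diff, e[nowrap], -1)
    wrap = ~nowrap
    if wrap.any():
        np.add.at(diff, s[wrap], 1)
        diff[L] -= wrap.sum()
        diff[0] += wrap.sum()
        np.add.at(diff, e[wrap] - L, -1)
    depth = np.cumsum(diff[:L])
    total = int(aln.length[sel].sum())
    average = total / L
    sd_pct = float(depth.std() / average * 100) if average > 0 else 0.0
    return CoverageProfile(depth=depth, average=average, sd_pct=sd_pct)
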