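"""K-mer seeded, banded alignment of reads against annotated family loci.

Reads are compared only against the family's annotated locus sequences (the
simulation generates reads from loci only, so genome-wide mapping collapses
to this target set).  Candidate loci are found by exact k-mer seeds on either
strand; each candidate is then scored by a banded, read-global alignment
(every read base is consumed; the alignment may start and end anywhere in the
locus) around the best-supported seed diagonal.  Hits below a configurable
identity threshold are discarded — the threshold is how this package encodes
the contrast between a strict short-read aligner and a lenient long-read
aligner when confronted with high-error reads.

``brute_force_align`` is a deliberately independent implementation (full
unbanded, unseeded dynamic programming in NumPy) with the same scoring and
filtering, used as the test oracle for the seeded path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from numba import njit

from .family_synth import ParameterError, codes_to_seq, seq_to_codes
from .read_sim import ReadRecord

__all__ = [
    "AlignParams",
    "AlignmentHit",
    "KmerIndex",
    "IndexingError",
    "build_index",
    "align_read",
    "brute_force_align",
    "hits_to_tsv",
    "hits_to_sam",
]

_NEG = np.int32(-(10**7))


class IndexingError(ValueError):
    """A locus sequence is too short to index."""


@dataclass(frozen=True)
class AlignParams:
    """Aligner parameterization.

    ``band_fraction`` sets the band half-width as a fraction of the read
    length; ``min_identity`` is the accepted-hit threshold (0.8 default for
    accurate profiles, 0.9 "strict" / 0.6 "lenient" for high-error long
    reads); ``max_hits`` caps retained hits per read.
    """

    k: int = 13
    band_fraction: float = 0.25
    match: int = 1
    mismatch: int = -1
    gap: int = -2
    min_identity: float = 0.8
    max_hits: int = 100

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ParameterError("k must be >= 8")
        if not 0.0 < self.band_fraction <= 0.5:
            raise ParameterError("band_fraction must lie in (0, 0.5]")
        if not 0.0 <= self.min_identity <= 1.0:
            raise ParameterError("min_identity must lie in [0, 1]")


@dataclass(frozen=True)
class AlignmentHit:
    """One candidate (read, locus) alignment."""

    read_id: str
    locus_id: str
    score: int
    identity: float
    locus_offset: int
    strand: str = "+"
    matches: int = 0
    columns: int = 0


class KmerIndex:
    """Exact k-mer -> (locus, position) postings over the forward strands."""

    def __init__(self, loci: Mapping[str, str], k: int):
        self.k = k
        self.locus_ids: list[str] = sorted(loci)
        self.codes: list[np.ndarray] = []
        self.postings: dict[int, list[tuple[int, int]]] = {}
        for li, locus_id in enumerate(self.locus_ids):
            seq = loci[locus_id]
            if len(seq) < k:
                raise IndexingError(
                    f"locus {locus_id} shorter than k={k}; cannot index"
                )
            codes = seq_to_codes(seq)
            self.codes.append(codes)
            for pos, kmer in enumerate(_rolling_kmers(codes, k)):
                self.postings.setdefault(kmer, []).append((li, pos))

    def lookup(self, kmer: int) -> list[tuple[int, int]]:
        return self.postings.get(kmer, [])

    @property
    def n_postings(self) -> int:
        return sum(len(v) for v in self.postings.values())


def _rolling_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed k-mers at every position (vectorized rolling window)."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    # strided window multiply-accumulate
    kmers = np.zeros(n, dtype=np.int64)
    c = codes.astype(np.int64)
    for j in range(k):
        kmers += c[j : j + n] * weights[j]
    return kmers


def build_index(loci: Mapping[str, str], k: int = 13) -> KmerIndex:
    """Index all locus sequences for seeding (forward strand only)."""
    return KmerIndex(loci, k)


@njit(cache=True)
def _banded_dp(read, win, center, band, match, mismatch, gap):  # pragma: no cover
    """Read-global, locus-ends-free DP within a diagonal band.

    ``center`` is the window column on the read-start diagonal; row i may
    occupy columns [center+i-band, center+i+band].  Returns (score, end_col,
    H) with H retained for traceback.
    """
    m = read.shape[0]
    w = win.shape[0]
    H = np.full((m + 1, w + 1), _NEG, np.int32)
    lo0 = max(0, center - band)
    hi0 = min(w, center + band)
    for j in range(lo0, hi0 + 1):
        H[0, j] = 0
    for i in range(1, m + 1):
        lo = max(0, center + i - band)
        hi = min(w, center + i + band)
        if lo > w:
            break
        if lo == 0:
            H[i, 0] = H[i - 1, 0] + gap
            lo = 1
        ri = read[i - 1]
        for j in range(lo, hi + 1):
            s = match if win[j - 1] == ri else mismatch
            best = H[i - 1, j - 1] + s
            v = H[i - 1, j] + gap
            if v > best:
                best = v
            h = H[i, j - 1] + gap
            if h > best:
                best = h
            H[i, j] = best
    lo = max(0, center + m - band)
    hi = min(w, center + m + band)
    best_j = lo
    best = H[m, lo]
    for j in range(lo + 1, hi + 1):
        if H[m, j] > best:
            best = H[m, j]
            best_j = j
    return best, best_j, H


@njit(cache=True)
def _traceback(H, read, win, end_j, match, mismatch, gap):  # pragma: no cover
    """Walk the DP matrix back from (m, end_j); diag > up > left preference.

    Returns (matches, columns, start_col).
    """
    i = read.shape[0]
    j = end_j
    n_match = 0
    n_col = 0
    while i > 0:
        h = H[i, j]
        if j > 0:
            s = match if win[j - 1] == read[i - 1] else mismatch
            if h == H[i - 1, j - 1] + s:
                if s == match:
                    n_match += 1
                n_col += 1
                i -= 1
                j -= 1
                continue
        if h == H[i - 1, j] + gap:
            n_col += 1
            i -= 1
            continue
        # horizontal (gap in read)
        n_col += 1
        j -= 1
    return n_match, n_col, j


def _read_codes(read: "ReadRecord | str") -> tuple[str, np.ndarray]:
    if isinstance(read, str):
        return "", seq_to_codes(read)
    return read.read_id, seq_to_codes(read.sequence)


def _postprocess(hits: list[AlignmentHit], params: AlignParams) -> list[AlignmentHit]:
    """Identity filter, per-locus dedup, score ordering, truncation."""
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        if hit.identity < params.min_identity:
            continue
        prev = best.get(hit.locus_id)
        if prev is None or (hit.score, hit.strand == "+") > (
            prev.score,
            prev.strand == "+",
        ):
            best[hit.locus_id] = hit
    ordered = sorted(best.values(), key=lambda h: (-h.score, h.locus_id))
    return ordered[: params.max_hits]


def align_read(
    read: "ReadRecord | str",
    index: KmerIndex,
    loci: Optional[Mapping[str, str]] = None,
    params: AlignParams = AlignParams(),
) -> list[AlignmentHit]:
    """Seeded, banded alignment of one read against the indexed loci.

    Candidates are loci sharing at least one exact k-mer with the read on
    either strand; each is aligned in a window around its best-supported
    seed diagonal.  Hits are identity-filtered, sorted by descending score
    (ties by locus_id) and truncated to ``max_hits``.
    """
    read_id, fwd = _read_codes(read)
    m = fwd.size
    k = index.k
    if m < k:
        return []
    rc = (3 - fwd)[::-1]
    band = max(1, int(np.ceil(params.band_fraction * m)))

    hits: list[AlignmentHit] = []
    for strand, codes in (("+", fwd), ("-", rc)):
        # diagonal votes per candidate locus
        diag_votes: dict[int, dict[int, int]] = {}
        for pos, kmer in enumerate(_rolling_kmers(codes, k)):
            for li, lpos in index.lookup(int(kmer)):
                d = lpos - pos
                votes = diag_votes.setdefault(li, {})
                votes[d] = votes.get(d, 0) + 1
        for li, votes in diag_votes.items():
            diag = max(votes, key=lambda d: (votes[d], -abs(d)))
            locus_codes = index.codes[li]
            L = locus_codes.size
            ws = min(max(0, diag - band), L)
            we = min(L, max(diag, 0) + m + band)
            win = locus_codes[ws:we]
            if win.size == 0:
                continue
            center = diag - ws
            score, end_j, H = _banded_dp(
                fwd if strand == "+" else rc,
                win,
                center,
                band,
                params.match,
                params.mismatch,
                params.gap,
            )
            if score <= _NEG // 2:
                continue
            n_match, n_col, start_j = _traceback(
                H,
                fwd if strand == "+" else rc,
                win,
                end_j,
                params.match,
                params.mismatch,
                params.gap,
            )
            identity = n_match / n_col if n_col else 0.0
            hits.append(
                AlignmentHit(
                    read_id=read_id,
                    locus_id=index.locus_ids[li],
                    score=int(score),
                    identity=identity,
                    locus_offset=ws + start_j,
                    strand=strand,
                    matches=n_match,
                    columns=n_col,
                )
            )
    return _postprocess(hits, params)


# ---------------------------------------------------------------------------
# Brute-force oracle: full DP, no seeds, no band.  Kept independent of the
# numba kernel on purpose (separate code path for oracle-equivalence tests).


def _full_dp_rows(read: np.ndarray, locus: np.ndarray, match, mismatch, gap):
    """Full read-global/locus-ends-free DP matrix via row-wise NumPy scans."""
    m, w = read.size, locus.size
    c = -gap  # positive horizontal decay
    jar = np.arange(w + 1, dtype=np.int64) * c
    H = np.empty((m + 1, w + 1), dtype=np.int64)
    H[0] = 0
    for i in range(1, m + 1):
        sub = np.where(locus == read[i - 1], match, mismatch)
        diag = H[i - 1, :-1] + sub
        up = H[i - 1, 1:] + gap
        v = np.empty(w + 1, dtype=np.int64)
        v[0] = H[i - 1, 0] + gap
        v[1:] = np.maximum(diag, up)
        # horizontal gap runs: H[i,j] = max_{k<=j} v[k] + gap*(j-k)
        H[i] = np.maximum.accumulate(v + jar) - jar
    return H


def _traceback_py(H, read, locus, end_j, match, mismatch, gap):
    i = read.size
    j = end_j
    n_match = n_col = 0
    while i > 0:
        h = H[i, j]
        if j > 0:
            s = match if locus[j - 1] == read[i - 1] else mismatch
            if h == H[i - 1, j - 1] + s:
                n_match += s == match
                n_col += 1
                i -= 1
                j -= 1
                continue
        if h == H[i - 1, j] + gap:
            n_col += 1
            i -= 1
            continue
        n_col += 1
        j -= 1
    return n_match, n_col, j


def brute_force_align(
    read: "ReadRecord | str",
    loci: Mapping[str, str],
    params: AlignParams = AlignParams(),
) -> list[AlignmentHit]:
    """Align ``read`` against every locus on both strands with full DP.

    Same scoring, filtering and ordering as :func:`align_read`, but without
    seeding or banding.  Intended for small instances (test oracle).
    """
    read_id, fwd = _read_codes(read)
    rc = (3 - fwd)[::-1]
    hits: list[AlignmentHit] = []
    for locus_id in sorted(loci):
        locus_codes = seq_to_codes(loci[locus_id])
        for strand, codes in (("+", fwd), ("-", rc)):
            H = _full_dp_rows(codes, locus_codes, params.match, params.mismatch, params.gap)
            end_j = int(np.argmax(H[-1]))
            score = int(H[-1, end_j])
            n_match, n_col, start_j = _traceback_py(
                H, codes, locus_codes, end_j, params.match, params.mismatch, params.gap
            )
            identity = n_match / n_col if n_col else 0.0
            hits.append(
                AlignmentHit(
                    read_id=read_id,
                    locus_id=locus_id,
                    score=score,
                    identity=identity,
                    locus_offset=start_j,
                    strand=strand,
                    matches=n_match,
                    columns=n_col,
                )
            )
    return _postprocess(hits, params)


# ---------------------------------------------------------------------------
# Export


def hits_to_tsv(hits_by_read: Mapping[str, Sequence[AlignmentHit]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tlocus_id\tscore\tidentity\tlocus_offset\tstrand\n")
        for read_id in hits_by_read:
            for h in hits_by_read[read_id]:
                fh.write(
                    f"{read_id}\t{h.locus_id}\t{h.score}\t{h.identity:.6g}\t"
                    f"{h.locus_offset}\t{h.strand}\n"
                )


def _cigar_for_hit(read_codes: np.ndarray, locus_codes: np.ndarray, params: AlignParams):
    """Recompute an explicit alignment path for SAM output (small data only)."""
    H = _full_dp_rows(read_codes, locus_codes, params.match, params.mismatch, params.gap)
    end_j = int(np.argmax(H[-1]))
    i, j = read_codes.size, end_j
    ops: list[str] = []
    while i > 0:
        h = H[i, j]
        if j > 0:
            s = params.match if locus_codes[j - 1] == read_codes[i - 1] else params.mismatch
            if h == H[i - 1, j - 1] + s:
                ops.append("M")
                i -= 1
                j -= 1
                continue
        if h == H[i - 1, j] + params.gap:
            ops.append("I")
            i -= 1
            continue
        ops.append("D")
        j -= 1
    ops.reverse()
    cigar = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1][1] += 1
        else:
            cigar.append([op, 1])
    return j, "".join(f"{n}{op}" for op, n in cigar)


def hits_to_sam(
    reads: Sequence[ReadRecord],
    hits_by_read: Mapping[str, Sequence[AlignmentHit]],
    loci: Mapping[str, str],
    path: str | Path,
    params: AlignParams = AlignParams(),
) -> None:
    """Write retained hits as SAM with loci as reference sequences.

    The best hit per read is primary; further hits carry the secondary flag.
    Explicit CIGARs are recomputed per exported record, so this is meant for
    small hit tables (interoperability, not throughput).
    """
    import pysam

    ids = sorted(loci)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": lid, "LN": len(loci[lid])} for lid in ids],
    }
    tid = {lid: n for n, lid in enumerate(ids)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in reads:
            hits = hits_by_read.get(rec.read_id, [])
            if not hits:
                a = pysam.AlignedSegment(out.header)
                a.query_name = rec.read_id
                a.query_sequence = rec.sequence
                a.query_qualities = pysam.qualitystring_to_array(rec.qualities)
                a.flag = 4
                out.write(a)
                continue
            fwd = seq_to_codes(rec.sequence)
            for rank, hit in enumerate(hits):
                codes = fwd if hit.strand == "+" else (3 - fwd)[::-1]
                start, cigar = _cigar_for_hit(
                    codes, seq_to_codes(loci[hit.locus_id]), params
                )
                a = pysam.AlignedSegment(out.header)
                a.query_name = rec.read_id
                a.query_sequence = codes_to_seq(codes)
                a.query_qualities = pysam.qualitystring_to_array(rec.qualities)
                a.reference_id = tid[hit.locus_id]
                a.reference_start = start
                a.cigarstring = cigar
                a.mapping_quality = 60 if len(hits) == 1 else 3
                a.flag = (16 if hit.strand == "-" else 0) | (256 if rank else 0)
                a.set_tag("AS", hit.score)
                out.write(a)
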