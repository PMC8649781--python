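"""Intergenic windows, background model, and shared inverted repeats.

The transposon ends are located by finding pairs of intergenic regions that
share inverted repeats.  The repeat search emulates a word-size-4 BLASTn of
each region against the reverse complement of the other: exact 4-mer seeds
are grouped by diagonal, extended ungapped (+2 match / -3 mismatch), and
promising segments are refined by a banded affine local alignment
(open -5, extend -2, band width ±4).  Alignments are accepted when the
aligned length is 15-40 columns with at most two gap openings and six
mismatches; a score floor of 10 stands in for the permissive E-value cutoff
of the original search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Contig, OrfRecord, Params
from .seq import N_CODE, encode, revcomp

MATCH = 2
MISMATCH = -3
GAP_OPEN = -5   # first base of a gap costs GAP_OPEN + GAP_EXTEND
GAP_EXTEND = -2
MIN_SCORE = 10  # reporting floor for local alignments
WORD = 4
BAND = 4


@dataclass
class IntergenicRegion:
    region_id: str
    contig_id: str
    start: int
    end: int
    sequence: str
    side: str  # left-of-tnsB | right-of-tnsB | outside

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InvertedRepeatMatch:
    region_a: str
    region_b: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    length: int      # alignment columns, gaps included
    mismatches: int
    gaps: int        # gap openings


@dataclass
class EndPairCandidate:
    region_pair: tuple[str, str]
    shared_irs: list[InvertedRepeatMatch]
    min_dist_to_tnsb: int


# ---------------------------------------------------------------------------
# Window extraction and background

def extract_window(
    contig: Contig,
    orfs: list[OrfRecord],
    tnsb_orf: OrfRecord,
    params: Params | None = None,
) -> list[IntergenicRegion]:
    """Maximal non-ORF spans longer than ``min_intergenic_len`` within
    ``window`` bp on either side of the tnsB ORF, clipped to the window and
    the contig edges."""
    params = params or Params()
    contig_orfs = [o for o in orfs if o.contig_id == contig.id]
    if tnsb_orf.orf_id not in {o.orf_id for o in contig_orfs}:
        raise KeyError(f"tnsB ORF {tnsb_orf.orf_id} not in ORF table for {contig.id}")
    ws = max(0, tnsb_orf.start - params.window)
    we = min(contig.length, tnsb_orf.end + params.window)

    covered = sorted((o.start, o.end) for o in contig_orfs)
    merged: list[list[int]] = []
    for s, e in covered:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    regions: list[IntergenicRegion] = []
    pos = ws
    bounds = [iv for iv in merged if iv[1] > ws and iv[0] < we]
    for s, e in bounds + [[we, we]]:
        gs, ge = pos, min(s, we)
        if ge - gs > params.min_intergenic_len:
            if ge <= tnsb_orf.start:
                side = "left-of-tnsB"
            elif gs >= tnsb_orf.end:
                side = "right-of-tnsB"
            else:
                side = "outside"
            regions.append(
                IntergenicRegion(
                    region_id=f"{contig.id}:{gs}-{ge}",
                    contig_id=contig.id,
                    start=gs,
                    end=ge,
                    sequence=contig.sequence[gs:ge],
                    side=side,
                )
            )
        pos = max(pos, e)
    return regions


def build_background(regions: list[IntergenicRegion]) -> np.ndarray:
    """Order-0 nucleotide frequencies over the pooled regions, with a
    pseudocount of 1 per letter.  N is excluded from the counts."""
    if not regions:
        raise ValueError("need at least one region to build a background")
    counts = np.ones(4, dtype=float)
    usable = 0
    for r in regions:
        enc = encode(r.sequence)
        enc = enc[enc != N_CODE]
        usable += enc.size
        counts += np.bincount(enc, minlength=4)
    if usable == 0:
        raise ValueError("regions contain no usable (non-N) nucleotides")
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Inverted-repeat search

def _seed_diagonals(a: np.ndarray, brc: np.ndarray) -> set[int]:
    """Diagonals (i - j) carrying at least one exact WORD-mer match between
    ``a`` and ``brc``."""
    la, lb = len(a), len(brc)
    if la < WORD or lb < WORD:
        return set()
    index: dict[tuple, list[int]] = {}
    for j in range(lb - WORD + 1):
        w = brc[j : j + WORD]
        if (w == N_CODE).any():
            continue
        index.setdefault(tuple(w.tolist()), []).append(j)
    diags: set[int] = set()
    for i in range(la - WORD + 1):
        w = a[i : i + WORD]
        if (w == N_CODE).any():
            continue
        for j in index.get(tuple(w.tolist()), ()):
            diags.add(i - j)
    return diags


def _best_segments(match: np.ndarray) -> list[tuple[int, int, int]]:
    """All maximal positive-scoring ungapped segments (+2/-3) along one
    diagonal, as (start, end, score) in diagonal coordinates."""
    score = np.where(match, MATCH, MISMATCH)
    segments = []
    best, best_s, best_e = 0, 0, 0
    cur, cur_s = 0, 0
    for k, v in enumerate(score):
        if cur == 0:
            cur_s = k
        cur += v
        if cur <= 0:
            if best >= MIN_SCORE:
                segments.append((best_s, best_e, best))
            cur, best = 0, 0
        elif cur > best:
            best, best_s, best_e = cur, cur_s, k + 1
    if best >= MIN_SCORE:
        segments.append((best_s, best_e, best))
    return segments


def _banded_local(a: np.ndarray, b: np.ndarray, band: int = BAND):
    """Banded affine Smith-Waterman around the main diagonal of two short
    windows.  Returns (a_start, a_end, b_start, b_end, length, mismatches,
    gap_openings, score) for the best local alignment, or None."""
    la, lb = len(a), len(b)
    NEG = -(10 ** 9)
    H = [[0] * (lb + 1) for _ in range(la + 1)]
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (horizontal)
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (vertical)
    best, bi, bj = 0, 0, 0
    for i in range(1, la + 1):
        jlo = max(1, i - band)
        jhi = min(lb, i + band)
        for j in range(jlo, jhi + 1):
            E[i][j] = max(E[i][j - 1] + GAP_EXTEND, H[i][j - 1] + GAP_OPEN + GAP_EXTEND)
            F[i][j] = max(F[i - 1][j] + GAP_EXTEND, H[i - 1][j] + GAP_OPEN + GAP_EXTEND)
            ai, bj_ = a[i - 1], b[j - 1]
            sub = MATCH if (ai == bj_ and ai != N_CODE) else MISMATCH
            h = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best < MIN_SCORE:
        return None
    # traceback
    i, j = bi, bj
    length = mismatches = gap_opens = 0
    state = "H"
    while i > 0 and j > 0 and H[i][j] > 0:
        if state == "H":
            ai, bj_ = a[i - 1], b[j - 1]
            sub = MATCH if (ai == bj_ and ai != N_CODE) else MISMATCH
            if H[i][j] == E[i][j]:
                state = "E"
                continue
            if H[i][j] == F[i][j]:
                state = "F"
                continue
            length += 1
            if sub == MISMATCH:
                mismatches += 1
            i, j = i - 1, j - 1
        elif state == "E":
            gap_opens += 1
            while j > 0 and E[i][j] != H[i][j - 1] + GAP_OPEN + GAP_EXTEND:
                length += 1
                j -= 1
            length += 1
            j -= 1
            state = "H"
        else:  # F
            gap_opens += 1
            while i > 0 and F[i][j] != H[i - 1][j] + GAP_OPEN + GAP_EXTEND:
                length += 1
                i -= 1
            length += 1
            i -= 1
            state = "H"
    return (i, bi, j, bj, length, mismatches, gap_opens, best)


def _banded_local_all(a: np.ndarray, b: np.ndarray, band: int = BAND,
                      depth: int = 8) -> list[tuple]:
    """All non-overlapping local alignments in a window: take the best, then
    recurse into the flanking sub-windows (BLAST finds multiple HSPs along a
    diagonal the same way)."""
    aln = _banded_local(a, b, band)
    if aln is None or depth == 0:
        return []
    ai, aj, bi, bj = aln[:4]
    out = [aln]
    for sub in _banded_local_all(a[:ai], b[:bi], band, depth - 1):
        out.append(sub)
    for sub in _banded_local_all(a[aj:], b[bj:], band, depth - 1):
        si, sj, ti, tj, *rest = sub
        out.append((si + aj, sj + aj, ti + bj, tj + bj, *rest))
    return out


def _pair_matches(seq_a: str, seq_b: str, params: Params):
    """Accepted inverted-repeat alignments between seq_a and seq_b, as
    tuples of coordinates in a and b plus (length, mismatches, gaps)."""
    a = encode(seq_a)
    brc = encode(revcomp(seq_b))
    la, lb = len(a), len(brc)
    results = {}
    for d in sorted(_seed_diagonals(a, brc)):
        i0 = max(0, d)
        j0 = max(0, -d)
        n = min(la - i0, lb - j0)
        if n < WORD:
            continue
        sa = a[i0 : i0 + n]
        sb = brc[j0 : j0 + n]
        match = (sa == sb) & (sa != N_CODE)
        pad0 = params.ir_max_len + 4
        segments = _best_segments(match)
        # merge nearby segments on the diagonal into one alignment window
        clusters: list[list[int]] = []
        for ks, ke, _score in sorted(segments):
            if clusters and ks - clusters[-1][1] < pad0:
                clusters[-1][1] = max(clusters[-1][1], ke)
            else:
                clusters.append([ks, ke])
        for ks, ke in clusters:
            alns = None
            for pad in (pad0, 3 * pad0):
                # clip both starts by the same amount so the seed diagonal
                # stays the main diagonal of the banded alignment window
                cut = max(0, pad - (i0 + ks), pad - (j0 + ks))
                awin = (i0 + ks - pad + cut, min(la, i0 + ke + pad))
                bwin = (j0 + ks - pad + cut, min(lb, j0 + ke + pad))
                alns = _banded_local_all(a[awin[0] : awin[1]], brc[bwin[0] : bwin[1]])
                # an alignment flush with a window edge may be a truncated
                # over-long repeat: retry once with a wider window
                wa, wb = awin[1] - awin[0], bwin[1] - bwin[0]
                touches = any(
                    (ai <= 1 and awin[0] > 0) or (bi <= 1 and bwin[0] > 0)
                    or (aj >= wa - 1 and awin[1] < la) or (bj >= wb - 1 and bwin[1] < lb)
                    for ai, aj, bi, bj, *_ in alns
                )
                if not touches:
                    break
            for ai, aj, bi, bj, length, mm, gaps, score in alns:
                a_start, a_end = awin[0] + ai, awin[0] + aj
                jrc_start, jrc_end = bwin[0] + bi, bwin[0] + bj
                b_start, b_end = len(seq_b) - jrc_end, len(seq_b) - jrc_start
                key = (a_start, a_end, b_start, b_end)
                prev = results.get(key)
                if prev is None or score > prev[3]:
                    results[key] = (mm, gaps, length, score)
    # containment cull before filtering: an alignment overlapping a
    # higher-scoring one in both regions is a re-trimming of the same
    # physical repeat, not a distinct shared repeat
    ranked = sorted(
        ((k[0], k[1], k[2], k[3], *v) for k, v in results.items()),
        key=lambda t: (-t[7], t[4] + t[5], t[0], t[2]),
    )
    distinct = []
    for t in ranked:
        dominated = any(
            t[0] < k[1] and k[0] < t[1] and t[2] < k[3] and k[2] < t[3]
            for k in distinct
        )
        if not dominated:
            distinct.append(t)
    out = [
        (t[0], t[1], t[2], t[3], t[6], t[4], t[5])
        for t in distinct
        if params.ir_min_len <= t[6] <= params.ir_max_len
        and t[4] <= params.ir_max_mismatches
        and t[5] <= params.ir_max_gaps
    ]
    out.sort(key=lambda t: (t[5] + t[6], -t[4], t[0], t[2]))
    return out[: params.max_hsps]


def find_inverted_repeats(
    regions: list[IntergenicRegion],
    params: Params | None = None,
    pair_filter=None,
) -> list[InvertedRepeatMatch]:
    """All accepted inverted repeats between every pair of distinct regions.

    Records are emitted for both orderings of each pair, with coordinates
    swapped, so the output is symmetric.  ``pair_filter(ra, rb)``, when
    given, restricts which region pairs are aligned (for example, only
    pairs that could flank the transposase).
    """
    params = params or Params()
    matches: list[InvertedRepeatMatch] = []
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            ra, rb = regions[i], regions[j]
            if pair_filter is not None and not pair_filter(ra, rb):
                continue
            for a_s, a_e, b_s, b_e, length, mm, gaps in _pair_matches(
                ra.sequence, rb.sequence, params
            ):
                matches.append(
                    InvertedRepeatMatch(ra.region_id, rb.region_id, a_s, a_e,
                                        b_s, b_e, length, mm, gaps)
                )
                matches.append(
                    InvertedRepeatMatch(rb.region_id, ra.region_id, b_s, b_e,
                                        a_s, a_e, length, mm, gaps)
                )
    return matches


# ---------------------------------------------------------------------------
# End-pair candidates

def region_tnsb_distance(region: IntergenicRegion, tnsb_orf: OrfRecord) -> int:
    """Distance from the region's nearest edge to the strand-aware start
    codon of the tnsB ORF."""
    sc = tnsb_orf.start_codon
    if region.end <= sc:
        return sc - region.end
    if region.start >= sc:
        return region.start - sc
    return 0


def select_end_pairs(
    matches: list[InvertedRepeatMatch],
    regions: list[IntergenicRegion],
    tnsb_orf: OrfRecord,
    params: Params | None = None,
) -> list[EndPairCandidate]:
    """Region pairs flanking tnsB that share two or more inverted repeats,
    with at least one region less than 20 kb from the tnsB start codon."""
    params = params or Params()
    by_id = {r.region_id: r for r in regions}
    shared: dict[tuple[str, str], list[InvertedRepeatMatch]] = {}
    for m in matches:
        if m.region_a not in by_id or m.region_b not in by_id:
            raise KeyError(f"match references unknown region {m.region_a}/{m.region_b}")
        key = tuple(sorted((m.region_a, m.region_b)))
        if m.region_a == key[0]:  # count each unordered pair once
            shared.setdefault(key, []).append(m)
    out: list[EndPairCandidate] = []
    for (ra_id, rb_id), irs in sorted(shared.items()):
        if len(irs) < params.pair_min_shared_ir:
            continue
        ra, rb = by_id[ra_id], by_id[rb_id]
        left, right = (ra, rb) if ra.start <= rb.start else (rb, ra)
        if not (left.end <= tnsb_orf.start and right.start >= tnsb_orf.end):
            continue
        dist = min(region_tnsb_distance(ra, tnsb_orf),
                   region_tnsb_distance(rb, tnsb_orf))
        if dist >= params.pair_max_tnsb_dist:
            continue
        out.append(EndPairCandidate((ra_id, rb_id), irs, dist))
    return out
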