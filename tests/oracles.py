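"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity by the most direct method available
(full dynamic programming, exhaustive enumeration, position-by-position
counting) without sharing code paths with the package implementation.
"""

from __future__ import annotations

import numpy as np

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -3, -5, -2
COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(COMP)[::-1]


def smith_waterman(a: str, b: str):
    """Full affine local alignment of two strings; returns the single best
    alignment as (a_start, a_end, b_start, b_end, length, mismatches,
    gap_openings, score, contains_word4)."""
    la, lb = len(a), len(b)
    NEG = -10**9
    H = np.zeros((la + 1, lb + 1))
    E = np.full((la + 1, lb + 1), NEG, dtype=float)
    F = np.full((la + 1, lb + 1), NEG, dtype=float)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i, j] = max(E[i, j - 1] + GAP_EXTEND, H[i, j - 1] + GAP_OPEN + GAP_EXTEND)
            F[i, j] = max(F[i - 1, j] + GAP_EXTEND, H[i - 1, j] + GAP_OPEN + GAP_EXTEND)
            sub = MATCH if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else MISMATCH
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
    bi, bj = np.unravel_index(np.argmax(H), H.shape)
    best = H[bi, bj]
    if best <= 0:
        return None
    i, j = int(bi), int(bj)
    length = mism = gaps = run = 0
    state = "H"
    while i > 0 and j > 0 and H[i, j] > 0:
        if state == "H":
            if H[i, j] == E[i, j]:
                state = "E"
                continue
            if H[i, j] == F[i, j]:
                state = "F"
                continue
            match = a[i - 1] == b[j - 1] and a[i - 1] != "N"
            length += 1
            if match:
                run += 1
            else:
                mism += 1
                run = 0
            i, j = i - 1, j - 1
        elif state == "E":
            gaps += 1
            run = 0
            while j > 0 and E[i, j] != H[i, j - 1] + GAP_OPEN + GAP_EXTEND:
                length += 1
                j -= 1
            length += 1
            j -= 1
            state = "H"
        else:
            gaps += 1
            run = 0
            while i > 0 and F[i, j] != H[i - 1, j] + GAP_OPEN + GAP_EXTEND:
                length += 1
                i -= 1
            length += 1
            i -= 1
            state = "H"
    # word-4 check: any exact ungapped 4-mer shared inside the aligned spans
    asub, bsub = a[i:int(bi)], b[j:int(bj)]
    words = {asub[k : k + 4] for k in range(len(asub) - 3) if "N" not in asub[k : k + 4]}
    has_word = any(bsub[k : k + 4] in words for k in range(len(bsub) - 3))
    return (i, int(bi), j, int(bj), length, mism, gaps, float(best), has_word)


def ir_accept(a: str, b: str, min_len=15, max_len=40, max_mm=6, max_gaps=2,
              min_score=10) -> bool:
    """Oracle accept/reject for an inverted repeat between a and b: best
    local alignment of a against revcomp(b), subject to the word-size-4
    seeding the search method prescribes, passes the length/gap/mismatch
    filters."""
    aln = smith_waterman(a, revcomp(b))
    if aln is None:
        return False
    _, _, _, _, length, mism, gaps, score, has_word = aln
    return (
        has_word
        and score >= min_score
        and min_len <= length <= max_len
        and mism <= max_mm
        and gaps <= max_gaps
    )


def bh_stepup(pvalues, m=None):
    """Textbook definition: q_i = min over j with p_j >= p_i of m*p_j/rank_j."""
    p = list(pvalues)
    m = m or len(p)
    order = sorted(range(len(p)), key=lambda i: p[i])
    rank = {i: r + 1 for r, i in enumerate(order)}
    q = []
    for i in range(len(p)):
        vals = [m * p[j] / rank[j] for j in range(len(p)) if p[j] >= p[i]]
        q.append(min(1.0, min(vals)))
    return q


def enumerate_pvalues(int_mat, background):
    """Exact distribution of integer PWM scores by enumerating all 4^w
    windows; returns dict score -> P(score' >= score)."""
    w = int_mat.shape[0]
    bg = np.asarray(background)
    scores = {}
    stack = [(0, 0, 1.0)]
    while stack:
        col, s, prob = stack.pop()
        if col == w:
            scores[s] = scores.get(s, 0.0) + prob
            continue
        for b in range(4):
            stack.append((col + 1, s + int(int_mat[col, b]), prob * bg[b]))
    out = {}
    for s in scores:
        out[s] = sum(p for s2, p in scores.items() if s2 >= s)
    return out


def best_offset_alignment(pa: np.ndarray, pb: np.ndarray, min_overlap=10):
    """Exhaustive scan over all offsets and both orientations of motif B,
    maximizing mean per-column Pearson r."""
    best = None
    for orient, mb in (("+", pb), ("-", pb[::-1, ::-1])):
        wb = mb.shape[0]
        for off in range(-(wb - 1), pa.shape[0]):
            lo, hi = max(0, off), min(pa.shape[0], off + wb)
            if hi - lo < min_overlap:
                continue
            rs = []
            for i in range(lo, hi):
                x, y = pa[i], mb[i - off]
                xc, yc = x - x.mean(), y - y.mean()
                d = np.sqrt((xc**2).sum() * (yc**2).sum())
                rs.append(0.0 if d == 0 else float((xc * yc).sum() / d))
            r = float(np.mean(rs))
            if best is None or r > best[2]:
                best = (off, orient, r)
    return best


def intergenic_positions(contig_len, orf_spans, window_span):
    """Position-membership oracle: positions inside the window covered by no
    ORF, grouped into maximal runs."""
    ws, we = window_span
    covered = np.zeros(contig_len, dtype=bool)
    for s, e in orf_spans:
        covered[s:e] = True
    runs = []
    pos = ws
    while pos < we:
        if not covered[pos]:
            start = pos
            while pos < we and not covered[pos]:
                pos += 1
            runs.append((start, pos))
        else:
            pos += 1
    return runs


def hamming_hits(query: str, target: str, max_mm: int):
    """All positions where query matches target with <= max_mm mismatches
    (N never matches)."""
    k = len(query)
    out = []
    for i in range(len(target) - k + 1):
        mm = sum(
            1
            for x, y in zip(query, target[i : i + k])
            if x != y or x == "N" or y == "N"
        )
        if mm <= max_mm:
            out.append((i, mm))
    return out


def lca_by_counting(lineages, threshold=0.8):
    n = len(lineages)
    depth = 0
    result = []
    while True:
        counts = {}
        for lin in lineages:
            if len(lin) > depth:
                counts[tuple(lin[: depth + 1])] = counts.get(tuple(lin[: depth + 1]), 0) + 1
        if not counts:
            break
        path, c = max(sorted(counts.items()), key=lambda kv: kv[1])
        if c >= threshold * n and list(path[:-1]) == result:
            result = list(path)
            depth += 1
        else:
            break
    return result if result else "unknown"
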