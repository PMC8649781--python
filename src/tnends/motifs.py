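"""PWM motif discovery, scanning and comparison.

Discovery fits an any-number-of-repetitions (ANR) site model by
expectation-maximization over both strands of a candidate end-region pair,
seeded from enriched exact 8-mers, with motif widths 15-20 selected by an
E-value-like significance (the probability under the order-0 background of
the training sites' scores, Bonferroni-scaled by the number of candidate
start positions).  Scanning scores every non-N window by log-odds against
the background, converts scores to exact p-values with a dynamic program
over discretized column score distributions, and controls the
false-discovery rate across all scanned windows with Benjamini-Hochberg
q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Params
from .seq import N_CODE, encode, revcomp_arr


@dataclass(frozen=True)
class MotifSite:
    """A training-site occurrence recorded during discovery (region
    coordinates, forward frame)."""

    region_id: str
    start: int
    end: int
    strand: str


@dataclass
class PWM:
    motif_id: str
    probs: np.ndarray            # width x 4, columns sum to 1
    nsites: int = 0
    significance: float = 1.0    # E-value-like discovery score
    sites: list[MotifSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM probs must be width x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1 within 1e-9")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            motif_id=self.motif_id + "_rc",
            probs=self.probs[::-1, ::-1].copy(),
            nsites=self.nsites,
            significance=self.significance,
        )

    def information_content(self, background: np.ndarray | None = None) -> float:
        """Mean information content per column, in bits."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        return float(np.mean(np.sum(self.probs * np.log2(self.probs / bg), axis=1)))


@dataclass(frozen=True)
class MotifOccurrence:
    motif_id: str
    region_id: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float
    qvalue: float


# ---------------------------------------------------------------------------
# Scoring and exact p-values

def log_odds_score(pwm: PWM, window: str, background: np.ndarray) -> float:
    """Sum over columns of log2(p_col(base) / bg(base)); N is rejected."""
    enc = encode(window)
    if enc.size != pwm.width:
        raise ValueError(f"window length {enc.size} != motif width {pwm.width}")
    if (enc == N_CODE).any():
        raise ValueError("window contains N")
    lod = np.log2(pwm.probs / np.asarray(background))
    return float(lod[np.arange(pwm.width), enc].sum())


class PValueTable:
    """Exact null distribution of PWM scores under an order-0 background.

    Column log-odds are shifted to be non-negative and discretized to
    integers (rounding down, which makes reported p-values conservative);
    the distribution of the integer total over random background windows is
    obtained by convolving the per-column distributions.  ``sf[s]`` is
    P(integer score >= s).
    """

    def __init__(self, pwm: PWM, background: np.ndarray, granularity: int = 4096):
        if granularity < 1000:
            raise ValueError("granularity must be >= 1000 bins")
        bg = np.asarray(background, dtype=float)
        lod = np.log2(pwm.probs / bg)
        self.col_min = lod.min(axis=1)
        shifted = lod - self.col_min[:, None]
        span = shifted.max(axis=1).sum()
        self.step = span / granularity if span > 0 else 1.0
        self.int_mat = np.floor(shifted / self.step).astype(np.int64)
        self.lod = lod
        max_total = int(self.int_mat.max(axis=1).sum())
        pmf = np.zeros(max_total + 1)
        pmf[0] = 1.0
        top = 0
        for c in range(pwm.width):
            new = np.zeros_like(pmf)
            for b in range(4):
                s = int(self.int_mat[c, b])
                new[s : top + s + 1] += bg[b] * pmf[: top + 1]
            pmf = new
            top += int(self.int_mat[c].max())
        self.pmf = pmf
        self.sf = np.cumsum(pmf[::-1])[::-1]

    def pvalue_int(self, s: int | np.ndarray) -> float | np.ndarray:
        s = np.clip(s, 0, None)
        out = np.where(s >= self.sf.size, 0.0, self.sf[np.minimum(s, self.sf.size - 1)])
        return float(out) if np.isscalar(s) or np.ndim(s) == 0 else out

    def pvalue(self, score: float) -> float:
        """P-value for a real-valued log-odds score (bits)."""
        s = int(np.floor((score - self.col_min.sum()) / self.step))
        return float(self.pvalue_int(max(s, 0))) if s < self.sf.size else 0.0


def pvalue_table(pwm: PWM, background: np.ndarray, granularity: int = 4096) -> PValueTable:
    return PValueTable(pwm, background, granularity)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg

def bh_qvalues(pvalues, m: int | None = None) -> np.ndarray:
    """Step-up BH q-values, input order preserved.

    ``m`` overrides the number of tests when the supplied p-values are the
    surviving subset of a larger scan (they must then be the m smallest).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m_eff = int(m) if m is not None else p.size
    if m_eff < p.size:
        raise ValueError("m must be >= number of p-values supplied")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1)
    q_sorted = p[order] * m_eff / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Scanning

def _window_int_scores(enc: np.ndarray, int_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer scores for every window plus a validity mask (no N)."""
    w = int_mat.shape[0]
    n = enc.size - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(enc, w)
    valid = ~(win == N_CODE).any(axis=1)
    safe = np.where(win == N_CODE, 0, win)
    scores = int_mat[np.arange(w)[None, :], safe].sum(axis=1)
    return scores, valid


def scan_regions(
    pwm: PWM,
    regions,
    background: np.ndarray,
    params: Params | None = None,
    granularity: int = 4096,
) -> list[MotifOccurrence]:
    """FIMO-style scan of a motif over intergenic regions.

    Every non-N window on both strands is a test; windows with p below the
    nominal ceiling enter BH correction with m equal to the total test
    count, and occurrences with q at or below ``scan_fdr`` are returned.
    Overlapping hits of the motif on the same region are resolved greedily
    by lowest p-value regardless of strand, so a near-palindromic motif
    reports one site per physical location.
    """
    params = params or Params()
    if not regions:
        return []
    tab_f = PValueTable(pwm, background, granularity)
    tab_r = PValueTable(pwm.reverse_complement(), background, granularity)
    w = pwm.width
    m_total = 0
    cand: list[tuple[float, float, str, int, str]] = []  # (p, score, region, start, strand)
    for region in regions:
        enc = encode(region.sequence)
        for strand, tab in (("+", tab_f), ("-", tab_r)):
            scores, valid = _window_int_scores(enc, tab.int_mat)
            m_total += int(valid.sum())
            if scores.size == 0:
                continue
            pv = tab.pvalue_int(scores)
            keep = valid & (pv <= params.scan_p_ceiling)
            for pos in np.flatnonzero(keep):
                bits = float(tab.lod[np.arange(w), enc[pos : pos + w]].sum())
                cand.append((float(pv[pos]), bits, region.region_id, int(pos), strand))
    if not cand:
        return []
    qvals = bh_qvalues([c[0] for c in cand], m=m_total)
    occs = [
        MotifOccurrence(pwm.motif_id, rid, pos, pos + w, strand, bits, p, float(q))
        for (p, bits, rid, pos, strand), q in zip(cand, qvals)
        if q <= params.scan_fdr
    ]
    # overlap resolution per region (site-level dedup): an occurrence is
    # dropped only when a strictly better-p occurrence overlaps it, so the
    # outcome is invariant under reverse-complementing the scan
    occs.sort(key=lambda o: (o.pvalue, o.region_id, o.start, o.strand))
    kept: list[MotifOccurrence] = []
    taken: dict[str, list[tuple[int, int, float]]] = {}
    for o in occs:
        spans = taken.setdefault(o.region_id, [])
        if any(o.start < e and s < o.end and p < o.pvalue for s, e, p in spans):
            continue
        spans.append((o.start, o.end, o.pvalue))
        kept.append(o)
    kept.sort(key=lambda o: (o.region_id, o.start, o.strand))
    return kept


# ---------------------------------------------------------------------------
# Discovery

class _Strand:
    """One scanning frame (region x strand) with its forward-coordinate map."""

    def __init__(self, region_id: str, enc: np.ndarray, strand: str):
        self.region_id = region_id
        self.strand = strand
        self.enc = enc if strand == "+" else revcomp_arr(enc)
        self.length = enc.size

    def fwd_span(self, pos: int, w: int) -> tuple[int, int]:
        if self.strand == "+":
            return pos, pos + w
        return self.length - pos - w, self.length - pos


def _usable_windows(frame: _Strand, w: int, masked: np.ndarray) -> np.ndarray:
    """Start positions (frame coordinates) of windows free of N and of
    previously masked positions."""
    n = frame.enc.size - w + 1
    if n <= 0:
        return np.zeros(0, dtype=int)
    win = np.lib.stride_tricks.sliding_window_view(frame.enc, w)
    ok = ~(win == N_CODE).any(axis=1)
    if masked.any():
        m = masked if frame.strand == "+" else masked[::-1]
        mwin = np.lib.stride_tricks.sliding_window_view(m, w)
        ok &= ~mwin.any(axis=1)
    return np.flatnonzero(ok)


def _enriched_seeds(frames, masked, background, n_seeds: int, k: int = 8):
    """Canonical k-mers (min of word and its reverse complement) ranked by
    observed/expected count over all usable windows."""
    counts: dict[tuple, int] = {}
    bg = np.asarray(background)
    for frame, mask in zip(frames, masked):
        if frame.strand != "+":
            continue  # canonicalization covers the minus strand
        for pos in _usable_windows(frame, k, mask):
            word = tuple(frame.enc[pos : pos + k].tolist())
            rc = tuple((3 - np.array(word))[::-1].tolist())
            counts[min(word, rc)] = counts.get(min(word, rc), 0) + 1
    scored = []
    for word, c in counts.items():
        if c < 2:
            continue
        exp = np.prod(bg[list(word)])
        scored.append((c / max(exp, 1e-300), c, word))
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return [np.array(w[2]) for w in scored[:n_seeds]]


def _em_fit(frames, masked, seed_word, w, background, params, rng):
    """EM under the ANR model at fixed width; returns (pwm_probs, sites) or
    None when no usable windows exist."""
    bg = np.asarray(background)
    window_sets = []
    for frame, mask in zip(frames, masked):
        pos = _usable_windows(frame, w, mask)
        if pos.size:
            mat = np.lib.stride_tricks.sliding_window_view(frame.enc, w)[pos]
            window_sets.append((frame, pos, mat))
    if not window_sets:
        return None
    all_mat = np.concatenate([m for _, _, m in window_sets])
    n = all_mat.shape[0]
    logb = np.log(bg)[all_mat].sum(axis=1)

    probs = np.tile(bg, (w, 1))
    off = (w - seed_word.size) // 2
    for i, b in enumerate(seed_word):
        col = np.full(4, 0.1)
        col[b] = 0.7
        probs[off + i] = col
    probs = probs + rng.dirichlet(np.ones(4), size=w) * 0.02
    probs /= probs.sum(axis=1, keepdims=True)

    lam = min(((params.motif_min_sites + params.motif_max_sites) / 2) / n, 0.3)
    cols = np.arange(w)
    Z = None
    for _ in range(40):
        logf = np.log(probs)[cols[None, :], all_mat].sum(axis=1)
        log_ratio = np.log(lam) + logf - (np.log1p(-lam) + logb)
        Z = 1.0 / (1.0 + np.exp(-np.clip(log_ratio, -500, 500)))
        counts = np.full((w, 4), params.pseudocount)
        np.add.at(counts, (cols[None, :], all_mat), Z[:, None])
        new = counts / counts.sum(axis=1, keepdims=True)
        if np.abs(new - probs).max() < 1e-4:
            probs = new
            break
        probs = new

    # greedy non-overlapping site selection in forward coordinates
    order = np.argsort(-Z, kind="stable")
    bounds = np.cumsum([0] + [m.shape[0] for _, _, m in window_sets])
    chosen: list[tuple[int, MotifSite]] = []
    taken: dict[str, list[tuple[int, int]]] = {}

    def try_take(gidx: int, zmin: float) -> bool:
        k = np.searchsorted(bounds, gidx, side="right") - 1
        frame, pos, _ = window_sets[k]
        if Z[gidx] < zmin:
            return False
        s, e = frame.fwd_span(int(pos[gidx - bounds[k]]), w)
        spans = taken.setdefault(frame.region_id, [])
        if any(s < e2 and s2 < e for s2, e2 in spans):
            return False
        spans.append((s, e))
        chosen.append((gidx, MotifSite(frame.region_id, s, e, frame.strand)))
        return True

    for gidx in order:
        if len(chosen) >= params.motif_max_sites:
            break
        try_take(int(gidx), 0.5)
    if len(chosen) < params.motif_min_sites:
        for gidx in order:
            if len(chosen) >= params.motif_min_sites:
                break
            try_take(int(gidx), 0.0)
    if len(chosen) < params.motif_min_sites:
        return None

    counts = np.full((w, 4), params.pseudocount)
    for gidx, _ in chosen:
        np.add.at(counts, (cols, all_mat[gidx]), 1.0)
    final = counts / counts.sum(axis=1, keepdims=True)
    site_windows = all_mat[[g for g, _ in chosen]]
    return final, [s for _, s in chosen], site_windows, n


def _significance(site_windows, n_windows, background, granularity=2048):
    """E-value-like motif significance.

    Null: refit a PWM to k random background windows and measure its total
    log-likelihood ratio (per-column multinomial G-statistic, distribution
    computed exactly by dynamic programming over the column compositions).
    Because the null includes the fit, a motif over-fitted to background
    noise is not significant.  The LLR p-value is Bonferroni-scaled by
    C(N, k) candidate site selections (union bound, in log space)."""
    k, w = site_windows.shape
    bg = np.asarray(background, dtype=float)
    counts = np.zeros((w, 4))
    np.add.at(counts, (np.arange(w)[None, :].repeat(k, 0), site_windows), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(counts / (k * bg))
    observed = float(np.where(counts > 0, terms, 0.0).sum())  # nats

    # exact per-column null: counts ~ Multinomial(k, bg), LLR of the MLE fit
    comps, probs_c = _multinomial_llr_atoms(k, bg)
    step = max(comps.max(), 1e-9) * w / granularity
    atom_bins = np.ceil(comps / step).astype(int)        # ceil: conservative
    obs_bin = int(np.floor(observed / step))
    pmf = np.zeros(atom_bins.max() * w + 1)
    pmf[0] = 1.0
    top = 0
    for _ in range(w):
        new = np.zeros_like(pmf)
        for b, pc in zip(atom_bins, probs_c):
            new[b : top + b + 1] += pc * pmf[: top + 1]
        pmf = new
        top += int(atom_bins.max())
    sf = np.cumsum(pmf[::-1])[::-1]
    p_llr = float(sf[obs_bin]) if 0 <= obs_bin < sf.size else (1.0 if obs_bin < 0 else 0.0)
    log_comb = float(
        np.log(np.arange(n_windows, n_windows - k, -1)).sum()
        - np.log(np.arange(1, k + 1)).sum()
    )
    log_e = log_comb + (np.log(p_llr) if p_llr > 0 else np.log(1e-300))
    return float(np.exp(min(log_e, 0.0)))


def _multinomial_llr_atoms(k: int, bg: np.ndarray):
    """All base-count compositions of k sites in one column with their
    multinomial probabilities and LLR values (nats)."""
    from itertools import combinations_with_replacement
    from math import lgamma

    atoms = {}
    for combo in combinations_with_replacement(range(4), k):
        n = np.bincount(np.array(combo), minlength=4)
        key = tuple(n.tolist())
        if key in atoms:
            continue
        logp = lgamma(k + 1) - sum(lgamma(c + 1) for c in n) + float(
            (n * np.log(bg)).sum()
        )
        llr = float(np.where(n > 0, n * np.log(np.maximum(n, 1) / (k * bg)), 0.0).sum())
        atoms[key] = (max(llr, 0.0), np.exp(logp))
    vals = np.array([v[0] for v in atoms.values()])
    probs = np.array([v[1] for v in atoms.values()])
    return vals, probs


def discover_motifs(region_a, region_b, background, params: Params | None = None,
                    seed: int = 0) -> list[PWM]:
    """Discover up to ``motif_max_n`` PWMs shared by two candidate end
    regions, under the ANR site model on both strands.

    Only motifs whose significance is at most ``motif_evalue_max`` are
    returned; the training sites of each accepted motif are masked before
    the next round.  Deterministic for a fixed seed.
    """
    params = params or Params()
    for r in (region_a, region_b):
        if len(r.sequence) < params.motif_max_w:
            raise ValueError(f"region {r.region_id} shorter than motif_max_w")
    rng = np.random.default_rng(seed)
    enc_a, enc_b = encode(region_a.sequence), encode(region_b.sequence)
    frames = [
        _Strand(region_a.region_id, enc_a, "+"),
        _Strand(region_a.region_id, enc_a, "-"),
        _Strand(region_b.region_id, enc_b, "+"),
        _Strand(region_b.region_id, enc_b, "-"),
    ]
    masked = {region_a.region_id: np.zeros(enc_a.size, bool),
              region_b.region_id: np.zeros(enc_b.size, bool)}

    def frame_masks():
        return [masked[f.region_id] for f in frames]

    found: list[PWM] = []
    for round_no in range(params.motif_max_n):
        seeds = _enriched_seeds(frames, frame_masks(), background, n_seeds=3)
        if not seeds:
            break
        best = None
        for seed_word in seeds:
            for w in range(params.motif_min_w, params.motif_max_w + 1):
                fit = _em_fit(frames, frame_masks(), seed_word, w, background,
                              params, rng)
                if fit is None:
                    continue
                probs, sites, site_windows, n_win = fit
                sig = _significance(site_windows, n_win, background)
                if best is None or sig < best[0]:
                    best = (sig, probs, sites)
        if best is None or best[0] > params.motif_evalue_max:
            break
        sig, probs, sites = best
        found.append(
            PWM(
                motif_id=f"m{round_no + 1}",
                probs=probs,
                nsites=len(sites),
                significance=sig,
                sites=sites,
            )
        )
        for s in sites:
            masked[s.region_id][s.start : s.end] = True
    return found


# ---------------------------------------------------------------------------
# Motif comparison

@dataclass(frozen=True)
class MotifAlignment:
    offset: int
    orientation: str  # "+" or "-"
    mean_r: float
    overlap: int


def _column_r(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return 0.0
    return float((xc * yc).sum() / denom)


def compare_motifs(pwm_a: PWM, pwm_b: PWM,
                   params: Params | None = None) -> MotifAlignment | None:
    """Best ungapped alignment of two PWMs over all offsets and both
    orientations, scored by the mean per-column Pearson correlation of the
    probability columns; None when no offset reaches the minimum overlap."""
    params = params or Params()
    wa, wb = pwm_a.width, pwm_b.width
    best: MotifAlignment | None = None
    for orientation, b_probs in (("+", pwm_b.probs), ("-", pwm_b.probs[::-1, ::-1])):
        for offset in range(-(wb - 1), wa):
            lo = max(0, offset)
            hi = min(wa, offset + wb)
            ov = hi - lo
            if ov < params.tomtom_min_overlap:
                continue
            rs = [
                _column_r(pwm_a.probs[i], b_probs[i - offset])
                for i in range(lo, hi)
            ]
            mean_r = float(np.mean(rs))
            cand = MotifAlignment(offset, orientation, mean_r, ov)
            if (best is None or mean_r > best.mean_r
                    or (mean_r == best.mean_r and orientation == "+" and best.orientation == "-")):
                best = cand
    return best


def motifs_aligned(pwm_a: PWM, pwm_b: PWM, params: Params | None = None) -> bool:
    params = params or Params()
    aln = compare_motifs(pwm_a, pwm_b, params)
    return aln is not None and aln.mean_r >= params.tomtom_min_r
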