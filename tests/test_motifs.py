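"""Motif scoring, exact p-values, BH, discovery and comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from tnends.io import Params
from tnends.motifs import (PWM, PValueTable, bh_qvalues, compare_motifs,
                           discover_motifs, log_odds_score, pvalue_table,
                           scan_regions)
from tnends.repeats import IntergenicRegion, build_background
from tnends.synth import _rand_seq, _sample_site, random_pwm

UNIFORM = np.full(4, 0.25)


def _region(rid, seq):
    return IntergenicRegion(rid, "c", 0, len(seq), seq, "outside")


def _pwm_from_consensus(s, p=0.97):
    idx = {c: i for i, c in enumerate("ACGT")}
    probs = np.full((len(s), 4), (1 - p) / 3)
    for i, c in enumerate(s):
        probs[i, idx[c]] = p
    return PWM("m", probs)


# ---------------------------------------------------------------------------
# log-odds scoring

def test_background_pwm_scores_zero_everywhere():
    pwm = PWM("bg", np.tile(UNIFORM, (6, 1)))
    for window in ("ACGTAC", "AAAAAA", "GGGCCC"):
        assert log_odds_score(pwm, window, UNIFORM) == pytest.approx(0.0)


def test_width_one_closed_form():
    probs = np.array([[0.97, 0.01, 0.01, 0.01]])
    pwm = PWM("w1", probs)
    assert log_odds_score(pwm, "A", UNIFORM) == pytest.approx(np.log2(0.97 / 0.25))


def test_log_odds_matches_summation_oracle(rng):
    for _ in range(25):
        w = int(rng.integers(1, 25))
        probs = rng.dirichlet(np.ones(4), size=w)
        bg = rng.dirichlet(np.ones(4) * 10)
        pwm = PWM("m", probs)
        window = "".join("ACGT"[i] for i in rng.integers(0, 4, size=w))
        direct = sum(
            np.log2(probs[i, "ACGT".index(c)] / bg["ACGT".index(c)])
            for i, c in enumerate(window)
        )
        assert log_odds_score(pwm, window, bg) == pytest.approx(direct, abs=1e-12)


def test_log_odds_rejects_bad_windows():
    pwm = _pwm_from_consensus("ACGTA")
    with pytest.raises(ValueError):
        log_odds_score(pwm, "ACGT", UNIFORM)
    with pytest.raises(ValueError):
        log_odds_score(pwm, "ACGNN", UNIFORM)


# ---------------------------------------------------------------------------
# p-value table

def test_pvalue_width_one_max_score():
    pwm = _pwm_from_consensus("A")
    tab = pvalue_table(pwm, UNIFORM)
    max_int = int(tab.int_mat.max())
    assert tab.pvalue_int(max_int) == pytest.approx(0.25)


def test_pvalue_boundaries_and_monotonicity(rng):
    pwm = PWM("m", rng.dirichlet(np.ones(4), size=8))
    tab = pvalue_table(pwm, UNIFORM)
    assert tab.pvalue_int(0) == pytest.approx(1.0)          # p(min score) = 1
    assert tab.pvalue_int(tab.sf.size) == 0.0               # p(> max score) = 0
    assert np.all(np.diff(tab.sf) <= 1e-15)                 # non-increasing


def test_pvalue_dp_equals_exhaustive_enumeration(rng):
    """DP survival function equals enumeration over all 4^w windows at the
    same discretization, for every width up to 6."""
    for w in range(1, 7):
        probs = rng.dirichlet(np.ones(4), size=w)
        bg = rng.dirichlet(np.ones(4) * 5)
        tab = pvalue_table(PWM("m", probs), bg)
        expect = oracles.enumerate_pvalues(tab.int_mat, bg)
        for s, p in expect.items():
            assert tab.pvalue_int(s) == pytest.approx(p, abs=1e-3)


def test_pvalue_table_rejects_coarse_granularity(rng):
    pwm = PWM("m", rng.dirichlet(np.ones(4), size=5))
    with pytest.raises(ValueError):
        pvalue_table(pwm, UNIFORM, granularity=999)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg

def test_bh_single_pvalue():
    assert bh_qvalues([0.01]) == pytest.approx([0.01])


def test_bh_hand_computed_stepup():
    q = bh_qvalues([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)


def test_bh_matches_independent_oracle(rng):
    for _ in range(10):
        p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
        assert np.allclose(bh_qvalues(p), oracles.bh_stepup(p), atol=1e-12)
    # with a larger test universe m
    p = rng.uniform(0, 1e-3, size=12)
    assert np.allclose(bh_qvalues(p, m=500), oracles.bh_stepup(p, m=500), atol=1e-12)


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
def test_bh_monotone_in_p(pvals):
    q = bh_qvalues(pvals)
    order = np.argsort(pvals)
    assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_qvalues([0.5, 1.5])


# ---------------------------------------------------------------------------
# scanning

def test_scan_recovers_planted_site(rng, params):
    pwm = _pwm_from_consensus("ACGTACGTACGTACGTAC", p=0.9)
    seq = _rand_seq(rng, 150, 0.5) + pwm.consensus + _rand_seq(rng, 150, 0.5)
    occs = scan_regions(pwm, [_region("r1", seq)], UNIFORM, params)
    assert occs, "planted consensus site not recovered"
    best = min(occs, key=lambda o: o.pvalue)
    assert (best.start, best.end, best.strand) == (150, 168, "+")


def test_scan_empty_region_list(params):
    pwm = _pwm_from_consensus("ACGTACGTACGTACG")
    assert scan_regions(pwm, [], UNIFORM, params) == []


def test_scan_qvalues_match_bh_oracle(rng, params):
    """Occurrence q-values equal an independent step-up BH computed over the
    full candidate p-value list (m = all scanned windows, both strands)."""
    from tnends.seq import encode

    pwm = _pwm_from_consensus("ACGTACGTACGTACGTAC", p=0.85)
    regions = [
        _region("r1", _rand_seq(rng, 200, 0.5) + pwm.consensus + _rand_seq(rng, 200, 0.5)),
        _region("r2", _rand_seq(rng, 300, 0.5)),
    ]
    relaxed = Params(scan_fdr=0.999, scan_p_ceiling=0.05)
    occs = scan_regions(pwm, regions, UNIFORM, relaxed)
    assert occs
    # rebuild the candidate list independently
    tabs = {"+": PValueTable(pwm, UNIFORM),
            "-": PValueTable(pwm.reverse_complement(), UNIFORM)}
    cands, m = [], 0
    w = pwm.width
    for r in regions:
        enc = encode(r.sequence)
        for strand, tab in tabs.items():
            for pos in range(r.length - w + 1):
                m += 1
                s = int(tab.int_mat[np.arange(w), enc[pos:pos + w]].sum())
                p = float(tab.pvalue_int(s))
                if p <= relaxed.scan_p_ceiling:
                    cands.append(((r.region_id, pos, strand), p))
    qs = oracles.bh_stepup([p for _, p in cands], m=m)
    expect = {key: q for (key, _), q in zip(cands, qs)}
    for o in occs:
        assert o.qvalue == pytest.approx(expect[(o.region_id, o.start, o.strand)],
                                         rel=1e-9)


def test_scan_strand_symmetry(rng, params):
    """Scanning the reverse-complemented region with the reverse-complemented
    PWM mirrors the occurrences with identical scores and p-values."""
    from tnends.seq import revcomp

    pwm = PWM("m", np.asarray(random_pwm(16, 1.6, rng).probs))
    seq = _rand_seq(rng, 120, 0.5) + _sample_site(pwm, rng) + _rand_seq(rng, 120, 0.5)
    occs_f = scan_regions(pwm, [_region("r", seq)], UNIFORM, params)
    occs_r = scan_regions(pwm.reverse_complement(),
                          [_region("r", revcomp(seq))], UNIFORM, params)
    # reverse-complementing both the region and the motif preserves the
    # strand of each physical match; only the coordinates mirror
    L = len(seq)
    mirrored = {(L - o.end, L - o.start, o.strand,
                 round(o.pvalue, 12)) for o in occs_r}
    direct = {(o.start, o.end, o.strand, round(o.pvalue, 12)) for o in occs_f}
    assert direct == mirrored


# ---------------------------------------------------------------------------
# discovery

def _planted_pair(seed, nsites=3, bits=1.6, L=300, width=18):
    rng = np.random.default_rng(seed)
    pwm = random_pwm(width, bits, rng)
    regions, truths = [], []
    for rid in ("ra", "rb"):
        seq = list(_rand_seq(rng, L, 0.5))
        sites, pos = [], 10
        for _ in range(nsites):
            pos += int(rng.integers(10, 40))
            site = _sample_site(pwm, rng)
            if rid == "rb":  # opposite strand on the second region
                from tnends.seq import revcomp
                site = revcomp(site)
            seq[pos:pos + width] = site
            sites.append((pos, pos + width))
            pos += width
        regions.append(_region(rid, "".join(seq)))
        truths.append(sites)
    return regions, truths, pwm


def test_discovery_recovers_planted_motif(params):
    regions, truths, planted = _planted_pair(seed=11)
    bg = build_background(regions)
    pwms = discover_motifs(regions[0], regions[1], bg, params, seed=11)
    assert pwms, "no motif discovered on planted input"
    first = pwms[0]
    assert params.motif_min_w <= first.width <= params.motif_max_w
    for site in first.sites:
        truth = truths[0] if site.region_id == "ra" else truths[1]
        assert any(site.start < e and s < site.end for s, e in truth)
    assert first.significance <= params.motif_evalue_max
    strands = {s.strand for s in first.sites}
    assert strands == {"+", "-"}  # arrays planted on opposite strands


def test_discovery_planted_recovery_rate(params):
    """Over 100 seeded trials at >=1.5 bits/column and 3 sites per region,
    the first discovered motif is the planted one (>=80% of its training
    sites on planted coordinates) in at least 95 trials."""
    recovered = 0
    for seed in range(100):
        regions, truths, _ = _planted_pair(seed=500 + seed, bits=1.5)
        bg = build_background(regions)
        pwms = discover_motifs(regions[0], regions[1], bg, params, seed=seed)
        if not pwms:
            continue
        first = pwms[0]
        on = sum(
            any(s.start < e and st < s.end
                for st, e in (truths[0] if s.region_id == "ra" else truths[1]))
            for s in first.sites
        )
        recovered += on >= 0.8 * len(first.sites)
    assert recovered >= 95


def test_discovery_null_input_scores_worse_than_planted(params):
    rng = np.random.default_rng(3)
    null_regions = [_region("ra", _rand_seq(rng, 300, 0.5)),
                    _region("rb", _rand_seq(rng, 300, 0.5))]
    bg = build_background(null_regions)
    null_pwms = discover_motifs(null_regions[0], null_regions[1], bg, params, seed=3)
    planted_regions, _, _ = _planted_pair(seed=3)
    bgp = build_background(planted_regions)
    planted_pwms = discover_motifs(planted_regions[0], planted_regions[1], bgp,
                                   params, seed=3)
    null_best = min((p.significance for p in null_pwms), default=1.0)
    assert planted_pwms[0].significance < null_best


def test_discovery_deterministic(params):
    regions, _, _ = _planted_pair(seed=21)
    bg = build_background(regions)
    a = discover_motifs(regions[0], regions[1], bg, params, seed=77)
    b = discover_motifs(regions[0], regions[1], bg, params, seed=77)
    assert len(a) == len(b)
    for x, y in zip(a, b):
        assert np.array_equal(x.probs, y.probs) and x.sites == y.sites


def test_discovery_rejects_short_regions(params):
    short = _region("ra", "ACGTACGTACGT")
    ok = _region("rb", "ACGT" * 30)
    with pytest.raises(ValueError):
        discover_motifs(short, ok, UNIFORM, params, seed=0)


# ---------------------------------------------------------------------------
# comparison

def test_compare_motif_with_itself(rng, params):
    pwm = PWM("m", rng.dirichlet(np.ones(4), size=15))
    aln = compare_motifs(pwm, pwm, params)
    assert (aln.offset, aln.orientation) == (0, "+")
    assert aln.mean_r == pytest.approx(1.0)


def test_compare_below_min_overlap_is_no_alignment(rng, params):
    a = PWM("a", rng.dirichlet(np.ones(4), size=9))
    b = PWM("b", rng.dirichlet(np.ones(4), size=9))
    assert compare_motifs(a, b, params) is None  # max overlap 9 < 10


def test_compare_matches_exhaustive_offset_oracle(rng, params):
    for _ in range(10):
        wa, wb = int(rng.integers(10, 21)), int(rng.integers(10, 21))
        a = PWM("a", rng.dirichlet(np.ones(4), size=wa))
        b = PWM("b", rng.dirichlet(np.ones(4), size=wb))
        got = compare_motifs(a, b, params)
        expect = oracles.best_offset_alignment(a.probs, b.probs)
        assert got.mean_r == pytest.approx(expect[2], abs=1e-12)


def test_compare_finds_reverse_complement_match(rng, params):
    probs = random_pwm(16, 1.8, rng).probs
    a = PWM("a", probs)
    b = PWM("b", probs[::-1, ::-1].copy())
    aln = compare_motifs(a, b, params)
    assert aln.orientation == "-" and aln.mean_r == pytest.approx(1.0)
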