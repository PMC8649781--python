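"""Window extraction, background model, inverted repeats, end pairs."""

import numpy as np
import pytest

import oracles
from tnends.io import Contig, OrfRecord, Params
from tnends.repeats import (IntergenicRegion, build_background, extract_window,
                            find_inverted_repeats, select_end_pairs)
from tnends.seq import revcomp


def _region(rid, seq, start=0, side="outside", contig="c1"):
    return IntergenicRegion(rid, contig, start, start + len(seq), seq, side)


# ---------------------------------------------------------------------------
# extract_window

def test_gap_length_threshold_is_strict(dna_factory, rng):
    # 49-bp and 50-bp gaps excluded; 51-bp kept ("longer than 50 bp")
    seq = dna_factory(rng, 3000)
    contig = Contig("c1", seq)
    orfs = [
        OrfRecord("a", "c1", 0, 1000, "+"),
        OrfRecord("tnsB", "c1", 1049, 2000, "+"),   # 49-bp gap
        OrfRecord("b", "c1", 2051, 2900, "+"),      # 51-bp gap
    ]
    regions = extract_window(contig, orfs, orfs[1])
    assert [(r.start, r.end) for r in regions] == [(2000, 2051), (2900, 3000)]
    assert regions[0].side == "right-of-tnsB"


def test_degenerate_gene_content_clips_to_window(dna_factory, rng):
    contig = Contig("c1", dna_factory(rng, 300_000))
    tnsb = OrfRecord("tnsB", "c1", 150_000, 151_500, "+")
    regions = extract_window(contig, [tnsb], tnsb)
    assert len(regions) == 2
    left, right = regions
    assert (left.start, left.end) == (150_000 - 125_000, 150_000)
    assert (right.start, right.end) == (151_500, 151_500 + 125_000)


def test_missing_tnsb_raises(dna_factory, rng):
    contig = Contig("c1", dna_factory(rng, 1000))
    tnsb = OrfRecord("tnsB", "c1", 100, 400, "+")
    with pytest.raises(KeyError):
        extract_window(contig, [], tnsb)


def test_window_matches_interval_complement_oracle(dna_factory, rng, params):
    for trial in range(20):
        trng = np.random.default_rng(trial)
        L = 40_000
        contig = Contig("c1", dna_factory(trng, L))
        orfs, pos = [], 0
        for i in range(30):
            pos += int(trng.integers(0, 400))
            end = min(pos + int(trng.integers(100, 2000)), L)
            if end - pos < 100:
                break
            orfs.append(OrfRecord(f"o{i}", "c1", pos, end, "+"))
            pos = end
        tnsb = orfs[len(orfs) // 2]
        got = [(r.start, r.end) for r in extract_window(contig, orfs, tnsb, params)]
        ws = max(0, tnsb.start - params.window)
        we = min(L, tnsb.end + params.window)
        runs = oracles.intergenic_positions(L, [(o.start, o.end) for o in orfs],
                                            (ws, we))
        expect = [(s, e) for s, e in runs if e - s > params.min_intergenic_len]
        assert got == expect


# ---------------------------------------------------------------------------
# background

def test_background_pseudocount_arithmetic():
    r = _region("r1", "AAAA")
    bg = build_background([r])
    assert np.allclose(bg, [5 / 8, 1 / 8, 1 / 8, 1 / 8])


def test_background_converges_to_uniform():
    r = _region("r1", "ACGT" * 2500)
    bg = build_background([r])
    assert np.allclose(bg, 0.25, atol=1e-3)


def test_background_recovers_gc(dna_factory, rng):
    r = _region("r1", dna_factory(rng, 10_000, gc=0.6))
    bg = build_background([r])
    assert abs((bg[1] + bg[2]) - 0.6) < 0.02
    assert bg.sum() == pytest.approx(1.0, abs=1e-9)


def test_background_errors():
    with pytest.raises(ValueError):
        build_background([])
    with pytest.raises(ValueError):
        build_background([_region("r1", "NNNN")])


# ---------------------------------------------------------------------------
# inverted repeats

def test_planted_exact_22bp_inverted_repeat(dna_factory, rng, params):
    core = dna_factory(rng, 22)
    a = dna_factory(rng, 100) + core + dna_factory(rng, 100)
    b = dna_factory(rng, 80) + revcomp(core) + dna_factory(rng, 90)
    matches = find_inverted_repeats([_region("ra", a), _region("rb", b)], params)
    fwd = [m for m in matches if m.region_a == "ra"]
    assert fwd, "planted 22-bp inverted repeat not found"
    best = min(fwd, key=lambda m: m.mismatches + m.gaps)
    assert best.mismatches == 0 and best.gaps == 0
    assert best.a_start <= 100 + 22 and best.a_end >= 100  # overlaps planted


def test_14bp_repeat_below_length_floor(dna_factory, params):
    rng = np.random.default_rng(7)
    core = dna_factory(rng, 14)
    a = dna_factory(rng, 120) + core + dna_factory(rng, 120)
    b = dna_factory(rng, 120) + revcomp(core) + dna_factory(rng, 120)
    matches = find_inverted_repeats([_region("ra", a), _region("rb", b)], params)
    planted = [
        m for m in matches if m.region_a == "ra"
        and m.a_start < 134 and m.a_end > 120 and m.mismatches == 0
    ]
    assert planted == []


def test_no_match_violates_filter_caps(dna_factory, rng, params):
    regions = [_region(f"r{i}", dna_factory(rng, 400)) for i in range(4)]
    for m in find_inverted_repeats(regions, params):
        assert params.ir_min_len <= m.length <= params.ir_max_len
        assert m.mismatches <= params.ir_max_mismatches
        assert m.gaps <= params.ir_max_gaps


def test_symmetry_of_match_set(dna_factory, rng, params):
    core = dna_factory(rng, 20)
    a = dna_factory(rng, 60) + core + dna_factory(rng, 60)
    b = dna_factory(rng, 50) + revcomp(core) + dna_factory(rng, 50)
    ra, rb = _region("ra", a), _region("rb", b)
    matches = find_inverted_repeats([ra, rb], params)
    fwd = {(m.a_start, m.a_end, m.b_start, m.b_end)
           for m in matches if m.region_a == "ra"}
    rev = {(m.b_start, m.b_end, m.a_start, m.a_end)
           for m in matches if m.region_a == "rb"}
    assert fwd == rev


def _mutate(core, n_mm, n_gaps, rng):
    s = list(core)
    for pos in rng.choice(len(s), size=n_mm, replace=False):
        s[pos] = rng.choice([c for c in "ACGT" if c != s[pos]])
    for _ in range(n_gaps):
        pos = int(rng.integers(2, len(s) - 2))
        s.pop(pos)
    return "".join(s)


def test_agreement_with_smith_waterman_oracle(dna_factory, params):
    """Accept/reject of planted repeats (0-6 mismatches, 0-2 gaps, lengths
    12-45) agrees with a full quadratic affine-DP oracle applying the same
    filters and the word-size-4 seeding the search prescribes."""
    agree = 0
    total = 0
    for trial in range(100):
        rng = np.random.default_rng(20_000 + trial)
        la, lb = int(rng.integers(80, 301)), int(rng.integers(80, 301))
        core_len = int(rng.integers(12, 46))
        core = dna_factory(rng, core_len)
        n_mm = int(rng.integers(0, 5))
        n_gaps = int(rng.integers(0, 3))
        mutated = _mutate(core, min(n_mm, core_len // 4), n_gaps, rng)
        pa = int(rng.integers(0, la - core_len))
        pb = int(rng.integers(0, lb - len(mutated)))
        a = dna_factory(rng, la)
        b = dna_factory(rng, lb)
        a = a[:pa] + core + a[pa + core_len:]
        b = b[:pb] + revcomp(mutated) + b[pb + len(mutated):]

        matches = find_inverted_repeats([_region("ra", a), _region("rb", b)], params)
        found = any(
            m.region_a == "ra"
            and m.a_start < pa + core_len and m.a_end > pa
            and m.b_start < pb + len(mutated) and m.b_end > pb
            for m in matches
        )
        # oracle on the planted neighbourhood
        a_win = a[max(0, pa - 15): pa + core_len + 15]
        b_win = b[max(0, pb - 15): pb + len(mutated) + 15]
        expect = oracles.ir_accept(a_win, b_win)
        total += 1
        agree += found == expect
    assert agree == total, f"finder disagreed with SW oracle on {total - agree} cases"


def test_reverse_complement_mirror(dna_factory, rng, params):
    """Reverse-complementing both region sequences yields the mirrored match
    set (coordinates mapped by x -> L - x)."""
    core = dna_factory(rng, 20)
    a = dna_factory(rng, 70) + core + dna_factory(rng, 70)
    b = dna_factory(rng, 60) + revcomp(core) + dna_factory(rng, 60)
    m1 = find_inverted_repeats([_region("ra", a), _region("rb", b)], params)
    m2 = find_inverted_repeats(
        [_region("ra", revcomp(a)), _region("rb", revcomp(b))], params
    )
    la, lb = len(a), len(b)
    set1 = {(m.a_start, m.a_end, m.b_start, m.b_end)
            for m in m1 if m.region_a == "ra"}
    set2 = {(la - m.a_end, la - m.a_start, lb - m.b_end, lb - m.b_start)
            for m in m2 if m.region_a == "ra"}
    assert set1 == set2


# ---------------------------------------------------------------------------
# end pairs

def _tnsb_at(start, end):
    return OrfRecord("tnsB", "c1", start, end, "+")


def test_end_pair_requires_two_shared_repeats(dna_factory, rng, params):
    core = dna_factory(rng, 22)
    a = dna_factory(rng, 80) + core + dna_factory(rng, 80)
    b = dna_factory(rng, 80) + revcomp(core) + dna_factory(rng, 80)
    ra = _region("ra", a, start=1000, side="left-of-tnsB")
    rb = _region("rb", b, start=9000, side="right-of-tnsB")
    matches = find_inverted_repeats([ra, rb], params)
    tnsb = _tnsb_at(4000, 5500)
    n_shared = len([m for m in matches if m.region_a == "ra"])
    pairs = select_end_pairs(matches, [ra, rb], tnsb, params)
    if n_shared == 1:
        assert pairs == []
    else:
        assert len(pairs) >= 1  # chance second repeat: rule satisfied


def test_end_pair_distance_and_flanking_rules(dna_factory, rng, params):
    core1, core2 = dna_factory(rng, 22), dna_factory(rng, 20)
    a = core1 + dna_factory(rng, 30) + core2 + dna_factory(rng, 30)
    b = dna_factory(rng, 30) + revcomp(core2) + dna_factory(rng, 30) + revcomp(core1)
    # both regions > 20 kb from tnsB start codon: rejected
    ra = _region("ra", a, start=1000, side="left-of-tnsB")
    rb = _region("rb", b, start=80_000, side="right-of-tnsB")
    matches = find_inverted_repeats([ra, rb], params)
    assert len([m for m in matches if m.region_a == "ra"]) >= 2
    far_tnsb = _tnsb_at(27_000, 28_500)
    assert select_end_pairs(matches, [ra, rb], far_tnsb, params) == []
    # one region within 20 kb: accepted
    near_tnsb = _tnsb_at(15_000, 16_500)
    pairs = select_end_pairs(matches, [ra, rb], near_tnsb, params)
    assert len(pairs) == 1 and pairs[0].min_dist_to_tnsb == 15_000 - 1000 - len(a)
    # both regions on the same side of tnsB: rejected
    side_tnsb = _tnsb_at(90_000, 91_500)
    assert select_end_pairs(matches, [ra, rb], side_tnsb, params) == []


def test_end_pairs_match_brute_force_filter(dna_factory, params):
    """Random layouts: candidate set equals a direct filter over all region
    pairs (>=2 shared, <20 kb, flanking)."""
    for trial in range(5):
        rng = np.random.default_rng(31_000 + trial)
        core = dna_factory(rng, 24)
        regions = []
        for i in range(6):
            seq = dna_factory(rng, 150)
            if rng.random() < 0.7:
                ins = core if rng.random() < 0.5 else revcomp(core)
                seq = seq[:40] + ins + seq[40 + len(ins):]
                seq2 = seq[:100] + (revcomp(core) if ins == core else core) + seq[124:]
                seq = seq2 if rng.random() < 0.5 else seq
            start = int(rng.integers(0, 40_000))
            regions.append(_region(f"r{i}", seq, start=start))
        tnsb = _tnsb_at(20_000, 21_500)
        matches = find_inverted_repeats(regions, params)
        got = {tuple(sorted(p.region_pair))
               for p in select_end_pairs(matches, regions, tnsb, params)}
        by_id = {r.region_id: r for r in regions}
        counts = {}
        for m in matches:
            key = tuple(sorted((m.region_a, m.region_b)))
            if m.region_a == key[0]:
                counts[key] = counts.get(key, 0) + 1
        expect = set()
        for (x, y), n in counts.items():
            rx, ry = by_id[x], by_id[y]
            if n < 2:
                continue
            left, right = sorted([rx, ry], key=lambda r: r.start)
            if not (left.end <= tnsb.start and right.start >= tnsb.end):
                continue
            def dist(r):
                sc = tnsb.start
                return sc - r.end if r.end <= sc else r.start - sc
            if min(dist(rx), dist(ry)) < 20_000:
                expect.add((x, y))
        assert got == expect
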