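"""Filter cascade from discovered motifs to transposon boundary calls.

Discovered motifs are filtered on significance (<=1e-5), presence in both
end regions, and presence on both strands.  Surviving motifs are scanned
over the whole intergenic window and subjected to the four occurrence
criteria: (i) spacing between consecutive instances on a region <=75 bp,
(ii) total instance length per region <=120 bp, (iii) instances on fewer
than 5 regions, (iv) product of occurrence q-values (combined q) < 0.01.
The motif with the lowest combined q wins, and the outermost occurrence
coordinates become the element's boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy

from .io import OrfRecord, Params
from .loci import CandidateLocus
from .motifs import (PWM, MotifOccurrence, compare_motifs, motifs_aligned,
                     scan_regions)
from .repeats import IntergenicRegion


@dataclass
class MotifCandidate:
    pwm: PWM
    occurrences: list[MotifOccurrence]
    source_pair: tuple[str, str] | None = None

    @property
    def combined_q(self) -> float:
        q = 1.0
        for o in self.occurrences:
            q *= o.qvalue
        return q

    @property
    def n_regions(self) -> int:
        return len({o.region_id for o in self.occurrences})


@dataclass
class TransposonCall:
    contig_id: str
    tnsb_orf: OrfRecord
    le_start: int
    re_end: int
    motif_id: str
    le_occurrences: list[MotifOccurrence]
    re_occurrences: list[MotifOccurrence]
    regions: dict = field(default_factory=dict)  # region_id -> (start, end)
    boundary_basis: str = "outermost-motif"
    winning_pwm: PWM | None = None
    combined_q: float = 1.0

    def occurrence_contig_span(self, occ: MotifOccurrence) -> tuple[int, int]:
        rs, _ = self.regions[occ.region_id]
        return rs + occ.start, rs + occ.end


@dataclass
class FilterLog:
    """Audit trail: one (rule, subject, verdict, detail) row per decision."""

    rows: list[tuple[str, str, bool, str]] = field(default_factory=list)

    def record(self, rule: str, subject: str, passed: bool, detail: str = "") -> None:
        self.rows.append((rule, subject, passed, detail))


# ---------------------------------------------------------------------------
# Discovery-stage filters

def filter_discovered_motifs(
    pwms: list[PWM], params: Params | None = None, log: FilterLog | None = None
) -> list[PWM]:
    """Keep motifs with significance <= motif_p_max whose training sites
    occur in both regions of the pair and on both strands."""
    params = params or Params()
    out = []
    for pwm in pwms:
        sig_ok = pwm.significance <= params.motif_p_max
        regions = {s.region_id for s in pwm.sites}
        strands = {s.strand for s in pwm.sites}
        both_regions = len(regions) >= 2
        both_strands = len(strands) >= 2
        if log is not None:
            log.record("motif_p_max<=%g" % params.motif_p_max, pwm.motif_id,
                       sig_ok, f"significance={pwm.significance:.3g}")
            log.record("sites_in_both_sequences", pwm.motif_id, both_regions,
                       f"regions={len(regions)}")
            log.record("sites_on_both_strands", pwm.motif_id, both_strands,
                       f"strands={''.join(sorted(strands))}")
        if sig_ok and both_regions and both_strands:
            out.append(pwm)
    return out


# ---------------------------------------------------------------------------
# Occurrence-stage filters

def _occurrence_violations(cand: MotifCandidate, params: Params) -> list[str]:
    by_region: dict[str, list[MotifOccurrence]] = {}
    for o in cand.occurrences:
        by_region.setdefault(o.region_id, []).append(o)
    violations = []
    for rid, occs in by_region.items():
        occs = sorted(occs, key=lambda o: o.start)
        for prev, nxt in zip(occs, occs[1:]):
            if nxt.start - prev.end > params.occ_max_spacing:
                violations.append(f"spacing>{params.occ_max_spacing} on {rid}")
                break
        total = sum(o.end - o.start for o in occs)
        if total > params.occ_max_total_len:
            violations.append(f"total_len {total}>{params.occ_max_total_len} on {rid}")
    if cand.n_regions > params.occ_max_regions:
        violations.append(f"regions {cand.n_regions}>{params.occ_max_regions}")
    if not cand.combined_q < params.combined_q_max:
        violations.append(f"combined_q {cand.combined_q:.3g}>={params.combined_q_max}")
    return violations


def apply_occurrence_filters(
    candidates: list[MotifCandidate],
    params: Params | None = None,
    log: FilterLog | None = None,
) -> MotifCandidate | None:
    """Remove candidates violating any of the four occurrence criteria and
    return the survivor with the lowest combined q (ties: more occurrences,
    then lexicographic motif id)."""
    params = params or Params()
    survivors = []
    for cand in candidates:
        if not cand.occurrences:
            if log is not None:
                log.record("has_occurrences", cand.pwm.motif_id, False, "")
            continue
        violations = _occurrence_violations(cand, params)
        if log is not None:
            log.record(
                "occurrence_filters(spacing<=%d,total<=%d,regions<%d,combined_q<%g)"
                % (params.occ_max_spacing, params.occ_max_total_len,
                   params.occ_max_regions + 1, params.combined_q_max),
                cand.pwm.motif_id, not violations,
                "; ".join(violations) or "all four criteria pass")
        if not violations:
            survivors.append(cand)
    if not survivors:
        return None
    return min(
        survivors,
        key=lambda c: (c.combined_q, -len(c.occurrences), c.pwm.motif_id),
    )


# ---------------------------------------------------------------------------
# Cross-homolog consensus

def _patristic_groups(ids: list[str], tree: dendropy.Tree, max_dist: float):
    """Single-linkage groups of transposase ids at patristic distance
    < max_dist on the supplied tree; ids absent from the tree become
    singletons (with a warning)."""
    taxa = {t.label: t for t in tree.taxon_namespace}
    present = [i for i in ids if i in taxa]
    missing = [i for i in ids if i not in taxa]
    for i in missing:
        warnings.warn(f"transposase {i} missing from tree; treated as singleton")
    pdm = tree.phylogenetic_distance_matrix() if present else None
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a_i in range(len(present)):
        for b_i in range(a_i + 1, len(present)):
            a, b = present[a_i], present[b_i]
            if pdm.patristic_distance(taxa[a], taxa[b]) < max_dist:
                parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def consensus_across_homologs(
    motif_by_transposase: dict[str, MotifCandidate],
    tree: dendropy.Tree | None,
    params: Params | None = None,
) -> list[tuple[str, MotifCandidate]]:
    """Pool per-transposase winning motifs across closely related
    transposases (patristic distance < 1, single linkage); within each
    group a motif must align with at least half of the other motifs to be
    kept.  Near-identical survivors (mean r >= dedup_min_r) collapse to the
    lowest-combined-q representative."""
    params = params or Params()
    ids = sorted(motif_by_transposase)
    if tree is None:
        groups = [[i] for i in ids]
    else:
        groups = _patristic_groups(ids, tree, params.tree_dist_max)
    kept: list[tuple[str, MotifCandidate]] = []
    for group in groups:
        if len(group) == 1:
            kept.append((group[0], motif_by_transposase[group[0]]))
            continue
        for tid in group:
            me = motif_by_transposase[tid]
            others = [motif_by_transposase[o] for o in group if o != tid]
            n_aligned = sum(
                motifs_aligned(me.pwm, other.pwm, params) for other in others
            )
            if n_aligned >= params.consensus_min_frac * len(others):
                kept.append((tid, me))
    # dedup near-identical motifs
    kept.sort(key=lambda t: (t[1].combined_q, t[0]))
    reps: list[tuple[str, MotifCandidate]] = []
    for tid, cand in kept:
        dup = False
        for _, rep in reps:
            aln = compare_motifs(cand.pwm, rep.pwm, params)
            if aln is not None and aln.mean_r >= params.dedup_min_r:
                dup = True
                break
        if not dup:
            reps.append((tid, cand))
    return reps


# ---------------------------------------------------------------------------
# Final competitive scan and boundary call

def _partition_and_span(
    winner: MotifCandidate,
    regions: list[IntergenicRegion],
    tnsb_orf: OrfRecord,
):
    """Split the winning motif's occurrences into left/right end arrays and
    derive the boundary span in contig coordinates.

    The end region on each side is the region carrying the most occurrences
    (ties: nearest tnsB); occurrences on other regions counted for the
    region filter do not extend the boundary span.
    """
    by_id = {r.region_id: r for r in regions}
    side_occs: dict[str, dict[str, list[MotifOccurrence]]] = {"L": {}, "R": {}}
    for o in winner.occurrences:
        r = by_id[o.region_id]
        if r.end <= tnsb_orf.start:
            side_occs["L"].setdefault(o.region_id, []).append(o)
        elif r.start >= tnsb_orf.end:
            side_occs["R"].setdefault(o.region_id, []).append(o)
    if not side_occs["L"] or not side_occs["R"]:
        return None

    def pick(side: str) -> str:
        def dist(rid):
            r = by_id[rid]
            return min(abs(tnsb_orf.start - r.end), abs(r.start - tnsb_orf.end))
        return min(side_occs[side], key=lambda rid: (-len(side_occs[side][rid]), dist(rid)))

    le_rid, re_rid = pick("L"), pick("R")
    le = sorted(side_occs["L"][le_rid], key=lambda o: o.start)
    re = sorted(side_occs["R"][re_rid], key=lambda o: o.start)
    le_start = by_id[le_rid].start + le[0].start
    re_end = by_id[re_rid].start + re[-1].end
    return le, re, le_start, re_end


def competitive_scan_and_call(
    locus: CandidateLocus,
    regions: list[IntergenicRegion],
    motif_set: list[PWM],
    background,
    params: Params | None = None,
    log: FilterLog | None = None,
) -> TransposonCall | None:
    """Scan every motif of the consensus set over the locus window, pick the
    winner by the occurrence criteria, and record the outermost occurrence
    coordinates as the element's boundaries."""
    params = params or Params()
    if not motif_set:
        return None
    candidates = [
        MotifCandidate(pwm=pwm, occurrences=scan_regions(pwm, regions, background, params))
        for pwm in motif_set
    ]
    winner = apply_occurrence_filters(candidates, params, log)
    if winner is None:
        return None
    parts = _partition_and_span(winner, regions, locus.tnsb_orf)
    if parts is None:
        if log is not None:
            log.record("spans_tnsb", winner.pwm.motif_id, False,
                       "occurrences on one side of tnsB only")
        return None
    le, re, le_start, re_end = parts
    return TransposonCall(
        contig_id=locus.contig_id,
        tnsb_orf=locus.tnsb_orf,
        le_start=le_start,
        re_end=re_end,
        motif_id=winner.pwm.motif_id,
        le_occurrences=le,
        re_occurrences=re,
        regions={r.region_id: (r.start, r.end) for r in regions},
        winning_pwm=winner.pwm,
        combined_q=winner.combined_q,
    )
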