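"""End-to-end orchestration: loci -> windows -> repeats -> motifs -> calls.

Each locus receives a child seed spawned deterministically from the run
seed, so reruns with the same inputs and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .boundaries import (FilterLog, MotifCandidate, TransposonCall,
                         competitive_scan_and_call,
                         consensus_across_homologs, filter_discovered_motifs)
from .io import (Contig, OrfRecord, Params, read_fasta, read_hmm_hits,
                 read_orfs, write_calls, write_motif)
from .loci import CandidateLocus, find_candidate_loci
from .motifs import PWM, discover_motifs
from .repeats import (build_background, extract_window, find_inverted_repeats,
                      select_end_pairs)

logger = logging.getLogger("tnends")


@dataclass
class LocusResult:
    locus: CandidateLocus
    call: TransposonCall | None
    log: FilterLog
    n_regions: int = 0
    n_ir_matches: int = 0
    n_end_pairs: int = 0
    n_motifs_discovered: int = 0
    n_motifs_surviving: int = 0

    @property
    def status(self) -> str:
        return "called" if self.call is not None else "ends not predicted"


@dataclass
class RunConfig:
    """Paths, seed and thresholds for one pipeline run."""

    contigs: str
    orfs: str
    hits: str
    out_dir: str
    params: Params = field(default_factory=Params)
    orf_dialect: str = "gff3"
    tree: str | None = None
    seed: int = 0


def locus_seed(run_seed: int, index: int) -> int:
    """Stable per-locus child seed (kept below 2**31)."""
    return int(np.random.SeedSequence([run_seed, index]).generate_state(1)[0] % (2 ** 31))


def delineate_locus(
    contig: Contig,
    orfs: list[OrfRecord],
    locus: CandidateLocus,
    params: Params,
    seed: int = 0,
    motif_set: list[PWM] | None = None,
) -> LocusResult:
    """Run the boundary-delineation cascade for one candidate locus.

    When ``motif_set`` is given (the cross-homolog consensus set), discovery
    is skipped and only the final competitive scan runs.
    """
    log = FilterLog()
    result = LocusResult(locus=locus, call=None, log=log)
    regions = extract_window(contig, orfs, locus.tnsb_orf, params)
    result.n_regions = len(regions)
    if len(regions) < 2:
        log.record("window", locus.tnsb_orf.orf_id, False, "fewer than 2 regions")
        return result
    background = build_background(regions)

    if motif_set is None:
        tnsb = locus.tnsb_orf

        def could_flank(ra, rb):
            left, right = (ra, rb) if ra.start <= rb.start else (rb, ra)
            if not (left.end <= tnsb.start and right.start >= tnsb.end):
                return False
            from .repeats import region_tnsb_distance

            return min(region_tnsb_distance(ra, tnsb),
                       region_tnsb_distance(rb, tnsb)) < params.pair_max_tnsb_dist

        matches = find_inverted_repeats(regions, params, pair_filter=could_flank)
        result.n_ir_matches = len(matches) // 2
        pairs = select_end_pairs(matches, regions, locus.tnsb_orf, params)
        result.n_end_pairs = len(pairs)
        log.record("end_pairs(shared_ir>=%d,dist<%d)" %
                   (params.pair_min_shared_ir, params.pair_max_tnsb_dist),
                   locus.tnsb_orf.orf_id, bool(pairs), f"{len(pairs)} candidate pair(s)")
        if not pairs:
            return result
        by_id = {r.region_id: r for r in regions}
        motif_set = []
        for i, pair in enumerate(pairs):
            ra, rb = by_id[pair.region_pair[0]], by_id[pair.region_pair[1]]
            try:
                pwms = discover_motifs(ra, rb, background, params,
                                       seed=locus_seed(seed, i))
            except ValueError:
                continue
            result.n_motifs_discovered += len(pwms)
            for p in pwms:
                p.motif_id = f"pair{i}_{p.motif_id}"
            motif_set.extend(filter_discovered_motifs(pwms, params, log))
        result.n_motifs_surviving = len(motif_set)
        if not motif_set:
            return result

    result.call = competitive_scan_and_call(
        locus, regions, motif_set, background, params, log
    )
    return result


def run_pipeline(config: RunConfig) -> list[LocusResult]:
    """Full run over input files; writes calls, motifs, logs and a summary
    into the output directory and returns the per-locus results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.params
    params.to_yaml(out / "params.yaml")

    contigs = read_fasta(config.contigs)
    by_id = {c.id: c for c in contigs}
    orfs = read_orfs(config.orfs, dialect=config.orf_dialect,
                     known_contigs=set(by_id))
    hits = read_hmm_hits(config.hits)
    loci = find_candidate_loci(contigs, orfs, hits, params)
    logger.info("found %d candidate loci", len(loci))

    results: list[LocusResult] = []
    for i, locus in enumerate(loci):
        res = delineate_locus(by_id[locus.contig_id], orfs, locus, params,
                              seed=locus_seed(config.seed, 1000 + i))
        results.append(res)
        logger.info("locus %s on %s: %s", locus.tnsb_orf.orf_id,
                    locus.contig_id, res.status)

    # optional cross-homolog consensus + final competitive rescan
    if config.tree is not None:
        tree = dendropy.Tree.get(path=config.tree, schema="newick",
                                 preserve_underscores=True)
        winners = {
            res.locus.tnsb_orf.orf_id: MotifCandidate(
                pwm=res.call.winning_pwm,
                occurrences=res.call.le_occurrences + res.call.re_occurrences,
            )
            for res in results
            if res.call is not None and res.call.winning_pwm is not None
        }
        if winners:
            consensus = consensus_across_homologs(winners, tree, params)
            motif_set = [c.pwm for _, c in consensus]
            for i, res in enumerate(results):
                res2 = delineate_locus(
                    by_id[res.locus.contig_id], orfs, res.locus, params,
                    seed=locus_seed(config.seed, 2000 + i), motif_set=motif_set,
                )
                results[i] = res2

    _write_outputs(results, out, params)
    return results


def _write_outputs(results: list[LocusResult], out: Path, params: Params) -> None:
    calls = [r.call for r in results if r.call is not None]
    write_calls(calls, out / "calls.gff3", format="gff3")
    write_calls(calls, out / "calls.bed", format="bed")
    with open(out / "summary.tsv", "w") as fh:
        fh.write("contig\ttnsb_orf\tstatus\tle_start\tre_end\tmotif\t"
                 "n_le_sites\tn_re_sites\n")
        for r in results:
            if r.call is None:
                fh.write(f"{r.locus.contig_id}\t{r.locus.tnsb_orf.orf_id}\t"
                         f"{r.status}\t.\t.\t.\t0\t0\n")
            else:
                c = r.call
                fh.write(f"{c.contig_id}\t{c.tnsb_orf.orf_id}\t{r.status}\t"
                         f"{c.le_start}\t{c.re_end}\t{c.motif_id}\t"
                         f"{len(c.le_occurrences)}\t{len(c.re_occurrences)}\n")
    motif_path = out / "motifs.meme"
    if motif_path.exists():
        motif_path.unlink()
    for i, r in enumerate(results):
        if r.call is not None and r.call.winning_pwm is not None:
            write_motif(r.call.winning_pwm, motif_path, mode="w" if i == 0 else "a")
    with open(out / "filters.log", "w") as fh:
        for r in results:
            for rule, subject, passed, detail in r.log.rows:
                verdict = "PASS" if passed else "FAIL"
                fh.write(f"{r.locus.tnsb_orf.orf_id}\t{rule}\t{subject}\t"
                         f"{verdict}\t{detail}\n")
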