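"""Candidate Tn7-like transposon locus selection.

A locus is nominated when an ORF (i) hits the TnsB transposase model with a
bitscore of at least 60 bits, (ii) at least one other core-machinery model
(TnsA/TnsC/TnsD/TniQ/TnsE) hits an ORF on the same contig, and (iii) two
model-hit-bearing ORFs form a putative operon: codirected and separated by
less than 50 bp of noncoding sequence.  Loci whose hit ORFs lie within 3 kb
of a contig edge are discarded as potentially truncated elements.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import Contig, HmmHit, OrfRecord, Params


def is_tnsb(model: str) -> bool:
    return model.split(".")[0].lower() == "tnsb"


@dataclass
class CandidateLocus:
    contig_id: str
    tnsb_orf: OrfRecord
    tnsb_bitscore: float
    supporting_hits: list[HmmHit]
    operon_pair: tuple[str, str]


def _gap(a: OrfRecord, b: OrfRecord) -> int:
    """Noncoding separation between two ORFs on genome coordinates.

    Negative when they overlap; overlap satisfies any gap ceiling.
    """
    first, second = (a, b) if a.start <= b.start else (b, a)
    return second.start - first.end


def _operon_pairs(
    hit_orfs: list[OrfRecord], params: Params
) -> list[tuple[OrfRecord, OrfRecord]]:
    pairs = []
    for i in range(len(hit_orfs)):
        for j in range(i + 1, len(hit_orfs)):
            a, b = hit_orfs[i], hit_orfs[j]
            if a.strand == b.strand and _gap(a, b) < params.operon_max_gap:
                pairs.append((a, b))
    return pairs


def edge_filter(orfs: list[OrfRecord], contig_length: int, params: Params) -> bool:
    """True (keep) unless any hit ORF lies less than ``edge_min_dist`` from a
    contig boundary.  A distance of exactly 3 kb is kept."""
    for o in orfs:
        if o.start < params.edge_min_dist or o.end > contig_length - params.edge_min_dist:
            return False
    return True


def find_candidate_loci(
    contigs: list[Contig],
    orfs: list[OrfRecord],
    hits: list[HmmHit],
    params: Params | None = None,
) -> list[CandidateLocus]:
    """Apply the three selection heuristics plus the contig-edge filter.

    Output is sorted by contig id then tnsB coordinate and is independent of
    input row order.  A TnsB ORF appearing in several qualifying operon
    pairs yields one locus with the smallest-gap pair recorded.
    """
    params = params or Params()
    contig_len = {c.id: c.length for c in contigs}
    orf_by_id = {o.orf_id: o for o in orfs}

    hits_by_orf: dict[str, list[HmmHit]] = {}
    for h in hits:
        if h.orf_id not in orf_by_id:
            raise KeyError(f"hit references unknown ORF: {h.orf_id}")
        hits_by_orf.setdefault(h.orf_id, []).append(h)

    # hit-bearing ORFs per contig
    by_contig: dict[str, list[OrfRecord]] = {}
    for orf_id in hits_by_orf:
        o = orf_by_id[orf_id]
        by_contig.setdefault(o.contig_id, []).append(o)

    loci: list[CandidateLocus] = []
    for contig_id, hit_orfs in by_contig.items():
        if contig_id not in contig_len:
            raise KeyError(f"ORFs reference unknown contig: {contig_id}")
        hit_orfs = sorted(hit_orfs, key=lambda o: (o.start, o.orf_id))
        pairs = _operon_pairs(hit_orfs, params)
        contig_hits = [h for o in hit_orfs for h in hits_by_orf[o.orf_id]]
        for o in hit_orfs:
            tnsb_hits = [
                h
                for h in hits_by_orf[o.orf_id]
                if is_tnsb(h.model) and h.bitscore >= params.tnsb_min_bitscore
            ]
            if not tnsb_hits:
                continue
            others = [h for h in contig_hits if not is_tnsb(h.model)]
            if not others:
                continue
            my_pairs = pairs
            if params.require_tnsb_in_operon:
                my_pairs = [p for p in pairs if o in p]
            if not my_pairs:
                continue
            best_pair = min(my_pairs, key=lambda p: (_gap(*p), p[0].orf_id, p[1].orf_id))
            locus_orfs = {o, *best_pair}
            if not edge_filter(sorted(locus_orfs, key=lambda x: x.start),
                               contig_len[contig_id], params):
                continue
            loci.append(
                CandidateLocus(
                    contig_id=contig_id,
                    tnsb_orf=o,
                    tnsb_bitscore=max(h.bitscore for h in tnsb_hits),
                    supporting_hits=sorted(others, key=lambda h: (h.orf_id, h.model)),
                    operon_pair=(best_pair[0].orf_id, best_pair[1].orf_id),
                )
            )
    loci.sort(key=lambda l: (l.contig_id, l.tnsb_orf.start, l.tnsb_orf.orf_id))
    return loci
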