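"""CAST validation: protospacer search and boundary-to-target distances.

CRISPR-associated transposons integrate a fixed distance (~50 bp)
downstream of the site matched by a CRISPR spacer, so the distance from a
predicted boundary to the nearest protospacer edge is an independent check
of boundary accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Contig, Params
from .seq import N_CODE, encode, revcomp


@dataclass(frozen=True)
class Spacer:
    spacer_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 15:
            raise ValueError(f"spacer {self.spacer_id} shorter than 15 bp")


@dataclass(frozen=True)
class ProtospacerHit:
    spacer_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    mismatches: int


def find_protospacers(
    spacers: list[Spacer],
    contig: Contig,
    search_window: tuple[int, int],
    params: Params | None = None,
) -> list[ProtospacerHit]:
    """Full-length, ungapped matches of each spacer (either strand) within
    the window, allowing up to ``spacer_max_mismatches`` mismatches.
    N never matches."""
    params = params or Params()
    ws, we = search_window
    if not (0 <= ws <= we <= contig.length):
        raise ValueError(f"window {search_window} outside contig {contig.id}")
    target = encode(contig.sequence[ws:we])
    hits: list[ProtospacerHit] = []
    for sp in spacers:
        for strand, query in (("+", sp.sequence), ("-", revcomp(sp.sequence))):
            q = encode(query)
            k = q.size
            n = target.size - k + 1
            if n <= 0:
                continue
            win = np.lib.stride_tricks.sliding_window_view(target, k)
            mm = ((win != q[None, :]) | (win == N_CODE) | (q[None, :] == N_CODE)).sum(axis=1)
            for pos in np.flatnonzero(mm <= params.spacer_max_mismatches):
                hits.append(
                    ProtospacerHit(sp.spacer_id, contig.id, ws + int(pos),
                                   ws + int(pos) + k, strand, int(mm[pos]))
                )
    hits.sort(key=lambda h: (h.start, h.spacer_id, h.strand))
    return hits


def boundary_target_distance(call, hit: ProtospacerHit) -> tuple[int, str]:
    """Distance from the nearest predicted boundary to the nearest edge of a
    protospacer lying outside the element; returns (distance, side)."""
    if hit.start < call.re_end and call.le_start < hit.end:
        raise ValueError(
            f"protospacer {hit.spacer_id} overlaps the element span "
            f"[{call.le_start}, {call.re_end})"
        )
    if hit.end <= call.le_start:
        return call.le_start - hit.end, "left"
    return hit.start - call.re_end, "right"
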