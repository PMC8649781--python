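"""Validate a boundary call with a CRISPR spacer (CAST logic).

CRISPR-associated transposons integrate ~50 bp downstream of the site
matched by one of their spacers, so the distance from a predicted boundary
to the protospacer is an independent accuracy check.  A protospacer is
planted 55 bp upstream of the left end; the measured distance should
reproduce that offset exactly when the boundary call is exact.
"""

from tnends import Params, boundary_target_distance, find_protospacers
from tnends.synth import generate_cast_locus


class Span:
    def __init__(self, le_start, re_end):
        self.le_start, self.re_end = le_start, re_end


contig, orfs, hits, truth, spacer = generate_cast_locus(seed=4, offset=55)
call = Span(truth.planted_le_outer, truth.planted_re_outer)  # exact call

window = (max(0, call.le_start - 5000), call.le_start)
hits_ = find_protospacers([spacer], contig, window, Params())
print(f"spacer {spacer.spacer_id}: {spacer.sequence}")
for h in hits_:
    if h.mismatches == 0:
        d, side = boundary_target_distance(call, h)
        print(f"protospacer at [{h.start}, {h.end}) strand {h.strand}: "
              f"{d} bp from the {side} boundary")
# The printed distance (55 bp) equals the planted offset and falls in the
# 50-60 bp range typical of CAST integration sites.
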