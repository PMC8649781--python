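"""Functional-category enrichment of transposon cargo genes.

Pairs each sampled transposon with a random genomic locus of identical
length from its host genome, sums functional-category counts over both
sets, and summarizes the per-category frequency ratio over resampling
iterations.  Here one category ("C") is planted at 3x weight in the
transposon table; the null categories should bracket ratio 1.
"""

from tnends import Params, cog_enrichment
from tnends.synth import generate_null_annotations

tn, genome, lengths = generate_null_annotations(
    n_transposons=400, seed=0, tn_weight_boost={"C": 3.0})
res = cog_enrichment(tn, genome, lengths, Params(enrich_iters=100), seed=0)

print(res.to_frame().round(3).to_string(index=False))
# The "C" row shows a mean ratio well above 1 with an interval excluding 1
# (the planted enrichment).  The other categories sit slightly below 1:
# relative frequencies sum to 1, so boosting one category necessarily
# depresses the rest.  On a fully null fixture (no boost) every interval
# brackets 1.
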