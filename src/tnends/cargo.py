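"""Cargo-gene statistics: functional-category enrichment by resampling,
pathway completeness, and consensus lowest-common-ancestor labels.

The enrichment contrast follows a paired resampling design: each sampled
transposon is matched with a uniformly placed genomic locus of identical
length from its host genome, category counts are summed over each set, and
the per-category ratio of relative frequencies is summarized over
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Params

NO_COG = "-"  # category assigned to unannotated ORFs


@dataclass
class EnrichmentResult:
    categories: list[str]
    mean_ratio: np.ndarray      # per category, mean over iterations
    lo: np.ndarray              # 2.5th percentile
    hi: np.ndarray              # 97.5th percentile
    iterations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": self.categories,
                "mean_ratio": self.mean_ratio,
                "ci_lo": self.lo,
                "ci_hi": self.hi,
                "iterations": self.iterations,
            }
        )


class _GenomeIndex:
    """Per-genome sorted ORF midpoints with cumulative category counts, so
    the category counts of any window are two searchsorted calls and a row
    difference."""

    def __init__(self, ann: pd.DataFrame, length: int, cats: list[str]):
        self.length = int(length)
        mids = ((ann["start"] + ann["end"]) // 2).to_numpy()
        order = np.argsort(mids, kind="stable")
        self.mids = mids[order]
        codes = pd.Categorical(ann["category"], categories=cats).codes[order]
        onehot = np.zeros((len(codes) + 1, len(cats)), dtype=np.int64)
        if len(codes):
            np.add.at(onehot[1:], (np.arange(len(codes)), codes), 1)
        self.cum = np.cumsum(onehot, axis=0)

    def window_counts(self, start: int, end: int) -> np.ndarray:
        i = np.searchsorted(self.mids, start, side="left")
        j = np.searchsorted(self.mids, end, side="left")
        return self.cum[j] - self.cum[i]


def cog_enrichment(
    tn_annotations: pd.DataFrame,
    genome_annotations: pd.DataFrame,
    genome_lengths: dict[str, int],
    params: Params | None = None,
    seed: int = 0,
    tn_lengths: dict[str, int] | None = None,
    tn_genomes: dict[str, str] | None = None,
) -> EnrichmentResult:
    """Relative frequency of each category in transposons versus matched
    random genomic loci.

    ``tn_annotations`` columns: element_id, orf_id, category, and (unless
    supplied separately) element_length and genome_id.  Each iteration
    samples ``enrich_n_pairs`` transposons without replacement and one
    equal-length locus per transposon from its host genome; a pseudocount
    of 1 per category is applied to the genomic (denominator) counts.
    """
    params = params or Params()
    rng = np.random.default_rng(seed)
    if tn_lengths is None:
        tn_lengths = dict(
            tn_annotations.groupby("element_id")["element_length"].first()
        )
    if tn_genomes is None:
        tn_genomes = dict(tn_annotations.groupby("element_id")["genome_id"].first())
    elements = sorted(tn_lengths)
    if len(elements) < params.enrich_n_pairs:
        raise ValueError(
            f"need >= {params.enrich_n_pairs} transposons, have {len(elements)}"
        )
    cats = sorted(
        set(tn_annotations["category"]) | set(genome_annotations["category"])
    )
    ncat = len(cats)

    tn_codes = pd.Categorical(tn_annotations["category"], categories=cats).codes
    tn_elem = pd.Categorical(
        tn_annotations["element_id"], categories=elements
    ).codes
    elem_counts = np.zeros((len(elements), ncat), dtype=np.int64)
    np.add.at(elem_counts, (tn_elem, tn_codes), 1)

    genomes = {
        g: _GenomeIndex(sub, genome_lengths[g], cats)
        for g, sub in genome_annotations.groupby("genome_id")
    }
    elem_len = np.array([tn_lengths[e] for e in elements])
    elem_gen = [tn_genomes[e] for e in elements]

    ratios = np.empty((params.enrich_iters, ncat))
    for it in range(params.enrich_iters):
        pick = rng.choice(len(elements), size=params.enrich_n_pairs, replace=False)
        tn_sum = elem_counts[pick].sum(axis=0)
        bg_sum = np.ones(ncat, dtype=np.int64)  # pseudocount 1 per category
        for ei in pick:
            gi = genomes[elem_gen[ei]]
            span = int(elem_len[ei])
            if gi.length <= span:
                raise ValueError(f"genome {elem_gen[ei]} shorter than element")
            start = int(rng.integers(0, gi.length - span + 1))
            bg_sum += gi.window_counts(start, start + span)
        tn_freq = tn_sum / max(tn_sum.sum(), 1)
        bg_freq = bg_sum / bg_sum.sum()
        ratios[it] = tn_freq / bg_freq
    return EnrichmentResult(
        categories=cats,
        mean_ratio=ratios.mean(axis=0),
        lo=np.percentile(ratios, 2.5, axis=0),
        hi=np.percentile(ratios, 97.5, axis=0),
        iterations=params.enrich_iters,
    )


def pathway_completeness(
    tn_annotations: pd.DataFrame,
    pathway_defs: pd.DataFrame,
    params: Params | None = None,
) -> pd.DataFrame:
    """Transposon x pathway matrix of completeness fractions: categories of
    the pathway carried by the transposon over the pathway's category
    count.  Pathways represented (fraction > 0) in fewer than
    ``pathway_min_tns`` transposons are dropped."""
    params = params or Params()
    pathways: dict[str, set[str]] = {
        p: set(sub["category"]) for p, sub in pathway_defs.groupby("pathway_id")
    }
    for p, members in pathways.items():
        if not members:
            raise ValueError(f"pathway {p} has no member categories")
    elem_cats = {
        e: set(sub["category"]) for e, sub in tn_annotations.groupby("element_id")
    }
    mat = pd.DataFrame(
        {
            p: {e: len(cats & members) / len(members) for e, cats in elem_cats.items()}
            for p, members in pathways.items()
        }
    ).sort_index()
    present = (mat > 0).sum(axis=0)
    return mat.loc[:, present[present >= params.pathway_min_tns].index]


def consensus_lca(member_lineages: list[list[str]], threshold: float = 0.8):
    """Deepest rank at which at least ``threshold`` of the members share the
    same taxon path; "unknown" when even the shallowest rank has no
    consensus.  Permutation-invariant in the member list."""
    if not member_lineages:
        raise ValueError("empty member list")
    n = len(member_lineages)
    depth = max(len(l) for l in member_lineages)
    consensus: list[str] = []
    for rank in range(depth):
        paths: dict[tuple, int] = {}
        for lin in member_lineages:
            if len(lin) > rank:
                key = tuple(lin[: rank + 1])
                paths[key] = paths.get(key, 0) + 1
        if not paths:
            break
        best_path, count = max(paths.items(), key=lambda kv: (kv[1], kv[0]))
        if count >= threshold * n and list(best_path[:-1]) == consensus:
            consensus = list(best_path)
        else:
            break
    return consensus if consensus else "unknown"
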