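"""Synthetic contigs with planted TnsB binding-site arrays and ground truth.

The generator emulates the end architecture of Tn7: an array of binding
sites on the plus strand upstream of the element's cargo (left end) and an
inverted array downstream (right end), a tnsB marker ORF with a codirected
second core-gene ORF inside, gene-dense flanks, and optional decoy repeats
chosen to exercise the repeat filters (direct repeats and
length-violating inverted repeats).  Site instances are sampled from a PWM
of controlled information content, not pasted as consensus, so recovery
difficulty tracks the information content.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cast import Spacer
from .io import Contig, HmmHit, OrfRecord
from .motifs import PWM
from .seq import revcomp


@dataclass
class SynthTruth:
    contig_id: str
    planted_le_sites: list[tuple[int, int, str]]
    planted_re_sites: list[tuple[int, int, str]]
    planted_le_outer: int | None
    planted_re_outer: int | None
    tnsb_orf: OrfRecord
    seed: int
    protospacer: tuple[int, int, int] | None = None  # (start, end, offset)
    decoys: list[tuple[str, int, int]] = field(default_factory=list)
    pwm: PWM | None = None

    def to_json(self, path: str | Path) -> None:
        data = {
            "contig_id": self.contig_id,
            "planted_le_sites": self.planted_le_sites,
            "planted_re_sites": self.planted_re_sites,
            "planted_le_outer": self.planted_le_outer,
            "planted_re_outer": self.planted_re_outer,
            "tnsb_orf": [self.tnsb_orf.orf_id, self.tnsb_orf.start,
                         self.tnsb_orf.end, self.tnsb_orf.strand],
            "seed": self.seed,
            "protospacer": self.protospacer,
            "decoys": self.decoys,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


def _dominant_prob(info_bits: float) -> float:
    """Dominant-base probability giving a column the requested information
    content (uniform background), by bisection."""

    def info(p):
        q = (1 - p) / 3
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -(p * np.log2(p) + 3 * np.where(q > 0, q * np.log2(q), 0.0))
        return 2.0 - h

    lo, hi = 0.2500001, 1 - 1e-9
    for _ in range(80):
        mid = (lo + hi) / 2
        if info(mid) < info_bits:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def random_pwm(width: int, info_bits: float, rng: np.random.Generator) -> PWM:
    p = _dominant_prob(info_bits)
    probs = np.full((width, 4), (1 - p) / 3)
    dom = rng.integers(0, 4, size=width)
    probs[np.arange(width), dom] = p
    return PWM("planted", probs)


def _sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    return "".join(
        "ACGT"[rng.choice(4, p=pwm.probs[i])] for i in range(pwm.width)
    )


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


class _Builder:
    def __init__(self, rng: np.random.Generator, gc: float, contig_id: str):
        self.rng = rng
        self.gc = gc
        self.contig_id = contig_id
        self.parts: list[str] = []
        self.pos = 0
        self.orfs: list[OrfRecord] = []
        self.n_orf = 0
        self.gap_spans: list[tuple[int, int]] = []  # candidate decoy areas

    def emit(self, seq: str) -> tuple[int, int]:
        span = (self.pos, self.pos + len(seq))
        self.parts.append(seq)
        self.pos += len(seq)
        return span

    def gap(self, n: int, decoy_ok: bool = False) -> tuple[int, int]:
        span = self.emit(_rand_seq(self.rng, n, self.gc))
        if decoy_ok:
            self.gap_spans.append(span)
        return span

    def orf(self, n: int, strand: str | None = None, name: str | None = None) -> OrfRecord:
        strand = strand or ("+" if self.rng.random() < 0.5 else "-")
        s, e = self.emit(_rand_seq(self.rng, n, self.gc))
        self.n_orf += 1
        rec = OrfRecord(name or f"orf{self.n_orf:04d}", self.contig_id, s, e, strand)
        self.orfs.append(rec)
        return rec

    def gene_fill(self, target: int, decoy_ok: bool = False) -> None:
        """Alternate gaps and genes until at least ``target`` bp are laid."""
        start = self.pos
        while self.pos - start < target:
            self.gap(int(self.rng.integers(80, 180)), decoy_ok=decoy_ok)
            self.orf(int(self.rng.integers(800, 1300)))


def generate_locus(
    seed: int = 0,
    info_bits: float = 1.5,
    n_left: int = 3,
    n_right: int = 4,
    site_spacing: tuple[int, int] = (4, 30),
    cargo_len: int = 15_000,
    gc: float = 0.5,
    padding: int = 6_000,
    n_decoys: int = 2,
    motif_width: int = 18,
    contig_id: str | None = None,
) -> tuple[Contig, list[OrfRecord], list[HmmHit], SynthTruth]:
    """One synthetic contig with a planted Tn7-style element.

    Defaults reproduce the canonical Tn7 end architecture: three binding
    sites at the left end, four (inverted) at the right end, sites of 18 bp
    at 1.5 bits/column, cargo between the arrays, and gene-dense flanks of
    ``padding`` bp so the element is comfortably clear of the contig edges.
    """
    rng = np.random.default_rng(seed)
    contig_id = contig_id or f"synth_{seed}"
    pwm = random_pwm(motif_width, info_bits, rng)
    b = _Builder(rng, gc, contig_id)

    b.gene_fill(padding, decoy_ok=True)

    # left end array (plus strand)
    le_sites: list[tuple[int, int, str]] = []
    b.gap(int(rng.integers(20, 60)))
    for i in range(n_left):
        if i:
            b.gap(int(rng.integers(*site_spacing)))
        s, e = b.emit(_sample_site(pwm, rng))
        le_sites.append((s, e, "+"))
    if n_left == 0:
        b.gap(120)
    b.gap(int(rng.integers(20, 60)))

    # cargo upstream of tnsB; first cargo gene abuts the left-end array, as
    # in gene-dense transposon interiors
    b.orf(int(rng.integers(800, 1300)))
    b.gene_fill(max(cargo_len // 2 - 2600, 0))
    b.gap(int(rng.integers(60, 120)))
    tnsb = b.orf(1500, strand="+", name=f"orf{b.n_orf + 1:04d}_tnsB")
    b.gap(int(rng.integers(5, 45)))  # operon gap < 50 bp
    tnsc = b.orf(900, strand="+", name=f"orf{b.n_orf + 1:04d}_tnsC")
    b.gene_fill(max(cargo_len // 2 - 2400, 0))

    # right end array (minus strand: reverse-complemented site samples)
    b.gap(int(rng.integers(20, 60)))
    re_sites: list[tuple[int, int, str]] = []
    for i in range(n_right):
        if i:
            b.gap(int(rng.integers(*site_spacing)))
        s, e = b.emit(revcomp(_sample_site(pwm, rng)))
        re_sites.append((s, e, "-"))
    if n_right == 0:
        b.gap(120)
    b.gap(int(rng.integers(20, 60)))

    b.orf(int(rng.integers(800, 1300)))
    b.gene_fill(padding, decoy_ok=True)

    sequence = "".join(b.parts)

    # decoy repeats in the flanks: direct repeats and too-short inverted
    # repeats, which must be rejected by the repeat filters
    decoys: list[tuple[str, int, int]] = []
    left_gaps = [g for g in b.gap_spans if g[1] < (le_sites[0][0] if le_sites else tnsb.start)]
    right_gaps = [g for g in b.gap_spans if g[0] > (re_sites[-1][1] if re_sites else tnsc.end)]
    seq = list(sequence)
    for k in range(n_decoys):
        if not left_gaps or not right_gaps:
            break
        kind = "direct" if k % 2 == 0 else "short_ir"
        size = 22 if kind == "direct" else 10
        unit = _rand_seq(rng, size, gc)
        lg = left_gaps[int(rng.integers(0, len(left_gaps)))]
        rg = right_gaps[int(rng.integers(0, len(right_gaps)))]
        if lg[1] - lg[0] <= size + 4 or rg[1] - rg[0] <= size + 4:
            continue
        lp = int(rng.integers(lg[0] + 2, lg[1] - size - 2))
        rp = int(rng.integers(rg[0] + 2, rg[1] - size - 2))
        second = unit if kind == "direct" else revcomp(unit)
        seq[lp : lp + size] = unit
        seq[rp : rp + size] = second
        decoys.append((kind, lp, rp))
    sequence = "".join(seq)

    contig = Contig(contig_id, sequence)
    hits = [
        HmmHit(tnsb.orf_id, "TnsB", float(rng.uniform(80, 120)), 1e-30),
        HmmHit(tnsc.orf_id, "TnsC", float(rng.uniform(70, 100)), 1e-25),
    ]
    truth = SynthTruth(
        contig_id=contig_id,
        planted_le_sites=le_sites,
        planted_re_sites=re_sites,
        planted_le_outer=le_sites[0][0] if le_sites else None,
        planted_re_outer=re_sites[-1][1] if re_sites else None,
        tnsb_orf=tnsb,
        seed=seed,
        decoys=decoys,
        pwm=pwm,
    )
    return contig, b.orfs, hits, truth


def generate_cast_locus(
    seed: int = 0,
    protospacer_len: int = 32,
    offset: int = 55,
    **locus_kwargs,
) -> tuple[Contig, list[OrfRecord], list[HmmHit], SynthTruth, Spacer]:
    """A planted element plus a protospacer ending ``offset`` bp upstream of
    the left boundary, mimicking CAST integration downstream of its target."""
    if offset < 0:
        raise ValueError("offset must be >= 0")
    contig, orfs, hits, truth = generate_locus(seed=seed, **locus_kwargs)
    if truth.planted_le_outer is None:
        raise ValueError("CAST locus requires planted sites")
    end = truth.planted_le_outer - offset
    start = end - protospacer_len
    if start < 0:
        raise ValueError("offset places the protospacer off the contig")
    rng = np.random.default_rng(seed + 7_777_777)
    proto = _rand_seq(rng, protospacer_len, locus_kwargs.get("gc", 0.5))
    sequence = contig.sequence[:start] + proto + contig.sequence[end:]
    contig = Contig(contig.id, sequence)
    truth.protospacer = (start, end, offset)
    return contig, orfs, hits, truth, Spacer(f"spacer_{seed}", proto)


def generate_null_annotations(
    n_transposons: int = 150,
    n_genomes: int = 8,
    categories: list[str] | None = None,
    mean_orfs: float = 12.0,
    seed: int = 0,
    tn_weight_boost: dict[str, float] | None = None,
    genome_length: int = 300_000,
):
    """Paired annotation tables drawn from one multinomial (the null of no
    enrichment), plus genome lengths.

    ``tn_weight_boost`` multiplies the sampling weight of chosen categories
    in the transposon table only, to plant a known enrichment.
    """
    if n_transposons <= 0 or n_genomes <= 0:
        raise ValueError("counts must be positive")
    if categories is None:
        categories = ["C", "D", "E", "F", "G", "H", "I", "J", "K", "L", "M", "-"]
    if not categories:
        raise ValueError("empty category alphabet")
    rng = np.random.default_rng(seed)
    w = np.ones(len(categories))
    w /= w.sum()
    tw = w.copy()
    if tn_weight_boost:
        for cat, mult in tn_weight_boost.items():
            tw[categories.index(cat)] *= mult
        tw /= tw.sum()

    genome_rows = []
    for g in range(n_genomes):
        gid = f"g{g:02d}"
        pos = 100
        i = 0
        while pos + 800 < genome_length:
            cat = categories[rng.choice(len(categories), p=w)]
            genome_rows.append((gid, f"{gid}_orf{i:05d}", pos, pos + 800, cat))
            pos += int(rng.integers(900, 1200))
            i += 1
    genome_df = pd.DataFrame(
        genome_rows, columns=["genome_id", "orf_id", "start", "end", "category"]
    )

    tn_rows = []
    for t in range(n_transposons):
        eid = f"tn{t:04d}"
        gid = f"g{int(rng.integers(0, n_genomes)):02d}"
        length = int(rng.integers(5_000, 30_001))
        n = max(1, int(rng.poisson(mean_orfs)))
        for i in range(n):
            cat = categories[rng.choice(len(categories), p=tw)]
            tn_rows.append((eid, f"{eid}_orf{i:03d}", cat, length, gid))
    tn_df = pd.DataFrame(
        tn_rows,
        columns=["element_id", "orf_id", "category", "element_length", "genome_id"],
    )
    lengths = {f"g{g:02d}": genome_length for g in range(n_genomes)}
    return tn_df, genome_df, lengths
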