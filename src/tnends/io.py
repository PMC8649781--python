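"""Input/output for every external format the pipeline touches.

Internal coordinates are always 0-based half-open.  GFF3 is read and written
1-based inclusive; BED is written 0-based half-open.  Every writer converts
exactly once.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from Bio import SeqIO

from .seq import clean


@dataclass
class Contig:
    """A nucleotide sequence with an identifier.

    The sequence is uppercased on ingest and restricted to {A,C,G,T,N};
    anything else is mapped to N.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        self.sequence = clean(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfRecord:
    """A predicted ORF, 0-based half-open on its contig."""

    orf_id: str
    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"ORF {self.orf_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"ORF {self.orf_id}: strand must be + or -")

    @property
    def start_codon(self) -> int:
        """Strand-aware coordinate of the start codon."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class HmmHit:
    orf_id: str
    model: str
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if not self.model:
            raise ValueError("hit model must be non-empty")
        if not np.isfinite(self.bitscore):
            raise ValueError(f"hit {self.orf_id}: non-finite bitscore")


@dataclass
class Params:
    """Every numeric threshold of the method, with its default.

    Units are base pairs unless noted.  Defaults reproduce the published
    search conditions for Tn7-like transposons.
    """

    tnsb_min_bitscore: float = 60.0       # bits; TnsB HMM hit floor
    operon_max_gap: int = 50              # max noncoding gap inside an operon
    edge_min_dist: int = 3000             # min distance of hit ORFs to contig edge
    min_intergenic_len: int = 50          # regions must be strictly longer
    window: int = 125_000                 # search span on either side of tnsB
    ir_min_len: int = 15
    ir_max_len: int = 40
    ir_max_gaps: int = 2
    ir_max_mismatches: int = 6
    pair_max_tnsb_dist: int = 20_000      # end region to tnsB start codon
    pair_min_shared_ir: int = 2
    motif_min_w: int = 15
    motif_max_w: int = 20
    motif_max_n: int = 10                 # motifs per region pair
    motif_min_sites: int = 4
    motif_max_sites: int = 6
    motif_evalue_max: float = 0.1         # discovery significance gate
    motif_p_max: float = 1e-5             # post-discovery significance filter
    scan_fdr: float = 0.1                 # q-value ceiling for occurrences
    scan_p_ceiling: float = 1e-3          # nominal p ceiling before BH
    occ_max_spacing: int = 75
    occ_max_total_len: int = 120
    occ_max_regions: int = 4              # "fewer than 5 intergenic sequences"
    combined_q_max: float = 0.01
    tree_dist_max: float = 1.0            # patristic distance for grouping
    consensus_min_frac: float = 0.5       # must align with >= this fraction
    tomtom_min_overlap: int = 10          # columns
    tomtom_min_r: float = 0.6             # mean Pearson r to call "aligned"
    dedup_min_r: float = 0.95             # collapse near-identical motifs
    enrich_n_pairs: int = 100
    enrich_iters: int = 1000
    lca_consensus: float = 0.8
    pathway_min_tns: int = 10
    max_hsps: int = 100                   # IR matches kept per region pair
    pseudocount: float = 0.1              # per PWM cell
    spacer_max_mismatches: int = 2
    require_tnsb_in_operon: bool = False  # whether the operon pair must include tnsB

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                continue
            if not v > 0:
                raise ValueError(f"Params.{f.name} must be strictly positive, got {v}")
        if self.ir_min_len > self.ir_max_len:
            raise ValueError("ir_min_len must be <= ir_max_len")
        if self.motif_min_w > self.motif_max_w:
            raise ValueError("motif_min_w must be <= motif_max_w")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Params":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter(s) in {path}: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[Contig]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        contigs.append(Contig(id=rec.id, sequence=str(rec.seq)))
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# ORF tables

def read_orfs(
    path: str | Path,
    dialect: str = "gff3",
    known_contigs: set[str] | None = None,
) -> list[OrfRecord]:
    """Read ORF coordinates from GFF3 or a 5-column TSV.

    Both dialects carry 1-based inclusive coordinates (the GFF3 convention);
    they are converted to 0-based half-open here, and nowhere else.
    """
    if dialect not in ("gff3", "tsv"):
        raise ValueError(f"unknown dialect: {dialect}")
    orfs: list[OrfRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if dialect == "gff3":
                    if len(cols) < 9:
                        raise ValueError("expected 9 GFF3 columns")
                    contig_id, _, ftype = cols[0], cols[1], cols[2]
                    if ftype not in ("CDS", "gene", "ORF"):
                        continue
                    start1, end1, strand = int(cols[3]), int(cols[4]), cols[6]
                    orf_id = _gff_attr(cols[8], "ID") or f"orf_{lineno}"
                else:
                    if len(cols) < 5:
                        raise ValueError("expected 5 TSV columns")
                    orf_id, contig_id = cols[0], cols[1]
                    start1, end1, strand = int(cols[2]), int(cols[3]), cols[4]
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from exc
            if start1 > end1:
                raise ValueError(f"{path}:{lineno}: start > end ({start1} > {end1})")
            if known_contigs is not None and contig_id not in known_contigs:
                import warnings

                warnings.warn(f"{path}:{lineno}: unknown contig {contig_id}; skipped")
                continue
            orfs.append(OrfRecord(orf_id, contig_id, start1 - 1, end1, strand))
    return orfs


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def write_orfs(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    """Write ORFs as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for o in orfs:
            fh.write(
                f"{o.contig_id}\ttnends\tCDS\t{o.start + 1}\t{o.end}\t.\t"
                f"{o.strand}\t0\tID={o.orf_id}\n"
            )


# ---------------------------------------------------------------------------
# HMM hit tables

def read_hmm_hits(path: str | Path) -> list[HmmHit]:
    """Read a HMMER domtblout file or a simplified 4-column TSV.

    The TSV columns are (orf_id, model, bitscore, evalue).  domtblout rows
    are recognised by their >=22 whitespace-separated fields; target name,
    query name, full-sequence E-value and score are taken from the standard
    columns.
    """
    hits: list[HmmHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if len(fields) >= 22:  # domtblout
                    orf_id, model = fields[0], fields[3]
                    evalue, bitscore = float(fields[6]), float(fields[7])
                elif len(fields) >= 4:
                    orf_id, model = fields[0], fields[1]
                    bitscore, evalue = float(fields[2]), float(fields[3])
                else:
                    raise ValueError("expected >=4 columns")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad hit row ({exc})") from exc
            hits.append(HmmHit(orf_id, model, bitscore, evalue))
    return hits


def write_hmm_hits(hits: Iterable[HmmHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# orf_id\tmodel\tbitscore\tevalue\n")
        for h in hits:
            fh.write(f"{h.orf_id}\t{h.model}\t{h.bitscore:g}\t{h.evalue:g}\n")


# ---------------------------------------------------------------------------
# Boundary calls

def write_calls(calls, path: str | Path, format: str = "gff3") -> None:
    """Write transposon calls with one parent feature and one child per
    binding-site occurrence.  GFF3 is 1-based inclusive; BED is 0-based
    half-open (children as blocks of a second BED line set)."""
    if format not in ("gff3", "bed"):
        raise ValueError(f"unknown format: {format}")
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
        for i, call in enumerate(calls):
            name = f"transposon_{i + 1}"
            occs = list(call.le_occurrences) + list(call.re_occurrences)
            if format == "gff3":
                fh.write(
                    f"{call.contig_id}\ttnends\tmobile_genetic_element\t"
                    f"{call.le_start + 1}\t{call.re_end}\t.\t+\t.\t"
                    f"ID={name};motif={call.motif_id};tnsB={call.tnsb_orf.orf_id}\n"
                )
                for j, occ in enumerate(occs):
                    s, e = call.occurrence_contig_span(occ)
                    fh.write(
                        f"{call.contig_id}\ttnends\tbinding_site\t{s + 1}\t{e}\t"
                        f"{occ.score:.3f}\t{occ.strand}\t.\t"
                        f"ID={name}.site{j + 1};Parent={name}\n"
                    )
            else:
                fh.write(
                    f"{call.contig_id}\t{call.le_start}\t{call.re_end}\t{name}\t0\t+\n"
                )
                for j, occ in enumerate(occs):
                    s, e = call.occurrence_contig_span(occ)
                    fh.write(
                        f"{call.contig_id}\t{s}\t{e}\t{name}.site{j + 1}\t0\t{occ.strand}\n"
                    )


def read_calls_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read parent-level call spans back from a BED file (0-based half-open).

    Child binding-site lines (name contains '.site') are skipped.
    """
    spans = []
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 4 or ".site" in cols[3]:
                continue
            spans.append((cols[0], int(cols[1]), int(cols[2]), cols[3]))
    return spans


# ---------------------------------------------------------------------------
# Minimal MEME motif format

def write_motif(pwm, path: str | Path, background=None, mode: str = "w") -> None:
    """Write a PWM in minimal MEME motif text format."""
    probs = np.asarray(pwm.probs, dtype=float)
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("PWM columns must sum to 1 within 1e-9")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    new = mode == "w" or not Path(path).exists()
    with open(path, mode) as fh:
        if new or mode == "w":
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
            fh.write(
                "Background letter frequencies\n"
                + " ".join(f"{b} {bg[i]:.6f}" for i, b in enumerate("ACGT"))
                + "\n\n"
            )
        fh.write(f"MOTIF {pwm.motif_id}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {probs.shape[0]} "
            f"nsites= {pwm.nsites} E= {pwm.significance:.3e}\n"
        )
        for row in probs:
            fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
        fh.write("\n")


def read_motifs(path: str | Path):
    """Parse motifs back from minimal MEME format."""
    from .motifs import PWM

    motifs = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if lines[i].startswith("MOTIF"):
            motif_id = lines[i].split()[1]
            i += 1
            header = lines[i]
            toks = header.replace("=", "= ").split()
            w = int(toks[toks.index("w=") + 1])
            nsites = int(toks[toks.index("nsites=") + 1]) if "nsites=" in toks else 0
            ev = float(toks[toks.index("E=") + 1]) if "E=" in toks else 1.0
            rows = []
            for j in range(w):
                rows.append([float(x) for x in lines[i + 1 + j].split()])
            motifs.append(
                PWM(
                    motif_id=motif_id,
                    probs=np.asarray(rows, dtype=float),
                    nsites=nsites,
                    significance=ev,
                )
            )
            i += 1 + w
        else:
            i += 1
    return motifs
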