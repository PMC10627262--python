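"""Synthetic genome + annotation generator with planted promoter elements.

Genes are laid out left to right along one chromosome with random
intergenic gaps, each gene carrying one transcript (5'UTR + body) on a
randomly chosen strand.  Background sequence is i.i.d. at a configurable
GC fraction (default 0.36, typical of plant intergenic DNA).  Core
promoter elements are planted at declared TSS-relative windows and
written strand-correctly (reverse-complemented for minus-strand genes),
and every plant is recorded in a truth table so scans can be validated
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "ElementPlant",
    "GenomeSpec",
    "SimGene",
    "SyntheticGenome",
    "GenomeSizingError",
    "ELEMENT_SEQUENCES",
    "DEFAULT_PLANT_WINDOWS",
    "simulate_genome",
    "mirror_genome",
    "write_fasta",
]

# Planted element sequences; each is the consensus (argmax chain) of the
# matching synthetic PWM shipped under promstab/data, so a planted element
# scores a relative PWM score of exactly 1.0.
ELEMENT_SEQUENCES = {
    "TATA": "GTATAAATAG",
    "YPatch": "TTCTTCTCCT",
    "Inr": "CTCATTCA",
    "CA": "CAACAACA",
    "GA": "GAGAGAGA",
}

# Default TSS-relative planting windows (no position 0), chosen inside the
# windows both scan methods examine for each element.
DEFAULT_PLANT_WINDOWS = {
    "TATA": (-33, -24),
    "YPatch": (-30, -21),
    "Inr": (-4, 4),
    "CA": (-20, -13),
    "GA": (5, 12),
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class GenomeSizingError(ValueError):
    """The requested genes and spacing do not fit in chrom_length."""


@dataclass
class ElementPlant:
    """One element planted at a TSS-relative window for one gene."""

    element: str
    start: int  # TSS-relative, no position 0
    end: int
    sequence: str | None = None  # default: ELEMENT_SEQUENCES[element]

    def resolved_sequence(self) -> str:
        seq = self.sequence or ELEMENT_SEQUENCES[self.element]
        return seq.upper()

    def positions(self) -> list[int]:
        if self.start == 0 or self.end == 0 or self.start >= self.end:
            raise ValueError(f"bad plant window ({self.start}, {self.end})")
        return [p for p in range(self.start, self.end + 1) if p != 0]


def _auto_window(element: str, sequence: str | None) -> tuple[int, int]:
    frm, to = DEFAULT_PLANT_WINDOWS[element]
    if sequence is not None:
        n = len(sequence)
        to = frm + n - 1 + (1 if frm < 0 <= frm + n - 1 else 0)
        # recompute skipping position 0
        pos = []
        p = frm
        while len(pos) < n:
            if p != 0:
                pos.append(p)
            p += 1
        to = pos[-1]
    return frm, to


def plant(element: str, window: tuple[int, int] | None = None, sequence: str | None = None) -> ElementPlant:
    """Convenience constructor using the element's default window."""
    if window is None:
        window = _auto_window(element, sequence)
    return ElementPlant(element, window[0], window[1], sequence)


@dataclass
class GenomeSpec:
    """Layout and planting plan for one synthetic chromosome."""

    n_genes: int
    chrom_length: int | None = None  # None: auto-size to fit
    strand_fraction: float = 0.3  # probability a gene is on the minus strand
    intergenic_min: int = 300
    intergenic_max: int = 1500
    utr5_min: int = 50
    utr5_max: int = 200
    body_length: int = 300  # transcribed sequence downstream of the 5'UTR
    gc_background: float = 0.36
    element_plan: dict[int, list[ElementPlant]] = field(default_factory=dict)
    chrom_name: str = "chr1"
    transcript_prefix: str = "g"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not 0 <= self.strand_fraction <= 1:
            raise ValueError("strand_fraction must be in [0, 1]")
        if not 0 < self.gc_background < 1:
            raise ValueError("gc_background must be in (0, 1)")
        if self.intergenic_min < 1 or self.intergenic_min > self.intergenic_max:
            raise ValueError("need 1 <= intergenic_min <= intergenic_max")
        if self.utr5_min < 0 or self.utr5_min > self.utr5_max:
            raise ValueError("need 0 <= utr5_min <= utr5_max")


@dataclass
class SimGene:
    gene_id: str
    transcript_id: str
    strand: str
    start: int  # 1-based closed, gene == transcript span
    end: int
    utr5_length: int

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class SyntheticGenome:
    chrom_name: str
    sequence: str
    genes: list[SimGene]
    truth: pd.DataFrame  # transcript, element, rel_start, rel_end, sequence

    def write(self, outdir) -> dict[str, str]:
        """Write genome.fa, annotation.gff3 and elements_truth.tsv."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": str(outdir / "genome.fa"),
            "gff3": str(outdir / "annotation.gff3"),
            "truth": str(outdir / "elements_truth.tsv"),
        }
        write_fasta({self.chrom_name: self.sequence}, paths["fasta"])
        with open(paths["gff3"], "w") as fh:
            fh.write(self.to_gff3())
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths

    def to_gff3(self) -> str:
        lines = ["##gff-version 3"]
        if self.sequence:
            lines.append(
                f"##sequence-region {self.chrom_name} 1 {len(self.sequence)}"
            )
        src = "promstab_sim"
        for g in sorted(self.genes, key=lambda x: (x.start, x.gene_id)):
            row = [self.chrom_name, src, "gene", str(g.start), str(g.end), ".", g.strand, "."]
            lines.append("\t".join(row + [f"ID={g.gene_id}"]))
            row[2] = "mRNA"
            lines.append("\t".join(row + [f"ID={g.transcript_id};Parent={g.gene_id}"]))
            row[2] = "exon"
            lines.append(
                "\t".join(row + [f"ID={g.transcript_id}.exon1;Parent={g.transcript_id}"])
            )
            if g.utr5_length > 0:
                if g.strand == "+":
                    us, ue = g.start, g.start + g.utr5_length - 1
                else:
                    us, ue = g.end - g.utr5_length + 1, g.end
                lines.append(
                    "\t".join(
                        [
                            self.chrom_name, src, "five_prime_UTR", str(us), str(ue),
                            ".", g.strand, ".",
                            f"ID={g.transcript_id}.utr5;Parent={g.transcript_id}",
                        ]
                    )
                )
        return "\n".join(lines) + "\n"


def write_fasta(chroms: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _rel_to_genomic(g: SimGene, p: int) -> int:
    """Map a TSS-relative position (no 0) to a genomic 1-based coordinate."""
    step = p - 1 if p > 0 else p
    return g.tss + step if g.strand == "+" else g.tss - step


def simulate_genome(spec: GenomeSpec) -> SyntheticGenome:
    """Generate sequence, gene models and a planted-element truth table.

    Layout draws an intergenic gap before each gene, so every gene's
    upstream region is at least ``intergenic_min`` bp of pure intergenic
    sequence on either strand.
    """
    rng = np.random.default_rng(spec.seed)

    genes: list[SimGene] = []
    pos = 0  # rightmost coordinate used so far
    for i in range(spec.n_genes):
        gap = int(rng.integers(spec.intergenic_min, spec.intergenic_max + 1))
        utr_len = int(rng.integers(spec.utr5_min, spec.utr5_max + 1))
        start = pos + gap + 1
        end = start + utr_len + spec.body_length - 1
        strand = "-" if rng.random() < spec.strand_fraction else "+"
        gid = f"{spec.transcript_prefix}{i + 1:05d}"
        genes.append(SimGene(gid, f"{gid}.t1", strand, start, end, utr_len))
        pos = end
    tail_gap = int(rng.integers(spec.intergenic_min, spec.intergenic_max + 1)) if spec.n_genes else 0
    needed = pos + tail_gap
    if spec.chrom_length is None:
        chrom_length = max(needed, 1000)
    else:
        chrom_length = spec.chrom_length
        if chrom_length < needed:
            raise GenomeSizingError(
                f"chrom_length {chrom_length} cannot fit {spec.n_genes} genes "
                f"with the requested spacing (needs >= {needed})"
            )

    gc = spec.gc_background
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=chrom_length, p=probs).copy()

    truth_rows = []
    for i, g in enumerate(genes):
        for pl in spec.element_plan.get(i, []):
            seq = pl.resolved_sequence()
            positions = pl.positions()
            if len(seq) != len(positions):
                raise ValueError(
                    f"gene {g.gene_id}: element {pl.element} sequence length "
                    f"{len(seq)} does not match window ({pl.start}, {pl.end})"
                )
            for p in positions:
                if p < 0 and -p > _upstream_gap(genes, i, chrom_length):
                    raise ValueError(
                        f"gene {g.gene_id}: plant position {p} outside the "
                        "intergenic gap"
                    )
                if p > 0 and p > g.utr5_length:
                    raise ValueError(
                        f"gene {g.gene_id}: plant position {p} beyond the 5'UTR"
                    )
            for base, p in zip(seq, positions):
                coord = _rel_to_genomic(g, p)
                if g.strand == "-":
                    base = base.translate(_COMPLEMENT)
                arr[coord - 1] = base.encode()
            truth_rows.append(
                {
                    "transcript": g.transcript_id,
                    "element": pl.element,
                    "rel_start": pl.start,
                    "rel_end": pl.end,
                    "sequence": seq,
                }
            )

    truth = pd.DataFrame(
        truth_rows, columns=["transcript", "element", "rel_start", "rel_end", "sequence"]
    )
    return SyntheticGenome(spec.chrom_name, arr.tobytes().decode(), genes, truth)


def _upstream_gap(genes: list[SimGene], i: int, chrom_length: int) -> int:
    """Intergenic bases available upstream (5') of gene i's TSS."""
    g = genes[i]
    if g.strand == "+":
        left = genes[i - 1].end if i > 0 else 0
        return g.start - left - 1
    right = genes[i + 1].start if i + 1 < len(genes) else chrom_length + 1
    return right - g.end - 1


def mirror_genome(sim: SyntheticGenome) -> SyntheticGenome:
    """The same genome on the opposite strand: reverse-complemented
    sequence with every gene's coordinates remapped and strand flipped.

    Promoter extraction and scanning must give identical results on the
    mirrored genome; the truth table is unchanged because TSS-relative
    coordinates are strand-invariant.
    """
    L = len(sim.sequence)
    rc = str(Seq(sim.sequence).reverse_complement())
    genes = [
        replace(
            g,
            strand="-" if g.strand == "+" else "+",
            start=L - g.end + 1,
            end=L - g.start + 1,
        )
        for g in sim.genes
    ]
    return SyntheticGenome(sim.chrom_name, rc, genes, sim.truth.copy())
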