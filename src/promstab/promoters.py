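"""TSS-anchored promoter extraction from a genome FASTA and GFF3 annotation.

Every transcript is anchored at its annotated 5' end (the TSS).  The
upstream *intergenic* sequence runs from the nearest annotated gene
boundary on the 5' side (either strand), capped at ``max_upstream``
bases, up to the base adjacent to the TSS; the 5'UTR is the annotated
five_prime_UTR sequence downstream of the TSS.  Both are reported in
transcript orientation (minus-strand genes reverse-complemented).

TSS-relative coordinates follow the biologist's convention: position -1
is the base immediately upstream of the TSS, +1 is the first transcribed
base, and there is no position 0.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio.Seq import Seq
from pyfaidx import Fasta

__all__ = [
    "TranscriptModel",
    "PromoterSequence",
    "find_tss",
    "extract_upstream",
    "extract_utr5",
    "window_sequence",
    "window_with_positions",
    "load_transcripts",
    "extract_promoters",
    "write_promoters",
    "read_promoters",
]


@dataclass
class TranscriptModel:
    """A transcript's span, strand, 5'UTR intervals and upstream neighbor.

    Coordinates are 1-based closed (GFF3 convention).  ``upstream_boundary``
    is the genomic coordinate of the nearest annotated gene edge on the
    transcript's 5' side (any strand), or None if there is no such gene.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    utr5_intervals: list[tuple[int, int]] = field(default_factory=list)
    upstream_boundary: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"transcript {self.transcript_id}: unknown strand {self.strand!r}"
            )
        for s, e in self.utr5_intervals:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: UTR interval ({s}, {e}) "
                    f"outside transcript span ({self.start}, {self.end})"
                )


@dataclass
class PromoterSequence:
    """Upstream (intergenic) and 5'UTR sequence pair, transcript-oriented.

    ``upstream`` ends at TSS-relative position -1; ``utr5`` starts at +1.
    ``intergenic_length`` equals ``len(upstream)`` (after the extraction cap).
    """

    transcript_id: str
    upstream: str
    utr5: str

    @property
    def intergenic_length(self) -> int:
        return len(self.upstream)


def find_tss(t: TranscriptModel) -> int:
    """Genomic coordinate of the annotated transcript 5' end."""
    return t.start if t.strand == "+" else t.end


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """1-based closed slice of a pyfaidx Fasta (or plain dict of strings)."""
    if start > end:
        return ""
    if isinstance(genome, dict):
        return genome[chrom][start - 1 : end].upper()
    return str(genome[chrom][start - 1 : end]).upper()


def _chrom_length(genome, chrom: str) -> int:
    if isinstance(genome, dict):
        return len(genome[chrom])
    return len(genome[chrom])


def extract_upstream(
    genome, t: TranscriptModel, max_len: int = 2000
) -> tuple[str, int]:
    """Intergenic sequence upstream of the TSS, in transcript orientation.

    Runs from ``min(max_len, distance to the upstream neighbor boundary)``
    bases upstream to the base adjacent to the TSS, truncated at the
    chromosome edge.  Returns ``(sequence, intergenic_length)``.
    """
    tss = find_tss(t)
    chrom_len = _chrom_length(genome, t.chrom)
    if t.strand == "+":
        avail = (tss - 1) if t.upstream_boundary is None else (tss - 1 - t.upstream_boundary)
        length = max(0, min(max_len, avail))
        seq = _fetch(genome, t.chrom, tss - length, tss - 1)
    else:
        avail = (chrom_len - tss) if t.upstream_boundary is None else (t.upstream_boundary - 1 - tss)
        length = max(0, min(max_len, avail))
        seq = str(Seq(_fetch(genome, t.chrom, tss + 1, tss + length)).reverse_complement())
    return seq, len(seq)


def extract_utr5(genome, t: TranscriptModel) -> str:
    """Concatenated five_prime_UTR sequence in transcript order.

    Empty string when the annotation carries no five_prime_UTR features;
    no inference from CDS is attempted.
    """
    if not t.utr5_intervals:
        return ""
    ivals = sorted(t.utr5_intervals, reverse=(t.strand == "-"))
    parts = []
    for s, e in ivals:
        piece = _fetch(genome, t.chrom, s, e)
        if t.strand == "-":
            piece = str(Seq(piece).reverse_complement())
        parts.append(piece)
    return "".join(parts)


def _positions(frm: int, to: int):
    if frm == 0 or to == 0:
        raise ValueError("TSS-relative coordinates have no position 0")
    if frm > to:
        raise ValueError(f"window start {frm} must be <= end {to}")
    return [p for p in range(frm, to + 1) if p != 0]


def window_with_positions(
    p: PromoterSequence, frm: int, to: int
) -> tuple[str, list[int]]:
    """Window bases plus the realized TSS-relative position of each base.

    Negative positions index the upstream sequence backwards from -1;
    positive positions index the 5'UTR forwards from +1.  Positions beyond
    the available sequence are clipped, so the returned window may be
    shorter than requested.
    """
    up, dn = p.upstream, p.utr5
    bases: list[str] = []
    kept: list[int] = []
    for pos in _positions(frm, to):
        if pos < 0:
            idx = len(up) + pos
            if 0 <= idx:
                bases.append(up[idx])
                kept.append(pos)
        else:
            idx = pos - 1
            if idx < len(dn):
                bases.append(dn[idx])
                kept.append(pos)
    return "".join(bases), kept


def window_sequence(p: PromoterSequence, frm: int, to: int) -> str:
    """Bases at TSS-relative positions ``frm..to`` (no position 0), clipped."""
    return window_with_positions(p, frm, to)[0]


# -- GFF3 loading -------------------------------------------------------------

def load_transcripts(gff3_path) -> list[TranscriptModel]:
    """Build TranscriptModels for every mRNA feature of a GFF3 file.

    Transcripts are mRNA features with a Parent gene; the upstream
    neighbor boundary is the nearest edge of any OTHER gene feature on the
    transcript's 5' side, regardless of strand.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g in db.features_of_type("gene"):
        genes_by_chrom.setdefault(g.seqid, []).append((g.start, g.end, g.id))

    ends_sorted: dict[str, list[tuple[int, str]]] = {}
    starts_sorted: dict[str, list[tuple[int, str]]] = {}
    for chrom, spans in genes_by_chrom.items():
        ends_sorted[chrom] = sorted((e, gid) for s, e, gid in spans)
        starts_sorted[chrom] = sorted((s, gid) for s, e, gid in spans)

    out: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA"):
        gene_id = mrna.attributes.get("Parent", [None])[0]
        utrs = sorted(
            (u.start, u.end)
            for u in db.children(mrna, featuretype="five_prime_UTR")
        )
        chrom = mrna.seqid
        if mrna.strand == "+":
            # nearest gene end strictly left of the TSS, skipping own gene
            boundary = None
            cand = ends_sorted.get(chrom, [])
            i = bisect.bisect_left(cand, (mrna.start, "")) - 1
            while i >= 0:
                e, gid = cand[i]
                if gid != gene_id:
                    boundary = e
                    break
                i -= 1
        else:
            boundary = None
            cand = starts_sorted.get(chrom, [])
            i = bisect.bisect_right(cand, (mrna.end, "\x7f"))
            while i < len(cand):
                s, gid = cand[i]
                if gid != gene_id:
                    boundary = s
                    break
                i += 1
        out.append(
            TranscriptModel(
                transcript_id=mrna.id,
                gene_id=gene_id,
                chrom=chrom,
                strand=mrna.strand,
                start=mrna.start,
                end=mrna.end,
                utr5_intervals=utrs,
                upstream_boundary=boundary,
            )
        )
    out.sort(key=lambda t: t.transcript_id)
    return out


def extract_promoters(
    fasta_path,
    gff3_path,
    max_upstream: int = 2000,
    transcript_ids=None,
) -> list[PromoterSequence]:
    """Extract PromoterSequences for all (or selected) transcripts."""
    genome = Fasta(str(fasta_path))
    transcripts = load_transcripts(gff3_path)
    if transcript_ids is not None:
        wanted = set(transcript_ids)
        transcripts = [t for t in transcripts if t.transcript_id in wanted]
    out = []
    for t in transcripts:
        up, _ = extract_upstream(genome, t, max_len=max_upstream)
        utr = extract_utr5(genome, t)
        out.append(PromoterSequence(t.transcript_id, up, utr))
    return out


def write_promoters(promoters: list[PromoterSequence], path) -> None:
    df = pd.DataFrame(
        {
            "transcript": [p.transcript_id for p in promoters],
            "intergenic_length": [p.intergenic_length for p in promoters],
            "upstream_seq": [p.upstream for p in promoters],
            "utr5_seq": [p.utr5 for p in promoters],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_promoters(path) -> list[PromoterSequence]:
    df = pd.read_csv(path, sep="\t", na_filter=False, dtype=str)
    return [
        PromoterSequence(r.transcript, r.upstream_seq, r.utr5_seq)
        for r in df.itertuples()
    ]
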