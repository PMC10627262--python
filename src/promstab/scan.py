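"""Core promoter element labeling by PWM and octamer scanning.

Two complementary screens are applied to each TSS-anchored promoter:

* a *motif scan* that slides a position weight matrix (PWM) across a
  fixed TSS-relative window and calls an element present when the best
  min-max-normalized ("relative") score exceeds a threshold
  (default 0.85, strict); and
* an *octamer scan* that calls an element present when at least one
  8-mer from the element's list occurs entirely inside a (narrower)
  TSS-relative window.

An element counts as present if EITHER method is positive.  Promoters
whose intergenic region is shorter than 100 bp are Unscannable; the
remaining promoters are classified TATA, YPatch or Coreless (precedence
TATA > YPatch; Inr, CA and GA flags are recorded but do not change the
class).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .promoters import PromoterSequence, window_with_positions

__all__ = [
    "PWM",
    "OctamerSet",
    "ScanWindows",
    "MotifHit",
    "OctamerHit",
    "CorePromoterLabel",
    "pwm_relative_score",
    "motif_scan",
    "octamer_scan",
    "combine_labels",
    "scan_promoter",
    "scan_promoters",
    "load_pwm",
    "load_pwm_dir",
    "load_octamers",
    "load_octamer_dir",
    "default_pwms",
    "default_octamers",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

MIN_INTERGENIC = 100  # bp; shorter intergenic regions are Unscannable

MOTIF_ELEMENTS = ("TATA", "YPatch", "Inr")
OCTAMER_ELEMENTS = ("TATA", "YPatch", "CA", "GA")
CLASS_ELEMENTS = ("TATA", "YPatch")  # precedence order for the class call


@dataclass
class PWM:
    """Position weight matrix with per-position scores for A, C, G, T.

    ``weights`` has shape (length, 4), column order A, C, G, T.  Scores are
    additive (log-odds-like); only differences within a position matter
    for the min-max-normalized relative score.
    """

    name: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise ValueError(f"PWM {self.name}: weights must be (length, 4)")
        if self.weights.shape[0] < 2:
            raise ValueError(f"PWM {self.name}: length must be >= 2")
        if not np.isfinite(self.weights).all():
            raise ValueError(f"PWM {self.name}: non-finite weights")

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @property
    def consensus(self) -> str:
        """Per-position argmax chain (ties broken toward A<C<G<T)."""
        return "".join(_BASES[i] for i in self.weights.argmax(axis=1))

    @classmethod
    def from_frequencies(
        cls,
        name: str,
        freqs: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.01,
    ) -> "PWM":
        """Convert a position frequency/count matrix to log2-odds weights."""
        f = np.asarray(freqs, dtype=float)
        if (f < 0).any():
            raise ValueError(f"PWM {name}: negative frequencies")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        f = f + pseudocount
        f = f / f.sum(axis=1, keepdims=True)
        return cls(name, np.log2(f / bg))


@dataclass
class OctamerSet:
    """Named set of 8-mers over A/C/G/T defining one octamer element."""

    name: str
    octamers: frozenset[str]

    def __post_init__(self) -> None:
        self.octamers = frozenset(s.upper() for s in self.octamers)
        for s in self.octamers:
            if len(s) != 8 or any(c not in _BASE_INDEX for c in s):
                raise ValueError(
                    f"octamer set {self.name}: {s!r} is not an 8-mer over ACGT"
                )


@dataclass
class ScanWindows:
    """TSS-relative (from, to) scan windows per element and method.

    Defaults: motif scan TATA (-100, -1), YPatch (-100, +100),
    Inr (-10, +10); octamer scan TATA (-45, -18), YPatch (-50, +50),
    CA (-35, -1), GA (-35, +75).  No position 0 exists.
    """

    motif: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "TATA": (-100, -1),
            "YPatch": (-100, 100),
            "Inr": (-10, 10),
        }
    )
    octamer: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "TATA": (-45, -18),
            "YPatch": (-50, 50),
            "CA": (-35, -1),
            "GA": (-35, 75),
        }
    )

    def __post_init__(self) -> None:
        for method in (self.motif, self.octamer):
            for elem, (frm, to) in method.items():
                if frm == 0 or to == 0 or frm >= to:
                    raise ValueError(f"bad window for {elem}: ({frm}, {to})")

    @classmethod
    def from_dict(cls, d: dict) -> "ScanWindows":
        w = cls()
        for method in ("motif", "octamer"):
            for elem, pair in d.get(method, {}).items():
                getattr(w, method)[elem] = (int(pair[0]), int(pair[1]))
        w.__post_init__()
        return w


@dataclass
class MotifHit:
    flag: bool
    best_score: float | None  # None when no valid offset (short or all-N)
    best_position: int | None  # TSS-relative start of the best window


@dataclass
class OctamerHit:
    flag: bool
    matches: list[tuple[str, int]]  # (octamer, TSS-relative start)


@dataclass
class CorePromoterLabel:
    transcript_id: str
    scannable: bool
    motif: dict[str, MotifHit]
    octamer: dict[str, OctamerHit]
    combined: dict[str, bool]
    promoter_class: str  # TATA | YPatch | Coreless | Unscannable


def pwm_relative_score(pwm: PWM, seq: str) -> tuple[float | None, int | None]:
    """Best min-max-normalized PWM score over all forward-strand offsets.

    The raw score at an offset is the sum of per-position weights for the
    window's bases; the relative score rescales it by the least and
    greatest raw scores any sequence could achieve, giving a value in
    [0, 1].  Offsets whose window contains a non-ACGT base are skipped;
    returns (None, None) when no offset is valid.
    """
    seq = seq.upper()
    L = pwm.length
    if len(seq) < L:
        return None, None
    lo = pwm.weights.min(axis=1).sum()
    hi = pwm.weights.max(axis=1).sum()
    span = hi - lo
    best: float | None = None
    best_off: int | None = None
    w = pwm.weights
    for off in range(len(seq) - L + 1):
        raw = 0.0
        ok = True
        for j in range(L):
            idx = _BASE_INDEX.get(seq[off + j])
            if idx is None:
                ok = False
                break
            raw += w[j, idx]
        if not ok:
            continue
        rel = (raw - lo) / span if span > 0 else 1.0
        if best is None or rel > best:
            best, best_off = rel, off
    if best is None:
        return None, None
    return float(best), best_off


def motif_scan(
    p: PromoterSequence,
    pwms: dict[str, PWM],
    windows: ScanWindows | None = None,
    threshold: float = 0.85,
) -> dict[str, MotifHit]:
    """PWM scan of each element's TSS-relative window; flag iff best > threshold."""
    windows = windows or ScanWindows()
    hits: dict[str, MotifHit] = {}
    for elem, (frm, to) in windows.motif.items():
        if elem not in pwms:
            continue
        seq, positions = window_with_positions(p, frm, to)
        score, off = pwm_relative_score(pwms[elem], seq)
        if score is None:
            hits[elem] = MotifHit(False, None, None)
        else:
            hits[elem] = MotifHit(score > threshold, score, positions[off])
    return hits


def octamer_scan(
    p: PromoterSequence,
    octamers: dict[str, OctamerSet],
    windows: ScanWindows | None = None,
) -> dict[str, OctamerHit]:
    """Exact 8-mer containment scan of each element's TSS-relative window."""
    windows = windows or ScanWindows()
    hits: dict[str, OctamerHit] = {}
    for elem, (frm, to) in windows.octamer.items():
        if elem not in octamers:
            continue
        seq, positions = window_with_positions(p, frm, to)
        matches: list[tuple[str, int]] = []
        for off in range(len(seq) - 7):
            kmer = seq[off : off + 8]
            if kmer in octamers[elem].octamers:
                matches.append((kmer, positions[off]))
        hits[elem] = OctamerHit(bool(matches), matches)
    return hits


def combine_labels(
    transcript_id: str,
    motif_hits: dict[str, MotifHit],
    octamer_hits: dict[str, OctamerHit],
    scannable: bool,
) -> CorePromoterLabel:
    """OR the two methods per element and assign the promoter class.

    Class precedence: TATA, then YPatch, else Coreless; Unscannable
    overrides everything.  Both combined flags are retained so a
    different precedence can be re-applied downstream.
    """
    elements = sorted(set(motif_hits) | set(octamer_hits))
    combined = {
        e: (e in motif_hits and motif_hits[e].flag)
        or (e in octamer_hits and octamer_hits[e].flag)
        for e in elements
    }
    if not scannable:
        cls = "Unscannable"
    else:
        cls = "Coreless"
        for e in CLASS_ELEMENTS:
            if combined.get(e, False):
                cls = e
                break
    return CorePromoterLabel(transcript_id, scannable, motif_hits, octamer_hits, combined, cls)


def scan_promoter(
    p: PromoterSequence,
    pwms: dict[str, PWM],
    octamers: dict[str, OctamerSet],
    windows: ScanWindows | None = None,
    threshold: float = 0.85,
    min_intergenic: int = MIN_INTERGENIC,
) -> CorePromoterLabel:
    scannable = p.intergenic_length >= min_intergenic
    if not scannable:
        return combine_labels(p.transcript_id, {}, {}, False)
    m = motif_scan(p, pwms, windows, threshold)
    o = octamer_scan(p, octamers, windows)
    return combine_labels(p.transcript_id, m, o, True)


def scan_promoters(
    promoters: list[PromoterSequence],
    pwms: dict[str, PWM],
    octamers: dict[str, OctamerSet],
    windows: ScanWindows | None = None,
    threshold: float = 0.85,
    min_intergenic: int = MIN_INTERGENIC,
) -> pd.DataFrame:
    """Label a promoter list; one row per promoter, flat columns for TSV."""
    rows = []
    for p in promoters:
        lab = scan_promoter(p, pwms, octamers, windows, threshold, min_intergenic)
        row: dict = {
            "transcript": lab.transcript_id,
            "intergenic_length": p.intergenic_length,
            "scannable": lab.scannable,
            "class": lab.promoter_class,
        }
        for e in MOTIF_ELEMENTS:
            hit = lab.motif.get(e)
            row[f"motif_{e}"] = bool(hit and hit.flag)
            row[f"motif_{e}_score"] = (
                round(hit.best_score, 6) if hit and hit.best_score is not None else math.nan
            )
            row[f"motif_{e}_pos"] = (
                hit.best_position if hit and hit.best_position is not None else pd.NA
            )
        for e in OCTAMER_ELEMENTS:
            hit = lab.octamer.get(e)
            row[f"oct_{e}"] = bool(hit and hit.flag)
            row[f"oct_{e}_matches"] = (
                ";".join(f"{k}@{pos}" for k, pos in hit.matches) if hit else ""
            )
        for e in sorted(set(MOTIF_ELEMENTS) | set(OCTAMER_ELEMENTS)):
            row[f"combined_{e}"] = lab.combined.get(e, False)
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("transcript", kind="stable").reset_index(drop=True)
    return df


def write_labels(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_filter=True, keep_default_na=True)


# -- PWM / octamer file loading ----------------------------------------------

def load_pwm(path, background: np.ndarray | None = None) -> PWM:
    """Load a JASPAR-like plain-text PWM.

    Format: an optional ``>name`` header, then four rows labeled A, C, G,
    T with whitespace-separated numbers (brackets allowed).  All-non-
    negative matrices are treated as frequencies/counts and converted to
    log2-odds against ``background`` (default uniform); matrices with
    negative entries are used as additive scores directly.
    """
    path = Path(path)
    name = path.stem
    rows: dict[str, list[float]] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            name = line[1:].strip() or name
            continue
        parts = line.replace("[", " ").replace("]", " ").split()
        if parts[0].upper() in _BASE_INDEX and len(parts) > 1:
            rows[parts[0].upper()] = [float(x) for x in parts[1:]]
    if set(rows) != set(_BASES):
        raise ValueError(f"PWM file {path}: need rows for A, C, G and T")
    mat = np.array([rows[b] for b in _BASES], dtype=float).T  # (length, 4)
    if (mat >= 0).all():
        return PWM.from_frequencies(name, mat, background=background)
    return PWM(name, mat)


def load_pwm_dir(directory, background: np.ndarray | None = None) -> dict[str, PWM]:
    pwms = {}
    for path in sorted(Path(directory).glob("*.pwm")):
        pwm = load_pwm(path, background=background)
        pwms[pwm.name] = pwm
    return pwms


def load_octamers(path, name: str | None = None) -> OctamerSet:
    """Load an octamer list (one 8-mer per line, '#' comments allowed)."""
    path = Path(path)
    kmers = [
        ln.strip().upper()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    return OctamerSet(name or path.stem, frozenset(kmers))


def load_octamer_dir(directory) -> dict[str, OctamerSet]:
    sets = {}
    for path in sorted(Path(directory).glob("*.txt")):
        s = load_octamers(path)
        sets[s.name] = s
    return sets


def default_pwms() -> dict[str, PWM]:
    """Synthetic idealized PWMs shipped with the package.

    These are constructed matrices whose consensus chains match the
    element sequences the synthetic genome generator plants; real
    analyses should supply PWM files from a curated motif source.
    """
    root = resources.files("promstab").joinpath("data/motifs_synthetic")
    with resources.as_file(root) as d:
        return load_pwm_dir(d)


def default_octamers() -> dict[str, OctamerSet]:
    """Synthetic octamer lists shipped with the package (see default_pwms)."""
    root = resources.files("promstab").joinpath("data/octamers_synthetic")
    with resources.as_file(root) as d:
        return load_octamer_dir(d)
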