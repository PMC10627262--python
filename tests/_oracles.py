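"""Independent brute-force oracles and random-case generators for scans."""

import numpy as np

from promstab.promoters import PromoterSequence
from promstab.scan import PWM

BASES = "ACGT"


def brute_force_relative_score(pwm, seq):
    """Direct per-offset summation with dict lookups (oracle)."""
    cols = [
        {b: float(pwm.weights[i, j]) for j, b in enumerate(BASES)}
        for i in range(pwm.length)
    ]
    lo = sum(min(c.values()) for c in cols)
    hi = sum(max(c.values()) for c in cols)
    best, best_off = None, None
    for off in range(len(seq) - pwm.length + 1):
        window = seq[off : off + pwm.length]
        if any(b not in BASES for b in window):
            continue
        raw = sum(cols[i][b] for i, b in enumerate(window))
        rel = (raw - lo) / (hi - lo) if hi > lo else 1.0
        if best is None or rel > best:
            best, best_off = rel, off
    return best, best_off


def brute_force_octamer(p, kmers, frm, to):
    """Windowed substring search on the explicit coordinate axis (oracle)."""
    axis = list(range(-len(p.upstream), 0)) + list(range(1, len(p.utr5) + 1))
    seq = p.upstream + p.utr5
    window = [(pos, base) for pos, base in zip(axis, seq) if frm <= pos <= to]
    text = "".join(b for _, b in window)
    matches = []
    for i in range(len(text) - 7):
        if text[i : i + 8] in kmers:
            matches.append((text[i : i + 8], window[i][0]))
    return matches


def random_pwm(rng, length):
    return PWM("rnd", rng.normal(size=(length, 4)))


def random_promoter(rng, up_len=120, utr_len=60):
    up = "".join(rng.choice(list(BASES), size=up_len)) if up_len else ""
    dn = "".join(rng.choice(list(BASES), size=utr_len)) if utr_len else ""
    return PromoterSequence("p", up, dn)
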