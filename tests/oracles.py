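"""Naive, independent reference implementations used to check production code.

Everything here is deliberately written the slow, obvious way: explicit
256-entry tables keyed by tetramer strings, pure-Python window scans and
term-by-term log sums, with no shared code with the package internals.
"""

import itertools
import math

TETRAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=4)]


def naive_counts(seq: str):
    """Tetramer and mononucleotide counts by explicit window scan."""
    seq = seq.upper()
    tet = {t: 0 for t in TETRAMERS}
    valid_windows = 0
    for i in range(len(seq) - 3):
        w = seq[i:i + 4]
        if all(c in "ACGT" for c in w):
            tet[w] += 1
            valid_windows += 1
    mono = {b: seq.count(b) for b in "ACGT"}
    return tet, mono, valid_windows


def naive_dkl_ouv(seq: str):
    """(D_KL in nats, D_OUV) by term-by-term summation over the 256 table."""
    tet, mono, valid = naive_counts(seq)
    total = sum(mono.values())
    mono_freq = {b: mono[b] / total for b in "ACGT"}
    dkl = 0.0
    ouv_sum = 0.0
    for t in TETRAMERS:
        obs = tet[t] / valid
        if obs == 0:
            continue
        exp = 1.0
        for c in t:
            exp *= mono_freq[c]
        dkl += obs * math.log(obs / exp)
        ouv_sum += obs / exp
    return dkl, ouv_sum / 256.0
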