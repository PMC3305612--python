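"""Tetranucleotide signature statistics against a zero-order Markov null.

The central quantity is the relative entropy (Kullback-Leibler divergence)
between the observed tetranucleotide frequencies of a DNA sequence and the
frequencies expected if every base occurred independently with its
sequence-wide frequency (a zero-order Markov model):

    D_KL(s) = sum_i O(z_i|s) * log( O(z_i|s) / E(z_i|s) )

where z_1..z_256 enumerate all tetramers and E is the product of the four
mononucleotide frequencies.  A high D_KL means strong dependence between
neighbouring bases (a pronounced genome signature); a low D_KL means the
sequence looks like an independent-base shuffle of itself.  The related
oligonucleotide-usage statistic

    D_OUV(s) = (1/256) * sum_i O(z_i|s) / E(z_i|s)

is the mean observed/expected ratio over the 256 tetramer cells.

Conventions (documented, switchable where noted):

* logarithms are natural (nats) by default; pass ``log_base`` to change;
* only the given strand is counted -- no reverse-complement pooling;
* sequences are treated as linear (no wrap-around windows);
* tetramer windows containing any non-ACGT symbol are skipped, and
  mononucleotide frequencies are taken over unambiguous ACGT bases only;
* 0 * log 0 := 0 in D_KL, and zero-observed cells contribute 0 to D_OUV;
* frequencies are raw maximum-likelihood estimates (no pseudocounts);
* tetramers are indexed in lexicographic order over A < C < G < T.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BASES",
    "TETRAMERS",
    "SequenceRecord",
    "KmerSpectrum",
    "EntropyResult",
    "encode",
    "count_tetramers",
    "zero_order_expected",
    "kl_divergence",
    "ouv",
    "at_content",
    "analyze_sequence",
]

BASES = "ACGT"
K = 4
N_TETRAMERS = 4**K

#: all 256 tetramers in lexicographic order over A < C < G < T
TETRAMERS = tuple("".join(p) for p in itertools.product(BASES, repeat=K))

CLASS_LABELS = ("chromosome", "island", "phage", "plasmid", "gene", "other")
DOMAIN_LABELS = ("bacteria", "archaea", "synthetic")

# byte -> base code lookup; -1 marks anything that is not an unambiguous base
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)


class SignatureError(ValueError):
    """Raised for sequences or spectra the statistics are undefined on."""


def encode(residues: str) -> np.ndarray:
    """Map a DNA string to int8 codes A=0, C=1, G=2, T=3; other symbols -> -1."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for arrays of valid codes (0..3)."""
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass
class SequenceRecord:
    """One DNA sequence with optional cohort metadata.

    Residues are upper-cased on construction.  IUPAC ambiguity codes are
    retained in the string but excluded from all counting.
    """

    id: str
    residues: str
    class_label: str | None = None
    phylum: str | None = None
    domain_label: str | None = None

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if self.class_label is not None and self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def codes(self) -> np.ndarray:
        return encode(self.residues)


@dataclass
class KmerSpectrum:
    """Observed and zero-order expected tetramer frequencies for one sequence."""

    observed: np.ndarray  # (256,) frequencies, lexicographic tetramer order
    expected: np.ndarray  # (256,) zero-order product frequencies
    mono: np.ndarray  # (4,) mononucleotide frequencies (A, C, G, T)
    valid_windows: int  # number of counted (N-free) tetramer positions


@dataclass
class EntropyResult:
    """Per-sequence summary: D_KL, D_OUV, composition and size."""

    id: str
    dkl: float  # relative entropy, nats unless a log base was requested
    douv: float  # mean observed/expected tetramer ratio
    at_content: float
    gc_content: float
    length: int
    valid_windows: int


def count_tetramers(record: SequenceRecord) -> KmerSpectrum:
    """Count overlapping tetramer windows (step 1) on the given strand.

    Windows containing any non-ACGT symbol are skipped; mononucleotide
    frequencies are computed over all unambiguous bases of the sequence.
    """
    codes = record.codes()
    n = codes.size
    if n < K:
        raise SignatureError(f"sequence too short: {record.id} ({n} < {K} bp)")
    valid = codes >= 0
    base_counts = np.bincount(codes[valid], minlength=4).astype(float)

    c0, c1, c2, c3 = codes[:-3], codes[1:-2], codes[2:-1], codes[3:]
    win_ok = valid[:-3] & valid[1:-2] & valid[2:-1] & valid[3:]
    idx = (
        (c0.astype(np.int32) << 6)
        | (c1.astype(np.int32) << 4)
        | (c2.astype(np.int32) << 2)
        | c3.astype(np.int32)
    )
    counts = np.bincount(idx[win_ok], minlength=N_TETRAMERS).astype(float)
    valid_windows = int(win_ok.sum())
    if valid_windows == 0:
        raise SignatureError(f"no countable tetramers in {record.id}")

    mono = base_counts / base_counts.sum()
    observed = counts / valid_windows
    expected = zero_order_expected(mono)
    return KmerSpectrum(observed=observed, expected=expected, mono=mono,
                        valid_windows=valid_windows)


def zero_order_expected(mono: np.ndarray) -> np.ndarray:
    """Expected tetramer frequencies under independent bases.

    ``expected[w1 w2 w3 w4] = mono[w1] * mono[w2] * mono[w3] * mono[w4]``.
    """
    mono = np.asarray(mono, dtype=float)
    if mono.shape != (4,) or np.any(mono < 0):
        raise SignatureError("mono must be 4 non-negative frequencies")
    if abs(mono.sum() - 1.0) > 1e-6:
        raise SignatureError(f"mono frequencies sum to {mono.sum():.6g}, not 1")
    return np.einsum("i,j,k,l->ijkl", mono, mono, mono, mono).ravel()


def _check_support(spectrum: KmerSpectrum) -> np.ndarray:
    obs = np.asarray(spectrum.observed, dtype=float)
    exp = np.asarray(spectrum.expected, dtype=float)
    mask = obs > 0
    if np.any(exp[mask] <= 0):
        raise SignatureError(
            "inconsistent spectrum: observed tetramer with zero expectation")
    return mask


def kl_divergence(spectrum: KmerSpectrum, log_base: float | None = None) -> float:
    """Relative entropy sum_i O_i log(O_i / E_i) in nats (or ``log_base`` units).

    Cells with zero observed frequency contribute nothing (0 log 0 := 0).
    """
    mask = _check_support(spectrum)
    obs = spectrum.observed[mask]
    exp = spectrum.expected[mask]
    val = float(np.sum(obs * np.log(obs / exp)))
    if log_base is not None:
        val /= math.log(log_base)
    # Gibbs' inequality guarantees >= 0; clip float round-off on the boundary.
    return 0.0 if -1e-9 < val < 0.0 else val


def ouv(spectrum: KmerSpectrum) -> float:
    """Mean observed/expected tetramer ratio, (1/256) sum_i O_i / E_i.

    Zero-observed cells contribute 0, so a homopolymer scores 1/256.
    """
    mask = _check_support(spectrum)
    return float(np.sum(spectrum.observed[mask] / spectrum.expected[mask])
                 / N_TETRAMERS)


def at_content(record: SequenceRecord) -> float:
    """(#A + #T) / (#A + #C + #G + #T), ignoring ambiguous symbols."""
    codes = record.codes()
    counts = np.bincount(codes[codes >= 0], minlength=4)
    total = counts.sum()
    if total == 0:
        raise SignatureError(f"no unambiguous bases in {record.id}")
    return float((counts[0] + counts[3]) / total)


def analyze_sequence(record: SequenceRecord,
                     log_base: float | None = None) -> EntropyResult:
    """Compute the full per-sequence entropy summary."""
    spectrum = count_tetramers(record)
    at = float(spectrum.mono[0] + spectrum.mono[3])
    return EntropyResult(
        id=record.id,
        dkl=kl_divergence(spectrum, log_base=log_base),
        douv=ouv(spectrum),
        at_content=at,
        gc_content=1.0 - at,
        length=record.length,
        valid_windows=spectrum.valid_windows,
    )
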