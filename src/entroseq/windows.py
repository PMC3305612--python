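"""Per-chromosome relative-entropy profiles over non-overlapping windows.

A chromosome is cut into consecutive, non-overlapping windows (default
5 kbp); the relative entropy D_KL of each window is computed independently
and compared with the whole-sequence value.  Stable genomes give flat
profiles; regions of anomalously low D_KL — candidate horizontally acquired
or mutationally decayed segments — show up as runs of windows far below the
profile's typical level and can be flagged as genomic intervals.

Coordinates are 0-based, half-open throughout (BED convention).  The
trailing partial window is dropped.  Windows without any countable tetramer
(e.g. all-N) carry NaN and are excluded from summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signature import SequenceRecord, SignatureError, analyze_sequence

__all__ = ["WindowProfile", "profile", "flag_low_entropy"]


@dataclass
class WindowProfile:
    """Ordered per-window D_KL values plus the whole-sequence reference."""

    id: str
    window_size: int
    window_starts: np.ndarray  # 0-based starts, multiples of window_size
    window_dkls: np.ndarray  # nats; NaN marks uncountable windows
    whole_dkl: float

    @property
    def n_windows(self) -> int:
        return int(self.window_starts.size)

    @property
    def mean_window_dkl(self) -> float:
        return float(np.nanmean(self.window_dkls))


def profile(record: SequenceRecord, window_size: int = 5000) -> WindowProfile:
    """Compute the D_KL profile of ``record`` over non-overlapping windows.

    Each window's spectrum and divergence are computed on the window
    subsequence alone (mononucleotide frequencies included), so a window is
    compared against its own local zero-order null.
    """
    if window_size < 1000:
        raise ValueError("window_size must be >= 1000 bp "
                         "(256-cell spectra are too sparse below that)")
    n = record.length // window_size
    if n < 1:
        raise ValueError(
            f"sequence {record.id} ({record.length} bp) is shorter than one "
            f"window ({window_size} bp)")
    starts = np.arange(n, dtype=np.int64) * window_size
    dkls = np.empty(n)
    for i, s in enumerate(starts):
        sub = SequenceRecord(id=f"{record.id}:{s}",
                             residues=record.residues[s:s + window_size])
        try:
            dkls[i] = analyze_sequence(sub).dkl
        except SignatureError:
            dkls[i] = np.nan
    return WindowProfile(id=record.id, window_size=window_size,
                         window_starts=starts, window_dkls=dkls,
                         whole_dkl=analyze_sequence(record).dkl)


def flag_low_entropy(prof: WindowProfile, k: float = 2.0, *,
                     min_run: int = 3,
                     robust: bool = True) -> list[tuple[int, int]]:
    """Flag maximal runs of windows with anomalously low D_KL.

    A window is "low" when its D_KL falls below ``center - k * scale`` of
    the profile.  With ``robust=True`` (default) the center is the median
    and the scale the normal-consistent MAD (1.4826 * MAD); with
    ``robust=False`` they are the mean and sample SD.  The robust default
    keeps the threshold anchored to the bulk of the chromosome even when
    the anomalous region itself spans a sizeable fraction of the windows,
    which would otherwise inflate the SD and mask the region.

    Runs shorter than ``min_run`` windows are discarded: isolated dips at
    the few-percent level are expected from sampling noise alone, whereas
    compositionally distinct regions extend over many consecutive windows.
    Returns merged intervals as 0-based, half-open bp coordinates.
    """
    vals = prof.window_dkls
    finite = np.isfinite(vals)
    n = int(finite.sum())
    if prof.n_windows < 10:
        raise ValueError("profile too short to flag (< 10 windows)")
    if n < 10:
        raise ValueError("profile too short to flag (< 10 countable windows)")
    v = vals[finite]
    if robust:
        center = float(np.median(v))
        scale = 1.4826 * float(np.median(np.abs(v - center)))
    else:
        center = float(np.mean(v))
        scale = float(np.std(v, ddof=1))
    low = np.zeros(prof.n_windows, dtype=bool)
    low[finite] = v < center - k * scale

    intervals: list[tuple[int, int]] = []
    i = 0
    while i < low.size:
        if low[i]:
            j = i
            while j + 1 < low.size and low[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                intervals.append((int(prof.window_starts[i]),
                                  int(prof.window_starts[j]) + prof.window_size))
            i = j + 1
        else:
            i += 1
    return intervals
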