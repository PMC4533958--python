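"""Read-length and base-composition signature profiling.

Length histograms are computed over *all* reads (normalized per-sample
counts); the 5'U / 5'G / position-10 A signature fractions and the
positional base-frequency / information-content profiles are computed on
*unique* sequences only — the two denominators are deliberately
different.  Position numbering is 1-based from the 5' end; T and U are
treated as the same base, with {A, C, G, U} as the canonical internal
alphabet.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ALPHABET = ("A", "C", "G", "U")
_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

LENGTH_RANGE = (18, 36)          # closed range reported in histograms
SIGNATURE_LENGTHS = (24, 36)     # closed range for signature fractions


def _as_sequences(reads) -> list[str]:
    """Accept a BED6+seq DataFrame or any iterable of sequence strings."""
    if isinstance(reads, pd.DataFrame):
        return reads["seq"].tolist()
    return list(reads)


@dataclass
class LengthHistogram:
    """Per-length read counts over a closed length range."""

    counts: pd.Series            # index: length, values: read counts
    excluded: int                # reads outside the range
    fractions: pd.Series | None  # counts / total reads in range, if normalized

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def length_histogram(reads, length_range: tuple[int, int] = LENGTH_RANGE,
                     normalize: bool = False) -> LengthHistogram:
    """Histogram of read lengths over a closed range.

    Reads outside the range are excluded from the histogram but counted
    in the ``excluded`` tally.  An empty read set yields an all-zero
    histogram.  With ``normalize`` the per-length fractions of in-range
    reads are attached.
    """
    lo, hi = length_range
    seqs = _as_sequences(reads)
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64,
                          count=len(seqs))
    in_range = (lengths >= lo) & (lengths <= hi)
    idx = pd.RangeIndex(lo, hi + 1, name="length")
    counts = pd.Series(
        np.bincount(lengths[in_range] - lo, minlength=hi - lo + 1),
        index=idx, name="count")
    fractions = None
    if normalize:
        total = counts.sum()
        fractions = (counts / total if total > 0
                     else counts.astype(float)).rename("fraction")
    return LengthHistogram(counts=counts, excluded=int((~in_range).sum()),
                           fractions=fractions)


def unique_sequences(reads) -> tuple[set[str], int]:
    """Exact string deduplication; returns the set and its size."""
    seqs = set(_as_sequences(reads))
    return seqs, len(seqs)


def _canonical(seq: str) -> str | None:
    """Uppercase, T->U; None if the sequence has a non-ACGTU symbol."""
    s = seq.upper().replace("T", "U")
    if any(c not in "ACGU" for c in s):
        return None
    return s


def _char_matrix(seqs: list[str], length: int) -> np.ndarray:
    """(n, length) uint8 matrix of uppercase bytes, T mapped to U."""
    arr = np.array(seqs, dtype=f"S{length}").view("S1").reshape(len(seqs),
                                                                length)
    b = arr.view(np.uint8).copy()
    lower = (b >= ord("a")) & (b <= ord("z"))
    b[lower] -= 32
    b[b == ord("T")] = ord("U")
    return b


def signature_fractions(sequences, lengths: tuple[int, int] = SIGNATURE_LENGTHS
                        ) -> pd.DataFrame:
    """Per-length 5'U, 5'G and position-10 A fractions on unique sequences.

    Returns a DataFrame indexed by length with columns ``frac_5U``,
    ``frac_5G``, ``frac_10A`` and ``n`` (number of unique sequences of
    that length).  Lengths with no sequences have NaN fractions, not 0.
    Sequences containing a symbol outside ACGTU are skipped with a
    warning.
    """
    lo, hi = lengths
    uniq, _ = unique_sequences(sequences)
    by_len: dict[int, list[str]] = {}
    for s in uniq:
        by_len.setdefault(len(s), []).append(s)

    n = Counter()
    u5 = Counter()
    g5 = Counter()
    a10 = Counter()
    skipped = 0
    valid_bases = np.frombuffer(b"ACGU", dtype=np.uint8)
    for L, seqs in by_len.items():
        if not lo <= L <= hi:
            continue
        mat = _char_matrix(sorted(seqs), L)
        ok = np.isin(mat, valid_bases).all(axis=1)
        skipped += int((~ok).sum())
        mat = mat[ok]
        n[L] = mat.shape[0]
        u5[L] = int((mat[:, 0] == ord("U")).sum())
        g5[L] = int((mat[:, 0] == ord("G")).sum())
        if L >= 10:
            a10[L] = int((mat[:, 9] == ord("A")).sum())
    if skipped:
        log.warning("skipped %d sequences with non-ACGTU symbols", skipped)
    idx = pd.RangeIndex(lo, hi + 1, name="length")
    out = pd.DataFrame(index=idx)
    out["n"] = [n[L] for L in idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = out["n"].to_numpy(float)
        denom[denom == 0] = np.nan
        out["frac_5U"] = [u5[L] for L in idx] / denom
        out["frac_5G"] = [g5[L] for L in idx] / denom
        out["frac_10A"] = [a10[L] for L in idx] / denom
    return out[["frac_5U", "frac_5G", "frac_10A", "n"]]


@dataclass
class PositionalProfile:
    """Column-stochastic base-frequency matrix with per-position entropy
    (H, bits) and information content (IC = 2 - H, bits)."""

    length: int
    frequencies: pd.DataFrame    # 4 x L, rows A/C/G/U, columns 1..L
    entropy: np.ndarray          # H per position, bits
    information: np.ndarray      # IC per position, bits
    n_sequences: int


def positional_profile(sequences, length: int) -> PositionalProfile:
    """Base-frequency matrix and information content for unique sequences
    of one length.  H = -sum p log2 p with 0 log2 0 = 0; IC = 2 - H."""
    lo, hi = LENGTH_RANGE
    if not lo <= length <= hi:
        raise ValueError(f"length must be in [{lo}, {hi}], got {length}")
    uniq, _ = unique_sequences(sequences)
    seqs = [s for s in uniq if len(s) == length]
    counts = np.zeros((4, length), dtype=float)
    n = 0
    if seqs:
        mat = _char_matrix(sorted(seqs), length)
        valid_bases = np.frombuffer(b"ACGU", dtype=np.uint8)
        mat = mat[np.isin(mat, valid_bases).all(axis=1)]
        n = mat.shape[0]
        for i, base in enumerate(b"ACGU"):
            counts[i] = (mat == base).sum(axis=0)
    if n == 0:
        freqs = np.full((4, length), 0.25)
    else:
        freqs = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    H = -plogp.sum(axis=0)
    freq_df = pd.DataFrame(freqs, index=list(ALPHABET),
                           columns=pd.RangeIndex(1, length + 1,
                                                 name="position"))
    return PositionalProfile(length=length, frequencies=freq_df, entropy=H,
                             information=2.0 - H, n_sequences=n)


# --------------------------------------------------------------------------
# tabular exports
# --------------------------------------------------------------------------

def histogram_table(reads_by_sample: dict[str, object],
                    length_range: tuple[int, int] = LENGTH_RANGE
                    ) -> pd.DataFrame:
    """Long-format per-sample length histogram (length, sample, count,
    fraction)."""
    rows = []
    for sample, reads in reads_by_sample.items():
        h = length_histogram(reads, length_range, normalize=True)
        for L in h.counts.index:
            rows.append((sample, int(L), int(h.counts[L]),
                         float(h.fractions[L])))
    return pd.DataFrame(rows, columns=["sample", "length", "count",
                                       "fraction"])


def signature_table(reads_by_group: dict[str, object],
                    lengths: tuple[int, int] = SIGNATURE_LENGTHS
                    ) -> pd.DataFrame:
    """Per-group signature fractions pooled over the group's unique
    sequences (per-sample variants can be had by passing singleton
    groups)."""
    frames = []
    for group, reads in reads_by_group.items():
        t = signature_fractions(reads, lengths).reset_index()
        t.insert(0, "group", group)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def logo_table(reads_by_group: dict[str, object],
               lengths=(30, 33)) -> pd.DataFrame:
    """Positional base-frequency / entropy matrices (the data behind a
    sequence logo) for the requested lengths, one row per position."""
    rows = []
    for group, reads in reads_by_group.items():
        for L in lengths:
            prof = positional_profile(reads, L)
            for j in range(L):
                rows.append((group, L, j + 1,
                             *prof.frequencies.iloc[:, j].tolist(),
                             prof.entropy[j], prof.information[j]))
    return pd.DataFrame(rows, columns=["group", "length", "position",
                                       "A", "C", "G", "U", "H", "IC"])
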