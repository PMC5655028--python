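"""Exact scanning of promoters for PIF3 binding motifs.

PIF3 binds the G-box (CACGTG, its own reverse complement) and the PBE-box
(CACATG) in target promoters.  Sequences are upstream regions whose 3' end
abuts the A of the ATG start codon; hit positions are reported as negative
offsets of the motif's 5'-most base on the forward-strand coordinate
(-1 = the base immediately upstream of ATG).  Minus-strand hits are
occurrences of the reverse complement on the forward strand, reported at
the same coordinate convention, so plus/minus hits of palindromic motifs
coincide.  Matching is exact and case-insensitive; overlaps are allowed
and windows containing N never match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "G_BOX",
    "PBE_BOX",
    "DEFAULT_MOTIFS",
    "PromoterRecord",
    "MotifHit",
    "reverse_complement",
    "scan_motifs",
    "position_histogram",
    "histogram_modes",
    "presence_table",
]

G_BOX = "CACGTG"
PBE_BOX = "CACATG"
DEFAULT_MOTIFS = {"G-box": G_BOX, "PBE-box": PBE_BOX}
DEFAULT_WINDOW = 3000

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _validate_sequence(seq: str, what: str = "sequence") -> str:
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in _ALPHABET:
            raise ValueError(f"illegal character {ch!r} at position {i} in {what}")
    return up


@dataclass(frozen=True)
class PromoterRecord:
    """An upstream sequence whose 3' end is adjacent to the ATG."""

    seq_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_sequence(self.sequence, self.seq_id))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence.

    offset: position of the motif's 5'-most base relative to ATG (negative;
    -1 is the base immediately upstream of the A).  matched_text is the
    forward-strand substring (equals the motif on '+', its reverse
    complement on '-').
    """

    seq_id: str
    motif_name: str
    strand: str
    offset: int
    matched_text: str


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement over A/C/G/T/N (case-insensitive)."""
    return _validate_sequence(seq)[::-1].translate(_COMPLEMENT)


def scan_motifs(
    record: PromoterRecord,
    motifs: dict[str, str] | None = None,
    window: int = DEFAULT_WINDOW,
) -> list[MotifHit]:
    """All exact motif occurrences on both strands within the window.

    Only the last ``window`` bases (closest to ATG) are scanned when the
    sequence is longer; shorter sequences are scanned in full.  Hits are
    ordered by offset, then strand ('+' before '-'), then motif name.
    """
    if motifs is None:
        motifs = DEFAULT_MOTIFS
    seq = record.sequence
    if window < len(seq):
        seq = seq[len(seq) - window:]
    n = len(seq)
    hits: list[MotifHit] = []
    for name, motif in motifs.items():
        motif = _validate_sequence(motif, f"motif {name!r}")
        if not motif:
            raise ValueError("empty motif")
        m = len(motif)
        rc = reverse_complement(motif)
        for i in range(n - m + 1):
            text = seq[i : i + m]
            if "N" in text:
                continue
            offset = i - n
            if text == motif:
                hits.append(MotifHit(record.seq_id, name, "+", offset, text))
            if text == rc:
                hits.append(MotifHit(record.seq_id, name, "-", offset, text))
    hits.sort(key=lambda h: (h.offset, h.strand, h.motif_name))
    return hits


def position_histogram(
    hits: list[MotifHit],
    bin_bp: int = 100,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Hit counts per offset bin over [-window, 0).

    Returns a frame with bin_start, bin_end (offsets, bin_start inclusive)
    and count; the total count equals the number of hits.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be > 0")
    if window % bin_bp != 0:
        raise ValueError("bin_bp must divide the window")
    edges = np.arange(-window, 1, bin_bp)
    counts = np.zeros(edges.size - 1, dtype=int)
    for h in hits:
        if not -window <= h.offset < 0:
            continue
        counts[(h.offset + window) // bin_bp] += 1
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )


def histogram_modes(hist: pd.DataFrame, min_separation: int = 2) -> list[int]:
    """Local maxima of the binned counts, as candidate positional clusters.

    A non-empty bin is a mode when it is at least as high as its immediate
    neighbours and strictly higher than the nearest differing neighbour on
    each side; modes closer than ``min_separation`` lower-or-empty bins are
    merged (the higher one kept).  Returns bin_start offsets.
    """
    c = hist["count"].to_numpy()
    starts = hist["bin_start"].to_numpy()
    candidates = []
    for i in range(c.size):
        if c[i] == 0:
            continue
        # nearest differing neighbour on each side
        left = next((c[j] for j in range(i - 1, -1, -1) if c[j] != c[i]), -1)
        right = next((c[j] for j in range(i + 1, c.size) if c[j] != c[i]), -1)
        if c[i] > left and c[i] > right:
            if candidates and c[candidates[-1]] == c[i] and all(
                c[j] == c[i] for j in range(candidates[-1], i)
            ):
                continue  # plateau: keep the first bin only
            candidates.append(i)
    # enforce separation: drop the lower of two modes without a gap between
    modes: list[int] = []
    for i in candidates:
        if modes:
            prev = modes[-1]
            between = c[prev + 1 : i]
            lower = np.sum(between < min(c[prev], c[i]))
            if lower < min_separation:
                if c[i] > c[prev]:
                    modes[-1] = i
                continue
        modes.append(i)
    return [int(starts[i]) for i in modes]


def presence_table(hits: list[MotifHit], seq_ids=None, motif_names=None) -> pd.DataFrame:
    """Gene x motif presence/absence plus hit counts.

    Row order follows ``seq_ids`` when given, else first appearance in the
    hit list.  Columns: ``<motif>`` (bool) and ``<motif>_count`` per motif.
    """
    if motif_names is None:
        motif_names = sorted({h.motif_name for h in hits}) or list(DEFAULT_MOTIFS)
    if seq_ids is None:
        seen: list[str] = []
        for h in hits:
            if h.seq_id not in seen:
                seen.append(h.seq_id)
        seq_ids = seen
    counts = {
        (sid, m): 0 for sid in seq_ids for m in motif_names
    }
    for h in hits:
        key = (h.seq_id, h.motif_name)
        if key in counts:
            counts[key] += 1
    data = {}
    for m in motif_names:
        data[m] = [counts[(sid, m)] > 0 for sid in seq_ids]
        data[f"{m}_count"] = [counts[(sid, m)] for sid in seq_ids]
    return pd.DataFrame(data, index=pd.Index(seq_ids, name="seq_id"))
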