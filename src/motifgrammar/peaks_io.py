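"""ChIP-seq peak I/O: narrowPeak/BED parsing, strongest-peak selection, and
fixed-width windows around peak centres with their genomic sequences.

All coordinates are 0-based half-open (BED convention).  The peak centre is
the narrowPeak summit when present, otherwise the floor of the interval
midpoint; windows are ``[centre - flank, centre + flank)`` so every sequence
fed to the scanner has identical length ``2 * flank``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from pyfaidx import Fasta

log = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "Window",
    "LabelledSequence",
    "read_narrowpeak",
    "select_top_peaks",
    "peak_center",
    "make_windows",
    "fetch_sequences",
    "write_windows_bed",
    "write_fasta",
    "read_fasta",
]


@dataclass(frozen=True)
class Peak:
    """One ChIP-seq peak interval with its significance and class label."""

    chrom: str
    start: int
    end: int
    neg_log10_p: float = 0.0
    signal: float = 0.0
    summit_offset: int = -1
    cell_type: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start >= end")
        if self.neg_log10_p < 0:
            raise ValueError("neg_log10_p must be >= 0")
        if self.summit_offset != -1 and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside peak of length "
                f"{self.end - self.start}"
            )


@dataclass(frozen=True)
class Window:
    """A fixed-width genomic window centred on a peak."""

    chrom: str
    start: int
    end: int
    cell_type: str
    source_peak_id: str


@dataclass(frozen=True)
class LabelledSequence:
    """An uppercase A/C/G/T/N sequence with its cell-type label."""

    id: str
    sequence: str
    cell_type: str


class PeakParseError(ValueError):
    pass


def read_narrowpeak(path: str | Path, cell_type: str) -> list[Peak]:
    """Read an ENCODE narrowPeak (BED6+4) or plain BED (>=3 columns) file.

    narrowPeak column 8 (0-based 7) is -log10 p and column 10 the summit
    offset; plain BED lines default to significance 0 and no summit.
    Track/comment lines are skipped.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 3:
                raise PeakParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise PeakParseError(
                    f"{path}:{lineno}: malformed coordinates {f[1]!r}, {f[2]!r}"
                ) from exc
            if end <= start:
                raise PeakParseError(f"{path}:{lineno}: end <= start")
            neg_log10_p = 0.0
            signal = 0.0
            summit = -1
            if len(f) >= 10:  # full narrowPeak
                try:
                    signal = float(f[6])
                    neg_log10_p = float(f[7])
                    summit = int(f[9])
                except ValueError as exc:
                    raise PeakParseError(
                        f"{path}:{lineno}: malformed narrowPeak numeric fields"
                    ) from exc
                if neg_log10_p < 0:  # ENCODE uses -1 for "not available"
                    neg_log10_p = 0.0
                if summit < 0:
                    summit = -1
            try:
                peaks.append(
                    Peak(
                        chrom=f[0],
                        start=start,
                        end=end,
                        neg_log10_p=neg_log10_p,
                        signal=signal,
                        summit_offset=summit,
                        cell_type=cell_type,
                    )
                )
            except ValueError as exc:
                raise PeakParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def select_top_peaks(peaks: list[Peak], n: int) -> list[Peak]:
    """The ``n`` strongest unique peaks by -log10 p.

    Duplicate intervals (same chrom/start/end) collapse to the one with the
    largest -log10 p (ties: larger signal).  The survivors are sorted by
    -log10 p descending, then signal descending, then (chrom, start)
    ascending, and the first ``min(n, available)`` returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    best: dict[tuple[str, int, int], Peak] = {}
    for p in peaks:
        key = (p.chrom, p.start, p.end)
        cur = best.get(key)
        if cur is None or (p.neg_log10_p, p.signal) > (cur.neg_log10_p, cur.signal):
            best[key] = p
    ranked = sorted(
        best.values(),
        key=lambda p: (-p.neg_log10_p, -p.signal, p.chrom, p.start),
    )
    if len(ranked) < n:
        log.warning(
            "requested %d peaks but only %d unique peaks available", n, len(ranked)
        )
    return ranked[:n]


def peak_center(peak: Peak) -> int:
    """Summit position when recorded, else the floor of the interval midpoint."""
    if peak.summit_offset >= 0:
        return peak.start + peak.summit_offset
    return (peak.start + peak.end) // 2


def make_windows(
    peaks: list[Peak],
    flank: int,
    contig_lengths: dict[str, int] | None = None,
) -> list[Window]:
    """``[centre - flank, centre + flank)`` windows, one per peak.

    Windows that would extend past a contig boundary (or below position 0)
    are dropped, with a logged count, so that every downstream sequence has
    length exactly ``2 * flank``.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    windows: list[Window] = []
    dropped = 0
    for i, p in enumerate(peaks):
        if contig_lengths is not None and p.chrom not in contig_lengths:
            raise KeyError(f"contig {p.chrom!r} absent from contig-length table")
        c = peak_center(p)
        start, end = c - flank, c + flank
        if start < 0 or (
            contig_lengths is not None and end > contig_lengths[p.chrom]
        ):
            dropped += 1
            continue
        windows.append(
            Window(
                chrom=p.chrom,
                start=start,
                end=end,
                cell_type=p.cell_type,
                source_peak_id=f"{p.cell_type}_{p.chrom}_{p.start}_{p.end}_{i}",
            )
        )
    if dropped:
        log.info("dropped %d window(s) extending past contig boundaries", dropped)
    return windows


def fetch_sequences(windows: list[Window], genome: str | Path | Fasta) -> list[LabelledSequence]:
    """Extract reference-strand window sequences from an indexed FASTA.

    Soft-masked (lowercase) bases are uppercased; windows beyond contig
    bounds raise (they should have been dropped by :func:`make_windows`).
    """
    fa = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    out: list[LabelledSequence] = []
    for w in windows:
        if w.chrom not in fa:
            raise KeyError(f"contig {w.chrom!r} absent from FASTA")
        if w.end > len(fa[w.chrom]):
            raise ValueError(
                f"window {w.chrom}:{w.start}-{w.end} exceeds contig length "
                f"{len(fa[w.chrom])}"
            )
        seq = fa[w.chrom][w.start : w.end].seq.upper()
        out.append(
            LabelledSequence(id=w.source_peak_id, sequence=seq, cell_type=w.cell_type)
        )
    return out


def write_windows_bed(windows: list[Window], path: str | Path,
                      scores: dict[str, float] | None = None) -> None:
    """Write windows as BED6 (name = source peak id, strand '.')."""
    with open(path, "w") as fh:
        for w in windows:
            score = int(round(scores.get(w.source_peak_id, 0))) if scores else 0
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{w.source_peak_id}\t{score}\t.\n"
            )


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write (name, sequence) records as FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (name, sequence) records (whole file in memory)."""
    records: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records
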