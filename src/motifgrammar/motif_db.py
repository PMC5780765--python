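"""Motif database handling: HOMER-format PWMs with log-odds detection thresholds.

A motif is a position probability matrix (PPM) over A,C,G,T together with a
log-odds score cut-off above which a sequence window is called a hit.  The
on-disk representation is the HOMER motif format::

    >CONSENSUS<TAB>NAME<TAB>THRESHOLD
    pA pC pG pT      (one row per motif position)

Scores are natural-log likelihood ratios against a background base
distribution (uniform by default), with a small pseudocount applied to the
probabilities so that zero entries never produce -inf scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

BASES = "ACGT"
#: default background base frequencies (A, C, G, T)
UNIFORM_BACKGROUND = np.array([0.25, 0.25, 0.25, 0.25])
#: default pseudocount added to PPM entries before taking log-odds
DEFAULT_PSEUDOCOUNT = 1e-3
#: fraction of the maximum achievable score used when a file omits a threshold
DEFAULT_THRESHOLD_FRACTION = 0.8

__all__ = [
    "PWM",
    "MotifDatabase",
    "read_homer_motifs",
    "write_homer_motifs",
    "write_meme_motifs",
    "logodds_matrix",
    "max_score",
    "UNIFORM_BACKGROUND",
    "DEFAULT_PSEUDOCOUNT",
]


@dataclass
class PWM:
    """A named position probability matrix with a detection threshold.

    ``probs`` has one row per position, columns in A,C,G,T order; each row
    sums to 1 (renormalised on input if within 1e-2 of 1).  ``detection_threshold``
    is the log-odds score at or above which a window counts as an occurrence.
    """

    name: str
    consensus: str
    probs: np.ndarray
    detection_threshold: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"PWM {self.name!r}: probs must be width x 4")
        if self.probs.shape[0] < 1:
            raise ValueError(f"PWM {self.name!r}: width must be >= 1")
        if (self.probs < 0).any():
            raise ValueError(f"PWM {self.name!r}: negative probabilities")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "PWM":
        """PWM matching the reverse complement of this motif's sites."""
        rc = self.probs[::-1, ::-1].copy()
        return PWM(
            name=self.name,
            consensus=_revcomp_iupac(self.consensus),
            probs=rc,
            detection_threshold=self.detection_threshold,
        )


@dataclass
class MotifDatabase:
    """Ordered collection of PWMs with unique names."""

    motifs: list[PWM] = field(default_factory=list)
    source: str = ""

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def __getitem__(self, key):
        if isinstance(key, str):
            for m in self.motifs:
                if m.name == key:
                    return m
            raise KeyError(key)
        return self.motifs[key]

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.motifs]


def _revcomp_iupac(s: str) -> str:
    comp = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn", "TGCAYRMKVBHDNtgcayrmkvbhdn")
    return s.translate(comp)[::-1]


def _unique_name(name: str, seen: dict[str, int]) -> str:
    """Disambiguate duplicate motif names with _2, _3, ... suffixes."""
    if name not in seen:
        seen[name] = 1
        return name
    seen[name] += 1
    new = f"{name}_{seen[name]}"
    # guard against a literal "FOO_2" already present in the file
    while new in seen:
        seen[name] += 1
        new = f"{name}_{seen[name]}"
    seen[new] = 1
    return new


def read_homer_motifs(path: str | Path) -> MotifDatabase:
    """Parse a HOMER-format motif file into a :class:`MotifDatabase`.

    File order is preserved.  Probability rows summing within [0.99, 1.01]
    are renormalised to exactly 1; rows outside that band raise.  A header
    missing its threshold gets ``0.8 * max achievable log-odds score`` (with
    the default background/pseudocount) and a warning.
    """
    path = Path(path)
    motifs: list[PWM] = []
    seen: dict[str, int] = {}
    header: tuple[str, str, float | None] | None = None
    rows: list[list[float]] = []
    header_line = 0

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        consensus, name, thr = header
        if not rows:
            raise ValueError(
                f"{path}:{header_line}: motif {name!r} has no probability rows"
            )
        mat = np.array(rows, dtype=float)
        sums = mat.sum(axis=1)
        bad = np.where((sums < 0.99) | (sums > 1.01))[0]
        if bad.size:
            raise ValueError(
                f"{path}: motif {name!r} row {bad[0] + 1} sums to "
                f"{sums[bad[0]]:.4f}, outside [0.99, 1.01]"
            )
        mat = mat / sums[:, None]
        uname = _unique_name(name, seen)
        pwm = PWM(name=uname, consensus=consensus, probs=mat, detection_threshold=0.0)
        if thr is None:
            pwm.detection_threshold = DEFAULT_THRESHOLD_FRACTION * max_score(pwm)
            log.warning(
                "motif %s: no detection threshold in file; defaulting to "
                "%.1f x max achievable score = %.4f",
                uname, DEFAULT_THRESHOLD_FRACTION, pwm.detection_threshold,
            )
        else:
            pwm.detection_threshold = thr
        motifs.append(pwm)
        header, rows = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split("\t")
                if len(parts) == 1:  # tolerate space-separated headers
                    parts = line[1:].split()
                consensus = parts[0] if parts else ""
                name = parts[1] if len(parts) > 1 else consensus
                thr: float | None = None
                if len(parts) > 2 and parts[2] != "":
                    try:
                        thr = float(parts[2])
                    except ValueError as exc:
                        raise ValueError(
                            f"{path}:{lineno}: bad threshold {parts[2]!r}"
                        ) from exc
                header = (consensus, name, thr)
                header_line = lineno
            else:
                fields = line.split()
                if len(fields) != 4:
                    raise ValueError(
                        f"{path}:{lineno}: expected 4 probabilities, got "
                        f"{len(fields)}"
                    )
                try:
                    rows.append([float(x) for x in fields])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric entry") from exc
    flush()
    return MotifDatabase(motifs=motifs, source=str(path))


def write_homer_motifs(db: MotifDatabase, path: str | Path) -> None:
    """Serialise a database back to HOMER motif format."""
    with open(path, "w") as fh:
        for m in db:
            fh.write(f">{m.consensus}\t{m.name}\t{m.detection_threshold!r}\n")
            for row in m.probs:
                fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def write_meme_motifs(db: MotifDatabase, path: str | Path,
                      background: np.ndarray = UNIFORM_BACKGROUND) -> None:
    """Export to MEME minimal motif format (writer only, for interoperability)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {0:.5f} C {1:.5f} G {2:.5f} T {3:.5f}\n\n".format(*background))
        for m in db:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in m.probs:
                fh.write(" " + "  ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def logodds_matrix(
    pwm: PWM,
    background: np.ndarray = UNIFORM_BACKGROUND,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Natural-log odds scoring matrix for a PWM.

    ``entry[i, b] = log(((p[i, b] + c) / (1 + 4c)) / background[b])`` with
    pseudocount ``c``.  A zero probability with pseudocount 0 is rejected
    rather than yielding -inf.
    """
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or (background <= 0).any():
        raise ValueError("background must be 4 positive frequencies")
    if abs(background.sum() - 1.0) > 1e-6:
        raise ValueError("background frequencies must sum to 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    adj = (pwm.probs + pseudocount) / (1.0 + 4.0 * pseudocount)
    if (adj == 0).any():
        raise ValueError(
            f"PWM {pwm.name!r}: zero probability with pseudocount 0 would "
            "give a -inf score; use a positive pseudocount"
        )
    return np.log(adj / background[None, :])


def max_score(
    pwm: PWM,
    background: np.ndarray = UNIFORM_BACKGROUND,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Maximum achievable log-odds score (sum of per-position maxima)."""
    return float(logodds_matrix(pwm, background, pseudocount).max(axis=1).sum())
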