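"""Synthetic labelled sequence datasets with planted motif grammars.

The generator emulates the input the pipeline sees in a real study —
fixed-length sequence windows around ChIP-seq peak centres, labelled by
cell type — with a known, planted ground truth: each class is defined by
requirement clauses ("at least k instances of motif M"), optional exclusion
clauses, and a shared background of decoy motifs planted uniformly across
classes.  Windows sit at the centre of longer background contigs so the
peak-to-window part of the pipeline (and the window-size sweep) can run on
synthetic data exactly as it would on a genome.

Planted instances are sampled from the PWM (not its consensus) and
re-sampled until they score at or above the motif's detection threshold, so
by construction every class-c window re-scans to counts satisfying c's
clauses while remaining realistically noisy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .motif_db import (
    DEFAULT_THRESHOLD_FRACTION,
    MotifDatabase,
    PWM,
    logodds_matrix,
    max_score,
    write_homer_motifs,
)
from .motif_scanner import count_occurrences
from .peaks_io import LabelledSequence, Peak, Window, write_fasta

log = logging.getLogger(__name__)

#: default per-decoy-motif planting rate (expected instances per window);
#: with ~44 decoys of width 8 this keeps the expected planted footprint
#: (~35 bp) well below the 240 bp window capacity so non-overlapping
#: placement always succeeds
DEFAULT_LAMBDA_BG = 0.1
#: default half-width of the central region where required motifs are planted
DEFAULT_PLANT_HALFWIDTH = 100

__all__ = [
    "GrammarSpec",
    "SyntheticDataset",
    "make_random_pwm",
    "make_random_database",
    "default_benchmark",
    "generate_dataset",
    "null_dataset",
]

_BASES = "ACGT"


@dataclass
class GrammarSpec:
    """Planted class-specific grammar over a motif database.

    ``requirements[cls]`` is a list of (motif name, minimum count) clauses;
    ``exclusions[cls]`` lists motifs forced absent from class ``cls``.
    Decoy motifs are planted in every class at Poisson rate ``lambda_bg``
    per window.
    """

    classes: list[str]
    requirements: dict[str, list[tuple[str, int]]]
    exclusions: dict[str, list[str]] = field(default_factory=dict)
    decoy_motifs: list[str] = field(default_factory=list)
    lambda_bg: float = DEFAULT_LAMBDA_BG
    window_length: int = 240
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def validate(self, db: MotifDatabase) -> None:
        names = set(db.names)
        maxw = max(m.width for m in db)
        if self.window_length < maxw + 2:
            raise ValueError(
                f"window_length {self.window_length} must be >= max motif "
                f"width + 2 ({maxw + 2})"
            )
        for cls in self.classes:
            for motif, k in self.requirements.get(cls, []):
                if motif not in names:
                    raise ValueError(f"required motif {motif!r} not in database")
                if k < 1:
                    raise ValueError(f"min_count for {motif!r} must be >= 1")
            for motif in self.exclusions.get(cls, []):
                if motif not in names:
                    raise ValueError(f"excluded motif {motif!r} not in database")
        for motif in self.decoy_motifs:
            if motif not in names:
                raise ValueError(f"decoy motif {motif!r} not in database")
        if abs(sum(self.background) - 1.0) > 1e-6:
            raise ValueError("background frequencies must sum to 1")

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "requirements": {
                c: [[m, k] for m, k in v] for c, v in self.requirements.items()
            },
            "exclusions": self.exclusions,
            "decoy_motifs": self.decoy_motifs,
            "lambda_bg": self.lambda_bg,
            "window_length": self.window_length,
            "background": list(self.background),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GrammarSpec":
        return cls(
            classes=list(d["classes"]),
            requirements={
                c: [(m, int(k)) for m, k in v] for c, v in d["requirements"].items()
            },
            exclusions={c: list(v) for c, v in d.get("exclusions", {}).items()},
            decoy_motifs=list(d.get("decoy_motifs", [])),
            lambda_bg=float(d.get("lambda_bg", DEFAULT_LAMBDA_BG)),
            window_length=int(d.get("window_length", 240)),
            background=tuple(d.get("background", (0.25, 0.25, 0.25, 0.25))),
        )


@dataclass
class SyntheticDataset:
    """Generated windows plus everything needed to run the pipeline on them."""

    sequences: list[LabelledSequence]
    windows: list[Window]
    peaks: list[Peak]
    contigs: list[tuple[str, str]]
    database: MotifDatabase
    truth: GrammarSpec
    seed: int

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA/BED/TSV/JSON artefacts; byte-identical per seed."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "windows_fasta": outdir / "windows.fasta",
            "genome_fasta": outdir / "genome.fasta",
            "windows_bed": outdir / "windows.bed",
            "labels_tsv": outdir / "labels.tsv",
            "truth_json": outdir / "truth.json",
            "motifs_homer": outdir / "motifs.homer",
        }
        write_fasta([(s.id, s.sequence) for s in self.sequences], paths["windows_fasta"])
        write_fasta(self.contigs, paths["genome_fasta"])
        with open(paths["windows_bed"], "w") as fh:
            for w in self.windows:
                fh.write(
                    f"{w.chrom}\t{w.start}\t{w.end}\t{w.source_peak_id}\t0\t.\n"
                )
        with open(paths["labels_tsv"], "w") as fh:
            fh.write("sample_id\tcell_type\n")
            for s in self.sequences:
                fh.write(f"{s.id}\t{s.cell_type}\n")
        with open(paths["truth_json"], "w") as fh:
            json.dump({"seed": self.seed, "grammar": self.truth.to_dict()}, fh, indent=1)
        write_homer_motifs(self.database, paths["motifs_homer"])
        for cls in self.truth.classes:
            p = outdir / f"peaks_{cls}.narrowPeak"
            with open(p, "w") as fh:
                for pk in self.peaks:
                    if pk.cell_type != cls:
                        continue
                    fh.write(
                        f"{pk.chrom}\t{pk.start}\t{pk.end}\t{pk.cell_type}\t0\t.\t"
                        f"{pk.signal!r}\t{pk.neg_log10_p!r}\t-1\t{pk.summit_offset}\n"
                    )
            paths[f"peaks_{cls}"] = p
        return paths


def make_random_pwm(
    width: int = 8,
    concentration: float = 50.0,
    seed: int | np.random.Generator = 0,
    name: str = "MOTIF",
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> PWM:
    """Random PWM with Dirichlet rows sharpened towards a random consensus.

    Each row is Dirichlet(1 + concentration * e_b) for a uniformly chosen
    preferred base b: high concentration approaches a consensus (one-hot)
    matrix.  The detection threshold is ``threshold_fraction`` times the
    maximum achievable log-odds score.
    """
    if width < 4:
        raise ValueError("width must be >= 4")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = np.empty((width, 4))
    for i in range(width):
        b = int(rng.integers(4))
        alpha = np.ones(4)
        alpha[b] += concentration
        rows[i] = rng.dirichlet(alpha)
    consensus = "".join(_BASES[int(j)] for j in rows.argmax(axis=1))
    pwm = PWM(name=name, consensus=consensus, probs=rows, detection_threshold=0.0)
    pwm.detection_threshold = threshold_fraction * max_score(pwm)
    return pwm


def make_random_database(
    n_motifs: int,
    width: int = 8,
    concentration: float = 50.0,
    seed: int = 0,
    prefix: str = "M",
) -> MotifDatabase:
    """Database of ``n_motifs`` random PWMs named ``{prefix}001`` ..."""
    rng = np.random.default_rng(seed)
    digits = max(2, len(str(n_motifs)))
    motifs = [
        make_random_pwm(width=width, concentration=concentration, seed=rng,
                        name=f"{prefix}{i + 1:0{digits}d}")
        for i in range(n_motifs)
    ]
    return MotifDatabase(motifs=motifs, source=f"random(seed={seed})")


def default_benchmark(seed: int = 0, n_motifs: int = 50) -> tuple[GrammarSpec, MotifDatabase]:
    """The default planted benchmark: 5 classes over a 50-motif database.

    Classes cell1..cell4 each require >= 3 instances of their own motif
    (M01..M04); cell5 is the conjunctive class requiring M06 >= 1 AND
    M07 >= 1.  All remaining motifs (including M05) are decoys planted in
    every class at rate ``lambda_bg`` per window of 240 bp.
    """
    db = make_random_database(n_motifs, width=8, concentration=50.0, seed=seed)
    names = db.names
    classes = [f"cell{i}" for i in range(1, 6)]
    requirements = {
        "cell1": [(names[0], 3)],
        "cell2": [(names[1], 3)],
        "cell3": [(names[2], 3)],
        "cell4": [(names[3], 3)],
        "cell5": [(names[5], 1), (names[6], 1)],
    }
    informative = {m for v in requirements.values() for m, _ in v}
    grammar = GrammarSpec(
        classes=classes,
        requirements=requirements,
        decoy_motifs=[m for m in names if m not in informative],
        lambda_bg=DEFAULT_LAMBDA_BG,
        window_length=240,
    )
    grammar.validate(db)
    return grammar, db


# --------------------------------------------------------------------------
# generation internals
# --------------------------------------------------------------------------

def _sample_instance(pwm: PWM, rng: np.random.Generator, max_tries: int = 50) -> np.ndarray:
    """Sample a site from the PWM, re-sampling until it passes the threshold."""
    lo = logodds_matrix(pwm)
    cum = pwm.probs.cumsum(axis=1)
    for _ in range(max_tries):
        u = rng.random(pwm.width)
        codes = (u[:, None] > cum).sum(axis=1).astype(np.int8)
        score = float(lo[np.arange(pwm.width), codes].sum())
        if score >= pwm.detection_threshold:
            return codes
    # fall back to the consensus, which always reaches the threshold
    return pwm.probs.argmax(axis=1).astype(np.int8)


def _place(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    lo: int,
    hi: int,
    width: int,
    max_tries: int = 1000,
) -> int:
    """Uniform non-overlapping placement of one instance in [lo, hi]."""
    if hi < lo:
        raise ValueError("window too crowded: no room for a motif instance; "
                         "use longer windows or fewer planted instances")
    for _ in range(max_tries):
        pos = int(rng.integers(lo, hi + 1))
        if all(pos + width <= s or pos >= e for s, e in occupied):
            occupied.append((pos, pos + width))
            return pos
    raise ValueError(
        "window too crowded to place all motif instances without overlap; "
        "use longer windows or fewer planted instances"
    )


def _generate(
    grammar: GrammarSpec,
    db: MotifDatabase,
    n_per_class: int,
    seed: int,
    plant_halfwidth: int,
    contig_length: int | None,
    with_signal: bool,
) -> SyntheticDataset:
    grammar.validate(db)
    rng = np.random.default_rng(seed)
    wl = grammar.window_length
    maxw = max(m.width for m in db)
    if contig_length is None:
        contig_length = max(620, wl + 20)
    if contig_length < wl:
        raise ValueError("contig_length must be >= window_length")
    centre = contig_length // 2
    half = min(plant_halfwidth, wl // 2 - maxw)
    if half < 1:
        raise ValueError("window too short for the planting half-width")
    bg = np.asarray(grammar.background)

    pwms = {m.name: m for m in db}
    # lambda_bg is the expected decoy count per *window*; decoys are planted
    # anywhere on the contig, so the contig-level rate is scaled up to match
    lam_contig = grammar.lambda_bg * contig_length / wl
    decoys = (
        list(grammar.decoy_motifs)
        if with_signal
        else list(db.names)  # under the null every motif is background
    )

    sequences: list[LabelledSequence] = []
    windows: list[Window] = []
    peaks: list[Peak] = []
    contigs: list[tuple[str, str]] = []
    base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)

    for cls in grammar.classes:
        reqs = grammar.requirements.get(cls, []) if with_signal else []
        excl = grammar.exclusions.get(cls, []) if with_signal else []
        for i in range(n_per_class):
            for _attempt in range(20):
                codes = rng.choice(4, size=contig_length, p=bg).astype(np.int8)
                occupied: list[tuple[int, int]] = []
                # background decoys, planted anywhere on the contig
                k_decoy = rng.poisson(lam_contig, size=len(decoys))
                for name, k in zip(decoys, k_decoy):
                    pwm = pwms[name]
                    for _ in range(int(k)):
                        pos = _place(rng, occupied, 0, contig_length - pwm.width, pwm.width)
                        codes[pos : pos + pwm.width] = _sample_instance(pwm, rng)
                # class-defining requirements, planted near the window centre
                for name, min_count in reqs:
                    pwm = pwms[name]
                    k = int(min_count + rng.integers(0, 2))  # small surplus in {0, 1}
                    for _ in range(k):
                        pos = _place(
                            rng, occupied,
                            centre - half, centre + half - pwm.width, pwm.width,
                        )
                        codes[pos : pos + pwm.width] = _sample_instance(pwm, rng)
                seq = base_arr[codes].tobytes().decode("ascii")
                window_seq = seq[centre - wl // 2 : centre + (wl - wl // 2)]
                if excl and any(
                    count_occurrences(pwms[m], window_seq) > 0 for m in excl
                ):
                    continue  # spurious hit of an excluded motif: redraw
                break
            else:
                raise ValueError(
                    f"could not satisfy exclusion clauses for class {cls!r} "
                    "after 20 redraws"
                )
            name = f"{cls}_{i:04d}"
            chrom = f"ctg_{name}"
            contigs.append((chrom, seq))
            sequences.append(
                LabelledSequence(id=name, sequence=window_seq, cell_type=cls)
            )
            windows.append(
                Window(
                    chrom=chrom,
                    start=centre - wl // 2,
                    end=centre + (wl - wl // 2),
                    cell_type=cls,
                    source_peak_id=name,
                )
            )
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=centre - wl // 2,
                    end=centre + (wl - wl // 2),
                    neg_log10_p=float(n_per_class - i),
                    signal=float(n_per_class - i),
                    summit_offset=wl // 2,
                    cell_type=cls,
                )
            )
    log.info(
        "generated %d %s windows (%d classes x %d)",
        len(sequences), "signal" if with_signal else "null",
        len(grammar.classes), n_per_class,
    )
    return SyntheticDataset(
        sequences=sequences,
        windows=windows,
        peaks=peaks,
        contigs=contigs,
        database=db,
        truth=grammar,
        seed=seed,
    )


def generate_dataset(
    grammar: GrammarSpec,
    db: MotifDatabase,
    n_per_class: int = 300,
    seed: int = 0,
    plant_halfwidth: int = DEFAULT_PLANT_HALFWIDTH,
    contig_length: int | None = None,
) -> SyntheticDataset:
    """Generate a labelled dataset whose classes satisfy the planted grammar.

    Windows are i.i.d. background sequence at the configured base
    frequencies; each requirement clause (motif, k) plants ``k`` plus a
    random surplus in {0, 1} non-overlapping instances within
    ``plant_halfwidth`` bp of the window centre; decoys are planted
    Poisson(``lambda_bg``) per window in every class; windows with spurious
    hits of an excluded motif are redrawn.  Deterministic given ``seed``.
    """
    return _generate(grammar, db, n_per_class, seed, plant_halfwidth,
                     contig_length, with_signal=True)


def null_dataset(
    grammar: GrammarSpec,
    db: MotifDatabase,
    n_per_class: int = 300,
    seed: int = 0,
    plant_halfwidth: int = DEFAULT_PLANT_HALFWIDTH,
    contig_length: int | None = None,
) -> SyntheticDataset:
    """Matched null: same generative process with the class clauses ignored.

    Labels are assigned but carry no signal — every motif (including the
    formerly required ones) is planted as a decoy at rate ``lambda_bg`` in
    every class — so the dataset calibrates chance-level AUROC and the
    scaled-MDA reporting threshold.
    """
    return _generate(grammar, db, n_per_class, seed, plant_halfwidth,
                     contig_length, with_signal=False)
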