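"""Construction of labeled promoter classification datasets.

Positives are TSS-anchored sequence windows from transcripts whose
expression is tissue-specific (TSp) in a target tissue.  Two negative-set
designs are supported:

* **Model A** — windows sampled at random genomic locations outside an
  exclusion set (typically all annotated promoter windows), capturing
  general promoter-vs-background biology.
* **Model B** — non-TSp promoter windows, or genomic nulls matched to the
  positives in GC content and soft-masked (repeat) fraction, capturing the
  tissue-specific signal proper.

All genomic coordinates are 0-based, half-open.  Minus-strand windows are
reverse-complemented so that every stored sequence reads 5'->3' in the
transcription direction and "upstream"/"downstream" are defined relative
to transcription.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

EXPRESSION_GROUPS = ("TSp", "TEn", "Wide", "Low", "Null")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving soft-mask case."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterRecord:
    """A TSS-anchored promoter window.

    ``sequence`` reads 5'->3' in transcription orientation; its length is
    ``upstream + downstream``.  ``label`` is 1 iff the transcript is
    tissue-specific (TSp) for the dataset's target tissue.
    """

    transcript_id: str
    chrom: str
    tss: int
    strand: str
    tissue: str
    expression_group: str
    sequence: str
    window: tuple[int, int]  # (upstream bp, downstream bp)
    label: int | None = None
    split: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        up, down = self.window
        if len(self.sequence) != up + down:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} "
                f"!= upstream+downstream {up + down}"
            )

    @property
    def upstream(self) -> int:
        return self.window[0]

    @property
    def downstream(self) -> int:
        return self.window[1]

    @property
    def gc(self) -> float:
        return gc_fraction(self.sequence)

    @property
    def repeat_fraction(self) -> float:
        return soft_mask_fraction(self.sequence)


@dataclass
class NegativeSetSpec:
    """Parameters for negative-set sampling.

    ``mode`` is ``random_nonpromoter`` (Model A) or ``matched_null``
    (Model B).  Tolerances bound the allowed |GC| and |repeat-fraction|
    mismatch of a matched null relative to its positive.
    """

    mode: str = "matched_null"
    gc_tolerance: float = 0.02
    repeat_tolerance: float = 0.05
    exclusion_intervals: Mapping[str, Sequence[tuple[int, int]]] = field(default_factory=dict)
    seed: int = 0
    max_attempts: int = 200

    def __post_init__(self) -> None:
        if self.mode not in ("random_nonpromoter", "matched_null"):
            raise ValueError(f"unknown negative-set mode {self.mode!r}")
        for tol in (self.gc_tolerance, self.repeat_tolerance):
            if not 0 < tol <= 0.5:
                raise ValueError(f"tolerance {tol} outside (0, 0.5]")


def gc_fraction(seq: str) -> float:
    """GC fraction over A/C/G/T bases, case-insensitive; N excluded."""
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (s.count("G") + s.count("C")) / acgt


def soft_mask_fraction(seq: str) -> float:
    """Fraction of lowercase (soft-masked, repeat-annotated) bases."""
    if not seq:
        return 0.0
    return sum(c.islower() for c in seq) / len(seq)


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Load a (soft-masked) genome FASTA into a contig->sequence dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def extract_promoter_window(
    genome: Mapping[str, str], chrom: str, tss: int, strand: str,
    upstream: int, downstream: int,
) -> str:
    """Extract one promoter window in transcription orientation.

    Plus strand: ``genome[tss-upstream : tss+downstream)``.  Minus strand:
    reverse complement of ``genome[tss-downstream : tss+upstream)``.
    Windows falling outside the contig raise; they are never clipped,
    which would silently break the length invariant.
    """
    if upstream <= 0 or downstream <= 0:
        raise ValueError("upstream and downstream must be positive")
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    contig = genome[chrom]
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    elif strand == "-":
        start, end = tss - downstream, tss + upstream
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if start < 0 or end > len(contig):
        raise ValueError(
            f"window [{start}, {end}) for TSS {chrom}:{tss}({strand}) "
            f"exceeds contig bounds [0, {len(contig)})"
        )
    seq = contig[start:end]
    return seq if strand == "+" else reverse_complement(seq)


def extract_promoter_windows(
    annotations: pd.DataFrame | Iterable[Mapping],
    genome: Mapping[str, str],
    upstream: int,
    downstream: int,
) -> list[PromoterRecord]:
    """Extract promoter windows for every annotated TSS.

    ``annotations`` needs columns/keys ``transcript_id``, ``chrom``,
    ``tss``, ``strand``, ``tissue``, ``expression_group``.
    """
    if isinstance(annotations, pd.DataFrame):
        rows = annotations.to_dict("records")
    else:
        rows = list(annotations)
    records = []
    for row in rows:
        group = row["expression_group"]
        if group not in EXPRESSION_GROUPS:
            raise ValueError(f"unknown expression group {group!r}")
        seq = extract_promoter_window(
            genome, row["chrom"], int(row["tss"]), row["strand"],
            upstream, downstream,
        )
        records.append(PromoterRecord(
            transcript_id=row["transcript_id"], chrom=row["chrom"],
            tss=int(row["tss"]), strand=row["strand"], tissue=row["tissue"],
            expression_group=group, sequence=seq,
            window=(upstream, downstream),
        ))
    return records


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------

def label_by_tissue(
    records: Sequence[PromoterRecord],
    tissue: str,
    negative_groups: Iterable[str] = ("TEn", "Wide", "Low", "Null"),
) -> tuple[list[PromoterRecord], dict[str, int]]:
    """Assign binary labels for a target tissue.

    Label 1: TSp records of ``tissue``.  Label 0: records whose group is in
    ``negative_groups``.  Everything else (e.g. TSp of another tissue) is
    dropped.  Returns the labeled records and a per-category count report.
    """
    negative_groups = set(negative_groups)
    bad = negative_groups - set(EXPRESSION_GROUPS[1:])
    if bad:
        raise ValueError(f"invalid negative groups: {sorted(bad)}")
    labeled: list[PromoterRecord] = []
    counts: dict[str, int] = {"positive": 0, "negative": 0, "dropped": 0}
    for rec in records:
        if rec.expression_group == "TSp" and rec.tissue == tissue:
            rec.label = 1
            counts["positive"] += 1
            labeled.append(rec)
        elif rec.expression_group in negative_groups:
            rec.label = 0
            counts["negative"] += 1
            labeled.append(rec)
        else:
            counts["dropped"] += 1
        counts[rec.expression_group] = counts.get(rec.expression_group, 0) + 1
    if counts["positive"] == 0:
        raise ValueError(f"no TSp records for tissue {tissue!r}: empty positive class")
    return labeled, counts


# ---------------------------------------------------------------------------
# Negative sampling
# ---------------------------------------------------------------------------

def _intersects(intervals: Sequence[tuple[int, int]], start: int, end: int) -> bool:
    """True if half-open [start, end) intersects any half-open interval."""
    for s, e in intervals:
        if start < e and s < end:
            return True
    return False


def sample_random_negatives(
    genome: Mapping[str, str],
    exclusion: Mapping[str, Sequence[tuple[int, int]]],
    n: int,
    length: int,
    seed: int,
    max_attempts_factor: int = 200,
) -> list[tuple[str, int, int, str]]:
    """Model A negatives: random genomic windows disjoint from ``exclusion``.

    Returns ``(chrom, start, end, sequence)`` tuples.  Sampling is uniform
    over valid window start positions across contigs and deterministic
    under ``seed``.  Negatives may overlap each other (only exclusion-set
    disjointness is required).
    """
    rng = np.random.default_rng(seed)
    chroms = [c for c, s in genome.items() if len(s) >= length]
    if not chroms:
        raise ValueError(f"no contig of length >= {length}")
    weights = np.array([len(genome[c]) - length + 1 for c in chroms], dtype=float)
    weights /= weights.sum()
    out: list[tuple[str, int, int, str]] = []
    attempts = 0
    max_attempts = max_attempts_factor * n
    while len(out) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} negatives after {attempts} attempts "
                f"({len(out)} placed)"
            )
        attempts += 1
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        start = int(rng.integers(0, len(genome[chrom]) - length + 1))
        end = start + length
        if _intersects(exclusion.get(chrom, ()), start, end):
            continue
        out.append((chrom, start, end, genome[chrom][start:end]))
    return out


def sample_matched_negatives(
    genome: Mapping[str, str],
    positives: Sequence[PromoterRecord],
    spec: NegativeSetSpec,
) -> tuple[list[tuple[str, int, int, str]], list[str]]:
    """Model B negatives: one GC/repeat-matched genomic null per positive.

    For each positive, random windows are drawn until one satisfies
    ``|GC(neg) - GC(pos)| <= gc_tolerance`` and
    ``|repeat(neg) - repeat(pos)| <= repeat_tolerance`` while avoiding the
    exclusion intervals.  Unmatchable positives are reported, not fatal.

    Returns (negatives, unmatched transcript ids).
    """
    rng = np.random.default_rng(spec.seed)
    negatives: list[tuple[str, int, int, str]] = []
    unmatched: list[str] = []
    for pos in positives:
        length = len(pos.sequence)
        target_gc = pos.gc
        target_rep = pos.repeat_fraction
        chroms = [c for c, s in genome.items() if len(s) >= length]
        if not chroms:
            unmatched.append(pos.transcript_id)
            continue
        weights = np.array([len(genome[c]) - length + 1 for c in chroms], dtype=float)
        weights /= weights.sum()
        found = False
        for _ in range(spec.max_attempts):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            start = int(rng.integers(0, len(genome[chrom]) - length + 1))
            end = start + length
            if _intersects(spec.exclusion_intervals.get(chrom, ()), start, end):
                continue
            seq = genome[chrom][start:end]
            if (abs(gc_fraction(seq) - target_gc) <= spec.gc_tolerance
                    and abs(soft_mask_fraction(seq) - target_rep) <= spec.repeat_tolerance):
                negatives.append((chrom, start, end, seq))
                found = True
                break
        if not found:
            unmatched.append(pos.transcript_id)
    if unmatched:
        logger.warning("matched-null sampling: %d/%d positives unmatched",
                       len(unmatched), len(positives))
    return negatives, unmatched


# ---------------------------------------------------------------------------
# Redundancy reduction
# ---------------------------------------------------------------------------

def _ungapped_identity(a: str, b: str, max_shift: int = 20) -> float:
    """Best ungapped identity over a band of relative offsets.

    Identity = matching positions at the best offset divided by the length
    of the shorter sequence.  Substitution-level redundancy (near copies)
    scores near 1; unrelated sequences score near the background 0.25.
    """
    if len(b) > len(a):
        a, b = b, a
    best = 0
    for shift in range(-max_shift, max_shift + 1):
        if shift >= 0:
            pa, pb = a[shift:shift + len(b)], b[: len(a) - shift]
        else:
            pa, pb = a[: len(b) + shift], b[-shift:]
        m = sum(x == y for x, y in zip(pa, pb))
        if m > best:
            best = m
    return best / len(b)


def cluster_reduce(
    sequences: Sequence[str],
    identity: float = 0.8,
    coverage: float = 0.8,
    external_cmd: str | None = None,
) -> list[int]:
    """Reduce redundancy, keeping one representative per sequence cluster.

    Returns indices of retained representatives.  If ``external_cmd`` names
    an available clustering tool (mmseqs-style, invoked as
    ``<cmd> easy-cluster`` with the identity/coverage thresholds), it is
    used; otherwise a greedy internal clusterer assigns each sequence to
    the first representative with ungapped identity >= ``identity`` over
    >= ``coverage`` of the shorter sequence, processing longest-first.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    if external_cmd and shutil.which(external_cmd):
        try:
            return _external_cluster(sequences, identity, coverage, external_cmd)
        except Exception:  # pragma: no cover - depends on host tool
            logger.warning("external clustering failed; using internal fallback",
                           exc_info=True)
    order = sorted(range(len(sequences)), key=lambda i: (-len(sequences[i]), i))
    reps: list[int] = []
    for i in order:
        seq = sequences[i]
        assigned = False
        for r in reps:
            rep = sequences[r]
            # shorter sequence must be >= coverage of the longer one, else the
            # alignment cannot cover enough of the pair to call it redundant
            if min(len(seq), len(rep)) < coverage * max(len(seq), len(rep)):
                continue
            if _ungapped_identity(rep, seq) >= identity:
                assigned = True
                break
        if not assigned:
            reps.append(i)
    return sorted(reps)


def _external_cluster(sequences, identity, coverage, cmd):  # pragma: no cover
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fasta"
        fasta.write_text("".join(f">s{i}\n{s}\n" for i, s in enumerate(sequences)))
        subprocess.run(
            [cmd, "easy-cluster", str(fasta), str(Path(tmp) / "res"), str(Path(tmp) / "tmp"),
             "--min-seq-id", str(identity), "-c", str(coverage)],
            check=True, capture_output=True,
        )
        reps = [int(r.id[1:]) for r in SeqIO.parse(str(Path(tmp) / "res_rep_seq.fasta"), "fasta")]
    return sorted(reps)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def stratified_split(
    records: Sequence[PromoterRecord],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> dict[str, str]:
    """Stratified train/validation/test assignment.

    Each class is shuffled (seeded) and partitioned so per-class counts
    match ``ratios`` up to rounding (largest-remainder apportionment).
    Returns transcript_id -> {"train", "validation", "test"} and stamps
    ``record.split`` in place.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    by_class: dict[int, list[PromoterRecord]] = {}
    for rec in records:
        if rec.label is None:
            raise ValueError(f"record {rec.transcript_id} has no label")
        by_class.setdefault(rec.label, []).append(rec)
    if len(by_class) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    names = ("train", "validation", "test")
    assignment: dict[str, str] = {}
    for label in sorted(by_class):
        members = sorted(by_class[label], key=lambda r: r.transcript_id)
        if len(members) < 3:
            raise ValueError(f"class {label} has {len(members)} members (< 3)")
        perm = rng.permutation(len(members))
        exact = np.array(ratios) * len(members)
        counts = np.floor(exact).astype(int)
        rem = exact - counts
        for _ in range(len(members) - counts.sum()):
            j = int(np.argmax(rem))
            counts[j] += 1
            rem[j] = -1
        bounds = np.cumsum(counts)
        for pos, idx in enumerate(perm):
            part = names[int(np.searchsorted(bounds, pos, side="right"))]
            rec = members[idx]
            rec.split = part
            assignment[rec.transcript_id] = part
    return assignment


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

def write_dataset_fasta(records: Sequence[PromoterRecord], path: str | Path) -> None:
    """Write records as FASTA with ``id|label|split|tissue|group`` headers."""
    with open(path, "w") as fh:
        for rec in records:
            header = "|".join([
                rec.transcript_id, str(rec.label), rec.split or "NA",
                rec.tissue, rec.expression_group,
            ])
            fh.write(f">{header}\n{rec.sequence}\n")


def write_interval_bed(records: Sequence[PromoterRecord], path: str | Path) -> None:
    """Companion BED of the genomic source intervals (0-based half-open)."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.strand == "+":
                start, end = rec.tss - rec.upstream, rec.tss + rec.downstream
            else:
                start, end = rec.tss - rec.downstream, rec.tss + rec.upstream
            fh.write(f"{rec.chrom}\t{start}\t{end}\t{rec.transcript_id}\t0\t{rec.strand}\n")


def dataset_manifest(records: Sequence[PromoterRecord]) -> pd.DataFrame:
    """TSV-ready manifest of one row per record."""
    return pd.DataFrame([
        {
            "transcript_id": r.transcript_id, "chrom": r.chrom, "tss": r.tss,
            "strand": r.strand, "tissue": r.tissue,
            "expression_group": r.expression_group, "label": r.label,
            "split": r.split, "length": len(r.sequence),
            "gc": round(r.gc, 4), "repeat_fraction": round(r.repeat_fraction, 4),
        }
        for r in records
    ])
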