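"""Genomic interval annotation of SNPs.

Builds the per-SNP annotation matrix used to stratify heritability:
functional classes are sets of genomic intervals (BED convention, 0-based
half-open), SNPs are 1-based point positions, and a SNP belongs to a class
when one of its intervals contains the SNP position.  Besides plain interval
classes the module derives the composite classes used in brain-trait
heritability partitioning:

* splice donor / acceptor flanks — the first / last ``flank_nt`` bases of
  each annotated intron, kept only where conserved;
* conservation-derived enhancer proxies — bases scoring above a PhastCons-like
  threshold, minus all already-annotated classes, split into a mammal-depth
  and a (disjoint) primate-depth class;
* subtraction classes such as brain-specific promoters (tissue promoters
  minus generic promoters).

Set arithmetic on intervals is delegated to :mod:`pyranges`; point membership
is a binary search on the merged interval arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

logger = logging.getLogger(__name__)

BASE_CLASS = "base"

Interval = tuple[str, int, int]


def _to_pyranges(intervals: Iterable[Interval]) -> pr.PyRanges:
    ivs = list(intervals)
    if not ivs:
        return pr.PyRanges(pd.DataFrame({"Chromosome": [], "Start": [], "End": []}))
    chroms, starts, ends = zip(*ivs)
    return pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [str(c) for c in chroms],
                "Start": np.asarray(starts, dtype=np.int64),
                "End": np.asarray(ends, dtype=np.int64),
            }
        )
    )


def _from_pyranges(gr: pr.PyRanges) -> tuple[Interval, ...]:
    if len(gr) == 0:
        return ()
    df = gr.df.sort_values(["Chromosome", "Start", "End"], kind="stable")
    return tuple(
        (str(c), int(s), int(e))
        for c, s, e in zip(df.Chromosome, df.Start, df.End)
    )


@dataclass(frozen=True)
class IntervalSet:
    """A named set of genomic intervals in 0-based half-open coordinates.

    Intervals may overlap on input; :meth:`normalized` returns the sorted,
    merged form.  All set operations return normalized sets.
    """

    name: str
    intervals: tuple[Interval, ...]

    def __post_init__(self) -> None:
        ivs = tuple((str(c), int(s), int(e)) for c, s, e in self.intervals)
        for c, s, e in ivs:
            if s < 0:
                raise ValueError(f"{self.name}: negative coordinate in ({c}, {s}, {e})")
            if s >= e:
                raise ValueError(f"{self.name}: empty or inverted interval ({c}, {s}, {e})")
        object.__setattr__(self, "intervals", ivs)

    def normalized(self) -> "IntervalSet":
        """Sorted, merged (book-ended intervals joined) copy."""
        if not self.intervals:
            return IntervalSet(self.name, ())
        merged = _to_pyranges(self.intervals).merge()
        return IntervalSet(self.name, _from_pyranges(merged))

    def subtract(self, other: "IntervalSet", name: str | None = None) -> "IntervalSet":
        """Base-wise set difference ``self \\ other``, normalized."""
        out = _to_pyranges(self.intervals).merge().subtract(_to_pyranges(other.intervals).merge())
        return IntervalSet(name or self.name, _from_pyranges(out)).normalized()

    def union(self, other: "IntervalSet", name: str | None = None) -> "IntervalSet":
        return IntervalSet(
            name or self.name, self.intervals + other.intervals
        ).normalized()

    def intersect(self, other: "IntervalSet", name: str | None = None) -> "IntervalSet":
        out = _to_pyranges(self.intervals).merge().intersect(_to_pyranges(other.intervals).merge())
        return IntervalSet(name or self.name, _from_pyranges(out)).normalized()

    def total_bases(self) -> int:
        return sum(e - s for _, s, e in self.normalized().intervals)

    def contains_points(self, chroms: Sequence, pos0: np.ndarray) -> np.ndarray:
        """Membership of 0-based point positions.

        Parameters
        ----------
        chroms : sequence of chromosome labels, one per point.
        pos0 : 0-based positions (a SNP at 1-based position p has pos0 = p-1).
        """
        pos0 = np.asarray(pos0, dtype=np.int64)
        chroms = np.asarray([str(c) for c in chroms])
        out = np.zeros(pos0.shape[0], dtype=bool)
        norm = self.normalized()
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in norm.intervals:
            by_chrom.setdefault(c, []).append((s, e))
        for c, ivs in by_chrom.items():
            sel = chroms == c
            if not sel.any():
                continue
            starts = np.array([s for s, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e in ivs], dtype=np.int64)
            p = pos0[sel]
            idx = np.searchsorted(starts, p, side="right") - 1
            hit = (idx >= 0) & (p < ends[np.clip(idx, 0, None)])
            out[sel] = hit
        return out


def union_all(sets: Sequence[IntervalSet], name: str) -> IntervalSet:
    """Normalized union of several interval sets."""
    ivs: tuple[Interval, ...] = ()
    for s in sets:
        ivs = ivs + tuple(s.intervals)
    return IntervalSet(name, ivs).normalized()


@dataclass(frozen=True)
class ConservationTrack:
    """Scored intervals (chrom, start, end, score in [0, 1]) at one lineage depth.

    Intervals must be non-overlapping after sorting; uncovered bases score 0.
    """

    name: str
    intervals: tuple[tuple[str, int, int, float], ...]

    def __post_init__(self) -> None:
        ivs = sorted(
            ((str(c), int(s), int(e), float(v)) for c, s, e, v in self.intervals),
            key=lambda t: (t[0], t[1], t[2]),
        )
        prev: dict[str, int] = {}
        for c, s, e, v in ivs:
            if s < 0 or s >= e:
                raise ValueError(f"{self.name}: bad interval ({c}, {s}, {e})")
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.name}: score {v} outside [0, 1]")
            if c in prev and s < prev[c]:
                raise ValueError(f"{self.name}: overlapping scored intervals on {c}")
            prev[c] = e
        object.__setattr__(self, "intervals", tuple(ivs))

    def threshold(self, min_score: float, name: str | None = None) -> IntervalSet:
        """Bases scoring >= ``min_score`` as a normalized interval set."""
        ivs = tuple((c, s, e) for c, s, e, v in self.intervals if v >= min_score)
        return IntervalSet(name or self.name, ivs).normalized()

    def mean_score(self, chrom: str, start: int, end: int) -> float:
        """Mean score over [start, end); uncovered bases contribute 0."""
        chrom = str(chrom)
        total = 0.0
        for c, s, e, v in self.intervals:
            if c != chrom:
                continue
            ov = min(e, end) - max(s, start)
            if ov > 0:
                total += ov * v
        return total / (end - start)


@dataclass(frozen=True)
class GeneModel:
    """Intron coordinates with strand, the minimal gene model needed here."""

    introns: tuple[tuple[str, int, int, str], ...]

    def __post_init__(self) -> None:
        ivs = []
        for c, s, e, strand in self.introns:
            s, e = int(s), int(e)
            if s < 0 or s >= e:
                raise ValueError(f"bad intron ({c}, {s}, {e})")
            if strand == ".":  # unstranded: assume forward
                logger.warning("unstranded intron (%s, %d, %d) treated as '+'", c, s, e)
                strand = "+"
            if strand not in {"+", "-"}:
                raise ValueError(f"intron strand must be '+' or '-', got {strand!r}")
            ivs.append((str(c), s, e, strand))
        object.__setattr__(self, "introns", tuple(ivs))


@dataclass
class AnnotationMatrix:
    """Per-SNP binary membership across named classes.

    The universal ``base`` class (all ones) is always the first column.
    ``proportion_of_snps`` is the per-class column mean — the genome-wide
    "proportion of SNPs" statistic reported alongside enrichments.
    """

    snp_ids: np.ndarray
    class_names: list[str]
    matrix: np.ndarray  # M x C, uint8 in {0, 1}

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape != (
            len(self.snp_ids),
            len(self.class_names),
        ):
            raise ValueError("annotation matrix shape does not match ids/names")
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("duplicate class names")
        if self.class_names[0] != BASE_CLASS or not (self.matrix[:, 0] == 1).all():
            raise ValueError("first class must be the all-ones 'base' class")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("annotation entries must be 0/1")

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[0]

    @property
    def proportion_of_snps(self) -> np.ndarray:
        return self.matrix.sum(axis=0) / self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.class_names)
        df.insert(0, "SNP", self.snp_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnotationMatrix":
        names = [c for c in df.columns if c != "SNP"]
        return cls(df["SNP"].to_numpy(), names, df[names].to_numpy())


def derive_splice_sites(
    genes: GeneModel,
    cons: ConservationTrack,
    flank_nt: int = 70,
    min_score: float = 0.5,
    mode: str = "mean",
) -> tuple[IntervalSet, IntervalSet]:
    """Conserved splice-regulatory flanks of annotated introns.

    The donor flank is the first ``flank_nt`` bases of the intron in
    transcription direction (5' end), the acceptor flank the last
    ``flank_nt``; introns shorter than the flank contribute their whole
    extent to both.  A flank is kept according to the conservation rule:

    * ``mode="mean"`` — kept whole iff its mean conservation score
      (uncovered bases scoring 0) is >= ``min_score``;
    * ``mode="intersect"`` — restricted base-wise to the regions scoring
      >= ``min_score``.

    Returns normalized ``(donor, acceptor)`` sets; an empty gene model
    yields empty sets.
    """
    if flank_nt < 1:
        raise ValueError("flank_nt must be >= 1")
    if mode not in {"mean", "intersect"}:
        raise ValueError(f"unknown conservation mode {mode!r}")
    donor_ivs: list[Interval] = []
    acceptor_ivs: list[Interval] = []
    for c, s, e, strand in genes.introns:
        f = min(flank_nt, e - s)
        head = (c, s, s + f)
        tail = (c, e - f, e)
        if strand == "+":
            donor, acceptor = head, tail
        else:
            donor, acceptor = tail, head
        donor_ivs.append(donor)
        acceptor_ivs.append(acceptor)

    def conserved(ivs: list[Interval], name: str) -> IntervalSet:
        if mode == "mean":
            kept = [iv for iv in ivs if cons.mean_score(*iv) >= min_score]
            return IntervalSet(name, tuple(kept)).normalized()
        high = cons.threshold(min_score, name)
        return IntervalSet(name, tuple(ivs)).normalized().intersect(high, name)

    return conserved(donor_ivs, "splice_donor"), conserved(acceptor_ivs, "splice_acceptor")


def derive_exclusive_class(
    source: IntervalSet, excluded: Sequence[IntervalSet], name: str | None = None
) -> IntervalSet:
    """Base-wise ``source`` minus the union of ``excluded``, normalized.

    This is how subtraction classes such as brain-specific promoters
    (tissue promoters minus generic promoters) are built.
    """
    out = source.normalized()
    if excluded:
        out = out.subtract(union_all(excluded, "_excluded"), name or source.name)
    elif name:
        out = IntervalSet(name, out.intervals)
    return out


def derive_conserved_classes(
    cons_mammal: ConservationTrack,
    cons_primate: ConservationTrack,
    other_classes: Sequence[IntervalSet],
    min_score: float = 0.5,
) -> tuple[IntervalSet, IntervalSet, float]:
    """Enhancer-proxy classes from deep conservation, minus known annotation.

    Highly conserved bases (score >= ``min_score``) that fall outside every
    already-annotated class are taken as putative regulatory elements.  The
    mammal-depth class is carved out first; the primate-depth class
    additionally excludes the mammal class, so the two are disjoint.

    Returns ``(mammal_conserved, primate_conserved, overlap_fraction)`` where
    ``overlap_fraction`` is the fraction of primate-conserved bases (after
    removing ``other_classes``) that overlap the mammal-conserved class
    before the final subtraction — a measure of how much primate-lineage
    conservation merely recapitulates deeper conservation.
    """
    mammal = derive_exclusive_class(
        cons_mammal.threshold(min_score, "mammal_conserved"), other_classes
    )
    primate_raw = derive_exclusive_class(
        cons_primate.threshold(min_score, "primate_conserved"), other_classes
    )
    n_primate = primate_raw.total_bases()
    shared = primate_raw.intersect(mammal).total_bases()
    overlap_fraction = shared / n_primate if n_primate else 0.0
    primate = primate_raw.subtract(mammal, "primate_conserved")
    return mammal, primate, overlap_fraction


def build_annotation_matrix(panel, classes: Sequence[IntervalSet]) -> AnnotationMatrix:
    """Per-SNP class membership matrix with a prepended all-ones base class.

    A SNP at 1-based position ``p`` is inside a 0-based half-open interval
    ``[s, e)`` iff ``s < p <= e`` (equivalently, base ``p - 1`` is covered).
    """
    names = [c.name for c in classes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate class names")
    if BASE_CLASS in names:
        raise ValueError(f"class name {BASE_CLASS!r} is reserved")
    M = len(panel.snp_id)
    if M == 0:
        raise ValueError("panel has no SNPs")
    cols = [np.ones(M, dtype=np.uint8)]
    pos0 = np.asarray(panel.pos, dtype=np.int64) - 1
    for cls in classes:
        cols.append(cls.contains_points(panel.chrom, pos0).astype(np.uint8))
    return AnnotationMatrix(
        np.asarray(panel.snp_id), [BASE_CLASS] + names, np.column_stack(cols)
    )


def filter_snps(sumstats, panel, exclusion: Sequence[IntervalSet]):
    """Drop summary-statistic SNPs inside any exclusion region.

    Exclusion regions are high-LD leverage regions (e.g. the MHC and the
    GPHN yin-yang region) whose coordinates are supplied by configuration.
    SNPs absent from the panel cannot be located and are kept, with a
    warning.  Raises if nothing survives.
    """
    from .sldsr import SumStats

    if not exclusion:
        return sumstats
    idx = pd.Index(np.asarray(panel.snp_id))
    loc = idx.get_indexer(np.asarray(sumstats.snp_id))
    known = loc >= 0
    if not known.all():
        logger.warning("%d sumstats SNPs not in panel; kept unfiltered", (~known).sum())
    excl = union_all(exclusion, "_exclusion")
    drop = np.zeros(len(sumstats.snp_id), dtype=bool)
    if known.any():
        chroms = np.asarray(panel.chrom)[loc[known]]
        pos0 = np.asarray(panel.pos)[loc[known]] - 1
        drop[known] = excl.contains_points(chroms, pos0)
    kept = ~drop
    logger.info("excluded %d of %d SNPs in high-LD regions", drop.sum(), drop.size)
    if not kept.any():
        raise ValueError("all SNPs fall in exclusion regions; nothing to regress")
    n = sumstats.n if np.isscalar(sumstats.n) else np.asarray(sumstats.n)[kept]
    return SumStats(
        snp_id=np.asarray(sumstats.snp_id)[kept],
        n=n,
        chisq=np.asarray(sumstats.chisq)[kept],
    )


# ---------------------------------------------------------------------------
# BED-style I/O


def read_bed(path: str | Path, name: str | None = None) -> IntervalSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return IntervalSet(
        name or Path(path).stem,
        tuple(zip(df.chrom.astype(str), df.start.astype(int), df.end.astype(int))),
    )


def write_bed(ivset: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, s, e in ivset.normalized().intervals:
            fh.write(f"{c}\t{s}\t{e}\n")


def read_conservation(path: str | Path, name: str | None = None) -> ConservationTrack:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "score"])
    return ConservationTrack(
        name or Path(path).stem,
        tuple(zip(df.chrom.astype(str), df.start.astype(int),
                  df.end.astype(int), df.score.astype(float))),
    )


def write_conservation(track: ConservationTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, s, e, v in track.intervals:
            fh.write(f"{c}\t{s}\t{e}\t{v:.6g}\n")


def read_gene_model(path: str | Path) -> GeneModel:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "strand"])
    return GeneModel(tuple(zip(df.chrom.astype(str), df.start.astype(int),
                               df.end.astype(int), df.strand.astype(str))))


def read_annotation_matrix(path: str | Path) -> AnnotationMatrix:
    return AnnotationMatrix.from_frame(pd.read_csv(path, sep="\t"))


def write_annotation_matrix(annot: AnnotationMatrix, path: str | Path) -> None:
    annot.to_frame().to_csv(path, sep="\t", index=False)
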