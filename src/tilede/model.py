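"""Domain types shared across the pipeline.

All genomic intervals are 0-based, half-open ``[start, end)``.  Conversion
to and from 1-based inclusive conventions (GFF3) happens only in the
readers and writers of :mod:`tilede.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class FormatError(ValueError):
    """Raised when an external file cannot be parsed."""


@dataclass
class GenomeSequence:
    """A reference genome held in memory.

    Parameters
    ----------
    chrom_names:
        Chromosome identifiers in genome order.
    sequences:
        Upper-case DNA per chromosome, alphabet ``{A, C, G, T, N}``.
    masked_regions:
        Optional per-chromosome intervals excluded from probe mapping
        (e.g. an rDNA locus).  A match whose start lies inside a masked
        interval is suppressed.
    """

    chrom_names: list[str]
    sequences: dict[str, str]
    masked_regions: dict[str, list[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValidationError("duplicate chromosome names")
        for name in self.chrom_names:
            if name not in self.sequences:
                raise ValidationError(f"missing sequence for chromosome {name!r}")
            bad = set(self.sequences[name]) - set("ACGTN")
            if bad:
                raise ValidationError(
                    f"chromosome {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )
        for name, ivals in self.masked_regions.items():
            if name not in self.sequences:
                raise ValidationError(f"masked region on unknown chromosome {name!r}")
            n = len(self.sequences[name])
            for s, e in ivals:
                if not (0 <= s < e <= n):
                    raise ValidationError(
                        f"masked interval ({s}, {e}) out of bounds for {name!r} (length {n})"
                    )

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def chrom_index(self, chrom: str) -> int:
        return self.chrom_names.index(chrom)

    def is_masked_start(self, chrom: str, pos: int) -> bool:
        for s, e in self.masked_regions.get(chrom, ()):
            if s <= pos < e:
                return True
        return False


@dataclass
class AnnotationFeature:
    """An annotated gene/ORF: a strand, and sorted disjoint exon intervals."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    synonyms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            raise ValidationError(f"feature {self.gene_id} has no exons")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValidationError(f"empty exon ({s}, {e}) in {self.gene_id}")
            if s < prev_end:
                raise ValidationError(f"exons of {self.gene_id} overlap or are unsorted")
            prev_end = e

    @property
    def span(self) -> Interval:
        """Genomic footprint from first exon start to last exon end."""
        return (self.exons[0][0], self.exons[-1][1])


@dataclass(frozen=True)
class ProbeRecord:
    """One physical array probe: identifier, array (x, y) cell, 25-mer."""

    probe_id: str
    x: int
    y: int
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"probe {self.probe_id} has an empty sequence")
        if self.x < 0 or self.y < 0:
            raise ValidationError(f"probe {self.probe_id} has negative array coordinates")


@dataclass(frozen=True, order=True)
class GenomeMatch:
    """An exact genomic hit of a probe.

    ``strand == "-"`` means the probe sequence equals the reverse
    complement of the genomic interval ``[start, end)``.
    """

    chrom: str
    start: int
    end: int
    strand: str
    probe_id: str


@dataclass
class MatchReport:
    """Uniqueness classification of probe-to-genome matches."""

    matches_by_probe: dict[str, list[GenomeMatch]]
    n_unmapped: int
    n_unique: int
    n_multi: int

    def unique_matches(self) -> list[GenomeMatch]:
        """The single match of every uniquely mapping probe, sorted."""
        out = [m[0] for m in self.matches_by_probe.values() if len(m) == 1]
        out.sort(key=lambda m: (m.chrom, m.start, m.strand, m.probe_id))
        return out


@dataclass(frozen=True)
class ProbePlacement:
    """A probe together with its unique genomic placement (a CDF row)."""

    probe_id: str
    x: int
    y: int
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class Probeset:
    """A named group of probes summarized into one expression value."""

    probeset_id: str
    members: list[ProbePlacement]

    def __post_init__(self) -> None:
        ids = [m.probe_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate probe in probeset {self.probeset_id}")

    @property
    def probe_ids(self) -> list[str]:
        return [m.probe_id for m in self.members]


@dataclass
class StepCounts:
    """Probe bookkeeping through the five CDF-construction steps.

    Counts are monotone non-increasing from ``total`` through
    ``intragenic``; ``n_probesets`` counts the surviving probesets.
    """

    total: int
    unique_seq: int
    in_genome: int
    unique_in_genome: int
    intragenic: int
    n_probesets: int

    def __post_init__(self) -> None:
        seq = [self.total, self.unique_seq, self.in_genome,
               self.unique_in_genome, self.intragenic]
        if any(b > a for a, b in zip(seq, seq[1:])):
            raise ValidationError(f"step counts not monotone: {seq}")

    def as_rows(self) -> list[tuple[str, int]]:
        return [
            ("total_probes", self.total),
            ("unique_probes_step1", self.unique_seq),
            ("probes_in_genome_step2", self.in_genome),
            ("unique_probes_in_genome_step3", self.unique_in_genome),
            ("intragenic_probes_step4", self.intragenic),
            ("probesets_step5", self.n_probesets),
        ]


@dataclass
class PipelineParams:
    """Tunables of the probe-filtering pipeline.

    ``min_probes_per_set`` defaults to 4: smaller probesets do not
    support statistically meaningful summarization.  ``containment_rule``
    decides whether a probe must lie fully inside a single exon
    (``"full"``) or merely overlap one (``"any-overlap"``).
    ``strand_rule`` controls whether the probe's match strand must equal
    (``"require-sense"``) or oppose (``"require-antisense"``) the
    annotated strand, or is ignored.
    """

    min_probes_per_set: int = 4
    containment_rule: str = "full"
    strand_rule: str = "require-sense"

    def __post_init__(self) -> None:
        if self.min_probes_per_set < 1:
            raise ValidationError("min_probes_per_set must be >= 1")
        if self.containment_rule not in ("full", "any-overlap"):
            raise ValidationError(f"unknown containment_rule {self.containment_rule!r}")
        if self.strand_rule not in ("require-sense", "require-antisense", "ignore"):
            raise ValidationError(f"unknown strand_rule {self.strand_rule!r}")


@dataclass
class SegmentationParams:
    """Parameters of the dTR segmentation algorithm.

    Defaults follow the published procedure: probes whose between-condition
    log2 difference exceeds 0.8 are selected; selected probes less than
    60 nt apart are clustered; only regions spanning more than 180 nt whose
    mean difference also exceeds 0.8 survive; surviving regions closer than
    120 nt are fused.
    """

    min_probe_diff: float = 0.8
    cluster_gap: int = 60
    min_region_len: int = 180
    fuse_gap: int = 120
    include_subthreshold_in_mean: bool = False

    def __post_init__(self) -> None:
        if min(self.min_probe_diff, self.cluster_gap,
               self.min_region_len, self.fuse_gap) <= 0:
            raise ValidationError("segmentation parameters must be positive")
        if self.fuse_gap < self.cluster_gap:
            raise ValidationError("fuse_gap must be >= cluster_gap")


@dataclass
class DiffSignalTrack:
    """Per-(chromosome, strand) probe-level differential signal.

    ``probes`` is a list of ``(start, end, log2_diff)`` sorted by start,
    one entry per uniquely mapping probe on this strand.
    """

    chrom: str
    strand: str
    probes: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        starts = [p[0] for p in self.probes]
        if starts != sorted(starts):
            raise ValidationError(
                f"track {self.chrom}{self.strand} is not sorted by start"
            )


@dataclass(frozen=True)
class OverlapAnnotation:
    """How a dTR relates to one annotated ORF."""

    gene_id: str
    overlap_class: str  # orf_within_dtr | dtr_within_orf | partial_start | partial_end

    _SYMBOLS = {
        "orf_within_dtr": "> {} <",
        "dtr_within_orf": "< {} >",
        "partial_start": "<{}",
        "partial_end": "{}>",
    }

    @property
    def symbol(self) -> str:
        return self._SYMBOLS[self.overlap_class].format(self.gene_id)


@dataclass
class DTR:
    """A differentially transcribed region on one strand.

    ``direction`` is ``"up"`` (over-expressed in the treated condition)
    or ``"down"``; ``mean_diff`` averages the log2 differences of the
    member probes; ``overlaps`` lists the annotated ORFs the region
    touches (empty for non-annotated transcripts).
    """

    dtr_id: Optional[str]
    chrom: str
    strand: str
    start: int
    end: int
    direction: str
    mean_diff: float
    n_probes: int
    member_probes: list[tuple[int, int, float]] = field(default_factory=list)
    overlaps: list[OverlapAnnotation] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def overlap_class(self) -> str:
        return "none" if not self.overlaps else self.overlaps[0].overlap_class
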