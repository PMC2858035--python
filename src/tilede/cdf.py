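"""The five-step probe-filtering pipeline that builds a custom CDF.

Starting from the raw probe complement of an array, the pipeline
(1) removes sequence-duplicate probes, (2) maps the survivors exactly to
the genome on both strands, (3) discards probes hitting more than one
genomic position, (4) keeps probes lying inside annotated exons/ORFs,
and (5) groups them into per-gene probesets, dropping genes represented
by fewer than ``min_probes_per_set`` probes (default 4).  The resulting
probeset collection plays the role of a Chip Description File for
downstream RMA-style summarization.

An amplicon-referenced variant locates PCR amplicon sequences in the
genome and uses them as single-exon pseudo-features in steps 4-5, which
reproduces probe selection against a PCR-spotted array design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .mapping import classify_matches, karp_rabin_search
from .model import (
    AnnotationFeature,
    GenomeMatch,
    GenomeSequence,
    PipelineParams,
    ProbePlacement,
    ProbeRecord,
    Probeset,
    StepCounts,
)

logger = logging.getLogger(__name__)


@dataclass
class BuildLog:
    """Reasons for probe/gene exclusions, for audit output."""

    ambiguous_probes: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    low_count_genes: list[tuple[str, int]] = field(default_factory=list)
    skipped_amplicons: list[tuple[str, str]] = field(default_factory=list)


def dedupe_probes(probes: Sequence[ProbeRecord]) -> list[ProbeRecord]:
    """Step 1: keep exactly one probe per distinct sequence.

    The retained representative is the first probe in (y, x) array
    order; output preserves the input order of the retained probes.
    """
    best: dict[str, ProbeRecord] = {}
    for p in probes:
        cur = best.get(p.sequence)
        if cur is None or (p.y, p.x) < (cur.y, cur.x):
            best[p.sequence] = p
    keep = {id(v) for v in best.values()}
    return [p for p in probes if id(p) in keep]


def _assignable_genes(
    match: GenomeMatch,
    features: Sequence[AnnotationFeature],
    params: PipelineParams,
) -> list[str]:
    out = []
    for f in features:
        if f.chrom != match.chrom:
            continue
        if params.strand_rule == "require-sense" and match.strand != f.strand:
            continue
        if params.strand_rule == "require-antisense" and match.strand == f.strand:
            continue
        for s, e in f.exons:
            if params.containment_rule == "full":
                hit = s <= match.start and match.end <= e
            else:  # any-overlap
                hit = match.start < e and s < match.end
            if hit:
                out.append(f.gene_id)
                break
    return out


def intersect_annotation(
    matches: Sequence[GenomeMatch],
    features: Sequence[AnnotationFeature],
    params: PipelineParams,
    log: Optional[BuildLog] = None,
) -> dict[str, str]:
    """Step 4: assign uniquely mapping probes to genes.

    Under the default ``containment_rule="full"`` a probe is assigned to
    a gene iff its genomic interval lies fully inside one exon of that
    gene; a probe spanning a splice junction therefore matches neither
    exon.  Probes assignable to more than one gene are dropped (logged)
    so that probesets partition the probes.
    """
    assignments: dict[str, str] = {}
    for m in matches:
        genes = _assignable_genes(m, features, params)
        if len(genes) == 1:
            assignments[m.probe_id] = genes[0]
        elif len(genes) > 1:
            if log is not None:
                log.ambiguous_probes.append((m.probe_id, tuple(genes)))
            logger.info("probe %s assignable to %d genes; dropped", m.probe_id, len(genes))
    return assignments


def assemble_probesets(
    assignments: Mapping[str, str],
    probes_by_id: Mapping[str, ProbeRecord],
    match_by_id: Mapping[str, GenomeMatch],
    params: PipelineParams,
    log: Optional[BuildLog] = None,
) -> list[Probeset]:
    """Step 5: group assigned probes into per-gene probesets.

    Genes with fewer than ``min_probes_per_set`` assigned probes are not
    incorporated (logged).  Probesets are returned in lexicographic
    probeset_id order with members sorted by genomic position.
    """
    by_gene: dict[str, list[ProbePlacement]] = {}
    for probe_id, gene_id in assignments.items():
        p = probes_by_id[probe_id]
        m = match_by_id[probe_id]
        by_gene.setdefault(gene_id, []).append(
            ProbePlacement(probe_id, p.x, p.y, m.chrom, m.start, m.end, m.strand)
        )
    out: list[Probeset] = []
    for gene_id in sorted(by_gene):
        members = sorted(by_gene[gene_id], key=lambda pl: (pl.chrom, pl.start, pl.probe_id))
        if len(members) < params.min_probes_per_set:
            if log is not None:
                log.low_count_genes.append((gene_id, len(members)))
            logger.info("gene %s has %d probes (< %d); excluded",
                        gene_id, len(members), params.min_probes_per_set)
            continue
        out.append(Probeset(probeset_id=gene_id, members=members))
    return out


def build_cdf(
    probes: Sequence[ProbeRecord],
    genome: GenomeSequence,
    features: Sequence[AnnotationFeature],
    params: Optional[PipelineParams] = None,
    log: Optional[BuildLog] = None,
) -> tuple[list[Probeset], StepCounts]:
    """Run the full five-step pipeline.

    Returns the probeset collection and the per-step probe counts
    (monotone non-increasing).  Deterministic given its inputs.
    """
    params = params or PipelineParams()
    deduped = dedupe_probes(probes)
    matches = karp_rabin_search(deduped, genome)
    report = classify_matches(matches, deduped)
    unique = report.unique_matches()
    assignments = intersect_annotation(unique, features, params, log=log)
    probes_by_id = {p.probe_id: p for p in deduped}
    match_by_id = {m.probe_id: m for m in unique}
    probesets = assemble_probesets(assignments, probes_by_id, match_by_id, params, log=log)
    counts = StepCounts(
        total=len(probes),
        unique_seq=len(deduped),
        in_genome=len(deduped) - report.n_unmapped,
        unique_in_genome=report.n_unique,
        intragenic=len(assignments),
        n_probesets=len(probesets),
    )
    return probesets, counts


def amplicons_to_features(
    amplicons: Mapping[str, str],
    genome: GenomeSequence,
    log: Optional[BuildLog] = None,
) -> list[AnnotationFeature]:
    """Locate amplicon sequences in the genome as single-exon pseudo-features.

    Each amplicon must occur exactly once in the genome (both strands
    counted); amplicons not found, or found more than once, are skipped
    with a warning.
    """
    matches = karp_rabin_search(dict(amplicons), genome)
    by_amp: dict[str, list[GenomeMatch]] = {a: [] for a in amplicons}
    for m in matches:
        by_amp[m.probe_id].append(m)
    feats: list[AnnotationFeature] = []
    for amp_id, hits in by_amp.items():
        if len(hits) == 0:
            logger.warning("amplicon %s not found in genome; skipped", amp_id)
            if log is not None:
                log.skipped_amplicons.append((amp_id, "not_found"))
            continue
        if len(hits) > 1:
            logger.warning("amplicon %s occurs %d times in genome; skipped",
                           amp_id, len(hits))
            if log is not None:
                log.skipped_amplicons.append((amp_id, "multi_locus"))
            continue
        hit = hits[0]
        feats.append(AnnotationFeature(
            gene_id=amp_id, chrom=hit.chrom, strand=hit.strand,
            exons=[(hit.start, hit.end)],
        ))
    return feats


def build_cdf_from_amplicons(
    probes: Sequence[ProbeRecord],
    genome: GenomeSequence,
    amplicons: Mapping[str, str],
    params: Optional[PipelineParams] = None,
    log: Optional[BuildLog] = None,
) -> tuple[list[Probeset], StepCounts]:
    """Amplicon-referenced CDF: steps 4-5 run against located amplicons.

    Amplicon targets are double-stranded PCR products, so the strand
    rule is forced to ``"ignore"``: tiling probes from either strand
    within an amplicon interval are eligible.
    """
    params = params or PipelineParams()
    feats = amplicons_to_features(amplicons, genome, log=log)
    amp_params = PipelineParams(
        min_probes_per_set=params.min_probes_per_set,
        containment_rule=params.containment_rule,
        strand_rule="ignore",
    )
    return build_cdf(probes, genome, feats, amp_params, log=log)
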