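"""Strand-specific segmentation of differentially transcribed regions.

Works on per-(chromosome, strand) tracks of probe-level log2 signal
differences between two conditions.  For each direction (up/down)
independently: probes whose difference exceeds the threshold are
selected; runs of selected probes separated by less than ``cluster_gap``
nucleotides are clustered; clusters spanning more than
``min_region_len`` whose mean difference also exceeds the threshold are
kept; surviving regions closer than ``fuse_gap`` are fused (iterated to
a fixed point, without re-testing length — fusion can only grow a
region).  Strands and directions are never mixed.

Detected regions (dTRs) can then be turned into a probeset collection
and quantified exactly like annotated genes.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from .model import (
    DTR,
    AnnotationFeature,
    DiffSignalTrack,
    GenomeMatch,
    GenomeSequence,
    OverlapAnnotation,
    PipelineParams,
    ProbePlacement,
    ProbeRecord,
    Probeset,
    SegmentationParams,
    ValidationError,
)

def build_diff_tracks(
    normalized,
    matches: Sequence[GenomeMatch],
    design: Mapping[str, str],
    genome: Optional[GenomeSequence] = None,
    control: Optional[str] = None,
    treated: Optional[str] = None,
) -> tuple[list[DiffSignalTrack], int]:
    """Per-probe differential signal placed on genomic coordinates.

    For every uniquely mapping probe present in the quantile-normalized
    intensity matrix, computes mean log2(treated) - mean log2(control)
    and routes it to the (chromosome, strand) track of its match.
    Returns the tracks (chromosome order, "+" before "-") and the count
    of matrix probes without a genomic match (skipped).
    """
    conditions: list[str] = []
    for a in normalized.columns:
        if design.get(a) is None:
            raise ValidationError(f"array {a!r} missing from design")
        if design[a] not in conditions:
            conditions.append(design[a])
    if len(conditions) != 2:
        raise ValidationError(f"exactly 2 conditions required, got {conditions}")
    if control is None and treated is None:
        control, treated = conditions
    elif control is None:
        control = next(c for c in conditions if c != treated)
    elif treated is None:
        treated = next(c for c in conditions if c != control)

    log2 = np.log2(normalized.to_numpy(dtype=float))
    cols = list(normalized.columns)
    trt_idx = [i for i, a in enumerate(cols) if design[a] == treated]
    ctl_idx = [i for i, a in enumerate(cols) if design[a] == control]
    diff = log2[:, trt_idx].mean(axis=1) - log2[:, ctl_idx].mean(axis=1)
    diff_by_probe = dict(zip(normalized.index, diff))

    match_by_probe = {m.probe_id: m for m in matches}
    buckets: dict[tuple[str, str], list[tuple[int, int, float]]] = {}
    n_skipped = 0
    for probe_id, d in diff_by_probe.items():
        m = match_by_probe.get(probe_id)
        if m is None:
            n_skipped += 1
            continue
        buckets.setdefault((m.chrom, m.strand), []).append((m.start, m.end, float(d)))

    if genome is not None:
        chrom_order = {c: i for i, c in enumerate(genome.chrom_names)}
    else:
        chrom_order = {c: i for i, c in enumerate(sorted({k[0] for k in buckets}))}
    tracks = []
    for (chrom, strand) in sorted(buckets, key=lambda k: (chrom_order[k[0]], k[1])):
        probes = sorted(buckets[(chrom, strand)])
        tracks.append(DiffSignalTrack(chrom=chrom, strand=strand, probes=probes))
    return tracks, n_skipped


def _cluster(
    selected: list[tuple[int, int, float]], gap: int
) -> list[list[tuple[int, int, float]]]:
    clusters: list[list[tuple[int, int, float]]] = []
    for p in selected:
        if clusters and p[0] - clusters[-1][-1][1] < gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


def segment(
    track: DiffSignalTrack,
    params: Optional[SegmentationParams] = None,
    all_probes_for_mean: Optional[bool] = None,
) -> list[DTR]:
    """Detect dTRs on one (chromosome, strand) track.

    Up- and down-regulated regions are segmented independently and never
    fused together.  ``all_probes_for_mean`` (default from params)
    switches the region-mean filter to average over every tiled probe
    inside the region boundaries instead of only the selected
    above-threshold members.
    """
    params = params or SegmentationParams()
    if all_probes_for_mean is None:
        all_probes_for_mean = params.include_subthreshold_in_mean
    starts = [p[0] for p in track.probes]
    if starts != sorted(starts):
        raise ValidationError("track must be sorted by start")

    out: list[DTR] = []
    for direction, sign in (("up", 1.0), ("down", -1.0)):
        selected = [p for p in track.probes if sign * p[2] > params.min_probe_diff]
        regions = []
        for cluster in _cluster(selected, params.cluster_gap):
            start, end = cluster[0][0], cluster[-1][1]
            if end - start <= params.min_region_len:
                continue
            members = cluster
            if all_probes_for_mean:
                members = [p for p in track.probes if start <= p[0] and p[1] <= end]
            if abs(float(np.mean([p[2] for p in members]))) <= params.min_probe_diff:
                continue
            regions.append((start, end, cluster))

        # fuse to a fixed point; fused regions keep the union of member
        # probes and are not re-tested against the length filter
        changed = True
        while changed:
            changed = False
            fused = []
            for reg in regions:
                if fused and reg[0] - fused[-1][1] < params.fuse_gap:
                    prev = fused[-1]
                    fused[-1] = (prev[0], max(prev[1], reg[1]), prev[2] + reg[2])
                    changed = True
                else:
                    fused.append(reg)
            regions = fused

        for start, end, cluster in regions:
            members = cluster
            if all_probes_for_mean:
                members = [p for p in track.probes if start <= p[0] and p[1] <= end]
            out.append(DTR(
                dtr_id=None, chrom=track.chrom, strand=track.strand,
                start=start, end=end, direction=direction,
                mean_diff=float(np.mean([p[2] for p in members])),
                n_probes=len(cluster), member_probes=list(cluster),
            ))
    out.sort(key=lambda d: (d.start, d.end, d.direction))
    return out


def segment_tracks(
    tracks: Sequence[DiffSignalTrack],
    params: Optional[SegmentationParams] = None,
    genome: Optional[GenomeSequence] = None,
) -> list[DTR]:
    """Segment every track and assign deterministic dTR identifiers."""
    dtrs: list[DTR] = []
    for t in tracks:
        dtrs.extend(segment(t, params))
    if genome is not None:
        chrom_order = {c: i for i, c in enumerate(genome.chrom_names)}
    else:
        chrom_order = {c: i for i, c in enumerate(sorted({d.chrom for d in dtrs}))}
    dtrs.sort(key=lambda d: (chrom_order[d.chrom], d.strand, d.start, d.end))
    return name_dtrs(dtrs, chrom_order)


def name_dtrs(dtrs: Sequence[DTR], chrom_order: Mapping[str, int]) -> list[DTR]:
    """Assign ids ``dTR<chrom#><strand#><ordinal:04d>``.

    Chromosome numbers are 1-based genome order; strand code 0 for "+",
    1 for "-"; the ordinal counts dTRs per (chromosome, strand) in
    positional order.  Requires input sorted by (chrom, strand, start);
    stable across reruns on identical input.
    """
    counters: dict[tuple[str, str], int] = {}
    for d in dtrs:
        key = (d.chrom, d.strand)
        counters[key] = counters.get(key, 0) + 1
        strand_code = 0 if d.strand == "+" else 1
        d.dtr_id = f"dTR{chrom_order[d.chrom] + 1}{strand_code}{counters[key]:04d}"
    return list(dtrs)


def dtr_cdf(
    dtrs: Sequence[DTR],
    matches: Sequence[GenomeMatch],
    probes_by_id: Mapping[str, ProbeRecord],
    params: Optional[PipelineParams] = None,
) -> list[Probeset]:
    """Build a probeset per dTR from probes contained in its interval.

    A probe joins a dTR's probeset iff its unique match lies fully
    inside the dTR interval on the dTR's strand.  dTRs with fewer than
    ``min_probes_per_set`` probes are dropped, mirroring the gene rule.
    """
    params = params or PipelineParams()
    out: list[Probeset] = []
    for d in dtrs:
        members = []
        for m in matches:
            if (m.chrom == d.chrom and m.strand == d.strand
                    and d.start <= m.start and m.end <= d.end):
                p = probes_by_id[m.probe_id]
                members.append(ProbePlacement(
                    m.probe_id, p.x, p.y, m.chrom, m.start, m.end, m.strand))
        if len(members) < params.min_probes_per_set:
            continue
        members.sort(key=lambda pl: (pl.start, pl.probe_id))
        out.append(Probeset(probeset_id=d.dtr_id or f"{d.chrom}{d.strand}{d.start}",
                            members=members))
    return out


def classify_overlap(
    dtr: DTR, features: Sequence[AnnotationFeature]
) -> list[OverlapAnnotation]:
    """Relate a dTR to every annotated ORF it intersects positionally.

    Classification uses the ORF's genomic span on any strand (antisense
    dTRs do overlap the sense ORF): ``orf_within_dtr`` when the ORF lies
    entirely inside the dTR, ``dtr_within_orf`` for the converse,
    ``partial_start``/``partial_end`` when exactly one ORF end falls
    inside the dTR (the other extending past the dTR's start or end,
    respectively).  Returns one record per overlapping gene; an empty
    list means a non-annotated region.
    """
    out: list[OverlapAnnotation] = []
    for f in features:
        if f.chrom != dtr.chrom:
            continue
        s, e = f.span
        if not (s < dtr.end and dtr.start < e):
            continue
        inside_start = dtr.start <= s < dtr.end
        inside_end = dtr.start < e <= dtr.end
        if inside_start and inside_end:
            cls = "orf_within_dtr"
        elif not inside_start and not inside_end:
            cls = "dtr_within_orf"
        elif inside_end:  # ORF begins before the dTR, ends inside it
            cls = "partial_start"
        else:  # ORF starts inside the dTR and runs past its end
            cls = "partial_end"
        out.append(OverlapAnnotation(gene_id=f.gene_id, overlap_class=cls))
    return out


def annotate_dtrs(
    dtrs: Sequence[DTR], features: Sequence[AnnotationFeature]
) -> list[DTR]:
    for d in dtrs:
        d.overlaps = classify_overlap(d, features)
    return list(dtrs)
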