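"""Readers and writers for the external formats the pipeline touches.

External conventions are converted at this boundary and nowhere else:
GFF3 is 1-based inclusive, bedGraph and the internal model are 0-based
half-open.  Flat tab-delimited tables (probe table, intensity matrix,
probe map, design, dTR table) may carry ``#`` comment headers which all
readers skip.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import (
    DTR,
    AnnotationFeature,
    DiffSignalTrack,
    FormatError,
    GenomeSequence,
    Interval,
    ProbePlacement,
    ProbeRecord,
    Probeset,
    StepCounts,
    ValidationError,
)

#: Probe-level intensities: rows indexed by probe_id, one column per array.
IntensityMatrix = pd.DataFrame

PROBE_MAP_COLUMNS = ["probeset_id", "probe_id", "x", "y", "chrom", "start", "end", "strand"]


# ---------------------------------------------------------------------------
# genome / annotation

def read_genome(
    path: str | Path,
    mask: Optional[Sequence[tuple[str, int, int]]] = None,
) -> GenomeSequence:
    """Read a FASTA genome, upper-casing sequences.

    ``mask`` lists ``(chrom, start, end)`` intervals (0-based half-open)
    to exclude from probe mapping, e.g. an rDNA locus.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty FASTA file")
    if not text.lstrip().startswith(">"):
        raise FormatError(f"{path}: not a FASTA file (no '>' header)")
    names: list[str] = []
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA record {rec.id!r}")
        names.append(rec.id)
        seqs[rec.id] = str(rec.seq).upper()
    if not names:
        raise FormatError(f"{path}: no FASTA records")

    masked: dict[str, list[Interval]] = {}
    for chrom, s, e in mask or ():
        if chrom not in seqs:
            raise ValidationError(f"mask interval on undeclared chromosome {chrom!r}")
        masked.setdefault(chrom, []).append((s, e))
    return GenomeSequence(chrom_names=names, sequences=seqs, masked_regions=masked)


def _merge_intervals(ivals: list[Interval]) -> tuple[list[Interval], bool]:
    ivals = sorted(ivals)
    merged: list[Interval] = []
    overlapped = False
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            if s < merged[-1][1]:
                overlapped = True
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged, overlapped


def read_annotation(path: str | Path) -> list[AnnotationFeature]:
    """Read gene models from GFF3 into 0-based half-open exon intervals.

    Exons (or CDS when a gene has no exon children) are grouped per gene
    through the gene/mRNA/exon hierarchy.  Overlapping exons within one
    gene are merged with a warning; exon features that trace to no gene
    are skipped with a warning.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[AnnotationFeature] = []
    used_exons: set[str] = set()
    seen_ids: set[str] = set()
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {gene.id!r} has unknown strand {gene.strand!r}"
            )
        exon_feats = list(db.children(gene, featuretype="exon"))
        if not exon_feats:
            exon_feats = list(db.children(gene, featuretype="CDS"))
        if exon_feats:
            ivals = [(f.start - 1, f.end) for f in exon_feats]
            used_exons.update(f.id for f in exon_feats)
        else:
            ivals = [(gene.start - 1, gene.end)]
        merged, overlapped = _merge_intervals(ivals)
        if overlapped:
            warnings.warn(f"overlapping exons in gene {gene.id!r} were merged")
        synonyms = list(gene.attributes.get("Alias", [])) + [
            s for s in gene.attributes.get("Name", []) if s != gene.id
        ]
        if gene.id in seen_ids:
            raise ValidationError(f"duplicate gene id {gene.id!r} in annotation")
        seen_ids.add(gene.id)
        features.append(
            AnnotationFeature(
                gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
                exons=merged, synonyms=synonyms,
            )
        )
    for exon in db.features_of_type("exon"):
        if exon.id not in used_exons:
            warnings.warn(f"exon {exon.id!r} has no parent gene; skipped")
    return features


def write_annotation(features: Sequence[AnnotationFeature], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive) with exon children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            s, e = f.span
            attrs = f"ID={f.gene_id}"
            if f.synonyms:
                attrs += ";Alias=" + ",".join(f.synonyms)
            fh.write(f"{f.chrom}\ttilede\tgene\t{s + 1}\t{e}\t.\t{f.strand}\t.\t{attrs}\n")
            for i, (xs, xe) in enumerate(f.exons, start=1):
                fh.write(
                    f"{f.chrom}\ttilede\texon\t{xs + 1}\t{xe}\t.\t{f.strand}\t.\t"
                    f"ID={f.gene_id}.exon{i};Parent={f.gene_id}\n"
                )


def write_genome(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# flat tables

def read_probe_table(path: str | Path) -> list[ProbeRecord]:
    """Read the probe definition TSV: probe_id, x, y, sequence."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str})
    required = {"probe_id", "x", "y", "sequence"}
    if not required.issubset(df.columns):
        raise FormatError(f"probe table missing columns {sorted(required - set(df.columns))}")
    probes = [
        ProbeRecord(r.probe_id, int(r.x), int(r.y), str(r.sequence).upper())
        for r in df.itertuples()
    ]
    xy = [(p.x, p.y) for p in probes]
    if len(set(xy)) != len(xy):
        raise ValidationError("duplicate (x, y) array coordinates in probe table")
    return probes


def write_probe_table(
    probes: Sequence[ProbeRecord], path: str | Path, header: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("probe_id\tx\ty\tsequence\n")
        for p in probes:
            fh.write(f"{p.probe_id}\t{p.x}\t{p.y}\t{p.sequence}\n")


def read_intensities(path: str | Path) -> IntensityMatrix:
    """Read the probe-by-array intensity TSV (strictly positive values)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col="probe_id")
    if df.empty:
        raise FormatError(f"{path}: empty intensity matrix")
    if (df.to_numpy() <= 0).any():
        raise ValidationError("intensity matrix contains non-positive values")
    return df.astype(float)


def write_intensities(
    m: IntensityMatrix, path: str | Path, header: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        m.to_csv(fh, sep="\t", index_label="probe_id", lineterminator="\n")


def read_design(path: str | Path) -> dict[str, str]:
    """Read the design TSV (array_id, condition), preserving row order."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"array_id", "condition"}.issubset(df.columns):
        raise FormatError("design table needs columns array_id, condition")
    return dict(zip(df.array_id, df.condition))


def write_design(design: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("array_id\tcondition\n")
        for array_id, condition in design.items():
            fh.write(f"{array_id}\t{condition}\n")


# ---------------------------------------------------------------------------
# probe map (flat CDF)

def write_probe_map(
    probesets: Sequence[Probeset], path: str | Path, header: Sequence[str] = ()
) -> None:
    """Write the flat probe-map TSV, one row per probe.

    Rows are ordered by probeset_id (lexicographic), then genomic
    position, regardless of input order.
    """
    rows = []
    for ps in probesets:
        seen: set[str] = set()
        for m in ps.members:
            if m.probe_id in seen:
                raise ValidationError(
                    f"duplicate probe {m.probe_id!r} in probeset {ps.probeset_id}"
                )
            seen.add(m.probe_id)
            rows.append((ps.probeset_id, m.probe_id, m.x, m.y,
                         m.chrom, m.start, m.end, m.strand))
    rows.sort(key=lambda r: (r[0], r[4], r[5], r[7]))
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("\t".join(PROBE_MAP_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(str(v) for v in r) + "\n")


def read_probe_map(path: str | Path) -> list[Probeset]:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"probeset_id": str, "probe_id": str})
    if list(df.columns) != PROBE_MAP_COLUMNS:
        raise FormatError(f"probe map must have columns {PROBE_MAP_COLUMNS}")
    out: list[Probeset] = []
    for psid, grp in df.groupby("probeset_id", sort=True):
        members = [
            ProbePlacement(r.probe_id, int(r.x), int(r.y), r.chrom,
                           int(r.start), int(r.end), r.strand)
            for r in grp.itertuples()
        ]
        out.append(Probeset(probeset_id=str(psid), members=members))
    return out


def write_step_counts(counts: StepCounts, path: str | Path,
                      header: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("step\tn\n")
        for name, n in counts.as_rows():
            fh.write(f"{name}\t{n}\n")


# ---------------------------------------------------------------------------
# tracks and dTR tables

def export_tracks(
    tracks: Sequence[DiffSignalTrack],
    out_dir: str | Path,
    prefix: str = "diff",
    display_threshold: float = 1.75,
) -> dict[tuple[str, str], Path]:
    """Write differential-signal bedGraph files, one per (strand, direction).

    Positions whose absolute log2 difference is below
    ``log2(display_threshold)`` (default 1.75-fold) are omitted, matching
    the browser-display convention.  Overlapping probe intervals from a
    tiling design are trimmed at the next probe start so each file holds
    sorted, non-overlapping intervals.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cut = float(np.log2(display_threshold))
    strand_name = {"+": "plus", "-": "minus"}

    lines: dict[tuple[str, str], list[str]] = {
        (s, d): [] for s in "+-" for d in ("up", "down")
    }
    for track in tracks:
        starts = [p[0] for p in track.probes]
        if starts != sorted(starts):
            raise ValidationError(f"track {track.chrom}{track.strand} is unsorted")
        for direction, keep in (("up", lambda v: v >= cut),
                                ("down", lambda v: v <= -cut)):
            sel = [(s, e, v) for s, e, v in track.probes if keep(v)]
            for i, (s, e, v) in enumerate(sel):
                if i + 1 < len(sel):
                    e = min(e, sel[i + 1][0])
                if e > s:
                    lines[(track.strand, direction)].append(
                        f"{track.chrom}\t{s}\t{e}\t{v:.4f}\n"
                    )

    paths: dict[tuple[str, str], Path] = {}
    for (strand, direction), rows in lines.items():
        p = out_dir / f"{prefix}.{strand_name[strand]}.{direction}.bedGraph"
        with open(p, "w") as fh:
            fh.write(
                f'track type=bedGraph name="{prefix} {strand}{direction}"\n'
            )
            fh.writelines(rows)
        paths[(strand, direction)] = p
    return paths


def write_dtr_table(
    dtrs: Sequence[DTR],
    path: str | Path,
    quant: Optional[Mapping[str, tuple[float, float]]] = None,
    header: Sequence[str] = (),
) -> None:
    """Write the dTR table, one row per (dTR, overlapping gene).

    ``quant`` optionally maps dtr_id to (log2_ratio, p_value) from
    probeset-level quantification; without it the segmentation-level
    mean difference is reported and p_value is empty.  The overlap
    column uses the </> symbol convention: ``> name <`` for an ORF
    inside the dTR, ``< name >`` for a dTR inside the ORF, ``<name`` /
    ``name>`` for partial overlap at one end.
    """
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("dtr_id\tlog2_ratio\tp_value\tchrom\tstrand\tstart\tend\t"
                 "length\toverlap\n")
        for d in dtrs:
            if quant is not None and d.dtr_id in quant:
                ratio, p = quant[d.dtr_id]
                ratio_s, p_s = f"{ratio:.4f}", ("" if np.isnan(p) else f"{p:.3g}")
            else:
                ratio_s, p_s = f"{d.mean_diff:.4f}", ""
            symbols = [o.symbol for o in d.overlaps] or [""]
            for sym in symbols:
                fh.write(
                    f"{d.dtr_id}\t{ratio_s}\t{p_s}\t{d.chrom}\t{d.strand}\t"
                    f"{d.start}\t{d.end}\t{d.length}\t{sym}\n"
                )


def write_dtr_bed(dtrs: Sequence[DTR], path: str | Path) -> None:
    """dTR intervals as BED6 (score = |mean diff| scaled to 0-1000)."""
    with open(path, "w") as fh:
        for d in dtrs:
            score = int(min(1000, round(abs(d.mean_diff) * 250)))
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.dtr_id}\t{score}\t{d.strand}\n")


# ---------------------------------------------------------------------------
# provenance headers

def file_checksum(path: str | Path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


def provenance_header(
    params: Mapping[str, object] = (), inputs: Sequence[str | Path] = ()
) -> list[str]:
    """Comment lines recording tool version, config hash and input checksums.

    Paths are reduced to basenames so outputs are byte-identical across
    working directories.
    """
    from . import __version__

    items = sorted((str(k), str(v)) for k, v in dict(params).items())
    cfg = hashlib.md5(repr(items).encode()).hexdigest()
    lines = [f"tilede version={__version__}", f"config md5={cfg}"]
    for p in inputs:
        lines.append(f"input {Path(p).name} md5={file_checksum(p)}")
    return lines
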