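"""Seeded generators for genomes, annotations, probe designs and intensities.

The default specification emulates a compact fission-yeast-like study:
two 100 kb chromosomes, 60 annotated genes, a 25-mer probe set tiling
both strands every 20 nt (so three probes fall within any 60 nt window),
two replicate hybridizations per condition, multiplicative log-normal
intensity noise, ten differentially expressed genes and a handful of
planted non-annotated transcripts (intergenic and antisense) that only
appear under the treated condition.  Every planted anomaly is recorded
in a ground-truth object so that pipeline bookkeeping and recovery can
be checked exactly.

An alternative ``layout="exonic"`` places probes only inside exons (an
expression-array-like design); planted duplicate / multi-mapping /
unmapped / intergenic probes then let each filtering step of the CDF
pipeline be audited against known counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as tio
from .model import (
    AnnotationFeature,
    GenomeSequence,
    ProbeRecord,
    ValidationError,
    revcomp,
)

_ALPHABET = np.array(list("ACGT"))


@dataclass
class SimulationSpec:
    """Parameters of one simulated study.  All randomness flows from ``seed``."""

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (100_000, 100_000)
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (600, 2400)
    two_exon_fraction: float = 0.25
    intron_length_range: tuple[int, int] = (60, 200)
    feature_margin: int = 400
    probe_length: int = 25
    tiling_step: int = 20
    layout: str = "tiling"  # or "exonic"
    # planted probe anomalies (mainly for the exonic bookkeeping fixture)
    n_duplicate_probes: int = 0
    n_multimap_probes: int = 0
    n_unmapped_probes: int = 0
    n_intergenic_probes: int = 0
    # expression ground truth
    n_de_genes: int = 10
    de_effect_range: tuple[float, float] = (1.0, 2.0)
    n_intergenic_transcripts: int = 5
    transcript_length_range: tuple[int, int] = (300, 600)
    transcript_effect: float = 1.5
    n_antisense_transcripts: int = 1
    # intensity model (log2 scale)
    baseline_log2: float = 6.0
    expressed_boost_log2: float = 2.0
    probe_affinity_sigma: float = 0.3
    noise_sigma: float = 0.15
    replicates: int = 2
    condition_names: tuple[str, str] = ("control", "stress")

    def __post_init__(self) -> None:
        if self.layout not in ("tiling", "exonic"):
            raise ValidationError(f"unknown layout {self.layout!r}")
        if self.tiling_step >= 60:
            raise ValidationError("tiling_step must stay below the 60 nt cluster gap")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths))]


@dataclass
class GroundTruth:
    """Everything that was planted, for exact downstream checks."""

    de_genes: dict[str, float] = field(default_factory=dict)
    transcripts: pd.DataFrame = field(default_factory=pd.DataFrame)
    duplicate_probe_ids: list[str] = field(default_factory=list)
    multimap_probe_ids: list[str] = field(default_factory=list)
    unmapped_probe_ids: list[str] = field(default_factory=list)
    intergenic_probe_ids: list[str] = field(default_factory=list)
    probe_positions: dict[str, tuple[str, str, int, int]] = field(default_factory=dict)

    def frames(self) -> dict[str, pd.DataFrame]:
        return {
            "de_genes": pd.DataFrame(
                sorted(self.de_genes.items()), columns=["gene_id", "log2_effect"]
            ),
            "transcripts": self.transcripts,
            "planted_probes": pd.DataFrame(
                [("duplicate", p) for p in self.duplicate_probe_ids]
                + [("multimap", p) for p in self.multimap_probe_ids]
                + [("unmapped", p) for p in self.unmapped_probe_ids]
                + [("intergenic", p) for p in self.intergenic_probe_ids],
                columns=["kind", "probe_id"],
            ),
        }


def _place_features(spec: SimulationSpec, rng: np.random.Generator):
    """Lay genes and planted transcripts along the chromosomes.

    Sequential placement with randomized gaps of at least
    ``feature_margin`` guarantees non-overlap and clearance between
    annotation and planted intergenic transcripts.
    """
    chroms = spec.chrom_names()
    items = [("gene", i) for i in range(spec.n_genes)] + [
        ("transcript", j) for j in range(spec.n_intergenic_transcripts)
    ]
    order = rng.permutation(len(items))
    cursors = {c: spec.feature_margin for c in chroms}
    lengths = dict(zip(chroms, spec.chrom_lengths))
    genes: list[AnnotationFeature] = []
    transcripts: list[dict] = []
    for k, idx in enumerate(order):
        kind, i = items[idx]
        chrom = chroms[k % len(chroms)]
        if kind == "gene":
            length = int(rng.integers(*spec.gene_length_range))
        else:
            length = int(rng.integers(*spec.transcript_length_range))
        gap = int(rng.integers(0, spec.feature_margin))
        start = cursors[chrom] + gap
        end = start + length
        if end + spec.feature_margin > lengths[chrom]:
            raise ValidationError(
                f"simulation spec infeasible: features do not fit on {chrom}"
            )
        cursors[chrom] = end + spec.feature_margin
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "gene":
            gene_id = f"gene{i + 1:03d}"
            if length >= 400 and rng.random() < spec.two_exon_fraction:
                intron = int(rng.integers(*spec.intron_length_range))
                ex1 = int(rng.integers(150, length - intron - 150))
                exons = [(start, start + ex1), (start + ex1 + intron, end)]
            else:
                exons = [(start, end)]
            genes.append(AnnotationFeature(gene_id, chrom, strand, exons))
        else:
            transcripts.append({
                "transcript_id": f"planted{i + 1:02d}", "kind": "intergenic",
                "chrom": chrom, "strand": strand, "start": start, "end": end,
                "log2_effect": spec.transcript_effect,
            })
    genes.sort(key=lambda g: (g.chrom, g.span[0]))
    return genes, transcripts


def _random_kmer(rng: np.random.Generator, k: int) -> str:
    return "".join(_ALPHABET[rng.integers(0, 4, k)])


def simulate_genome_and_probes(
    spec: SimulationSpec,
) -> tuple[GenomeSequence, list[AnnotationFeature], list[ProbeRecord], GroundTruth]:
    """Generate (genome, annotation, probe table, ground truth).

    Fully reproducible from ``spec.seed``; planted anomalies are
    verified during construction (unique / duplicated / absent exactly
    as requested) so downstream step counts are exact.
    """
    rng = np.random.default_rng([spec.seed, 0])
    truth = GroundTruth()
    chroms = spec.chrom_names()

    genes, transcripts = _place_features(spec, rng)

    # raw random sequence per chromosome, as mutable char arrays
    seq_arrays = {
        c: _ALPHABET[rng.integers(0, 4, n)].copy()
        for c, n in zip(chroms, spec.chrom_lengths)
    }

    exon_blocks = [(g.chrom, s, e) for g in genes for s, e in g.exons]

    def clear_of_exons(chrom: str, start: int, end: int, margin: int) -> bool:
        for c, s, e in exon_blocks:
            if c == chrom and start - margin < e and s < end + margin:
                return False
        return True

    # plant multi-mapper repeats before extracting any probe sequence:
    # the same probe-length k-mer written at two intergenic positions,
    # deliberately misaligned with the tiling grid so that no tiled
    # window coincides with a repeat copy
    L = spec.probe_length
    multi_seqs: list[str] = []
    for i in range(spec.n_multimap_probes):
        kmer = _random_kmer(rng, L)
        placed = 0
        attempts = 0
        while placed < 2:
            attempts += 1
            if attempts > 10_000:
                raise ValidationError("could not place multi-mapper repeats")
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(0, spec.chrom_lengths[chroms.index(chrom)] - L))
            if pos % spec.tiling_step == 0:
                continue
            if not clear_of_exons(chrom, pos, pos + L, L + spec.tiling_step):
                continue
            seq_arrays[chrom][pos : pos + L] = list(kmer)
            placed += 1
        multi_seqs.append(kmer)

    sequences = {c: "".join(a) for c, a in seq_arrays.items()}
    genome = GenomeSequence(chrom_names=chroms, sequences=sequences)

    # base probe complement
    probes: list[ProbeRecord] = []

    def add_probe(pid: str, seq: str, chrom: Optional[str], strand: str,
                  start: int, end: int) -> None:
        probes.append(ProbeRecord(pid, 0, 0, seq))  # x,y assigned afterwards
        if chrom is not None:
            truth.probe_positions[pid] = (chrom, strand, start, end)

    if spec.layout == "tiling":
        for chrom in chroms:
            seq = sequences[chrom]
            for start in range(0, len(seq) - L + 1, spec.tiling_step):
                window = seq[start : start + L]
                add_probe(f"{chrom}:{start}:+", window, chrom, "+", start, start + L)
                add_probe(f"{chrom}:{start}:-", revcomp(window), chrom, "-", start, start + L)
    else:  # exonic
        for g in genes:
            seq = sequences[g.chrom]
            for s, e in g.exons:
                for start in range(s, e - L + 1, spec.tiling_step):
                    window = seq[start : start + L]
                    pseq = window if g.strand == "+" else revcomp(window)
                    add_probe(f"{g.gene_id}:{start}", pseq, g.chrom, g.strand,
                              start, start + L)

    base_seqs = {p.sequence for p in probes}
    if len(base_seqs) != len(probes):
        raise ValidationError(
            "random genome produced coincidental duplicate probe sequences; "
            "use another seed"
        )

    # planted duplicates: re-spot existing probe sequences under new ids
    if spec.n_duplicate_probes:
        picks = rng.choice(len(probes), size=spec.n_duplicate_probes, replace=False)
        for i, k in enumerate(sorted(int(v) for v in picks)):
            src = probes[k]
            pid = f"dup{i + 1:03d}"
            pos = truth.probe_positions.get(src.probe_id)
            add_probe(pid, src.sequence, *(pos or (None, "+", 0, 0)))
            truth.duplicate_probe_ids.append(pid)

    # planted multi-mappers: one probe per repeated k-mer
    for i, kmer in enumerate(multi_seqs):
        pid = f"multi{i + 1:03d}"
        add_probe(pid, kmer, None, "+", 0, 0)
        truth.multimap_probe_ids.append(pid)

    # planted unmapped probes: random k-mers absent from both strands
    for i in range(spec.n_unmapped_probes):
        for _ in range(1000):
            kmer = _random_kmer(rng, L)
            rc = revcomp(kmer)
            if kmer in base_seqs:
                continue
            if any(kmer in s or rc in s for s in sequences.values()):
                continue
            break
        else:
            raise ValidationError("could not generate unmapped probes")
        pid = f"unmapped{i + 1:03d}"
        add_probe(pid, kmer, None, "+", 0, 0)
        truth.unmapped_probe_ids.append(pid)

    # planted intergenic probes: unique genomic windows clear of all exons
    for i in range(spec.n_intergenic_probes):
        for _ in range(10_000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(0, spec.chrom_lengths[chroms.index(chrom)] - L))
            if spec.layout == "tiling" and pos % spec.tiling_step == 0:
                continue
            if not clear_of_exons(chrom, pos, pos + L, 0):
                continue
            window = sequences[chrom][pos : pos + L]
            if window in base_seqs or window in multi_seqs:
                continue
            break
        else:
            raise ValidationError("could not place intergenic probes")
        pid = f"inter{i + 1:03d}"
        add_probe(pid, window, chrom, "+", pos, pos + L)
        truth.intergenic_probe_ids.append(pid)

    # assign array coordinates row-major; planted extras come last and
    # therefore lose the (y, x)-first tie-break against their originals
    width = 1000
    probes = [
        ProbeRecord(p.probe_id, i % width, i // width, p.sequence)
        for i, p in enumerate(probes)
    ]

    # expression ground truth: DE genes and antisense transcripts
    gene_ids = [g.gene_id for g in genes]
    de_picks = rng.choice(len(gene_ids), size=spec.n_de_genes, replace=False)
    for k in sorted(int(v) for v in de_picks):
        mag = rng.uniform(*spec.de_effect_range)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        truth.de_genes[gene_ids[k]] = float(sign * mag)

    non_de = [g for g in genes if g.gene_id not in truth.de_genes]
    anti_rows = []
    if spec.n_antisense_transcripts:
        hosts = rng.choice(len(non_de), size=spec.n_antisense_transcripts,
                           replace=False)
        for j, k in enumerate(sorted(int(v) for v in hosts)):
            host = non_de[k]
            s, e = host.span
            anti_rows.append({
                "transcript_id": f"antisense{j + 1:02d}", "kind": "antisense",
                "chrom": host.chrom,
                "strand": "-" if host.strand == "+" else "+",
                "start": s, "end": e, "log2_effect": spec.transcript_effect,
            })
    truth.transcripts = pd.DataFrame(
        transcripts + anti_rows,
        columns=["transcript_id", "kind", "chrom", "strand", "start", "end",
                 "log2_effect"],
    )

    return genome, genes, probes, truth


def simulate_intensities(
    spec: SimulationSpec,
    probes: list[ProbeRecord],
    features: list[AnnotationFeature],
    truth: GroundTruth,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Raw intensities for two replicated conditions.

    log2 intensity = baseline + per-probe affinity + expression boosts
    (sense-strand containment only) + N(0, noise_sigma) per array;
    intensities are 2 to that power, i.e. multiplicative log-normal
    noise.  Differential effects multiply treated-condition signal by
    2**effect; planted transcripts carry signal only when treated.
    """
    rng = np.random.default_rng([spec.seed, 1])
    control, treated = spec.condition_names
    arrays = [f"{c}_{r + 1}" for c in spec.condition_names for r in range(spec.replicates)]
    design = {a: a.rsplit("_", 1)[0] for a in arrays}

    n = len(probes)
    affinity = rng.normal(0.0, spec.probe_affinity_sigma, n)
    base = np.full(n, spec.baseline_log2) + affinity

    ctrl_boost = np.zeros(n)
    trt_boost = np.zeros(n)
    pos = [truth.probe_positions.get(p.probe_id) for p in probes]

    def contained(p, chrom, strand, s, e) -> bool:
        return p is not None and p[0] == chrom and p[1] == strand and s <= p[2] and p[3] <= e

    for g in features:
        effect = truth.de_genes.get(g.gene_id, 0.0)
        for i, p in enumerate(pos):
            if any(contained(p, g.chrom, g.strand, s, e) for s, e in g.exons):
                ctrl_boost[i] += spec.expressed_boost_log2
                trt_boost[i] += spec.expressed_boost_log2 + effect
    for row in truth.transcripts.itertuples():
        for i, p in enumerate(pos):
            if contained(p, row.chrom, row.strand, row.start, row.end):
                trt_boost[i] += row.log2_effect

    cols = {}
    for a in arrays:
        boost = trt_boost if design[a] == treated else ctrl_boost
        noise = rng.normal(0.0, spec.noise_sigma, n) if spec.noise_sigma > 0 else 0.0
        cols[a] = np.power(2.0, base + boost + noise)
    m = pd.DataFrame(cols, index=pd.Index([p.probe_id for p in probes], name="probe_id"))
    return m, design


def write_fixture(spec: SimulationSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate a full fixture set and write it as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, features, probes, truth = simulate_genome_and_probes(spec)
    intensities, design = simulate_intensities(spec, probes, features, truth)

    paths = {
        "genome": outdir / "genome.fasta",
        "annotation": outdir / "annotation.gff3",
        "probes": outdir / "probes.tsv",
        "intensities": outdir / "intensities.tsv",
        "design": outdir / "design.tsv",
    }
    tio.write_genome(genome, paths["genome"])
    tio.write_annotation(features, paths["annotation"])
    tio.write_probe_table(probes, paths["probes"])
    tio.write_intensities(intensities, paths["intensities"])
    tio.write_design(design, paths["design"])
    for name, frame in truth.frames().items():
        p = outdir / f"truth_{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths[f"truth_{name}"] = p
    return paths
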