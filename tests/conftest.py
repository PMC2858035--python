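"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's own code paths: exact
matching uses Python's C-level ``str.find`` scan, and median polish is
re-implemented with plain loops and ``statistics.median``.
"""

from __future__ import annotations

import statistics

import numpy as np
import pytest

from tilede.model import DiffSignalTrack, GenomeMatch, GenomeSequence, revcomp


# ---------------------------------------------------------------------------
# exact-search oracle

def naive_search(patterns: dict[str, str], genome: GenomeSequence) -> list[GenomeMatch]:
    """Both-strand exact search by repeated ``str.find``."""
    out = []
    for pid, pat in patterns.items():
        for chrom in genome.chrom_names:
            seq = genome.sequences[chrom]
            for target, strand in ((pat, "+"), (revcomp(pat), "-")):
                i = seq.find(target)
                while i != -1:
                    if not genome.is_masked_start(chrom, i):
                        out.append(GenomeMatch(chrom, i, i + len(pat), strand, pid))
                    i = seq.find(target, i + 1)
    order = {c: i for i, c in enumerate(genome.chrom_names)}
    out.sort(key=lambda m: (order[m.chrom], m.start, m.strand, m.probe_id))
    return out


def random_genome(rng: np.random.Generator, n_chroms=1, min_len=200, max_len=5000,
                  with_n=False) -> GenomeSequence:
    alphabet = "ACGTN" if with_n else "ACGT"
    names = [f"c{i}" for i in range(n_chroms)]
    seqs = {}
    for name in names:
        length = int(rng.integers(min_len, max_len + 1))
        probs = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else None
        seqs[name] = "".join(
            rng.choice(list(alphabet), size=length, p=probs)
        )
    return GenomeSequence(chrom_names=names, sequences=seqs)


def random_patterns(rng: np.random.Generator, genome: GenomeSequence,
                    n: int, lengths=(25,)) -> dict[str, str]:
    """A mix of genome-derived (hit-guaranteed) and random patterns."""
    out = {}
    chroms = genome.chrom_names
    for i in range(n):
        L = int(rng.choice(lengths))
        kind = rng.random()
        if kind < 0.45:
            chrom = chroms[int(rng.integers(len(chroms)))]
            seq = genome.sequences[chrom]
            if len(seq) >= L:
                s = int(rng.integers(0, len(seq) - L + 1))
                pat = seq[s : s + L]
            else:
                pat = "".join(rng.choice(list("ACGT"), size=L))
        elif kind < 0.7:
            chrom = chroms[int(rng.integers(len(chroms)))]
            seq = genome.sequences[chrom]
            if len(seq) >= L:
                s = int(rng.integers(0, len(seq) - L + 1))
                pat = revcomp(seq[s : s + L])
            else:
                pat = "".join(rng.choice(list("ACGT"), size=L))
        else:
            pat = "".join(rng.choice(list("ACGT"), size=L))
        if "N" in pat:
            pat = pat.replace("N", "A")
        out[f"p{i}"] = pat
    return out


# ---------------------------------------------------------------------------
# median-polish oracle

def naive_median_polish(matrix, tol=0.01, max_iter=10):
    """Loop-based Tukey median polish (same sweep schedule, no numpy)."""
    z = [list(map(float, row)) for row in matrix]
    nr, nc = len(z), len(z[0])
    t = 0.0
    r = [0.0] * nr
    c = [0.0] * nc
    for _ in range(max_iter):
        biggest = 0.0
        for i in range(nr):
            med = statistics.median(z[i])
            for j in range(nc):
                z[i][j] -= med
            r[i] += med
            biggest = max(biggest, abs(med))
        d = statistics.median(c)
        c = [v - d for v in c]
        t += d
        biggest = max(biggest, abs(d))
        for j in range(nc):
            med = statistics.median(z[i][j] for i in range(nr))
            for i in range(nr):
                z[i][j] -= med
            c[j] += med
            biggest = max(biggest, abs(med))
        d = statistics.median(r)
        r = [v - d for v in r]
        t += d
        biggest = max(biggest, abs(d))
        if biggest < tol:
            break
    return t, r, c, z


# ---------------------------------------------------------------------------
# segmentation oracle

def brute_segment(probes, params):
    """Explicit enumeration of clusters and pairwise fusion scans.

    Returns (strand-agnostic) regions as (start, end, direction,
    mean_diff, n_selected) tuples, sorted.
    """
    results = []
    for direction, sign in (("up", 1.0), ("down", -1.0)):
        sel = [p for p in probes if sign * p[2] > params.min_probe_diff]
        # enumerate clusters by cutting at large gaps
        cuts = [k for k in range(1, len(sel))
                if sel[k][0] - sel[k - 1][1] >= params.cluster_gap]
        bounds = [0] + cuts + [len(sel)]
        clusters = [sel[a:b] for a, b in zip(bounds, bounds[1:]) if b > a]
        regions = []
        for cl in clusters:
            start, end = cl[0][0], cl[-1][1]
            if end - start <= params.min_region_len:
                continue
            mean = sum(p[2] for p in cl) / len(cl)
            if abs(mean) <= params.min_probe_diff:
                continue
            regions.append([start, end, list(cl)])
        # pairwise fusion until no adjacent pair qualifies
        done = False
        while not done:
            done = True
            for k in range(len(regions) - 1):
                if regions[k + 1][0] - regions[k][1] < params.fuse_gap:
                    a, b = regions[k], regions[k + 1]
                    regions[k] = [a[0], max(a[1], b[1]), a[2] + b[2]]
                    del regions[k + 1]
                    done = False
                    break
        for start, end, cl in regions:
            mean = sum(p[2] for p in cl) / len(cl)
            results.append((start, end, direction, mean, len(cl)))
    results.sort()
    return results


def random_track(rng: np.random.Generator, n_max=200, chrom="c0", strand="+"):
    n = int(rng.integers(0, n_max + 1))
    gaps = rng.integers(5, 120, size=n)
    starts = np.cumsum(gaps)
    diffs = rng.normal(0.0, 1.0, size=n)
    probes = [(int(s), int(s) + 25, float(d)) for s, d in zip(starts, diffs)]
    return DiffSignalTrack(chrom=chrom, strand=strand, probes=probes)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
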