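"""Exact probe-to-genome mapping with a Karp-Rabin rolling hash.

Probes are short (typically 25-nt) DNA patterns; the genome is searched
on both strands by hashing every genomic window of each distinct pattern
length with a base-4 polynomial hash (one base per nucleotide, matching
the four-letter alphabet) and comparing against the pattern hashes.
Every hash hit is verified by direct string comparison, so hash
collisions can cost time but never correctness.  Reverse-strand hits are
found by searching the reverse complement of each pattern against the
forward genome.

Windows containing ``N`` never match (the hash may collide but
verification rejects them), and matches starting inside a masked genome
region are suppressed.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from .model import (
    GenomeMatch,
    GenomeSequence,
    MatchReport,
    ProbeRecord,
    ValidationError,
    revcomp,
)

# Polynomial hash parameters: base 4 (alphabet size), Mersenne-prime modulus.
_BASE = np.uint64(4)
_MOD = np.uint64(2**31 - 1)

# Byte-level encoding table: A,C,G,T -> 0..3; N -> 4 (never matches); else 255.
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
_ENC[ord("N")] = 4


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pattern_hash(seq: str) -> int:
    h = np.uint64(0)
    for c in _encode(seq):
        h = (h * _BASE + np.uint64(c)) % _MOD
    return int(h)


def _window_hashes(code: np.ndarray, length: int) -> np.ndarray:
    """Hash of every genomic window of ``length``, computed column-wise.

    Equivalent to the classic rolling recurrence but vectorized: the
    j-th pass folds the j-th character of every window into the running
    hash simultaneously.
    """
    n = len(code) - length + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    h = np.zeros(n, dtype=np.uint64)
    c = code.astype(np.uint64)
    for j in range(length):
        h = (h * _BASE + c[j : j + n]) % _MOD
    return h


ProbeInput = Union[Sequence[ProbeRecord], Mapping[str, str]]


def _as_pattern_map(probes: ProbeInput) -> dict[str, str]:
    if isinstance(probes, Mapping):
        items = dict(probes)
    else:
        items = {p.probe_id: p.sequence for p in probes}
    for pid, seq in items.items():
        if not seq or set(seq) - set("ACGT"):
            raise ValidationError(
                f"probe {pid!r}: pattern must be non-empty over ACGT, got {seq!r}"
            )
    return items


def karp_rabin_search(probes: ProbeInput, genome: GenomeSequence) -> list[GenomeMatch]:
    """Find every exact occurrence of every probe on both genome strands.

    Parameters
    ----------
    probes:
        ``ProbeRecord`` sequence or a mapping ``probe_id -> pattern``.
        Patterns may have mixed lengths.
    genome:
        Reference genome; matches starting inside ``masked_regions`` are
        excluded, and windows overlapping an ``N`` cannot match.

    Returns
    -------
    Matches sorted by (chromosome order, start, strand, probe_id).  A
    reverse-strand match at ``[start, end)`` means the probe sequence
    equals the reverse complement of that interval.
    """
    patterns = _as_pattern_map(probes)
    if not patterns:
        return []

    # Group searched strings by length; each searched string carries the
    # (probe_id, strand) pairs it stands for.  A palindromic probe
    # contributes the same string on both strands and therefore reports
    # two matches per locus.
    by_length: dict[int, dict[str, list[tuple[str, str]]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for pid, seq in patterns.items():
        by_length[len(seq)][seq].append((pid, "+"))
        by_length[len(seq)][revcomp(seq)].append((pid, "-"))

    out: list[GenomeMatch] = []
    for chrom in genome.chrom_names:
        seq = genome.sequences[chrom]
        code = _encode(seq)
        for length, targets in by_length.items():
            win = _window_hashes(code, length)
            if win.size == 0:
                continue
            table: dict[int, list[str]] = defaultdict(list)
            for s in targets:
                table[_pattern_hash(s)].append(s)
            wanted = np.fromiter(table.keys(), dtype=np.uint64, count=len(table))
            hits = np.nonzero(np.isin(win, wanted))[0]
            for start in hits.tolist():
                window = seq[start : start + length]
                for cand in table[int(win[start])]:
                    if cand != window:
                        continue  # hash collision or N window
                    if genome.is_masked_start(chrom, start):
                        continue
                    for pid, strand in targets[cand]:
                        out.append(
                            GenomeMatch(chrom, start, start + length, strand, pid)
                        )

    order = {c: i for i, c in enumerate(genome.chrom_names)}
    out.sort(key=lambda m: (order[m.chrom], m.start, m.strand, m.probe_id))
    return out


def classify_matches(
    matches: Iterable[GenomeMatch], probes: Sequence[ProbeRecord]
) -> MatchReport:
    """Partition probes into unmapped / unique / multi-mapping.

    Uniqueness counts matches over both strands combined: a probe hitting
    one locus on both strands (palindrome) is multi-mapping.
    """
    known = {p.probe_id for p in probes}
    by_probe: dict[str, list[GenomeMatch]] = {p.probe_id: [] for p in probes}
    for m in matches:
        if m.probe_id not in known:
            raise ValidationError(f"match references unknown probe {m.probe_id!r}")
        by_probe[m.probe_id].append(m)

    counts = [len(v) for v in by_probe.values()]
    return MatchReport(
        matches_by_probe=by_probe,
        n_unmapped=sum(c == 0 for c in counts),
        n_unique=sum(c == 1 for c in counts),
        n_multi=sum(c >= 2 for c in counts),
    )
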