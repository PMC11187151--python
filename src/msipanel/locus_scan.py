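"""Microsatellite locus discovery in reference sequences.

Scans DNA sequences for maximal tandem repeat tracts with a primitive unit
of 1-5 bp repeated 7-13 whole times — the repeat class used to nominate
candidate loci for MSI profiling. Mononucleotide tracts in this copy range
are the classic MSI markers (BAT-25/BAT-26 style); the scanner generalises
to units up to 5 bp.

Conventions
-----------
* Only whole unit copies count; a trailing partial unit is excluded from the
  reported interval and does not contribute to the copy count.
* Tracts exceeding the upper copy bound are excluded entirely, not truncated.
* Only the forward strand is scanned; the reported unit is the
  lexicographically smallest rotation, which makes reports deterministic.
* ``N`` (or any non-ACGT character) terminates a tract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

_ACGT = frozenset("ACGT")


class NonPrimitiveUnitError(ValueError):
    """Raised when a repeat unit is itself a repetition of a shorter unit."""


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """A maximal genomic tandem-repeat tract eligible for MSI profiling.

    Coordinates are 0-based half-open; ``end - start == unit_len * copies``.
    ``unit`` is the canonical (lexicographically smallest) rotation of the
    primitive repeat unit.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    unit: str
    unit_len: int
    copies: int
    gene_label: str | None = None

    def __post_init__(self) -> None:
        if self.unit_len != len(self.unit):
            raise ValueError("unit_len must equal len(unit)")
        if self.end - self.start != self.unit_len * self.copies:
            raise ValueError("interval length must equal unit_len * copies")


def canonical_unit(unit: str) -> str:
    """Return the canonical rotation of a primitive repeat unit.

    The canonical form is the lexicographically smallest rotation, so "TA"
    and "AT" describe the same dinucleotide tract. Units that are whole-number
    repetitions of a shorter string (e.g. "AA", "ACAC") are rejected with
    :class:`NonPrimitiveUnitError` — such tracts are described by their
    shorter primitive unit instead.
    """
    if not unit:
        raise ValueError("unit must be non-empty")
    if not _ACGT.issuperset(unit):
        raise ValueError(f"unit contains non-ACGT characters: {unit!r}")
    # standard primitivity test: u is non-primitive iff u occurs in (u+u)[1:-1]
    if unit in (unit + unit)[1:-1]:
        raise NonPrimitiveUnitError(f"unit {unit!r} repeats a shorter unit")
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def is_primitive(unit: str) -> bool:
    return unit not in (unit + unit)[1:-1]


def default_locus_id(chrom: str, start: int, end: int, unit: str) -> str:
    return f"{chrom}:{start}-{end}:{unit}"


def scan_sequence(
    chrom: str,
    seq: str,
    min_unit: int = 1,
    max_unit: int = 5,
    min_copies: int = 7,
    max_copies: int | None = 13,
) -> list[MicrosatelliteLocus]:
    """Scan one sequence for maximal primitive repeat tracts.

    For each period ``k`` the positions where ``seq[i] == seq[i+k]`` form
    runs; a maximal run of length ``r`` is a periodic region of length
    ``r + k`` whose whole-copy prefix is the reported tract. Primitivity of
    the observed unit guarantees (Fine–Wilf, at >=7 copies) that ``k`` is the
    minimal period, so every physical tract is reported under exactly one
    unit length.

    ``max_copies=None`` disables the upper copy bound.
    """
    seq = seq.upper()
    n = len(seq)
    out: dict[tuple[int, int], MicrosatelliteLocus] = {}
    if n == 0:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    for k in range(min_unit, max_unit + 1):
        if n < k * min_copies:
            continue
        eq = (arr[:-k] == arr[k:]) & valid[:-k] & valid[k:]
        if not eq.any():
            continue
        # boundaries of runs of True
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # exclusive
        for i, j in zip(starts, ends):
            tract_len = (j - i) + k  # periodic region length
            copies = tract_len // k
            if copies < min_copies:
                continue
            if max_copies is not None and copies > max_copies:
                continue
            unit = seq[i : i + k]
            if not is_primitive(unit):
                continue  # found at its primitive period instead
            start, end = int(i), int(i + copies * k)
            key = (start, end)
            if key in out and out[key].unit_len <= k:
                continue  # prefer the shorter unit (defensive; unreachable)
            cu = canonical_unit(unit)
            out[key] = MicrosatelliteLocus(
                locus_id=default_locus_id(chrom, start, end, cu),
                chrom=chrom,
                start=start,
                end=end,
                unit=cu,
                unit_len=k,
                copies=int(copies),
            )
    return [out[k] for k in sorted(out)]


def scan_reference(
    sequences: Mapping[str, str],
    min_unit: int = 1,
    max_unit: int = 5,
    min_copies: int = 7,
    max_copies: int | None = 13,
) -> list[MicrosatelliteLocus]:
    """Scan a named collection of sequences; output sorted by (chrom, start)."""
    if not sequences:
        raise ValueError("sequence collection is empty")
    if not (1 <= min_unit <= max_unit):
        raise ValueError("require 1 <= min_unit <= max_unit")
    if min_copies < 1 or (max_copies is not None and min_copies > max_copies):
        raise ValueError("require 1 <= min_copies <= max_copies")
    loci: list[MicrosatelliteLocus] = []
    for chrom in sorted(sequences):
        loci.extend(
            scan_sequence(chrom, sequences[chrom], min_unit, max_unit, min_copies, max_copies)
        )
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci
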