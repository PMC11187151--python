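"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a pipeline quantity with a deliberately different
algorithm (string slicing, nested loops, direct counting) so that agreement
with the library is informative. Nothing here imports the code paths it
checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

_ACGT = set("ACGT")


def _primitive(unit: str) -> bool:
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def _canonical(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def brute_force_tracts(
    seq: str,
    min_unit: int = 1,
    max_unit: int = 5,
    min_copies: int = 7,
    max_copies: int | None = 13,
) -> set[tuple[int, int, str]]:
    """All maximal whole-copy primitive repeat tracts as (start, end, unit).

    A tract anchors at the start of its maximal periodic region (extending
    left by even one character would preserve the period); its reported end
    excludes any trailing partial unit. Tracts above max_copies are omitted
    entirely. Non-ACGT characters break periodicity.
    """
    seq = seq.upper()
    n = len(seq)
    found: set[tuple[int, int, str]] = set()
    for k in range(min_unit, max_unit + 1):
        for i in range(n - k * min_copies + 1):
            unit = seq[i : i + k]
            if not _ACGT.issuperset(unit) or not _primitive(unit):
                continue
            # left-maximal: a single preceding character must break the period
            if i > 0 and seq[i - 1] == seq[i - 1 + k] and seq[i - 1] in _ACGT:
                continue
            # extend the periodic region char by char
            j = i + k
            while j < n and seq[j] in _ACGT and seq[j] == seq[j - k]:
                j += 1
            copies = (j - i) // k
            if copies < min_copies:
                continue
            if max_copies is not None and copies > max_copies:
                continue
            found.add((i, i + copies * k, _canonical(unit)))
    return found


def novel_fraction_call(
    tumor_hist: dict[int, int],
    normal_hist: dict[int, int],
    tau: float = 0.10,
    min_cov: int = 20,
    min_allele_frac: float = 0.05,
) -> tuple[float | None, bool, bool]:
    """(statistic, unstable, no_call) for the paired novel-fraction rule."""
    cov_t = sum(tumor_hist.values())
    cov_n = sum(normal_hist.values())
    if cov_t < min_cov or cov_n < min_cov:
        return None, False, True
    support = {
        l for l, c in normal_hist.items() if Fraction(c, cov_n) >= Fraction(min_allele_frac)
    }
    novel = sum(c for l, c in tumor_hist.items() if l not in support)
    stat = novel / cov_t
    return stat, stat >= tau, False


def best_panel(
    unstable_rows: list[list[bool]],
    is_dmmr: list[bool],
    candidate_ids: list[str],
    k_min: int = 2,
    k_max: int = 8,
    min_unstable: int = 2,
) -> tuple[tuple[str, ...], Fraction, Fraction]:
    """Exhaustive panel search oracle with exact rational scores.

    Returns (locus ids, specificity, sensitivity) of the best subset under
    the >=min_unstable rule, maximizing sensitivity subject to
    specificity == 1, ties to smaller size then lexicographic ids; if no
    subset reaches full specificity, the (specificity, sensitivity)
    lexicographic best.
    """
    order = sorted(range(len(candidate_ids)), key=lambda i: candidate_ids[i])
    n_d = sum(is_dmmr)
    n_p = len(is_dmmr) - n_d
    best = None
    for k in range(k_min, min(k_max, len(order)) + 1):
        for combo in itertools.combinations(order, k):
            tp = fp = 0
            for row, d in zip(unstable_rows, is_dmmr):
                pos = sum(row[i] for i in combo) >= min_unstable
                if pos and d:
                    tp += 1
                elif pos and not d:
                    fp += 1
            sens = Fraction(tp, n_d) if n_d else Fraction(0)
            spec = Fraction(n_p - fp, n_p) if n_p else Fraction(0)
            ids = tuple(candidate_ids[i] for i in combo)
            meets = spec == 1
            key = (meets, sens if meets else Fraction(-1), spec, sens, -k)
            if best is None or key > best[0] or (key == best[0] and ids < best[1]):
                best = (key, ids, spec, sens)
    assert best is not None
    return best[1], best[2], best[3]
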