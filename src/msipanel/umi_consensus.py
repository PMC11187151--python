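"""UMI family collapsing to consensus repeat lengths.

Reads sharing a (sample, locus, UMI) triple derive from one input molecule;
their strict-majority tract length is that molecule's consensus length.
Collapsing families cancels most PCR stutter, which is the error-suppression
role UMI tagging plays in amplicon MSI assays. Families with no strict
majority are dropped (and tallied), as are families below the minimum size.

The consensus rule is strict majority with tie-drop rather than plurality or
mean: it is auditable, conservative, and ties are rare once families reach
three reads. ``min_family_size`` defaults to 1 so non-UMI data degrade
gracefully; 3 is the recommended setting for real UMI libraries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PROFILE_COLUMNS = ["sample_id", "locus_id", "tract_len_units", "family_count"]
QC_COLUMNS = ["sample_id", "n_families_in", "n_tie_dropped", "n_small_dropped", "n_kept"]


@dataclass
class LengthProfile:
    """Histogram of UMI-consensus repeat lengths for one (sample, locus)."""

    sample_id: str
    locus_id: str
    hist: dict[int, int]
    n_families: int

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.hist):
            raise ValueError("tract lengths must be >= 1")
        if any(v < 0 for v in self.hist.values()):
            raise ValueError("counts must be non-negative")
        if self.n_families != sum(self.hist.values()):
            raise ValueError("n_families must equal the histogram total")

    @classmethod
    def from_hist(cls, sample_id: str, locus_id: str, hist: dict[int, int]) -> "LengthProfile":
        return cls(sample_id, locus_id, dict(hist), sum(hist.values()))


def collapse_to_profiles(
    observations: pd.DataFrame, min_family_size: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse UMI-tagged reads to per-(sample, locus) consensus profiles.

    Parameters
    ----------
    observations
        Long table with columns sample_id, locus_id, umi, tract_len_units.
        May span many samples.
    min_family_size
        Families with fewer reads are discarded before consensus.

    Returns
    -------
    profiles, qc
        ``profiles``: columns sample_id, locus_id, tract_len_units,
        family_count (one row per observed consensus length).
        ``qc``: per-sample tallies of dropped families.
    """
    required = {"sample_id", "locus_id", "umi", "tract_len_units"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    lens = observations["tract_len_units"].to_numpy()
    if lens.size and lens.min() < 1:
        raise ValueError("tract_len_units must be >= 1")
    if min_family_size < 1:
        raise ValueError("min_family_size must be >= 1")

    if not len(observations):
        return (
            pd.DataFrame(columns=PROFILE_COLUMNS),
            pd.DataFrame(columns=QC_COLUMNS),
        )

    s_codes, s_cats = pd.factorize(observations["sample_id"], use_na_sentinel=False)
    l_codes, l_cats = pd.factorize(observations["locus_id"], use_na_sentinel=False)
    u_codes, _ = pd.factorize(observations["umi"], use_na_sentinel=False)
    n_l, n_u = len(l_cats), int(u_codes.max()) + 1
    lens = lens.astype(np.int64)
    max_len = int(lens.max())

    fam_key = (s_codes.astype(np.int64) * n_l + l_codes) * n_u + u_codes
    pair_key = fam_key * (max_len + 1) + lens
    pairs, pair_counts = np.unique(pair_key, return_counts=True)
    fam_of_pair = pairs // (max_len + 1)
    len_of_pair = (pairs % (max_len + 1)).astype(np.int64)

    fam_starts = np.flatnonzero(
        np.concatenate(([True], fam_of_pair[1:] != fam_of_pair[:-1]))
    )
    fam_sizes = np.add.reduceat(pair_counts, fam_starts)
    fam_maxc = np.maximum.reduceat(pair_counts, fam_starts)
    fam_ids = fam_of_pair[fam_starts]
    big_enough = fam_sizes >= min_family_size
    # a strict majority (count > size/2) is necessarily unique
    strict = 2 * fam_maxc > fam_sizes
    keep_fam = big_enough & strict

    # map each pair back to its family's slot
    fam_slot = np.repeat(
        np.arange(fam_starts.size), np.diff(np.append(fam_starts, pairs.size))
    )
    sel = keep_fam[fam_slot] & (pair_counts == fam_maxc[fam_slot])
    cons_fam = fam_of_pair[sel]
    cons_len = len_of_pair[sel]

    sl_key = cons_fam // n_u  # (sample, locus) combined code
    out_key = sl_key * (max_len + 1) + cons_len
    uniq_out, out_counts = np.unique(out_key, return_counts=True)
    out_sl = uniq_out // (max_len + 1)
    profiles = pd.DataFrame(
        {
            "sample_id": np.asarray(s_cats)[(out_sl // n_l).astype(np.intp)],
            "locus_id": np.asarray(l_cats)[(out_sl % n_l).astype(np.intp)],
            "tract_len_units": (uniq_out % (max_len + 1)).astype(int),
            "family_count": out_counts.astype(int),
        }
    ).sort_values(["sample_id", "locus_id", "tract_len_units"], ignore_index=True)

    fam_sample = (fam_ids // n_u // n_l).astype(np.intp)
    n_s = len(s_cats)
    qc = pd.DataFrame(
        {
            "sample_id": np.asarray(s_cats),
            "n_families_in": np.bincount(fam_sample, minlength=n_s),
            "n_tie_dropped": np.bincount(fam_sample[big_enough & ~strict], minlength=n_s),
            "n_small_dropped": np.bincount(fam_sample[~big_enough], minlength=n_s),
            "n_kept": np.bincount(fam_sample[keep_fam], minlength=n_s),
        }
    )
    return profiles, qc


def profiles_index(profiles: pd.DataFrame) -> dict[tuple[str, str], LengthProfile]:
    """Index a long profile table into LengthProfile objects keyed by (sample, locus)."""
    out: dict[tuple[str, str], LengthProfile] = {}
    sid = profiles["sample_id"].to_numpy()
    lid = profiles["locus_id"].to_numpy()
    ln = profiles["tract_len_units"].to_numpy()
    ct = profiles["family_count"].to_numpy()
    for i in range(len(profiles)):
        key = (sid[i], lid[i])
        prof = out.get(key)
        if prof is None:
            out[key] = LengthProfile(key[0], key[1], {int(ln[i]): int(ct[i])}, int(ct[i]))
        else:
            prof.hist[int(ln[i])] = prof.hist.get(int(ln[i]), 0) + int(ct[i])
            prof.n_families += int(ct[i])
    return out
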