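"""Synthetic UMI-Seq cohort generator.

Emulates the data layout of an amplicon MSI study: matched tumor/normal
FFPE pairs plus unmatched validation tumors, profiled at a catalog of
microsatellite loci with UMI-tagged reads. Deficient-MMR (dMMR) tumors
carry somatic repeat-length shifts at a planted subset of informative
mononucleotide loci; proficient-MMR (pMMR) tumors are largely stable;
every read is subject to PCR stutter (±1 repeat unit) that downstream
UMI-consensus collapsing is meant to suppress.

The generator is deterministic in the master seed. Randomness for each
(sample, locus) cell comes from an independent substream derived by
hashing the identifiers, so adding samples or loci to a configuration
never perturbs the reads of existing ones.

The generator works at repeat-tract-length resolution: it emits, per read,
the number of repeat units observed, not base-level sequence. That is the
quantity MSI callers consume; base-calling error and alignment are out of
scope.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .locus_scan import MicrosatelliteLocus, default_locus_id

_UMI_POOL_BITS = 12  # supports up to 4096 families per (sample, locus)
_UMI_POOL = [f"U{i:04d}" for i in range(1 << _UMI_POOL_BITS)]

READ_COLUMNS = ["sample_id", "locus_id", "umi", "tract_len_units"]
SAMPLE_COLUMNS = ["sample_id", "patient_id", "tissue", "mmr_status", "cohort"]


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults mirror a paired-design MSI panel study: ~100 matched
    tumor/normal pairs for training, a smaller unmatched tumor set for
    validation, a few hundred candidate loci of which a small
    mononucleotide subset is truly informative for dMMR.
    """

    seed: int = 0
    n_paired_patients: int = 93
    n_unmatched_tumors: int = 32
    frac_dmmr: float = 0.5
    n_loci: int = 200
    n_informative: int = 8
    p_unstable_dmmr: float = 0.85
    p_unstable_pmmr: float = 0.02
    p_decoy_unstable: float = 0.01
    stutter_eps: float = 0.08
    purity: float = 0.6
    shift_set: tuple[int, ...] = (-3, -2, -1, 1, 2)
    families_per_locus: float = 60.0
    reads_per_family_mean: float = 4.0
    polymorphic_frac: float = 0.05

    def validate(self) -> None:
        for name in (
            "frac_dmmr",
            "p_unstable_dmmr",
            "p_unstable_pmmr",
            "p_decoy_unstable",
            "stutter_eps",
            "purity",
            "polymorphic_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_informative > self.n_loci:
            raise ValueError("n_informative must not exceed n_loci")
        if self.families_per_locus <= 0 or self.reads_per_family_mean <= 0:
            raise ValueError("family/read means must be positive")
        if any(s == 0 for s in self.shift_set) or not self.shift_set:
            raise ValueError("shift_set must be non-empty and exclude 0")
        if min(self.n_paired_patients, self.n_unmatched_tumors, self.n_loci) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    informative_locus_ids: set[str]
    polymorphic_locus_ids: set[str]
    # (sample_id, locus_id) -> somatic shift in repeat units (never 0)
    somatic_shifts: dict[tuple[str, str], int]
    # (patient_id, locus_id) -> germline tract length; only loci whose
    # germline differs from the catalog's copies field are listed
    germline_overrides: dict[tuple[str, str], int]

    def germline_length(self, patient_id: str, locus_id: str, default: int) -> int:
        return self.germline_overrides.get((patient_id, locus_id), default)

    def unstable_loci(self, sample_id: str) -> set[str]:
        return {l for (s, l) in self.somatic_shifts if s == sample_id}


class CohortData(NamedTuple):
    samples: pd.DataFrame
    loci: list[MicrosatelliteLocus]
    reads: pd.DataFrame
    truth: CohortTruth


def _substream(seed: int, *keys) -> np.random.Generator:
    """Independent RNG substream keyed by hashed string identifiers."""
    token = "\x1f".join(str(k) for k in keys).encode()
    h = hashlib.sha256(token).digest()
    ent = int.from_bytes(h[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, ent]))


def _zero_truncated_poisson(mean: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Poisson(mean) conditioned on >=1, by redrawing zeros."""
    out = rng.poisson(mean, size=n)
    while True:
        zeros = out == 0
        if not zeros.any():
            return out
        out[zeros] = rng.poisson(mean, size=int(zeros.sum()))


def _family_read_lengths(
    germline_len: int,
    somatic_shift: int,
    purity: float,
    stutter_eps: float,
    n_families: int,
    reads_per_family_mean: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized core: returns (family index per read, tract length per read).

    Each UMI family corresponds to one input molecule. When a somatic shift
    is present, a family derives from the tumor clone with probability
    ``purity`` and then carries the shifted length; otherwise it is germline.
    Each read of a family reports the molecule length, slipped by ±1 unit
    (equal split) with probability ``stutter_eps``.
    """
    if n_families == 0:
        return np.empty(0, dtype=np.int32), np.empty(0, dtype=np.int16)
    true_len = np.full(n_families, germline_len, dtype=np.int16)
    if somatic_shift != 0:
        tumor_derived = rng.random(n_families) < purity
        true_len[tumor_derived] += somatic_shift
    sizes = _zero_truncated_poisson(reads_per_family_mean, n_families, rng)
    fam_idx = np.repeat(np.arange(n_families, dtype=np.int32), sizes)
    lens = true_len[fam_idx].astype(np.int16)
    if stutter_eps > 0:
        u = rng.random(lens.size)
        lens = lens + (u < stutter_eps / 2).astype(np.int16)
        lens = lens - ((u >= stutter_eps / 2) & (u < stutter_eps)).astype(np.int16)
    return fam_idx, np.maximum(lens, 1).astype(np.int16)


def simulate_locus_reads(
    germline_len: int,
    somatic_shift: int,
    purity: float,
    stutter_eps: float,
    n_families: int,
    reads_per_family_mean: float,
    rng: np.random.Generator,
    sample_id: str = "S",
    locus_id: str = "L",
) -> pd.DataFrame:
    """Simulate UMI-tagged reads for one sample at one locus.

    Returns a DataFrame with columns sample_id, locus_id, umi,
    tract_len_units (one row per read).
    """
    if germline_len < 2:
        raise ValueError("germline_len must be >= 2")
    if somatic_shift != 0 and germline_len + somatic_shift < 1:
        raise ValueError("shifted length must stay >= 1")
    if not (0 <= purity <= 1 and 0 <= stutter_eps <= 1):
        raise ValueError("purity and stutter_eps must lie in [0, 1]")
    if n_families < 0 or reads_per_family_mean <= 0:
        raise ValueError("n_families >= 0 and reads_per_family_mean > 0 required")
    fam_idx, lens = _family_read_lengths(
        germline_len, somatic_shift, purity, stutter_eps, n_families, reads_per_family_mean, rng
    )
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "locus_id": locus_id,
            "umi": np.asarray(_UMI_POOL, dtype=object)[fam_idx],
            "tract_len_units": lens,
        }
    )


_DECOY_UNITS = ("A", "T", "C", "AT", "AG")
_DECOY_WEIGHTS = (0.45, 0.2, 0.15, 0.1, 0.1)


def make_catalog(config: SimulationConfig) -> list[MicrosatelliteLocus]:
    """Deterministic synthetic locus catalog.

    Loci are laid out on four synthetic chromosomes with non-overlapping
    coordinates; unit composition is mononucleotide-dominated, matching the
    repeat class MSI panels target. Copy numbers span the 7–13 discovery
    window and serve as the default germline tract length.
    """
    rng = _substream(config.seed, "catalog")
    loci: list[MicrosatelliteLocus] = []
    pos = [1000] * 4
    unit_idx = rng.choice(len(_DECOY_UNITS), size=config.n_loci, p=_DECOY_WEIGHTS)
    copies_all = rng.integers(7, 14, size=config.n_loci)
    for i in range(config.n_loci):
        unit = _DECOY_UNITS[unit_idx[i]]
        copies = int(copies_all[i])
        c = i % 4
        chrom = f"chr{c + 1}"
        start = pos[c]
        end = start + len(unit) * copies
        pos[c] = end + 997  # spacer
        loci.append(
            MicrosatelliteLocus(
                locus_id=default_locus_id(chrom, start, end, unit),
                chrom=chrom,
                start=start,
                end=end,
                unit=unit,
                unit_len=len(unit),
                copies=copies,
                gene_label=f"G{i:04d}",
            )
        )
    return loci


def _pick_informative(
    config: SimulationConfig, loci: Sequence[MicrosatelliteLocus]
) -> list[str]:
    mono = [l.locus_id for l in loci if l.unit_len == 1]
    if len(mono) < config.n_informative:
        raise ValueError("not enough mononucleotide loci for n_informative")
    rng = _substream(config.seed, "informative")
    pick = rng.choice(len(mono), size=config.n_informative, replace=False)
    return sorted(mono[i] for i in np.sort(pick))


def _pick_polymorphic(
    config: SimulationConfig, loci: Sequence[MicrosatelliteLocus], informative: set[str]
) -> list[str]:
    # Polymorphic (germline-variable) loci are drawn from the decoys only:
    # panel candidates are pre-screened against known polymorphisms in
    # practice, and the polymorphism filter exists to remove exactly these.
    decoys = sorted(l.locus_id for l in loci if l.locus_id not in informative)
    n_poly = int(round(config.polymorphic_frac * config.n_loci))
    n_poly = min(n_poly, len(decoys))
    if n_poly == 0:
        return []
    rng = _substream(config.seed, "polymorphic")
    pick = rng.choice(len(decoys), size=n_poly, replace=False)
    return sorted(decoys[i] for i in np.sort(pick))


def _make_samples(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    n_paired_dmmr = int(round(config.frac_dmmr * config.n_paired_patients))
    rng = _substream(config.seed, "labels")
    paired_status = np.array(
        ["dMMR"] * n_paired_dmmr + ["pMMR"] * (config.n_paired_patients - n_paired_dmmr)
    )
    rng.shuffle(paired_status)
    for i in range(config.n_paired_patients):
        pid = f"P{i + 1:04d}"
        status = paired_status[i]
        rows.append((f"{pid}T", pid, "tumor", status, "train"))
        rows.append((f"{pid}N", pid, "normal", status, "train"))
    n_unm_dmmr = int(round(config.frac_dmmr * config.n_unmatched_tumors))
    unm_status = np.array(
        ["dMMR"] * n_unm_dmmr + ["pMMR"] * (config.n_unmatched_tumors - n_unm_dmmr)
    )
    rng.shuffle(unm_status)
    for i in range(config.n_unmatched_tumors):
        pid = f"Q{i + 1:04d}"
        rows.append((f"{pid}T", pid, "tumor", unm_status[i], "validation"))
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def simulate_cohort(
    config: SimulationConfig,
    loci: Sequence[MicrosatelliteLocus] | None = None,
    informative_ids: Sequence[str] | None = None,
    polymorphic_ids: Sequence[str] | None = None,
) -> CohortData:
    """Simulate a full cohort: sample sheet, locus catalog, reads, truth.

    ``loci`` / ``informative_ids`` / ``polymorphic_ids`` may be supplied to
    profile a new cohort (e.g. an unmatched validation set) at the same
    panel as a previous one; by default they are drawn from the seed.
    """
    config.validate()
    if loci is None:
        loci = make_catalog(config)
    loci = list(loci)
    informative = (
        set(informative_ids) if informative_ids is not None else set(_pick_informative(config, loci))
    )
    if polymorphic_ids is None:
        polymorphic_ids = _pick_polymorphic(config, loci, informative)
    polymorphic = set(polymorphic_ids)

    samples = _make_samples(config)
    truth = CohortTruth(
        informative_locus_ids=set(informative),
        polymorphic_locus_ids=set(polymorphic),
        somatic_shifts={},
        germline_overrides={},
    )

    shift_set = np.asarray(config.shift_set, dtype=np.int64)
    locus_ids = [l.locus_id for l in loci]
    sample_ids = samples["sample_id"].tolist()
    s_codes_parts: list[np.ndarray] = []
    l_codes_parts: list[np.ndarray] = []
    u_codes_parts: list[np.ndarray] = []
    len_parts: list[np.ndarray] = []

    # germline lengths per (patient, locus) for polymorphic loci
    copies_by_locus = {l.locus_id: l.copies for l in loci}
    patients = samples["patient_id"].unique()
    for lid in sorted(polymorphic):
        base = copies_by_locus[lid]
        for pid in patients:
            g = _substream(config.seed, "germline", pid, lid)
            delta = int(g.integers(-2, 3))
            if delta != 0:
                truth.germline_overrides[(pid, lid)] = base + delta

    sample_code = {sid: i for i, sid in enumerate(sample_ids)}
    for srow in samples.itertuples(index=False):
        is_tumor = srow.tissue == "tumor"
        if is_tumor:
            p_info = config.p_unstable_dmmr if srow.mmr_status == "dMMR" else config.p_unstable_pmmr
        for li, locus in enumerate(loci):
            lid = locus.locus_id
            rng = _substream(config.seed, "reads", srow.sample_id, lid)
            germline = truth.germline_length(srow.patient_id, lid, locus.copies)
            shift = 0
            if is_tumor:
                p = p_info if lid in informative else config.p_decoy_unstable
                if rng.random() < p:
                    ok = shift_set[germline + shift_set >= 1]
                    shift = int(ok[rng.integers(len(ok))])
                    truth.somatic_shifts[(srow.sample_id, lid)] = shift
            n_fam = int(rng.poisson(config.families_per_locus))
            n_fam = min(n_fam, len(_UMI_POOL))
            fam_idx, lens = _family_read_lengths(
                germline,
                shift,
                config.purity,
                config.stutter_eps,
                n_fam,
                config.reads_per_family_mean,
                rng,
            )
            if lens.size == 0:
                continue
            s_codes_parts.append(np.full(lens.size, sample_code[srow.sample_id], dtype=np.int32))
            l_codes_parts.append(np.full(lens.size, li, dtype=np.int32))
            u_codes_parts.append(fam_idx)
            len_parts.append(lens)

    if len_parts:
        reads = pd.DataFrame(
            {
                "sample_id": pd.Categorical.from_codes(
                    np.concatenate(s_codes_parts), categories=sample_ids
                ),
                "locus_id": pd.Categorical.from_codes(
                    np.concatenate(l_codes_parts), categories=locus_ids
                ),
                "umi": pd.Categorical.from_codes(
                    np.concatenate(u_codes_parts), categories=_UMI_POOL
                ),
                "tract_len_units": np.concatenate(len_parts),
            }
        )
    else:
        reads = pd.DataFrame(
            {
                "sample_id": pd.Categorical([], categories=sample_ids),
                "locus_id": pd.Categorical([], categories=locus_ids),
                "umi": pd.Categorical([], categories=_UMI_POOL),
                "tract_len_units": np.array([], dtype=np.int16),
            }
        )
    return CohortData(samples=samples, loci=loci, reads=reads, truth=truth)
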