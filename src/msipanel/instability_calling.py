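"""Per-locus instability calling from consensus length profiles.

The statistic is the *novel-length family fraction*: the fraction of a
tumor's consensus families whose tract length is absent from the reference
support (the matched normal's allele lengths, or the pooled support of a
panel of normals for unmatched tumors). A locus is unstable when that
fraction reaches ``tau`` at adequate family coverage; in baseline mode the
fraction must additionally exceed the normals' own novel-fraction
distribution by ``z_min`` standard deviations.

A novel-fraction statistic (rather than a distribution test such as KS or
chi-square) matches the working definition of microsatellite instability —
new allele lengths appearing in the tumor — and remains well behaved at the
low family counts FFPE material yields.

No-call loci (insufficient coverage, or no baseline) are never unstable;
downstream classification treats them as stable, which is conservative
toward specificity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .umi_consensus import LengthProfile, profiles_index

CALL_COLUMNS = [
    "sample_id",
    "locus_id",
    "statistic",
    "unstable",
    "no_call",
    "coverage_tumor",
    "coverage_ref",
    "mode",
]

DEFAULT_TAU = 0.10
DEFAULT_MIN_COV = 20
DEFAULT_MIN_ALLELE_FRAC = 0.05
DEFAULT_Z_MIN = 3.0
DEFAULT_SD_FLOOR = 0.01


@dataclass
class InstabilityCall:
    sample_id: str
    locus_id: str
    statistic: float  # NaN when no_call
    unstable: bool
    no_call: bool
    coverage_tumor: int
    coverage_ref: int
    mode: str  # "paired" | "baseline"


@dataclass
class NormalBaseline:
    """Pooled panel-of-normals reference for one locus."""

    locus_id: str
    pooled_support: set[int]
    n_normals: int
    mean_novel_frac: float
    sd_novel_frac: float
    pooled_families: int = 0

    def __post_init__(self) -> None:
        if not self.pooled_support:
            raise ValueError("pooled_support must be non-empty")
        if self.n_normals < 1 or self.sd_novel_frac < 0:
            raise ValueError("invalid baseline statistics")


def normal_support(profile: LengthProfile, min_allele_frac: float = DEFAULT_MIN_ALLELE_FRAC) -> set[int]:
    """Allele lengths carried by a normal at >= min_allele_frac of families."""
    if profile.n_families < 1:
        raise ValueError("normal profile has no families")
    cut = min_allele_frac * profile.n_families
    return {l for l, c in profile.hist.items() if c >= cut}


def _novel_fraction(hist: Mapping[int, int], support: set[int]) -> float:
    total = sum(hist.values())
    novel = sum(c for l, c in hist.items() if l not in support)
    return novel / total


def call_paired(
    tumor_profile: LengthProfile,
    normal_profile: LengthProfile,
    tau: float = DEFAULT_TAU,
    min_cov: int = DEFAULT_MIN_COV,
    min_allele_frac: float = DEFAULT_MIN_ALLELE_FRAC,
) -> InstabilityCall:
    """Call instability for a tumor locus against its matched normal."""
    if tumor_profile.locus_id != normal_profile.locus_id:
        raise ValueError("tumor and normal profiles refer to different loci")
    cov_t, cov_n = tumor_profile.n_families, normal_profile.n_families
    if cov_t < min_cov or cov_n < min_cov:
        return InstabilityCall(
            tumor_profile.sample_id, tumor_profile.locus_id, float("nan"),
            False, True, cov_t, cov_n, "paired",
        )
    stat = _novel_fraction(tumor_profile.hist, normal_support(normal_profile, min_allele_frac))
    return InstabilityCall(
        tumor_profile.sample_id, tumor_profile.locus_id, stat,
        stat >= tau, False, cov_t, cov_n, "paired",
    )


def build_baseline(
    normal_profiles: Sequence[LengthProfile],
    min_allele_frac: float = DEFAULT_MIN_ALLELE_FRAC,
) -> NormalBaseline:
    """Pool normals at one locus into a baseline.

    The pooled support is the union of each normal's support. Each normal is
    then scored against that pooled support *including its own contribution*
    (leave-one-in), giving the null distribution (mean, sd) of the
    novel-length fraction among normals.
    """
    if not normal_profiles:
        raise ValueError("need at least one normal profile")
    lid = normal_profiles[0].locus_id
    if any(p.locus_id != lid for p in normal_profiles):
        raise ValueError("profiles mix loci")
    pooled: set[int] = set()
    for p in normal_profiles:
        pooled |= normal_support(p, min_allele_frac)
    fracs = np.array([_novel_fraction(p.hist, pooled) for p in normal_profiles])
    return NormalBaseline(
        locus_id=lid,
        pooled_support=pooled,
        n_normals=len(normal_profiles),
        mean_novel_frac=float(fracs.mean()),
        sd_novel_frac=float(fracs.std(ddof=0)),
        pooled_families=int(sum(p.n_families for p in normal_profiles)),
    )


def call_unpaired(
    tumor_profile: LengthProfile,
    baseline: NormalBaseline | None,
    z_min: float = DEFAULT_Z_MIN,
    tau: float = DEFAULT_TAU,
    min_cov: int = DEFAULT_MIN_COV,
    sd_floor: float = DEFAULT_SD_FLOOR,
) -> InstabilityCall:
    """Call instability for an unmatched tumor against a panel-of-normals baseline."""
    cov_t = tumor_profile.n_families
    if baseline is None or cov_t < min_cov:
        return InstabilityCall(
            tumor_profile.sample_id, tumor_profile.locus_id, float("nan"),
            False, True, cov_t, 0 if baseline is None else baseline.pooled_families,
            "baseline",
        )
    stat = _novel_fraction(tumor_profile.hist, baseline.pooled_support)
    z_ok = (stat - baseline.mean_novel_frac) >= z_min * max(baseline.sd_novel_frac, sd_floor)
    return InstabilityCall(
        tumor_profile.sample_id, tumor_profile.locus_id, stat,
        stat >= tau and z_ok, False, cov_t, baseline.pooled_families, "baseline",
    )


def _empty_profile(sample_id: str, locus_id: str) -> LengthProfile:
    return LengthProfile(sample_id, locus_id, {}, 0)


def calls_to_frame(calls: Iterable[InstabilityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.sample_id, c.locus_id, c.statistic, c.unstable, c.no_call,
             c.coverage_tumor, c.coverage_ref, c.mode)
            for c in calls
        ],
        columns=CALL_COLUMNS,
    )


def call_cohort_paired(
    profiles: pd.DataFrame,
    samples: pd.DataFrame,
    locus_ids: Sequence[str],
    tau: float = DEFAULT_TAU,
    min_cov: int = DEFAULT_MIN_COV,
    min_allele_frac: float = DEFAULT_MIN_ALLELE_FRAC,
) -> pd.DataFrame:
    """Paired tumor-vs-normal calls for every (paired tumor, catalog locus).

    Emits an explicit row for every locus in ``locus_ids`` (no-call when a
    profile is missing), so downstream classification never sees gaps.
    """
    idx = profiles_index(profiles)
    calls: list[InstabilityCall] = []
    by_patient = samples.groupby("patient_id", sort=True)
    for pid, grp in by_patient:
        tumors = grp[grp["tissue"] == "tumor"]["sample_id"].tolist()
        normals = grp[grp["tissue"] == "normal"]["sample_id"].tolist()
        if not tumors or not normals:
            continue
        tid, nid = tumors[0], normals[0]
        for lid in locus_ids:
            tp = idx.get((tid, lid)) or _empty_profile(tid, lid)
            npf = idx.get((nid, lid)) or _empty_profile(nid, lid)
            calls.append(call_paired(tp, npf, tau, min_cov, min_allele_frac))
    return calls_to_frame(calls)


def build_cohort_baselines(
    profiles: pd.DataFrame,
    samples: pd.DataFrame,
    locus_ids: Sequence[str],
    min_allele_frac: float = DEFAULT_MIN_ALLELE_FRAC,
) -> dict[str, NormalBaseline]:
    """Per-locus baselines from all normal samples present in the cohort.

    Loci with no normal profile are omitted (tumors there become no-calls).
    """
    idx = profiles_index(profiles)
    normal_ids = samples.loc[samples["tissue"] == "normal", "sample_id"].tolist()
    baselines: dict[str, NormalBaseline] = {}
    for lid in locus_ids:
        profs = [idx[(nid, lid)] for nid in normal_ids if (nid, lid) in idx]
        profs = [p for p in profs if p.n_families >= 1]
        if profs:
            baselines[lid] = build_baseline(profs, min_allele_frac)
    return baselines


def call_cohort_baseline(
    profiles: pd.DataFrame,
    samples: pd.DataFrame,
    baselines: Mapping[str, NormalBaseline],
    locus_ids: Sequence[str],
    z_min: float = DEFAULT_Z_MIN,
    tau: float = DEFAULT_TAU,
    min_cov: int = DEFAULT_MIN_COV,
    sd_floor: float = DEFAULT_SD_FLOOR,
) -> pd.DataFrame:
    """Baseline-mode calls for every tumor sample in ``samples``."""
    idx = profiles_index(profiles)
    tumor_ids = samples.loc[samples["tissue"] == "tumor", "sample_id"].tolist()
    calls = []
    for tid in tumor_ids:
        for lid in locus_ids:
            tp = idx.get((tid, lid)) or _empty_profile(tid, lid)
            calls.append(call_unpaired(tp, baselines.get(lid), z_min, tau, min_cov, sd_floor))
    return calls_to_frame(calls)
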