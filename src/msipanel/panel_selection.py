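"""Candidate-locus selection cascade and panel optimization.

Stages, mirroring a staged MSI panel design:

1. ``polymorphism_filter`` — drop loci whose modal consensus length varies
   across normal samples (germline microsatellite polymorphism masquerades
   as instability in unmatched tumors).
2. ``dmmr_enrichment_filter`` — keep loci frequently unstable in dMMR
   training tumors and rarely unstable in pMMR tumors.
3. ``cluster_loci`` — hierarchical (Ward) clustering of per-locus
   instability-frequency profiles cut at six groups, refined by K-means
   initialized at the hierarchical centroids.
4. ``select_differential_cluster`` — retain the cluster(s) with pronounced
   dMMR-vs-pMMR differential instability.
5. ``optimize_panel`` — exhaustive search over candidate subsets scored by
   the ">= min_unstable loci unstable => MSI-H" rule, maximizing training
   sensitivity subject to 100% training specificity.

Clustering features are per-locus instability frequencies in the dMMR
group, the pMMR group, and overall, standardized — frequency features make
cluster structure independent of sample ordering and cohort size, unlike
raw per-sample binary vectors (available via ``features="binary"``).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

DEFAULT_N_CLUSTERS = 6
DEFAULT_GAP_TOL = 0.05
DEFAULT_MIN_GAP = 0.25
DEFAULT_SUBSET_BUDGET = 10**6


@dataclass
class CallMatrix:
    """Tumor-samples x loci instability calls with a no-call mask."""

    unstable: pd.DataFrame  # bool, rows = tumor sample ids
    no_call: pd.DataFrame  # bool, same shape
    labels: pd.Series  # dMMR / pMMR per sample
    cohort: pd.Series  # train / validation per sample

    def __post_init__(self) -> None:
        if self.unstable.shape != self.no_call.shape:
            raise ValueError("unstable and no_call must share a shape")
        if not self.unstable.index.equals(self.no_call.index):
            raise ValueError("row indices differ")

    @classmethod
    def from_calls(cls, calls: pd.DataFrame, samples: pd.DataFrame) -> "CallMatrix":
        """Pivot a long calls table; rows are tumor samples only."""
        meta = samples.set_index("sample_id")
        tumor_ids = [s for s in calls["sample_id"].unique() if meta.loc[s, "tissue"] == "tumor"]
        sub = calls[calls["sample_id"].isin(tumor_ids)]
        unstable = (
            sub.pivot(index="sample_id", columns="locus_id", values="unstable")
            .fillna(False)
            .astype(bool)
        )
        no_call = (
            sub.pivot(index="sample_id", columns="locus_id", values="no_call")
            .fillna(True)
            .astype(bool)
        )
        no_call = no_call.reindex(index=unstable.index, columns=unstable.columns)
        return cls(
            unstable=unstable,
            no_call=no_call,
            labels=meta.loc[unstable.index, "mmr_status"],
            cohort=meta.loc[unstable.index, "cohort"],
        )

    def train(self) -> "CallMatrix":
        keep = self.cohort == "train"
        return CallMatrix(
            self.unstable.loc[keep], self.no_call.loc[keep],
            self.labels.loc[keep], self.cohort.loc[keep],
        )

    def evaluable(self) -> pd.DataFrame:
        return ~self.no_call


@dataclass
class LocusMetrics:
    locus_id: str
    sensitivity: float  # fraction, NaN when undefined
    specificity: float
    n_dmmr: int  # evaluable dMMR tumors
    n_pmmr: int


@dataclass
class PanelModel:
    """An ordered locus subset plus the MSI-H threshold and training diagnostics."""

    locus_ids: list[str]
    min_unstable: int = 2
    train_sensitivity: float = float("nan")
    train_specificity: float = float("nan")
    constraint_met: bool = True
    selection_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.min_unstable > len(self.locus_ids):
            raise ValueError("min_unstable exceeds panel size")


def instability_frequencies(cm: CallMatrix, loci: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-locus instability frequency in dMMR, pMMR and overall (no-calls excluded)."""
    loci = list(loci) if loci is not None else list(cm.unstable.columns)
    U = cm.unstable[loci]
    E = ~cm.no_call[loci]
    is_d = (cm.labels == "dMMR").to_numpy()
    out = {}
    for name, mask in (("dMMR", is_d), ("pMMR", ~is_d), ("overall", np.ones(len(U), bool))):
        num = (U.to_numpy() & E.to_numpy())[mask].sum(0)
        den = E.to_numpy()[mask].sum(0)
        with np.errstate(invalid="ignore"):
            out[f"freq_{name}"] = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return pd.DataFrame(out, index=pd.Index(loci, name="locus_id"))


def polymorphism_filter(
    profiles: pd.DataFrame,
    samples: pd.DataFrame,
    locus_ids: Sequence[str],
    max_polymorphic_frac: float = 0.05,
) -> list[str]:
    """Drop loci whose modal consensus length varies across normal samples.

    A locus is germline-polymorphic (and useless for baseline-mode calling)
    when more than ``max_polymorphic_frac`` of normals disagree with the
    majority modal length. Loci never observed in a normal are retained.
    With no normal samples at all the filter is skipped with a warning.
    """
    normals = set(samples.loc[samples["tissue"] == "normal", "sample_id"])
    if not normals:
        warnings.warn("no normal samples; polymorphism filter skipped")
        return list(locus_ids)
    sub = profiles[profiles["sample_id"].isin(normals)]
    # modal length per (normal, locus); ties broken toward the smaller length
    sub = sub.sort_values(["sample_id", "locus_id", "family_count", "tract_len_units"],
                          ascending=[True, True, False, True])
    modal = sub.drop_duplicates(["sample_id", "locus_id"])
    retained = []
    grouped = modal.groupby("locus_id")["tract_len_units"]
    counts = {lid: g.value_counts() for lid, g in grouped}
    for lid in locus_ids:
        vc = counts.get(lid)
        if vc is None or len(vc) == 0:
            retained.append(lid)
            continue
        frac_differing = 1.0 - vc.iloc[0] / vc.sum()
        if frac_differing <= max_polymorphic_frac:
            retained.append(lid)
    return retained


def dmmr_enrichment_filter(
    cm: CallMatrix,
    min_dmmr_freq: float = 0.30,
    max_pmmr_freq: float = 0.05,
    locus_ids: Sequence[str] | None = None,
) -> list[str]:
    """Keep loci unstable in >= min_dmmr_freq of dMMR and <= max_pmmr_freq of pMMR tumors."""
    labels = set(cm.labels.unique())
    if not {"dMMR", "pMMR"} <= labels:
        raise ValueError("both dMMR and pMMR tumors are required")
    freq = instability_frequencies(cm, locus_ids)
    ok = (freq["freq_dMMR"] >= min_dmmr_freq) & (freq["freq_pMMR"] <= max_pmmr_freq)
    return list(freq.index[ok.fillna(False)])


def cluster_loci(
    features: pd.DataFrame,
    n_clusters: int = DEFAULT_N_CLUSTERS,
    seed: int = 0,
) -> pd.Series:
    """Hierarchical (Ward) cut at ``n_clusters``, refined by K-means.

    K-means is initialized at the centroids of the hierarchical clusters, so
    the refinement is deterministic given the seed. Returns integer labels
    indexed by locus_id.
    """
    if len(features) < n_clusters:
        raise ValueError("fewer loci than clusters")
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("features contain NaN")
    # standardize, guarding constant features
    sd = X.std(0)
    X = (X - X.mean(0)) / np.where(sd > 0, sd, 1.0)
    Z = linkage(X, method="ward")
    hier = fcluster(Z, t=n_clusters, criterion="maxclust")
    centroids = np.vstack([X[hier == c].mean(0) for c in np.unique(hier)])
    centroids = np.unique(centroids, axis=0)
    k = centroids.shape[0]
    if k == 1:
        lab = np.zeros(len(X), dtype=int)
    else:
        km = KMeans(n_clusters=k, init=centroids, n_init=1, random_state=seed)
        lab = km.fit_predict(X)
    return pd.Series(lab, index=features.index, name="cluster")


def select_differential_cluster(
    assignments: pd.Series,
    cm: CallMatrix,
    tol: float = DEFAULT_GAP_TOL,
    min_gap: float = DEFAULT_MIN_GAP,
) -> list[str]:
    """Loci of clusters with pronounced dMMR-vs-pMMR differential instability.

    The gap of a cluster is the mean over its loci of
    freq(dMMR) - freq(pMMR). Retained clusters are those within ``tol`` of
    the maximal gap, plus any cluster whose gap reaches the absolute floor
    ``min_gap`` — a cluster uniformly above the enrichment-filter margin is
    differential in its own right even when another cluster happens to sit
    higher by sampling noise.
    """
    if len(assignments) == 0:
        raise ValueError("no cluster assignments")
    freq = instability_frequencies(cm, list(assignments.index))
    gap = (freq["freq_dMMR"] - freq["freq_pMMR"]).groupby(assignments).mean()
    best = gap.max()
    keep_clusters = gap.index[(gap >= best - tol) | (gap >= min_gap)]
    return sorted(assignments.index[assignments.isin(keep_clusters)])


def per_locus_metrics(cm: CallMatrix, locus_ids: Sequence[str]) -> list[LocusMetrics]:
    """Per-locus diagnostic sensitivity/specificity vs the dMMR label."""
    labels = set(cm.labels.unique())
    if not {"dMMR", "pMMR"} <= labels:
        raise ValueError("both dMMR and pMMR tumors are required")
    is_d = (cm.labels == "dMMR").to_numpy()
    out = []
    for lid in locus_ids:
        u = cm.unstable[lid].to_numpy()
        e = ~cm.no_call[lid].to_numpy()
        n_d = int((e & is_d).sum())
        n_p = int((e & ~is_d).sum())
        sens = (u & e & is_d).sum() / n_d if n_d else float("nan")
        spec = (~u & e & ~is_d).sum() / n_p if n_p else float("nan")
        out.append(LocusMetrics(lid, float(sens), float(spec), n_d, n_p))
    return out


def _score_subset(
    U: np.ndarray, is_d: np.ndarray, cols: Sequence[int], min_unstable: int
) -> tuple[float, float]:
    """(specificity, sensitivity) of the >=min_unstable rule on bool matrix U."""
    counts = U[:, cols].sum(axis=1)
    pred = counts >= min_unstable
    sens = pred[is_d].mean() if is_d.any() else float("nan")
    spec = (~pred[~is_d]).mean() if (~is_d).any() else float("nan")
    return float(spec), float(sens)


def optimize_panel(
    cm: CallMatrix,
    candidates: Sequence[str],
    k_min: int = 2,
    k_max: int = 8,
    min_unstable: int = 2,
    require_full_specificity: bool = True,
    subset_budget: int = DEFAULT_SUBSET_BUDGET,
    method: str = "exhaustive",
) -> PanelModel:
    """Search candidate subsets for the best MSI-H panel on training tumors.

    Exhaustively enumerates subsets of size ``k_min``..``k_max`` and scores
    each with the ">= min_unstable unstable loci => MSI-H" rule (no-calls
    count as stable). Returns the subset maximizing sensitivity subject to
    100% specificity; ties break toward smaller panels, then lexicographic
    locus order. If no subset achieves full specificity the
    (specificity, sensitivity)-lexicographic best is returned with
    ``constraint_met=False``. ``method="greedy"`` grows the panel by forward
    selection instead (for large candidate sets).
    """
    cand = sorted(candidates)
    if len(cand) < k_min:
        raise ValueError("fewer candidates than k_min")
    labels = set(cm.labels.unique())
    if not {"dMMR", "pMMR"} <= labels:
        raise ValueError("both dMMR and pMMR tumors are required")
    U = (cm.unstable[cand].to_numpy() & ~cm.no_call[cand].to_numpy())
    is_d = (cm.labels == "dMMR").to_numpy()
    k_max = min(k_max, len(cand))

    if method == "greedy":
        subsets = _greedy_subsets(U, is_d, len(cand), k_min, k_max, min_unstable)
    elif method == "exhaustive":
        n_subsets = sum(math.comb(len(cand), k) for k in range(k_min, k_max + 1))
        if n_subsets > subset_budget:
            raise ValueError(
                f"{n_subsets} subsets exceed the enumeration budget {subset_budget}; "
                "use method='greedy' or raise subset_budget"
            )
        subsets = (
            c for k in range(k_min, k_max + 1) for c in itertools.combinations(range(len(cand)), k)
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    best = None  # (key, cols, spec, sens)
    best_per_size: dict[int, tuple] = {}
    for cols in subsets:
        spec, sens = _score_subset(U, is_d, cols, min_unstable)
        ids = tuple(cand[i] for i in cols)
        meets = (spec == 1.0) or not require_full_specificity
        # ranking: constraint first; among constrained subsets sensitivity,
        # then the relaxed (spec, sens) order, then smaller size; ids break
        # exact ties lexicographically below
        key = (meets, (sens if meets else -1.0), spec, sens, -len(cols))
        if best is None or key > best[0] or (key == best[0] and ids < best[1]):
            best = (key, ids, spec, sens)
        skey = (meets, (sens if meets else -1.0), spec, sens)
        prev = best_per_size.get(len(cols))
        if prev is None or skey > prev[0] or (skey == prev[0] and ids < prev[1]):
            best_per_size[len(cols)] = (skey, ids, spec, sens, spec == 1.0)
    assert best is not None
    _, ids, spec, sens = best
    meets = (spec == 1.0) or not require_full_specificity
    log = [
        {
            "size": k,
            "locus_ids": list(v[1]),
            "specificity": v[2],
            "sensitivity": v[3],
            "constraint_met": bool(v[4]),
        }
        for k, v in sorted(best_per_size.items())
    ]
    return PanelModel(
        locus_ids=list(ids),
        min_unstable=min_unstable,
        train_sensitivity=sens,
        train_specificity=spec,
        constraint_met=bool(meets),
        selection_log=log,
    )


def _greedy_subsets(
    U: np.ndarray, is_d: np.ndarray, n_cand: int, k_min: int, k_max: int, min_unstable: int
) -> list[tuple[int, ...]]:
    """Forward selection path: the nested subsets visited by greedy growth."""
    current: list[int] = []
    path = []
    remaining = list(range(n_cand))
    while len(current) < k_max and remaining:
        scored = []
        for j in remaining:
            spec, sens = _score_subset(U, is_d, current + [j], min_unstable)
            scored.append(((spec, sens), j))
        (spec, sens), pick = max(scored, key=lambda t: (t[0][0], t[0][1], -t[1]))
        current.append(pick)
        remaining.remove(pick)
        if len(current) >= k_min:
            path.append(tuple(sorted(current)))
    return path
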