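"""End-to-end orchestration: reads -> profiles -> calls -> panel -> evaluation.

Convenience layer used by the CLI, the acceptance script and the end-to-end
tests; each step simply delegates to the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import instability_calling as ic
from . import panel_selection as ps
from .classify_evaluate import ConfusionStats, classify_cohort, confusion_metrics
from .locus_scan import MicrosatelliteLocus
from .panel_selection import CallMatrix, PanelModel
from .synthetic_cohort import CohortData
from .umi_consensus import collapse_to_profiles


@dataclass
class SelectionParams:
    min_family_size: int = 1
    tau: float = ic.DEFAULT_TAU
    min_cov: int = ic.DEFAULT_MIN_COV
    min_allele_frac: float = ic.DEFAULT_MIN_ALLELE_FRAC
    max_polymorphic_frac: float = 0.05
    min_dmmr_freq: float = 0.30
    max_pmmr_freq: float = 0.05
    n_clusters: int = ps.DEFAULT_N_CLUSTERS
    cluster_seed: int = 0
    gap_tol: float = ps.DEFAULT_GAP_TOL
    min_gap: float = ps.DEFAULT_MIN_GAP
    k_min: int = 2
    k_max: int = 8
    min_unstable: int = 2
    mononucleotide_only: bool = True


@dataclass
class DesignResult:
    profiles: pd.DataFrame
    calls: pd.DataFrame
    call_matrix: CallMatrix
    retained_polymorphism: list[str]
    retained_enrichment: list[str]
    cluster_assignments: pd.Series
    candidates: list[str]
    panel: PanelModel
    train_stats: ConfusionStats


def design_panel(cohort: CohortData, params: SelectionParams | None = None) -> DesignResult:
    """Run the full selection cascade on a paired training cohort."""
    params = params or SelectionParams()
    locus_ids = [l.locus_id for l in cohort.loci]
    profiles, _qc = collapse_to_profiles(cohort.reads, params.min_family_size)
    calls = ic.call_cohort_paired(
        profiles, cohort.samples, locus_ids,
        tau=params.tau, min_cov=params.min_cov, min_allele_frac=params.min_allele_frac,
    )
    cm = CallMatrix.from_calls(calls, cohort.samples).train()

    eligible = locus_ids
    if params.mononucleotide_only:
        eligible = [l.locus_id for l in cohort.loci if l.unit_len == 1]

    kept_poly = ps.polymorphism_filter(
        profiles, cohort.samples, eligible, params.max_polymorphic_frac
    )
    kept_enriched = ps.dmmr_enrichment_filter(
        cm, params.min_dmmr_freq, params.max_pmmr_freq, kept_poly
    )
    features = ps.instability_frequencies(cm, kept_enriched)
    n_clusters = min(params.n_clusters, len(kept_enriched))
    if n_clusters < 1:
        raise ValueError("no loci survived the filters")
    assignments = ps.cluster_loci(features, n_clusters=n_clusters, seed=params.cluster_seed)
    candidates = ps.select_differential_cluster(
        assignments, cm, tol=params.gap_tol, min_gap=params.min_gap
    )
    panel = ps.optimize_panel(
        cm, candidates,
        k_min=min(params.k_min, len(candidates)),
        k_max=params.k_max, min_unstable=params.min_unstable,
    )
    preds = classify_cohort(panel, calls[calls["sample_id"].isin(cm.unstable.index)])
    train_stats = confusion_metrics(preds, cm.labels)
    return DesignResult(
        profiles=profiles, calls=calls, call_matrix=cm,
        retained_polymorphism=kept_poly, retained_enrichment=kept_enriched,
        cluster_assignments=assignments, candidates=candidates,
        panel=panel, train_stats=train_stats,
    )


def evaluate_unmatched(
    panel: PanelModel,
    normal_profiles: pd.DataFrame,
    normal_samples: pd.DataFrame,
    tumor_cohort: CohortData,
    params: SelectionParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ConfusionStats]:
    """Baseline-mode calling and evaluation of an unmatched tumor cohort.

    The panel-of-normals baseline is built from ``normal_profiles`` (e.g.
    the training cohort's normals); tumors come from ``tumor_cohort``.
    Returns (calls, predictions, confusion stats vs dMMR labels).
    """
    params = params or SelectionParams()
    locus_ids = panel.locus_ids
    baselines = ic.build_cohort_baselines(
        normal_profiles, normal_samples, locus_ids, params.min_allele_frac
    )
    tumor_profiles, _qc = collapse_to_profiles(tumor_cohort.reads, params.min_family_size)
    calls = ic.call_cohort_baseline(
        tumor_profiles, tumor_cohort.samples, baselines, locus_ids,
        tau=params.tau, min_cov=params.min_cov,
    )
    preds = classify_cohort(panel, calls)
    labels = tumor_cohort.samples.set_index("sample_id")["mmr_status"]
    stats = confusion_metrics(preds, labels)
    return calls, preds, stats
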