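"""Selection-cascade tests: filters, clustering, differential selection, optimizer."""

import numpy as np
import pandas as pd
import pytest

import msipanel as mp
from msipanel.panel_selection import (
    CallMatrix,
    cluster_loci,
    dmmr_enrichment_filter,
    instability_frequencies,
    optimize_panel,
    per_locus_metrics,
    polymorphism_filter,
    select_differential_cluster,
)
from oracles import best_panel


def make_matrix(unstable, labels, no_call=None, cohort=None):
    n, m = np.asarray(unstable).shape
    samples = [f"S{i:03d}" for i in range(n)]
    loci = [f"L{j:03d}" for j in range(m)]
    U = pd.DataFrame(np.asarray(unstable, bool), index=samples, columns=loci)
    N = pd.DataFrame(
        np.zeros((n, m), bool) if no_call is None else np.asarray(no_call, bool),
        index=samples, columns=loci,
    )
    return CallMatrix(
        unstable=U,
        no_call=N,
        labels=pd.Series(labels, index=samples),
        cohort=pd.Series(cohort or ["train"] * n, index=samples),
    )


def random_matrix(rng, n=30, m=12, p=0.3):
    labels = ["dMMR" if rng.random() < 0.5 else "pMMR" for _ in range(n)]
    return make_matrix(rng.random((n, m)) < p, labels)


# --- polymorphism filter ---------------------------------------------------


def normals_profiles(modal_lengths):
    rows = []
    samples = []
    for i, ml in enumerate(modal_lengths):
        sid = f"N{i:03d}"
        samples.append((sid, f"P{i:03d}", "normal", "pMMR", "train"))
        rows.append((sid, "L000", ml, 30))
        rows.append((sid, "L000", ml + 1, 2))
    profiles = pd.DataFrame(
        rows, columns=["sample_id", "locus_id", "tract_len_units", "family_count"]
    )
    sheet = pd.DataFrame(
        samples, columns=["sample_id", "patient_id", "tissue", "mmr_status", "cohort"]
    )
    return profiles, sheet


def test_shared_modal_length_is_retained():
    profiles, sheet = normals_profiles([10] * 40)
    assert polymorphism_filter(profiles, sheet, ["L000"]) == ["L000"]


def test_polymorphic_modal_lengths_dropped():
    profiles, sheet = normals_profiles([10] * 90 + [11] * 10)
    assert polymorphism_filter(profiles, sheet, ["L000"]) == []


def test_filter_skipped_without_normals():
    profiles, sheet = normals_profiles([10])
    sheet = sheet.assign(tissue="tumor")
    with pytest.warns(UserWarning):
        assert polymorphism_filter(profiles, sheet, ["L000"]) == ["L000"]


def test_simulated_polymorphic_loci_removed():
    """>=90% of truly polymorphic loci are caught on a simulated cohort."""
    cfg = mp.SimulationConfig(
        seed=3, n_paired_patients=40, n_unmatched_tumors=0, n_loci=100,
        n_informative=4, polymorphic_frac=0.05, families_per_locus=40.0,
    )
    cohort = mp.simulate_cohort(cfg)
    profiles, _ = mp.collapse_to_profiles(cohort.reads)
    locus_ids = [l.locus_id for l in cohort.loci]
    kept = set(polymorphism_filter(profiles, cohort.samples, locus_ids))
    poly = cohort.truth.polymorphic_locus_ids
    assert len(poly) == 5
    removed = poly - kept
    assert len(removed) / len(poly) >= 0.9


# --- dMMR enrichment filter ------------------------------------------------


def test_enrichment_keeps_dmmr_specific_loci():
    labels = ["dMMR"] * 10 + ["pMMR"] * 10
    col_a = [True] * 8 + [False] * 12          # freq 0.8 / 0.0 -> keep
    col_b = [True] * 2 + [False] * 18          # freq 0.2 -> drop
    col_c = [True] * 8 + [False] * 2 + [True] * 3 + [False] * 7  # pMMR 0.3 -> drop
    cm = make_matrix(np.array([col_a, col_b, col_c]).T, labels)
    assert dmmr_enrichment_filter(cm) == ["L000"]


def test_enrichment_requires_both_classes():
    cm = make_matrix(np.zeros((4, 3), bool), ["dMMR"] * 4)
    with pytest.raises(ValueError):
        dmmr_enrichment_filter(cm)


def test_enrichment_matches_independent_recount(rng):
    cm = random_matrix(rng, n=40, m=200, p=0.2)
    got = set(dmmr_enrichment_filter(cm, 0.30, 0.05))
    is_d = (cm.labels == "dMMR").to_numpy()
    expected = set()
    for lid in cm.unstable.columns:
        u = cm.unstable[lid].to_numpy()
        fd = u[is_d].mean()
        fp = u[~is_d].mean()
        if fd >= 0.30 and fp <= 0.05:
            expected.add(lid)
    assert got == expected


def test_no_calls_excluded_from_frequencies():
    labels = ["dMMR"] * 4 + ["pMMR"] * 4
    unstable = np.zeros((8, 1), bool)
    unstable[:2, 0] = True
    no_call = np.zeros((8, 1), bool)
    no_call[2:4, 0] = True  # two dMMR no-calls -> denominator 2
    cm = make_matrix(unstable, labels, no_call=no_call)
    freq = instability_frequencies(cm)
    assert freq.loc["L000", "freq_dMMR"] == pytest.approx(1.0)


# --- clustering and differential selection ---------------------------------


def test_identical_feature_vectors_share_cluster():
    X = pd.DataFrame(np.tile([0.5, 0.1, 0.3], (8, 1)), index=[f"L{i}" for i in range(8)])
    lab = cluster_loci(X, n_clusters=3, seed=0)
    assert lab.nunique() == 1


def test_separated_blobs_recovered_exactly(rng):
    a = rng.normal(0.0, 0.01, size=(10, 3))
    b = rng.normal(1.0, 0.01, size=(10, 3))
    X = pd.DataFrame(np.vstack([a, b]), index=[f"L{i:02d}" for i in range(20)])
    lab = cluster_loci(X, n_clusters=2, seed=1)
    assert lab.iloc[:10].nunique() == 1
    assert lab.iloc[10:].nunique() == 1
    assert lab.iloc[0] != lab.iloc[19]


def test_clustering_is_deterministic(rng):
    X = pd.DataFrame(rng.random((30, 3)), index=[f"L{i:02d}" for i in range(30)])
    a = cluster_loci(X, n_clusters=6, seed=7)
    b = cluster_loci(X, n_clusters=6, seed=7)
    assert (a == b).all()


def test_fewer_loci_than_clusters_rejected(rng):
    X = pd.DataFrame(rng.random((4, 3)))
    with pytest.raises(ValueError):
        cluster_loci(X, n_clusters=6)


def test_differential_selection_takes_argmax_cluster():
    labels = ["dMMR"] * 10 + ["pMMR"] * 10
    strong = np.r_[np.ones(10), np.zeros(10)].astype(bool)     # gap 1.0
    weak = np.r_[np.ones(1), np.zeros(19)].astype(bool)        # gap 0.1
    cm = make_matrix(np.array([strong, strong, weak, weak]).T, labels)
    assignments = pd.Series([0, 0, 1, 1], index=cm.unstable.columns)
    assert select_differential_cluster(assignments, cm) == ["L000", "L001"]


def test_differential_selection_keeps_clusters_within_tolerance():
    labels = ["dMMR"] * 50 + ["pMMR"] * 50
    a = np.r_[np.ones(35), np.zeros(65)].astype(bool)  # gap 0.70
    b = np.r_[np.ones(34), np.zeros(66)].astype(bool)  # gap 0.68
    cm = make_matrix(np.array([a, b]).T, labels)
    # disable the absolute floor to isolate the tie-tolerance rule
    got = select_differential_cluster(
        pd.Series([0, 1], index=cm.unstable.columns), cm, min_gap=1.1
    )
    assert got == ["L000", "L001"]


def test_differential_selection_matches_bruteforce_gaps(rng):
    for _ in range(10):
        cm = random_matrix(rng, n=30, m=15, p=0.3)
        assignments = pd.Series(rng.integers(0, 4, 15), index=cm.unstable.columns)
        got = select_differential_cluster(assignments, cm, tol=0.05, min_gap=0.25)
        freq = instability_frequencies(cm)
        gap = freq["freq_dMMR"] - freq["freq_pMMR"]
        cluster_gap = {c: gap[assignments == c].mean() for c in assignments.unique()}
        best = max(cluster_gap.values())
        keep = {c for c, g in cluster_gap.items() if g >= best - 0.05 or g >= 0.25}
        expected = sorted(assignments.index[assignments.isin(keep)])
        assert got == expected


# --- per-locus metrics ------------------------------------------------------


def test_perfect_locus_scores_perfectly():
    labels = ["dMMR"] * 5 + ["pMMR"] * 5
    u = np.r_[np.ones(5), np.zeros(5)].astype(bool)
    cm = make_matrix(u[:, None], labels)
    (m,) = per_locus_metrics(cm, ["L000"])
    assert m.sensitivity == 1.0 and m.specificity == 1.0
    assert (m.n_dmmr, m.n_pmmr) == (5, 5)


def test_metrics_match_independent_recount(rng):
    cm = random_matrix(rng, n=25, m=6, p=0.4)
    is_d = (cm.labels == "dMMR").to_numpy()
    for m in per_locus_metrics(cm, list(cm.unstable.columns)):
        u = cm.unstable[m.locus_id].to_numpy()
        assert m.sensitivity == pytest.approx(u[is_d].mean())
        assert m.specificity == pytest.approx(1 - u[~is_d].mean())


# --- panel optimization -----------------------------------------------------


def test_two_perfect_loci_win_with_smallest_size(rng):
    labels = ["dMMR"] * 12 + ["pMMR"] * 12
    n = len(labels)
    is_d = np.array([l == "dMMR" for l in labels])
    cols = [is_d.copy(), is_d.copy()]  # two perfect loci
    for _ in range(6):
        cols.append(rng.random(n) < 0.25)
    cm = make_matrix(np.array(cols).T, labels)
    panel = optimize_panel(cm, list(cm.unstable.columns), k_min=2, k_max=4)
    assert panel.locus_ids == ["L000", "L001"]
    assert panel.train_sensitivity == 1.0 and panel.train_specificity == 1.0
    assert panel.constraint_met


def test_relaxed_optimum_when_full_specificity_unreachable():
    labels = ["dMMR"] * 4 + ["pMMR"] * 4
    u = np.ones((8, 3), bool)  # every locus unstable everywhere
    cm = make_matrix(u, labels)
    panel = optimize_panel(cm, ["L000", "L001", "L002"], k_min=2, k_max=3)
    assert not panel.constraint_met
    assert panel.train_sensitivity == 1.0 and panel.train_specificity == 0.0


def test_optimizer_matches_exhaustive_oracle(rng):
    for _ in range(8):
        m = int(rng.integers(5, 11))
        cm = random_matrix(rng, n=int(rng.integers(10, 30)), m=m, p=0.35)
        cand = list(cm.unstable.columns)
        panel = optimize_panel(cm, cand, k_min=2, k_max=min(6, m))
        rows = cm.unstable.to_numpy().tolist()
        is_d = [l == "dMMR" for l in cm.labels]
        ids, spec, sens = best_panel(rows, is_d, cand, 2, min(6, m))
        assert tuple(panel.locus_ids) == ids
        assert panel.train_specificity == pytest.approx(float(spec))
        assert panel.train_sensitivity == pytest.approx(float(sens))


def test_adding_a_locus_never_hurts_sensitivity(rng):
    """Under the >=2 rule, growing a panel can only add MSI-H calls."""
    cm = random_matrix(rng, n=40, m=10, p=0.3)
    U = cm.unstable.to_numpy()
    is_d = (cm.labels == "dMMR").to_numpy()
    for _ in range(20):
        k = int(rng.integers(2, 9))
        cols = rng.choice(10, size=k, replace=False)
        extra = [c for c in range(10) if c not in cols]
        pred0 = U[:, cols].sum(1) >= 2
        pred1 = U[:, list(cols) + [extra[0]]].sum(1) >= 2
        assert (pred1 | ~pred0).all()  # pred0 => pred1
        assert pred1[is_d].mean() >= pred0[is_d].mean()
        assert (~pred1)[~is_d].mean() <= (~pred0)[~is_d].mean()


def test_greedy_matches_exhaustive_on_separable_instance(rng):
    labels = ["dMMR"] * 10 + ["pMMR"] * 10
    is_d = np.array([l == "dMMR" for l in labels])
    cols = [is_d.copy(), is_d.copy()] + [np.zeros(20, bool) for _ in range(5)]
    cm = make_matrix(np.array(cols).T, labels)
    cand = list(cm.unstable.columns)
    exh = optimize_panel(cm, cand, k_min=2, k_max=4, method="exhaustive")
    gre = optimize_panel(cm, cand, k_min=2, k_max=4, method="greedy")
    assert exh.locus_ids == gre.locus_ids


def test_enumeration_budget_guard(rng):
    cm = random_matrix(rng, n=10, m=30, p=0.3)
    with pytest.raises(ValueError, match="budget"):
        optimize_panel(cm, list(cm.unstable.columns), k_max=8, subset_budget=100)


def test_selection_log_reports_best_per_size(rng):
    cm = random_matrix(rng, n=20, m=8, p=0.3)
    panel = optimize_panel(cm, list(cm.unstable.columns), k_min=2, k_max=4)
    sizes = [e["size"] for e in panel.selection_log]
    assert sizes == [2, 3, 4]
    for e in panel.selection_log:
        assert len(e["locus_ids"]) == e["size"]


# --- cascade monotonicity ---------------------------------------------------


def test_cascade_is_monotone_on_simulated_cohort(tiny_cohort):
    res = mp.design_panel(tiny_cohort)
    catalog = {l.locus_id for l in tiny_cohort.loci}
    assert set(res.panel.locus_ids) <= set(res.candidates)
    assert set(res.candidates) <= set(res.retained_enrichment)
    assert set(res.retained_enrichment) <= set(res.retained_polymorphism)
    assert set(res.retained_polymorphism) <= catalog
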