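"""STC clustering: profile selection, assignment, permutation significance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dgetag.stc import (ModelProfile, assign_genes, group_significant_profiles,
                        normalize_gene_series, permutation_test,
                        select_model_profiles)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def pearson_or_zero(u, v):
    u = np.asarray(u, float) - np.mean(u)
    v = np.asarray(v, float) - np.mean(v)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def greedy_oracle(T, c, m):
    """Exhaustive greedy max-min selection over all candidates (pure python)."""
    candidates = list(itertools.product(range(-c, c + 1), repeat=T - 1))
    values = {ch: np.concatenate([[0.0], np.cumsum(ch)]) for ch in candidates}
    flat = tuple([0] * (T - 1))
    selected = [flat]
    remaining = [ch for ch in candidates if ch != flat]
    while len(selected) < m:
        best, best_d = None, -1.0
        for ch in remaining:  # lexicographic order preserved by product()
            d = min(1.0 - pearson_or_zero(values[ch], values[s]) for s in selected)
            if d > best_d + 1e-9:  # ties break to the earlier (lexicographic) candidate
                best, best_d = ch, d
        selected.append(best)
        remaining.remove(best)
    return selected


def test_selection_exhausts_small_space():
    profiles = select_model_profiles(T=3, c=1, m=9)
    assert len(profiles) == 9
    assert len({p.changes for p in profiles}) == 9
    assert profiles[0].changes == (0, 0)  # flat profile seeds the selection


def test_selection_matches_exhaustive_greedy_oracle():
    got = [p.changes for p in select_model_profiles(T=4, c=1, m=8)]
    assert got == greedy_oracle(4, 1, 8)


def test_selection_is_pure_function_of_parameters():
    a = [p.changes for p in select_model_profiles(T=5, c=2, m=30)]
    b = [p.changes for p in select_model_profiles(T=5, c=2, m=30)]
    assert a == b
    assert len(set(a)) == len(a)


def test_selection_rejects_oversized_m():
    with pytest.raises(ValueError, match="candidate space"):
        select_model_profiles(T=3, c=1, m=10)


def test_normalize_anchors_first_point():
    tpm = pd.DataFrame({"t1": [10.0, 7.0], "t2": [20.0, 7.0], "t3": [40.0, 7.0]},
                       index=["gA", "gB"])
    v = normalize_gene_series(tpm, pseudo=1.0, min_max_tpm=0.0)
    np.testing.assert_allclose(v.loc["gB"], 0.0)
    np.testing.assert_allclose(
        v.loc["gA"], [0.0, np.log2(21 / 11), np.log2(41 / 11)])


def test_normalize_round_trips(rng):
    tpm = pd.DataFrame(rng.uniform(0, 500, size=(30, 6)))
    v = normalize_gene_series(tpm, pseudo=1.0, min_max_tpm=0.0)
    anchor = tpm.iloc[:, 0].to_numpy() + 1.0
    back = np.exp2(v.to_numpy()) * anchor[:, None] - 1.0
    np.testing.assert_allclose(back, tpm.to_numpy(), rtol=1e-10, atol=1e-8)


def test_normalize_filters_low_expression():
    tpm = pd.DataFrame({"t1": [100.0, 0.0], "t2": [100.0, 0.0]}, index=["hi", "zero"])
    v = normalize_gene_series(tpm, min_max_tpm=5.0)
    assert list(v.index) == ["hi"]


def test_exact_profile_match_assigns_with_correlation_one():
    profiles = select_model_profiles(T=4, c=1, m=8)
    target = profiles[3]
    series = pd.DataFrame([target.values], index=["g"])
    assign = assign_genes(series, profiles)
    assert assign.loc["g", "profile_id"] == target.profile_id
    assert assign.loc["g", "correlation"] == pytest.approx(1.0)


def test_monotone_gene_lands_on_monotone_profile():
    profiles = select_model_profiles(T=4, c=1, m=8)
    series = pd.DataFrame([[0.0, 1.0, 2.0, 3.0]], index=["g"])
    assign = assign_genes(series, profiles)
    chosen = {p.profile_id: p for p in profiles}[assign.loc["g", "profile_id"]]
    assert all(ch >= 0 for ch in chosen.changes)
    assert sum(chosen.changes) > 0


def test_assignment_matches_brute_force_scan(rng):
    profiles = select_model_profiles(T=5, c=2, m=25)
    series = pd.DataFrame(rng.normal(0, 1, size=(100, 5)))
    series.iloc[:, 0] = 0.0
    assign = assign_genes(series, profiles)
    for g in series.index:
        corrs = [pearson_or_zero(series.loc[g], p.values) for p in profiles]
        assert assign.loc[g, "profile_id"] == profiles[int(np.argmax(corrs))].profile_id


def test_zero_variance_series_goes_to_flat_profile():
    profiles = select_model_profiles(T=4, c=1, m=8)
    series = pd.DataFrame([[0.0, 0.0, 0.0, 0.0]], index=["g"])
    assign = assign_genes(series, profiles)
    flat_pid = [p.profile_id for p in profiles if p.changes == (0, 0, 0)][0]
    assert assign.loc["g", "profile_id"] == flat_pid


def test_assigned_counts_sum_to_filtered_genes(rng):
    profiles = select_model_profiles(T=4, c=2, m=20)
    tpm = pd.DataFrame(rng.uniform(0, 200, size=(150, 4)))
    series = normalize_gene_series(tpm, min_max_tpm=5.0)
    assign = assign_genes(series, profiles)
    assert assign["profile_id"].value_counts().sum() == len(series)


def full_enumeration_expected_counts(tpm, profiles, pseudo=1.0, min_max_tpm=0.0):
    """Oracle: mean assigned count per profile over all T! orderings, written
    independently (pure python per-gene argmax)."""
    keep = tpm.max(axis=1) >= min_max_tpm
    raw = tpm.loc[keep].to_numpy(float)
    T = raw.shape[1]
    counts = np.zeros(len(profiles))
    orders = list(itertools.permutations(range(T)))
    for order in orders:
        perm = raw[:, list(order)]
        series = np.log2((perm + pseudo) / (perm[:, [0]] + pseudo))
        for row in series:
            corrs = [pearson_or_zero(row, p.values) for p in profiles]
            if np.allclose(row, 0.0):
                flat = next(i for i, p in enumerate(profiles) if not any(p.changes))
                counts[flat] += 1
            else:
                counts[int(np.argmax(corrs))] += 1
    return counts / len(orders)


def test_permutation_expectations_match_full_enumeration(rng):
    profiles = select_model_profiles(T=4, c=1, m=9)
    tpm = pd.DataFrame(rng.uniform(1, 300, size=(40, 4)))
    sig = permutation_test(tpm, profiles, n_perm=24, seed=0, min_max_tpm=0.0)
    oracle = full_enumeration_expected_counts(tpm, profiles)
    np.testing.assert_allclose(sig["expected"].to_numpy(), oracle, atol=1e-9)


def test_sampled_mode_approximates_exact_enumeration(rng):
    profiles = select_model_profiles(T=4, c=1, m=9)
    tpm = pd.DataFrame(rng.uniform(1, 300, size=(200, 4)))
    exact = permutation_test(tpm, profiles, n_perm=24, seed=0, min_max_tpm=0.0)
    sampled = permutation_test(tpm, profiles, n_perm=20, seed=5, min_max_tpm=0.0)
    # Monte-Carlo agreement: expected counts within a few genes of each other
    diff = np.abs(exact["expected"] - sampled["expected"])
    assert (diff <= np.maximum(6.0, 0.35 * exact["expected"] + 6.0)).all()


def test_planted_profile_is_flagged_significant(rng):
    """200 genes following one profile among 800 shuffled-label genes: the
    planted profile must be detected."""
    profiles = select_model_profiles(T=4, c=2, m=20)
    target = profiles[5]
    planted = np.exp2(np.tile(target.values, (200, 1)) + rng.normal(0, 0.2, (200, 4))) * 50
    null = rng.uniform(1, 300, size=(800, 4))
    tpm = pd.DataFrame(np.vstack([planted, null]))
    sig = permutation_test(tpm, profiles, n_perm=50, seed=1, min_max_tpm=0.0)
    row = sig.set_index("profile_id").loc[target.profile_id]
    assert row["significant"]
    assert row["observed"] > row["expected"]


def test_shuffled_labels_yield_no_signal(rng):
    """Time labels pre-shuffled per gene: the BH-controlled false-positive rate
    across profiles stays near nominal (checked over 10 seeds)."""
    profiles = select_model_profiles(T=4, c=1, m=9)
    n_sig = 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        tpm = r.uniform(1, 300, size=(300, 4))
        for row in tpm:  # independent shuffle per gene kills temporal structure
            r.shuffle(row)
        sig = permutation_test(pd.DataFrame(tpm), profiles, n_perm=24, seed=seed,
                               min_max_tpm=0.0)
        n_sig += int(sig["significant"].sum())
    assert n_sig <= 0.05 * 10 * len(profiles) + 3


def test_grouping_matches_transitive_closure_oracle():
    profiles = [
        ModelProfile(0, (1, 1, 1)),
        ModelProfile(1, (1, 1, 2)),    # highly correlated with 0
        ModelProfile(2, (-1, -1, -1)),
        ModelProfile(3, (1, -1, 1)),
        ModelProfile(4, (0, 0, 0)),    # flat: correlates 0 with everything
    ]
    sig = pd.DataFrame({"profile_id": [0, 1, 2, 3, 4], "significant": True})
    clusters = group_significant_profiles(profiles, sig, correlation_threshold=0.7)

    # oracle: union-find over thresholded correlations, written independently
    corr = np.zeros((5, 5))
    for i, a in enumerate(profiles):
        for j, b in enumerate(profiles):
            corr[i, j] = pearson_or_zero(a.values, b.values)
    groups = {i: {i} for i in range(5)}
    for i in range(5):
        for j in range(5):
            if i != j and corr[i, j] >= 0.7:
                merged = groups[i] | groups[j]
                for k in merged:
                    groups[k] = merged
    oracle = sorted({tuple(sorted(g)) for g in groups.values()})
    assert [tuple(c) for c in clusters] == oracle


def test_identical_shapes_group_together():
    profiles = [ModelProfile(0, (1, 1)), ModelProfile(1, (2, 2))]
    sig = pd.DataFrame({"profile_id": [0, 1], "significant": True})
    clusters = group_significant_profiles(profiles, sig, correlation_threshold=0.99)
    assert clusters == [[0, 1]]


def test_all_distinct_profiles_stay_singletons_at_threshold_one():
    profiles = [ModelProfile(0, (1, 0)), ModelProfile(1, (0, 1)),
                ModelProfile(2, (-1, 1))]
    sig = pd.DataFrame({"profile_id": [0, 1, 2], "significant": True})
    clusters = group_significant_profiles(profiles, sig, correlation_threshold=1.0)
    assert clusters == [[0], [1], [2]]
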