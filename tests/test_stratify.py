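"""cPAT assignment, type-count estimation, K-means typing, validation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from somportrait import (assign_cpats, cluster_types, enumerate_cpats,
                         estimate_type_count, pairwise_correlation,
                         validate_types)
from somportrait.stratify import EMPTY_CPAT, TypeStratifier


def profiles(arr, spots=("A", "B", "C")):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, columns=list(spots)[: arr.shape[1]],
                        index=[f"s{i}" for i in range(arr.shape[0])])


class TestCPATs:
    def test_no_overexpression_gives_empty_pattern(self, rng):
        P = profiles(rng.normal(size=(20, 3)) * 0.01)
        P.iloc[0] += 100  # one extreme sample pins the z-scale
        pats = assign_cpats(P, z_threshold=1.0)
        assert (pats.iloc[1:] == EMPTY_CPAT).all()

    def test_single_high_spot_singleton_pattern(self):
        base = np.zeros((10, 3))
        base[0, 1] = 5.0
        pats = assign_cpats(profiles(base))
        assert pats.iloc[0] == "B"
        assert (pats.iloc[1:] == EMPTY_CPAT).all()

    def test_zero_variance_spot_never_overexpressed(self):
        base = np.zeros((8, 2))
        base[:, 1] = 7.0  # constant -> no variance
        pats = assign_cpats(profiles(base, spots=("A", "B")))
        assert (pats == EMPTY_CPAT).all()

    def test_order_invariance_and_count_conservation(self, rng):
        P = profiles(rng.normal(size=(30, 3)))
        pats = assign_cpats(P)
        perm = rng.permutation(30)
        pats_perm = assign_cpats(P.iloc[perm])
        assert (pats_perm == pats.iloc[perm]).all()
        table = enumerate_cpats(pats, min_count=2)
        assert table["count"].sum() == 30

    def test_enumerate_majors(self):
        pats = pd.Series(["A"] * 6 + ["A+B"] * 3 + ["B"])
        table = enumerate_cpats(pats, min_count=3)
        majors = set(table.loc[table["major"], "cpat"])
        assert majors == {"A", "A+B"}

    def test_distinct_singletons_no_major(self):
        pats = pd.Series([f"S{i}" for i in range(7)])
        table = enumerate_cpats(pats, min_count=2)
        assert len(table) == 7 and not table["major"].any()

    def test_modal_pattern_recovers_planted_combination(self, reference_run):
        """Within each planted subtype the most frequent cPAT is exactly the
        planted over-expressed module combination (via matched spot ids)."""
        from somportrait import match_modules, spot_profile_matrix
        run = reference_run
        res = match_modules(run.spots, run.truth)
        mod2spot = dict(zip(res.pairs["module"], res.pairs["spot_id"]))
        matched = [s for s in run.spots if s.spot_id in set(mod2spot.values())]
        pats = assign_cpats(spot_profile_matrix(matched))
        hits = 0
        subtypes = run.truth.sample_type["subtype"]
        for st, mods in run.truth.subtype_modules.items():
            if not all(m in mod2spot for m in mods):
                continue
            planted = "+".join(sorted(mod2spot[m] for m in mods))
            modal = pats[subtypes == st].mode().iloc[0]
            hits += modal == planted
        assert hits >= 7  # at least 7 of the 9 subtypes


class TestEstimateTypeCount:
    def test_two_separated_groups(self, rng):
        X = np.vstack([rng.normal(0, 0.05, (12, 6)),
                       rng.normal(5, 0.05, (12, 6))])
        portraits = pd.DataFrame(X, index=[f"s{i}" for i in range(24)])
        pats = pd.Series(["A"] * 6 + ["B"] * 6 + ["C"] * 6 + ["D"] * 6,
                         index=portraits.index)
        assert estimate_type_count(pats, portraits, min_count=3) == 2

    def test_identical_centroids_forced_to_two_with_warning(self):
        portraits = pd.DataFrame(np.ones((20, 4)),
                                 index=[f"s{i}" for i in range(20)])
        pats = pd.Series(["A"] * 10 + ["B"] * 10, index=portraits.index)
        with pytest.warns(UserWarning, match="identical"):
            assert estimate_type_count(pats, portraits) == 2

    def test_single_major_pattern_warns_k1(self):
        portraits = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)),
                                 index=[f"s{i}" for i in range(10)])
        pats = pd.Series(["A"] * 10, index=portraits.index)
        with pytest.warns(UserWarning, match="single major"):
            assert estimate_type_count(pats, portraits) == 1

    def test_recovers_planted_type_number(self, multi_seed_runs):
        ks = [run.stratifier.n_types_ for run in multi_seed_runs]
        assert int(np.median(ks)) == 3


class TestClusterTypes:
    def test_two_point_clouds_split_perfectly(self, rng):
        X = np.vstack([rng.normal(-5, 0.3, (30, 8)),
                       rng.normal(5, 0.3, (30, 8))])
        portraits = pd.DataFrame(X, index=[f"s{i}" for i in range(60)])
        out = cluster_types(portraits, k=2, seed=0, n_subtypes=1)
        types = out["type"].to_numpy()
        assert len(np.unique(types[:30])) == 1
        assert len(np.unique(types[30:])) == 1
        assert types[0] != types[-1]

    def test_deterministic_given_seed(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 6)),
                         index=[f"s{i}" for i in range(50)])
        a = cluster_types(X, k=3, seed=9)
        b = cluster_types(X, k=3, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_subtype_prefix_matches_type(self, reference_run):
        a = reference_run.assignment
        assert (a.apply(lambda r: r["subtype"].startswith(f"{r['type']}."),
                        axis=1)).all()
        assert a["subtype"].nunique() == 9

    def test_rejects_k_above_n(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 3)))
        with pytest.raises(ValueError):
            cluster_types(X, k=5)

    def test_type_recovery_ari(self, multi_seed_runs):
        aris = [adjusted_rand_score(run.truth.sample_type["type"],
                                    run.assignment["type"])
                for run in multi_seed_runs]
        assert np.median(aris) >= 0.9

    def test_intermediate_cluster_named_m(self, reference_run):
        """With k=3 the label set is {1, M, 2} and M sits between the
        poles: its centroid correlates less negatively with each pole than
        the poles do with each other."""
        run = reference_run
        a = run.assignment
        assert set(a["type"].unique()) == {"1", "M", "2"}
        cents = {t: run.portraits[a["type"] == t].mean(axis=0)
                 for t in ("1", "M", "2")}
        r12 = np.corrcoef(cents["1"], cents["2"])[0, 1]
        assert r12 < np.corrcoef(cents["1"], cents["M"])[0, 1]
        assert r12 < np.corrcoef(cents["M"], cents["2"])[0, 1]


class TestPairwiseCorrelation:
    def test_duplicate_and_negated_samples(self):
        v = np.linspace(-1, 1, 10)
        P = pd.DataFrame([v, v, -v], index=["a", "b", "c"])
        C = pairwise_correlation(P)
        assert C.loc["a", "b"] == pytest.approx(1.0)
        assert C.loc["a", "c"] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(C), 1.0)
        np.testing.assert_allclose(C.to_numpy(), C.to_numpy().T)

    def test_zero_variance_row_zeroed(self, rng):
        P = pd.DataFrame(np.vstack([np.ones(8), rng.normal(size=(2, 8))]),
                         index=["flat", "x", "y"])
        C = pairwise_correlation(P)
        assert C.loc["flat", "x"] == 0.0 and C.loc["flat", "flat"] == 1.0

    def test_planted_poles_anti_correlate(self, reference_run):
        run = reference_run
        C = pairwise_correlation(run.portraits)
        t = run.truth.sample_type["type"]
        cross = C.loc[t == "1", t == "2"].to_numpy()
        assert cross.mean() < 0


class TestValidateTypes:
    def test_separated_clusters_zero_error(self, rng):
        X = np.vstack([rng.normal(-4, 0.2, (40, 5)),
                       rng.normal(4, 0.2, (40, 5))])
        P = pd.DataFrame(X, index=[f"s{i}" for i in range(80)])
        labels = pd.Series(["a"] * 40 + ["b"] * 40, index=P.index)
        assert validate_types(P, labels, seed=0) == pytest.approx(0.0)

    def test_shuffled_labels_near_chance(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 5)),
                         index=[f"s{i}" for i in range(200)])
        labels = pd.Series(rng.permutation(["a", "b"] * 100), index=X.index)
        rate = validate_types(X, labels, n_rounds=20, seed=1)
        assert 0.35 <= rate <= 0.65

    def test_recovered_types_validate_cleanly(self, reference_run):
        run = reference_run
        rate = validate_types(run.portraits, run.assignment["type"], seed=1)
        assert rate <= 0.10

    def test_single_class_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError):
            validate_types(X, pd.Series(["a"] * 10, index=X.index))


def test_stratifier_without_spots_uses_empty_patterns(rng):
    X = pd.DataFrame(np.vstack([rng.normal(-3, 0.2, (20, 4)),
                                rng.normal(3, 0.2, (20, 4))]),
                     index=[f"s{i}" for i in range(40)])
    strat = TypeStratifier(n_types=2, n_subtypes=1, random_state=0).fit(X)
    assert (strat.cpat_ == EMPTY_CPAT).all()
    assert strat.assignment_["type"].nunique() == 2
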