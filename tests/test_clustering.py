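import numpy as np
import pandas as pd
import pytest

from agetraj import io as aio
from agetraj.clustering import (
    TemporalProfiles,
    fcm_fit,
    group_average_trajectory,
    initial_direction_pct,
    monotonic_pct,
    standardize,
    summarize_clusters,
    validity_indices,
    validity_vote,
)
from agetraj.io import NormalizedMatrix, SampleSheet
from agetraj.simulate import ProfileArchetype, SimConfig, simulate

from conftest import norm_from_array


def _sheet_5x1():
    return SampleSheet(
        table=pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(5)],
             "age_weeks": [5.0, 12.0, 20.0, 27.0, 39.0],
             "replicate": [1] * 5}
        )
    )


def _profiles_from(rows) -> TemporalProfiles:
    arr = np.asarray(rows, float)
    return TemporalProfiles(
        profiles=pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                              columns=[5.0, 12.0, 20.0, 27.0, 39.0][: arr.shape[1]])
    )


class TestStandardize:
    def test_hand_computed_centering_and_scaling(self):
        norm = norm_from_array([[1, 2, 3, 4, 5]])
        prof = standardize(norm, _sheet_5x1())
        expected = np.array([-2, -1, 0, 1, 2]) / np.sqrt(2.5)
        np.testing.assert_allclose(prof.profiles.iloc[0], expected)

    def test_constant_profile_excluded_and_reported(self):
        norm = norm_from_array([[3, 3, 3, 3, 3], [1, 2, 3, 4, 5]])
        prof = standardize(norm, _sheet_5x1())
        assert prof.excluded == ["g0"]
        assert list(prof.profiles.index) == ["g1"]

    def test_idempotent_on_standardized_input(self):
        vals = np.array([[-2, -1, 0, 1, 2]]) / np.sqrt(2.5)
        norm = norm_from_array(vals)
        prof = standardize(norm, _sheet_5x1())
        np.testing.assert_allclose(prof.profiles.to_numpy(), vals, atol=1e-12)

    def test_profiles_have_zero_mean_unit_variance(self, small_sim):
        matrix, sheet, _ = small_sim
        norm = aio.log_transform(aio.rpkm(matrix))
        prof = standardize(norm, sheet)
        vals = prof.profiles.to_numpy()
        np.testing.assert_allclose(vals.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(vals.var(axis=1, ddof=1), 1, atol=1e-9)

    def test_missing_genes_raise(self, small_sim):
        matrix, sheet, _ = small_sim
        norm = aio.rpkm(matrix)
        with pytest.raises(KeyError):
            standardize(norm, sheet, genes=["nope"])


class TestFcmFit:
    def _two_clouds(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 0.1, (n, 5)) + np.array([1, 1, 0, -1, -1])
        b = rng.normal(0, 0.1, (n, 5)) + np.array([-1, -1, 0, 1, 1])
        return _profiles_from(np.vstack([a, b]))

    def test_memberships_rows_sum_to_one_and_objective_monotone(self):
        prof = self._two_clouds()
        fit = fcm_fit(prof, k=2, seed=1, n_starts=3)
        np.testing.assert_allclose(fit.membership.sum(axis=1), 1.0, atol=1e-9)
        diffs = np.diff(fit.objective_trace)
        assert (diffs <= 1e-8 * np.abs(fit.objective_trace[:-1]) + 1e-12).all()

    def test_separated_clouds_match_nearest_centroid_partition(self):
        prof = self._two_clouds()
        fit = fcm_fit(prof, k=2, seed=1, n_starts=5)
        labels = fit.hard_labels.to_numpy()
        x = prof.profiles.to_numpy()
        d = ((x[:, None, :] - fit.centroids[None]) ** 2).sum(axis=2)
        brute = d.argmin(axis=1)
        assert (labels == brute).all()
        # and the two planted clouds are exactly recovered
        assert len(set(labels[:40])) == 1 and len(set(labels[40:])) == 1
        assert labels[0] != labels[-1]

    def test_profile_at_centroid_gets_full_membership(self):
        prof = self._two_clouds()
        fit = fcm_fit(prof, k=2, seed=1, n_starts=3)
        extra = pd.DataFrame(
            fit.centroids[[0]], index=["at_centroid"], columns=prof.profiles.columns
        )
        prof2 = TemporalProfiles(profiles=pd.concat([prof.profiles, extra]))
        fit2 = fcm_fit(prof2, k=2, seed=1, n_starts=3)
        from agetraj.clustering import _fcm_memberships

        d2 = ((prof2.profiles.loc[["at_centroid"]].to_numpy()[:, None, :]
               - fit2.centroids[None]) ** 2).sum(axis=2)
        d2[0, d2.argmin()] = 0.0  # place exactly on its centroid
        u = _fcm_memberships(d2, m=2.0)
        assert u.max() == 1.0 and u.sum() == pytest.approx(1.0)

    def test_duplicated_profiles_leave_centroids_unchanged(self):
        prof = self._two_clouds()
        fit1 = fcm_fit(prof, k=2, seed=3, n_starts=5)
        doubled = TemporalProfiles(
            profiles=pd.concat([prof.profiles, prof.profiles.set_axis(
                [f"d{i}" for i in range(len(prof.profiles))])])
        )
        fit2 = fcm_fit(doubled, k=2, seed=3, n_starts=5)
        c1 = fit1.centroids[np.argsort(fit1.centroids[:, 0])]
        c2 = fit2.centroids[np.argsort(fit2.centroids[:, 0])]
        np.testing.assert_allclose(c1, c2, atol=1e-3)

    def test_small_fuzzifier_reproduces_kmeans_partition(self):
        from sklearn.cluster import KMeans

        prof = self._two_clouds(seed=5)
        fit = fcm_fit(prof, k=2, m=1.05, seed=2, n_starts=5)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(prof.profiles.to_numpy())
        ours = fit.hard_labels.to_numpy()
        theirs = km.labels_
        agree = max((ours == theirs).mean(), (ours != theirs).mean())
        assert agree == 1.0

    def test_k_must_be_below_n_profiles(self):
        prof = _profiles_from(np.eye(3))
        with pytest.raises(ValueError):
            fcm_fit(prof, k=3)


class TestValidityVote:
    def test_xie_beni_degrades_with_k_on_single_blob(self):
        rng = np.random.default_rng(0)
        prof = _profiles_from(rng.normal(0, 1, (150, 5)))
        _, table, _ = validity_vote(prof, range(2, 7), seed=0, n_starts=3)
        xb = table["xie_beni"].to_numpy()
        # monotone trend: later k never beats k=2, and the overall slope is up
        assert xb.argmin() == 0
        assert xb[-1] > xb[0]

    def test_vote_tie_breaks_toward_smaller_k(self):
        rng = np.random.default_rng(1)
        prof = _profiles_from(rng.normal(0, 1, (60, 5)))
        chosen, table, _ = validity_vote(prof, range(2, 5), seed=0, n_starts=2)
        votes = table["votes"]
        winners = votes[votes == votes.max()].index
        assert chosen == min(winners)

    def test_separated_structure_recovered_in_low_noise(self):
        # the five shaped archetypes at very low count noise: every index
        # votes for k=5 (flat genes carry no shape and are not simulated here)
        cfg = SimConfig(
            genes_per_archetype={
                a: 100
                for a in ("linear_up", "linear_down", "rapid_decay", "u_shape", "bell_shape")
            },
            nb_dispersion=1000.0,
            seed=400,
        )
        matrix, sheet, _ = simulate(cfg)
        prof = standardize(aio.log_transform(aio.rpkm(matrix)), sheet)
        chosen, table, _ = validity_vote(prof, range(2, 9), seed=0, n_starts=5)
        assert chosen == 5
        assert table.loc[5, "votes"] == 5


class TestSummaries:
    def test_monotonic_and_direction_flags(self):
        prof = _profiles_from(
            [[1, 0.5, 0, -0.5, -1]] * 70 + [[-1, 0, 1, 0.5, -0.5]] * 30
        )
        fit = fcm_fit(prof, k=2, seed=0, n_starts=5)
        summ = summarize_clusters(fit, prof)
        t = summ.table
        assert list(t["n_members"]) == [70, 30]
        np.testing.assert_allclose(t["pct_members"], [70.0, 30.0])
        big, small = t.iloc[0], t.iloc[1]
        assert big["monotonic"] and big["initial_direction"] == "down"
        assert not small["monotonic"] and small["initial_direction"] == "up"
        mono, inv = monotonic_pct(summ)
        assert (mono, inv) == (70.0, 30.0)
        down, up = initial_direction_pct(summ)
        assert (down, up) == (70.0, 30.0)

    def test_percentages_sum_to_100(self, small_sim):
        matrix, sheet, _ = small_sim
        norm = aio.log_transform(aio.rpkm(matrix))
        prof = standardize(norm, sheet)
        fit = fcm_fit(prof, k=4, seed=0, n_starts=3)
        summ = summarize_clusters(fit, prof)
        assert summ.table["pct_members"].sum() == pytest.approx(100.0, abs=0.1)

    def test_label_permutation_leaves_summary_multiset_unchanged(self):
        prof = _profiles_from(
            [[1, 0.5, 0, -0.5, -1]] * 40 + [[-1, -0.5, 0, 0.5, 1]] * 40
            + [[-1, 0, 1, 0, -1]] * 20
        )
        fit = fcm_fit(prof, k=3, seed=0, n_starts=5)
        summ1 = summarize_clusters(fit, prof)
        # permute cluster identities by permuting membership columns
        perm = [2, 0, 1]
        fit_perm = type(fit)(
            k=fit.k, m=fit.m,
            membership=fit.membership.iloc[:, perm].set_axis(range(3), axis=1),
            centroids=fit.centroids[perm],
            objective=fit.objective,
            objective_trace=fit.objective_trace,
            n_iter=fit.n_iter,
        )
        summ2 = summarize_clusters(fit_perm, prof)
        key = ["n_members", "monotonic", "initial_direction"]
        s1 = summ1.table[key].sort_values(key).reset_index(drop=True)
        s2 = summ2.table[key].sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(s1, s2)


class TestGroupAverageTrajectory:
    def test_linear_up_group_recovers_47pct_change(self):
        # the rising genes are a small share of the library so that the
        # column-total RPKM denominator stays stable across ages
        cfg = SimConfig(
            genes_per_archetype={"linear_up": 60, "flat": 1940},
            archetypes={
                "linear_up": ProfileArchetype("linear_up", amplitude=0.47),
                "flat": ProfileArchetype("flat", amplitude=0.0),
            },
            seed=21,
        )
        matrix, sheet, truth = simulate(cfg)
        norm = aio.rpkm(matrix)  # pct change is about raw expression scale
        mean_prof, sd, pct = group_average_trajectory(
            norm, sheet, truth.genes_of("linear_up")
        )
        assert pct == pytest.approx(47.0, abs=6.0)
        assert mean_prof.iloc[-1] > mean_prof.iloc[0]

    def test_flat_gene_has_near_zero_change(self):
        cfg = SimConfig(genes_per_archetype={"flat": 100}, seed=22)
        matrix, sheet, truth = simulate(cfg)
        norm = aio.rpkm(matrix)
        _, _, pct = group_average_trajectory(norm, sheet, truth.gene_ids)
        assert abs(pct) < 5.0

    def test_single_gene_group_equals_its_profile(self):
        norm = norm_from_array([[1, 2, 3, 4, 5]])
        mean_prof, sd, _ = group_average_trajectory(norm, _sheet_5x1(), ["g0"])
        expected = (np.array([1, 2, 3, 4, 5]) - 3) / np.sqrt(2.5)
        np.testing.assert_allclose(mean_prof, expected)
        np.testing.assert_allclose(sd, 0.0)

    def test_absent_genes_listed_in_error(self):
        norm = norm_from_array([[1, 2, 3, 4, 5]])
        with pytest.raises(KeyError, match="ghost"):
            group_average_trajectory(norm, _sheet_5x1(), ["ghost"])
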