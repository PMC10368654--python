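import dataclasses

import numpy as np
import pandas as pd
import pytest

from kelpshift import sdm
from kelpshift.geo import pairwise_haversine_km
from kelpshift.synthdata import (
    LandscapeConfig,
    OccurrenceSet,
    generate_landscape,
    generate_occurrences,
    niche_suitability,
)


@pytest.fixture(scope="module")
def niche_fit(stacks, landscape_cfg):
    """Reference fit on unpruned records + pseudo-absences (planted niche)."""
    present, _ = stacks
    occ = generate_occurrences(present, landscape_cfg, 600, seed=11)
    train = sdm.sample_pseudo_absences(occ, present, seed=13)
    table = sdm.training_table(train, present)
    return sdm.fit_brt_cv(table, seed=14)


def _separable_table(seed=0, n=200):
    """One informative predictor, clean separation, classes mixed in every band."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    x = np.where(y == 1, rng.uniform(1.0, 2.0, n), rng.uniform(-2.0, -1.0, n))
    return pd.DataFrame(
        {
            "lon": rng.uniform(0, 5, n),
            "lat": rng.uniform(0, 50, n),
            "max_temperature": x * -1.0,  # respects the negative-monotone direction
            "min_temperature": rng.normal(size=n),
            "y": y,
        }
    )


class TestThresholdSelection:
    def test_toy_scores(self):
        tau, sens, spec = sdm.select_threshold(np.array([0.1, 0.4, 0.6, 0.9]), np.array([0, 0, 1, 1]))
        assert tau == pytest.approx(0.6)
        assert sens == 1.0 and spec == 1.0

    def test_inverted_scores_degenerate(self):
        tau, sens, spec = sdm.select_threshold(np.array([0.9, 0.8, 0.1, 0.2]), np.array([0, 0, 1, 1]))
        assert sens + spec <= 1.0 + 1e-12

    def test_equals_exhaustive_scan_on_random_sets(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(6, 40))
            scores = rng.random(n).round(2)  # ties likely
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            tau, sens, spec = sdm.select_threshold(scores, labels)
            # oracle: brute force over candidates with the stated tie rules
            best = None
            for t in np.unique(scores):
                pred = scores >= t
                s = pred[labels == 1].mean()
                c = (~pred[labels == 0]).mean()
                key = (s + c, s, -t)
                if best is None or key > best[0]:
                    best = (key, t)
            assert tau == pytest.approx(best[1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sdm.select_threshold(np.array([0.1, 0.9]), np.array([1, 1]))


class TestPseudoAbsences:
    def test_counts_match_and_cells_disjoint(self, stacks, landscape_cfg):
        present, _ = stacks
        occ = generate_occurrences(present, landscape_cfg, 80, seed=3)
        out = sdm.sample_pseudo_absences(occ, present, seed=4)
        assert len(out.absences) == len(out.presences) == 80
        pr, pc = present.cell_of(out.presences["lon"].to_numpy(), out.presences["lat"].to_numpy())
        ar, ac = present.cell_of(out.absences["lon"].to_numpy(), out.absences["lat"].to_numpy())
        assert set(zip(pr.tolist(), pc.tolist())).isdisjoint(set(zip(ar.tolist(), ac.tolist())))
        assert present.habitat_mask[ar, ac].all()

    def test_determinism_and_exhaustion(self, stacks, landscape_cfg):
        present, _ = stacks
        occ = generate_occurrences(present, landscape_cfg, 50, seed=3)
        a = sdm.sample_pseudo_absences(occ, present, seed=9).data
        b = sdm.sample_pseudo_absences(occ, present, seed=9).data
        pd.testing.assert_frame_equal(a, b)
        big = generate_occurrences(present, landscape_cfg, 5000, seed=3)
        with pytest.raises(ValueError, match="unoccupied"):
            sdm.sample_pseudo_absences(big, present, seed=9)


class TestCorrelogram:
    def test_null_values_stop_at_first_class(self, stacks):
        """A spatially shuffled predictor: first class already insignificant.

        Calibrated per predictor (the test applies no multiplicity
        correction, so the family-wise stop rate shrinks as 0.95**k).
        """
        present, _ = stacks
        rows, cols = np.nonzero(present.habitat_mask)
        hits = 0
        n_runs = 50
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            shuffled = sdm.EnvStack(
                layers={
                    "max_temperature": _shuffle_on_mask(
                        present.layers["max_temperature"], present.habitat_mask, np.random.default_rng(seed + 7)
                    )
                },
                bathymetry=present.bathymetry,
                ocean_mask=present.ocean_mask,
                habitat_mask=present.habitat_mask,
                lon=present.lon,
                lat=present.lat,
            )
            idx = rng.choice(rows.size, size=40, replace=False)
            pts = OccurrenceSet(
                pd.DataFrame(
                    {
                        "lon": present.lon[cols[idx]],
                        "lat": present.lat[rows[idx]],
                        "label": "presence",
                        "source": "test",
                    }
                )
            )
            _, dist, _ = sdm.correlogram_prune(pts, shuffled, seed=seed, n_classes=4, n_perm=99)
            first = 2.0 * present.resolution * 111.32
            hits += dist == pytest.approx(first)
        assert hits >= int(0.9 * n_runs)

    def test_smooth_gradient_extends_past_first_class(self, stacks, landscape_cfg):
        present, _ = stacks
        occ = generate_occurrences(present, landscape_cfg, 60, seed=2, jitter=False)
        with pytest.warns(UserWarning, match="maximum tested distance"):
            _, dist, _ = sdm.correlogram_prune(occ, present, seed=3, n_classes=3, n_perm=49)
        assert dist > 2.0 * present.resolution * 111.32

    def test_no_retained_pair_within_pruning_distance(self, stacks, landscape_cfg):
        present, _ = stacks
        occ = generate_occurrences(present, landscape_cfg, 200, seed=5)
        pruned, dist, _ = sdm.correlogram_prune(occ, present, seed=6, n_classes=2, n_perm=49)
        d = pairwise_haversine_km(pruned.data["lon"].to_numpy(), pruned.data["lat"].to_numpy())
        np.fill_diagonal(d, np.inf)
        assert d.min() >= dist


def _shuffle_on_mask(arr, mask, rng):
    out = arr.copy()
    vals = out[mask]
    out[mask] = rng.permutation(vals)
    return out


class TestFitBrtCv:
    def test_separable_niche_gives_perfect_cv_auc(self):
        fit = sdm.fit_brt_cv(_separable_table(), hyper_grid=[{"n_trees": 100, "complexity": 1, "learning_rate": 0.01}])
        assert fit.cv_auc_mean == pytest.approx(1.0)
        assert fit.cv_auc_sd == pytest.approx(0.0)
        assert fit.cv_sens_mean == pytest.approx(1.0)

    def test_shuffled_labels_give_chance_auc(self):
        aucs = []
        for seed in range(20):
            table = _separable_table(seed)
            rng = np.random.default_rng(seed + 1000)
            table["y"] = rng.permutation(table["y"].to_numpy())
            if table.groupby(sdm.latitudinal_bands(table["lat"].to_numpy()))["y"].nunique().eq(2).sum() < 8:
                continue
            fit = sdm.fit_brt_cv(
                table, hyper_grid=[{"n_trees": 50, "complexity": 1, "learning_rate": 0.01}], seed=seed
            )
            aucs.append(fit.cv_auc_mean)
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_partial_responses_respect_monotone_directions(self, niche_fit):
        limits = sdm.response_tolerance_limits(niche_fit)  # raises on violation
        means = niche_fit.train[niche_fit.predictors].mean()
        for pred in niche_fit.predictors:
            grid = np.linspace(niche_fit.train[pred].min(), niche_fit.train[pred].max(), 256)
            frame = pd.DataFrame({p: np.full(256, means[p]) for p in niche_fit.predictors})
            frame[pred] = grid
            resp = niche_fit.predict_proba_frame(frame)
            diffs = np.diff(resp)
            if sdm.MONOTONE_DIRECTIONS[pred] < 0:
                assert (diffs <= 1e-9).all()
            else:
                assert (diffs >= -1e-9).all()

    def test_single_class_band_guard(self):
        table = _separable_table()
        table["lat"] = np.sort(table["lat"].to_numpy())
        table["y"] = np.where(table.index < 180, 0, 1)  # top bands pure presence
        table.loc[:5, "y"] = 1  # keep global classes mixed
        with pytest.raises(ValueError, match="latitudinal bands"):
            sdm.fit_brt_cv(table, hyper_grid=[{"n_trees": 50, "complexity": 1, "learning_rate": 0.01}])


class TestContributionsAndStepwise:
    HYPERS = {"n_trees": 150, "complexity": 2, "learning_rate": 0.05}

    def test_single_driver_dominates(self):
        table = _separable_table()
        contrib = sdm.relative_contributions(
            table, ["max_temperature", "min_temperature"], self.HYPERS
        )
        assert contrib["max_temperature"] >= 95.0
        assert contrib.sum() == pytest.approx(100.0, abs=0.1)

    def test_noise_predictor_removed_signal_retained(self):
        table = _separable_table()
        rng = np.random.default_rng(5)
        table["salinity"] = rng.normal(size=len(table))
        retained, log = sdm.stepwise_reduce(
            table, ["max_temperature", "salinity"], self.HYPERS
        )
        assert retained == ["max_temperature"]

    def test_single_predictor_returned_unchanged(self):
        table = _separable_table()
        retained, log = sdm.stepwise_reduce(table, ["max_temperature"], self.HYPERS)
        assert retained == ["max_temperature"]
        assert log.empty


class TestToleranceLimits:
    def test_planted_thermal_niche_recovered(self, niche_fit, landscape_cfg):
        limits = sdm.response_tolerance_limits(niche_fit)
        assert limits.loc["max_temperature", "limit"] == pytest.approx(
            landscape_cfg.niche["max_temperature"][1], abs=1.0
        )
        assert limits.loc["min_temperature", "limit"] == pytest.approx(
            landscape_cfg.niche["min_temperature"][0], abs=1.0
        )
        assert limits.loc["min_temperature", "limit"] < limits.loc["max_temperature", "limit"]

    def test_flat_response_reports_boundary_with_flag(self, niche_fit):
        limits = sdm.response_tolerance_limits(niche_fit)
        # salinity never binds on the synthetic landscape: boundary + flag
        assert bool(limits.loc["salinity", "flagged"])


class TestPredictionAndAreas:
    def test_identical_stacks_identical_maps(self, niche_fit, stacks):
        present, _ = stacks
        suit1, bin1 = sdm.predict_and_binarize(niche_fit, present)
        suit2, bin2 = sdm.predict_and_binarize(niche_fit, present)
        np.testing.assert_array_equal(suit1, suit2)
        np.testing.assert_array_equal(bin1, bin2)

    def test_binary_count_matches_threshold_rule(self, niche_fit, stacks):
        present, _ = stacks
        suit, binary = sdm.predict_and_binarize(niche_fit, present)
        expected = int((suit[np.isfinite(suit)] >= niche_fit.threshold).sum())
        assert int(binary.sum()) == expected

    def test_planted_niche_binary_map_jaccard(self, niche_fit, stacks, landscape_cfg):
        present, _ = stacks
        _, binary = sdm.predict_and_binarize(niche_fit, present)
        truth = niche_suitability(present, landscape_cfg.niche)
        jac = (binary & truth).sum() / (binary | truth).sum()
        assert jac >= 0.9

    def test_percent_change_convention_on_printed_areas(self):
        assert sdm.percent_change(981.99, 1640.02) == pytest.approx(40.12, abs=0.005)
        assert sdm.percent_change(8.66, 155.83) == pytest.approx(94.44, abs=0.005)
        assert sdm.percent_change(289.49, 667.75) == pytest.approx(56.65, abs=0.005)
        assert sdm.percent_change(626.55, 758.38) == pytest.approx(17.38, abs=0.005)

    def test_equal_maps_zero_change_and_area_additivity(self, stacks):
        present, _ = stacks
        rng = np.random.default_rng(0)
        binary = present.habitat_mask & (rng.random(present.shape) < 0.5)
        half = np.zeros(present.shape, dtype=bool)
        half[: present.shape[0] // 2] = True
        regions = {"north": half, "south": ~half}
        rep = sdm.area_and_change(binary, binary, present.lat, present.resolution, regions)
        assert rep["pct_change"].abs().max() == pytest.approx(0.0)
        assert rep.loc["north", "present_area"] + rep.loc["south", "present_area"] == pytest.approx(
            rep.loc["all", "present_area"]
        )

    def test_schoener_overlap_cases(self):
        a = np.array([[0.2, 0.3, 0.5]])
        assert sdm.schoener_overlap(a, a) == pytest.approx(1.0)
        b = np.array([[0.0, 0.0, 1.0]])
        c = np.array([[1.0, 0.0, 0.0]])
        assert sdm.schoener_overlap(b, c) == pytest.approx(0.0)
        # hand evaluation on a 3-cell toy
        x = np.array([[0.6, 0.2, 0.2]])
        y = np.array([[0.2, 0.2, 0.6]])
        assert sdm.schoener_overlap(x, y) == pytest.approx(1.0 - 0.5 * (0.4 + 0.0 + 0.4))
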