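import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from greyzone import (
    InfeasibleInjectionError,
    LatentConfig,
    TableValidationError,
    accuracy_study,
    calibrate_rho,
    cell_probs_from_latent,
    default_cutpoints,
    detect_grey_zones,
    from_counts,
    generate_table,
    inject_grey_zone,
    kappa_from_probs,
    matthews_corrcoef,
    summarize_replicates,
)
from greyzone.exceptions import AgreementTooLowError, ThresholdDomainError
from greyzone.simulation import _batch_counts, _batch_decisions


class TestCutpoints:
    def test_median_split(self):
        assert default_cutpoints(2) == pytest.approx([0.0])

    def test_r4_symmetric(self):
        cuts = default_cutpoints(4)
        assert cuts[1] == pytest.approx(0.0)
        assert cuts[0] == pytest.approx(norm.ppf(0.25))
        assert cuts[2] == -cuts[0]

    def test_r3_quantiles(self):
        assert default_cutpoints(3) == pytest.approx([-0.4307, 0.4307], abs=1e-4)


class TestCellProbs:
    def test_independence_quarter_cells(self):
        p = cell_probs_from_latent(LatentConfig(rho=0.0, R=2, n=1))
        assert p == pytest.approx(np.full((2, 2), 0.25), abs=1e-9)

    def test_comonotone_limit_concentrates_diagonal(self):
        p = cell_probs_from_latent(LatentConfig(rho=0.9999, R=3, n=1))
        assert p.sum() == pytest.approx(1.0)
        assert 1.0 - np.trace(p) < 0.01

    def test_symmetric_grid(self):
        p = cell_probs_from_latent(LatentConfig(rho=0.7, R=4, n=1))
        assert p == pytest.approx(p.T, abs=1e-9)

    def test_quadrature_oracle(self):
        """Cells match direct 2-D integration of the bivariate density."""
        rho, R = 0.9, 4
        cfg = LatentConfig(rho=rho, R=R, n=1)
        p = cell_probs_from_latent(cfg)
        edges = np.concatenate([[-8.0], cfg.cutpoints, [8.0]])
        det = 1 - rho**2

        def density(y, x):
            return np.exp(-(x * x - 2 * rho * x * y + y * y) / (2 * det)) / (
                2 * np.pi * np.sqrt(det)
            )

        for i in range(R):
            for j in range(R):
                ref, _ = integrate.dblquad(
                    density, edges[i], edges[i + 1], edges[j], edges[j + 1],
                    epsabs=1e-9,
                )
                assert p[i, j] == pytest.approx(ref, abs=1e-6)

    def test_invalid_cutpoints(self):
        with pytest.raises(TableValidationError, match="increasing"):
            LatentConfig(rho=0.5, R=3, n=10, cutpoints=[0.5, 0.1])


class TestGenerateTable:
    def test_multinomial_closure(self, rng):
        t = generate_table(LatentConfig(rho=0.6, R=4, n=137), rng)
        assert t.n == 137

    def test_large_n_kappa_near_plugin(self):
        cfg = LatentConfig(rho=0.99, R=3, n=10_000)
        target = kappa_from_probs(cell_probs_from_latent(cfg))
        t = generate_table(cfg, np.random.default_rng(5))
        from greyzone import cohen_kappa, make_weights

        k = cohen_kappa(t, make_weights("identity", 3)).value
        assert k == pytest.approx(target, abs=0.05)

    def test_fixed_seed_reproducible(self):
        cfg = LatentConfig(rho=0.8, R=3, n=50)
        a = generate_table(cfg, np.random.default_rng(11))
        b = generate_table(cfg, np.random.default_rng(11))
        assert np.array_equal(a.counts, b.counts)


def test_plugin_kappa_increasing_in_rho():
    kappas = [
        kappa_from_probs(cell_probs_from_latent(LatentConfig(rho=r, R=3, n=1)))
        for r in np.linspace(0.4, 0.99, 13)
    ]
    assert np.all(np.diff(kappas) > 0)


def test_calibrate_rho_roundtrip():
    rho = calibrate_rho(0.63, R=3)
    k = kappa_from_probs(cell_probs_from_latent(LatentConfig(rho=rho, R=3, n=1)))
    assert k == pytest.approx(0.63, abs=1e-6)


class TestInjection:
    def setup_method(self):
        self.base = cell_probs_from_latent(LatentConfig(rho=0.95, R=3, n=1))

    def test_probability_conserved_and_nonnegative(self):
        target = kappa_from_probs(self.base) - 0.1
        out = inject_grey_zone(self.base, (1, 2), target)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(out >= 0)
        assert out[0, 1] > self.base[0, 1]

    def test_hits_target_kappa(self):
        target = kappa_from_probs(self.base) - 0.15
        out = inject_grey_zone(self.base, (2, 1), target)
        assert kappa_from_probs(out) == pytest.approx(target, abs=1e-6)

    def test_donor_rule_lower_level_diagonal(self):
        target = kappa_from_probs(self.base) - 0.1
        out = inject_grey_zone(self.base, (3, 2), target)
        # donor is (2,2); cells other than donor and target unchanged
        assert out[1, 1] < self.base[1, 1]
        assert out[2, 1] > self.base[2, 1]
        assert out[0, 0] == pytest.approx(self.base[0, 0])

    def test_kappa_monotone_in_moved_fraction(self):
        """Justifies bisection: kappa never increases as diagonal mass
        moves off the diagonal."""
        donor_mass = self.base[0, 0]
        kappas = []
        for f in np.linspace(0, 0.9, 10):
            q = self.base.copy()
            q[0, 0] -= f * donor_mass
            q[0, 1] += f * donor_mass
            kappas.append(kappa_from_probs(q))
        assert np.all(np.diff(kappas) < 1e-12)

    def test_null_injection_leaves_grid_unchanged(self):
        q = self.base.copy()
        q[0, 0] -= 0.0
        assert kappa_from_probs(q) == kappa_from_probs(self.base)

    def test_non_adjacent_cell_rejected(self):
        with pytest.raises(TableValidationError, match="adjacent"):
            inject_grey_zone(self.base, (1, 3), 0.5)

    def test_unattainable_target_rejected(self):
        with pytest.raises(InfeasibleInjectionError, match="range"):
            inject_grey_zone(self.base, (1, 2), kappa_from_probs(self.base) + 0.1)


class TestMCC:
    def test_perfect_detector(self):
        mcc, undef = matthews_corrcoef(50, 0, 0, 50)
        assert mcc == 1.0 and not undef

    def test_all_negative_detector_is_zero_by_convention(self):
        mcc, undef = matthews_corrcoef(0, 0, 50, 50)
        assert mcc == 0.0 and undef

    def test_point_biserial_identity(self, rng):
        """MCC equals the Pearson correlation of the two binary vectors."""
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(1, 40, size=4)
            truth = np.r_[np.ones(tp + fn), np.zeros(fp + tn)]
            pred = np.r_[np.ones(tp), np.zeros(fn), np.ones(fp), np.zeros(tn)]
            mcc, _ = matthews_corrcoef(tp, fp, fn, tn)
            assert mcc == pytest.approx(np.corrcoef(truth, pred)[0, 1], abs=1e-12)


class TestAccuracyStudy:
    def test_injected_tables_flagged_more_often(self):
        res = accuracy_study(
            [(0.9, 500, 3, (1, 2))], reps=400, rng=np.random.default_rng(4)
        )
        (r,) = res
        assert r.sensitivity > 5 * (1 - r.specificity) + 0.05
        assert r.TP + r.FN == 400 and r.FP + r.TN == 400

    def test_reproducible_with_same_master_seed(self):
        runs = [
            accuracy_study(
                [(0.85, 200, 3, (2, 3))], reps=100, rng=np.random.default_rng(9)
            )[0]
            for _ in range(2)
        ]
        assert (runs[0].TP, runs[0].FP) == (runs[1].TP, runs[1].FP)

    def test_batch_decisions_match_per_table_pipeline(self, rng):
        """The vectorized Monte-Carlo path and detect_grey_zones agree
        table by table."""
        from greyzone import DEFAULT_THRESHOLD_MODEL

        probs = cell_probs_from_latent(LatentConfig(rho=0.8, R=3, n=1))
        counts = _batch_counts(probs, 150, 60, rng)
        batch = _batch_decisions(counts, 150, DEFAULT_THRESHOLD_MODEL)
        for c, decision in zip(counts, batch):
            try:
                with np.errstate(all="ignore"):
                    import warnings

                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        ref = detect_grey_zones(from_counts(c)).detected
            except (AgreementTooLowError, ThresholdDomainError):
                ref = False
            assert decision == ref


class TestSummaries:
    def test_shape_and_ordering(self, rng):
        df = summarize_replicates([0.7, 0.9], [100, 300], reps=200, rng=rng)
        assert len(df) == 4
        assert np.all(df["kappa_min"] <= df["kappa_med"])
        assert np.all(df["kappa_med"] <= df["kappa_max"])
        assert np.all(df["delta_med"] <= df["delta_p90"])
        assert np.all(df["delta_p95"] <= df["delta_max"])

    def test_median_kappa_up_median_delta_down_in_rho(self):
        df = summarize_replicates(
            [0.5, 0.65, 0.8, 0.9], [100], reps=500,
            rng=np.random.default_rng(12),
        )
        assert df["kappa_med"].is_monotonic_increasing
        assert df["delta_med"].is_monotonic_decreasing

    def test_reps_minimum_enforced(self, rng):
        with pytest.raises(TableValidationError, match="reps"):
            summarize_replicates([0.7], [100], reps=1, rng=rng)

    def test_deterministic_under_seed(self):
        a = summarize_replicates([0.8], [100], 100, np.random.default_rng(3))
        b = summarize_replicates([0.8], [100], 100, np.random.default_rng(3))
        assert a.equals(b)
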