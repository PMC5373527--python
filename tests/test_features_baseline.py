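"""CSP / FBCSP / band-power extractors: dimensionalities and oracles."""
import numpy as np
import pytest

from mibci import (EpochSet, FilterBankSpec, apply_csp, extract_bandpower,
                   extract_fbcsp, fit_csp)


def two_channel_toy(seed=0, n_per_class=40, n_samples=250):
    """Class A: noise only on channel 1; class B: noise only on channel 2."""
    rng = np.random.default_rng(seed)
    data = np.zeros((2 * n_per_class, 2, n_samples))
    data[:n_per_class, 0] = rng.standard_normal((n_per_class, n_samples))
    data[:n_per_class, 1] = 0.05 * rng.standard_normal((n_per_class, n_samples))
    data[n_per_class:, 1] = rng.standard_normal((n_per_class, n_samples))
    data[n_per_class:, 0] = 0.05 * rng.standard_normal((n_per_class, n_samples))
    labels = np.array(["MI-GRASP"] * n_per_class + ["REST"] * n_per_class,
                      object)
    return EpochSet(data, 250.0, labels, (0, 1), ["ch1", "ch2"])


class TestCSPFit:
    def test_toy_filter_isolates_discriminative_channel(self):
        ep = two_channel_toy()
        filters = fit_csp(ep, n_per_class=2)
        # the max-eigenvalue filter of the MI-GRASP problem loads on ch1
        idx = [i for i, (c, e) in enumerate(filters.class_tags)
               if c == "MI-GRASP" and e == "max"][0]
        w = filters.filters[idx]
        assert abs(w[0]) / abs(w[1]) > 10

    def test_three_class_default_gives_six_filters(self, small_epochs):
        filters = fit_csp(small_epochs, n_per_class=2)
        assert filters.n_filters == 6

    def test_eigenvalues_in_open_unit_interval(self, small_epochs):
        filters = fit_csp(small_epochs)
        assert np.all(filters.eigenvalues > 0)
        assert np.all(filters.eigenvalues < 1)

    def test_trial_order_invariance(self, small_epochs):
        perm = np.random.default_rng(0).permutation(small_epochs.n_trials)
        shuffled = EpochSet(small_epochs.data[perm], small_epochs.fs,
                            small_epochs.labels[perm], small_epochs.window,
                            small_epochs.channel_labels)
        f1 = fit_csp(small_epochs)
        f2 = fit_csp(shuffled)
        assert np.allclose(np.abs(f1.filters), np.abs(f2.filters), atol=1e-8)
        assert np.allclose(f1.eigenvalues, f2.eigenvalues, atol=1e-10)

    def test_top_filter_beats_random_filters(self):
        """Brute-force oracle: CSP max filter's class-variance ratio is at
        least that of the best of 1000 random unit filters."""
        ep = two_channel_toy(seed=3)
        filters = fit_csp(ep, n_per_class=2)
        idx = [i for i, (c, e) in enumerate(filters.class_tags)
               if c == "MI-GRASP" and e == "max"][0]
        w_csp = filters.filters[idx]

        def variance_ratio(w):
            proj = np.einsum("c,tcs->ts", w, ep.data)
            v = proj.var(axis=1)
            a = v[ep.labels == "MI-GRASP"].mean()
            b = v[ep.labels == "REST"].mean()
            return a / (a + b)

        rng = np.random.default_rng(0)
        best_random = 0.0
        for _ in range(1000):
            w = rng.standard_normal(2)
            w /= np.linalg.norm(w)
            best_random = max(best_random, variance_ratio(w))
        assert variance_ratio(w_csp) >= best_random - 1e-9

    def test_rejects_single_class(self):
        ep = two_channel_toy()
        ep = EpochSet(ep.data[:40], ep.fs, ep.labels[:40], ep.window,
                      ep.channel_labels)
        with pytest.raises(ValueError):
            fit_csp(ep)


class TestCSPApply:
    def test_shape_contract(self, small_epochs):
        filters = fit_csp(small_epochs)
        fm = apply_csp(filters, small_epochs)
        assert fm.values.shape == (small_epochs.n_trials, 6)

    def test_normalized_variances_sum_to_one(self, small_epochs):
        filters = fit_csp(small_epochs)
        fm = apply_csp(filters, small_epochs)
        sums = np.exp(fm.values).sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_gain_invariance(self, small_epochs):
        filters = fit_csp(small_epochs)
        scaled = EpochSet(small_epochs.data * 10.0, small_epochs.fs,
                          small_epochs.labels, small_epochs.window,
                          small_epochs.channel_labels)
        a = apply_csp(filters, small_epochs)
        b = apply_csp(filters, scaled)
        assert np.allclose(a.values, b.values)

    def test_channel_mismatch_rejected(self, small_epochs):
        filters = fit_csp(small_epochs)
        wrong = EpochSet(small_epochs.data[:, :5, :], small_epochs.fs,
                         small_epochs.labels, small_epochs.window,
                         small_epochs.channel_labels[:5])
        with pytest.raises(ValueError):
            apply_csp(filters, wrong)


class TestFBCSP:
    def test_default_bank_gives_18_columns(self, small_epochs):
        fm = extract_fbcsp(small_epochs)
        assert fm.n_features == 18
        assert fm.n_instances == small_epochs.n_trials

    def test_single_band_reduces_to_plain_csp(self, small_epochs):
        from mibci.features_baseline import _bandpass_epochs
        spec = FilterBankSpec([(7.0, 15.0)])
        fb = extract_fbcsp(small_epochs, spec)
        band = _bandpass_epochs(small_epochs, 7.0, 15.0)
        plain = apply_csp(fit_csp(band), band)
        assert np.allclose(np.sort(fb.values, axis=1),
                           np.sort(plain.values, axis=1), atol=1e-8)

    def test_invalid_band_spec_rejected(self):
        with pytest.raises(ValueError):
            FilterBankSpec([(15.0, 7.0)])


class TestBandPower:
    def test_twenty_channels_give_20_columns(self, small_epochs):
        fm = extract_bandpower(small_epochs)
        assert fm.n_features == 20

    def test_sinusoid_power_is_half_amplitude_squared(self):
        fs, amp = 250.0, 3.0
        t = np.arange(500) / fs
        data = 0.01 * np.random.default_rng(0).standard_normal((8, 2, 500))
        data[:, 0, :] += amp * np.sin(2 * np.pi * 15.0 * t)
        ep = EpochSet(data, fs, np.array(["REST"] * 4 + ["MI-GRASP"] * 4,
                                         object), (0, 2), ["a", "b"])
        fm = extract_bandpower(ep, band=(8.0, 24.0))
        power = np.exp(fm.values[:, 0]).mean()
        assert power == pytest.approx(amp ** 2 / 2, rel=0.05)

    def test_doubling_amplitude_adds_log_four(self, small_epochs):
        a = extract_bandpower(small_epochs)
        doubled = EpochSet(small_epochs.data * 2.0, small_epochs.fs,
                           small_epochs.labels, small_epochs.window,
                           small_epochs.channel_labels)
        b = extract_bandpower(doubled)
        assert np.allclose(b.values - a.values, np.log(4.0), atol=1e-9)

    def test_invalid_band_rejected(self, small_epochs):
        with pytest.raises(ValueError):
            extract_bandpower(small_epochs, band=(8.0, 200.0))
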