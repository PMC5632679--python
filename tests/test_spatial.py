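"""SSD and CSP spatial-filter estimation."""

import numpy as np
import pytest
from scipy.signal import butter, sosfiltfilt

import cogdepth as cd
from cogdepth.spatial import BandSpec, SpatialFilterBank, select_csp_components


def _band_power(x, band, fs):
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x, axis=-1).var(axis=-1)


def _alpha_band():
    # flankers of 3 Hz on each side equal the 6 Hz signal bandwidth
    return BandSpec(8.0, 14.0, flanker_hz=3.0, gap_hz=1.0)


class TestSSD:
    def test_planted_source_beats_best_channel(self):
        """First SSD component's band-to-flanker power ratio is at least the
        best single channel's ratio (oracle: direct per-channel ratios)."""
        rng = np.random.default_rng(0)
        fs, n = 200.0, 60_000
        sos = butter(4, [9, 11], btype="bandpass", fs=fs, output="sos")
        source = sosfiltfilt(sos, rng.standard_normal(n))
        mixing = rng.standard_normal(8)
        data = np.outer(mixing, source) + 0.8 * rng.standard_normal((8, n))
        rec = cd.Recording(
            data=data, channel_labels=[f"C{i}" for i in range(8)], fs=fs
        )
        band = _alpha_band()
        bank = cd.ssd_fit(rec, band)
        comp = bank.W[:, 0] @ data
        flank = band.flanker_bands

        def ratio(x):
            return _band_power(x, band.signal_band, fs) / (
                _band_power(x, flank[0], fs) + _band_power(x, flank[1], fs)
            )

        best_channel = max(ratio(data[i]) for i in range(8))
        assert ratio(comp) >= best_channel

    def test_white_noise_gives_unit_eigenvalues(self):
        rng = np.random.default_rng(1)
        rec = cd.Recording(
            data=rng.standard_normal((6, 50_000)),
            channel_labels=[f"C{i}" for i in range(6)],
            fs=200.0,
        )
        bank = cd.ssd_fit(rec, _alpha_band())
        # equal power in signal and (equal-bandwidth) flanker bands ⇒ λ ≈ 1
        assert np.all(bank.eigenvalues > 0.7)
        assert np.all(bank.eigenvalues < 1.4)

    def test_rank_deficient_data_truncated(self):
        rng = np.random.default_rng(2)
        latent = rng.standard_normal((3, 30_000))
        mixing = rng.standard_normal((8, 3))
        rec = cd.Recording(
            data=mixing @ latent,
            channel_labels=[f"C{i}" for i in range(8)],
            fs=200.0,
        )
        bank = cd.ssd_fit(rec, _alpha_band())
        assert bank.n_components <= 3

    def test_eigenvalues_sorted_descending(self):
        rng = np.random.default_rng(3)
        rec = cd.Recording(
            data=rng.standard_normal((6, 30_000)),
            channel_labels=[f"C{i}" for i in range(6)],
            fs=200.0,
        )
        bank = cd.ssd_fit(rec, _alpha_band())
        assert np.all(np.diff(bank.eigenvalues) <= 1e-12)


def _csp_epochs(rng, var_a=(1.0, 4.0), var_b=(4.0, 1.0), n=100, n_samp=200,
                mixing=None):
    stds_a = np.sqrt(np.array(var_a))
    stds_b = np.sqrt(np.array(var_b))
    n_ch = len(var_a)
    data = np.empty((2 * n, n_ch, n_samp))
    data[:n] = rng.standard_normal((n, n_ch, n_samp)) * stds_a[:, None]
    data[n:] = rng.standard_normal((n, n_ch, n_samp)) * stds_b[:, None]
    if mixing is not None:
        data = np.einsum("dc,tcs->tds", mixing, data)
    labels = np.array(["NT"] * n + ["DT"] * n)
    return cd.EpochSet(
        data=data,
        labels=labels,
        times=np.arange(n_samp) * 10.0,
        fs=100.0,
        channel_labels=[f"C{i}" for i in range(n_ch)],
    )


def _brute_force_csp(epochs, class_pair, n_grid=3600):
    """Oracle: maximize the class-A variance fraction over unit filters."""
    a, b = class_pair
    xa = epochs.data[epochs.labels == a]
    xb = epochs.data[epochs.labels == b]
    angles = np.linspace(0, np.pi, n_grid, endpoint=False)
    best_w, best_frac, best_score = None, None, -1.0
    for th in angles:
        w = np.array([np.cos(th), np.sin(th)])
        va = np.einsum("c,tcs->ts", w, xa).var(axis=-1).mean()
        vb = np.einsum("c,tcs->ts", w, xb).var(axis=-1).mean()
        frac = va / (va + vb)
        if max(frac, 1 - frac) > best_score:
            best_score, best_frac, best_w = max(frac, 1 - frac), frac, w
    return best_w, best_frac


class TestCSP:
    def test_axis_aligned_two_channel_problem(self):
        rng = np.random.default_rng(4)
        ep = _csp_epochs(rng)
        bank = cd.csp_fit(ep, ("NT", "DT"))
        lam = np.sort(bank.eigenvalues)
        assert np.allclose(lam, [0.2, 0.8], atol=0.04)
        for j in range(2):
            w = bank.W[:, j] / np.linalg.norm(bank.W[:, j])
            assert max(abs(w[0]), abs(w[1])) > 0.99  # axis-aligned

    def test_agrees_with_brute_force_search(self):
        """Filters match an exhaustive unit-norm grid search within 5°."""
        rng = np.random.default_rng(5)
        mixing = np.array([[1.0, 0.6], [-0.3, 1.2]])
        ep = _csp_epochs(rng, mixing=mixing)
        bank = cd.csp_fit(ep, ("NT", "DT"))
        w_oracle, _ = _brute_force_csp(ep, ("NT", "DT"))
        w = bank.W[:, 0] / np.linalg.norm(bank.W[:, 0])
        cosang = abs(w @ w_oracle)
        assert np.degrees(np.arccos(min(cosang, 1.0))) < 5.0

    def test_identical_covariances_give_half(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((50, 3, 100))
        data = np.concatenate([x, x])
        ep = cd.EpochSet(
            data=data,
            labels=np.array(["NT"] * 50 + ["DT"] * 50),
            times=np.arange(100) * 10.0,
            fs=100.0,
            channel_labels=["C0", "C1", "C2"],
        )
        bank = cd.csp_fit(ep, ("NT", "DT"))
        assert np.allclose(bank.eigenvalues, 0.5, atol=1e-9)

    def test_eigenvalue_complementarity(self):
        """Swapping the class order maps every λ to 1 − λ."""
        rng = np.random.default_rng(7)
        ep = _csp_epochs(rng, var_a=(1.0, 2.0, 5.0), var_b=(3.0, 2.0, 1.0))
        ab = cd.csp_fit(ep, ("NT", "DT"))
        ba = cd.csp_fit(ep, ("DT", "NT"))
        assert np.allclose(
            np.sort(ab.eigenvalues), np.sort(1 - ba.eigenvalues), atol=1e-9
        )

    def test_invariant_under_invertible_mixing(self):
        """Component log-variance features are unchanged (up to ordering and
        sign) by any invertible channel mixing.  Oracle: refit after mixing
        and compare eigenvalues and per-trial component variances."""
        rng = np.random.default_rng(8)
        ep = _csp_epochs(rng, var_a=(1.0, 4.0, 2.0), var_b=(4.0, 1.0, 2.5))
        mixing = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        mixed = ep.copy()
        mixed.data = np.einsum("dc,tcs->tds", mixing, ep.data)
        b0 = cd.csp_fit(ep, ("NT", "DT"))
        b1 = cd.csp_fit(mixed, ("NT", "DT"))
        assert np.allclose(np.sort(b0.eigenvalues), np.sort(b1.eigenvalues), atol=1e-9)
        v0 = np.einsum("ck,tcs->tks", b0.W, ep.data).var(axis=-1)
        v1 = np.einsum("ck,tcs->tks", b1.W, mixed.data).var(axis=-1)
        order0 = np.argsort(b0.eigenvalues)
        order1 = np.argsort(b1.eigenvalues)
        assert np.allclose(v0[:, order0], v1[:, order1], rtol=1e-6)

    def test_missing_class_raises(self):
        rng = np.random.default_rng(9)
        ep = _csp_epochs(rng)
        with pytest.raises(cd.MissingClassError):
            cd.csp_fit(ep, ("NT", "ST"))


def _fake_bank(lams):
    k = len(lams)
    return SpatialFilterBank(
        W=np.eye(k),
        A=np.eye(k),
        eigenvalues=np.array(lams),
        method="CSP",
        band=(8.0, 14.0),
        channel_labels=[f"C{i}" for i in range(k)],
        class_pair=("NT", "DT"),
    )


class TestComponentSelection:
    def test_three_per_class_from_extremes(self):
        lams = [0.9, 0.8, 0.7, 0.55, 0.45, 0.3, 0.2, 0.1]
        out = select_csp_components(_fake_bank(lams))
        assert sorted(out.eigenvalues) == [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]

    def test_all_half_returns_nothing(self):
        with pytest.warns(UserWarning):
            out = select_csp_components(_fake_bank([0.5, 0.5, 0.5]))
        assert out.n_components == 0

    def test_two_channel_bank_keeps_at_most_two(self):
        out = select_csp_components(_fake_bank([0.9, 0.1]))
        assert out.n_components <= 2

    def test_median_variance_consistency_check(self):
        """An eigenvalue contradicted by the median per-trial variance
        ordering across classes (outlier-driven) is rejected."""
        rng = np.random.default_rng(10)
        ep = _csp_epochs(rng, var_a=(1.0, 1.0), var_b=(1.0, 1.0), n=40)
        # one extreme class-A outlier trial inflates C0's mean covariance
        ep.data[0, 0, :] *= 30.0
        bank = cd.csp_fit(ep, ("NT", "DT"))
        out = select_csp_components(bank, ep)
        # the outlier-driven high-λ component must not survive the check
        assert np.all(np.maximum(out.eigenvalues, 1 - out.eigenvalues) < 0.9)


class TestApplyFilters:
    def test_identity_bank_preserves_data(self, noise_epochs):
        k = noise_epochs.n_channels
        bank = SpatialFilterBank(
            W=np.eye(k),
            A=np.eye(k),
            eigenvalues=np.ones(k),
            method="SSD",
            band=(8.0, 14.0),
            channel_labels=list(noise_epochs.channel_labels),
        )
        out = cd.apply_filters(bank, noise_epochs)
        assert np.array_equal(out.data, noise_epochs.data)
        assert np.array_equal(out.labels, noise_epochs.labels)

    def test_component_count_sets_channel_count(self):
        rng = np.random.default_rng(11)
        ep = _csp_epochs(rng, var_a=(1.0, 4.0, 2.0), var_b=(4.0, 1.0, 2.5))
        bank = cd.csp_fit(ep, ("NT", "DT"))
        sel = select_csp_components(bank, ep, max_per_class=1)
        out = cd.apply_filters(sel, ep)
        assert out.n_channels == sel.n_components

    def test_component_variance_fraction_matches_lambda(self):
        rng = np.random.default_rng(12)
        ep = _csp_epochs(rng)
        bank = cd.csp_fit(ep, ("NT", "DT"))
        comp = cd.apply_filters(bank, ep)
        va = comp.data[comp.labels == "NT"].var(axis=-1).mean(axis=0)
        vb = comp.data[comp.labels == "DT"].var(axis=-1).mean(axis=0)
        frac = va / (va + vb)
        assert np.allclose(frac, bank.eigenvalues, atol=0.02)

    def test_channel_mismatch_raises(self, noise_epochs):
        bank = _fake_bank([0.9, 0.1])
        with pytest.raises(cd.InvalidConfigurationError):
            cd.apply_filters(bank, noise_epochs)
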