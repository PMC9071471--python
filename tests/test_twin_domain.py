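import math

import numpy as np
import pytest

from psorakit import (
    ConsensusProfile,
    GenomeConfig,
    TranscriptionUnit,
    amplitude_change_percent,
    amplitude_expression_correlation,
    consensus_profile,
    extract_oriented_window,
    fit_domain_regression,
    per_tu_amplitude,
)
from psorakit.twin_domain import DomainFit, OrientedWindow

from conftest import make_track


def twin_profile(h=40, amp=0.38, neg_kb=23.0, pos_kb=25.0):
    """Noiseless triangular twin-domain consensus: +amp decaying upstream,
    -amp decaying downstream, zero at the midpoint."""
    pos = np.arange(-h, h + 1)
    vals = np.zeros(pos.size, dtype=float)
    up = pos < 0
    vals[up] = np.maximum(0.0, amp * (1 - np.abs(pos[up]) / neg_kb))
    dn = pos > 0
    vals[dn] = np.minimum(0.0, -amp * (1 - pos[dn] / pos_kb))
    return ConsensusProfile(values=vals, sem=np.zeros(pos.size), n_windows=1,
                            half_width_kb=h, n_per_position=np.ones(pos.size, int))


class TestOrientedWindow:
    def test_plus_strand_is_direct_slice(self, small_config, rng):
        track = make_track(small_config, rng.normal(size=small_config.n_bins),
                           kind="log2_enrichment")
        tu = TranscriptionUnit("t", 100_000, 102_000, "+", 1.0)
        w = extract_oriented_window(track, tu, half_width_kb=10)
        m = small_config.bin_of(101_000)
        np.testing.assert_array_equal(
            w.values, track.values[(m + np.arange(-10, 11)) % small_config.n_bins]
        )

    def test_minus_strand_is_reversed(self, small_config, rng):
        track = make_track(small_config, rng.normal(size=small_config.n_bins),
                           kind="log2_enrichment")
        plus = TranscriptionUnit("p", 100_000, 102_000, "+", 1.0)
        minus = TranscriptionUnit("m", 100_000, 102_000, "-", 1.0)
        wp = extract_oriented_window(track, plus, 10)
        wm = extract_oriented_window(track, minus, 10)
        np.testing.assert_array_equal(wm.values, wp.values[::-1])

    def test_strand_flip_with_mirrored_track_equivariant(self, small_config, rng):
        """Reversing strand and mirroring the genome yield the same window."""
        n = small_config.n_bins
        vals = rng.normal(size=n)
        track = make_track(small_config, vals, kind="log2_enrichment")
        # mirror about the TU midpoint bin m: mirrored[(m+k) % n] = vals[(m-k) % n]
        tu_p = TranscriptionUnit("p", 100_000, 102_000, "+", 1.0)
        m = small_config.bin_of(101_000)
        k = np.arange(n)
        mirrored = np.empty(n)
        mirrored[(m + k) % n] = vals[(m - k) % n]
        track_m = make_track(small_config, mirrored, kind="log2_enrichment")
        tu_m = TranscriptionUnit("m", 100_000, 102_000, "-", 1.0)
        wp = extract_oriented_window(track, tu_p, 10)
        wm = extract_oriented_window(track_m, tu_m, 10)
        np.testing.assert_allclose(wm.values, wp.values)

    def test_window_wraps_origin(self, small_config, rng):
        track = make_track(small_config, rng.normal(size=small_config.n_bins),
                           kind="log2_enrichment")
        tu = TranscriptionUnit("w", 1000, 3000, "+", 1.0)  # midpoint at 2 kb
        w = extract_oriented_window(track, tu, half_width_kb=10)
        m = small_config.bin_of(2000)
        expected = track.values[(m + np.arange(-10, 11)) % small_config.n_bins]
        np.testing.assert_array_equal(w.values, expected)


class TestConsensus:
    def test_single_window_mean_centered(self, rng):
        tu = TranscriptionUnit("t", 0, 2000, "+", 1.0)
        vals = rng.normal(size=21)
        w = OrientedWindow(tu=tu, half_width_kb=10, values=vals,
                           mask=np.zeros(21, bool))
        prof = consensus_profile([w])
        np.testing.assert_allclose(prof.values, vals - vals.mean(), atol=1e-12)
        assert prof.values.mean() == pytest.approx(0.0, abs=1e-9)

    def test_opposite_windows_cancel(self, rng):
        tu = TranscriptionUnit("t", 0, 2000, "+", 1.0)
        vals = rng.normal(size=21)
        wa = OrientedWindow(tu, 10, vals, np.zeros(21, bool))
        wb = OrientedWindow(tu, 10, -vals, np.zeros(21, bool))
        prof = consensus_profile([wa, wb])
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_noisy_triangle_recovered_within_sem(self):
        rng = np.random.default_rng(42)
        truth = twin_profile(h=40).values
        tu = TranscriptionUnit("t", 0, 2000, "+", 1.0)
        windows = [
            OrientedWindow(tu, 40, truth + rng.normal(0, 0.2, truth.size),
                           np.zeros(truth.size, bool))
            for _ in range(42)
        ]
        prof = consensus_profile(windows)
        centered = truth - truth.mean()
        assert np.all(np.abs(prof.values - centered) < 3 * np.maximum(prof.sem, 1e-9))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            consensus_profile([])

    def test_per_experiment_grouping_weights_experiments_equally(self, rng):
        """One experiment contributing many windows must not dominate a
        grouped consensus."""
        tu = TranscriptionUnit("t", 0, 2000, "+", 1.0)
        high = [OrientedWindow(tu, 10, np.full(21, 2.0) + rng.normal(0, 1e-9, 21),
                               np.zeros(21, bool)) for _ in range(9)]
        low_vals = np.zeros(21)
        low_vals[0] = 1.0  # non-constant so centering leaves structure
        low = [OrientedWindow(tu, 10, low_vals, np.zeros(21, bool))]
        flat = consensus_profile(high + low)
        grouped = consensus_profile(high + low, groups=[0] * 9 + [1])
        # ungrouped: the single 'low' window carries weight 1/10;
        # grouped: its experiment carries weight 1/2
        centered_low = low_vals - low_vals.mean()
        np.testing.assert_allclose(flat.values, centered_low / 10, atol=1e-8)
        np.testing.assert_allclose(grouped.values, centered_low / 2, atol=1e-8)


class TestDomainRegression:
    def test_exact_recovery_on_noiseless_triangle(self):
        prof = twin_profile(amp=0.38, neg_kb=23.0, pos_kb=25.0)
        up = fit_domain_regression(prof, "upstream")
        dn = fit_domain_regression(prof, "downstream")
        assert up.amplitude == pytest.approx(0.38, abs=1e-6)
        assert up.magnitude_kb == pytest.approx(23.0, abs=1e-6)
        assert dn.amplitude == pytest.approx(-0.38, abs=1e-6)
        assert dn.magnitude_kb == pytest.approx(25.0, abs=1e-6)

    @pytest.mark.parametrize("amp,neg,pos", [(0.2, 15.0, 18.0), (0.6, 30.0, 35.0)])
    def test_exact_recovery_for_other_generative_parameters(self, amp, neg, pos):
        prof = twin_profile(amp=amp, neg_kb=neg, pos_kb=pos)
        up = fit_domain_regression(prof, "upstream")
        dn = fit_domain_regression(prof, "downstream")
        assert up.amplitude == pytest.approx(amp, abs=1e-6)
        assert up.magnitude_kb == pytest.approx(neg, abs=1e-6)
        assert dn.magnitude_kb == pytest.approx(pos, abs=1e-6)

    def test_flat_profile_reports_no_domain(self):
        prof = ConsensusProfile(values=np.zeros(81), sem=np.zeros(81), n_windows=1,
                                half_width_kb=40, n_per_position=np.ones(81, int))
        fit = fit_domain_regression(prof, "upstream")
        assert not fit.detected
        assert math.isnan(fit.magnitude_kb)

    def test_confidence_ranges_bracket_point_estimates(self):
        rng = np.random.default_rng(3)
        vals = twin_profile().values + rng.normal(0, 0.02, 81)
        prof = ConsensusProfile(values=vals, sem=np.zeros(81), n_windows=1,
                                half_width_kb=40, n_per_position=np.ones(81, int))
        fit = fit_domain_regression(prof, "upstream")
        lo, hi = fit.amplitude_range
        assert lo < fit.amplitude < hi
        mlo, mhi = fit.magnitude_range
        assert mlo < fit.magnitude_kb < mhi

    def test_scan_matches_brute_force_oracle(self):
        """Expanding-window rule equals an exhaustive max-|r| scan."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            vals = rng.normal(size=81)
            prof = ConsensusProfile(values=vals, sem=np.zeros(81), n_windows=1,
                                    half_width_kb=40,
                                    n_per_position=np.ones(81, int))
            for side in ("upstream", "downstream"):
                fit = fit_domain_regression(prof, side)
                y = vals[39::-1] if side == "upstream" else vals[41:]
                best_k, best_r = None, -1.0
                for k in range(10, 41):
                    r = abs(np.corrcoef(np.arange(1, k + 1), y[:k])[0, 1])
                    if r > best_r + 1e-15:
                        best_r, best_k = r, k
                assert fit.window_kb == best_k

    def test_too_short_profile_rejected(self):
        prof = twin_profile(h=5)
        with pytest.raises(ValueError, match="start_kb"):
            fit_domain_regression(prof, "upstream", start_kb=10)

    def test_greedy_rule_stops_at_first_decline(self):
        """The greedy variant matches a reference first-local-maximum scan
        and never extends past the global-scan extent spuriously."""
        rng = np.random.default_rng(77)
        for _ in range(30):
            vals = rng.normal(size=81)
            prof = ConsensusProfile(values=vals, sem=np.zeros(81), n_windows=1,
                                    half_width_kb=40,
                                    n_per_position=np.ones(81, int))
            for side, series in (("upstream", vals[39::-1]),
                                 ("downstream", vals[41:])):
                fit = fit_domain_regression(prof, side, stop_rule="greedy")
                rs = [abs(np.corrcoef(np.arange(1, k + 1), series[:k])[0, 1])
                      for k in range(10, 41)]
                expected = 10
                for j in range(1, len(rs)):
                    if rs[j] > rs[expected - 10]:
                        expected = j + 10
                    else:
                        break
                assert fit.window_kb == expected


class TestPerTuAmplitude:
    def _canonical_track(self, config, tu, level=0.3, offset_kb=5):
        """+level upstream of the 5' end, -level downstream of the 3' end."""
        vals = np.zeros(config.n_bins)
        sign = 1 if tu.strand == "+" else -1
        up = config.bin_of((tu.five_prime_bp(config) - sign * offset_kb * 1000)
                           % config.genome_length_bp)
        dn = config.bin_of((tu.three_prime_bp(config) + sign * offset_kb * 1000)
                           % config.genome_length_bp)
        vals[up], vals[dn] = level, -level
        return make_track(config, vals, kind="log2_enrichment")

    def test_canonical_twin_domain_positive(self, small_config):
        tu = TranscriptionUnit("t", 100_000, 104_000, "+", 2.0)
        track = self._canonical_track(small_config, tu)
        table = per_tu_amplitude(track, [tu])
        assert table.loc[0, "amplitude"] == pytest.approx(0.6)

    def test_flat_track_gives_zero(self, small_config):
        tus = [TranscriptionUnit(f"t{i}", i * 10_000, i * 10_000 + 3000, "+", 1.0)
               for i in range(5)]
        track = make_track(small_config, np.zeros(small_config.n_bins),
                           kind="log2_enrichment")
        table = per_tu_amplitude(track, tus)
        assert (table["amplitude"] == 0).all()

    def test_inversion_flips_sign(self, small_config):
        plus = TranscriptionUnit("t", 100_000, 104_000, "+", 2.0)
        track = self._canonical_track(small_config, plus)
        minus = TranscriptionUnit("t", 100_000, 104_000, "-", 2.0)
        amp_p = per_tu_amplitude(track, [plus]).loc[0, "amplitude"]
        amp_m = per_tu_amplitude(track, [minus]).loc[0, "amplitude"]
        assert amp_m == pytest.approx(-amp_p)

    def test_masked_position_yields_nan(self, small_config):
        tu = TranscriptionUnit("t", 100_000, 104_000, "+", 2.0)
        track = self._canonical_track(small_config, tu)
        track.mask[small_config.bin_of(95_000)] = True
        table = per_tu_amplitude(track, [tu])
        assert table.loc[0, "masked"]
        assert math.isnan(table.loc[0, "amplitude"])


class TestAmplitudeExpression:
    def test_proportional_gives_r_one(self, rng):
        expr = rng.lognormal(0, 1, 500)
        amp = 0.01 * expr
        table = amplitude_expression_correlation(amp, expr, (1.0, 0.1))
        assert (table["r"] > 0.999).all()

    def test_permuted_amplitudes_uncorrelated(self):
        rng = np.random.default_rng(8)
        expr = rng.lognormal(0, 1, 2598)
        amp = rng.permutation(0.01 * expr)
        table = amplitude_expression_correlation(amp, expr, (1.0,))
        assert abs(table.loc[0, "r"]) < 0.05

    def test_top_subset_beats_all_when_only_top_has_signal(self):
        """Only strongly expressed TUs rise above local noise."""
        rng = np.random.default_rng(15)
        n = 2000
        expr = np.sort(rng.lognormal(0, 1.5, n))
        amp = np.where(expr >= np.quantile(expr, 0.9), 0.005 * expr, 0.0)
        amp = amp + rng.normal(0, 0.05, n)
        table = amplitude_expression_correlation(amp, expr, (1.0, 0.1))
        r_all = table.loc[table["top_fraction"] == 1.0, "r"].iloc[0]
        r_top = table.loc[table["top_fraction"] == 0.1, "r"].iloc[0]
        assert r_top > r_all

    def test_tiny_subset_skipped(self, rng):
        expr = rng.lognormal(0, 1, 50)
        table = amplitude_expression_correlation(0.01 * expr, expr, (1.0, 0.01))
        assert list(table["top_fraction"]) == [1.0]


class TestAmplitudeChange:
    def _fit(self, amp, side="upstream"):
        return DomainFit(side=side, slope=-amp / 23, intercept=amp, window_kb=23,
                         pearson_r=-1.0, amplitude=amp, magnitude_kb=23.0)

    def test_reduction_arithmetic(self):
        assert amplitude_change_percent(self._fit(0.05), self._fit(0.38)) == (
            pytest.approx(86.8, abs=0.1)
        )

    def test_identical_fits_zero_change(self):
        assert amplitude_change_percent(self._fit(0.38), self._fit(0.38)) == 0.0

    def test_increase_is_negative_reduction(self):
        assert amplitude_change_percent(self._fit(0.47), self._fit(0.38)) < 0

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            amplitude_change_percent(self._fit(0.1), self._fit(0.0))

    def test_side_mismatch_rejected(self):
        with pytest.raises(ValueError, match="side"):
            amplitude_change_percent(self._fit(0.1, "upstream"),
                                     self._fit(0.2, "downstream"))
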