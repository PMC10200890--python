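"""Ploidy inference: filters, allele ratios, EM mixtures, histogram
comparison and the four-criterion call."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyoploid import ploidy as pl
from karyoploid.simulate import SimConfig, simulate_allele_counts


def sites_frame(pairs):
    return pd.DataFrame(
        {
            "site_id": [f"s{i}" for i in range(len(pairs))],
            "ref_reads": [p[0] for p in pairs],
            "alt_reads": [p[1] for p in pairs],
        }
    )


class TestLoading:
    def test_coverage_filter_and_log(self):
        df = sites_frame([(15, 1), (20, 20), (3, 3), (30, 5), (9, 0)])
        kept, log = pl.load_site_counts(df, min_coverage=10, min_minor_reads=2)
        assert len(kept) == 2  # (20,20) and (30,5)
        assert log["input_sites"] == 5
        assert log["dropped_low_coverage"] == 2  # (3,3) and (9,0)
        assert log["dropped_low_minor"] == 1  # (15,1)

    def test_zero_thresholds_keep_everything(self):
        df, _ = simulate_allele_counts(SimConfig(seed=0, n_sites=1000))
        kept, log = pl.load_site_counts(df, min_coverage=0, min_minor_reads=0)
        assert len(kept) == 1000 and log["kept"] == 1000

    def test_missing_columns_rejected(self):
        with pytest.raises(pl.PloidyError, match="ref_reads"):
            pl.load_site_counts(pd.DataFrame({"x": [1]}))


class TestAlleleRatios:
    def test_single_site_arithmetic(self):
        med, ratios = pl.allele_ratio_stats(sites_frame([(30, 10)]))
        assert med == 3.0 and list(ratios) == [3.0]

    def test_median_of_three(self):
        med, ratios = pl.allele_ratio_stats(
            sites_frame([(10, 10), (30, 10), (10, 30)])
        )
        assert sorted(ratios) == [1.0, 3.0, 3.0]
        assert med == 3.0

    def test_monoallelic_error(self):
        with pytest.raises(pl.PloidyError):
            pl.allele_ratio_stats(sites_frame([(30, 0), (0, 12)]))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=1, max_value=1000))
    def test_scale_free(self, factor):
        base = sites_frame([(12, 30), (7, 7), (40, 10), (5, 25)])
        scaled = base.copy()
        scaled[["ref_reads", "alt_reads"]] *= factor
        m1, r1 = pl.allele_ratio_stats(base)
        m2, r2 = pl.allele_ratio_stats(scaled)
        assert m1 == m2
        assert np.allclose(r1, r2)

    def test_tetraploid_band(self):
        # known-tetraploid conditions: depth 40, dosage probs 0.4/0.2/0.4
        df, _ = simulate_allele_counts(SimConfig(seed=1, ploidy=4))
        kept, _ = pl.load_site_counts(df)
        med, _ = pl.allele_ratio_stats(kept)
        assert 2.0 < med < 3.2  # plausibility band around the observed 2.3-2.8


class TestMixtureFitting:
    def test_degenerate_half_frequencies(self):
        freqs = np.full(500, 0.5)
        fit = pl.fit_mixture(freqs, 2)
        assert fit.weights[0] == pytest.approx(1.0)
        fit3 = pl.fit_mixture(freqs, 3)
        assert fit.loglik >= fit3.loglik - 1e-6

    def test_loglik_monotone(self):
        df, _ = simulate_allele_counts(SimConfig(seed=2, ploidy=4))
        kept, _ = pl.load_site_counts(df)
        freqs = pl.alt_frequencies(kept)
        for model in (2, 3, 4, ("free", 3)):
            fit = pl.fit_mixture(freqs, model)
            diffs = np.diff(fit.loglik_trace)
            assert (diffs >= -1e-9).all()

    def test_too_few_sites_rejected(self):
        with pytest.raises(pl.PloidyError):
            pl.fit_mixture(np.full(10, 0.5), 2)

    def test_free_nests_fixed(self):
        df, _ = simulate_allele_counts(SimConfig(seed=2, ploidy=4))
        kept, _ = pl.load_site_counts(df)
        rpt = pl.ploidy_fit_report(kept)
        assert all(d >= -1e-6 for d in rpt.delta_loglik.values())

    def test_tetraploid_selected(self):
        df, _ = simulate_allele_counts(SimConfig(seed=2, ploidy=4))
        kept, _ = pl.load_site_counts(df)
        rpt = pl.ploidy_fit_report(kept)
        assert rpt.best_by_delta == 4

    def test_report_round_trip(self):
        df, _ = simulate_allele_counts(SimConfig(seed=3, ploidy=2))
        kept, _ = pl.load_site_counts(df)
        rpt = pl.ploidy_fit_report(kept, known_ploidy=2)
        again = pl.PloidyFitReport.from_dict(rpt.to_dict())
        assert again.delta_loglik == rpt.delta_loglik
        assert again.median_allele_ratio == rpt.median_allele_ratio
        assert again.known_ploidy == 2


class TestHistotest:
    def test_exact_match(self):
        h = np.array([5.0, 20.0, 50.0, 20.0, 5.0])
        slope, se, ssr, r2 = pl.histotest_stats(h, h)
        assert (slope, ssr, r2) == (1.0, 0.0, 1.0)
        assert se == 0.0

    def test_doubled_empirical(self):
        h = np.array([5.0, 20.0, 50.0, 20.0, 5.0])
        slope, _se, ssr, r2 = pl.histotest_stats(2 * h, h)
        assert slope == 2.0 and r2 == 1.0 and ssr == pytest.approx(0.0)

    def test_triploid_data_prefers_triploid_expectation(self):
        df, _ = simulate_allele_counts(SimConfig(seed=4, ploidy=3))
        kept, _ = pl.load_site_counts(df)
        freqs = pl.alt_frequencies(kept)
        r2_tri = pl.histotest(freqs, 3)[3]
        r2_dip = pl.histotest(freqs, 2)[3]
        assert r2_tri > r2_dip

    def test_empty_histogram_rejected(self):
        with pytest.raises(pl.PloidyError):
            pl.histotest_stats(np.zeros(5), np.zeros(5))


def _report_with(median, deltas, known=None):
    """A minimal hand-built report for decision-rule tests."""
    histo = {p: (1.0, 0.01, 0.1, 0.99) for p in deltas}
    return pl.PloidyFitReport(
        sample="x", n_sites=5000, loglik_fixed={p: -1.0 for p in deltas},
        loglik_free={p: 0.0 for p in deltas}, delta_loglik=deltas,
        histo=histo, median_allele_ratio=median,
        em_iterations={p: (5, 5) for p in deltas},
        converged={p: (True, True) for p in deltas}, known_ploidy=known,
    )


class TestCallPloidy:
    REF_DELTAS = {2: 900.0, 3: 700.0, 4: 1.0}

    def refs(self):
        return [
            _report_with(2.3, self.REF_DELTAS, known=4),
            _report_with(2.8, self.REF_DELTAS, known=4),
        ]

    def test_query_within_band_called(self):
        call = pl.call_ploidy(_report_with(2.5, self.REF_DELTAS), self.refs())
        assert call.call == "tetraploid" and call.ploidy == 4
        assert call.criteria["median_ratio_within_limits"]
        assert call.reference_limits == (2.3, 2.8)

    def test_query_outside_band_criterion_false(self):
        call = pl.call_ploidy(_report_with(1.1, self.REF_DELTAS), self.refs())
        assert not call.criteria["median_ratio_within_limits"]
        assert call.call == "ambiguous"  # delta says tetraploid, median not

    def test_diploid_query_against_tetraploid_references(self):
        dip = {2: 1.0, 3: 700.0, 4: 20.0}
        call = pl.call_ploidy(_report_with(1.1, dip), self.refs())
        assert call.call == "diploid" and call.ploidy == 2

    def test_reference_validation(self):
        with pytest.raises(pl.PloidyError):
            pl.call_ploidy(_report_with(2.5, self.REF_DELTAS), [])
        mixed = [
            _report_with(2.3, self.REF_DELTAS, known=4),
            _report_with(1.2, self.REF_DELTAS, known=2),
        ]
        with pytest.raises(pl.PloidyError):
            pl.call_ploidy(_report_with(2.5, self.REF_DELTAS), mixed)

    def test_simulated_diploid_vs_tetraploid_references(self):
        refs = []
        for seed in (11, 12):
            df, _ = simulate_allele_counts(SimConfig(seed=seed, ploidy=4))
            kept, _ = pl.load_site_counts(df)
            refs.append(pl.ploidy_fit_report(kept, known_ploidy=4))
        dfq, _ = simulate_allele_counts(SimConfig(seed=13, ploidy=2))
        keptq, _ = pl.load_site_counts(dfq)
        query = pl.ploidy_fit_report(keptq)
        call = pl.call_ploidy(query, refs)
        assert call.delta_choice == 2
        assert call.call == "diploid"


def test_histogram_plot_written(tmp_path):
    df, _ = simulate_allele_counts(SimConfig(seed=5, ploidy=4, n_sites=800))
    kept, _ = pl.load_site_counts(df)
    freqs = pl.alt_frequencies(kept)
    fit = pl.fit_mixture(freqs, 4)
    out = tmp_path / "hist.png"
    pl.plot_frequency_histogram(freqs, {4: fit}, out, title="toy")
    assert out.stat().st_size > 0
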