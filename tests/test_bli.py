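"""BLI: segmentation, per-phase fits, pseudo-first-order plot, propagation."""

import numpy as np
import pytest

from nlsbind import datasets
from nlsbind.bli import (
    PhaseSchedule,
    Segment,
    SegmentationError,
    Sensorgram,
    SensorgramKinetics,
    fit_association,
    fit_dissociation,
    propagate_kd,
    pseudo_first_order,
    segment_sensorgram,
)
from nlsbind.synth import NoiseSpec, gen_sensorgram_set, sensorgram_trace


def make_sensorgram(kon=0.068, koff=0.069, conc=5.0, schedule=None, **kw):
    schedule = schedule or PhaseSchedule()
    t, r = sensorgram_trace(kon, koff, 1.0, conc, schedule, **kw)
    return Sensorgram(time=t, response=r, ligand_conc=conc, schedule=schedule)


class TestSchedule:
    def test_default_phase_starts(self):
        s = PhaseSchedule()
        assert s.association_start == 180.0
        assert s.dissociation_start == 300.0
        assert s.total == 420.0

    def test_association_start_is_sum_of_preceding_phases(self):
        s = PhaseSchedule(baseline1_s=60, loading_s=60, baseline2_s=60,
                          association_s=60, dissociation_s=60)
        assert s.association_start == 180.0

    def test_durations_must_be_positive(self):
        with pytest.raises(ValueError):
            PhaseSchedule(loading_s=0)


class TestSegmentation:
    def test_segments_start_at_phase_boundaries(self):
        assoc, dissoc = segment_sensorgram(make_sensorgram())
        assert assoc.t0 == 180.0 and dissoc.t0 == 300.0
        assert assoc.time[0] >= 180.0 and assoc.time[-1] < 300.0
        assert dissoc.time[0] >= 300.0

    def test_truncated_trace_rejected(self):
        s = make_sensorgram()
        short = Sensorgram(time=s.time[s.time <= 250], response=s.response[s.time <= 250],
                           ligand_conc=s.ligand_conc, schedule=s.schedule)
        with pytest.raises(SegmentationError):
            segment_sensorgram(short)


class TestAssociationFit:
    def test_noiseless_exact_recovery(self):
        s = make_sensorgram(conc=3.0)
        assoc, _ = segment_sensorgram(s)
        fit = fit_association(assoc)
        kobs_true = 0.068 * 3.0 + 0.069
        assert fit.converged
        assert fit.kobs == pytest.approx(kobs_true, rel=1e-6)
        req_true = 1.0 * 3.0 / (3.0 + 0.069 / 0.068)
        assert fit.Req == pytest.approx(req_true, rel=1e-6)

    def test_recovery_with_drift(self):
        s = make_sensorgram(conc=5.0, assoc_drift=0.001)
        assoc, _ = segment_sensorgram(s)
        fit = fit_association(assoc)
        assert fit.kobs == pytest.approx(0.068 * 5.0 + 0.069, rel=1e-4)
        assert fit.drift == pytest.approx(0.001, rel=1e-3)

    def test_flat_trace_unidentifiable(self):
        t = np.arange(180.0, 300.0, 0.2)
        fit = fit_association(Segment(t, np.zeros_like(t), 180.0))
        assert not fit.converged
        assert fit.Req == pytest.approx(0.0, abs=1e-12)


class TestDissociationFit:
    def test_noiseless_exact_recovery(self):
        t = np.arange(300.0, 420.2, 0.2)
        r = 0.8 * np.exp(-0.13 * (t - 300.0))
        fit = fit_dissociation(Segment(t, r, 300.0))
        assert fit.converged
        assert fit.R1 == pytest.approx(0.8, rel=1e-6)
        assert fit.koff == pytest.approx(0.13, rel=1e-6)

    def test_recovery_with_drift(self):
        t = np.arange(300.0, 420.2, 0.2)
        r = 0.8 * np.exp(-0.069 * (t - 300.0)) - 5e-4 * (t - 300.0)
        fit = fit_dissociation(Segment(t, r, 300.0))
        assert fit.koff == pytest.approx(0.069, rel=1e-3)

    def test_constant_response_flagged_non_dissociating(self):
        t = np.arange(300.0, 420.2, 0.2)
        fit = fit_dissociation(Segment(t, np.full_like(t, 0.5), 300.0))
        assert fit.no_decay
        assert fit.koff == pytest.approx(0.0, abs=1e-6)


class TestPseudoFirstOrder:
    def test_exact_rates_from_linear_kobs(self):
        # kobs generated exactly as kon·[L] + koff with kon=0.068, koff=0.069
        points = [(1.0, 0.137), (2.0, 0.205), (3.0, 0.273), (5.0, 0.409), (10.0, 0.749)]
        res = pseudo_first_order(points)
        assert res.kon == pytest.approx(0.068, rel=1e-10)
        assert res.koff == pytest.approx(0.069, rel=1e-10)
        assert res.Kd == pytest.approx(0.069 / 0.068, rel=1e-10)
        assert res.intercept_valid

    def test_negative_intercept_voids_kd_but_keeps_kon(self):
        points = [(c, 0.05 * c - 0.02) for c in (1.0, 2.0, 5.0, 10.0)]
        res = pseudo_first_order(points)
        assert not res.intercept_valid
        assert res.Kd is None and res.koff is None
        assert res.kon == pytest.approx(0.05, rel=1e-8)

    def test_constant_kobs_flags_no_association(self):
        res = pseudo_first_order([(1.0, 0.1), (2.0, 0.1), (5.0, 0.1)])
        assert res.no_association

    def test_needs_three_distinct_concentrations(self):
        with pytest.raises(ValueError):
            pseudo_first_order([(1.0, 0.1), (1.0, 0.12), (1.0, 0.14)])


class TestPropagation:
    @pytest.mark.parametrize(
        "kon, kon_se, koff, koff_se, kd, kd_se",
        [
            (0.010, 0.003, 0.13, 0.02, 13.0, 4.38),
            (0.06, 0.01, 0.37, 0.05, 6.17, 1.32),
        ],
    )
    def test_quadrature_examples(self, kon, kon_se, koff, koff_se, kd, kd_se):
        got_kd, got_se = propagate_kd(kon, kon_se, koff, koff_se)
        assert got_kd == pytest.approx(kd, abs=0.01)
        assert got_se == pytest.approx(kd_se, abs=0.01)

    def test_zero_errors_propagate_to_zero(self):
        _, se = propagate_kd(0.05, 0.0, 0.5, 0.0)
        assert se == 0.0

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            propagate_kd(0.0, 0.01, 0.5, 0.05)

    @pytest.mark.parametrize("rel_se", [0.05, 0.15, 0.30])
    def test_quadrature_matches_monte_carlo(self, rel_se):
        """Quadrature SE of koff/kon within 10% of a resampling oracle.

        The oracle is the half-width of the central 68% of resampled ratios,
        which stays finite despite the ratio distribution's heavy tails.
        """
        rng = np.random.default_rng(42)
        kon, koff = 0.05, 0.5
        kon_se, koff_se = rel_se * kon, rel_se * koff
        ratios = (rng.normal(koff, koff_se, size=200_000)
                  / rng.normal(kon, kon_se, size=200_000))
        mc_se = (np.percentile(ratios, 84.135) - np.percentile(ratios, 15.865)) / 2
        _, quad_se = propagate_kd(kon, kon_se, koff, koff_se)
        assert quad_se == pytest.approx(mc_se, rel=0.10)


class TestEndToEnd:
    @pytest.mark.parametrize(
        "peptide, species",
        [
            ("D-NLS-NUPR1phospho", "full"),
            ("D-NLS-NUPR1L", "full"),
            ("D-NLS-PADI", "full"),
            ("D-NLS-NUPR1phospho", "ibb_truncated"),
            ("D-NLS-NUPR1L", "ibb_truncated"),
            ("D-NLS-PADI", "ibb_truncated"),
        ],
    )
    def test_noiseless_pipeline_reproduces_rate_ratio(self, peptide, species):
        """Sensorgram sets built from each reported (kon, koff) pair return
        Kd = koff/kon through the full two-step analysis."""
        kon, koff = datasets.bli_rates(peptide, species)
        sensorgrams = gen_sensorgram_set(kon, koff)
        res = SensorgramKinetics(sensorgrams).fit()
        assert res.intercept_valid
        assert res.kon == pytest.approx(kon, rel=1e-5)
        assert res.koff == pytest.approx(koff, rel=1e-5)
        assert res.Kd == pytest.approx(koff / kon, rel=1e-5)

    def test_steady_state_relation(self):
        """Req/Rmax = [L]/([L]+Kd) holds jointly for generator and fitter."""
        kon, koff = 0.068, 0.069
        kd = koff / kon
        for s in gen_sensorgram_set(kon, koff):
            assoc, _ = segment_sensorgram(s)
            fit = fit_association(assoc)
            expected = s.ligand_conc / (s.ligand_conc + kd)
            assert fit.Req == pytest.approx(expected, rel=1e-6)

    def test_pseudo_first_order_plot_renders(self):
        import matplotlib
        matplotlib.use("Agg")
        model = SensorgramKinetics(gen_sensorgram_set(0.068, 0.069))
        model.fit()
        ax = model.plot()
        assert "kobs" in ax.get_ylabel()

    def test_kobs_linear_in_concentration(self):
        kon, koff = 0.03, 0.2
        for s in gen_sensorgram_set(kon, koff):
            assoc, _ = segment_sensorgram(s)
            fit = fit_association(assoc)
            assert fit.kobs == pytest.approx(kon * s.ligand_conc + koff, rel=1e-6)
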