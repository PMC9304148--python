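"""Cooperative-binding model, Hill fitting, SEC calibration, qPCR."""

import itertools

import numpy as np
import pytest

from carhscan.binding import (
    BindingCurve,
    ExpressionSample,
    ExpressionTable,
    OccupancyConfig,
    RepeatArray,
    SECCalibration,
    call_oligomer,
    enumerate_occupancy,
    fit_hill,
    fraction_bound_from_intensities,
    hill,
    predict_bands,
    predict_footprints,
    relative_expression,
    sec_apparent_mr,
    sec_elution_volume,
)
from carhscan.simulate import EMSA_CONCENTRATIONS_NM, gen_emsa_curve


def brute_force_two_full_configs(n):
    """Independent enumeration of two non-overlapping tandem-pair placements."""
    out = set()
    for a in range(1, n):
        for b in range(a + 2, n):
            out.add(((a, 2), (b, 2)))
    return out


class TestOccupancy:
    def test_four_repeats_unique_double_config(self):
        configs = enumerate_occupancy(
            RepeatArray.from_string("IIII"), max_dimers=2, allow_partial=False
        )
        doubles = [c for c in configs if c.n_full == 2]
        assert len(doubles) == 1
        assert doubles[0].engaged_repeats == (1, 2, 3, 4)

    def test_five_repeats_three_double_configs(self):
        configs = enumerate_occupancy(
            RepeatArray.from_string("IIIII"), max_dimers=2, allow_partial=False
        )
        got = {
            tuple((p.start, p.engaged) for p in c.placements)
            for c in configs if c.n_full == 2
        }
        assert got == {((1, 2), (3, 2)), ((1, 2), (4, 2)), ((2, 2), (4, 2))}
        assert got == brute_force_two_full_configs(5)

    def test_three_repeats_max_one_full(self):
        configs = enumerate_occupancy(
            RepeatArray.from_string("III"), max_dimers=2, allow_partial=False
        )
        assert max(c.n_full for c in configs) == 1

    def test_mutated_repeats_never_engaged(self):
        configs = enumerate_occupancy(RepeatArray.from_string("IMII"), max_dimers=2)
        for c in configs:
            assert 2 not in c.engaged_repeats


class TestBands:
    # probe panel: layouts and their qualitative EMSA outcome
    PANEL = [
        ("IIIII", "double"),   # all five repeats
        ("IIII", "double"),    # dr1-DR4 / DR2-dr5 probes
        ("III", "single_plus_weak_upper"),  # three contiguous repeats
        ("MII", "single"),     # outlying repeat mutated
        ("IIM", "single"),
        ("IMI", "none"),       # central repeat mutated: no tandem pair
    ]

    @pytest.mark.parametrize("layout,category", PANEL)
    def test_probe_panel(self, layout, category):
        assert predict_bands(RepeatArray.from_string(layout)).category == category

    def test_double_band_needs_at_least_four_repeats(self):
        """Exhaustive over all-intact arrays length 1..8, full placements only."""
        for n in range(1, 9):
            pred = predict_bands(RepeatArray((True,) * n))
            assert (pred.category == "double") == (n >= 4), n

    def test_band_category_exhaustive_against_occupancy(self):
        """Category is consistent with brute-force placement counting for all
        intact/mutated layouts up to length 6."""
        for n in range(1, 7):
            for bits in itertools.product([True, False], repeat=n):
                arr = RepeatArray(bits)
                pred = predict_bands(arr)
                pairs = [i for i in range(n - 1) if bits[i] and bits[i + 1]]
                has_pair = bool(pairs)
                has_two_disjoint = any(
                    b >= a + 2 for a in pairs for b in pairs
                )
                if has_two_disjoint:
                    assert pred.category == "double"
                elif not has_pair:
                    assert pred.category == "none"
                else:
                    assert pred.category in ("single", "single_plus_weak_upper")


class TestFootprints:
    def test_two_full_dimers_on_four_repeats(self):
        arr = RepeatArray.from_string("IIII")
        config = [c for c in enumerate_occupancy(arr, 2, allow_partial=False)
                  if c.n_full == 2][0]
        pred = predict_footprints(arr, config)
        assert len(pred.oh_tracts) == 4
        centers = [(a + b) / 2 for a, b in pred.oh_tracts]
        assert np.allclose(np.diff(centers), 11.0)
        # DNase span: 4 repeats (44 bp) + 4 nt margin each side = 52 nt
        lo, hi = pred.dnase_span
        assert hi - lo + 1 == 52
        assert all(lo <= a and b <= hi for a, b in pred.oh_tracts)
        # Exo III stops just outside the bound block
        assert pred.exo3_sense_stop == 44 + 4
        assert pred.exo3_antisense_stop == 1 - 3

    def test_one_full_dimer_two_tracts(self):
        arr = RepeatArray.from_string("III")
        config = [c for c in enumerate_occupancy(arr, 1, allow_partial=False)
                  if c.n_full == 1][0]
        pred = predict_footprints(arr, config)
        assert len(pred.oh_tracts) == 2

    def test_tract_count_is_two_per_full_dimer(self):
        arr = RepeatArray((True,) * 6)
        for config in enumerate_occupancy(arr, 3, allow_partial=False):
            if config.n_full == 0:
                continue
            pred = predict_footprints(arr, config)
            assert len(pred.oh_tracts) == 2 * config.n_full

    def test_engaging_mutated_repeat_errors(self):
        from carhscan.binding import DimerPlacement

        arr = RepeatArray.from_string("IMI")
        bad = OccupancyConfig((DimerPlacement(1, 2),))
        with pytest.raises(ValueError, match="mutated"):
            predict_footprints(arr, bad)


class TestFractionBound:
    @pytest.mark.parametrize("free,expected", [
        (100.0, 0.0), (0.0, 1.0), (25.0, 0.75),
    ])
    def test_arithmetic(self, free, expected):
        f = fraction_bound_from_intensities([free], 100.0)
        assert f[0] == pytest.approx(expected)

    def test_clipping_and_reference_validation(self):
        f = fraction_bound_from_intensities([120.0], 100.0)
        assert f[0] == 0.0
        with pytest.raises(ValueError):
            fraction_bound_from_intensities([1.0], 0.0)


class TestHillFit:
    def test_noise_free_recovery_at_titration_concentrations(self):
        curve = gen_emsa_curve(amplitude=1.0, kd_nm=35.0, hill_h=2.0)
        fit = fit_hill(curve)
        assert fit.converged
        assert fit.kd == pytest.approx(35.0, abs=0.5)

    def test_half_maximal_at_kd(self):
        curve = gen_emsa_curve(amplitude=0.9, kd_nm=20.0, hill_h=1.5)
        fit = fit_hill(curve)
        assert fit.predict([fit.kd])[0] == pytest.approx(fit.amplitude / 2)

    @pytest.mark.parametrize("kd", [5.0, 35.0, 200.0])
    @pytest.mark.parametrize("h", [1.0, 2.0, 3.0])
    def test_recovery_grid_noise_free(self, kd, h):
        """(A, KD, h) recovered to 3 significant figures on clean curves."""
        conc = tuple(np.geomspace(0.1, 1000.0, 12))
        curve = gen_emsa_curve(amplitude=1.0, kd_nm=kd, hill_h=h,
                               concentrations=conc)
        fit = fit_hill(curve)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-3)
        assert fit.kd == pytest.approx(kd, rel=1e-3)
        assert fit.hill_h == pytest.approx(h, rel=1e-3)

    def test_noisy_replicates_median_kd_within_10pct(self):
        kds = []
        for seed in range(200):
            curve = gen_emsa_curve(kd_nm=35.0, hill_h=2.0, noise_sigma=0.03,
                                   seed=seed)
            kds.append(fit_hill(curve).kd)
        assert abs(np.median(kds) - 35.0) / 35.0 < 0.10

    def test_too_few_points_or_flat_curve_rejected(self):
        with pytest.raises(ValueError):
            fit_hill(BindingCurve((1.0, 2.0, 3.0), (0.1, 0.2, 0.3)))
        with pytest.raises(ValueError):
            fit_hill(BindingCurve((1.0, 2.0, 3.0, 4.0), (0.0, 0.0, 0.0, 0.0)))


class TestSEC:
    def test_printed_calibration_point(self):
        # log10 Mr = 8.1537 - 0.2316 * 13.0 -> ~139 kDa
        assert sec_apparent_mr(13.0) == pytest.approx(139.0, abs=0.5)

    def test_strictly_monotone_decreasing(self):
        ve = np.linspace(8.0, 20.0, 200)
        mr = [sec_apparent_mr(v) for v in ve]
        assert all(a > b for a, b in zip(mr, mr[1:]))

    def test_round_trip_identity(self):
        for ve in np.linspace(8.0, 20.0, 50):
            assert sec_elution_volume(sec_apparent_mr(ve)) == pytest.approx(
                ve, abs=1e-9
            )

    def test_inverse_query_for_dimer_mass(self):
        assert sec_elution_volume(59.0) == pytest.approx(14.6, abs=0.05)

    def test_nonpositive_volume_errors(self):
        with pytest.raises(ValueError):
            sec_apparent_mr(-1.0)


class TestOligomerCall:
    @pytest.mark.parametrize("apparent,protomer,n", [
        (59.0, 35.0, 2),   # dark-state dimer
        (31.0, 35.0, 1),   # photolyzed monomer
        (70.0, 35.0, 2),   # exact dimer
    ])
    def test_calls(self, apparent, protomer, n):
        call = call_oligomer(apparent, protomer)
        assert call.n == n

    def test_exact_multiple_within_tolerance(self):
        assert call_oligomer(70.0, 35.0).within_tolerance

    def test_tolerance_flag(self):
        assert not call_oligomer(50.0, 35.0, tol=0.25).within_tolerance


class TestExpression:
    def _table(self, rows, baseline="dark_B12"):
        return ExpressionTable(
            tuple(ExpressionSample(c, t, r) for c, t, r in rows), baseline
        )

    def test_baseline_fold_is_one(self):
        t = self._table([("dark_B12", 22.0, 18.0), ("light", 20.0, 18.0)])
        out = relative_expression(t).set_index("condition")
        assert out.loc["dark_B12", "mean_fold"] == pytest.approx(1.0)

    def test_one_cycle_lower_doubles(self):
        t = self._table([("dark_B12", 22.0, 18.0), ("light", 21.0, 18.0)])
        out = relative_expression(t).set_index("condition")
        assert out.loc["light", "mean_fold"] == pytest.approx(2.0)

    def test_replicates_mean_and_sem(self):
        rows = [("dark_B12", 22.0, 18.0)] + [("light", 20.0, 18.0)] * 3
        out = relative_expression(self._table(rows)).set_index("condition")
        assert out.loc["light", "mean_fold"] == pytest.approx(4.0)
        assert out.loc["light", "sem"] == pytest.approx(0.0)

    def test_missing_baseline_errors(self):
        with pytest.raises(ValueError, match="baseline"):
            self._table([("light", 20.0, 18.0)])
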