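"""Richardson extrapolation and grid-convergence index arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aerocath.gci import (
    MeshLevel,
    asymptotic_ratio,
    gci,
    grid_convergence_report,
    observed_order,
    per_level_errors,
    richardson_extrapolate,
)
from aerocath.synthetic import generate_mesh_series

# The three-mesh axial-velocity study: fine, medium, coarse [m/s].
V1, V2, V3 = 9.58, 9.41, 8.92


class TestObservedOrder:
    def test_study_value(self):
        assert observed_order(V1, V2, V3, 2.0) == pytest.approx(1.5273, abs=1e-3)

    def test_exact_second_order_data(self):
        v0, C = 3.0, 0.25
        v = [v0 + C * h**2 for h in (1, 2, 4)]
        assert observed_order(*v, 2.0) == pytest.approx(2.0, abs=1e-10)

    def test_converged_pair_rejected(self):
        with pytest.raises(ValueError, match="converged"):
            observed_order(9.5, 9.5, 9.0)

    def test_oscillatory_convergence_rejected(self):
        with pytest.raises(ValueError, match="oscillatory"):
            observed_order(9.5, 9.6, 9.4)


class TestRichardsonExtrapolation:
    def test_study_value(self):
        p = observed_order(V1, V2, V3, 2.0)
        assert richardson_extrapolate(V1, V2, 2.0, p) == pytest.approx(9.67, abs=0.005)

    def test_converged_limit(self):
        assert richardson_extrapolate(5.0, 5.0, 2.0, 2.0) == 5.0

    def test_exact_recovery_of_constructed_limit(self):
        v0, C, p = 7.31, -0.42, 1.7
        v = [v0 + C * h**p for h in (1, 2)]
        assert richardson_extrapolate(v[0], v[1], 2.0, p) == pytest.approx(v0, abs=1e-10)

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            richardson_extrapolate(9.5, 9.4, 1.0, 2.0)


class TestGCI:
    def test_coarse_pair_value(self):
        p = observed_order(V1, V2, V3, 2.0)
        assert gci(V2, V3, 2.0, p) == pytest.approx(3.65, abs=0.01)

    def test_fine_pair_value(self):
        # Coarse-normalization convention gives 1.20 here.
        p = observed_order(V1, V2, V3, 2.0)
        assert gci(V1, V2, 2.0, p) == pytest.approx(1.20, abs=0.01)

    def test_grid_independent_solution(self):
        assert gci(5.0, 5.0, 2.0, 2.0) == 0.0


class TestAsymptoticRatio:
    def test_study_value_end_to_end(self):
        p = observed_order(V1, V2, V3, 2.0)
        ratio = asymptotic_ratio(gci(V2, V3, 2.0, p), gci(V1, V2, 2.0, p), 2.0, p)
        assert ratio == pytest.approx(1.05, abs=0.01)

    def test_exact_order_data_limit(self):
        """For exact p-th-order data the coarse-normalized ratio equals
        v2/v3 identically, hence tends to 1 as the grid-to-grid change
        becomes small relative to the solution value."""
        v0, p = 2.0, 1.6
        for C in (0.3, 0.01, 1e-4):
            v = [v0 + C * h**p for h in (1, 2, 4)]
            p_obs = observed_order(*v, 2.0)
            ratio = asymptotic_ratio(
                gci(v[1], v[2], 2.0, p_obs), gci(v[0], v[1], 2.0, p_obs), 2.0, p_obs
            )
            assert ratio == pytest.approx(v[1] / v[2], rel=1e-10)
        assert ratio == pytest.approx(1.0, abs=1e-3)  # small-change limit

    def test_strictly_decreasing_in_p(self):
        ratios = [asymptotic_ratio(3.0, 1.0, 2.0, p) for p in (1.0, 1.5, 2.0, 3.0)]
        assert np.all(np.diff(ratios) < 0)

    def test_zero_gci12_rejected(self):
        with pytest.raises(ValueError):
            asymptotic_ratio(3.0, 0.0, 2.0, 2.0)


class TestPerLevelErrors:
    def test_study_values(self):
        errs = per_level_errors((V1, V2, V3), 9.6703125)
        assert errs[0] == pytest.approx(0.93, abs=0.01)
        assert errs[1] == pytest.approx(2.69, abs=0.01)
        assert errs[2] == pytest.approx(7.76, abs=0.01)

    def test_exact_value_gives_zero(self):
        assert per_level_errors([9.67], 9.67) == [0.0]

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            per_level_errors([1.0], 0.0)


class TestFullReport:
    def test_levels_sorted_by_cell_count(self):
        levels = [
            MeshLevel("M3", 98_854, V3),
            MeshLevel("M1", 404_620, V1),
            MeshLevel("M2", 196_107, V2),
        ]
        rep = grid_convergence_report(levels)
        assert rep.extrapolated_value == pytest.approx(9.67, abs=0.005)
        assert rep.asymptotic_ratio == pytest.approx(1.05, abs=0.01)
        assert rep.in_asymptotic_range

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        p=st.floats(min_value=0.5, max_value=4.0),
        r=st.floats(min_value=1.2, max_value=4.0),
        v0=st.floats(min_value=-50, max_value=50),
        C=st.floats(min_value=0.1, max_value=5.0),
    )
    def test_recovers_constructed_order_and_limit(self, p, r, v0, C):
        v = [v0 + C * (r**i) ** p for i in range(3)]
        if abs(v0) < 0.1 or abs(v[1]) < 1e-3 or abs(v[2]) < 1e-3:
            return  # normalizations are undefined near a zero solution
        rep = grid_convergence_report(tuple(v), r=r)
        assert rep.observed_order_p == pytest.approx(p, rel=1e-7)
        assert rep.extrapolated_value == pytest.approx(v0, rel=1e-6, abs=1e-7)
        # Coarse-normalized asymptotic ratio is exactly |v2/v3| here.
        assert rep.asymptotic_ratio == pytest.approx(abs(v[1] / v[2]), rel=1e-7)


class TestSyntheticMeshSeries:
    def test_noise_free_series_inverts_the_study(self):
        # Parameters chosen to regenerate the three reference velocities.
        p = observed_order(V1, V2, V3, 2.0)
        v0 = richardson_extrapolate(V1, V2, 2.0, p)
        levels = generate_mesh_series(v0=v0, C=V1 - v0, p=p, r=2.0, n_levels=3)
        values = [round(m.observable_value, 2) for m in levels]
        assert values == [V1, V2, V3]

    def test_noise_free_recovery(self):
        levels = generate_mesh_series(v0=4.0, C=0.5, p=1.8, r=2.0, n_levels=3)
        rep = grid_convergence_report(levels)
        assert rep.observed_order_p == pytest.approx(1.8, abs=1e-9)

    def test_noisy_order_estimates_center_on_truth(self):
        ps = []
        for seed in range(100):
            levels = generate_mesh_series(
                v0=9.67, C=-0.09, p=1.53, r=2.0, n_levels=3, noise_sd=0.002, seed=seed
            )
            v = [m.observable_value for m in levels]
            try:
                ps.append(observed_order(*v, 2.0))
            except ValueError:
                continue  # noise occasionally breaks monotonicity
        assert len(ps) > 60
        assert np.mean(ps) == pytest.approx(1.53, abs=0.15)
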