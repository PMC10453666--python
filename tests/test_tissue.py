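"""Extravascular diffusion-reaction dynamics and fibrosis adsorption."""

import numpy as np
import pytest

from coroperf.fixtures import micro_domain
from coroperf.tissue_transport import (
    TissueParams,
    TissueState,
    roi_signal,
    step_fibrosis,
    step_tissue,
    step_tissue_and_fibrosis,
)
from coroperf.tree_transport import CFLError


def make_state(**params):
    return TissueState(domain=micro_domain(), params=TissueParams(**params))


class TestParams:
    @pytest.mark.parametrize(
        "kw", [{"phi": 0.0}, {"phi": 1.0}, {"lam": 0.0}, {"lam_f": 1.5}]
    )
    def test_invalid_fractions_rejected(self, kw):
        with pytest.raises(ValueError):
            TissueParams(**kw)


class TestStepTissue:
    def test_uniform_state_is_steady(self):
        state = make_state(k_e=0.0)
        state.Ce[:] = 0.4
        step_tissue(state, None, dt=0.5 * state.cfl_dt())
        assert np.allclose(state.Ce, 0.4, rtol=1e-14)

    def test_venous_clearance_matches_closed_form(self):
        """No diffusion, no sources: Ce decays like (1 - ke dt)^n, which
        approaches exp(-ke t); compare over 100 steps."""
        state = make_state(k_e=0.007, diffusion=0.0)
        state.Ce[:] = 1.0
        dt = 0.1
        for _ in range(100):
            step_tissue(state, None, dt=dt)
        expected = (1.0 - 0.007 * dt) ** 100
        assert np.allclose(state.Ce, expected, rtol=1e-12)
        assert expected == pytest.approx(np.exp(-0.007 * dt * 100), rel=2e-4)

    def test_point_source_budget(self):
        """A single-cell source on a reflective all-masked grid grows the
        total extravascular mass by exactly the injected mass per step."""
        state = make_state(k_e=0.0)
        dt = 0.5 * state.cfl_dt()
        injected = 1e-3
        src = np.zeros(state.domain.grid_shape)
        src[4, 5] = injected
        masses = [state.extravascular_mass()]
        for _ in range(50):
            step_tissue(state, src, dt=dt)
            masses.append(state.extravascular_mass())
        steps = np.diff(masses)
        assert np.allclose(steps, injected, rtol=1e-12)

    def test_tuple_source_equals_grid_source(self):
        s1 = make_state(k_e=0.0)
        s2 = make_state(k_e=0.0)
        dt = 0.5 * s1.cfl_dt()
        grid = np.zeros(s1.domain.grid_shape)
        grid[2, 3] = 0.5
        step_tissue(s1, grid, dt=dt)
        step_tissue(s2, (np.array([2]), np.array([3]), np.array([0.5])), dt=dt)
        assert np.array_equal(s1.Ce, s2.Ce)

    def test_cfl_violation_raises(self):
        state = make_state()
        with pytest.raises(CFLError):
            step_tissue(state, None, dt=10.0 * state.cfl_dt())

    def test_mass_conserved_by_pure_diffusion(self):
        state = make_state(k_e=0.0)
        rng = np.random.default_rng(2)
        state.Ce[:] = rng.random(state.domain.grid_shape)
        std0 = state.Ce.std()
        m0 = state.extravascular_mass()
        dt = 0.9 * state.cfl_dt()
        for _ in range(100):
            step_tissue(state, None, dt=dt)
            assert abs(state.extravascular_mass() - m0) < 1e-10 * m0
        # diffusion also smooths toward the mean
        assert state.Ce.std() < std0


class TestFibrosis:
    def fibrotic_state(self, **overrides):
        dom = micro_domain()
        dom.fibrosis_mask = np.zeros(dom.grid_shape, dtype=bool)
        dom.fibrosis_mask[4:6, 4:6] = True
        kw = dict(lam=1.0, lam_f=0.5, k_e=0.0, k_f=0.0, k_ef=0.01, diffusion=0.0)
        kw.update(overrides)
        return TissueState(domain=dom, params=TissueParams(**kw))

    def test_no_adsorption_keeps_cf_constant(self):
        state = self.fibrotic_state(k_ef=0.0)
        state.Cf[state.domain.fibrosis_mask] = 0.3
        step_fibrosis(state, dt=0.1)
        assert np.allclose(state.Cf[state.domain.fibrosis_mask], 0.3)

    def test_two_compartment_exchange_conserves_mass(self):
        """k_f = k_e = De = 0: the volume-weighted mass of Ce + Cf is
        constant while Cf rises monotonically (adsorption trap),
        matching the closed-form two-compartment exchange at rate k_ef."""
        state = self.fibrotic_state()
        fib = state.domain.fibrosis_mask
        state.Ce[fib] = 1.0
        dt = 0.25
        total0 = state.extravascular_mass() + state.fibrotic_mass()
        cf_prev = 0.0
        for n in range(1, 201):
            step_tissue_and_fibrosis(state, None, dt=dt, check_cfl=False)
            total = state.extravascular_mass() + state.fibrotic_mass()
            assert total == pytest.approx(total0, rel=1e-12)
            cf = state.Cf[fib].mean()
            assert cf > cf_prev
            cf_prev = cf
        # discrete closed form: Ce decays by (1 - lam_f k_ef dt)^n
        lam_f, k_ef = state.params.lam_f, state.params.k_ef
        assert state.Ce[fib].mean() == pytest.approx(
            (1 - lam_f * k_ef * dt) ** 200, rel=1e-10
        )

    def test_healthy_rows_leave_cf_zero(self):
        """lam_f = 0, k_ef = 0 (healthy/ischemia parameter rows): the
        fibrotic compartment never charges."""
        state = make_state(lam_f=0.0, k_ef=0.0)
        state.Ce[:] = 1.0
        for _ in range(50):
            step_tissue_and_fibrosis(state, None, dt=0.5 * state.cfl_dt())
        assert not state.Cf.any()

    def test_empty_mask_warns(self):
        state = make_state()
        with pytest.warns(UserWarning):
            step_fibrosis(state, dt=0.1)


class TestRoiSignal:
    def test_uniform_value(self):
        state = make_state()
        state.Ce[:] = 0.8
        roi = np.zeros(state.domain.grid_shape, dtype=bool)
        roi[:3, :3] = True
        assert roi_signal(state, roi) == pytest.approx(0.8)

    def test_union_mean_is_count_weighted(self):
        state = make_state()
        rng = np.random.default_rng(4)
        state.Ce[:] = rng.random(state.domain.grid_shape)
        a = np.zeros_like(state.domain.mask)
        b = np.zeros_like(state.domain.mask)
        a[:2, :] = True
        b[5:6, :] = True
        na, nb = a.sum(), b.sum()
        merged = (na * roi_signal(state, a) + nb * roi_signal(state, b)) / (na + nb)
        assert roi_signal(state, a | b) == pytest.approx(merged, rel=1e-12)

    def test_empty_roi_rejected(self):
        state = make_state()
        with pytest.raises(ValueError):
            roi_signal(state, np.zeros(state.domain.grid_shape, dtype=bool))

    def test_fibrosis_weighted_variant(self):
        state = make_state(lam=1.0, lam_f=0.5)
        roi = np.zeros(state.domain.grid_shape, dtype=bool)
        roi[0, 0] = True
        state.Ce[0, 0] = 1.0
        state.Cf[0, 0] = 2.0
        assert roi_signal(state, roi, include_fibrosis=True) == pytest.approx(2.0)
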