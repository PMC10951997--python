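import numpy as np
import pytest

from oslet.scoring import (
    FieldMaps,
    combine_fields,
    estimate_uncertainty,
    roi_statistics,
    score_field,
    total_deposited_energy_mev,
)
from oslet.transport import BeamField, StepLog, transport_field

from conftest import water_box


def _manual_log(vox, dE, dx, n_hist=1, shape=(4, 4, 4)):
    n = len(vox)
    return StepLog(field_id=0,
                   history=np.zeros(n, dtype=np.int32),
                   vox=np.asarray(vox, dtype=np.int32),
                   dE=np.asarray(dE, dtype=np.float32),
                   dx=np.asarray(dx, dtype=np.float32),
                   spot=np.zeros(n_hist, dtype=np.int32),
                   e0=np.full(n_hist, float(np.sum(dE))),
                   e_exit=np.zeros(n_hist),
                   total_weight=float(n_hist), grid_shape=shape)


class TestScoreField:
    def test_single_step_let(self):
        """1 MeV over 1 mm in water: dE/dx = 10 MeV/cm = 1 keV/um."""
        ph = water_box(shape=(4, 4, 4), spacing=2.0)
        log = _manual_log([0], [1.0], [0.1], shape=ph.shape)
        maps = score_field(log, ph)
        assert maps.let_d.reshape(-1)[0] == pytest.approx(1.0, rel=1e-6)

    def test_two_step_dose_average(self):
        """Steps with (dE, dE/dx) = (1,2) and (3,4): dose-average 3.5 MeV/cm."""
        ph = water_box(shape=(4, 4, 4), spacing=2.0)
        log = _manual_log([5, 5], [1.0, 3.0], [0.5, 0.75], shape=ph.shape)
        maps = score_field(log, ph)
        assert maps.let_d.reshape(-1)[5] == pytest.approx(0.35, rel=1e-5)  # keV/um

    def test_dose_unit_conversion(self):
        ph = water_box(shape=(4, 4, 4), spacing=2.0)
        log = _manual_log([0], [10.0], [0.1], shape=ph.shape)
        maps = score_field(log, ph)
        # 10 MeV into a 8e-3 cm3 voxel of water
        assert maps.dose.reshape(-1)[0] == pytest.approx(10 * 1.602176634e-10 / 8e-3)

    def test_let_undefined_where_no_dose(self):
        ph = water_box(shape=(4, 4, 4))
        log = _manual_log([0], [1.0], [0.1], shape=ph.shape)
        maps = score_field(log, ph)
        assert np.isnan(maps.let_d.reshape(-1)[1])

    def test_empty_log_rejected(self, model):
        ph = water_box(shape=(4, 4, 4))
        log = _manual_log([], [], [])
        with pytest.raises(ValueError):
            score_field(log, ph)

    def test_let_matches_stopping_power_proximally(self, quiet_model):
        """Monoenergetic beam: scored LET_D at depth tracks the analytic
        stopping power over the proximal 80% of the range."""
        from oslet.transport import csda_range, energy_from_range, stopping_power

        ph = water_box(shape=(16, 50, 16), spacing=2.0)
        center = np.array(ph.shape) * ph.spacing / 2
        beam = BeamField(0.0, center, spot_energy=[90.0], spot_u=[0.0], spot_v=[0.0],
                        spot_weight=[1.0], spot_sigma=[0.0])
        log, _ = transport_field(ph, beam, 100, seed=8, model=quiet_model)
        maps = score_field(log, ph)
        r0 = csda_range(90.0, model=quiet_model)
        i, k = ph.shape[0] // 2, ph.shape[2] // 2
        for j in range(2, ph.shape[1]):
            z = (j + 0.5) * 0.2  # cm, depth at distal voxel face
            if z > 0.8 * r0:
                break
            e_z = energy_from_range(r0 - (j + 0.5) * 0.2, model=quiet_model)
            expected = 0.1 * stopping_power(e_z, model=quiet_model)
            assert maps.let_d[i, j, k] == pytest.approx(expected, rel=0.05)


class TestCombineFields:
    def _maps(self, let, dose, shape=(2, 2, 2)):
        d = np.full(shape, float(dose))
        l = np.full(shape, float(let))
        return FieldMaps(dose=d, let_d=l, n_histories=1)

    def test_equal_weight_combination(self):
        c = combine_fields([self._maps(2, 1), self._maps(4, 1)])
        assert np.allclose(c.let_d, 3.0)
        assert np.allclose(c.dose, 2.0)

    def test_dose_weighted_combination(self):
        c = combine_fields([self._maps(2, 1), self._maps(4, 3)])
        assert np.allclose(c.let_d, 3.5)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_fields([self._maps(2, 1), self._maps(2, 1, shape=(3, 3, 3))])

    def test_pooled_scoring_identity(self, model):
        """combine_fields of per-field scorings equals score_field on the
        pooled StepLog -- the central algebraic identity of the two scoring
        equations."""
        ph = water_box(shape=(24, 40, 24))
        center = np.array(ph.shape) * ph.spacing / 2
        logs = []
        for ang, e in ((-20.0, 90.0), (0.0, 95.0), (20.0, 100.0)):
            beam = BeamField(ang, center, spot_energy=[e], spot_u=[0.0], spot_v=[0.0],
                            spot_weight=[1.0], spot_sigma=[3.0])
            log, _ = transport_field(ph, beam, 400, seed=int(e), model=model)
            logs.append(log)
        combined = combine_fields([score_field(lg, ph) for lg in logs])
        pooled = StepLog(
            field_id=0,
            history=np.concatenate([lg.history + 1000 * i for i, lg in enumerate(logs)]),
            vox=np.concatenate([lg.vox for lg in logs]),
            dE=np.concatenate([lg.dE for lg in logs]),
            dx=np.concatenate([lg.dx for lg in logs]),
            spot=np.concatenate([lg.spot for lg in logs]),
            e0=np.concatenate([lg.e0 for lg in logs]),
            e_exit=np.concatenate([lg.e_exit for lg in logs]),
            total_weight=3.0, grid_shape=ph.shape)
        direct = score_field(pooled, ph)
        both = np.isfinite(combined.let_d) & np.isfinite(direct.let_d)
        assert np.isfinite(combined.let_d).sum() == np.isfinite(direct.let_d).sum()
        rel = np.abs(combined.let_d[both] - direct.let_d[both]) / direct.let_d[both]
        assert rel.max() < 1e-10
        # identical per-proton normalization: weight 1 per 400 histories per field
        rel_d = np.abs(combined.dose - direct.dose) / np.where(direct.dose > 0, direct.dose, 1)
        assert np.nanmax(rel_d) < 1e-10

    def test_combined_let_within_field_envelope(self, model):
        ph = water_box(shape=(24, 40, 24))
        center = np.array(ph.shape) * ph.spacing / 2
        fields = []
        for ang, e in ((-20.0, 85.0), (20.0, 100.0)):
            beam = BeamField(ang, center, spot_energy=[e], spot_u=[0.0], spot_v=[0.0],
                            spot_weight=[1.0], spot_sigma=[4.0])
            log, _ = transport_field(ph, beam, 500, seed=21, model=model)
            fields.append(score_field(log, ph))
        c = combine_fields(fields)
        ok = np.isfinite(c.let_d)
        lets = np.stack([f.let_d for f in fields])[:, ok]
        lo = np.nanmin(lets, axis=0)
        hi = np.nanmax(lets, axis=0)
        assert np.all(c.let_d[ok] >= lo - 1e-9)
        assert np.all(c.let_d[ok] <= hi + 1e-9)

    def test_total_energy_bookkeeping(self, model):
        ph = water_box(shape=(20, 50, 20))
        center = np.array(ph.shape) * ph.spacing / 2
        beam = BeamField(0.0, center, spot_energy=[95.0], spot_u=[0.0], spot_v=[0.0],
                        spot_weight=[1.0], spot_sigma=[2.0])
        log, _ = transport_field(ph, beam, 300, seed=6, model=model)
        maps = score_field(log, ph)
        scored = total_deposited_energy_mev(maps, ph) * log.n_histories / log.total_weight
        assert scored == pytest.approx(float(log.dE.astype(np.float64).sum()), rel=1e-6)


class TestUncertainty:
    def _log(self, model):
        ph = water_box(shape=(16, 40, 16))
        center = np.array(ph.shape) * ph.spacing / 2
        beam = BeamField(0.0, center, spot_energy=[90.0], spot_u=[0.0], spot_v=[0.0],
                        spot_weight=[1.0], spot_sigma=[3.0])
        log, _ = transport_field(ph, beam, 1000, seed=11, model=model)
        return ph, log

    def test_duplication_leaves_batch_means_unchanged(self, model):
        import dataclasses

        ph, log = self._log(model)
        rel1, _ = estimate_uncertainty(log, ph, n_batches=5)
        dup = dataclasses.replace(
            log,
            history=np.concatenate([log.history, log.history]),
            vox=np.concatenate([log.vox, log.vox]),
            dE=np.concatenate([log.dE, log.dE]),
            dx=np.concatenate([log.dx, log.dx]))
        rel2, _ = estimate_uncertainty(dup, ph, n_batches=5)
        ok = np.isfinite(rel1)
        assert np.allclose(rel1[ok], rel2[ok])  # relative SD is scale-free

    def test_zero_variance_gives_zero(self):
        ph = water_box(shape=(4, 4, 4))
        n = 10
        log = StepLog(field_id=0, history=np.arange(n, dtype=np.int32),
                      vox=np.zeros(n, dtype=np.int32), dE=np.ones(n, dtype=np.float32),
                      dx=np.full(n, 0.1, dtype=np.float32),
                      spot=np.zeros(n, dtype=np.int32), e0=np.ones(n), e_exit=np.zeros(n),
                      total_weight=float(n), grid_shape=ph.shape)
        rel, _ = estimate_uncertainty(log, ph, n_batches=5)
        assert rel.reshape(-1)[0] == 0.0

    def test_scaling_with_histories(self, model):
        """Quadrupling histories roughly halves the mean relative SD."""
        ph = water_box(shape=(16, 40, 16))
        center = np.array(ph.shape) * ph.spacing / 2
        beam = BeamField(0.0, center, spot_energy=[90.0], spot_u=[0.0], spot_v=[0.0],
                        spot_weight=[1.0], spot_sigma=[3.0])
        mask = np.zeros(ph.shape, dtype=bool)
        mask[6:10, 10:16, 6:10] = True
        means = []
        for n in (1000, 4000):
            log, _ = transport_field(ph, beam, n, seed=13, model=model)
            _, m = estimate_uncertainty(log, ph, n_batches=10, mask=mask)
            means.append(m)
        ratio = means[0] / means[1]
        assert 2.0 * 0.7 < ratio < 2.0 * 1.3

    def test_validation(self, model):
        ph, log = self._log(model)
        with pytest.raises(ValueError):
            estimate_uncertainty(log, ph, n_batches=3)


class TestRoiStatistics:
    def test_mean_and_population_sd(self):
        ph = water_box(shape=(3, 3, 3))
        vals = np.zeros(ph.shape)
        vals[0, 0, 0], vals[1, 0, 0], vals[2, 0, 0] = 1.0, 2.0, 3.0
        mask = np.zeros(ph.shape, dtype=bool)
        mask[:, 0, 0] = True
        st = roi_statistics(vals, mask, ph)
        assert st.mean == pytest.approx(2.0)
        assert st.sd == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_uniform_sd_zero(self):
        ph = water_box(shape=(3, 3, 3))
        st = roi_statistics(np.full(ph.shape, 5.0), np.ones(ph.shape, dtype=bool), ph)
        assert st.sd == 0.0

    def test_com_of_symmetric_disk(self, phantom):
        lay = phantom.osld_layout
        st = roi_statistics(np.ones(phantom.shape), phantom.masks["osld_roi"], phantom)
        assert np.linalg.norm(st.center_of_mass_mm[:2] - lay.centers[0][:2]) < 0.1 * 2.0

    def test_empty_mask_rejected(self):
        ph = water_box(shape=(3, 3, 3))
        with pytest.raises(ValueError):
            roi_statistics(np.ones(ph.shape), np.zeros(ph.shape, dtype=bool), ph)
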