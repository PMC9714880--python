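"""Model wiring: field sizes, stimulus encoding, reach drive, pause routing,
and the architectural invariants (fixed point, symmetry, pause monotonicity)."""

import numpy as np
import pytest

from actionreg import build_architecture
from actionreg.architecture import (GroupTaskParams, PAUSE_SLICES,
                                    StimulusDrive, count_bumps, encode_stimuli,
                                    pause_routing, reach_drive)
from actionreg.config import SimConfig
from actionreg.control import rhc_execute
from actionreg.errors import ConfigurationError, InvalidParameterError, WiringError
from actionreg.tasks import TrialSpec, build_timeline

LABELS = np.linspace(0.0, 180.0, 181)


def _noise_free(**overrides) -> SimConfig:
    cfg = SimConfig(**overrides)
    cfg.fields["reach_planning"].noise_sigma = 0.0
    return cfg


class TestBuild:
    def test_default_fields_and_sizes(self, cfg):
        arch = build_architecture(cfg)
        sizes = {name: spec.n_neurons for name, spec in arch.specs.items()}
        assert sizes == {"spatial_sensory": 181, "expected_outcome": 181,
                         "reach_planning": 181, "stop_context": 100,
                         "conflict_context": 100, "pause": 225}
        assert {s.start for s in PAUSE_SLICES.values()} == {0, 75, 150}
        report = arch.validation_report()
        assert sum("field " in line for line in report) == 6
        assert sum("projection " in line for line in report) == 6

    def test_mismatched_one_to_one_is_wiring_error(self, cfg):
        from actionreg.fields import Projection
        arch = build_architecture(cfg)
        arch.projections.append(
            Projection("stop_context", "reach_planning", "one_to_one", 1.0))
        with pytest.raises(WiringError):
            arch._validate()

    def test_unknown_group_rejected(self, cfg):
        with pytest.raises(ConfigurationError):
            GroupTaskParams.from_config(cfg, "martian", "decision")

    def test_rest_is_architecture_fixed_point(self):
        """500 ms with no stimuli and noise off leaves every field within
        1e-6 of its resting level."""
        cfg = _noise_free()
        arch = build_architecture(cfg)
        gt = GroupTaskParams.from_config(cfg, "neurotypical", "decision")
        zero = np.zeros(181)
        for _ in range(500):
            arch.step(zero, zero, 0.0, 0.0, gt, dt=cfg.dt_ms, rngs={})
        for name, spec in arch.specs.items():
            assert np.max(np.abs(arch.states[name].u - spec.h)) < 1e-6, name


class TestStimuli:
    def test_single_target_unimodal(self):
        drive = StimulusDrive((0.0,), 0.0, 100.0, amplitude=8.0, width=10.0)
        bump = encode_stimuli([drive], LABELS).at(50.0)
        assert np.argmax(bump) == 0
        assert count_bumps(bump / bump.max(), 0.5) == 1

    def test_choice_trial_bimodal_and_mirror_symmetric(self):
        drive = StimulusDrive((0.0, 180.0), 0.0, 100.0, amplitude=8.0, width=10.0)
        bump = encode_stimuli([drive], LABELS).at(0.0)
        assert np.allclose(bump, bump[::-1])
        assert count_bumps(bump / bump.max(), 0.5) == 2

    def test_inactive_outside_window(self):
        drive = StimulusDrive((90.0,), 100.0, 200.0, amplitude=8.0, width=10.0)
        tl = encode_stimuli([drive], LABELS)
        assert np.all(tl.at(99.9) == 0.0)
        assert np.all(tl.at(200.0) == 0.0)
        assert tl.at(100.0).max() > 0

    def test_zero_amplitude_gives_zero_drive(self):
        drive = StimulusDrive((90.0,), 0.0, 100.0, amplitude=0.0, width=10.0)
        assert np.all(encode_stimuli([drive], LABELS).at(50.0) == 0.0)

    def test_direction_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            StimulusDrive((200.0,), 0.0, 100.0, amplitude=8.0, width=10.0)


class TestReachDrive:
    GAINS = {"eta_pos": 1.0, "eta_reward": 0.5, "eta_pau": 0.3}

    def test_zero_inputs_zero_output(self):
        out = reach_drive(np.zeros(181), np.zeros(181), 0.0, self.GAINS)
        assert np.all(out == 0.0)

    def test_weighted_sum_matches_hand_computation(self):
        v_pos = np.full(181, 0.8)
        v_reward = np.full(181, 0.4)
        out = reach_drive(v_pos, v_reward, 2.0, self.GAINS)
        assert np.allclose(out, 1.0 * 0.8 + 0.5 * 0.4 - 0.3 * 2.0)

    def test_pause_term_strictly_inhibitory(self):
        v = np.full(181, 0.5)
        low = reach_drive(v, v, 1.0, self.GAINS)
        high = reach_drive(v, v, 1.0, {**self.GAINS, "eta_pau": 0.6})
        assert np.all(high < low)

    def test_size_mismatch_is_wiring_error(self):
        with pytest.raises(WiringError):
            reach_drive(np.zeros(181), np.zeros(100), 0.0, self.GAINS)


class TestPauseRouting:
    def _outputs(self, n_bumps):
        out = np.zeros(181)
        if n_bumps >= 1:
            out[5:15] = 0.9
        if n_bumps >= 2:
            out[165:175] = 0.9
        return out

    def test_single_target_selection_tonic_only(self, cfg):
        gt = GroupTaskParams.from_config(cfg, "neurotypical", "decision")
        drive = pause_routing(self._outputs(1), np.zeros(100), np.zeros(100), gt, cfg)
        assert np.all(drive[PAUSE_SLICES["selection"]] == 0.0)

    def test_two_targets_trigger_selection_subpopulation(self, cfg):
        gt = GroupTaskParams.from_config(cfg, "neurotypical", "decision")
        drive = pause_routing(self._outputs(2), np.zeros(100), np.zeros(100), gt, cfg)
        assert np.all(drive[PAUSE_SLICES["selection"]] > 0.0)
        assert np.all(drive[PAUSE_SLICES["conflict"]] == 0.0)

    def test_context_fields_route_to_their_subpopulations(self, cfg):
        gt = GroupTaskParams.from_config(cfg, "neurotypical", "stop_signal")
        drive = pause_routing(self._outputs(1), np.full(100, 0.9),
                              np.full(100, 0.9), gt, cfg)
        assert np.all(drive[PAUSE_SLICES["conflict"]] > 0.0)
        assert np.all(drive[PAUSE_SLICES["stop"]] > gt.pause_tonic["stop"])

    def test_pd_decision_tonic_exceeds_neurotypical(self, cfg):
        nt = cfg.tonic_for("neurotypical", "decision")
        pd = cfg.tonic_for("pd", "decision")
        assert pd["selection"] > nt["selection"]
        nt_f = cfg.tonic_for("neurotypical", "flanker")
        pd_f = cfg.tonic_for("pd", "flanker")
        assert pd_f["conflict"] > nt_f["conflict"]

    def test_neurotypical_stop_tonic_exceeds_pd(self, cfg):
        assert (cfg.tonic_for("neurotypical", "stop_signal")["stop"]
                > cfg.tonic_for("pd", "stop_signal")["stop"])


def _first_crossing(cfg, trial, group="neurotypical", pause_clamp=False):
    arch = build_architecture(cfg)
    gt = GroupTaskParams.from_config(cfg, group, trial.task)
    tl = build_timeline(trial, cfg, ssd=trial.ssd)
    res = rhc_execute(arch, tl, gt, cfg, master_seed=0, pause_clamp=pause_clamp)
    return res.events["t_cross"], res


class TestInvariants:
    def test_pause_clamp_speeds_choice_threshold_crossing(self):
        """With the pause output clamped to zero, choice-trial reach activity
        crosses the initiation threshold earlier (noise off)."""
        cfg = _noise_free()
        trial = TrialSpec("decision", "choice", "right")
        t_clamped, _ = _first_crossing(cfg, trial, pause_clamp=True)
        t_free, _ = _first_crossing(cfg, trial, pause_clamp=False)
        assert t_clamped is not None
        assert t_free is None or t_clamped < t_free

    def test_reflection_symmetry(self):
        """Mirroring the stimulus mirrors the reach trajectory (noise off)."""
        cfg = _noise_free()
        _, res_r = _first_crossing(cfg, TrialSpec("decision", "instructed", "right"))
        _, res_l = _first_crossing(cfg, TrialSpec("decision", "instructed", "left"))
        n = min(len(res_r.times), len(res_l.times))
        assert np.allclose(res_r.positions[:n, 0], -res_l.positions[:n, 0], atol=1e-9)
        assert np.allclose(res_r.positions[:n, 1], res_l.positions[:n, 1], atol=1e-9)

    def test_pause_gain_monotone_in_rt(self):
        """Increasing eta_pau never decreases the simulated RT (noise off,
        instructed go trials where the pause is tonically active)."""
        crossings = []
        for eta in (0.0, 0.035, 0.05):
            cfg = _noise_free(eta_pau=eta)
            trial = TrialSpec("stop_signal", "go", "right")
            t_cross, _ = _first_crossing(cfg, trial)
            crossings.append(np.inf if t_cross is None else t_cross)
        assert crossings == sorted(crossings)
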