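"""Kinetic transport model: structure, thermodynamics, dynamics, bias."""

import copy
import math

import numpy as np
import pytest

from dimerbias import (
    BiasSpec,
    ConfigError,
    ValidationError,
    alpha_for_equilibrium,
    apply_bias,
    bias_from_populations,
    build_model,
    check_cycles,
    compare_heterodimers,
    default_config,
    simulate_uptake,
    steady_state,
)
from dimerbias.transport import rate_matrix

DRUG_FREE = ("E", "EH", "EH2")


def two_state_config(k_io=3.0, k_oi=7.0):
    """Single species, flips only: analytically solvable."""
    return {
        "species": ["E"],
        "binding": [],
        "flips": [{"species": "E", "k_in_to_out": k_io, "k_out_to_in": k_oi}],
        "boundary": {"pH_in": 7.0, "pH_out": 7.0, "S_out": 0.0, "S_in_0": 0.0},
        "vesicle": {"volume_L": 1e-18, "n_transporters": 1},
    }


def symmetric_config(S=1e-6):
    """Default topology with zero gradients: pH and substrate equal on both
    faces, all rates face-symmetric -> true thermodynamic equilibrium."""
    cfg = default_config()
    cfg["boundary"] = {"pH_in": 7.0, "pH_out": 7.0, "S_out": S, "S_in_0": S}
    return cfg


class TestBuildModel:
    def test_default_topology_counts(self):
        model = build_model()
        assert len(model.states) == 10
        assert len(model.binding_edges) == 8  # 4 reactions x 2 faces
        assert len(model.flip_edges) == 5

    def test_flip_between_different_species_rejected(self):
        cfg = default_config()
        cfg["flips"].append({"from": "EH", "to": "ES", "k_in_to_out": 1, "k_out_to_in": 1})
        with pytest.raises(ConfigError, match="same species"):
            build_model(cfg)

    def test_negative_rate_rejected(self):
        cfg = default_config()
        cfg["binding"][0]["k_on"] = -1.0
        with pytest.raises(ConfigError, match="negative"):
            build_model(cfg)

    def test_dangling_state_rejected(self):
        cfg = default_config()
        cfg["species"].append("EX")  # no edges reach it
        with pytest.raises(ConfigError, match="dangling"):
            build_model(cfg)

    def test_locked_state_scenario(self):
        """Omitting the drug-bound flips leaves a valid model in which the
        loaded transporter cannot cross the membrane."""
        cfg = default_config()
        cfg["flips"] = [f for f in cfg["flips"] if f["species"] not in ("ES", "EHS")]
        model = build_model(cfg)
        assert {f.species for f in model.flip_edges} == set(DRUG_FREE)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        path = tmp_path / "model.yaml"
        path.write_text(yaml.safe_dump(default_config()))
        assert build_model(path) == build_model()


class TestCycleAudit:
    def test_default_model_is_consistent(self):
        reports = check_cycles(build_model())
        assert reports  # the ten-state graph has independent cycles
        assert all(r.consistent for r in reports)

    def test_zero_gradient_cycles_have_zero_driving(self):
        for rep in check_cycles(build_model(symmetric_config())):
            assert rep.log_rate_product == pytest.approx(0.0, abs=1e-12)
            assert rep.driving_force == pytest.approx(0.0, abs=1e-12)

    def test_one_proton_cycle_driving_is_ln10_per_pH_unit(self):
        cfg = default_config()
        cfg["boundary"].update({"pH_in": 8.0, "pH_out": 7.0})
        reports = check_cycles(build_model(cfg))
        # the E <-> EH protonation/flip cycle moves exactly one proton
        proton = [
            r for r in reports
            if {"E_in", "E_out", "EH_in", "EH_out"} == set(r.states)
        ]
        assert len(proton) == 1
        assert abs(proton[0].driving_force) == pytest.approx(math.log(10.0), rel=1e-9)
        assert proton[0].consistent

    def test_bias_never_changes_cycle_mismatch(self):
        """The geometric-mean flip rescaling cancels around every closed
        cycle: conformational bias injects no energy."""
        model = build_model()
        before = check_cycles(model)
        bias = bias_from_populations(0.96, toward="out", bound_exponent=0.5)
        after = check_cycles(apply_bias(model, bias))
        for b, a in zip(before, after):
            assert a.states == b.states
            assert a.mismatch == pytest.approx(b.mismatch, abs=1e-12)
            assert a.log_rate_product == pytest.approx(b.log_rate_product, abs=1e-9)


class TestApplyBias:
    def test_identity_bias(self):
        model = build_model()
        same = apply_bias(model, BiasSpec(per_species_alpha={s: 1.0 for s in DRUG_FREE}))
        assert same == model

    def test_alpha_sets_target_flip_equilibrium(self):
        """Alpha derived from a 96/4 population split makes the isolated
        two-state flip equilibrium exactly 24."""
        model = build_model(two_state_config(k_io=50.0, k_oi=50.0))
        alpha = alpha_for_equilibrium(model, "E", out_over_in=24.0)
        biased = apply_bias(model, BiasSpec(per_species_alpha={"E": alpha}))
        occ = steady_state(biased)
        p_in, p_out = occ[0], occ[1]
        assert p_out / p_in == pytest.approx(24.0, rel=1e-9)
        # geometric mean of the flip rates is preserved
        f0, f1 = model.flip_edges[0], biased.flip_edges[0]
        assert f1.k_in_to_out * f1.k_out_to_in == pytest.approx(
            f0.k_in_to_out * f0.k_out_to_in, rel=1e-12
        )

    def test_drug_free_only_bias_leaves_bound_flips_untouched(self):
        model = build_model()
        bias = bias_from_populations(0.96, toward="out", bound_exponent=0.0)
        biased = apply_bias(model, bias)
        for f0, f1 in zip(model.flip_edges, biased.flip_edges):
            if f0.species in ("ES", "EHS"):
                assert f1 == f0
            else:
                assert f1.k_in_to_out > f0.k_in_to_out

    def test_invalid_alpha(self):
        with pytest.raises(ValidationError):
            BiasSpec(per_species_alpha={"E": 0.0})

    def test_mirrored_is_reciprocal(self):
        bias = bias_from_populations(0.96)
        for sp, a in bias.per_species_alpha.items():
            assert bias.mirrored().per_species_alpha[sp] == pytest.approx(1.0 / a)


class TestSimulateUptake:
    def test_two_state_relaxation_matches_closed_form(self):
        """Starting all transporters inward-facing, the occupancy relaxes
        mono-exponentially with rate k_io + k_oi."""
        k_io, k_oi = 3.0, 7.0
        model = build_model(two_state_config(k_io, k_oi))
        res = simulate_uptake(
            model, t_end=1.0, n_points=50, initial_occupancies=np.array([1.0, 0.0])
        )
        p_eq = k_oi / (k_io + k_oi)
        expected = p_eq + (1.0 - p_eq) * np.exp(-(k_io + k_oi) * res.times)
        assert np.allclose(res.occupancies[:, 0], expected, atol=1e-7)

    def test_occupancies_conserved(self):
        res = simulate_uptake(build_model(), t_end=10.0, n_points=100)
        assert np.abs(res.occupancies.sum(axis=1) - 1.0).max() <= 1e-8

    def test_zero_gradient_is_stationary(self):
        """At equilibrium boundary conditions nothing is pumped: the interior
        concentration stays put (no perpetual motion)."""
        S = 1e-6
        res = simulate_uptake(build_model(symmetric_config(S)), t_end=50.0, n_points=100)
        assert np.abs(res.S_in - S).max() / S <= 1e-6

    def test_steady_state_matches_null_space_oracle(self):
        """Long clamped-substrate integration lands on the rate-matrix null
        space solution, state by state."""
        model = build_model()
        S_in = 1e-6
        cfg = default_config()
        cfg["boundary"]["S_in_0"] = S_in
        model = build_model(cfg)
        n = len(model.states)
        start = np.full(n, 1.0 / n)  # far from stationarity
        res = simulate_uptake(
            model, t_end=5.0, n_points=50,
            initial_occupancies=start, clamp_internal_substrate=True,
        )
        oracle = steady_state(model, S_in)
        assert np.abs(res.occupancies[-1] - oracle).max() <= 1e-8
        # and the oracle really is stationary under the generator
        assert np.abs(rate_matrix(model, S_in) @ oracle).max() <= 1e-8

    def test_gradient_drives_uptake(self):
        res = simulate_uptake(build_model(), t_end=10.0, n_points=100)
        assert res.initial_rate > 0
        assert res.final_S_in > 0


class TestCompareHeterodimers:
    def test_identity_biases_give_unit_ratio(self):
        model = build_model()
        unit = BiasSpec(per_species_alpha={s: 1.0 for s in DRUG_FREE})
        rate_ratio, final_ratio = compare_heterodimers(model, unit, unit, t_end=5.0)
        assert rate_ratio == pytest.approx(1.0, rel=1e-6)
        assert final_ratio == pytest.approx(1.0, rel=1e-6)

    def test_non_mirror_biases_rejected(self):
        model = build_model()
        a = BiasSpec(per_species_alpha={"E": 2.0})
        b = BiasSpec(per_species_alpha={"E": 3.0})
        with pytest.raises(ValidationError, match="mirror"):
            compare_heterodimers(model, a, b, t_end=1.0)

    def test_inward_open_favoring_transports_faster(self):
        """The inward-open-favoring heterodimer beats its mirror image: the
        tilt that stabilizes the inward empty carrier strengthens loading-
        face binding and loosens release-face binding through cycle closure."""
        model = build_model()
        bias_in = bias_from_populations(0.96, toward="in", bound_exponent=0.0)
        rate_ratio, final_ratio = compare_heterodimers(
            model, bias_in, bias_in.mirrored(), t_end=10.0
        )
        assert rate_ratio > 1.0
        assert final_ratio > 1.0

    def test_face_relabeling_inverts_ratio(self):
        """Under a face-symmetric baseline, swapping the two bias specs
        inverts the reported ratio exactly (relabeling symmetry)."""
        cfg = symmetric_config()
        cfg["boundary"]["S_in_0"] = 0.0  # substrate gradient only
        model = build_model(cfg)
        bias_in = bias_from_populations(0.9, toward="in", bound_exponent=0.0)
        bias_out = bias_in.mirrored()
        r_fwd, _ = compare_heterodimers(model, bias_in, bias_out, t_end=5.0)
        r_swapped, _ = compare_heterodimers(model, bias_out, bias_in, t_end=5.0)
        assert r_swapped == pytest.approx(1.0 / r_fwd, rel=1e-6)

    def test_inward_bias_dominates_mirror_at_every_skew(self):
        """At every tested equilibrium skew the inward-open-favoring model
        transports faster than its outward-favoring mirror; extreme skew in
        either direction slows transport (alternating access needs flips both
        ways), so dominance over the mirror — not monotonicity in skew — is
        the directional signature."""
        model = build_model()
        for skew in (2.0, 5.0, 24.0):
            alpha = 1.0 / math.sqrt(skew)  # toward inward-open
            bias = BiasSpec(per_species_alpha={s: alpha for s in DRUG_FREE})
            r_in = simulate_uptake(apply_bias(model, bias), t_end=10.0, n_points=100)
            r_out = simulate_uptake(
                apply_bias(model, bias.mirrored()), t_end=10.0, n_points=100
            )
            assert r_in.initial_rate > r_out.initial_rate
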