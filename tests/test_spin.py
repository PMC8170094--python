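"""Spin-density classification, donor attribution and energy statistics."""

import numpy as np
import pytest

from bc1sox import spin
from bc1sox.errors import (
    AnomalousSpinError,
    InsufficientReferenceError,
    UnattributableError,
)


def record(sid="s0", state="up", energy=0.0, **spins):
    base = {"O2": 2.0, "SQ": -1.0, "Fe1": -4.0, "Fe2": 4.0, "S1": 0.25, "S2": 0.25}
    base.update(spins)
    return spin.FragmentSpinRecord(sid, state, base, energy)


class TestO2Classification:
    @pytest.mark.parametrize(
        "state, s, expected",
        [
            ("up", 1.98, "no_ET"),
            ("down", -1.02, "transferred"),
            ("up", 2.0, "no_ET"),
            ("down", -1.9, "no_ET"),
            ("up", 0.6, "transferred"),
        ],
    )
    def test_magnitude_dichotomy(self, state, s, expected):
        assert spin.classify_o2_transfer(record(state=state, O2=s)) == expected

    def test_small_magnitude_is_anomalous(self):
        with pytest.raises(AnomalousSpinError):
            spin.classify_o2_transfer(record(O2=0.2))

    def test_sign_mismatch_is_anomalous(self):
        with pytest.raises(AnomalousSpinError):
            spin.classify_o2_transfer(record(state="up", O2=-1.0))

    def test_unconverged_record_rejected(self):
        r = record()
        r.converged = False
        with pytest.raises(ValueError):
            spin.classify_o2_transfer(r)


class TestReferenceAndDelta:
    def test_mean_of_one_is_itself(self):
        r = record()
        assert spin.reference_mean_spins([r]) == r.spins

    def test_fragmentwise_arithmetic_mean(self):
        ref = spin.reference_mean_spins([record(Fe2=3.6), record(sid="s1", Fe2=4.0)])
        assert ref["Fe2"] == pytest.approx(3.8)

    def test_mismatched_fragment_sets_rejected(self):
        r2 = spin.FragmentSpinRecord("s1", "up", {"O2": 2.0, "SQ": -1.0}, 0.0)
        with pytest.raises(ValueError):
            spin.reference_mean_spins([record(), r2])

    def test_empty_reference_rejected(self):
        with pytest.raises(InsufficientReferenceError):
            spin.reference_mean_spins([])

    def test_delta_of_reference_is_zero(self):
        r = record()
        delta = spin.delta_spin(r, r.spins)
        assert all(v == 0.0 for v in delta.values())

    def test_delta_arithmetic(self):
        reference = record(SQ=-1.0, Fe2=3.8).spins
        delta = spin.delta_spin(record(SQ=-0.05, Fe2=3.2), reference)
        assert delta["SQ"] == pytest.approx(0.95)
        assert delta["Fe2"] == pytest.approx(-0.6)


class TestDonorAttribution:
    def test_semiquinone_donor_gets_full_weight(self):
        label, w = spin.attribute_donor(
            {"O2": -1.0, "SQ": 0.97, "Fe1": 0.01, "Fe2": 0.0, "S1": 0.0, "S2": 0.0},
            "up",
        )
        assert label == "model_I"
        assert w == {"SQ": 1.0}

    def test_cluster_donor_weights_are_normalized_shares(self):
        label, w = spin.attribute_donor(
            {"O2": -1.0, "SQ": 0.0, "Fe1": 0.0, "Fe2": -0.5, "S1": -0.25, "S2": -0.25},
            "up",
        )
        assert label == "model_II"
        assert w == pytest.approx({"Fe2": 0.5, "S1": 0.25, "S2": 0.25})

    def test_exact_tie_breaks_to_cluster(self):
        label, _ = spin.attribute_donor(
            {"O2": -1.0, "SQ": 0.5, "Fe1": 0.0, "Fe2": 0.5, "S1": 0.0, "S2": 0.0},
            "up",
        )
        assert label == "model_II"

    def test_vanishing_pools_are_unattributable(self):
        with pytest.raises(UnattributableError):
            spin.attribute_donor(
                {"O2": -1.0, "SQ": 0.1, "Fe1": 0.0, "Fe2": 0.1, "S1": 0.0, "S2": 0.0},
                "up",
            )


class TestOutliersAndStats:
    def test_equal_energies_flag_nothing(self):
        records = [record(sid=f"s{i}", energy=5.0) for i in range(4)]
        labels = {r.snapshot_id: "no_ET" for r in records}
        assert spin.flag_outliers(records, labels) == set()

    def test_median_deviation_rule(self):
        energies = {"a": 0.0, "b": 2.0, "c": 4.0, "d": -120.0}
        records = [record(sid=k, energy=v) for k, v in energies.items()]
        labels = {k: "no_ET" for k in energies}
        assert spin.flag_outliers(records, labels, threshold=50.0) == {"d"}

    def test_huge_threshold_flags_nothing(self):
        records = [record(sid=f"s{i}", energy=100.0 * i) for i in range(5)]
        labels = {r.snapshot_id: "no_ET" for r in records}
        assert spin.flag_outliers(records, labels, threshold=1e12) == set()

    def test_class_stats_relative_to_no_transfer_mean(self):
        records = [record(sid=f"n{i}", energy=e) for i, e in enumerate((0, 2, 4))]
        records += [record(sid=f"m{i}", energy=e, O2=1.0, Fe2=3.5)
                    for i, e in enumerate((-38, -40))]
        cls = [spin.EtClassification(f"n{i}", "no_ET") for i in range(3)]
        cls += [spin.EtClassification(f"m{i}", "model_II", {"Fe2": 1.0})
                for i in range(2)]
        stats = spin.class_energy_stats(records, cls)
        assert stats.classes["no_ET"].mean_rel == 0.0
        assert stats.classes["no_ET"].sd == pytest.approx(2.0)
        assert stats.classes["model_II"].mean_rel == pytest.approx(-41.0)
        assert stats.total == 5

    def test_single_member_class_has_no_sd(self):
        records = [record(sid=f"n{i}", energy=float(i)) for i in range(2)]
        records.append(record(sid="m0", energy=-30.0, O2=1.0, SQ=0.0))
        cls = [spin.EtClassification(f"n{i}", "no_ET") for i in range(2)]
        cls.append(spin.EtClassification("m0", "model_I", {"SQ": 1.0}))
        stats = spin.class_energy_stats(records, cls)
        assert stats.classes["model_I"].sd is None

    def test_missing_no_transfer_class_rejected(self):
        records = [record(sid="m0", energy=0.0, O2=1.0)]
        cls = [spin.EtClassification("m0", "model_I", {"SQ": 1.0})]
        with pytest.raises(InsufficientReferenceError):
            spin.class_energy_stats(records, cls)


class TestGaussianFit:
    def _stats(self, **classes):
        return spin.ClassEnergyStats(
            {k: spin.ClassStat(*v) for k, v in classes.items()}
        )

    def test_moment_matched_parameters(self):
        fits = spin.gaussian_class_fit(self._stats(no_ET=(77, 0.0, 14.730)))
        assert fits["no_ET"].mean == 0.0
        assert fits["no_ET"].sd == 14.730
        assert not fits["no_ET"].degenerate

    def test_symmetric_pair(self):
        # data {-1, +1}: mean 0, sample sd sqrt(2)
        x = np.array([-1.0, 1.0])
        fits = spin.gaussian_class_fit(
            self._stats(no_ET=(2, float(x.mean()), float(x.std(ddof=1))))
        )
        assert fits["no_ET"].sd == pytest.approx(np.sqrt(2))

    def test_zero_sd_flagged_degenerate(self):
        with pytest.warns(UserWarning):
            fits = spin.gaussian_class_fit(self._stats(no_ET=(3, 0.0, 0.0)))
        assert fits["no_ET"].degenerate

    def test_single_member_class_rejected(self):
        with pytest.raises(ValueError):
            spin.gaussian_class_fit(self._stats(no_ET=(1, 0.0, None)))


class TestEnsembleConsistency:
    def test_delta_spin_sums_to_zero_for_transfer_classes(self):
        """Spin conservation: the electron gained by O2 is lost by the donor."""
        from bc1sox import synth

        cfg = synth.SpinGenConfig(
            n_no_et=10, n_model_i=5, n_model_ii=5, n_outlier=0,
            spin_noise_sd=0.0, o2_spin_orientation="down",
        )
        records, labels = synth.gen_spin_tables(cfg)
        ref = spin.reference_mean_spins(
            [r for r, lab in zip(records, labels) if lab == "no_ET"]
        )
        for r, lab in zip(records, labels):
            if lab in ("model_I", "model_II"):
                assert sum(spin.delta_spin(r, ref).values()) == pytest.approx(0.0, abs=1e-9)

    def test_csv_roundtrip(self, tmp_path):
        from bc1sox import synth

        records, _ = synth.gen_spin_tables(synth.SpinGenConfig(seed=8))
        path = tmp_path / "spins.csv"
        spin.write_spin_table(records, path)
        back = spin.read_spin_table(path)
        assert len(back) == len(records)
        assert back[0].spins == pytest.approx(records[0].spins)
        assert back[0].o2_spin_state == records[0].o2_spin_state
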