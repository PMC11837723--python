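"""Pair construction, the RI stability gate and change detection."""

import numpy as np
import pytest

from sfpf.physiology import pao2_given_ri, respiratory_index
from sfpf.trending import (change_correlations, change_detection,
                           consecutive_pairs, stability_gate)

H = 3600.0


def pair_with_ri(dp_factory, ri1, ri2, dt_hours=1.0, admission_id="a",
                 fio2=(1.0, 1.0), spo2=(94.0, 94.0), paco2=40.0):
    """Two valid datapoints whose RIs are exactly ri1 and ri2."""
    dps = []
    for i, (ri, f, s) in enumerate(zip((ri1, ri2), fio2, spo2)):
        dps.append(dp_factory(pao2=pao2_given_ri(ri, f, paco2), fio2=f, spo2=s,
                              paco2=paco2, time=i * dt_hours * H,
                              admission_id=admission_id))
    return dps


class TestConsecutivePairs:
    def test_counts_per_admission(self, dp_factory):
        dps = [dp_factory(time=i * H, admission_id="a") for i in range(5)]
        dps += [dp_factory(time=i * H, admission_id="b") for i in range(3)]
        dps += [dp_factory(time=i * H, admission_id="c") for i in range(2)]
        dps += [dp_factory(time=0.0, admission_id="d")]
        pairs = consecutive_pairs(dps)
        by_adm = {adm: sum(1 for p in pairs if p.admission_id == adm)
                  for adm in "abcd"}
        assert by_adm == {"a": 4, "b": 2, "c": 1, "d": 0}

    def test_invalid_datapoints_skipped(self, dp_factory):
        dps = [dp_factory(time=0.0), dp_factory(time=H, valid=False),
               dp_factory(time=2 * H)]
        pairs = consecutive_pairs(dps)
        assert len(pairs) == 1 and pairs[0].dt == 2 * H

    def test_proportional_changes_and_ri(self, dp_factory):
        a, b = pair_with_ri(dp_factory, 2.0, 2.2, fio2=(0.5, 0.6))
        (p,) = consecutive_pairs([a, b])
        assert p.d_fio2 == pytest.approx(0.2)
        assert p.ri_first == pytest.approx(2.0, abs=1e-9)
        assert p.ri_change == pytest.approx(0.1, abs=1e-9)

    def test_missing_paco2_gives_no_ri(self, dp_factory):
        a = dp_factory(time=0.0, paco2=None)
        b = dp_factory(time=H, paco2=None)
        (p,) = consecutive_pairs([a, b])
        assert p.ri_change is None


class TestStabilityGate:
    def test_long_interval_excluded(self, dp_factory):
        pairs = consecutive_pairs(pair_with_ri(dp_factory, 2.0, 2.0, dt_hours=7.0))
        gated, excl = stability_gate(pairs)
        assert gated == [] and excl["dt"] == 1

    def test_large_ri_change_excluded(self, dp_factory):
        pairs = consecutive_pairs(pair_with_ri(dp_factory, 2.0, 2.5, dt_hours=3.0))
        gated, excl = stability_gate(pairs)
        assert gated == [] and excl["ri_change"] == 1

    def test_stable_pair_retained(self, dp_factory):
        pairs = consecutive_pairs(pair_with_ri(dp_factory, 2.0, 2.2, dt_hours=3.0))
        gated, _ = stability_gate(pairs)
        assert len(gated) == 1 and gated[0].stable

    def test_ri_floor_and_missing_paco2_counted(self, dp_factory):
        low = consecutive_pairs(pair_with_ri(dp_factory, 0.01, 0.012))
        no_paco2 = consecutive_pairs(
            [dp_factory(time=0.0, paco2=None), dp_factory(time=H, paco2=None)])
        gated, excl = stability_gate(low + no_paco2)
        assert gated == []
        assert excl["ri_floor"] == 1 and excl["missing_paco2"] == 1

    def test_gate_idempotent_never_grows(self, dp_factory):
        pairs = consecutive_pairs(
            pair_with_ri(dp_factory, 2.0, 2.1)
            + pair_with_ri(dp_factory, 3.0, 4.0, admission_id="b"))
        gated, _ = stability_gate(pairs)
        again, _ = stability_gate(gated)
        assert len(again) == len(gated) <= len(pairs)


class TestChangeCorrelations:
    def test_pao2_proportional_to_fio2(self, dp_factory):
        pairs = []
        for i, (f1, f2) in enumerate([(0.3, 0.6), (0.4, 0.5), (0.5, 0.4),
                                      (0.6, 0.3), (0.3, 0.45)]):
            a = dp_factory(pao2=200 * f1, fio2=f1, time=0.0, admission_id=str(i))
            b = dp_factory(pao2=200 * f2, fio2=f2, time=H, admission_id=str(i))
            pairs += consecutive_pairs([a, b])
        r_pao2, _ = change_correlations(pairs, require_fio2_change=True)
        assert r_pao2 == pytest.approx(1.0)

    def test_constant_spo2_reported_absent(self, dp_factory):
        pairs = []
        for i, (f1, f2) in enumerate([(0.3, 0.6), (0.4, 0.5), (0.5, 0.35)]):
            a = dp_factory(fio2=f1, spo2=94.0, time=0.0, admission_id=str(i))
            b = dp_factory(fio2=f2, spo2=94.0, time=H, admission_id=str(i))
            pairs += consecutive_pairs([a, b])
        _, r_spo2 = change_correlations(pairs)
        assert r_spo2 is None  # zero variance: undefined, not a number

    def test_requires_two_pairs(self, dp_factory):
        pairs = consecutive_pairs(pair_with_ri(dp_factory, 2.0, 2.1))
        with pytest.raises(ValueError):
            change_correlations(pairs)


class TestChangeDetection:
    def test_no_changes_rate_absent(self, dp_factory):
        pairs = consecutive_pairs([dp_factory(time=i * H) for i in range(4)])
        matrix, rate = change_detection(pairs)
        assert rate is None
        assert matrix[1, 1] == len(pairs) == matrix.sum()

    def test_partial_detection_rate(self, dp_factory):
        pairs = []
        # 4 PF category changes (severe -> moderate direction up/down mix),
        # only one matched by an SF transition in the same direction
        specs = [  # (pao2_1, pao2_2, spo2_1, spo2_2) at fio2 1.0
            (95.0, 150.0, 94.0, 95.0),   # PF severe->moderate, SF stays severe
            (95.0, 150.0, 94.0, 95.0),   # PF severe->moderate, SF stays severe
            (150.0, 95.0, 94.0, 95.0),   # PF moderate->severe, SF stays severe
            (95.0, 150.0, 94.0, 97.0),   # placeholder, replaced below
        ]
        for i, (p1, p2, s1, s2) in enumerate(specs):
            a = dp_factory(pao2=p1, spo2=s1, fio2=1.0, time=0.0, admission_id=str(i))
            b = dp_factory(pao2=p2, spo2=s2, fio2=1.0, time=H, admission_id=str(i))
            pairs += consecutive_pairs([a, b])
        # make the last one detected: raise its second SpO2 via lower FiO2
        a = dp_factory(pao2=95.0, spo2=94.0, fio2=1.0, time=0.0, admission_id="x")
        b = dp_factory(pao2=150.0, spo2=94.0, fio2=0.6, time=H, admission_id="x")
        pairs = pairs[:-1] + consecutive_pairs([a, b])
        matrix, rate = change_detection(pairs)
        assert matrix.sum() == 4
        assert rate == pytest.approx(0.25)

    def test_row_sums_are_pf_transition_frequencies(self, dp_factory):
        rng = np.random.default_rng(8)
        pairs = []
        for i in range(30):
            a = dp_factory(pao2=float(rng.uniform(60, 350)), time=0.0,
                           fio2=1.0, spo2=float(rng.integers(85, 97)),
                           admission_id=str(i))
            b = dp_factory(pao2=float(rng.uniform(60, 350)), time=H,
                           fio2=1.0, spo2=float(rng.integers(85, 97)),
                           admission_id=str(i))
            pairs += consecutive_pairs([a, b])
        matrix, _ = change_detection(pairs)
        for j, name in enumerate(("down", "same", "up")):
            assert matrix[j].sum() == sum(p.pf_transition == name for p in pairs)
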