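"""Dyadic tallies, the rate formulas, and attribute similarity matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gestnet import (
    DyadTallies,
    build_networks,
    communication_rate,
    proximity_rate,
    similarity_matrix,
    tally_dyads,
)
from gestnet.coding import code_events

from _oracles import tally_by_double_loop


def make_tallies(labels, party, p10, comm):
    return DyadTallies(labels, np.asarray(party), np.asarray(p10),
                       {k: np.asarray(v) for k, v in comm.items()})


class TestRates:
    def test_rate_arithmetic_forced_by_formula(self):
        """One event over 30 within-10 m scans is one event per hour."""
        t = make_tallies(
            ["A", "B"], [[0, 30], [30, 0]], [[0, 30], [30, 0]],
            {"single": [[0, 1], [0, 0]]},
        )
        ca = communication_rate(t, "single")
        assert ca.values[0, 1] == pytest.approx(1.0)
        assert ca.values[1, 0] == 0.0

    def test_zero_count_and_zero_exposure(self):
        t = make_tallies(
            ["A", "B"], [[0, 4], [4, 0]], [[0, 4], [0, 0]],
            {"single": [[0, 0], [0, 0]]},
        )
        ca = communication_rate(t, "single")
        assert np.all(ca.values == 0)
        assert t.zero_exposure_mask()[1, 0] and not t.zero_exposure_mask()[0, 1]

    def test_proximity_bounds_and_extremes(self):
        t = make_tallies(["A", "B"], [[0, 6], [9, 0]], [[0, 6], [0, 0]], {})
        prox = proximity_rate(t)
        assert prox.values[0, 1] == 60.0  # always within 10 m
        assert prox.values[1, 0] == 0.0   # never within 10 m

    def test_p10_exceeding_party_rejected(self):
        t = make_tallies(["A", "B"], [[0, 2], [0, 0]], [[0, 3], [0, 0]], {})
        with pytest.raises(ValueError, match="exceeds party"):
            proximity_rate(t)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rates_match_minutes_bookkeeping(self, seed):
        """Randomized tallies: CA equals events / (minutes of co-proximity / 60),
        with each scan worth one 2-min interval; PROX in [0, 60] always."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        labels = [f"n{i}" for i in range(n)]
        party = rng.integers(0, 40, size=(n, n))
        np.fill_diagonal(party, 0)
        p10 = rng.integers(0, party + 1)
        c = rng.integers(0, 10, size=(n, n))
        np.fill_diagonal(c, 0)
        t = make_tallies(labels, party, p10, {"single": c})
        ca = communication_rate(t, "single").values
        prox = proximity_rate(t).values
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                minutes = p10[i, j] * 2.0
                expect = c[i, j] / (minutes / 60.0) if minutes else 0.0
                assert ca[i, j] == pytest.approx(expect)
                hours_in_party = party[i, j] * 2.0 / 60.0
                expect_p = (p10[i, j] * 2.0) / hours_in_party if party[i, j] else 0.0
                assert prox[i, j] == pytest.approx(expect_p)
        assert (prox >= 0).all() and (prox <= 60).all()

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        n = 5
        party = rng.integers(1, 20, size=(n, n))
        np.fill_diagonal(party, 0)
        p10 = rng.integers(0, party + 1)
        c = rng.integers(0, 5, size=(n, n))
        np.fill_diagonal(c, 0)
        labels = [f"n{i}" for i in range(n)]
        base = make_tallies(labels, party, p10, {"single": c})
        doubled_c = make_tallies(labels, party, p10, {"single": 2 * c})
        assert np.allclose(
            communication_rate(doubled_c, "single").values,
            2 * communication_rate(base, "single").values,
        )
        doubled_exposure = make_tallies(labels, 2 * party, 2 * p10, {"single": c})
        assert np.allclose(
            proximity_rate(doubled_exposure).values, proximity_rate(base).values
        )

    def test_unknown_tally_key(self):
        t = make_tallies(["A", "B"], [[0, 1], [1, 0]], [[0, 1], [1, 0]], {})
        with pytest.raises(KeyError):
            communication_rate(t, "persistence")


class TestTally:
    def _scan_frame(self, rows):
        return pd.DataFrame(
            [
                {
                    "follow_id": r.get("follow", "f0"),
                    "focal_id": r["focal"],
                    "scan_index": r.get("idx", 1),
                    "time_min": r["time_min"],
                    "party_members": ";".join(r["party"]),
                    "within10_members": ";".join(r["w10"]),
                }
                for r in rows
            ]
        )

    def _seq_frame(self, rows):
        return pd.DataFrame(
            [
                {
                    "sequence_id": f"s{i}",
                    "signaller": r["signaller"],
                    "recipient": r["recipient"],
                    "context": "g",
                    "cls": r["cls"],
                    "n_gestures": 1,
                    "first_time_s": r["first_time_s"],
                    "response_present": r.get("response_present", False),
                    "response_category": r.get("response_category", ""),
                }
                for i, r in enumerate(rows)
            ]
        )

    def test_direct_p10_count_and_empty_log(self):
        scans = self._scan_frame(
            [
                {"focal": "A", "idx": k + 1, "time_min": 2.0 * k,
                 "party": ["B"], "w10": ["B"] if k < 6 else []}
                for k in range(9)
            ]
        )
        t = tally_dyads(scans, self._seq_frame([]), ["A", "B"])
        assert t.p10[0, 1] == 6 and t.party[0, 1] == 9
        assert all(v.sum() == 0 for v in t.comm.values())

    def test_sequence_attributed_to_interval_of_first_gesture(self):
        scans = self._scan_frame(
            [
                {"focal": "A", "idx": 1, "time_min": 0.0, "party": ["B"], "w10": ["B"]},
                {"focal": "A", "idx": 2, "time_min": 2.0, "party": ["B"], "w10": []},
            ]
        )
        seqs = self._seq_frame(
            [
                {"signaller": "A", "recipient": "B", "cls": "single",
                 "first_time_s": 119.0},          # inside scan 1's interval
                {"signaller": "A", "recipient": "B", "cls": "single",
                 "first_time_s": 121.0},          # scan 2: B not within 10 m
                {"signaller": "A", "recipient": "B", "cls": "rapid",
                 "first_time_s": 1000.0},         # outside any follow interval
            ]
        )
        t = tally_dyads(scans, seqs, ["A", "B"])
        assert t.comm["single"][0, 1] == 1
        assert t.n_excluded == 2

    def test_unknown_node_rejected(self):
        scans = self._scan_frame(
            [{"focal": "A", "time_min": 0.0, "party": ["B"], "w10": ["B"]}]
        )
        seqs = self._seq_frame(
            [{"signaller": "A", "recipient": "Z", "cls": "single",
              "first_time_s": 10.0}]
        )
        with pytest.raises(KeyError, match="unknown node"):
            tally_dyads(scans, seqs, ["A", "B"])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_double_loop_oracle(self, seed):
        """Random small scan sets and sequence logs: tallies equal the
        spec-literal double loop over scans x sequences."""
        rng = np.random.default_rng(seed)
        labels = ["A", "B", "C"]
        scan_rows = []
        for f in range(rng.integers(1, 4)):
            focal = labels[rng.integers(3)]
            base = f * 60.0
            for k in range(3):
                others = [l for l in labels if l != focal]
                party = [l for l in others if rng.random() < 0.6]
                w10 = [l for l in party if rng.random() < 0.6]
                scan_rows.append(
                    {"follow": f"f{f}", "focal": focal, "idx": k + 1,
                     "time_min": base + 2.0 * k, "party": party, "w10": w10}
                )
        seq_rows = []
        for _ in range(rng.integers(0, 12)):
            a, b = rng.choice(3, size=2, replace=False)
            seq_rows.append(
                {
                    "signaller": labels[a],
                    "recipient": labels[b],
                    "cls": ["single", "rapid", "persistence"][rng.integers(3)],
                    "first_time_s": float(rng.uniform(0, 200 * 60)),
                }
            )
        t = tally_dyads(self._scan_frame(scan_rows), self._seq_frame(seq_rows), labels)
        party_o, p10_o, comm_o, excl_o = tally_by_double_loop(
            scan_rows, seq_rows, labels
        )
        assert np.array_equal(t.party, party_o)
        assert np.array_equal(t.p10, p10_o)
        for k, v in comm_o.items():
            assert np.array_equal(t.comm[k], v)
        assert t.n_excluded == excl_o


class TestSimilarity:
    def test_fixture_age_and_oestrous_counts(self, fixture_attrs):
        age = similarity_matrix(fixture_attrs, "age")
        oes = similarity_matrix(fixture_attrs, "oestrous")
        assert age.values.sum() == 30          # ordered same-age dyads
        assert (age.values == 0).sum() - 12 == 102
        assert oes.values.sum() == 36          # male x cycling female, both ways

    def test_sex_similarity_by_definition(self, fixture_attrs):
        sex = similarity_matrix(fixture_attrs, "sex")
        assert sex.values.sum() == 60          # 2 * (C(6,2) + C(6,2))

    def test_symmetry_and_zero_diagonal(self, fixture_attrs):
        for kind in ("sex", "age", "oestrous", "kin"):
            m = similarity_matrix(fixture_attrs, kind)
            assert m.is_symmetric()
            assert np.all(np.diag(m.values) == 0)
            assert set(np.unique(m.values)) <= {0.0, 1.0}

    def test_kin_from_synthetic_pedigree(self):
        attrs = pd.DataFrame(
            {
                "id": ["A", "B", "C"],
                "sex": ["male", "female", "female"],
                "age": [10, 30, 40],
                "reproductive_status": ["not_applicable", "cycling", "nursing"],
                "mother_id": pd.array(["B", "", ""], dtype="string"),
            }
        )
        kin = similarity_matrix(attrs, "kin")
        assert kin.values.sum() == 2
        assert kin.values[0, 1] == kin.values[1, 0] == 1

    def test_missing_age_rejected(self):
        attrs = pd.DataFrame(
            {"id": ["A", "B"], "sex": ["male", "male"], "age": [20, np.nan],
             "reproductive_status": ["not_applicable"] * 2}
        )
        with pytest.raises(ValueError, match="age"):
            similarity_matrix(attrs, "age")

    def test_unknown_kind(self, fixture_attrs):
        with pytest.raises(ValueError, match="unknown similarity"):
            similarity_matrix(fixture_attrs, "rank")


def test_build_networks_end_to_end(small_dataset):
    _, attrs, scans, events, _ = small_dataset
    seqs = code_events(events)
    nets, tallies = build_networks(scans, seqs, attrs)
    n = len(attrs)
    assert nets["proximity"].n_dyads == n * (n - 1)
    assert (nets["proximity"].values <= 60).all()
    for name, m in nets.items():
        assert m.labels == list(attrs["id"].astype(str))
        assert (m.values >= 0).all()
    # every coded sequence lands in exactly one class tally or is excluded
    total = sum(tallies.comm[k].sum() for k in ("single", "rapid", "persistence"))
    assert total + tallies.n_excluded == len(seqs)
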