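"""Vote caller: CC cleaning, filament calls, polarity unification, summaries."""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from mtlumen import (
    AssignmentRule,
    EulerTriplet,
    call_filament,
    call_table,
    clean_by_cc,
    pf_distribution,
    summarize_protrusions,
    unify_polarity,
)


def make_table(rows):
    df = pd.DataFrame(
        rows,
        columns=["particle_id", "filament_id", "class_n", "class_polarity", "cc"],
    )
    return df


def filament_df(votes, ccs, fid=0):
    return pd.DataFrame(
        {
            "particle_id": range(len(votes)),
            "filament_id": fid,
            "class_n": [v[0] for v in votes],
            "class_polarity": [v[1] for v in votes],
            "cc": ccs,
        }
    )


class TestCleanByCC:
    def test_keeps_80_percent_of_100(self):
        rng = np.random.default_rng(0)
        df = make_table(
            [(i, i // 10, 13, "plus", c) for i, c in enumerate(rng.permutation(100) / 100)]
        )
        assert len(clean_by_cc(df)) == 80

    def test_ceil_rule_small_table(self):
        df = make_table([(i, 0, 13, "plus", 0.1 + 0.01 * i) for i in range(10)])
        assert len(clean_by_cc(df)) == 8

    def test_tie_break_drops_lowest_id(self):
        df = make_table([(i, 0, 13, "plus", 0.2) for i in range(5)])
        kept = clean_by_cc(df)
        assert len(kept) == 4
        assert 0 not in set(kept["particle_id"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            clean_by_cc(make_table([]))

    def test_per_filament_scope(self):
        rows = [(i, 0, 13, "plus", 0.9 - 0.01 * i) for i in range(10)]
        rows += [(10 + i, 1, 13, "plus", 0.1 + 0.01 * i) for i in range(10)]
        df = make_table(rows)
        rule = AssignmentRule(clean_scope="per-filament")
        kept = clean_by_cc(df, rule)
        assert (kept["filament_id"] == 0).sum() == 8
        assert (kept["filament_id"] == 1).sum() == 8
        # global cleaning instead sacrifices the low-cc filament
        kept_g = clean_by_cc(df)
        assert (kept_g["filament_id"] == 1).sum() < 8


class TestCallFilament:
    def test_supermajority_assigned_regardless_of_cc(self):
        votes = [(13, "plus")] * 7 + [(12, "plus")] * 3
        call = call_filament(filament_df(votes, [0.01] * 10))
        assert call.assigned and call.n_pf == 13 and call.polarity == "plus"

    def test_minority_with_good_cc_assigned(self):
        votes = [(13, "plus")] * 11 + [(12, "plus")] * 5 + [(14, "minus")] * 4
        call = call_filament(filament_df(votes, [0.14] * 20))
        assert call.assigned and call.n_pf == 13

    def test_minority_with_poor_cc_undetermined(self):
        votes = [(13, "plus")] * 11 + [(12, "plus")] * 5 + [(14, "minus")] * 4
        call = call_filament(filament_df(votes, [0.10] * 20))
        assert not call.assigned

    def test_three_way_split_undetermined(self):
        votes = [(13, "plus")] * 4 + [(12, "plus")] * 4 + [(14, "plus")] * 2
        call = call_filament(filament_df(votes, [0.5] * 10))
        assert not call.assigned

    def test_exact_tie_undetermined(self):
        votes = [(13, "plus")] * 5 + [(12, "minus")] * 5
        call = call_filament(filament_df(votes, [0.9] * 10))
        assert not call.assigned

    def test_cc_min_monotonicity(self):
        # raising cc_min can only turn assigned into undetermined
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = rng.integers(4, 12)
            votes = [
                ((13, "plus") if rng.random() < 0.6 else (12, "plus"))
                for _ in range(n)
            ]
            ccs = rng.uniform(0, 0.3, n)
            lo = call_filament(filament_df(votes, ccs), AssignmentRule(cc_min=0.10))
            hi = call_filament(filament_df(votes, ccs), AssignmentRule(cc_min=0.20))
            if hi.assigned:
                assert lo.assigned

    def test_brute_force_oracle_equivalence(self):
        """Exhaustive-enumeration oracle over all vote counts for <= 12
        particles agrees with call_filament on 1,000 random tables."""

        def oracle(votes, ccs, rule):
            counts = Counter(votes)
            top = max(counts.values())
            winners = [c for c, k in counts.items() if k == top]
            frac = top / len(votes)
            cc = float(np.mean(ccs))
            if len(winners) != 1:
                return None
            if frac >= rule.f_major or (frac >= rule.f_minor and cc >= rule.cc_min):
                return winners[0]
            return None

        rule = AssignmentRule()
        rng = np.random.default_rng(123)
        classes = list(itertools.product((12, 13, 14, 15), ("plus", "minus")))
        for _ in range(1000):
            n = int(rng.integers(1, 13))
            votes = [classes[i] for i in rng.integers(0, len(classes), n)]
            ccs = np.round(rng.uniform(0, 0.3, n), 4)
            expected = oracle(votes, ccs, rule)
            got = call_filament(filament_df(votes, ccs), rule)
            if expected is None:
                assert not got.assigned
            else:
                assert got.assigned and (got.n_pf, got.polarity) == expected

    def test_particle_order_invariance(self):
        rng = np.random.default_rng(77)
        votes = [(13, "plus")] * 6 + [(12, "plus")] * 4
        ccs = list(rng.uniform(0, 0.3, 10))
        df = filament_df(votes, ccs)
        shuffled = df.sample(frac=1.0, random_state=1)
        a = call_filament(clean_by_cc(df))
        b = call_filament(clean_by_cc(shuffled))
        assert (a.assigned, a.n_pf, a.polarity) == (b.assigned, b.n_pf, b.polarity)


class TestProtrusionSummary:
    def make_calls(self, rows):
        return pd.DataFrame(
            rows,
            columns=["filament_id", "protrusion_id", "assigned", "n_pf", "polarity"],
        )

    def test_uniform_single(self):
        calls = self.make_calls(
            [(i, 0, True, 13, "plus") for i in range(3)]
        )
        out = summarize_protrusions(calls)
        assert out.iloc[0]["orientation"] == "uniform"
        assert out.iloc[0]["pf_mix"] == "single"

    def test_single_assigned_excluded(self):
        calls = self.make_calls(
            [(0, 0, True, 13, "plus"), (1, 0, False, None, None)]
        )
        assert summarize_protrusions(calls).iloc[0]["orientation"] == "excluded"

    def test_mixed_orientation_and_pf(self):
        calls = self.make_calls(
            [(0, 0, True, 13, "plus"), (1, 0, True, 12, "minus")]
        )
        out = summarize_protrusions(calls)
        assert out.iloc[0]["orientation"] == "mixed"
        assert out.iloc[0]["pf_mix"] == "mixed"


class TestUnifyPolarity:
    def particle_table(self):
        return pd.DataFrame(
            {
                "particle_id": range(4),
                "filament_id": [0, 0, 1, 1],
                "class_n": 13,
                "class_polarity": ["plus"] * 2 + ["minus"] * 2,
                "cc": 0.2,
                "rot": [10.0, 20.0, 30.0, 40.0],
                "tilt": [45.0, 60.0, 90.0, 120.0],
                "psi": [5.0, -5.0, 15.0, -15.0],
            }
        )

    def calls(self, pol1="minus"):
        return pd.DataFrame(
            {
                "filament_id": [0, 1],
                "assigned": [True, True],
                "n_pf": [13, 13],
                "polarity": ["plus", pol1],
            }
        )

    def test_all_plus_unchanged(self):
        table = self.particle_table()
        out = unify_polarity(table, self.calls("plus"))
        pd.testing.assert_frame_equal(out, table)

    def test_minus_directions_reversed(self):
        table = self.particle_table()
        out = unify_polarity(table, self.calls("minus"))
        for i in (2, 3):
            before = EulerTriplet(
                table["rot"][i], table["tilt"][i], table["psi"][i]
            ).direction()
            row = out[out["particle_id"] == i].iloc[0]
            after = EulerTriplet(row["rot"], row["tilt"], row["psi"]).direction()
            np.testing.assert_allclose(after, -before, atol=1e-9)

    def test_idempotent_on_directions(self):
        table = self.particle_table()
        calls = self.calls("minus")
        once = unify_polarity(table, calls)
        plus_calls = calls.assign(polarity="plus")
        twice = unify_polarity(once, plus_calls)
        for i in once["particle_id"]:
            a = once[once.particle_id == i].iloc[0]
            b = twice[twice.particle_id == i].iloc[0]
            np.testing.assert_allclose(
                EulerTriplet(a.rot, a.tilt, a.psi).direction(),
                EulerTriplet(b.rot, b.tilt, b.psi).direction(),
                atol=1e-9,
            )

    def test_undetermined_filaments_dropped(self):
        table = self.particle_table()
        calls = pd.DataFrame(
            {
                "filament_id": [0, 1],
                "assigned": [True, False],
                "n_pf": [13, None],
                "polarity": ["plus", None],
            }
        )
        out = unify_polarity(table, calls)
        assert set(out["filament_id"]) == {0}


class TestPfDistribution:
    def calls_frame(self, entries):
        return pd.DataFrame(
            entries, columns=["filament_id", "assigned", "n_pf", "polarity", "replicate"]
        )

    def test_single_replicate_fractions(self):
        calls = self.calls_frame(
            [
                (0, True, 13, "plus", 1),
                (1, True, 13, "plus", 1),
                (2, True, 13, "plus", 1),
                (3, True, 12, "plus", 1),
            ]
        )
        per_group, _ = pf_distribution(calls)
        p13 = per_group[(per_group.replicate == 1) & (per_group.n_pf == 13)]
        assert p13["percent"].iloc[0] == pytest.approx(75.0)

    def test_cross_replicate_mean_sd(self):
        entries = []
        fid = 0
        for rep, pct13 in [(1, 90), (2, 96)]:
            for _ in range(pct13):
                entries.append((fid, True, 13, "plus", rep)); fid += 1
            for _ in range(100 - pct13):
                entries.append((fid, True, 12, "plus", rep)); fid += 1
        per_group, summary = pf_distribution(self.calls_frame(entries))
        row = summary[summary.n_pf == 13].iloc[0]
        assert row["mean_percent"] == pytest.approx(93.0)
        assert row["sd_percent"] == pytest.approx(4.2426, abs=1e-3)

    def test_all_undetermined_flagged(self):
        calls = self.calls_frame([(0, False, None, None, 1), (1, False, None, None, 1)])
        per_group, summary = pf_distribution(calls)
        assert per_group["percent"].isna().all()


class TestCallTableEndToEnd:
    def test_filaments_emptied_by_cleaning_are_undetermined(self):
        rows = [(i, 0, 13, "plus", 0.9) for i in range(16)]
        rows += [(16 + i, 1, 13, "plus", 0.01) for i in range(4)]
        df = pd.DataFrame(
            rows, columns=["particle_id", "filament_id", "class_n", "class_polarity", "cc"]
        )
        calls = call_table(df)
        assert calls.set_index("filament_id").loc[1, "assigned"] == False  # noqa: E712
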