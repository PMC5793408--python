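import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leakguard.cohort_analysis import (
    SubmissionRecord,
    best_per_team,
    leak_recurrence,
    read_submission_table,
    records_to_frame,
    spearman_rho,
    summarize,
)
from leakguard.errors import ConstantInputError, LeakguardError
from leakguard.vcf_io import VariantKey


def _midranks(values):
    """Brute-force average ranks: for each value, mean rank of its tie group."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and values[order[j]] == values[order[i]]:
            j += 1
        mean_rank = (i + j + 1) / 2  # ranks are 1-based
        for k in order[i:j]:
            ranks[k] = mean_rank
        i = j
    return ranks


def _pearson(x, y):
    mx, my = sum(x) / len(x), sum(y) / len(y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def brute_force_spearman(x, y):
    return _pearson(_midranks(list(x)), _midranks(list(y)))


def _rec(tumour="IS1", sid="s1", team="t1", f1=0.8, leaks=1, admin=False,
         precision=None, recall=None):
    # pick a precision/recall pair consistent with f1 (p = r = f1 works)
    p = f1 if precision is None else precision
    r = f1 if recall is None else recall
    return SubmissionRecord(tumour, sid, team, p, r, f1, leaks, admin)


class TestSpearman:
    def test_strictly_antimonotone_is_minus_one(self):
        assert spearman_rho([1, 2, 3, 4], [9, 7, 4, 1]) == pytest.approx(-1.0)

    def test_tied_example_matches_brute_force_midrank_pearson(self):
        x, y = [1, 2, 3, 4], [2, 2, 5, 7]
        assert spearman_rho(x, y) == pytest.approx(brute_force_spearman(x, y))

    def test_joint_permutation_invariance(self):
        x, y = [3, 1, 4, 1, 5, 9], [2, 6, 5, 3, 5, 8]
        rho = spearman_rho(x, y)
        perm = [4, 2, 0, 5, 1, 3]
        assert spearman_rho([x[i] for i in perm], [y[i] for i in perm]) == pytest.approx(rho)

    def test_constant_vector_is_undefined_correlation_error(self):
        with pytest.raises(ConstantInputError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [2, 1])

    @settings(max_examples=300, deadline=None)
    @given(
        st.integers(min_value=3, max_value=12).flatmap(
            lambda n: st.tuples(
                st.lists(st.integers(0, 5), min_size=n, max_size=n),
                st.lists(st.integers(0, 5), min_size=n, max_size=n),
            )
        )
    )
    def test_matches_brute_force_on_short_tied_vectors(self, xy):
        """Oracle: mid-rank Pearson computed from first principles, ties included."""
        x, y = xy
        if all(v == x[0] for v in x) or all(v == y[0] for v in y):
            return
        assert spearman_rho(x, y) == pytest.approx(brute_force_spearman(x, y), abs=1e-12)


class TestSummarize:
    def test_order_statistics_by_hand(self):
        records = [_rec(sid=f"s{i}", leaks=l) for i, l in enumerate([0, 1, 1, 2, 45300])]
        summary = summarize(records)
        assert summary.leak_median == 1
        assert summary.leak_min == 0
        assert summary.leak_max == 45300

    def test_even_count_uses_mean_of_central_pair(self):
        records = [_rec(sid=f"s{i}", leaks=l) for i, l in enumerate([0, 1, 3, 10])]
        assert summarize(records).leak_median == 2.0

    def test_single_record_median_min_max_coincide(self):
        summary = summarize([_rec(leaks=7)])
        assert summary.leak_median == summary.leak_min == summary.leak_max == 7

    def test_per_tumour_grouping_and_rho_sign(self):
        records = []
        for i in range(6):
            records.append(_rec("IS1", f"a{i}", f"t{i}", f1=0.5 + 0.08 * i, leaks=10 - i))
            records.append(_rec("IS2", f"b{i}", f"t{i}", f1=0.9, leaks=0))
        summary = summarize(records)
        assert set(summary.per_tumour) == {"IS1", "IS2"}
        assert summary.per_tumour["IS1"].spearman_rho == pytest.approx(-1.0)
        assert summary.per_tumour["IS2"].spearman_rho is None  # constant: undefined
        assert summary.per_tumour["IS2"].leak_median == 0

    def test_invariant_to_record_order(self, rng):
        records = [
            _rec("IS%d" % (i % 3 + 1), f"s{i}", f"t{i % 5}", f1=rng.random(),
                 leaks=rng.randint(0, 50))
            for i in range(30)
        ]
        shuffled = records[:]
        rng.shuffle(shuffled)
        assert summarize(records) == summarize(shuffled)

    def test_exclude_admin_drops_flagged_rows(self):
        records = [_rec(sid="user", leaks=0), _rec(sid="admin", leaks=100, admin=True),
                   _rec(sid="user2", leaks=2)]
        assert summarize(records).leak_max == 100
        assert summarize(records, exclude_admin=True).leak_max == 2

    def test_empty_input_is_contract_violation(self):
        with pytest.raises(LeakguardError):
            summarize([])


class TestBestPerTeam:
    def test_highest_f1_wins(self):
        records = [_rec(sid="lo", f1=0.8), _rec(sid="hi", f1=0.9)]
        assert [r.submission_id for r in best_per_team(records)] == ["hi"]

    def test_f1_tie_broken_by_fewest_leaks_then_id(self):
        records = [_rec(sid="b", f1=0.9, leaks=3), _rec(sid="a", f1=0.9, leaks=0)]
        assert [r.submission_id for r in best_per_team(records)] == ["a"]
        records = [_rec(sid="b", f1=0.9, leaks=0), _rec(sid="a", f1=0.9, leaks=0)]
        assert [r.submission_id for r in best_per_team(records)] == ["a"]

    def test_exhaustive_three_teams_two_tumours(self):
        records = []
        expected = set()
        for tumour in ("IS1", "IS2"):
            for team in ("t1", "t2", "t3"):
                best_f1 = 0.0
                for i in range(4):
                    f1 = round(random.Random(hash((tumour, team, i)) % 2**31).random(), 3)
                    records.append(_rec(tumour, f"{tumour}.{team}.{i}", team, f1=f1))
                # brute-force expectation
                group = [r for r in records if r.tumour == tumour and r.team_id == team]
                expected.add(sorted(group, key=lambda r: (-r.f1, r.leak_count, r.submission_id))[0].submission_id)
        chosen = best_per_team(records)
        assert len(chosen) == 6
        assert {r.submission_id for r in chosen} == expected

    def test_missing_team_id_skipped_with_warning(self, caplog):
        records = [_rec(sid="ok"), _rec(sid="anon", team="")]
        with caplog.at_level("WARNING"):
            chosen = best_per_team(records)
        assert [r.submission_id for r in chosen] == ["ok"]
        assert any("anon" in message for message in caplog.messages)


class TestLeakRecurrence:
    k = staticmethod(lambda pos: VariantKey("1", pos, "A", "G"))

    def test_disjoint_sets_all_occurrences_one(self):
        result = leak_recurrence([{self.k(1)}, {self.k(2)}, {self.k(3)}])
        assert set(result.occurrences.values()) == {1}
        assert result.n_recurrent == 0

    def test_multiset_union_oracle(self):
        a, b, c = self.k(1), self.k(2), self.k(3)
        result = leak_recurrence([("s1", {a, b}), ("s2", {b, c}), ("s3", {b})])
        assert result.occurrences == {a: 1, b: 3, c: 1}
        assert result.n_distinct == 3
        assert result.n_recurrent == 1

    def test_empty_list_gives_empty_result(self):
        result = leak_recurrence([])
        assert result.occurrences == {} and result.n_distinct == 0


class TestSubmissionTableIO:
    def test_round_trip_tsv(self, tmp_path):
        records = [_rec(sid=f"s{i}", leaks=i, admin=(i == 2)) for i in range(4)]
        path = tmp_path / "subs.tsv"
        records_to_frame(records).to_csv(path, sep="\t", index=False)
        assert read_submission_table(path) == records

    def test_column_order_free_and_csv(self, tmp_path):
        path = tmp_path / "subs.csv"
        path.write_text(
            "leak_count,f1,team_id,tumour,submission_id,precision,recall,is_admin\n"
            "3,0.5,tA,IS2,sub9,0.5,0.5,true\n"
        )
        (record,) = read_submission_table(path)
        assert record.tumour == "IS2" and record.leak_count == 3 and record.is_admin

    def test_missing_column_is_clear_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("tumour\tf1\nIS1\t0.5\n")
        with pytest.raises(LeakguardError, match="missing required column"):
            read_submission_table(path)

    def test_f1_inconsistent_with_precision_recall_warns(self, caplog):
        with caplog.at_level("WARNING"):
            SubmissionRecord("IS1", "s", "t", 0.9, 0.5, 0.9, 0)
        assert any("inconsistent" in message for message in caplog.messages)
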