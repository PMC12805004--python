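"""Survey record I/O, curation rules, color counting, parity summaries."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import catsym as cs


def _rec(language="l", glottocode="glot1234", family="fam", size=4,
         domain="seasons", source=""):
    return cs.SystemRecord(
        language=language, glottocode=glottocode, family=family,
        domain=domain, size=size, source=source,
    )


class TestReadSystemRecords:
    def _write(self, tmp_path, rows):
        path = tmp_path / "systems.csv"
        pd.DataFrame(
            rows,
            columns=["language", "glottocode", "family", "domain", "size"],
        ).to_csv(path, index=False)
        return path

    def test_well_formed_file(self, tmp_path):
        path = self._write(tmp_path, [
            ("a", "aaaa1234", "F1", "seasons", 4),
            ("b", "bbbb1234", "F1", "seasons", 3),
            ("c", "cccc1234", "F2", "seasons", 2),
        ])
        records = cs.read_system_records(path)
        assert len(records) == 3
        assert [r.parity for r in records] == ["even", "odd", "even"]

    def test_non_integer_size_fails_naming_row(self, tmp_path):
        path = self._write(tmp_path, [
            ("a", "aaaa1234", "F1", "seasons", 4),
            ("b", "bbbb1234", "F1", "seasons", "4.5"),
        ])
        with pytest.raises(ValueError, match="row 3.*4.5"):
            cs.read_system_records(path)

    def test_missing_glottocode_flagged_not_dropped(self, tmp_path):
        path = self._write(tmp_path, [
            ("natleba", "", "F1", "day_names", 5),
            ("b", "bbbb1234", "F1", "day_names", 7),
        ])
        records = cs.read_system_records(path)
        assert len(records) == 2
        assert records[0].excluded_from_regression
        assert not records[1].excluded_from_regression

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"language": ["a"], "size": [3]}).to_csv(
            path, index=False
        )
        with pytest.raises(ValueError, match="missing columns"):
            cs.read_system_records(path)

    def test_round_trip_write_read(self, tmp_path):
        records = [_rec(language=f"l{i}", size=i + 1) for i in range(4)]
        path = tmp_path / "out.csv"
        cs.write_system_records(records, path)
        assert cs.read_system_records(path) == records


class TestDedupeByGlottocode:
    def test_conflicting_parity_keeps_contradicting_record(self):
        records = [
            _rec(language="w1", glottocode="waja1257", size=4),
            _rec(language="w2", glottocode="waja1257", size=3),
        ]
        kept = cs.dedupe_by_glottocode(records, predicted_parity="even")
        assert [r.size for r in kept] == [3]
        kept = cs.dedupe_by_glottocode(records, predicted_parity="odd")
        assert [r.size for r in kept] == [4]

    def test_agreeing_duplicates_keep_first(self):
        records = [
            _rec(language="a1", glottocode="aaaa1234", size=2),
            _rec(language="a2", glottocode="aaaa1234", size=4),
            _rec(language="b", glottocode="bbbb1234", size=3),
        ]
        kept = cs.dedupe_by_glottocode(records, predicted_parity="even")
        assert [(r.language, r.size) for r in kept] == [("a1", 2), ("b", 3)]

    def test_no_duplicates_unchanged(self):
        records = [_rec(glottocode=f"g{i:03d}1234") for i in range(3)]
        assert cs.dedupe_by_glottocode(records, "even") == records

    def test_unpredicted_conflict_warns_and_keeps_first(self):
        records = [
            _rec(language="a1", glottocode="aaaa1234", size=4),
            _rec(language="a2", glottocode="aaaa1234", size=3),
        ]
        with pytest.warns(UserWarning, match="conflicting parity"):
            kept = cs.dedupe_by_glottocode(records, "none")
        assert [r.language for r in kept] == ["a1"]

    def test_missing_glottocode_passes_through(self):
        records = [_rec(glottocode=""), _rec(glottocode="")]
        assert cs.dedupe_by_glottocode(records, "even") == records

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(
        st.tuples(st.integers(0, 4), st.integers(1, 9)),
        min_size=1, max_size=20,
    ))
    def test_matches_brute_force_selection(self, raw):
        """Property: dedupe equals per-glottocode manual selection."""
        records = [
            _rec(language=f"l{i}", glottocode=f"g{g}aa1234", size=size)
            for i, (g, size) in enumerate(raw)
        ]
        kept = cs.dedupe_by_glottocode(records, predicted_parity="even")
        seen = {}
        for r in records:  # brute-force re-selection
            seen.setdefault(r.glottocode, []).append(r)
        expected = {}
        for g, dups in seen.items():
            odd = [r for r in dups if r.parity == "odd"]
            expected[g] = (
                odd[0] if odd and any(r.parity == "even" for r in dups)
                else dups[0]
            )
        assert len(kept) == len(seen)
        assert {r.glottocode: r for r in kept} == expected


class TestLargestPerLanguage:
    def test_keeps_maximum_size(self):
        records = [
            _rec(language="alyawarr", size=4, source="s1"),
            _rec(language="alyawarr", size=4, source="s2"),
            _rec(language="alyawarr", size=8, source="s3"),
            _rec(language="other", size=2),
        ]
        kept = cs.largest_per_language(records)
        assert [(r.language, r.size) for r in kept] == [
            ("alyawarr", 8), ("other", 2),
        ]

    def test_tie_keeps_first(self):
        records = [
            _rec(language="a", size=4, source="first"),
            _rec(language="a", size=4, source="second"),
        ]
        kept = cs.largest_per_language(records)
        assert [r.source for r in kept] == ["first"]

    def test_single_record_unchanged(self):
        records = [_rec()]
        assert cs.largest_per_language(records) == records


class TestCountColorTerms:
    def _table(self):
        # 10 participants; "warm" reaches 6/10 on chip c1; "cool" tops at 5/10
        rows = []
        for p in range(10):
            rows.append((f"p{p}", "c1", "warm" if p < 6 else "x"))
            rows.append((f"p{p}", "c2", "cool" if p < 5 else f"y{p}"))
        return pd.DataFrame(rows, columns=["participant", "chip", "term"])

    def test_boundary_inclusive_at_threshold(self):
        assert cs.count_color_terms(self._table(), threshold=0.6) == 1

    def test_below_threshold_not_counted(self):
        df = self._table()
        df.loc[(df.chip == "c1") & (df.term == "warm"), "term"] = [
            "warm"] * 5 + ["z"]
        assert cs.count_color_terms(df, threshold=0.6) == 0

    def test_synthetic_consensus_count_recovered(self):
        df = cs.simulate_color_table(
            n_participants=10, n_chips=12, n_consensus_terms=4, seed=3
        )
        assert cs.count_color_terms(df, threshold=0.6) == 4
        # brute-force recount
        n = df.participant.nunique()
        frac = df.groupby(["chip", "term"]).participant.nunique() / n
        assert (frac.groupby("term").max() >= 0.6).sum() == 4

    def test_invariant_to_row_order_and_monotone_in_threshold(self):
        df = cs.simulate_color_table(10, 8, 3, seed=9)
        shuffled = df.sample(frac=1.0, random_state=0)
        assert cs.count_color_terms(df) == cs.count_color_terms(shuffled)
        counts = [
            cs.count_color_terms(df, threshold=t)
            for t in (0.2, 0.4, 0.6, 0.8, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_double_answer_rejected(self):
        df = pd.DataFrame(
            [("p1", "c1", "a"), ("p1", "c1", "b")],
            columns=["participant", "chip", "term"],
        )
        with pytest.raises(ValueError, match="more than one term"):
            cs.count_color_terms(df)

    def test_empty_table_rejected(self):
        df = pd.DataFrame(columns=["participant", "chip", "term"])
        with pytest.raises(ValueError, match="empty"):
            cs.count_color_terms(df)


class TestParitySummary:
    def test_powers_of_two_flag(self):
        summary = cs.parity_summary(
            [_rec(size=s, language=f"l{i}") for i, s in enumerate((2, 4, 8, 4))]
        )
        assert summary.all_powers_of_two
        assert summary.n_even == 4 and summary.n_odd == 0
        assert summary.size_histogram == {2: 1, 4: 2, 8: 1}

    def test_odd_sizes(self):
        summary = cs.parity_summary([_rec(size=3), _rec(size=5)])
        assert summary.n_odd == 2 and not summary.all_powers_of_two

    def test_size_one_is_power_of_two(self):
        summary = cs.parity_summary([_rec(size=1)])
        assert summary.n_odd == 1 and summary.all_powers_of_two

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cs.parity_summary([])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.integers(1, 12), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    def test_counts_invariant_under_permutation(self, sizes, rnd):
        records = [_rec(language=f"l{i}", size=s) for i, s in enumerate(sizes)]
        shuffled = list(records)
        rnd.shuffle(shuffled)
        a, b = cs.parity_summary(records), cs.parity_summary(shuffled)
        assert (a.n_odd, a.n_even, a.size_histogram) == (
            b.n_odd, b.n_even, b.size_histogram
        )
        assert a.n == len(sizes)
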