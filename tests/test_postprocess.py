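import pytest
from hypothesis import given, settings, strategies as st

from discngram import (
    DataError,
    MotifInterval,
    SequenceProfile,
    SequenceRecord,
    map_to_sequences,
    mask_sequence,
    merge_contiguous,
    remove_substrings,
)
from .conftest import dataset_from_dict

gram_sets = st.lists(
    st.text(alphabet="ACDEG", min_size=4, max_size=8), min_size=0, max_size=12
)


class TestRemoveSubstrings:
    def test_substring_of_longer_gram_removed(self):
        assert remove_substrings(["LMPQS", "SLMPQST"]) == ["SLMPQST"]

    def test_disjoint_unchanged(self):
        assert set(remove_substrings(["AAAA", "CCCC"])) == {"AAAA", "CCCC"}

    @given(gram_sets)
    @settings(derandomize=True)
    def test_idempotent_and_substring_free(self, grams):
        once = remove_substrings(grams)
        assert remove_substrings(once) == once
        assert set(once) <= set(grams)
        for s in once:
            assert not any(s != t and s in t for t in once)

    @given(gram_sets)
    @settings(derandomize=True)
    def test_maximal_strings_survive(self, grams):
        if not grams:
            return
        out = set(remove_substrings(grams))
        longest = max(grams, key=len)
        maximal = [
            g for g in grams if not any(g != t and g in t for t in grams)
        ]
        assert longest in out
        assert set(maximal) == out


def _interval(seq_id, start, end, text, label="A"):
    return MotifInterval(
        seq_id=seq_id, class_label=label, start=start, end=end, text=text
    )


class TestMapping:
    def test_single_hit_one_based(self):
        ds = dataset_from_dict(
            {"A": ["XXGSSIMYY".replace("X", "P")], "B": ["AAAA"], "C": ["CCCC"]}
        )
        # sequence is PPGSSIMYY
        profiles = map_to_sequences(["GSSIM"], ds, "A")
        assert len(profiles) == 1
        (hit,) = profiles[0].hits
        assert (hit.start, hit.end, hit.text) == (3, 7, "GSSIM")

    def test_repeated_gram_yields_two_intervals(self):
        ds = dataset_from_dict(
            {"A": ["GSSIMAAGSSIM"], "B": ["CCCC"], "C": ["DDDD"]}
        )
        profiles = map_to_sequences(["GSSIM"], ds, "A")
        starts = [h.start for h in profiles[0].hits]
        assert starts == [1, 8]

    def test_matches_all_positions_scan(self):
        seq = "ACACACGTACAC".replace("T", "D").replace("G", "E")
        ds = dataset_from_dict({"A": [seq], "B": ["KKKK"], "C": ["MMMM"]})
        grams = ["ACAC", "CACA"]
        profiles = map_to_sequences(grams, ds, "A")
        expected = []
        for g in grams:
            for i in range(len(seq) - len(g) + 1):
                if seq[i : i + len(g)] == g:
                    expected.append((i + 1, i + len(g), g))
        got = [(h.start, h.end, h.text) for h in profiles[0].hits]
        assert sorted(got) == sorted(expected)


class TestMerge:
    def _merge(self, spans, texts=None):
        hits = [
            _interval("s1", a, b, texts[i] if texts else "Z" * (b - a + 1))
            for i, (a, b) in enumerate(spans)
        ]
        profile = SequenceProfile(seq_id="s1", hits=hits)
        return [(m.start, m.end) for m in merge_contiguous(profile)]

    def test_adjacent_merge(self):
        assert self._merge([(3, 8), (9, 12)]) == [(3, 12)]

    def test_overlap_merge(self):
        assert self._merge([(3, 8), (6, 12)]) == [(3, 12)]

    def test_gap_of_two_not_merged(self):
        assert self._merge([(3, 8), (11, 14)]) == [(3, 8), (11, 14)]

    def test_chain_merges_transitively(self):
        assert self._merge([(1, 5), (5, 9), (10, 14)]) == [(1, 14)]

    def test_merged_text_is_stitched_from_sequence(self):
        seq = "MKVLADEGHKPQ"
        hits = [
            _interval("s1", 1, 5, seq[0:5]),
            _interval("s1", 4, 9, seq[3:9]),
            _interval("s1", 10, 12, seq[9:12]),
        ]
        merged = merge_contiguous(SequenceProfile("s1", hits))
        assert [(m.start, m.end, m.text) for m in merged] == [(1, 12, seq)]

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=30),
                st.integers(min_value=0, max_value=7),
            ),
            min_size=1,
            max_size=10,
        )
    )
    @settings(derandomize=True)
    def test_coverage_preserved_and_gaps_at_least_two(self, raw):
        spans = [(a, a + w) for a, w in raw]
        hits = [_interval("s1", a, b, "Z" * (b - a + 1)) for a, b in spans]
        merged = merge_contiguous(SequenceProfile("s1", hits))
        covered = set()
        for a, b in spans:
            covered.update(range(a, b + 1))
        merged_cover = set()
        for m in merged:
            merged_cover.update(range(m.start, m.end + 1))
        assert merged_cover == covered
        for x, y in zip(merged, merged[1:]):
            assert x.end < y.start - 1


class TestMask:
    def test_worked_example(self):
        rec = SequenceRecord("s1", "PENEPGSSIM", "A")
        masked = mask_sequence(rec, [_interval("s1", 6, 10, "GSSIM")])
        assert masked == "XXXXXGSSIM"

    def test_no_motifs_all_masked(self):
        rec = SequenceRecord("s1", "PENEP", "A")
        assert mask_sequence(rec, []) == "XXXXX"

    def test_full_span_identity(self):
        rec = SequenceRecord("s1", "PENEP", "A")
        assert mask_sequence(rec, [_interval("s1", 1, 5, "PENEP")]) == "PENEP"

    def test_overlapping_motifs_rejected(self):
        rec = SequenceRecord("s1", "PENEPGSSIM", "A")
        with pytest.raises(DataError, match="merge"):
            mask_sequence(
                rec,
                [_interval("s1", 1, 5, "PENEP"), _interval("s1", 4, 8, "EPGSS")],
            )

    def test_out_of_bounds_rejected(self):
        rec = SequenceRecord("s1", "PENEP", "A")
        with pytest.raises(DataError, match="exceeds"):
            mask_sequence(rec, [_interval("s1", 3, 9, "NEPXXXX")])

    def test_length_and_unmasked_residues_preserved(self):
        rec = SequenceRecord("s1", "MKVLADEGHK", "A")
        motifs = [_interval("s1", 2, 4, "KVL"), _interval("s1", 7, 9, "EGH")]
        masked = mask_sequence(rec, motifs)
        assert len(masked) == len(rec.residues)
        for m in motifs:
            assert masked[m.start - 1 : m.end] == rec.residues[m.start - 1 : m.end]
        for i, ch in enumerate(masked, 1):
            if not any(m.start <= i <= m.end for m in motifs):
                assert ch == "X"
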