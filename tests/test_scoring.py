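import math

import pytest

from discngram import (
    ConfigurationError,
    DiscriminativeNGram,
    build_profile,
    dampen,
    damping_factor,
    dedupe_across_classes,
    discriminative_ratio,
    enrich_profile,
    select_discriminative,
)
from discngram.ngram_core import FrequencyProfile
from discngram.scoring import DampedProfile
from discngram.substitution import CombinedNGram
from .conftest import dataset_from_dict


class TestDampingFactor:
    @pytest.mark.parametrize("k", range(1, 11))
    def test_closed_form(self, k):
        assert damping_factor(10, k) == pytest.approx(
            math.log(10 / (k - 0.1)), abs=1e-15
        )

    def test_nonzero_when_present_everywhere(self):
        assert damping_factor(10, 10) == pytest.approx(0.01005, abs=5e-6)

    def test_single_class_presence(self):
        assert damping_factor(10, 1) == pytest.approx(2.4079, abs=5e-5)

    def test_strictly_decreasing_in_presence(self):
        for c in (3, 5, 10):
            factors = [damping_factor(c, k) for k in range(1, c + 1)]
            assert all(a > b for a, b in zip(factors, factors[1:]))
            assert factors[-1] > 0

    @pytest.mark.parametrize("k", [0, 11, -1])
    def test_domain_errors(self, k):
        with pytest.raises(ValueError):
            damping_factor(10, k)


class TestDampen:
    def _profile(self, counts, labels):
        return FrequencyProfile(n=4, class_index=labels, counts=counts)

    def test_single_class_presence_weight(self):
        labels = tuple(f"C{i}" for i in range(10))
        profile = self._profile({"AAAA": [5] + [0] * 9}, labels)
        damped = dampen(profile)
        assert damped.weights["AAAA"][0] == pytest.approx(5 * math.log(10 / 0.9))
        assert damped.weights["AAAA"][1:] == [0.0] * 9

    def test_ubiquitous_gram_shrunk(self):
        labels = tuple(f"C{i}" for i in range(10))
        profile = self._profile({"AAAA": [2] * 10}, labels)
        damped = dampen(profile)
        factor = math.log(10 / 9.9)
        assert damped.damping["AAAA"] == pytest.approx(factor)
        assert damped.weights["AAAA"] == pytest.approx([2 * factor] * 10)

    def test_presence_uses_raw_counts_not_enriched(self):
        profile = self._profile(
            {"AAAA": [4, 0, 0], "AAAS": [0, 1, 0]}, ("A", "B", "C")
        )
        enriched = {
            "AAAA": CombinedNGram("AAAA", ("AAAS",), [4, 1, 0]),
            "AAAS": CombinedNGram("AAAS", ("AAAA",), [4, 1, 0]),
        }
        damped = dampen(profile, enriched)
        # raw presence of AAAA is 1 class even though enriched touches 2
        assert damped.damping["AAAA"] == pytest.approx(math.log(3 / 0.9))
        assert damped.weights["AAAA"] == pytest.approx(
            [4 * math.log(3 / 0.9), 1 * math.log(3 / 0.9), 0.0]
        )


class TestDiscriminativeRatio:
    @pytest.mark.parametrize(
        "weights, expected_dr, expected_class",
        [
            ([7, 0, 0, 0, 0], 7.0, "0"),  # both runners-up zero: mean -> 1
            ([12, 4, 0], 3.0, "0"),  # only third zero: mean = second
            ([5, 0.6, 0.2], 5.0, "0"),  # fractional mean forced to 1
            ([50, 8, 2, 0], 10.0, "0"),  # plain ratio: 50 / mean(8, 2)
        ],
    )
    def test_degenerate_rules(self, weights, expected_dr, expected_class):
        dr, top = discriminative_ratio(weights)
        assert dr == pytest.approx(expected_dr)
        assert top == expected_class

    def test_two_classes_rejected(self):
        with pytest.raises(ConfigurationError):
            discriminative_ratio([5, 1])

    def test_all_zero_weights(self):
        dr, _ = discriminative_ratio([0, 0, 0])
        assert dr == 0.0


def _damped(weights_by_gram, labels=("A", "B", "C"), groups=None):
    return DampedProfile(
        class_index=labels,
        weights=weights_by_gram,
        damping={g: 1.0 for g in weights_by_gram},
        groups=groups,
    )


class TestSelection:
    def test_boundary_is_inclusive(self):
        damped = _damped({"AAAA": [10.0, 2.0, 0.0], "CCCC": [4.99, 0.0, 0.0]})
        selected = {it.gram for it in select_discriminative(damped, 5.0)}
        assert selected == {"AAAA"}  # dr 10 in, dr 4.99 out
        selected = {it.gram for it in select_discriminative(damped, 4.99)}
        assert selected == {"AAAA", "CCCC"}

    def test_constituents_emitted_with_combined_dr(self):
        groups = {
            "AAAA": CombinedNGram("AAAA", ("AAAS", "AASA"), [9, 0, 0]),
            "AAAS": CombinedNGram("AAAS", ("AAAA",), [9, 0, 0]),
            "AASA": CombinedNGram("AASA", ("AAAA",), [9, 0, 0]),
        }
        damped = _damped(
            {"AAAA": [9.0, 0.0, 0.0], "AAAS": [9.0, 0.0, 0.0],
             "AASA": [9.0, 0.0, 0.0]},
            groups=groups,
        )
        out = select_discriminative(damped, 5.0)
        by_gram = {}
        for it in out:
            by_gram.setdefault(it.gram, []).append(it)
        assert set(by_gram) == {"AAAA", "AAAS", "AASA"}
        for items in by_gram.values():
            assert all(it.dr == 9.0 and it.assigned_class == "A" for it in items)

    def test_threshold_must_exceed_one(self):
        damped = _damped({"AAAA": [10.0, 0.0, 0.0]})
        with pytest.raises(ConfigurationError):
            select_discriminative(damped, 1.0)

    def test_top_class_tie_never_selected(self):
        damped = _damped({"AAAA": [10.0, 10.0, 2.0]})
        assert select_discriminative(damped, 1.5) == []

    def test_raising_threshold_never_adds_grams(self, toy_three_class, blosum62):
        profile = build_profile(toy_three_class, 4)
        damped = dampen(profile, enrich_profile(profile, blosum62))
        low = {it.gram for it in select_discriminative(damped, 2.0)}
        high = {it.gram for it in select_discriminative(damped, 6.0)}
        assert high <= low


class TestDedupe:
    def test_highest_dr_survives(self):
        items = [
            DiscriminativeNGram("AAAA", "A", 9.0),
            DiscriminativeNGram("AAAA", "B", 6.0),
        ]
        out = dedupe_across_classes(items)
        assert len(out) == 1 and out[0].assigned_class == "A"

    def test_no_duplicates_identity(self):
        items = [
            DiscriminativeNGram("AAAA", "A", 9.0),
            DiscriminativeNGram("CCCC", "B", 6.0),
        ]
        out = dedupe_across_classes(items)
        assert {(i.gram, i.assigned_class, i.dr) for i in out} == {
            (i.gram, i.assigned_class, i.dr) for i in items
        }

    def test_dr_tie_goes_to_smaller_class_label(self):
        items = [
            DiscriminativeNGram("AAAA", "B", 9.0),
            DiscriminativeNGram("AAAA", "A", 9.0),
        ]
        out = dedupe_across_classes(items)
        assert out[0].assigned_class == "A"

    def test_one_class_per_gram(self, toy_three_class, blosum62):
        profile = build_profile(toy_three_class, 4)
        damped = dampen(profile, enrich_profile(profile, blosum62))
        out = dedupe_across_classes(select_discriminative(damped, 2.0))
        grams = [it.gram for it in out]
        assert len(grams) == len(set(grams))


def test_sf2_equals_sf1_without_eligible_neighbors(blosum62):
    """On a profile with no similar gram pairs, combining changes nothing."""
    ds = dataset_from_dict(
        {"A": ["AAAAAAAA"], "B": ["MMMMMMMM"], "C": ["HHHHHHHH"]}
    )
    profile = build_profile(ds, 4)
    enriched = enrich_profile(profile, blosum62)
    assert all(not grp.constituents for grp in enriched.values())
    sf1 = dampen(profile, enriched)
    sf2 = dampen(profile)
    assert sf1.weights == sf2.weights
    s1 = select_discriminative(sf1, 2.0)
    s2 = select_discriminative(sf2, 2.0)
    assert {(i.gram, i.assigned_class, i.dr) for i in s1} == {
        (i.gram, i.assigned_class, i.dr) for i in s2
    }
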