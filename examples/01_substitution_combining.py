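"""Combine BLOSUM62-similar n-grams around a seed.

Builds a tiny two-class frequency profile containing TLSNPK and three
single-position variants, finds the variants whose differing residue pair
has a positive substitution score, and pools their class-wise counts into a
combined n-gram.
"""

from discngram import combine, find_similar, load_blosum62
from discngram.ngram_core import FrequencyProfile

profile = FrequencyProfile(
    n=6,
    class_index=("membrane", "nuclear"),
    counts={
        "TLSNPK": [3, 0],
        "TLNNPK": [2, 1],
        "TLSDPK": [1, 0],
        "TLSSPK": [0, 2],
        "TLPNPK": [1, 1],  # S->P scores below +1: not similar
        "QQQQQQ": [5, 5],
    },
)

matrix = load_blosum62()
similars = find_similar("TLSNPK", profile, matrix)
combined = combine("TLSNPK", similars, profile)

print("seed:         TLSNPK")
print("similar grams:", ", ".join(sorted(similars)))
print("combined:     ", combined.display)
print("pooled counts:", dict(zip(profile.class_index, combined.counts)))
# The combined gram TL[SN][NDS]PK pools the counts of the seed and every
# variant reachable by one positively-scoring residue change; TLPNPK stays
# out because S/P scores -1 in BLOSUM62.
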