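"""Combining of similar n-grams via BLOSUM62-positive single-residue changes.

Two same-length n-grams are similar when they differ at exactly one position
and the pair of differing residues has a substitution score at or above the
BLOSUM62 threshold (default 1, i.e. a positive score).  Around each n-gram
present in the dataset we form a combined n-gram pooling the class-wise raw
counts of the seed and all of its similar neighbors; in bracket display a
combined gram reads e.g. TL[SN][NDS]PK.  Grouping is seed-centric: every
gram is the seed of its own (possibly overlapping) group, and groups are
never merged transitively.  Only grams actually present in the dataset are
eligible as neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io_formats import SubstitutionMatrix
from .ngram_core import FrequencyProfile


@dataclass(frozen=True)
class SubstitutionConfig:
    """Substitution behaviour: SF1 when enabled, SF2 (no combining) when not."""

    blosum_threshold: int = 1
    enabled: bool = True


@dataclass(frozen=True)
class CombinedNGram:
    """A seed n-gram pooled with its single-position similar variants.

    ``constituents`` are the similar neighbors (seed excluded), sorted
    lexicographically; ``counts`` is the class-wise sum of the raw counts of
    the seed and all constituents.
    """

    seed: str
    constituents: tuple[str, ...]
    counts: list[int]

    @property
    def members(self) -> tuple[str, ...]:
        return (self.seed, *self.constituents)

    @property
    def position_sets(self) -> tuple[tuple[str, ...], ...]:
        """Residues observed at each position, seed residue first then
        first-seen order over the lexicographically sorted constituents."""
        sets = []
        for i, a in enumerate(self.seed):
            seen = [a]
            for other in self.constituents:
                r = other[i]
                if r not in seen:
                    seen.append(r)
            sets.append(tuple(seen))
        return tuple(sets)

    @property
    def display(self) -> str:
        """Bracket notation, e.g. ``TL[SN][NDS]PK``."""
        parts = []
        for residues in self.position_sets:
            if len(residues) == 1:
                parts.append(residues[0])
            else:
                parts.append("[" + "".join(residues) + "]")
        return "".join(parts)


def find_similar(
    seed: str,
    profile: FrequencyProfile,
    matrix: SubstitutionMatrix,
    cfg: SubstitutionConfig = SubstitutionConfig(),
) -> set[str]:
    """Every profile gram at Hamming distance 1 from ``seed`` whose differing
    residue pair scores >= the threshold.  Never includes the seed."""
    if not cfg.enabled:
        return set()
    counts = profile.counts
    similars: set[str] = set()
    for i, a in enumerate(seed):
        prefix, suffix = seed[:i], seed[i + 1 :]
        for b in matrix.positive_partners(a, cfg.blosum_threshold):
            candidate = prefix + b + suffix
            if candidate in counts:
                similars.add(candidate)
    return similars


def combine(
    seed: str, similars: Iterable[str], profile: FrequencyProfile
) -> CombinedNGram:
    """Pool the seed with its similar neighbors into a combined n-gram with
    class-wise summed raw counts."""
    width = profile.num_classes
    zeros = [0] * width
    ordered = tuple(sorted(similars))
    total = list(profile.counts.get(seed, zeros))
    for other in ordered:
        row = profile.counts.get(other, zeros)
        for c in range(width):
            total[c] += row[c]
    return CombinedNGram(seed=seed, constituents=ordered, counts=total)


def enrich_profile(
    profile: FrequencyProfile,
    matrix: SubstitutionMatrix,
    cfg: SubstitutionConfig = SubstitutionConfig(),
) -> dict[str, CombinedNGram]:
    """Build the combined n-gram for every gram in the profile (seed-centric).

    With substitution disabled every combined gram is the trivial singleton
    carrying the raw counts (SF2 mode).

    Neighbor finding buckets grams by the n keys obtained by deleting one
    position: grams sharing a key differ only at that position, so each
    bucket is scanned pairwise and filtered by the substitution score of the
    two differing residues.
    """
    counts = profile.counts
    if not cfg.enabled:
        return {
            g: CombinedNGram(seed=g, constituents=(), counts=list(row))
            for g, row in counts.items()
        }
    score = matrix.score
    threshold = cfg.blosum_threshold
    neighbors: dict[str, list[str]] = {g: [] for g in counts}
    for i in range(profile.n):
        buckets: dict[str, list[str]] = {}
        setdefault = buckets.setdefault
        for g in counts:
            setdefault(g[:i] + g[i + 1 :], []).append(g)
        for members in buckets.values():
            if len(members) < 2:
                continue
            for g in members:
                a = g[i]
                glist = neighbors[g]
                for h in members:
                    if h is not g and score(a, h[i]) >= threshold:
                        glist.append(h)
    width = profile.num_classes
    enriched: dict[str, CombinedNGram] = {}
    for g, row in counts.items():
        found = neighbors[g]
        if not found:
            enriched[g] = CombinedNGram(seed=g, constituents=(), counts=list(row))
            continue
        found.sort()
        total = list(row)
        for h in found:
            other = counts[h]
            for c in range(width):
                total[c] += other[c]
        enriched[g] = CombinedNGram(seed=g, constituents=tuple(found), counts=total)
    return enriched
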