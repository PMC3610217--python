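"""The scoring function: dampening, discriminative ratio, and selection.

Real sequence class sets are unbalanced, so raw occurrence counts are
normalized by a TF-IDF-style dampening factor

    ln(|C| / (k - 0.1))

where |C| is the number of classes and k the number of classes in which the
n-gram occurs (raw, pre-substitution presence).  The -0.1 denominator
adjustment keeps the factor strictly positive when k = |C| (otherwise
ln 1 = 0 would erase ubiquitous grams entirely) and is applied uniformly so
the factor stays strictly decreasing in k.

An n-gram's discriminative ratio (DR) is its highest dampened class weight
divided by the mean of its second- and third-highest weights, with three
degenerate-case rules:

    (a) second and third highest both zero  -> mean forced to 1,
    (b) only the third highest zero         -> mean = second highest,
    (c) a resulting mean strictly between 0 and 1 -> mean forced to 1.

Grams with DR at or above the selection threshold T are called
discriminative for their top class; when a combined gram qualifies, all of
its constituent grams are emitted as discriminative with the combined
counts' DR.  An n-gram can be discriminative in at most one class: duplicate
texts are resolved by keeping the record with the highest DR.

The statistic needs at least three classes; two-class datasets are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError
from .ngram_core import FrequencyProfile
from .substitution import CombinedNGram


def damping_factor(num_classes: int, presence_count: int) -> float:
    """ln(|C| / (k - 0.1)); strictly decreasing in the presence count k."""
    if num_classes < 2:
        raise ConfigurationError("dampening needs at least two classes")
    if not 1 <= presence_count <= num_classes:
        raise ValueError(
            f"presence count must lie in [1, {num_classes}], got {presence_count}"
        )
    return math.log(num_classes / (presence_count - 0.1))


@dataclass(frozen=True)
class DiscriminativeNGram:
    """An n-gram assigned to the class where its dampened weight peaks."""

    gram: str
    assigned_class: str
    dr: float
    threshold: float | None = None


@dataclass
class DampedProfile:
    """Dampened per-class weights for every n-gram of one size.

    ``groups`` carries the combined n-grams the weights were computed from
    (None in SF2 mode) so that selection can emit constituents.
    """

    class_index: tuple[str, ...]
    weights: dict[str, list[float]]
    damping: dict[str, float]
    groups: dict[str, CombinedNGram] | None = None
    _ratios: dict[str, tuple[float, str | None]] | None = field(
        default=None, repr=False
    )

    def ratios(self) -> dict[str, tuple[float, str | None]]:
        """gram -> (DR, top class); top class is None on a tie for the
        highest weight, in which case the gram is never discriminative."""
        if self._ratios is None:
            labels = self.class_index
            out: dict[str, tuple[float, str | None]] = {}
            for g, w in self.weights.items():
                dr, top, tied = _ratio(w, labels)
                out[g] = (dr, None if tied else top)
            self._ratios = out
        return self._ratios


def dampen(
    profile: FrequencyProfile,
    enriched: Mapping[str, CombinedNGram] | None = None,
) -> DampedProfile:
    """Multiply each gram's (enriched) class counts by its dampening factor.

    The presence count k always comes from the RAW profile; combining
    already pools counts, and presence through combined groups would
    double-count.  Pass ``enriched`` from
    :func:`~discngram.substitution.enrich_profile` for SF1, or None for SF2.
    """
    num_classes = profile.num_classes
    if num_classes < 2:
        raise ConfigurationError("dampening needs at least two classes")
    factors = [float("nan")] + [
        damping_factor(num_classes, k) for k in range(1, num_classes + 1)
    ]
    weights: dict[str, list[float]] = {}
    damping: dict[str, float] = {}
    for g, raw in profile.counts.items():
        k = sum(1 for v in raw if v)
        f = factors[k]
        source = enriched[g].counts if enriched is not None else raw
        weights[g] = [v * f for v in source]
        damping[g] = f
    return DampedProfile(
        class_index=profile.class_index,
        weights=weights,
        damping=damping,
        groups=dict(enriched) if enriched is not None else None,
    )


def _ratio(
    weights: Sequence[float], labels: Sequence[str]
) -> tuple[float, str, bool]:
    w1 = w2 = w3 = 0.0
    top = 0
    for i, v in enumerate(weights):
        if v > w1:
            w1, w2, w3 = v, w1, w2
            top = i
        elif v > w2:
            w2, w3 = v, w2
        elif v > w3:
            w3 = v
    if w2 == 0.0 and w3 == 0.0:
        mean = 1.0
    elif w3 == 0.0:
        mean = w2
    else:
        mean = (w2 + w3) / 2.0
    if 0.0 < mean < 1.0:
        mean = 1.0
    tied = w1 > 0.0 and w2 == w1
    return w1 / mean, labels[top], tied


def discriminative_ratio(
    weights: Sequence[float], labels: Sequence[str] | None = None
) -> tuple[float, str]:
    """DR of a per-class weight vector and the label of the top class.

    Requires at least three classes (the statistic is undefined otherwise).
    On a tie for the top weight the first label in index order is returned;
    such grams are never selected as discriminative.
    """
    if len(weights) < 3:
        raise ConfigurationError(
            "the discriminative ratio needs at least three classes"
        )
    if labels is None:
        labels = [str(i) for i in range(len(weights))]
    dr, top, _ = _ratio(weights, labels)
    return dr, top


def select_discriminative(
    damped: DampedProfile, threshold: float
) -> list[DiscriminativeNGram]:
    """All grams with DR >= threshold, assigned to their top class.

    When a qualifying gram has a combined group, every constituent is also
    emitted with the combined DR and class.  The returned list may contain
    the same gram text more than once (as seed of one group and constituent
    of another); resolve with :func:`dedupe_across_classes`.
    """
    if len(damped.class_index) < 3:
        raise ConfigurationError("selection needs at least three classes")
    if not threshold > 1:
        raise ConfigurationError(f"selection threshold must exceed 1, got {threshold}")
    groups = damped.groups
    out: list[DiscriminativeNGram] = []
    for g, (dr, top) in damped.ratios().items():
        if top is None or dr < threshold:
            continue
        out.append(
            DiscriminativeNGram(gram=g, assigned_class=top, dr=dr, threshold=threshold)
        )
        if groups is not None:
            for h in groups[g].constituents:
                out.append(
                    DiscriminativeNGram(
                        gram=h, assigned_class=top, dr=dr, threshold=threshold
                    )
                )
    return out


def dedupe_across_classes(
    items: Iterable[DiscriminativeNGram],
) -> list[DiscriminativeNGram]:
    """Keep each gram text once, in the class where its DR is highest.

    Ties on DR are broken toward the lexicographically smaller class label.
    Output is sorted by (class, DR descending, gram) for determinism.
    """
    best: dict[str, DiscriminativeNGram] = {}
    for it in items:
        cur = best.get(it.gram)
        if (
            cur is None
            or it.dr > cur.dr
            or (it.dr == cur.dr and it.assigned_class < cur.assigned_class)
        ):
            best[it.gram] = it
    return sorted(best.values(), key=lambda it: (it.assigned_class, -it.dr, it.gram))
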