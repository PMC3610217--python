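"""Exhaustive n-gram extraction and per-class frequency profiling.

A sequence of length k yields the k - n + 1 overlapping windows of length n;
occurrences are counted individually (every sliding-window hit), not as
per-sequence presence.  For a dataset the per-class occurrence counts of all
windows form a frequency profile, the object every later stage works on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .errors import ConfigurationError, DataError
from .io_formats import LabeledDataset


def extract_ngrams(residues: str, n: int) -> list[str]:
    """All overlapping length-n windows of ``residues``, left to right.

    Returns ``max(0, k - n + 1)`` windows; a sequence shorter than n yields
    an empty list.
    """
    if n < 1:
        raise ConfigurationError(f"n-gram size must be >= 1, got {n}")
    return [residues[i : i + n] for i in range(len(residues) - n + 1)]


@dataclass
class FrequencyProfile:
    """Per-class occurrence counts for every distinct n-gram of one size.

    ``counts[g]`` is a vector of non-negative integers indexed parallel to
    ``class_index``.  The class order is the dataset's (lexicographic), so
    the profile does not depend on sequence input order.
    """

    n: int
    class_index: tuple[str, ...]
    counts: dict[str, list[int]]

    @property
    def num_classes(self) -> int:
        return len(self.class_index)

    def total_occurrences(self, label: str) -> int:
        ci = self.class_index.index(label)
        return sum(row[ci] for row in self.counts.values())

    def presence_count(self, gram: str) -> int:
        """Number of classes in which ``gram`` occurs at least once."""
        return sum(1 for v in self.counts[gram] if v)


def build_profile(dataset: LabeledDataset, n: int) -> FrequencyProfile:
    """Count every overlapping occurrence of every length-n window per class."""
    if n < 1:
        raise ConfigurationError(f"n-gram size must be >= 1, got {n}")
    if not dataset.records:
        raise DataError("cannot profile an empty dataset")
    index: Mapping[str, int] = {c: i for i, c in enumerate(dataset.classes)}
    width = len(dataset.classes)
    counts: dict[str, list[int]] = {}
    get = counts.get
    for rec in dataset.records:
        ci = index[rec.class_label]
        s = rec.residues
        for i in range(len(s) - n + 1):
            g = s[i : i + n]
            row = get(g)
            if row is None:
                row = [0] * width
                counts[g] = row
            row[ci] += 1
    return FrequencyProfile(n=n, class_index=dataset.classes, counts=counts)
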