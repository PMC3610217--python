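"""Substring removal, mapping onto sequences, interval merging, masking.

Coordinates are 1-based inclusive throughout.  Two mapped hits x and y merge
when end(x) >= start(y) - 1, i.e. they overlap or are exactly adjacent; the
sweep is applied to a fixed point so chains merge transitively.  Masking
flips every position not covered by a motif to 'X'.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import DataError
from .io_formats import LabeledDataset, SequenceRecord


@dataclass(frozen=True)
class MotifInterval:
    """A mapped (or merged) discriminative region on one sequence."""

    seq_id: str
    class_label: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    text: str

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise DataError(
                f"bad interval [{self.start}, {self.end}] on {self.seq_id!r}"
            )

    def overlaps(self, other: "MotifInterval") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class SequenceProfile:
    """Hits of discriminative n-grams on one sequence, sorted by start
    (ties by descending end, so the longest hit anchors a merge)."""

    seq_id: str
    hits: list[MotifInterval]


def remove_substrings(grams: Iterable[str]) -> list[str]:
    """Drop every gram that is a contiguous substring of a longer gram.

    Mirrors the declared sort (alphabetical, then size low-to-high) in its
    output order; idempotent, and never removes a maximal-length string.
    """
    ordered = sorted(set(grams))
    ordered.sort(key=len)  # stable: size primary, alphabetical secondary
    kept: list[str] = []
    for i, s in enumerate(ordered):
        # candidates strictly longer than s all sit further right
        j = i + 1
        while j < len(ordered) and len(ordered[j]) == len(s):
            j += 1
        if not any(s in t for t in ordered[j:]):
            kept.append(s)
    return kept


def map_to_sequences(
    grams: Sequence[str], dataset: LabeledDataset, class_label: str
) -> list[SequenceProfile]:
    """Locate every (overlapping) occurrence of every gram in every sequence
    of the given class."""
    if class_label not in dataset.classes:
        raise DataError(f"unknown class {class_label!r}")
    profiles = []
    for rec in dataset.records:
        if rec.class_label != class_label:
            continue
        hits: list[MotifInterval] = []
        residues = rec.residues
        for g in grams:
            pos = residues.find(g)
            while pos != -1:
                hits.append(
                    MotifInterval(
                        seq_id=rec.seq_id,
                        class_label=class_label,
                        start=pos + 1,
                        end=pos + len(g),
                        text=g,
                    )
                )
                pos = residues.find(g, pos + 1)
        hits.sort(key=lambda h: (h.start, -h.end))
        profiles.append(SequenceProfile(seq_id=rec.seq_id, hits=hits))
    return profiles


def merge_contiguous(profile: SequenceProfile) -> list[MotifInterval]:
    """Left-to-right sweep merging overlapping or adjacent hits.

    Output intervals pairwise satisfy end(i) < start(i+1) - 1.  Merged text
    is stitched from the hit texts (adjacency leaves no holes).
    """
    merged: list[MotifInterval] = []
    cur_start = cur_end = 0
    cur_text = ""
    cur_class = ""
    for h in sorted(profile.hits, key=lambda h: (h.start, -h.end)):
        if merged or cur_end:
            if h.start <= cur_end + 1:
                if h.end > cur_end:
                    cur_text += h.text[cur_end - h.start + 1 :]
                    cur_end = h.end
                continue
            merged.append(
                MotifInterval(profile.seq_id, cur_class, cur_start, cur_end, cur_text)
            )
        cur_start, cur_end, cur_text, cur_class = h.start, h.end, h.text, h.class_label
    if cur_end:
        merged.append(
            MotifInterval(profile.seq_id, cur_class, cur_start, cur_end, cur_text)
        )
    return merged


def mask_sequence(record: SequenceRecord, motifs: Sequence[MotifInterval]) -> str:
    """Equal-length string keeping residues under motifs, 'X' elsewhere.

    Motifs must be within bounds and non-overlapping (merge first).
    """
    length = len(record.residues)
    ordered = sorted(motifs, key=lambda m: m.start)
    prev_end = 0
    for m in ordered:
        if m.end > length:
            raise DataError(
                f"motif [{m.start}, {m.end}] exceeds sequence {record.seq_id!r} "
                f"of length {length}"
            )
        if m.start <= prev_end:
            raise DataError("overlapping motifs: merge before masking")
        prev_end = m.end
    out = ["X"] * length
    for m in ordered:
        out[m.start - 1 : m.end] = record.residues[m.start - 1 : m.end]
    return "".join(out)
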