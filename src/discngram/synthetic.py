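"""Synthetic class-labeled sequence sets with planted, mutated motifs.

The generator emulates the structure of real protein classification sets:
unbalanced class sizes, class-exclusive signal motifs planted into a
fraction of each class's sequences, single-residue BLOSUM62-positive
variants of the planted instances (mimicking positively selected point
mutations), and i.i.d. background residues.  Ground truth records every
planted interval so discovery output can be scored for motif recall and
background discovery rate.

Defaults reproduce the package's standard study conditions: five classes of
30/50/80/120/200 sequences of length 300 with two exclusive motifs per
class, plant rate 0.6 and mutation rate 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from .errors import ConfigurationError, DataError
from .io_formats import AMINO_ACIDS, LabeledDataset, SequenceRecord, load_blosum62
from .postprocess import MotifInterval
from .scoring import DiscriminativeNGram

#: Approximate Swiss-Prot amino-acid composition, for the natural-frequency
#: background preset.
NATURAL_FREQUENCIES: dict[str, float] = {
    "A": 0.0826, "C": 0.0139, "D": 0.0546, "E": 0.0672, "F": 0.0387,
    "G": 0.0707, "H": 0.0228, "I": 0.0591, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0475, "Q": 0.0393, "R": 0.0553,
    "S": 0.0665, "T": 0.0536, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}

IntOrRange = Union[int, tuple[int, int]]


@dataclass(frozen=True)
class SyntheticConfig:
    num_classes: int = 5
    seqs_per_class: tuple[int, ...] = (30, 50, 80, 120, 200)
    seq_length: IntOrRange = 300
    motifs_per_class: int = 2
    motif_length: IntOrRange = (6, 12)
    plant_rate: float = 0.6
    mutation_rate: float = 0.3
    background: Union[str, Mapping[str, float]] = "uniform"
    seed: int = 42

    def validate(self) -> None:
        if self.num_classes < 3:
            raise ConfigurationError("need at least three classes")
        if len(self.seqs_per_class) != self.num_classes:
            raise ConfigurationError(
                "seqs_per_class must list one size per class"
            )
        for rate in (self.plant_rate, self.mutation_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"rate {rate} outside [0, 1]")


@dataclass(frozen=True)
class PlantedInterval:
    seq_id: str
    class_label: str
    start: int  # 1-based inclusive
    end: int
    motif: str  # canonical motif string
    instance: str  # the possibly mutated planted text


@dataclass
class GroundTruth:
    motifs: dict[str, tuple[str, ...]]  # class label -> canonical motifs
    intervals: dict[str, tuple[PlantedInterval, ...]]  # seq_id -> plantings

    def all_intervals(self) -> list[PlantedInterval]:
        return [iv for ivs in self.intervals.values() for iv in ivs]


def _span(value: IntOrRange, rng: np.random.Generator) -> int:
    if isinstance(value, int):
        return value
    lo, hi = value
    return int(rng.integers(lo, hi + 1))


def _background_probs(background) -> np.ndarray:
    if background == "uniform":
        return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    if background == "natural":
        background = NATURAL_FREQUENCIES
    probs = np.array([background[a] for a in AMINO_ACIDS], dtype=float)
    return probs / probs.sum()


def _positive_partner_table() -> dict[str, str]:
    matrix = load_blosum62()
    return {a: "".join(matrix.positive_partners(a, 1)) for a in AMINO_ACIDS}


def generate(config: SyntheticConfig) -> tuple[LabeledDataset, GroundTruth]:
    """Deterministically generate a dataset with planted motifs.

    Mutated planted instances differ from the canonical motif at exactly one
    position with a BLOSUM62 score >= 1 for the substituted pair.  Class
    exclusivity is enforced by rejection: if a canonical motif happens to
    occur in another class's finished sequences, generation restarts from a
    derived seed (bounded retries).
    """
    config.validate()
    partners = _positive_partner_table()
    for attempt in range(8):
        rng = np.random.default_rng((config.seed, attempt))
        dataset, truth = _generate_once(config, rng, partners)
        if _exclusive(dataset, truth):
            return dataset, truth
    raise DataError(
        "could not generate class-exclusive motifs after bounded retries"
    )


def _generate_once(
    config: SyntheticConfig,
    rng: np.random.Generator,
    partners: Mapping[str, str],
) -> tuple[LabeledDataset, GroundTruth]:
    probs = _background_probs(config.background)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    labels = [f"C{i + 1:02d}" for i in range(config.num_classes)]

    # class-exclusive canonical motifs, pairwise non-substring
    motifs: dict[str, list[str]] = {}
    chosen: list[str] = []
    for label in labels:
        motifs[label] = []
        for _ in range(config.motifs_per_class):
            for _retry in range(100):
                length = _span(config.motif_length, rng)
                m = bytes(rng.choice(alphabet, size=length, p=probs)).decode()
                if all(m not in other and other not in m for other in chosen):
                    chosen.append(m)
                    motifs[label].append(m)
                    break
            else:
                raise DataError("could not draw distinct motifs")

    records: list[SequenceRecord] = []
    intervals: dict[str, tuple[PlantedInterval, ...]] = {}
    for label, n_seqs in zip(labels, config.seqs_per_class):
        for s in range(n_seqs):
            seq_id = f"{label}_seq{s + 1:04d}"
            length = _span(config.seq_length, rng)
            residues = list(bytes(rng.choice(alphabet, size=length, p=probs)).decode())
            planted: list[PlantedInterval] = []
            for motif in motifs[label]:
                if rng.random() >= config.plant_rate:
                    continue
                instance = _mutate(motif, config.mutation_rate, rng, partners)
                placed = _place(
                    residues, instance, planted, rng
                )
                if placed is None:
                    continue
                start, end = placed
                planted.append(
                    PlantedInterval(
                        seq_id=seq_id,
                        class_label=label,
                        start=start,
                        end=end,
                        motif=motif,
                        instance=instance,
                    )
                )
            records.append(
                SequenceRecord(
                    seq_id=seq_id, residues="".join(residues), class_label=label
                )
            )
            intervals[seq_id] = tuple(planted)
    dataset = LabeledDataset.from_records(records)
    truth = GroundTruth(
        motifs={c: tuple(ms) for c, ms in motifs.items()}, intervals=intervals
    )
    return dataset, truth


def _mutate(
    motif: str,
    mutation_rate: float,
    rng: np.random.Generator,
    partners: Mapping[str, str],
) -> str:
    """With probability ``mutation_rate``, substitute one position with a
    BLOSUM62-positive partner (at most one change per instance)."""
    if rng.random() >= mutation_rate:
        return motif
    eligible = [i for i, a in enumerate(motif) if partners[a]]
    if not eligible:
        return motif
    i = eligible[int(rng.integers(len(eligible)))]
    options = partners[motif[i]]
    b = options[int(rng.integers(len(options)))]
    return motif[:i] + b + motif[i + 1 :]


def _place(
    residues: list[str],
    instance: str,
    planted: Sequence[PlantedInterval],
    rng: np.random.Generator,
) -> tuple[int, int] | None:
    length = len(residues)
    width = len(instance)
    if width > length:
        return None
    for _ in range(100):
        pos = int(rng.integers(0, length - width + 1))
        start, end = pos + 1, pos + width
        if any(iv.start <= end and start <= iv.end for iv in planted):
            continue
        residues[pos : pos + width] = instance
        return start, end
    return None


def _exclusive(dataset: LabeledDataset, truth: GroundTruth) -> bool:
    for label, motifs in truth.motifs.items():
        for rec in dataset.records:
            if rec.class_label == label:
                continue
            if any(m in rec.residues for m in motifs):
                return False
    return True


# --- recovery scoring ------------------------------------------------------


@dataclass
class RecoveryReport:
    """How well discovery output recovers the planted signal.

    ``motif_recall`` is the fraction of planted motifs with at least one
    discriminative hit of the correct class overlapping one of the motif's
    planted intervals; ``background_discovery_rate`` is the fraction of
    discriminative items none of whose occurrences overlap any planted
    interval (items that map nowhere in their class count as background).
    """

    recall_by_class: dict[str, float]
    motif_recall: float
    background_discovery_rate: float
    n_items: int


def score_recovery(
    found: Sequence[Union[DiscriminativeNGram, MotifInterval]],
    truth: GroundTruth,
    dataset: LabeledDataset,
) -> RecoveryReport:
    """Score discriminative n-grams (or merged motif intervals) against the
    planted ground truth."""
    by_class = {
        c: [(r.seq_id, r.residues) for r in recs]
        for c, recs in dataset.by_class().items()
    }
    planted_by_seq: dict[str, tuple[PlantedInterval, ...]] = truth.intervals

    hit_motifs: set[tuple[str, str]] = set()  # (class, canonical motif)
    n_background = 0
    for item in found:
        occurrences: list[tuple[str, str, int, int]] = []
        if isinstance(item, MotifInterval):
            occurrences.append(
                (item.class_label, item.seq_id, item.start, item.end)
            )
        else:
            for seq_id, residues in by_class.get(item.assigned_class, ()):
                pos = residues.find(item.gram)
                while pos != -1:
                    occurrences.append(
                        (
                            item.assigned_class,
                            seq_id,
                            pos + 1,
                            pos + len(item.gram),
                        )
                    )
                    pos = residues.find(item.gram, pos + 1)
        overlapped_any = False
        for label, seq_id, start, end in occurrences:
            for iv in planted_by_seq.get(seq_id, ()):
                if iv.start <= end and start <= iv.end:
                    overlapped_any = True
                    if label == iv.class_label:
                        hit_motifs.add((iv.class_label, iv.motif))
        if not overlapped_any:
            n_background += 1

    recall_by_class: dict[str, float] = {}
    total_hit = total_motifs = 0
    for label, motifs in truth.motifs.items():
        if not motifs:
            continue
        hits = sum(1 for m in motifs if (label, m) in hit_motifs)
        recall_by_class[label] = hits / len(motifs)
        total_hit += hits
        total_motifs += len(motifs)
    return RecoveryReport(
        recall_by_class=recall_by_class,
        motif_recall=total_hit / total_motifs if total_motifs else 0.0,
        background_discovery_rate=n_background / len(found) if found else 0.0,
        n_items=len(found),
    )
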