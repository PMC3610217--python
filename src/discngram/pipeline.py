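"""End-to-end discovery pipeline.

Stage order: per n-gram size, extract and profile -> combine similar grams
(SF1) -> dampen -> discriminative ratio -> select at threshold -> pool all
sizes and deduplicate across classes -> per class: remove substring grams ->
map to the class's sequences -> merge contiguous hits into motifs ->
optionally mask non-discriminative regions.  The discovery path is fully
deterministic; randomness exists only in the synthetic generator.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ConfigurationError
from .io_formats import (
    LabeledDataset,
    SequenceRecord,
    SubstitutionMatrix,
    load_blosum62,
)
from .ngram_core import build_profile
from .postprocess import (
    MotifInterval,
    map_to_sequences,
    mask_sequence,
    merge_contiguous,
    remove_substrings,
)
from .scoring import (
    DampedProfile,
    DiscriminativeNGram,
    dampen,
    dedupe_across_classes,
    select_discriminative,
)
from .substitution import SubstitutionConfig, enrich_profile

logger = logging.getLogger("discngram")


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of a discovery run.

    ``n_min``..``n_max`` default to 4..8; larger sizes are allowed but emit
    a warning because the gram space grows steeply with n.  ``substitution``
    toggles SF1 (True) vs SF2 (False).
    """

    n_min: int = 4
    n_max: int = 8
    threshold: float = 5.0
    blosum_threshold: int = 1
    substitution: bool = True
    mask: bool = False
    min_length: int | None = None

    def sizes(self) -> range:
        if not 1 <= self.n_min <= self.n_max:
            raise ConfigurationError(
                f"invalid n-gram size range [{self.n_min}, {self.n_max}]"
            )
        if self.n_min < 4 or self.n_max > 8:
            warnings.warn(
                "n-gram sizes outside 4..8: expect a steep growth in "
                "the number of distinct grams",
                stacklevel=2,
            )
        return range(self.n_min, self.n_max + 1)


@dataclass
class DiscoveryResult:
    config: PipelineConfig
    ngrams: list[DiscriminativeNGram]  # pooled, deduped across classes
    class_grams: dict[str, list[str]]  # per class, after substring removal
    motifs: list[MotifInterval]  # merged intervals, all classes
    masked: list[SequenceRecord] | None
    stage_counts: dict[str, int]


def score_dataset(
    dataset: LabeledDataset,
    config: PipelineConfig,
    matrix: SubstitutionMatrix | None = None,
) -> dict[int, DampedProfile]:
    """Profile, combine and dampen every size; the returned damped profiles
    cache their DR values so threshold sweeps are cheap."""
    if dataset.num_classes < 3:
        raise ConfigurationError(
            "discovery needs at least three classes; the discriminative "
            "ratio is undefined for two-class datasets"
        )
    if config.min_length is not None:
        dataset = dataset.filter_min_length(config.min_length)
    if matrix is None:
        matrix = load_blosum62()
    sub_cfg = SubstitutionConfig(
        blosum_threshold=config.blosum_threshold, enabled=config.substitution
    )
    damped_by_size: dict[int, DampedProfile] = {}
    for n in config.sizes():
        profile = build_profile(dataset, n)
        enriched = enrich_profile(profile, matrix, sub_cfg)
        damped_by_size[n] = dampen(profile, enriched)
        logger.info("n=%d: %d distinct grams profiled", n, len(profile.counts))
    return damped_by_size


def select_pooled(
    damped_by_size: Mapping[int, DampedProfile], threshold: float
) -> list[DiscriminativeNGram]:
    """Select at one threshold across all sizes and deduplicate across
    classes (each gram text survives only where its DR is highest)."""
    selected: list[DiscriminativeNGram] = []
    for n in sorted(damped_by_size):
        selected.extend(select_discriminative(damped_by_size[n], threshold))
    return dedupe_across_classes(selected)


def discover(dataset: LabeledDataset, config: PipelineConfig) -> DiscoveryResult:
    """Run the full pipeline and return n-grams, merged motifs and
    (optionally) masked sequences."""
    if config.min_length is not None:
        dataset = dataset.filter_min_length(config.min_length)
        config = dataclasses.replace(config, min_length=None)
    damped_by_size = score_dataset(dataset, config)
    deduped = select_pooled(damped_by_size, config.threshold)
    logger.info(
        "selected %d discriminative grams at T=%s", len(deduped), config.threshold
    )

    class_grams: dict[str, list[str]] = {}
    motifs: list[MotifInterval] = []
    for label in dataset.classes:
        pooled = [it.gram for it in deduped if it.assigned_class == label]
        filtered = remove_substrings(pooled)
        class_grams[label] = filtered
        for profile in map_to_sequences(filtered, dataset, label):
            motifs.extend(merge_contiguous(profile))
        logger.info(
            "class %s: %d grams pooled, %d after substring removal",
            label,
            len(pooled),
            len(filtered),
        )

    masked = None
    if config.mask:
        by_seq: dict[str, list[MotifInterval]] = {}
        for m in motifs:
            by_seq.setdefault(m.seq_id, []).append(m)
        masked = [
            SequenceRecord(
                seq_id=rec.seq_id,
                residues=mask_sequence(rec, by_seq.get(rec.seq_id, [])),
                class_label=rec.class_label,
            )
            for rec in dataset.records
        ]

    stage_counts = {
        "grams_profiled": sum(
            len(d.weights) for d in damped_by_size.values()
        ),
        "grams_selected": len(deduped),
        "grams_after_substring_removal": sum(
            len(v) for v in class_grams.values()
        ),
        "motifs_merged": len(motifs),
    }
    return DiscoveryResult(
        config=config,
        ngrams=deduped,
        class_grams=class_grams,
        motifs=motifs,
        masked=masked,
        stage_counts=stage_counts,
    )
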