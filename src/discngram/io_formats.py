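"""Input/output layer: class-labeled FASTA reading, the BLOSUM62 matrix,
and deterministic TSV tables for n-grams, motifs and metrics.

Class labels are never parsed out of FASTA headers; they come either from
file grouping (one FASTA per class) or from an explicit per-record manifest.
All tables are TSV with a fixed column order so runs can be compared
byte-exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

from Bio import SeqIO

from .errors import ConfigurationError, DataError, FastaError

#: The 20-letter amino-acid alphabet (one-letter codes, alphabetical).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Residue policies for characters outside the 20-letter alphabet
#: (ambiguity codes B, Z, X, selenocysteine U, pyrrolysine O, stops '*', ...).
RESIDUE_POLICIES = ("drop", "reject")


@dataclass(frozen=True)
class SequenceRecord:
    """A single protein sequence with its class label.

    ``residues`` is an uppercase string over the 20-letter alphabet;
    ``seq_id`` must be unique within a dataset.
    """

    seq_id: str
    residues: str
    class_label: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class LabeledDataset:
    """An ordered collection of class-labeled sequences.

    ``classes`` holds the distinct labels in lexicographic order; this fixed
    order is what makes downstream frequency profiles independent of the
    order in which sequences were supplied.
    """

    records: tuple[SequenceRecord, ...]
    classes: tuple[str, ...]

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "LabeledDataset":
        recs = tuple(records)
        if not recs:
            raise DataError("dataset contains no sequences")
        seen_ids: set[str] = set()
        for rec in recs:
            if rec.seq_id in seen_ids:
                raise DataError(f"duplicate sequence id {rec.seq_id!r} in dataset")
            seen_ids.add(rec.seq_id)
        labels = tuple(sorted({r.class_label for r in recs}))
        return cls(records=recs, classes=labels)

    @property
    def num_classes(self) -> int:
        return len(self.classes)

    def by_class(self) -> dict[str, list[SequenceRecord]]:
        """Records grouped by class label, input order preserved."""
        groups: dict[str, list[SequenceRecord]] = {c: [] for c in self.classes}
        for rec in self.records:
            groups[rec.class_label].append(rec)
        return groups

    def filter_min_length(self, min_length: int) -> "LabeledDataset":
        """Drop sequences shorter than ``min_length`` residues."""
        kept = [r for r in self.records if len(r) >= min_length]
        if not kept:
            raise DataError(f"no sequence is at least {min_length} residues long")
        return LabeledDataset.from_records(kept)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric integer-valued amino-acid substitution matrix."""

    scores: Mapping[tuple[str, str], int]

    def score(self, a: str, b: str) -> int:
        return self.scores[(a, b)]

    def positive_partners(self, a: str, threshold: int = 1) -> tuple[str, ...]:
        """Residues b != a with score(a, b) >= threshold."""
        return tuple(
            b for b in AMINO_ACIDS if b != a and self.scores[(a, b)] >= threshold
        )


def load_blosum62() -> SubstitutionMatrix:
    """The standard BLOSUM62 integer matrix over the 20 amino acids."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    scores = {
        (a, b): int(mat[a, b]) for a in AMINO_ACIDS for b in AMINO_ACIDS
    }
    return SubstitutionMatrix(scores=scores)


def _clean_record(
    seq_id: str, residues: str, class_label: str, policy: str, source: str
) -> SequenceRecord | None:
    residues = residues.upper()
    if not residues:
        raise FastaError(f"{source}: record {seq_id!r} has an empty sequence")
    bad = set(residues) - _AA_SET
    if bad:
        if policy == "reject":
            raise DataError(
                f"{source}: record {seq_id!r} contains non-standard residues "
                f"{''.join(sorted(bad))!r}"
            )
        warnings.warn(
            f"{source}: dropping record {seq_id!r} with non-standard residues "
            f"{''.join(sorted(bad))!r}",
            stacklevel=3,
        )
        return None
    return SequenceRecord(seq_id=seq_id, residues=residues, class_label=class_label)


def _parse_fasta(source: Union[str, Path, IO[str]]) -> list[tuple[str, str]]:
    name = str(source)
    try:
        parsed = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(source, "fasta")]
    except (ValueError, OSError) as exc:  # malformed input or unreadable file
        raise FastaError(f"cannot parse FASTA {name}: {exc}") from exc
    if not parsed:
        raise FastaError(f"FASTA {name} contains no records")
    return parsed


def read_fasta_classes(
    sources: Mapping[str, Union[str, Path, IO[str]]],
    policy: str = "drop",
) -> LabeledDataset:
    """Read one FASTA source per class label into a :class:`LabeledDataset`.

    ``policy`` controls records with residues outside the 20-letter alphabet:
    ``"drop"`` removes them with a warning, ``"reject"`` raises.
    """
    if policy not in RESIDUE_POLICIES:
        raise ConfigurationError(f"unknown residue policy {policy!r}")
    records: list[SequenceRecord] = []
    for label, source in sources.items():
        class_records: list[SequenceRecord] = []
        for seq_id, residues in _parse_fasta(source):
            rec = _clean_record(seq_id, residues, label, policy, str(source))
            if rec is not None:
                class_records.append(rec)
        if not class_records:
            raise DataError(f"class {label!r} has no usable sequences")
        records.extend(class_records)
    return LabeledDataset.from_records(records)


def read_fasta_manifest(
    fasta: Union[str, Path, IO[str]],
    labels: Union[str, Path, Mapping[str, str]],
    policy: str = "drop",
) -> LabeledDataset:
    """Read a single FASTA plus a per-record label manifest.

    ``labels`` is either a mapping seq_id -> class label or the path of a
    two-column TSV (seq_id, class label; '#' comments allowed).
    """
    if policy not in RESIDUE_POLICIES:
        raise ConfigurationError(f"unknown residue policy {policy!r}")
    if not isinstance(labels, Mapping):
        mapping: dict[str, str] = {}
        with open(labels, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise DataError(
                        f"{labels}: line {lineno} is not a two-column manifest row"
                    )
                mapping[parts[0]] = parts[1]
        labels = mapping
    records: list[SequenceRecord] = []
    for seq_id, residues in _parse_fasta(fasta):
        if seq_id not in labels:
            raise DataError(f"record {seq_id!r} has no label in the manifest")
        rec = _clean_record(seq_id, residues, labels[seq_id], policy, str(fasta))
        if rec is not None:
            records.append(rec)
    dataset = LabeledDataset.from_records(records)
    for label in dataset.classes:
        if not any(r.class_label == label for r in dataset.records):
            raise DataError(f"class {label!r} has no usable sequences")
    return dataset


def write_fasta(records: Sequence[SequenceRecord], sink: Union[str, Path, IO[str]]) -> None:
    """Write records as single-line FASTA (deterministic, byte-stable)."""
    lines = [f">{rec.seq_id}\n{rec.residues}\n" for rec in records]
    _write_text("".join(lines), sink)


def _write_text(text: str, sink: Union[str, Path, IO[str]]) -> None:
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text, encoding="utf-8")


# --- n-gram tables ---------------------------------------------------------

NGRAM_TABLE_COLUMNS = ("ngram", "class", "dr", "n")


def write_ngrams_table(items, sink: Union[str, Path, IO[str]]) -> None:
    """Write scored n-grams as TSV: ngram, class, DR, n.

    Rows are ordered by (class, DR descending, ngram lexicographic) so the
    output is deterministic and diffable.
    """
    ordered = sorted(items, key=lambda it: (it.assigned_class, -it.dr, it.gram))
    lines = ["\t".join(NGRAM_TABLE_COLUMNS) + "\n"]
    for it in ordered:
        lines.append(f"{it.gram}\t{it.assigned_class}\t{it.dr!r}\t{len(it.gram)}\n")
    _write_text("".join(lines), sink)


def read_ngrams_table(source: Union[str, Path, IO[str]]):
    """Read a table written by :func:`write_ngrams_table`."""
    from .scoring import DiscriminativeNGram

    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or tuple(lines[0].split("\t")) != NGRAM_TABLE_COLUMNS:
        raise DataError("not an n-gram table: bad or missing header")
    items = []
    for lineno, line in enumerate(lines[1:], 2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise DataError(f"n-gram table line {lineno}: expected 4 columns")
        gram, label, dr, n = parts
        if len(gram) != int(n):
            raise DataError(f"n-gram table line {lineno}: length does not match n")
        items.append(
            DiscriminativeNGram(gram=gram, assigned_class=label, dr=float(dr))
        )
    return items


MOTIF_TABLE_COLUMNS = ("seq_id", "class", "start", "end", "motif")


def write_motif_table(motifs, sink: Union[str, Path, IO[str]]) -> None:
    """Write merged motif intervals as TSV (1-based inclusive coordinates)."""
    ordered = sorted(motifs, key=lambda m: (m.class_label, m.seq_id, m.start, m.end))
    lines = ["\t".join(MOTIF_TABLE_COLUMNS) + "\n"]
    for m in ordered:
        lines.append(f"{m.seq_id}\t{m.class_label}\t{m.start}\t{m.end}\t{m.text}\n")
    _write_text("".join(lines), sink)


def read_motif_table(source: Union[str, Path, IO[str]]):
    from .postprocess import MotifInterval

    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or tuple(lines[0].split("\t")) != MOTIF_TABLE_COLUMNS:
        raise DataError("not a motif table: bad or missing header")
    motifs = []
    for line in lines[1:]:
        if not line:
            continue
        seq_id, label, start, end, text_ = line.split("\t")
        motifs.append(
            MotifInterval(
                seq_id=seq_id,
                class_label=label,
                start=int(start),
                end=int(end),
                text=text_,
            )
        )
    return motifs


def read_pattern_file(source: Union[str, Path, IO[str]]) -> list[str]:
    """One pattern per line; blank lines and '#' comments ignored."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    patterns = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            patterns.append(line)
    return patterns
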