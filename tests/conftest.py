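import random

import pytest

from discngram import (
    LabeledDataset,
    SequenceRecord,
    load_blosum62,
)


@pytest.fixture(scope="session")
def blosum62():
    return load_blosum62()


def dataset_from_dict(class_sequences) -> LabeledDataset:
    records = []
    for label in sorted(class_sequences):
        for i, seq in enumerate(class_sequences[label]):
            records.append(
                SequenceRecord(
                    seq_id=f"{label}_{i}", residues=seq, class_label=label
                )
            )
    return LabeledDataset.from_records(records)


@pytest.fixture
def toy_three_class() -> LabeledDataset:
    """Three classes over a reduced alphabet; class A carries a repeated
    6-mer signal."""
    rng = random.Random(7)
    alphabet = "ACDEGK"
    data = {
        "A": [],
        "B": [],
        "C": [],
    }
    signal = "TLSNPK"
    for label in data:
        for _ in range(6):
            seq = "".join(rng.choice(alphabet) for _ in range(40))
            if label == "A":
                pos = rng.randint(0, 34)
                seq = seq[:pos] + signal + seq[pos + 6 :]
            data[label].append(seq)
    return dataset_from_dict(data)
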