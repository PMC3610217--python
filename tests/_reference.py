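"""Independent straight-line reference for discriminative n-gram discovery.

Deliberately naive and structurally different from the package: plain
dictionaries, neighbor search by generating all 20*n single-position
variants (the package buckets by deleted-position keys), and a literal
transcription of the dampening / ratio / selection rules.  Used only as an
oracle in tests.
"""

import math

from Bio.Align import substitution_matrices

AA = "ACDEFGHIKLMNPQRSTVWY"
_B62 = substitution_matrices.load("BLOSUM62")
BLOSUM = {(a, b): int(_B62[a, b]) for a in AA for b in AA}


def reference_discover(class_sequences, sizes, threshold,
                       substitution=True, blosum_threshold=1):
    """class_sequences: dict label -> list of residue strings.

    Returns dict gram -> (assigned class, DR) after selection at
    ``threshold`` and cross-class deduplication, pooled over ``sizes``.
    """
    labels = sorted(class_sequences)
    n_classes = len(labels)
    assert n_classes >= 3
    emitted = []  # (gram, label, dr)
    for n in sizes:
        counts = {}
        for label in labels:
            for seq in class_sequences[label]:
                for i in range(len(seq) - n + 1):
                    g = seq[i:i + n]
                    if g not in counts:
                        counts[g] = {c: 0 for c in labels}
                    counts[g][label] += 1
        for g in counts:
            members = [g]
            if substitution:
                for i in range(n):
                    for b in AA:
                        if b == g[i]:
                            continue
                        if BLOSUM[(g[i], b)] < blosum_threshold:
                            continue
                        h = g[:i] + b + g[i + 1:]
                        if h in counts:
                            members.append(h)
            combined = {c: sum(counts[m][c] for m in members) for c in labels}
            presence = sum(1 for c in labels if counts[g][c] > 0)
            factor = math.log(n_classes / (presence - 0.1))
            weights = {c: combined[c] * factor for c in labels}
            ranked = sorted(weights.values(), reverse=True)
            w1, w2, w3 = ranked[0], ranked[1], ranked[2]
            if w2 == 0 and w3 == 0:
                mean = 1.0
            elif w3 == 0:
                mean = w2
            else:
                mean = (w2 + w3) / 2.0
            if 0 < mean < 1:
                mean = 1.0
            dr = w1 / mean
            top = [c for c in labels if weights[c] == w1]
            if len(top) > 1:
                continue  # tie for the top class: not discriminative
            if dr >= threshold:
                for m in members:
                    emitted.append((m, top[0], dr))
    best = {}
    for gram, label, dr in emitted:
        if gram not in best:
            best[gram] = (label, dr)
        else:
            old_label, old_dr = best[gram]
            if dr > old_dr or (dr == old_dr and label < old_label):
                best[gram] = (label, dr)
    return best


def random_toy_dataset(rng, alphabet="ACDEGKLS"):
    """A small labeled sequence set with repeated planted words so that the
    selection stage has something to select."""
    n_classes = rng.randint(3, 5)
    labels = [f"K{i}" for i in range(n_classes)]
    data = {}
    for label in labels:
        n_seqs = rng.randint(4, 12)
        seqs = []
        word = "".join(rng.choice(alphabet) for _ in range(rng.randint(4, 7)))
        for _ in range(n_seqs):
            length = rng.randint(20, 50)
            seq = [rng.choice(alphabet) for _ in range(length)]
            if rng.random() < 0.7:
                pos = rng.randint(0, length - len(word))
                seq[pos:pos + len(word)] = word
            seqs.append("".join(seq))
        data[label] = seqs
    return data
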