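import numpy as np
import pytest

from bfoga import Alignment, FamilySpec, SequenceRecord, generate_family


@pytest.fixture(scope="session")
def family():
    """Packaged synthetic family: 6 sequences, 120-residue ancestor, 15%
    substitutions plus short indels, with its known true alignment."""
    return generate_family(FamilySpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_alignment_pair(rng, n_seqs, n_cols):
    """Two random alignments of the same random sequences, for scorer tests."""
    alpha = "ACDEFGHIKLMNPQRSTVWY"
    lengths = rng.integers(max(2, n_cols // 2), n_cols, size=n_seqs)
    seqs = [
        "".join(alpha[i] for i in rng.integers(0, 20, size=int(L)))
        for L in lengths
    ]

    def pad(width):
        rows = []
        for k, s in enumerate(seqs):
            gaps = width - len(s)
            pos = rng.choice(width, size=gaps, replace=False)
            row = np.full(width, "-", dtype="<U1")
            mask = np.ones(width, dtype=bool)
            mask[pos] = False
            row[mask] = list(s)
            rows.append((f"s{k}", "".join(row)))
        return Alignment(rows)

    width = int(max(lengths)) + int(rng.integers(1, 4))
    return pad(width), pad(width)


@pytest.fixture()
def toy_records():
    return [
        SequenceRecord("a", "ACDEFG"),
        SequenceRecord("b", "ACDEG"),
        SequenceRecord("c", "ACEFG"),
    ]
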