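import numpy as np
import pytest

from mavekit import TargetSequence, load_registry
from mavekit.fixtures import FixtureSpec, compliant_preset, generate_target


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture
def dna_target():
    return TargetSequence("toy", "ATGAAA")


@pytest.fixture
def protein_target():
    return TargetSequence("toy_pro", "MKLVEQ", molecule_type="protein")


@pytest.fixture(scope="session")
def preset_doc(registry):
    target = generate_target(FixtureSpec(seed=1, target_length=20))
    return compliant_preset(target, registry)


@pytest.fixture
def rng():
    return np.random.default_rng(20240419)


def equivalence_class(residues: str, start: int, end: int, state: str):
    """Brute-force oracle: every (start, end, state) whose application to
    ``residues`` yields the same edited string as the given allele."""
    edited = residues[:start] + state + residues[end:]
    out = set()
    n = len(residues)
    for s in range(n + 1):
        if residues[:s] != edited[:s]:
            continue
        for e in range(s, n + 1):
            tail = n - e
            if tail > len(edited) - s:
                continue
            if tail and residues[e:] != edited[len(edited) - tail :]:
                continue
            if not tail and len(edited) < s:
                continue
            out.add((s, e, edited[s : len(edited) - tail] if tail else edited[s:]))
    return out
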