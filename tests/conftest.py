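import itertools

import pytest

from eorscode import ConstraintProfile, load_reference_code


@pytest.fixture(scope="session")
def reference_code():
    return load_reference_code()


@pytest.fixture
def tiny_profile():
    """Smallest interesting instance: n=2, d=2, w=1."""
    return ConstraintProfile(n=2, d=2, w=1)


@pytest.fixture
def small_profile():
    return ConstraintProfile(n=4, d=3, w=2)


def brute_force_valid_words(n: int, w: int, nrl: bool = True) -> list[str]:
    """Independent enumeration oracle: plain string scan over all 4^n words."""
    out = []
    for tup in itertools.product("TCGA", repeat=n):
        word = "".join(tup)
        if sum(c in "GC" for c in word) != w:
            continue
        if nrl and any(word[i] == word[i + 1] for i in range(n - 1)):
            continue
        out.append(word)
    return out


def brute_force_hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))
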