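import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def brute_force_kmer_counts(seq: str, k: int) -> dict[str, int]:
    """Independent string-level oracle: enumerate windows, canonicalize by
    string comparison, tally; windows with non-ACGT symbols skipped."""
    comp = str.maketrans("ACGT", "TGCA")
    out: dict[str, int] = {}
    s = seq.upper()
    for i in range(len(s) - k + 1):
        w = s[i : i + k]
        if any(c not in "ACGT" for c in w):
            continue
        rc = w.translate(comp)[::-1]
        canon = min(w, rc)
        out[canon] = out.get(canon, 0) + 1
    return out


@pytest.fixture
def kmer_oracle():
    return brute_force_kmer_counts
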