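"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the package's rolling/vectorized
code paths: plain string slicing, substring search and scipy densities.
"""

import numpy as np
from scipy import stats as sps

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def char_encode(seq: str) -> int:
    """Character-by-character 2-bit packing (A=0, C=1, G=2, T=3, MSB first)."""
    value = 0
    for ch in seq:
        value = value * 4 + "ACGT".index(ch)
    return value


def naive_canonical_seq(seq: str) -> str:
    """Canonical form by comparing both strands as packed integers."""
    return seq if char_encode(seq) <= char_encode(revcomp(seq)) else revcomp(seq)


def substring_count(read: str, kmer: str) -> int:
    """Overlapping occurrences of a k-mer on either strand of a read."""
    total = 0
    for probe in {kmer, revcomp(kmer)}:
        start = 0
        while True:
            i = read.find(probe, start)
            if i < 0:
                break
            total += 1
            start = i + 1
    return total


def normal_loglik(count: float, mean: float, var: float) -> float:
    return float(sps.norm.logpdf(count, loc=mean, scale=np.sqrt(var)))
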