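"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's code paths: plain Python loops,
exact rational arithmetic and an explicitly written-out genetic code.
"""

import itertools
from fractions import Fraction

# The standard genetic code, written out by amino acid.
GENETIC_CODE: dict[str, str] = {}
for _aa, _codons in {
    "F": ["TTT", "TTC"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "I": ["ATT", "ATC", "ATA"], "M": ["ATG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "A": ["GCT", "GCC", "GCA", "GCG"], "Y": ["TAT", "TAC"],
    "*": ["TAA", "TAG", "TGA"], "H": ["CAT", "CAC"], "Q": ["CAA", "CAG"],
    "N": ["AAT", "AAC"], "K": ["AAA", "AAG"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "C": ["TGT", "TGC"], "W": ["TGG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
}.items():
    for _c in _codons:
        GENETIC_CODE[_c] = _aa
assert len(GENETIC_CODE) == 64


def naive_window_hp(counts: list[tuple[int, int]]) -> float:
    """Hp from a list of (ref, alt) read counts, straight from the formula."""
    maj = mnr = 0
    for r, a in counts:
        if r + a == 0:
            continue
        maj += max(r, a)
        mnr += min(r, a)
    return 2.0 * maj * mnr / float(maj + mnr) ** 2


def naive_site_fst(pa: float, pb: float) -> float:
    """Classical Fst via the algebraic identity pi_T - pi_S = (pA - pB)^2 / 2."""
    pbar = (pa + pb) / 2.0
    pi_t = 2.0 * pbar * (1.0 - pbar)
    if pi_t == 0.0:
        return 0.0
    return ((pa - pb) ** 2 / 2.0) / pi_t


def naive_window_fst(freq_pairs: list[tuple[float, float]]) -> float:
    num = den = 0.0
    for pa, pb in freq_pairs:
        pbar = (pa + pb) / 2.0
        num += (pa - pb) ** 2 / 2.0
        den += 2.0 * pbar * (1.0 - pbar)
    return num / den if den else 0.0


def exact_delta_af(ra: int, aa: int, rb: int, ab: int) -> Fraction:
    return abs(Fraction(aa, ra + aa) - Fraction(ab, rb + ab))


def exact_hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """P(overlap >= k) by exhaustive enumeration of all n-subsets of N items."""
    hits = total = 0
    items = list(range(N))
    for draw in itertools.combinations(items, n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return Fraction(hits, total)
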