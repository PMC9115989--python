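"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementation: the ORF
scanner enumerates every frame/start/stop combination directly, the
translation table is spelled out as the classic 64-character string,
the aligner is a suffix dynamic program over explicit gap states, and
the binomial p-values are computed by outcome enumeration.
"""

from __future__ import annotations

from math import comb

# Codons ordered T, C, A, G on each position (the textbook layout).
_ORDER = "TCAG"
_AA = ("FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR"
       "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG")
CODON_TABLE = {a + b + c: _AA[16 * i + 4 * j + k]
               for i, a in enumerate(_ORDER)
               for j, b in enumerate(_ORDER)
               for k, c in enumerate(_ORDER)}
STOPS = {codon for codon, aa in CODON_TABLE.items() if aa == "*"}

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate_oracle(seq: str) -> str:
    assert len(seq) % 3 == 0
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        out.append(CODON_TABLE.get(codon, "X") if "N" not in codon else "X")
    return "".join(out)


def longest_orf_oracle(seq: str, mode: str, frames: str = "six") -> int:
    """Longest ORF length in amino acids, by direct enumeration of every
    (strand, frame, start, end) combination."""
    strands = [seq] if frames == "three" else [seq, revcomp(seq)]
    best = 0
    for s in strands:
        for offset in range(3):
            codons = [s[i:i + 3] for i in range(offset, len(s) - 2, 3)]
            n = len(codons)
            for start in range(n):
                if mode == "strict" and codons[start] != "ATG":
                    continue
                length = 0
                for k in range(start, n):
                    if codons[k] in STOPS:
                        if mode == "strict":
                            best = max(best, length)
                        break
                    length += 1
                else:
                    if mode == "permissive":
                        best = max(best, length)
                    continue
                if mode == "permissive":
                    best = max(best, length)
    return best


def align_identity_oracle(a: str, b: str, match=1.0, mismatch=-1.0,
                          gap_open=-5.0, gap_extend=-2.0):
    """All (score, identities, columns) triples achievable by any global
    alignment of ``a`` and ``b`` under affine gap scoring, by dynamic
    programming over suffixes with explicit last-operation state.

    Returns (max_score, {percent identity of every optimal alignment}).
    """
    memo = {}

    def suffixes(i, j, last):
        key = (i, j, last)
        if key in memo:
            return memo[key]
        out = set()
        if i == len(a) and j == len(b):
            out.add((0.0, 0, 0))
        if i < len(a) and j < len(b):
            sc = match if a[i] == b[j] else mismatch
            ident = 1 if a[i] == b[j] else 0
            for s, d, c in suffixes(i + 1, j + 1, "M"):
                out.add((s + sc, d + ident, c + 1))
        # a gap of length L scores gap_open + (L-1)*gap_extend
        if i < len(a):  # gap in b
            g = gap_extend if last == "A" else gap_open
            for s, d, c in suffixes(i + 1, j, "A"):
                out.add((s + g, d, c + 1))
        if j < len(b):  # gap in a
            g = gap_extend if last == "B" else gap_open
            for s, d, c in suffixes(i, j + 1, "B"):
                out.add((s + g, d, c + 1))
        memo[key] = out
        return out

    triples = suffixes(0, 0, "M")
    best = max(s for s, _, _ in triples)
    pcts = {100.0 * d / c for s, d, c in triples if s == best}
    return best, pcts


def binom_pmf(k: int, n: int, p: float) -> float:
    return comb(n, k) * p ** k * (1 - p) ** (n - k)


def binom_p_greater(k: int, n: int, p0: float) -> float:
    """One-sided (greater) exact binomial p-value by enumeration."""
    return sum(binom_pmf(j, n, p0) for j in range(k, n + 1))


def binom_p_twosided(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value: sum of all outcomes no more
    likely than the observed one (the standard minlike definition)."""
    pk = binom_pmf(k, n, p0)
    return min(1.0, sum(binom_pmf(j, n, p0) for j in range(n + 1)
                        if binom_pmf(j, n, p0) <= pk * (1 + 1e-9)))
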