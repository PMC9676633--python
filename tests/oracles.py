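"""Independent reference implementations used only as test oracles.

These are deliberately written from the underlying definitions (brute-force
pathway enumeration for codon-counting dN/dS, exact-fraction constants for
Tajima's D) and share no code with the package.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations, permutations

from Bio.Seq import Seq

BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())  # '*' for stops


def oracle_codon_sites(codon: str) -> float:
    """Synonymous site count of one codon by exhaustive single-substitution
    enumeration (changes to stops are non-synonymous)."""
    syn = 0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if _aa(mut) == _aa(codon):
                syn += 1
    return syn / 3.0


def oracle_pathways(c1: str, c2: str) -> tuple[float, float]:
    """Average (syn, nonsyn) difference counts over all substitution orders,
    excluding pathways through stop intermediates unless all are blocked."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    results = []
    for order in permutations(diffs):
        cur = c1
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            steps.append((cur, nxt))
            if _aa(nxt) == "*" and nxt != c2:
                ok = False
            cur = nxt
        results.append((ok, steps))
    usable = [s for ok, s in results if ok] or [s for _, s in results]
    syn = sum(1 for steps in usable for a, b in steps if _aa(a) == _aa(b))
    total = sum(len(steps) for steps in usable)
    return syn / len(usable), (total - syn) / len(usable)


def oracle_ng86(seq1: str, seq2: str) -> tuple[float, float]:
    """(dN, dS) by counting + Jukes-Cantor, from scratch.  NaN on saturation."""
    assert len(seq1) == len(seq2) and len(seq1) % 3 == 0
    s_sites = sd = nd = 0.0
    n_codons = len(seq1) // 3
    for i in range(n_codons):
        a, b = seq1[3 * i : 3 * i + 3], seq2[3 * i : 3 * i + 3]
        s_sites += (oracle_codon_sites(a) + oracle_codon_sites(b)) / 2.0
        s, n = oracle_pathways(a, b)
        sd += s
        nd += n
    n_sites = 3 * n_codons - s_sites
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0

    def jc(p: float) -> float:
        return float("nan") if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return jc(pn), jc(ps)


def oracle_tajima_d(seqs: list[str]) -> float | None:
    """Tajima's D from first principles with exact-fraction constants.

    Returns None when undefined (S = 0 or zero variance).
    """
    n = len(seqs)
    L = len(seqs[0])
    seg = [i for i in range(L) if len({s[i] for s in seqs}) > 1]
    S = len(seg)
    if S == 0:
        return None
    pi_total = 0
    for a, b in combinations(seqs, 2):
        pi_total += sum(1 for i in seg if a[i] != b[i])
    n_pairs = n * (n - 1) // 2
    pi = Fraction(pi_total, n_pairs)

    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, 1) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return None
    return float(pi - S / a1) / math.sqrt(float(var))
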