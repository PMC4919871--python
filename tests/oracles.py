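"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths: the NLS subtype
oracle enumerates every anchoring position explicitly, and the Fisher
oracle enumerates the full hypergeometric support with exact rational
arithmetic.
"""

from math import comb

BASIC = ("K", "R")


def nls_subtype_oracle(seq: str, py_hint: bool = False) -> str:
    """Exhaustive-scan subtype call: PY > bipartite > monopartite."""
    if py_hint:
        return "PY"
    # bipartite: enumerate every (2-mer anchor, 10-spacer, 5-window)
    bipartite = False
    for i in range(len(seq)):
        if i + 1 < len(seq) and seq[i] in BASIC and seq[i + 1] in BASIC:
            w0 = i + 2 + 10
            n_basic = 0
            for j in range(w0, min(w0 + 5, len(seq))):
                if seq[j] in BASIC:
                    n_basic += 1
            if n_basic >= 3:
                bipartite = True
    if bipartite:
        return "bipartite"
    # monopartite: enumerate every 4-mer
    for i in range(len(seq)):
        four = seq[i : i + 4]
        if len(four) == 4 and four[0] == "K" and four[1] in BASIC and four[3] in BASIC:
            return "monopartite"
    return "non-classified"


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact enumeration of the hypergeometric support.

    Sums the probability of every table (with the observed margins)
    whose probability does not exceed the observed table's, using the
    standard 1 + 1e-7 relative tolerance for ties.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    # pmf(x) = C(r1,x) C(r2,c1-x) / C(n,c1); work on the integer numerators
    n_obs = comb(r1, a) * comb(r2, c1 - a)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        n_x = comb(r1, x) * comb(r2, c1 - x)
        if n_x * 10**7 <= n_obs * (10**7 + 1):  # <= pmf_obs x (1 + 1e-7)
            total += n_x
    return total / comb(n, c1)
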