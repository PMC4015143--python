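"""Independent brute-force oracles used by the test suite."""

from scipy import stats as sps


def fisher_two_sided_by_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration: sum the
    probabilities of every table with the same margins whose probability does
    not exceed the observed table's."""
    row1, col1, n = a + b, a + c, a + b + c + d
    obs = sps.hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = sps.hypergeom.pmf(x, n, col1, row1)
        if p <= obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)
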