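"""Independent small-scale oracles used by the test suite.

Everything here is computed by routes disjoint from the package's log-space
machinery: exact integer Stirling recurrences, brute-force enumeration of
ancestor configurations with rational arithmetic, direct partition
enumeration, and the closed-form Ewens sampling formula.
"""

from fractions import Fraction
from functools import lru_cache
from math import factorial, lgamma, log


@lru_cache(maxsize=None)
def stirling_unsigned(n: int, a: int) -> int:
    """Unsigned Stirling number of the first kind, exact integers."""
    if n == 0 and a == 0:
        return 1
    if a < 1 or a > n:
        return 0
    if n == a:
        return 1
    return (n - 1) * stirling_unsigned(n - 1, a) + stirling_unsigned(n - 1, a - 1)


def partitions(n: int, max_part: int | None = None):
    """All integer partitions of n, parts non-increasing."""
    if n == 0:
        yield ()
        return
    if max_part is None:
        max_part = n
    for k in range(min(n, max_part), 0, -1):
        for rest in partitions(n - k, k):
            yield (k,) + rest


def _k_coefficients(abundances) -> dict:
    """Exact K(D, A) by brute-force enumeration of ancestor counts a_i."""
    coeffs = {0: Fraction(1)}
    for n in abundances:
        new: dict = {}
        for a_i in range(1, n + 1):
            w = Fraction(
                stirling_unsigned(n, a_i) * factorial(a_i - 1), factorial(n - 1)
            )
            for total, c in coeffs.items():
                new[total + a_i] = new.get(total + a_i, Fraction(0)) + c * w
        coeffs = new
    return coeffs


def etienne_probability(abundances, theta: float, I: float) -> float:
    """Etienne sampling-formula probability by direct summation.

    Practical for J up to ~12; exact rational K coefficients, floats only in
    the final (theta, I) combination.
    """
    abundances = sorted(abundances, reverse=True)
    J = sum(abundances)
    S = len(abundances)
    phi: dict = {}
    for n in abundances:
        phi[n] = phi.get(n, 0) + 1
    prefactor = Fraction(factorial(J))
    for n in abundances:
        prefactor /= n
    for c in phi.values():
        prefactor /= factorial(c)

    def poch(x, k):
        out = 1.0
        for i in range(k):
            out *= x + i
        return out

    total = 0.0
    for A, K in _k_coefficients(abundances).items():
        total += float(K) * I**A / poch(theta, A)
    return float(prefactor) * theta**S / poch(I, J) * total


def ewens_log_probability(abundances, theta: float) -> float:
    """Ewens sampling formula (no dispersal limitation), closed form."""
    J = sum(abundances)
    S = len(abundances)
    phi: dict = {}
    for n in abundances:
        phi[n] = phi.get(n, 0) + 1
    out = lgamma(J + 1)
    for n in abundances:
        out -= log(n)
    for c in phi.values():
        out -= lgamma(c + 1)
    out += S * log(theta) + lgamma(theta) - lgamma(theta + J)
    return out
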