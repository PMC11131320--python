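"""Independent brute-force oracles used to cross-check the implementation.

These apply the category, continuity and test-statistic definitions literally
(exact fractions, textbook formulas) and share no code with the package's own
routines.
"""

from fractions import Fraction


def oracle_categories(counts: dict[str, int]) -> dict[str, str]:
    """Literal definitional category per provider from visit counts."""
    n = sum(counts.values())
    out = {}
    fractions = {k: Fraction(v, n) for k, v in counts.items()}
    max_frac = max(fractions.values())
    holders = [k for k, f in fractions.items() if f == max_frac]
    for k, f in fractions.items():
        if len(counts) == 1:
            out[k] = "Only"
        elif f < max_frac:
            out[k] = "Other"
        elif len(holders) > 1:
            out[k] = "MultPlur"
        elif f > Fraction(1, 2):
            out[k] = "Majority"
        else:
            out[k] = "Plurality"
    return out


def oracle_subtype(category: str, has_first: bool, has_last: bool) -> str:
    if category != "MultPlur":
        return "NA"
    if has_first and has_last:
        return "InitialFinal"
    if has_first:
        return "Initial"
    if has_last:
        return "Final"
    return "Neither"


def oracle_coc(counts) -> Fraction:
    n = sum(counts)
    if n == 1:
        return Fraction(1)
    return Fraction(sum(c * c for c in counts) - n, n * (n - 1))


def oracle_chi2_2x2(a, b, c, d) -> float:
    """Textbook Pearson chi-square: N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def oracle_paired_t(diffs) -> tuple[float, float]:
    """(t, df) from the closed form t = mean / (sd / sqrt(n))."""
    n = len(diffs)
    mean = sum(diffs) / n
    var = sum((x - mean) ** 2 for x in diffs) / (n - 1)
    return mean / (var**0.5 / n**0.5), n - 1
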