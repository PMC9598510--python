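"""Shared test data and independent oracle routines.

The brute-force routines here are deliberately naive (triple loops, direct
set algebra) and never share code with the package implementation they check.
"""

from __future__ import annotations

from fractions import Fraction

from crossddi.core_io import canonical_pair


def brute_force_interactome(protein_domains, gene_domains, ddi_pairs):
    """Triple-loop enumeration of (protein, gene) -> supporting (a, b) pairs."""
    pairs = {canonical_pair(a, b) for a, b in ddi_pairs}
    hits = {}
    for pid, pdoms in protein_domains.items():
        for gene, gdoms in gene_domains.items():
            support = set()
            for a in pdoms:
                for b in gdoms:
                    if canonical_pair(a, b) in pairs:
                        support.add((a, b))
            if support:
                hits[(pid, gene)] = support
    return hits


def brute_force_upper_tail(k, K, n, N):
    """P(X >= k) by exact rational enumeration of the hypergeometric pmf."""
    from math import comb

    denom = comb(N, n)
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return float(total)


# Published ranking of the twenty domain families that mediate the most
# predicted interactions, with each family's cancer-role category and
# dual-role ratio as printed (6 decimals; unannotated families render
# "Not available").  Used to check that the classification rules reproduce
# the printed categories and ratios.
TOP20_DOMAIN_TABLE = [
    ("PF00069", "Pkinase", "Dual role", "0.542857"),
    ("PF00400", "WD40", "Dual role", "0.722222"),
    ("PF00515", "TPR_1", "Unknown", None),
    ("PF07714", "Pkinase_Tyr", "Dual role", "0.315068"),
    ("PF00271", "Helicase_C", "Dual role", "0.833333"),
    ("PF00023", "Ank", "OCG", "0"),
    ("PF00072", "Response_reg", "Unknown", None),
    ("PF00270", "DEAD", "Dual role", "0.75"),
    ("PF00076", "RRM_1", "Dual role", "0.357143"),
    ("PF00560", "LRR_1", "TSG", "1"),
    ("PF00595", "PDZ", "Dual role", "0.8"),
    ("PF00071", "Ras", "Dual role", "0.4"),
    ("PF00169", "PH", "Dual role", "0.375"),
    ("PF00070", "Pyr_redox", "Unknown", None),
    ("PF00571", "CBS", "Unknown", None),
    ("PF00168", "C2", "Dual role", "0.705882"),
    ("PF00989", "PAS", "Dual role", "0.857143"),
    ("PF00097", "zf-C3HC4", "TSG", "1"),
    ("PF00249", "Myb_DNA-binding", "Dual role", "0.666667"),
    ("PF00149", "Metallophos", "Dual role", "0.8"),
]


def counts_from_ratio(ratio_str):
    """Smallest integer (tsg, ocg) gene counts consistent with a printed ratio.

    ``None`` (unannotated) maps to (0, 0); otherwise the printed decimal is
    converted to its simplest fraction t/(t+o).
    """
    if ratio_str is None:
        return (0, 0)
    frac = Fraction(ratio_str).limit_denominator(200)
    return (frac.numerator, frac.denominator - frac.numerator)
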