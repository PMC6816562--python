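"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: brute-force
enumeration, closed forms, and literal rule tables, coded separately from
the implementation they check.
"""

from __future__ import annotations

import itertools
import math
from math import comb


# ---------------------------------------------------------------------------
# fault probability by exhaustive genotype-space enumeration
# ---------------------------------------------------------------------------

def _factor_genotype_space(p, recessives, mode):
    """Yield (probability, expresses) over one gene's HWE genotype space.

    Alleles: the required allele "P", the listed recessives "q0..", and a
    pooled "other" allele (dominant to P) absorbing the remaining frequency.
    """
    freqs = {"P": p}
    for i, q in enumerate(recessives):
        freqs[f"q{i}"] = q
    other = 1.0 - sum(freqs.values())
    if other > 1e-15:
        freqs["other"] = other
    rec_class = {"P"} | {f"q{i}" for i in range(len(recessives))}
    for a, b in itertools.product(freqs, repeat=2):  # ordered pairs
        prob = freqs[a] * freqs[b]
        if mode == "dominant_or_better":
            expresses = {a, b} <= rec_class and "P" in (a, b)
        elif mode == "homozygous_recessive":
            expresses = {a, b} <= rec_class
        elif mode == "heterozygous_only":
            expresses = (a == "P") != (b == "P")
        elif mode == "het_or_hom":
            expresses = "P" in (a, b)
        else:
            raise ValueError(mode)
        yield prob, expresses


def enumerate_fault_probability(factors, lethal_frequencies=(), live_birth=False):
    """P(fault phenotype) by exhaustive enumeration over the joint genotype
    space of all factor genes, optionally conditioned on live birth.

    ``factors`` is a sequence of (p, recessives, mode) tuples.
    """
    spaces = [list(_factor_genotype_space(*f)) for f in factors]
    total = 0.0
    for combo in itertools.product(*spaces):
        prob = math.prod(c[0] for c in combo)
        if all(c[1] for c in combo):
            total += prob
    if live_birth and lethal_frequencies:
        viable = math.prod(1.0 - pl * pl for pl in lethal_frequencies)
        total /= viable
    return total


# ---------------------------------------------------------------------------
# Fisher 2x2 by exhaustive hypergeometric enumeration
# ---------------------------------------------------------------------------

def fisher_2x2_enumeration(table):
    """Two-sided Fisher exact p for a 2x2 table by enumerating every table
    with the observed margins and summing those no more probable."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):  # table [[k, r1-k], [c1-k, r2-c1+k]]
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------
# phenotype rule table for the ASIP x MC1R x CBD103 core
# ---------------------------------------------------------------------------

_ASIP_ORDER = ["ay", "aw", "at", "a"]
_ASIP_NAMES = {
    "ay": "fawn_sable",
    "aw": "wolf_sable",
    "at": "tan_points",
    "a": "recessive_black",
}
_PHAEO = {"fawn_sable", "wolf_sable", "tan_points"}


def core_phenotype_oracle(asip, mc1r, cbd):
    """(pattern, mask, grizzle) from unordered allele pairs, coded as a
    literal transcription of the narrative rules."""
    ee = sorted(mc1r) == ["e", "e"]
    kb = "KB_kbr" in cbd
    if ee:
        pattern = "solid_phaeomelanin"
    elif kb:
        pattern = "solid_eumelanin_or_brindle"
    else:
        top = next(a for a in _ASIP_ORDER if a in asip)
        pattern = _ASIP_NAMES[top]

    if "EM" in mc1r:
        mask = "present" if pattern in _PHAEO else "masked_by_epistasis"
    else:
        mask = "masked_by_epistasis" if ee else "absent"

    if "EG" not in mc1r:
        grizzle = "absent"
    elif pattern == "tan_points" and "EM" not in mc1r:
        grizzle = "expressed"
    else:
        grizzle = "carried_unexpressed"
    return pattern, mask, grizzle


# ---------------------------------------------------------------------------
# minimum Steiner-connector subset by brute force
# ---------------------------------------------------------------------------

def min_connectors(sig_graph, carriers):
    """Smallest set of non-carrier nodes whose addition connects all
    carriers through significant edges, or None if impossible."""
    import networkx as nx

    carriers = [c for c in carriers if c in sig_graph]
    if len(carriers) <= 1:
        return 0
    others = sorted(set(sig_graph.nodes) - set(carriers))
    for k in range(len(others) + 1):
        for subset in itertools.combinations(others, k):
            sub = sig_graph.subgraph(list(carriers) + list(subset))
            if len(sub) > 0 and nx.is_connected(sub):
                return k
    return None
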