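"""Independent oracles used by the test suite.

The ACMG 2015 combining table is transcribed here directly as count-level
predicates, deliberately separate from the engine implementation, so the
engine can be checked against an independent reading of the published
rules.  The Fisher oracle enumerates the hypergeometric distribution
directly.
"""

from __future__ import annotations

from math import comb

from vusreclass.acmg import Classification, EvidenceStrength, Polarity


def classify_by_rule_table(profile, *, single_bs_is_lb: bool = True) -> Classification:
    """Direct transcription of the 2015 combining table on strength counts."""
    S = EvidenceStrength
    vs = s = m = p = 0
    ba = bvs = bst = bmod = bsup = 0
    for item in profile:
        lvl = item.strength
        if item.criterion.polarity is Polarity.PATHOGENIC:
            if lvl is S.VERY_STRONG:
                vs += 1
            elif lvl is S.STRONG:
                s += 1
            elif lvl is S.MODERATE:
                m += 1
            else:
                p += 1
        else:
            if lvl is S.STAND_ALONE:
                ba += 1
            elif lvl is S.VERY_STRONG:
                bvs += 1
            elif lvl is S.STRONG:
                bst += 1
            elif lvl is S.MODERATE:
                bmod += 1
            else:
                bsup += 1

    if ba >= 1:
        return Classification.BENIGN

    # benign very-strong has no 2015 slot: counts as strong benign; benign
    # moderate counts as supporting
    bs = bst + bvs
    bp = bsup + bmod

    # Pathogenic combinations (ia-id, ii, iiia-iiic) plus >=2 very strong
    pathogenic_rules = [
        vs >= 1 and s >= 1,
        vs >= 1 and m >= 2,
        vs >= 1 and m >= 1 and p >= 1,
        vs >= 1 and p >= 2,
        vs >= 2,
        s >= 2,
        s >= 1 and m >= 3,
        s >= 1 and m >= 2 and p >= 2,
        s >= 1 and m >= 1 and p >= 4,
    ]
    # Likely pathogenic combinations (i-vi)
    lp_rules = [
        vs >= 1 and m >= 1,
        s >= 1 and m >= 1,
        s >= 1 and p >= 2,
        m >= 3,
        m >= 2 and p >= 2,
        m >= 1 and p >= 4,
    ]
    benign_rules = [bs >= 2]
    lb_rules = [
        bs >= 1 and bp >= 1,
        bp >= 2,
        single_bs_is_lb and bs >= 1,
    ]

    fired_path = any(pathogenic_rules) or any(lp_rules)
    fired_ben = any(benign_rules) or any(lb_rules)

    if fired_path and fired_ben:
        return Classification.VUS
    if fired_ben and (vs + s) >= 1:
        return Classification.VUS
    if fired_path and bs >= 1:
        return Classification.VUS
    if any(pathogenic_rules):
        return Classification.PATHOGENIC
    if any(lp_rules):
        return Classification.LIKELY_PATHOGENIC
    if any(benign_rules):
        return Classification.BENIGN
    if any(lb_rules):
        return Classification.LIKELY_BENIGN
    return Classification.VUS


def fisher_p_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by direct hypergeometric enumeration:
    the sum of probabilities of tables (with the same margins) no more
    likely than the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)
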