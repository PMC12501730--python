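"""Independent brute-force oracles used by the test suite.

These are deliberately separate, structurally different implementations
of the rule logic: the evidence-combination oracle enumerates the
guideline combinations as literal data patterns, and the segregation
oracle reasons about transmissible alleles.  They exist only to check the
package implementations and share no code with them.
"""

from itertools import product

from irdtriage.variant_model import EVIDENCE_CODES

# ---------------------------------------------------------------------------
# evidence-combination oracle: each pattern is a minimum-count requirement
# (n_very_strong, n_strong, n_moderate, n_supporting) on pathogenic codes

_PATHOGENIC_PATTERNS = [
    # PVS1 plus: one strong / two moderate / one moderate + one supporting /
    # two supporting
    (1, 1, 0, 0),
    (1, 0, 2, 0),
    (1, 0, 1, 1),
    (1, 0, 0, 2),
    (2, 0, 0, 0),
    # two strong
    (0, 2, 0, 0),
    # one strong plus: three moderate / two moderate + two supporting /
    # one moderate + four supporting
    (0, 1, 3, 0),
    (0, 1, 2, 2),
    (0, 1, 1, 4),
]

_LIKELY_PATTERNS = [
    (1, 0, 1, 0),  # PVS1 + one moderate
    (0, 1, 1, 0),  # one strong + one or two moderate
    (0, 1, 0, 2),  # one strong + >= two supporting
    (0, 0, 3, 0),  # >= three moderate
    (0, 0, 2, 2),  # two moderate + >= two supporting
    (0, 0, 1, 4),  # one moderate + >= four supporting
]


def _path_counts(tokens):
    counts = [0, 0, 0, 0]  # vs, s, m, p
    for t in tokens:
        if t == "PVS1":
            counts[0] += 1
        elif t.startswith("PS"):
            counts[1] += 1
        elif t.startswith("PM"):
            counts[2] += 1
        elif t.startswith("PP"):
            counts[3] += 1
    return counts


def _benign_counts(tokens):
    ba = sum(t == "BA1" for t in tokens)
    bs = sum(t.startswith("BS") for t in tokens)
    bp = sum(t.startswith("BP") for t in tokens)
    return ba, bs, bp


def _meets(counts, pattern):
    return all(c >= p for c, p in zip(counts, pattern))


def oracle_richards(tokens, conflict_policy="pathogenic_dominant"):
    """Classify a token collection by literal pattern matching."""
    tokens = list(tokens)
    assert all(t in EVIDENCE_CODES for t in tokens)
    counts = _path_counts(tokens)
    ba, bs, bp = _benign_counts(tokens)

    if any(_meets(counts, p) for p in _PATHOGENIC_PATTERNS):
        path = "P"
    elif any(_meets(counts, p) for p in _LIKELY_PATTERNS):
        path = "LP"
    else:
        path = None
    if ba >= 1 or bs >= 2:
        ben = "B"
    elif (bs >= 1 and bp >= 1) or bp >= 2:
        ben = "LB"
    else:
        ben = None

    has_path = sum(counts) > 0
    has_ben = (ba + bs + bp) > 0
    if conflict_policy == "strict" and has_path and has_ben:
        return "VUS"
    if path:
        return path
    if ben:
        return ben
    return "VUS"


# ---------------------------------------------------------------------------
# segregation oracle: enumerate what each parent can transmit

_TRANSMITS = {
    "hom_ref": {0},
    "het": {0, 1},
    "hom_alt": {1},
    "hemi_ref": {0},
    "hemi_alt": {1},
    "unavailable": None,
}


def oracle_trio(zygosity, modes, mother, father):
    """Expected verdict for a proband genotype given parental genotypes."""
    if zygosity == "homozygous":
        verdicts = []
        for gt in (mother, father):
            alleles = _TRANSMITS[gt]
            if alleles is None:
                verdicts.append(None)
            else:
                verdicts.append(1 in alleles)
        if False in verdicts:
            return "inconsistent"
        if None in verdicts:
            return "uninformative"
        return "consistent"
    if zygosity == "hemizygous":
        alleles = _TRANSMITS[mother]
        if alleles is None:
            return "uninformative"
        if 1 in alleles:
            return "consistent"
        return "possible_de_novo"
    # heterozygous proband: one alt allele from either parent
    available = [g for g in (mother, father) if g != "unavailable"]
    if any(1 in _TRANSMITS[g] for g in available):
        return "consistent"
    if len(available) == 2:
        return "possible_de_novo"
    return "uninformative"


def all_parent_combinations(include_hemi_father=False):
    mothers = ["hom_ref", "het", "hom_alt", "unavailable"]
    fathers = list(mothers) + (["hemi_ref", "hemi_alt"] if include_hemi_father else [])
    return list(product(mothers, fathers))
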