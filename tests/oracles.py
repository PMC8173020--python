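"""Brute-force mating-table oracles for the comparative-system steps.

These enumerate every ordered mating pair, every gamete combination and
every zygote outcome explicitly, instead of pooling gametes the way the
implementation does; under random mating the two routes must agree to
machine precision.
"""

import itertools

import numpy as np

# ---- translocation ---------------------------------------------------------
# gamete distributions per genotype; "U" = unbalanced (zygote dies)
_TRANS_GAMETES = {
    "TT": {"T": 1.0},
    "Tt": {"T": 0.25, "t": 0.25, "U": 0.5},
    "tt": {"t": 1.0},
}
_TRANS_LABELS = ("TT", "Tt", "tt")


def translocation_step_oracle(freqs, s):
    """Next-generation (TT, Tt, tt) frequencies by full enumeration."""
    weights = {"TT": 1.0 - s, "Tt": 1.0 - s / 2.0, "tt": 1.0}
    out = dict.fromkeys(_TRANS_LABELS, 0.0)
    for (g1, x1), (g2, x2) in itertools.product(
        zip(_TRANS_LABELS, freqs), repeat=2
    ):
        for a1, q1 in _TRANS_GAMETES[g1].items():
            for a2, q2 in _TRANS_GAMETES[g2].items():
                if a1 == "U" or a2 == "U":
                    continue  # zygote from any unbalanced gamete dies
                child = "".join(sorted(a1 + a2))
                child = {"TT": "TT", "Tt": "Tt", "tt": "tt"}[
                    child if child in ("TT", "tt") else "Tt"
                ]
                out[child] += x1 * x2 * q1 * q2 * weights[child]
    total = sum(out.values())
    return np.array([out[g] / total for g in _TRANS_LABELS])


# ---- two-locus engineered underdominance -----------------------------------
_TL_LABELS = tuple(
    a + b for a in ("AA", "Aa", "aa") for b in ("BB", "Bb", "bb")
)


def _locus_gametes(genotype):
    """Alleles transmitted by one locus genotype, with probabilities."""
    a, b = genotype
    if a == b:
        return {a: 1.0}
    return {a: 0.5, b: 0.5}


def _two_locus_gametes(genotype):
    """Joint gamete distribution over the two unlinked loci."""
    ga = _locus_gametes(genotype[:2])
    gb = _locus_gametes(genotype[2:])
    return {
        (aa, bb): pa * pb for aa, pa in ga.items() for bb, pb in gb.items()
    }


def _zygote(gam1, gam2):
    a = "".join(sorted((gam1[0], gam2[0])))
    b = "".join(sorted((gam1[1], gam2[1])))
    return a + b


def _viable(genotype):
    n_a = genotype[:2].count("A")
    n_b = genotype[2:].count("B")
    return not ((n_a > 0 and n_b == 0) or (n_b > 0 and n_a == 0))


def two_locus_step_oracle(freqs, s):
    """Next-generation 9-genotype frequencies by full enumeration."""
    out = dict.fromkeys(_TL_LABELS, 0.0)
    for (g1, x1), (g2, x2) in itertools.product(zip(_TL_LABELS, freqs), repeat=2):
        for gam1, q1 in _two_locus_gametes(g1).items():
            for gam2, q2 in _two_locus_gametes(g2).items():
                child = _zygote(gam1, gam2)
                if not _viable(child):
                    continue
                copies = child.count("A") + child.count("B")
                out[child] += x1 * x2 * q1 * q2 * (1.0 - s * copies / 4.0)
    total = sum(out.values())
    return np.array([out[g] / total for g in _TL_LABELS])
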