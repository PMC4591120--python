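"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production lookup tables: translation goes
through Biopython and pathways are enumerated explicitly, so agreement with
the package is a genuine two-route check.
"""

import itertools

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}
SENSE = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
         if a + b + c not in STOPS]


def aa(codon):
    return str(Seq(codon).translate())


def oracle_syn_sites(codon):
    """NG86 synonymous sites of one codon, from first principles."""
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in STOPS:
                continue
            valid += 1
            if aa(alt) == aa(codon):
                syn += 1
        if valid:
            total += syn / valid
    return total


def oracle_diffs(c1, c2):
    """(sd, nd) averaged over stop-free shortest pathways; None when every
    pathway is blocked by a stop codon."""
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    per_path = []
    for order in itertools.permutations(diff_pos):
        cur, sd, nd, ok = c1, 0, 0, True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in STOPS:
                ok = False
                break
            if aa(nxt) == aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            per_path.append((sd, nd))
    if not per_path:
        return None
    return (sum(p[0] for p in per_path) / len(per_path),
            sum(p[1] for p in per_path) / len(per_path))


def oracle_ng86_counts(codons_a, codons_b):
    """(S, N, Sd, Nd) for an aligned gap-free codon pair list; columns whose
    pathways are all blocked are skipped (out of the oracle's domain)."""
    sa = sum(oracle_syn_sites(c) for c in codons_a)
    sb = sum(oracle_syn_sites(c) for c in codons_b)
    S = (sa + sb) / 2
    N = 3 * len(codons_a) - S
    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        d = oracle_diffs(ca, cb)
        if d is None:
            continue
        sd += d[0]
        nd += d[1]
    return S, N, sd, nd


def brute_force_n50(lengths):
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if acc >= total / 2:
            return L
    raise AssertionError("unreachable")
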