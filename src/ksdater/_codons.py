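"""Genetic-code tables shared by the Ks estimators and the simulator.

Everything here is derived from the standard (nuclear) genetic code and is
precomputed once at import: per-codon synonymous-site fractions, shortest
substitution pathways between codon pairs, and per-position degeneracy
classes used for kappa estimation.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

NUCS = "ACGT"
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}

_standard = CodonTable.unambiguous_dna_by_id[1]

CODONS: tuple[str, ...] = tuple(a + b + c for a in NUCS for b in NUCS for c in NUCS)
STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

#: codon -> one-letter amino acid ('*' for stops)
AA_OF: dict[str, str] = {c: _standard.forward_table.get(c, "*") for c in CODONS}


def is_transition(n1: str, n2: str) -> bool:
    """A<->G or C<->T."""
    return (n1 in _PURINES) == (n2 in _PURINES) and n1 != n2


def is_synonymous(c1: str, c2: str) -> bool:
    return AA_OF[c1] == AA_OF[c2] and c1 not in STOP_CODONS and c2 not in STOP_CODONS


# --- single-nucleotide neighbourhoods ---------------------------------------

def codon_changes(codon: str) -> list[tuple[int, str, str]]:
    """All 9 single-nucleotide changes of a codon as (pos, new_nt, new_codon)."""
    out = []
    for pos in range(3):
        for nt in NUCS:
            if nt == codon[pos]:
                continue
            out.append((pos, nt, codon[: pos] + nt + codon[pos + 1 :]))
    return out


#: per sense codon: sum over positions of the synonymous fraction among
#: non-stop single-nucleotide changes (the NG86 synonymous-site count).
NG86_SYN_SITES: dict[str, float] = {}
#: per sense codon and position: (syn fraction, usable) with stops excluded
#: from the denominator at that position.
NG86_SYN_FRACTION: dict[str, tuple[float, float, float]] = {}

for _c in SENSE_CODONS:
    fracs = []
    for _pos in range(3):
        syn = 0
        valid = 0
        for _nt in NUCS:
            if _nt == _c[_pos]:
                continue
            alt = _c[:_pos] + _nt + _c[_pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if AA_OF[alt] == AA_OF[_c]:
                syn += 1
        fracs.append(syn / valid if valid else 0.0)
    NG86_SYN_FRACTION[_c] = tuple(fracs)
    NG86_SYN_SITES[_c] = sum(fracs)


#: degeneracy class per sense codon position: 4 if every alternative
#: nucleotide is synonymous, 0 if none is, else 2 (mixed).
DEGENERACY: dict[str, tuple[int, int, int]] = {}
for _c in SENSE_CODONS:
    klass = []
    for _pos in range(3):
        syn = sum(
            1
            for _nt in NUCS
            if _nt != _c[_pos]
            and is_synonymous(_c, _c[:_pos] + _nt + _c[_pos + 1 :])
        )
        klass.append(4 if syn == 3 else (0 if syn == 0 else 2))
    DEGENERACY[_c] = tuple(klass)


# --- substitution pathways ---------------------------------------------------

class PathwayStep:
    """One substitution step inside a codon-change pathway."""

    __slots__ = ("pos", "frm", "to", "is_ts", "is_syn", "target_codon")

    def __init__(self, pos: int, frm: str, to: str, is_ts: bool, is_syn: bool,
                 target_codon: str):
        self.pos = pos
        self.frm = frm
        self.to = to
        self.is_ts = is_ts
        self.is_syn = is_syn
        self.target_codon = target_codon


@lru_cache(maxsize=None)
def pathways(c1: str, c2: str) -> tuple[tuple[PathwayStep, ...], ...]:
    """All stop-free shortest substitution pathways from codon c1 to c2.

    A pathway visits one differing position per step; pathways passing
    through a stop codon are discarded.  May be empty if every ordering is
    blocked by a stop (only possible for 2- and 3-step pairs).
    """
    diff = [p for p in range(3) if c1[p] != c2[p]]
    paths = []
    for order in permutations(diff):
        cur = c1
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            steps.append(
                PathwayStep(pos, cur[pos], c2[pos], is_transition(cur[pos], c2[pos]),
                            AA_OF[cur] == AA_OF[nxt], nxt)
            )
            cur = nxt
        if ok:
            paths.append(tuple(steps))
    return tuple(paths)


@lru_cache(maxsize=None)
def ng86_diff_counts(c1: str, c2: str) -> tuple[float, float, bool]:
    """(synonymous, nonsynonymous) difference counts between two sense codons
    averaged with equal weight over all stop-free shortest pathways.

    Returns (sd, nd, fallback).  When every pathway is blocked by stops the
    raw nucleotide differences are split proportionally to the pair's mean
    synonymous-site fraction and ``fallback`` is True.
    """
    if c1 == c2:
        return 0.0, 0.0, False
    paths = pathways(c1, c2)
    ndiff = sum(1 for p in range(3) if c1[p] != c2[p])
    if not paths:
        s_frac = (NG86_SYN_SITES[c1] + NG86_SYN_SITES[c2]) / 6.0
        return ndiff * s_frac, ndiff * (1.0 - s_frac), True
    sd = sum(sum(1 for st in path if st.is_syn) for path in paths) / len(paths)
    return sd, ndiff - sd, False
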