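"""Pairwise synonymous/nonsynonymous distance estimation from codon alignments.

Two counting estimators are provided:

* ``ng86`` — the classical Nei–Gojobori (1986) method: synonymous sites are
  counted per codon position as the fraction of non-stop single-nucleotide
  changes that are synonymous; differences are averaged with equal weight
  over all stop-free shortest substitution pathways between the observed
  codons; proportions are corrected with the Jukes–Cantor formula
  d = -(3/4) ln(1 - (4/3) p).

* ``yn00`` — a Yang–Nielsen (2000)-style estimator: codon frequencies come
  from the F3x4 model pooled over both sequences; the transition/transversion
  ratio kappa is estimated from fourfold-degenerate and nondegenerate sites
  under the Kimura two-parameter model; site counts weight each possible
  change by kappa (transitions) and the target-codon frequency; pathway
  contributions are weighted the same way; and the synonymous and
  nonsynonymous distances each receive a Kimura two-parameter correction
  using their own transition/transversion split.

Both estimators are symmetric in their two inputs, ignore alignment columns
containing a gap or an N, and flag saturated pairs (correction argument out
of domain) rather than clamping them.

Codon alignments are built by aligning the translated proteins (global
Needleman–Wunsch, BLOSUM62, affine gaps) and mapping each aligned residue
back onto its source codon.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

from Bio import Align
from Bio.Align import substitution_matrices

from ._codons import (
    AA_OF,
    DEGENERACY,
    NG86_SYN_FRACTION,
    STOP_CODONS,
    is_transition,
    ng86_diff_counts,
    pathways,
)

GAP_CODON = "---"

# alignment scoring defaults, recorded in output metadata
ALIGN_MATRIX = "BLOSUM62"
GAP_OPEN = 10.0
GAP_EXTEND = 0.5


@dataclasses.dataclass
class CodonAlignment:
    id_a: str
    id_b: str
    codons_a: list[str]
    codons_b: list[str]

    @property
    def n_cols(self) -> int:
        return len(self.codons_a)

    @property
    def n_ungapped(self) -> int:
        return sum(1 for a, b in self.ungapped_pairs())

    def ungapped_pairs(self) -> Iterable[tuple[str, str]]:
        """Codon columns with no gap and no N on either side."""
        for a, b in zip(self.codons_a, self.codons_b):
            if a == GAP_CODON or b == GAP_CODON or "N" in a or "N" in b:
                continue
            yield a, b


@dataclasses.dataclass
class KsEstimate:
    id_a: str
    id_b: str
    method: str
    S: float
    N: float
    Sd: float
    Nd: float
    kappa: float
    ks: float | None        # None when saturated / out of correction domain
    ka: float | None
    flags: tuple[str, ...] = ()

    @property
    def defined(self) -> bool:
        return self.ks is not None and self.ka is not None


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(ALIGN_MATRIX)
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


def align_proteins(prot_a: str, prot_b: str) -> tuple[str, str]:
    """Global protein alignment; returns the two gapped rows.

    Scoring: BLOSUM62, gap open 10, gap extend 0.5.  The first optimal
    alignment reported by the dynamic program is taken (deterministic).
    """
    if not prot_a or not prot_b:
        raise ValueError("cannot align an empty protein")
    if "*" in prot_a or "*" in prot_b:
        raise ValueError("proteins with internal stops cannot be aligned")
    aln = next(iter(_ALIGNER.align(prot_a, prot_b)))
    rows = str(aln).strip("\n").split("\n")
    # Alignment.__getitem__ gives the gapped rows directly
    return str(aln[0]), str(aln[1])


def back_translate(aligned_a: str, aligned_b: str, cds_a: str, cds_b: str,
                   id_a: str = "a", id_b: str = "b") -> CodonAlignment:
    """Map a gapped protein alignment back onto its source codons."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned rows differ in length")
    for aligned, cds, name in ((aligned_a, cds_a, id_a), (aligned_b, cds_b, id_b)):
        n_res = sum(1 for ch in aligned if ch != "-")
        if 3 * n_res != len(cds):
            raise ValueError(
                f"{name}: CDS length {len(cds)} does not equal 3 x {n_res} "
                "aligned residues"
            )

    def row(aligned: str, cds: str) -> list[str]:
        out, i = [], 0
        for ch in aligned:
            if ch == "-":
                out.append(GAP_CODON)
            else:
                out.append(cds[3 * i : 3 * i + 3])
                i += 1
        return out

    return CodonAlignment(id_a=id_a, id_b=id_b,
                          codons_a=row(aligned_a, cds_a),
                          codons_b=row(aligned_b, cds_b))


def codon_align(cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b") -> CodonAlignment:
    """Protein-guided codon alignment of two CDSs (terminal stop allowed)."""
    from .cds_prep import translate

    def prep(cds: str) -> str:
        if len(cds) % 3:
            raise ValueError("CDS length not divisible by 3")
        prot = translate(cds)
        if prot.endswith("*"):
            prot = prot[:-1]
        return prot

    pa, pb = prep(cds_a), prep(cds_b)
    ra, rb = align_proteins(pa, pb)
    return back_translate(ra, rb, cds_a[: 3 * len(pa)], cds_b[: 3 * len(pb)],
                          id_a=id_a, id_b=id_b)


def _jc_correct(p: float) -> float | None:
    """Jukes–Cantor distance; None when p >= 3/4 (saturation)."""
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return None
    return -0.75 * math.log(arg)


def ng86(aln: CodonAlignment) -> KsEstimate:
    """Nei–Gojobori (1986) synonymous/nonsynonymous distances."""
    pairs = list(aln.ungapped_pairs())
    if not pairs:
        raise ValueError("no ungapped codon columns to estimate from")
    flags: set[str] = set()
    s_a = s_b = 0.0
    sd = nd = 0.0
    for ca, cb in pairs:
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"stop codon in alignment column ({ca}/{cb})")
        s_a += sum(NG86_SYN_FRACTION[ca])
        s_b += sum(NG86_SYN_FRACTION[cb])
        d_s, d_n, fallback = ng86_diff_counts(ca, cb)
        if fallback:
            flags.add("pathway_fallback")
        sd += d_s
        nd += d_n
    S = (s_a + s_b) / 2.0
    N = 3.0 * len(pairs) - S
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    if ks is None or ka is None:
        flags.add("saturated")
    return KsEstimate(id_a=aln.id_a, id_b=aln.id_b, method="NG86",
                      S=S, N=N, Sd=sd, Nd=nd, kappa=1.0,
                      ks=ks, ka=ka, flags=tuple(sorted(flags)))


# --- YN00 ---------------------------------------------------------------------

def f3x4_frequencies(aln: CodonAlignment) -> dict[str, float]:
    """F3x4 sense-codon frequencies pooled over both sequences."""
    pos_counts = [dict.fromkeys("ACGT", 0) for _ in range(3)]
    total = 0
    for row in (aln.codons_a, aln.codons_b):
        for codon in row:
            if codon == GAP_CODON or "N" in codon:
                continue
            for p, nt in enumerate(codon):
                pos_counts[p][nt] += 1
            total += 1
    if total == 0:
        raise ValueError("no codons to estimate frequencies from")
    pos_freq = [
        {nt: c / sum(d.values()) for nt, c in d.items()} for d in pos_counts
    ]
    raw = {}
    for codon in AA_OF:
        if codon in STOP_CODONS:
            continue
        raw[codon] = pos_freq[0][codon[0]] * pos_freq[1][codon[1]] * pos_freq[2][codon[2]]
    z = sum(raw.values())
    return {c: v / z for c, v in raw.items()}


def _k80(p: float, q: float) -> tuple[float, float] | None:
    """Kimura-2P transition (a) and transversion (b) distances per site;
    None when out of domain."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    a = -0.5 * math.log(w1) + 0.25 * math.log(w2)
    b = -0.5 * math.log(w2)
    return a, b


def estimate_kappa(aln: CodonAlignment, default: float = 2.0,
                   tol: float = 1e-6, max_iter: int = 100) -> tuple[float, tuple[str, ...]]:
    """Transition/transversion rate ratio from fourfold-degenerate and
    nondegenerate codon positions under the K80 model.

    Positions are used only when their degeneracy class agrees between the
    two codons.  Class estimates kappa_i = 2 a_i / b_i are combined weighted
    by the number of compared sites; iterated to the stated tolerance
    (the update has no feedback, so convergence is immediate).
    """
    counts = {0: [0, 0, 0], 4: [0, 0, 0]}  # class -> [n_sites, ts, tv]
    for ca, cb in aln.ungapped_pairs():
        da, db = DEGENERACY[ca], DEGENERACY[cb]
        for p in range(3):
            if da[p] != db[p] or da[p] not in (0, 4):
                continue
            rec = counts[da[p]]
            rec[0] += 1
            if ca[p] != cb[p]:
                if is_transition(ca[p], cb[p]):
                    rec[1] += 1
                else:
                    rec[2] += 1

    flags: set[str] = set()
    kappa = default
    for _ in range(max_iter):
        ests, weights = [], []
        for klass, (n, ts, tv) in counts.items():
            if n == 0:
                continue
            k80 = _k80(ts / n, tv / n)
            if k80 is None:
                continue
            a, b = k80
            if b <= 0.0:
                continue
            ests.append(2.0 * a / b)
            weights.append(n)
        if not ests:
            flags.add("kappa_default")
            new = default
        else:
            new = sum(k * w for k, w in zip(ests, weights)) / sum(weights)
            new = max(new, 1e-3)
        if abs(new - kappa) < tol:
            kappa = new
            break
        kappa = new
    return kappa, tuple(sorted(flags))


def _yn00_site_counts(codon: str, kappa: float, pi: dict[str, float]) -> float:
    """Synonymous sites of one codon with kappa- and frequency-weighted
    mutational opportunity, normalized per position (so S + N == 3)."""
    s = 0.0
    for p in range(3):
        wsyn = wtot = 0.0
        for nt in "ACGT":
            if nt == codon[p]:
                continue
            alt = codon[:p] + nt + codon[p + 1 :]
            if alt in STOP_CODONS:
                continue
            w = (kappa if is_transition(codon[p], nt) else 1.0) * pi.get(alt, 0.0)
            wtot += w
            if AA_OF[alt] == AA_OF[codon]:
                wsyn += w
        if wtot > 0.0:
            s += wsyn / wtot
    return s


def _yn00_diffs(ca: str, cb: str, kappa: float, pi: dict[str, float]
                ) -> tuple[float, float, float, float, bool]:
    """(Sd_ts, Sd_tv, Nd_ts, Nd_tv) for one codon pair, averaging over
    stop-free shortest pathways weighted by per-step kappa and target-codon
    frequency.  Returns fallback=True when all pathways are blocked."""
    if ca == cb:
        return 0.0, 0.0, 0.0, 0.0, False
    paths = pathways(ca, cb)
    if not paths:
        # proportional split of the raw differences, as in the NG86 fallback
        sd, nd, _ = ng86_diff_counts(ca, cb)
        ndiff = sd + nd
        ts = sum(1 for p in range(3)
                 if ca[p] != cb[p] and is_transition(ca[p], cb[p]))
        tv = (sum(1 for p in range(3) if ca[p] != cb[p])) - ts
        f_ts = ts / ndiff if ndiff else 0.0
        return sd * f_ts, sd * (1 - f_ts), nd * f_ts, nd * (1 - f_ts), True
    weights = []
    for path in paths:
        w = 1.0
        for st in path:
            w *= (kappa if st.is_ts else 1.0) * pi.get(st.target_codon, 1e-12)
        weights.append(w)
    z = sum(weights)
    if z <= 0.0:
        weights = [1.0] * len(paths)
        z = float(len(paths))
    out = [0.0, 0.0, 0.0, 0.0]
    for w, path in zip(weights, paths):
        for st in path:
            idx = (0 if st.is_syn else 2) + (0 if st.is_ts else 1)
            out[idx] += w / z
    return out[0], out[1], out[2], out[3], False


def yn00(aln: CodonAlignment, fix_kappa: float | None = None,
         codon_freqs: str = "f3x4") -> KsEstimate:
    """Yang–Nielsen (2000)-style Ks/Ka estimate.

    ``fix_kappa`` bypasses kappa estimation; ``codon_freqs`` is ``"f3x4"``
    (pooled from the pair) or ``"uniform"`` (equal sense-codon frequencies,
    the NG86 limiting case together with kappa = 1).
    """
    pairs = list(aln.ungapped_pairs())
    if len(pairs) < 10:
        raise ValueError("yn00 requires at least 10 ungapped codon columns")
    flags: set[str] = set()

    if codon_freqs == "f3x4":
        pi = f3x4_frequencies(aln)
    elif codon_freqs == "uniform":
        n_sense = len(AA_OF) - len(STOP_CODONS)
        pi = {c: 1.0 / n_sense for c in AA_OF if c not in STOP_CODONS}
    else:
        raise ValueError(f"unknown codon frequency model {codon_freqs!r}")

    if fix_kappa is not None:
        kappa = float(fix_kappa)
    else:
        kappa, kflags = estimate_kappa(aln)
        flags.update(kflags)

    s_a = s_b = 0.0
    sd_ts = sd_tv = nd_ts = nd_tv = 0.0
    for ca, cb in pairs:
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"stop codon in alignment column ({ca}/{cb})")
        s_a += _yn00_site_counts(ca, kappa, pi)
        s_b += _yn00_site_counts(cb, kappa, pi)
        d = _yn00_diffs(ca, cb, kappa, pi)
        sd_ts += d[0]
        sd_tv += d[1]
        nd_ts += d[2]
        nd_tv += d[3]
        if d[4]:
            flags.add("pathway_fallback")
    S = (s_a + s_b) / 2.0
    N = 3.0 * len(pairs) - S
    Sd = sd_ts + sd_tv
    Nd = nd_ts + nd_tv

    ks = ka = None
    if S > 0:
        k80 = _k80(sd_ts / S, sd_tv / S)
        if k80 is not None:
            ks = k80[0] + k80[1]       # d = a + b under K80
    if N > 0:
        k80 = _k80(nd_ts / N, nd_tv / N)
        if k80 is not None:
            ka = k80[0] + k80[1]
    if ks is None or ka is None:
        flags.add("saturated")
    return KsEstimate(id_a=aln.id_a, id_b=aln.id_b, method="YN00",
                      S=S, N=N, Sd=Sd, Nd=Nd, kappa=kappa,
                      ks=ks, ka=ka, flags=tuple(sorted(flags)))


_METHODS = {"ng86": ng86, "yn00": yn00}


def estimate(aln: CodonAlignment, method: str = "yn00", **kw) -> KsEstimate:
    try:
        fn = _METHODS[method.lower()]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose ng86 or yn00") from None
    return fn(aln, **kw)


def estimate_pair(cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b",
                  method: str = "yn00", **kw) -> KsEstimate:
    """Convenience: protein-guided codon alignment + distance estimate."""
    return estimate(codon_align(cds_a, cds_b, id_a=id_a, id_b=id_b),
                    method=method, **kw)
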