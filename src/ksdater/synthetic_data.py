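"""Generative models for every input of the pipeline, with known ground truth.

The sequence simulator is a mechanistic proposal-acceptance substitution
process on codons: point mutations are proposed uniformly across sites with
transition:transversion rate ratio kappa:1, proposals creating a stop codon
are rejected, nonsynonymous proposals are accepted with probability omega
and synonymous ones always.  Multiple hits and back-substitutions therefore
occur naturally, so the multiple-hit corrections in the estimators are
genuinely exercised.  The proposal intensity is calibrated per configuration
by a pilot run so that the *expected estimated* Ks of a generated pair
equals the requested target; target_ks is an expectation, not an exact
realization.

Also provided: a truncated-lognormal-mixture sampler for node-Ks age
distributions, a toy 12-column hit table with an independently evaluated
ground-truth pair set, and a small synthetic transcriptome of paralog
families for end-to-end recovery runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math

import numpy as np

from ._codons import AA_OF, SENSE_CODONS, STOP_CODONS
from .ks_engine import CodonAlignment, ng86, yn00
from .seq_io import HitRecord, SeqRecord

PILOT_REPLICATES = 1000
_REF_TARGET_KS = 0.3          # reference divergence for shared calibrations

_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}


@dataclasses.dataclass(frozen=True)
class EvolveConfig:
    n_codons: int = 500
    target_ks: float = 0.25
    omega: float = 0.2
    kappa: float = 2.0
    seed: int = 0
    #: estimator whose expectation the calibration pins to target_ks
    calibration_method: str = "ng86"

    def __post_init__(self):
        if self.omega < 0:
            raise ValueError("omega must be non-negative")
        if self.n_codons < 1:
            raise ValueError("n_codons must be positive")
        if self.target_ks < 0:
            raise ValueError("target_ks must be non-negative")


@dataclasses.dataclass
class MixtureSpec:
    weights: tuple[float, ...]
    mus: tuple[float, ...]        # ln-Ks scale
    sigmas: tuple[float, ...]
    n: int = 529
    seed: int = 0
    ks_range: tuple[float, float] = (0.0, 2.0)

    def __post_init__(self):
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if not (len(self.weights) == len(self.mus) == len(self.sigmas)):
            raise ValueError("weights, mus, sigmas must have equal length")


def random_cds(n_codons: int, seed: int) -> SeqRecord:
    """Uniform sense codons starting with ATG; deterministic given seed."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    codons = ["ATG"] + [
        SENSE_CODONS[i]
        for i in rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)
    ]
    return SeqRecord(id=f"sim{seed}", seq="".join(codons))


def _evolve_branch(codons: list[str], branch_ks: float, scale: float,
                   omega: float, kappa: float, rng: np.random.Generator
                   ) -> tuple[list[str], int, int]:
    """Evolve one lineage; returns (codons, realized syn, realized nonsyn)."""
    seq = list(codons)
    L3 = 3 * len(seq)
    n_prop = rng.poisson(scale * branch_ks * L3) if branch_ks > 0 else 0
    syn = nonsyn = 0
    for _ in range(n_prop):
        site = int(rng.integers(0, L3))
        ci, pos = divmod(site, 3)
        cur = seq[ci]
        nt = cur[pos]
        u = rng.random() * (kappa + 2.0)
        if u < kappa:
            new_nt = _TS_PARTNER[nt]
        else:
            new_nt = _TV_PARTNERS[nt][0] if u < kappa + 1.0 else _TV_PARTNERS[nt][1]
        new = cur[:pos] + new_nt + cur[pos + 1 :]
        if new in STOP_CODONS:
            continue
        if AA_OF[new] == AA_OF[cur]:
            seq[ci] = new
            syn += 1
        elif rng.random() < omega:
            seq[ci] = new
            nonsyn += 1
    return seq, syn, nonsyn


def pair_alignment(rec_a: SeqRecord, rec_b: SeqRecord) -> CodonAlignment:
    """Codon alignment of two equal-length, indel-free simulated CDSs."""
    if len(rec_a.seq) != len(rec_b.seq) or len(rec_a.seq) % 3:
        raise ValueError("simulated pair must be equal-length whole codons")
    split = lambda s: [s[i : i + 3] for i in range(0, len(s), 3)]
    return CodonAlignment(id_a=rec_a.id, id_b=rec_b.id,
                          codons_a=split(rec_a.seq), codons_b=split(rec_b.seq))


_ESTIMATORS = {"ng86": ng86, "yn00": yn00}
_CALIBRATION_CACHE: dict[tuple, float] = {}


def _stable_seed(*parts) -> int:
    h = hashlib.sha256("|".join(map(str, parts)).encode()).digest()
    return int.from_bytes(h[:4], "big") % 2**31


def _calibrated_scale(n_codons: int, target_ks: float, omega: float,
                      kappa: float, method: str,
                      pilot_reps: int = PILOT_REPLICATES) -> float:
    """Proposal-intensity multiplier making the expected estimated Ks of a
    generated pair equal target_ks, from a pilot run at unit scale.

    Cached per configuration; the pilot uses its own deterministic seed so
    the constant does not depend on the caller's random stream.
    """
    if target_ks == 0:
        return 0.0
    key = (n_codons, round(target_ks, 10), round(omega, 10), round(kappa, 10),
           method)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    estimator = _ESTIMATORS[method]
    rng = np.random.default_rng(_stable_seed("pilot", *key))
    est = []
    for _ in range(pilot_reps):
        anc = random_cds(n_codons, int(rng.integers(0, 2**31)))
        codons = [anc.seq[i : i + 3] for i in range(0, len(anc.seq), 3)]
        a, _, _ = _evolve_branch(codons, target_ks / 2, 1.0, omega, kappa, rng)
        b, _, _ = _evolve_branch(codons, target_ks / 2, 1.0, omega, kappa, rng)
        aln = CodonAlignment(id_a="a", id_b="b", codons_a=a, codons_b=b)
        e = estimator(aln)
        if e.ks is not None:
            est.append(e.ks)
    mean_ks = float(np.mean(est))
    if mean_ks <= 0:
        raise RuntimeError("calibration pilot produced no divergence")
    scale = target_ks / mean_ks
    _CALIBRATION_CACHE[key] = scale
    return scale


def evolve_pair(ancestor: SeqRecord, cfg: EvolveConfig
                ) -> tuple[SeqRecord, SeqRecord, dict]:
    """Two descendants of ``ancestor`` at expected estimated Ks = target_ks.

    Each lineage evolves for half the target divergence.  Returns the two
    sequences and the realized ground-truth substitution counts.
    """
    if len(ancestor.seq) % 3:
        raise ValueError("ancestor length must be a multiple of 3")
    codons = [ancestor.seq[i : i + 3] for i in range(0, len(ancestor.seq), 3)]
    rng = np.random.default_rng(cfg.seed)
    if cfg.target_ks == 0:
        a = b = list(codons)
        counts = {"syn_a": 0, "nonsyn_a": 0, "syn_b": 0, "nonsyn_b": 0}
    else:
        scale = _calibrated_scale(len(codons), cfg.target_ks, cfg.omega,
                                  cfg.kappa, cfg.calibration_method)
        a, sa, na = _evolve_branch(codons, cfg.target_ks / 2, scale,
                                   cfg.omega, cfg.kappa, rng)
        b, sb, nb = _evolve_branch(codons, cfg.target_ks / 2, scale,
                                   cfg.omega, cfg.kappa, rng)
        counts = {"syn_a": sa, "nonsyn_a": na, "syn_b": sb, "nonsyn_b": nb}
    rec_a = SeqRecord(id=f"{ancestor.id}_a", seq="".join(a))
    rec_b = SeqRecord(id=f"{ancestor.id}_b", seq="".join(b))
    return rec_a, rec_b, counts


def evolve_family(ancestor: SeqRecord, duplication_times: list[float],
                  cfg: EvolveConfig) -> tuple[list[SeqRecord], dict]:
    """Sequential (ladder) duplications at the given pairwise divergences.

    ``duplication_times`` are pair-Ks depths of the duplication events;
    len(duplication_times) = m-1 events give m leaves whose true
    single-linkage node-Ks values are exactly the stated times.  Uses the
    shared reference calibration and scales linearly in branch length.
    """
    if not duplication_times:
        raise ValueError("at least one duplication is required")
    if any(t < 0 for t in duplication_times):
        raise ValueError("duplication times must be non-negative")
    if len(ancestor.seq) % 3:
        raise ValueError("ancestor length must be a multiple of 3")
    codons = [ancestor.seq[i : i + 3] for i in range(0, len(ancestor.seq), 3)]
    rng = np.random.default_rng(cfg.seed)
    scale = _calibrated_scale(len(codons), _REF_TARGET_KS, cfg.omega,
                              cfg.kappa, cfg.calibration_method) if any(
                                  t > 0 for t in duplication_times) else 0.0

    depths = sorted((t / 2.0 for t in duplication_times), reverse=True)
    leaves: list[SeqRecord] = []
    trunk = codons               # lineage that keeps duplicating
    trunk_depth = depths[0]      # time-before-present of the trunk state
    for i, d in enumerate(depths):
        # evolve the trunk down to this duplication
        trunk, _, _ = _evolve_branch(trunk, trunk_depth - d, scale,
                                     cfg.omega, cfg.kappa, rng)
        trunk_depth = d
        # one side becomes a leaf, evolving the remaining d to the present
        side, _, _ = _evolve_branch(trunk, d, scale, cfg.omega, cfg.kappa, rng)
        leaves.append(SeqRecord(id=f"{ancestor.id}_L{i}", seq="".join(side)))
    tip, _, _ = _evolve_branch(trunk, trunk_depth, scale, cfg.omega,
                               cfg.kappa, rng)
    leaves.append(SeqRecord(id=f"{ancestor.id}_L{len(depths)}",
                            seq="".join(tip)))
    truth = {"node_ks": sorted(duplication_times),
             "n_leaves": len(leaves)}
    return leaves, truth


def sample_ks_mixture(spec: MixtureSpec) -> np.ndarray:
    """Draw Ks values from a lognormal mixture truncated to ``ks_range``
    by resampling (component shapes inside the range stay intact)."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ks_range
    out = np.empty(spec.n)
    comps = rng.choice(len(spec.weights), size=spec.n, p=spec.weights)
    for i, k in enumerate(comps):
        while True:
            v = math.exp(rng.normal(spec.mus[k], spec.sigmas[k]))
            if lo < v < hi:
                out[i] = v
                break
    return out


# --- toy hit table ------------------------------------------------------------

def toy_hit_table() -> tuple[list[HitRecord], set[frozenset]]:
    """Fixed fixture of 12-column hits with planted self-hits, reciprocal
    duplicates and threshold-straddling rows, plus the ground-truth pair
    set evaluated independently row by row."""
    rows = [
        # qid   sid   pident alen mm go qs  qe  ss  se  evalue  bits
        ("u1", "u1", 100.0, 500, 0, 0, 1, 500, 1, 500, 0.0, 900.0),    # self
        ("u1", "u2", 85.0, 400, 60, 0, 1, 400, 1, 400, 1e-80, 500.0),  # pass
        ("u2", "u1", 85.0, 400, 60, 0, 1, 400, 1, 400, 1e-78, 495.0),  # reciprocal
        ("u1", "u3", 39.9, 400, 240, 0, 1, 400, 1, 400, 1e-40, 200.0), # pident fail
        ("u2", "u3", 40.0, 150, 90, 0, 1, 150, 1, 150, 1e-5, 80.0),    # boundary pass
        ("u3", "u4", 55.0, 149, 67, 0, 1, 149, 1, 149, 1e-30, 150.0),  # length fail
        ("u4", "u5", 70.0, 300, 90, 0, 1, 300, 1, 300, 2e-5, 120.0),   # evalue fail
        ("u5", "u6", 95.0, 600, 30, 0, 600, 1, 1, 600, 1e-100, 800.0), # minus strand pass
    ]
    hits = [HitRecord(*r) for r in rows]
    truth: set[frozenset] = set()
    for r in rows:
        qid, sid, pident, alen = r[0], r[1], r[2], r[3]
        evalue = r[10]
        # independent rule evaluation, spelled out literally
        if qid != sid and evalue <= 1e-5 and pident >= 40.0 and alen >= 150:
            truth.add(frozenset((qid, sid)))
    return hits, truth


# --- synthetic transcriptome --------------------------------------------------

@dataclasses.dataclass
class TranscriptomeSpec:
    """A small paralog-rich transcriptome with duplication events planted at
    known Ks.  ``events`` are (center_ks, ln_sd, weight): per family the
    event Ks is drawn lognormally around a center."""

    n_families: int = 150
    n_codons: int = 300
    omega: float = 0.2
    kappa: float = 2.0
    events: tuple = ((0.25, 0.08, 0.6), (1.33, 0.05, 0.4))
    p_triplet: float = 0.1
    seed: int = 0
    #: estimator the divergence calibration is pinned to; matches the
    #: pipeline's production estimator by default
    calibration_method: str = "yn00"


def simulate_transcriptome(spec: TranscriptomeSpec
                           ) -> tuple[list[SeqRecord], list[HitRecord], dict]:
    """Simulate families, their CDS FASTA and an all-by-all hit table.

    Families are mostly pairs; a fraction are triplets carrying one young
    and one old node.  The hit table contains self-hits and both directions
    of every within-family pair, with identity computed from the actual
    sequences.  Ground truth lists every planted node Ks.
    """
    rng = np.random.default_rng(spec.seed)
    weights = np.array([e[2] for e in spec.events], dtype=float)
    weights = weights / weights.sum()

    def draw_event() -> tuple[int, float]:
        k = int(rng.choice(len(spec.events), p=weights))
        center, sd, _ = spec.events[k]
        return k, float(np.exp(rng.normal(np.log(center), sd)))

    records: list[SeqRecord] = []
    hits: list[HitRecord] = []
    truth_nodes: list[dict] = []
    for f in range(spec.n_families):
        anc = random_cds(spec.n_codons, _stable_seed("anc", spec.seed, f))
        anc.id = f"fam{f}"
        cfg = EvolveConfig(
            n_codons=spec.n_codons, omega=spec.omega,
            kappa=spec.kappa, seed=_stable_seed("fam", spec.seed, f),
            calibration_method=spec.calibration_method,
        )
        if rng.random() < spec.p_triplet:
            (k1, t1), (k2, t2) = draw_event(), draw_event()
            times = sorted([t1, t2])
            leaves, _ = evolve_family(anc, times, cfg)
            events = sorted([(t1, k1), (t2, k2)])
            for t, k in events:
                truth_nodes.append({"family": f, "ks": t, "event": k})
        else:
            k1, t1 = draw_event()
            leaves, _ = evolve_family(anc, [t1], cfg)
            truth_nodes.append({"family": f, "ks": t1, "event": k1})
        records.extend(leaves)
        ids = [l.id for l in leaves]
        for i, a in enumerate(leaves):
            hits.append(_hit_row(a, a))
            for b in leaves[i + 1 :]:
                hits.append(_hit_row(a, b))
                hits.append(_hit_row(b, a))
    truth = {
        "nodes": truth_nodes,
        "event_centers": [e[0] for e in spec.events],
        "n_node_ks": len(truth_nodes),
    }
    return records, hits, truth


def _hit_row(a: SeqRecord, b: SeqRecord) -> HitRecord:
    L = len(a.seq)
    ident = sum(1 for x, y in zip(a.seq, b.seq) if x == y) / L
    return HitRecord(qid=a.id, sid=b.id, pident=round(100 * ident, 2),
                     aln_len=L, mismatches=int(L * (1 - ident)), gapopens=0,
                     qstart=1, qend=L, sstart=1, send=L,
                     evalue=1e-120 if a.id != b.id else 0.0,
                     bitscore=round(2 * L * ident, 1))
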