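"""Hit-guided coding-region extraction and protein quality filtering.

The best protein hit of a unigene defines its coding span: the query
interval is cut out, reverse-complemented when the hit is on the minus
strand (qstart > qend), trimmed at the 3' end to a whole number of codons,
and translated with the standard genetic code.  Proteins shorter than 50
residues or containing an internal stop are rejected; a terminal stop is
trimmed first, since a natural ORF end is not a quality defect.
"""

from __future__ import annotations

import dataclasses

from Bio.Seq import Seq

from .seq_io import HitRecord, SeqRecord

MIN_PROTEIN_AA = 50


@dataclasses.dataclass
class CdsRecord:
    id: str
    frame: int              # +1..+3 / -1..-3 relative to the unigene
    cds: str                # length divisible by 3, terminal stop trimmed
    protein: str            # no internal '*'
    n_codons: int


@dataclasses.dataclass
class Rejection:
    id: str
    reason: str             # "too_short" | "internal_stop"


def translate(cds: str) -> str:
    """Standard-code translation; codons containing N translate to 'X'."""
    return str(Seq(cds).translate())


def extract_cds(
    unigene: SeqRecord,
    best_hit: HitRecord,
    min_nt: int = 3 * MIN_PROTEIN_AA,
) -> CdsRecord | Rejection:
    """Extract and translate the hit-covered coding region of a unigene."""
    if best_hit.qid != unigene.id:
        raise ValueError(
            f"hit query {best_hit.qid!r} does not match unigene {unigene.id!r}"
        )
    lo, hi = best_hit.qspan
    if lo < 1 or hi > len(unigene.seq):
        raise ValueError(
            f"hit span [{lo}, {hi}] outside unigene {unigene.id!r} "
            f"(length {len(unigene.seq)})"
        )
    sub = unigene.seq[lo - 1 : hi]
    minus = best_hit.qstart > best_hit.qend
    if minus:
        sub = str(Seq(sub).reverse_complement())
    # trim the 3' end to a whole number of codons
    sub = sub[: len(sub) - (len(sub) % 3)]
    if len(sub) < min_nt:
        return Rejection(id=unigene.id, reason="too_short")
    protein = translate(sub)
    if protein.endswith("*"):
        protein = protein[:-1]
        sub = sub[:-3]
    if "*" in protein:
        return Rejection(id=unigene.id, reason="internal_stop")
    if len(protein) < MIN_PROTEIN_AA:
        return Rejection(id=unigene.id, reason="too_short")
    if minus:
        # frame counted from the 3' end of the unigene on the minus strand
        frame = -(((len(unigene.seq) - hi)) % 3 + 1)
    else:
        frame = (lo - 1) % 3 + 1
    return CdsRecord(id=unigene.id, frame=frame, cds=sub, protein=protein,
                     n_codons=len(sub) // 3)


def extract_all(
    unigenes: list[SeqRecord],
    best: dict[str, HitRecord],
) -> tuple[list[CdsRecord], list[Rejection]]:
    accepted: list[CdsRecord] = []
    rejected: list[Rejection] = []
    for uni in unigenes:
        hit = best.get(uni.id)
        if hit is None:
            rejected.append(Rejection(id=uni.id, reason="no_hit"))
            continue
        out = extract_cds(uni, hit)
        (accepted if isinstance(out, CdsRecord) else rejected).append(out)
    return accepted, rejected


def filter_proteins(
    records: list[SeqRecord],
    min_aa: int = MIN_PROTEIN_AA,
) -> tuple[list[SeqRecord], list[Rejection]]:
    """Keep proteins with >= ``min_aa`` residues and no internal stop.

    A single terminal '*' is trimmed before either rule is applied.
    """
    accepted: list[SeqRecord] = []
    rejected: list[Rejection] = []
    for rec in records:
        seq = rec.seq
        if seq.endswith("*"):
            seq = seq[:-1]
        if "*" in seq:
            rejected.append(Rejection(id=rec.id, reason="internal_stop"))
        elif len(seq) < min_aa:
            rejected.append(Rejection(id=rec.id, reason="too_short"))
        else:
            accepted.append(SeqRecord(id=rec.id, seq=seq, description=rec.description))
    return accepted, rejected
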