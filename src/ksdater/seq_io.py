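"""Readers and writers for the formats the pipeline consumes and emits.

FASTA sequences (via Biopython), 12-column tab-separated similarity hits
(the BLAST ``outfmt 6`` dialect), one-value-per-line Ks lists, and TSV
report tables.  All coordinates in hit files are 1-based inclusive, as in
the source format; internal code converts where needed and re-emits 1-based.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")


class FormatError(ValueError):
    """Malformed input file."""


@dataclasses.dataclass
class SeqRecord:
    """One FASTA entry: id, optional description, uppercase sequence."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass
class HitRecord:
    """One row of a 12-column tabular similarity hit."""

    qid: str
    sid: str
    pident: float
    aln_len: int
    mismatches: int
    gapopens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    @property
    def qspan(self) -> tuple[int, int]:
        """Normalized 1-based inclusive query span [min, max]."""
        return (min(self.qstart, self.qend), max(self.qstart, self.qend))

    @property
    def query_hit_bases(self) -> int:
        lo, hi = self.qspan
        return hi - lo + 1


def read_fasta(path: str | Path, alphabet: str = "nt") -> list[SeqRecord]:
    """Read a FASTA file into an ordered list of validated records.

    ``alphabet`` is ``"nt"`` (A/C/G/T plus N) or ``"aa"`` (20 amino acids
    plus X and ``*``).  Duplicate ids, empty sequences and characters
    outside the alphabet are hard errors.
    """
    if alphabet not in ("nt", "aa"):
        raise ValueError(f"alphabet must be 'nt' or 'aa', got {alphabet!r}")
    allowed = NT_ALPHABET if alphabet == "nt" else AA_ALPHABET
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        if not seq:
            raise FormatError(f"{path}: empty sequence for id {rec.id!r}")
        bad = set(seq) - allowed
        if bad:
            pos = next(i for i, ch in enumerate(seq) if ch in bad)
            raise FormatError(
                f"{path}: record {rec.id!r} has character {seq[pos]!r} at "
                f"position {pos + 1} outside the {alphabet} alphabet"
            )
        desc = rec.description[len(rec.id):].strip()
        records.append(SeqRecord(id=rec.id, seq=seq, description=desc))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


_HIT_TYPES = (str, str, float, int, int, int, int, int, int, int, float, float)


def read_hits(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit table.

    Lines starting with ``#`` are skipped.  A row with the wrong column
    count or a non-numeric numeric field is a hard error naming the line.
    """
    records: list[HitRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                vals = [typ(f) for typ, f in zip(_HIT_TYPES, fields)]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            rec = HitRecord(*vals)
            if not (0.0 <= rec.pident <= 100.0):
                raise FormatError(
                    f"{path}:{lineno}: percent identity {rec.pident} out of [0, 100]"
                )
            if rec.evalue < 0:
                raise FormatError(f"{path}:{lineno}: negative E-value")
            records.append(rec)
    return records


def write_hits(records: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.qid, r.sid, r.pident, r.aln_len, r.mismatches,
                        r.gapopens, r.qstart, r.qend, r.sstart, r.send,
                        r.evalue, r.bitscore,
                    )
                )
                + "\n"
            )


def read_ks_list(path: str | Path) -> list[float]:
    """One Ks value per line; blank lines and '#' comments skipped."""
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                v = float(line)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: not a number: {line!r}") from None
            if math.isnan(v):
                raise FormatError(f"{path}:{lineno}: NaN value")
            values.append(v)
    return values


def write_ks_list(values: Iterable[float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for v in values:
            fh.write(f"{v:.6g}\n")


def write_table(records: Sequence, path: str | Path, schema: Sequence[str],
                precision: int = 6) -> None:
    """Write records (dataclasses, dicts or attribute objects) as a TSV with
    a header row; floats rendered with ``precision`` significant digits."""
    rows = []
    for rec in records:
        row = {}
        for col in schema:
            if isinstance(rec, dict):
                if col not in rec:
                    raise KeyError(f"record missing field {col!r}")
                row[col] = rec[col]
            else:
                if not hasattr(rec, col):
                    raise KeyError(f"record missing field {col!r}")
                row[col] = getattr(rec, col)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(schema))
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{precision}g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
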