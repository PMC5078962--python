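"""Sequence I/O, basic genome statistics, and tabular result serialization.

Thin record types are used instead of full Biopython ``SeqRecord`` objects so
that every downstream structure stays a plain dataclass that serializes to
JSON/TSV without adapters; FASTA parsing itself is delegated to
``Bio.SeqIO``.

Coordinates throughout the package are 0-based, half-open, in amino-acid
positions for protein-domain hits and base-pair positions for nucleotide
intervals.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

NT_CHARS = set("ACGTNacgtn")
AA_CHARS = set("ACDEFGHIKLMNPQRSTVWYXacdefghiklmnpqrstvwyx*-")

DOMAIN_CLASSES = (
    "KS", "AT", "DH", "ER", "KR", "MT", "ACP", "C", "A", "PCP", "TE",
    "P450", "MONOOX",
)


class SequenceError(ValueError):
    """Malformed sequence input (alphabet, duplicate ids, empty files)."""


@dataclass(frozen=True)
class SeqRecordLite:
    """A sequence record: id, free-text description, residues, alphabet.

    ``alphabet`` is ``"nt"`` or ``"aa"``; it is inferred at read time from
    the residue content and validated against it.
    """

    id: str
    description: str
    seq: str
    alphabet: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.seq:
            raise SequenceError(f"record {self.id!r} has an empty sequence")
        if self.alphabet not in ("nt", "aa"):
            raise SequenceError(f"unknown alphabet {self.alphabet!r}")
        chars = NT_CHARS if self.alphabet == "nt" else AA_CHARS
        bad = set(self.seq) - chars
        if bad:
            raise SequenceError(
                f"record {self.id!r}: characters {sorted(bad)} not valid for "
                f"alphabet {self.alphabet!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def infer_alphabet(seq: str) -> str:
    """Classify a residue string as ``nt`` or ``aa``.

    A string drawn entirely from A/C/G/T/N (either case) is nucleotide;
    anything else containing valid amino-acid letters is protein.
    """
    s = set(seq)
    if s <= NT_CHARS:
        return "nt"
    if s <= AA_CHARS:
        return "aa"
    bad = s - AA_CHARS - NT_CHARS
    raise SequenceError(f"characters {sorted(bad)} fit neither alphabet")


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[SeqRecordLite]:
    """Read a FASTA file into a list of :class:`SeqRecordLite`.

    Order is preserved, whitespace inside sequences is stripped by the
    parser, and case is preserved.  Duplicate ids and empty files are
    errors.  ``alphabet`` forces nt/aa; by default it is inferred per
    record.
    """
    path = Path(path)
    records: list[SeqRecordLite] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        ab = alphabet or infer_alphabet(seq)
        records.append(SeqRecordLite(rec.id, rec.description, seq, ab))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SeqRecordLite], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else (
                f"{rec.id} {rec.description}".strip()
            )
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


@dataclass(frozen=True)
class GenomeStats:
    """Scaffold count, total length and GC content of a (draft) genome.

    ``gc_fraction`` is a percentage over unambiguous bases only: ambiguous
    codes (N) are excluded from the denominator so the statistic is
    well-defined on draft assemblies.
    """

    total_len: int
    gc_fraction: float
    n_scaffolds: int


def genome_stats(records: Sequence[SeqRecordLite]) -> GenomeStats:
    """Total length, GC percentage and scaffold count over ``records``."""
    if not records:
        raise SequenceError("genome_stats needs at least one record")
    for rec in records:
        if rec.alphabet != "nt":
            raise SequenceError(f"record {rec.id!r} is not nucleotide")
    total = sum(len(r) for r in records)
    gc = at = 0
    for rec in records:
        up = rec.seq.upper()
        gc += up.count("G") + up.count("C")
        at += up.count("A") + up.count("T")
    denom = gc + at
    frac = 100.0 * gc / denom if denom else 0.0
    return GenomeStats(total_len=total, gc_fraction=frac, n_scaffolds=len(records))


def read_domain_table(path: str | Path) -> list["DomainHit"]:
    """Read precomputed domain annotations from a TSV.

    Columns: protein_id, domain_class, start, end, strand_of_gene,
    gene_order_index.  Hits are returned sorted by
    (gene_order_index, start); coordinates are validated 0-based half-open.
    """
    from .domains import DomainHit  # local import to avoid a cycle

    path = Path(path)
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "protein_id":  # header row
                continue
            if len(parts) < 6:
                raise SequenceError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            pid, dclass, start, end, strand, order = parts[:6]
            if dclass not in DOMAIN_CLASSES:
                raise SequenceError(
                    f"{path}:{lineno}: unknown domain class {dclass!r}; "
                    f"allowed: {', '.join(DOMAIN_CLASSES)}"
                )
            start_i, end_i = int(start), int(end)
            if end_i <= start_i:
                raise SequenceError(f"{path}:{lineno}: end {end_i} <= start {start_i}")
            if strand not in ("+", "-"):
                raise SequenceError(f"{path}:{lineno}: strand must be + or -")
            hits.append(
                DomainHit(
                    protein_id=pid, domain_class=dclass, start=start_i, end=end_i,
                    score=float("nan"), gene_order_index=int(order), strand=strand,
                )
            )
    hits.sort(key=lambda h: (h.gene_order_index, h.start))
    return hits


def write_domain_table(hits: Sequence["DomainHit"], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("protein_id\tdomain_class\tstart\tend\tstrand_of_gene\tgene_order_index\n")
        for h in hits:
            fh.write(
                f"{h.protein_id}\t{h.domain_class}\t{h.start}\t{h.end}\t"
                f"{h.strand}\t{h.gene_order_index}\n"
            )


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, float) and obj != obj:  # NaN -> null
        return None
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_results(obj, path: str | Path, format: str = "json") -> None:
    """Serialize a result object (any package dataclass, dict, or list).

    ``json`` writes a stable, indented document; ``tsv`` expects a list of
    flat dataclasses/dicts and writes one row each.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_to_jsonable(obj), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "tsv":
        rows = obj if isinstance(obj, (list, tuple)) else [obj]
        rows = [_to_jsonable(r) for r in rows]
        if not rows:
            raise ValueError("nothing to write")
        cols = list(rows[0].keys())
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in rows:
                fh.write("\t".join(_tsv_cell(r.get(c)) for c in cols) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def _tsv_cell(v) -> str:
    if v is None:
        return ""
    if isinstance(v, (list, tuple, dict)):
        return json.dumps(v)
    return str(v)


def read_results(path: str | Path):
    """Read back a JSON result written by :func:`write_results`."""
    with open(path) as fh:
        return json.load(fh)


_META_RE = re.compile(r"(\w+)=(\S+)")


def parse_orf_metadata(rec: SeqRecordLite, default_order: int) -> tuple[int, str]:
    """Extract (gene_order_index, strand) from a record description.

    The synthetic generator and the CLI encode gene order and strand as
    ``order=N strand=+`` tokens in the FASTA description; records without
    tags default to file order on the forward strand.
    """
    meta = dict(_META_RE.findall(rec.description))
    order = int(meta.get("order", default_order))
    strand = meta.get("strand", "+")
    return order, strand
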