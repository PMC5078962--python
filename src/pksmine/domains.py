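"""Catalytic-domain detection and active-site signature classification.

PKS/NRPS catalytic domains (KS, AT, DH, ER, KR, MT, ACP, C, A, PCP, TE and
the tailoring classes P450/MONOOX) are located by Smith–Waterman alignment
of each protein against one packaged exemplar per class (BLOSUM62, affine
gaps 10/1), with a per-class score threshold calibrated on shuffled-sequence
nulls.  Signature residues are then read off the query at anchor columns of
the exemplar, mapped through the pairwise alignment — anchoring to alignment
columns rather than literature numbering, which drifts between references.

Signature interpretation follows the standard motif conventions of the
field: the KS active site is Cys in extension modules and Gln (KSQ) in
decarboxylative loading modules; the five-residue AT motif discriminates
methylmalonyl-CoA (YASHS) from malonyl-CoA (HAFHS) selection; KR and ER
fingerprints predict hydroxyl/methyl stereochemistry; the A-domain
binding-pocket code predicts the amino-acid substrate.  The KR/ER rules and
the pocket-code table ship as editable TSV reference data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import DOMAIN_CLASSES, SeqRecordLite, SequenceError, read_fasta

# Resolution priority when two classes claim overlapping residues with
# equal score (higher-scoring hit always wins first).
CLASS_PRIORITY = ("KS", "AT", "DH", "ER", "KR", "MT", "ACP", "C", "A", "PCP",
                  "TE", "P450", "MONOOX")

AT_METHYLMALONYL = "YASHS"
AT_MALONYL = "HAFHS"


@dataclass(frozen=True)
class DomainHit:
    """A located catalytic domain on one protein.

    Coordinates are 0-based half-open amino-acid positions on the protein.
    ``score`` is the Smith–Waterman alignment score against the class
    exemplar (NaN when the hit came from a precomputed table).
    """

    protein_id: str
    domain_class: str
    start: int
    end: int
    score: float
    gene_order_index: int
    strand: str = "+"
    ref_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.protein_id}: end {self.end} <= start {self.start}")
        if self.domain_class not in DOMAIN_CLASSES:
            raise ValueError(f"unknown domain class {self.domain_class!r}")


@dataclass(frozen=True)
class SignatureCall:
    """An extracted signature motif and its classification.

    ``confidence`` is ``exact`` for a direct motif/rule match, ``near`` for
    a one-mismatch match (AT and A-domain classifiers), and ``unknown``
    otherwise; ``call == "unknown"`` iff ``confidence == "unknown"``.
    ``rule_id`` records which rule of the packaged table fired.
    """

    hit: DomainHit
    motif: str
    call: str
    confidence: str
    rule_id: str = ""


@dataclass(frozen=True)
class Exemplar:
    """One reference domain: sequence, anchor columns, detection threshold."""

    id: str
    domain_class: str
    seq: str
    anchor_columns: tuple[int, ...]
    min_score: float


class ExemplarSet:
    """The packaged reference bundle: exemplars plus rule tables."""

    def __init__(
        self,
        exemplars: Mapping[str, Exemplar],
        kr_er_rules: Sequence[tuple[str, str, str, str]],
        a_codes: Mapping[str, str],
    ) -> None:
        self.exemplars = dict(exemplars)
        self.kr_er_rules = list(kr_er_rules)  # (rule_id, domain_class, pattern, call)
        self.a_codes = dict(a_codes)

    def by_class(self, domain_class: str) -> Exemplar:
        for ex in self.exemplars.values():
            if ex.domain_class == domain_class:
                return ex
        raise KeyError(f"no exemplar for class {domain_class!r}")

    def classes(self) -> list[str]:
        return sorted({e.domain_class for e in self.exemplars.values()},
                      key=CLASS_PRIORITY.index)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pksmine").joinpath("data", name)))


def load_references(data_dir: str | Path | None = None) -> ExemplarSet:
    """Load the packaged exemplar bundle (or one from ``data_dir``)."""
    base = Path(data_dir) if data_dir else _data_path("")
    seqs = {r.id: r for r in read_fasta(base / "exemplars_synthetic.fasta", alphabet="aa")}
    exemplars: dict[str, Exemplar] = {}
    with open(base / "anchors.tsv") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("exemplar_id"):
                continue
            ex_id, dclass, cols, min_score = line.split("\t")
            anchor = tuple(int(c) for c in cols.split(",")) if cols else ()
            exemplars[ex_id] = Exemplar(
                id=ex_id, domain_class=dclass, seq=seqs[ex_id].seq,
                anchor_columns=anchor, min_score=float(min_score),
            )
    rules: list[tuple[str, str, str, str]] = []
    with open(base / "kr_er_rules.tsv") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("rule_id"):
                continue
            rule_id, dclass, pattern, call = line.split("\t")
            rules.append((rule_id, dclass, pattern, call))
    codes: dict[str, str] = {}
    with open(base / "a_codes.tsv") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("substrate"):
                continue
            substrate, code = line.split("\t")
            codes[substrate] = code
    return ExemplarSet(exemplars, rules, codes)


def _aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    aligner.mode = mode
    return aligner


def _best_local(protein: str, exemplar: str):
    """Best local alignment of ``exemplar`` within ``protein`` (or None)."""
    aligner = _aligner("local")
    try:
        aln = next(iter(aligner.align(protein, exemplar)))
    except (StopIteration, ValueError):
        return None
    return aln


def detect_domains(
    protein: SeqRecordLite,
    references: ExemplarSet,
    min_score: float | None = None,
    gene_order_index: int = 0,
    strand: str = "+",
) -> list[DomainHit]:
    """Locate all catalytic domains on one protein.

    For each exemplar class, maximal-scoring non-overlapping local
    alignments are found by recursive split: the best hit is recorded, and
    the flanking segments are searched again until no alignment reaches the
    class threshold (``min_score`` overrides the per-class calibrated
    threshold when given).  Overlaps between classes are resolved by score,
    ties by the fixed class priority.  Hits are returned N-to-C.
    """
    if protein.alphabet != "aa":
        raise SequenceError(f"detect_domains needs a protein; {protein.id!r} is nucleotide")
    if not references.exemplars:
        raise ValueError("empty reference set")

    raw: list[DomainHit] = []
    for ex in references.exemplars.values():
        threshold = min_score if min_score is not None else ex.min_score
        raw.extend(
            _scan_class(protein.seq, ex, threshold, protein.id, gene_order_index, strand)
        )
    resolved = _resolve_overlaps(raw)
    resolved.sort(key=lambda h: h.start)
    return resolved


def _scan_class(
    seq: str, ex: Exemplar, threshold: float,
    protein_id: str, order: int, strand: str,
) -> list[DomainHit]:
    hits: list[DomainHit] = []
    # segments are (offset, subsequence) still to be searched
    stack = [(0, seq)]
    while stack:
        offset, segment = stack.pop()
        if len(segment) < 10:
            continue
        aln = _best_local(segment, ex.seq)
        if aln is None or aln.score < threshold:
            continue
        blocks = aln.aligned[0]  # blocks on the query protein
        start, end = int(blocks[0][0]), int(blocks[-1][1])
        hits.append(
            DomainHit(
                protein_id=protein_id, domain_class=ex.domain_class,
                start=offset + start, end=offset + end, score=float(aln.score),
                gene_order_index=order, strand=strand, ref_id=ex.id,
            )
        )
        stack.append((offset, segment[:start]))
        stack.append((offset + end, segment[end:]))
    return hits


def _resolve_overlaps(hits: list[DomainHit]) -> list[DomainHit]:
    """Greedy best-first overlap resolution across classes."""
    order = sorted(
        hits, key=lambda h: (-h.score, CLASS_PRIORITY.index(h.domain_class), h.start)
    )
    kept: list[DomainHit] = []
    for h in order:
        if all(h.end <= k.start or h.start >= k.end for k in kept):
            kept.append(h)
    return kept


def extract_signature(
    hit: DomainHit, protein: SeqRecordLite, reference: Exemplar
) -> str:
    """Read the query residues opposite the exemplar anchor columns.

    The exemplar is re-aligned locally to the hit region and each anchor
    column mapped through the alignment; a query gap opposite an anchor
    yields ``-`` in the motif.  Anchors falling outside the aligned span of
    the exemplar (hit shorter than the anchored region) raise an error.
    """
    if not reference.anchor_columns:
        raise ValueError(f"exemplar {reference.id!r} has no anchor definition")
    sub = protein.seq[hit.start : hit.end]
    aln = _best_local(sub, reference.seq)
    if aln is None:
        raise ValueError(f"hit {hit.protein_id}:{hit.start}-{hit.end} does not align")
    q_blocks, r_blocks = aln.aligned  # query(protein sub) blocks, exemplar blocks
    col_map: dict[int, int] = {}
    for (qs, qe), (rs, re_) in zip(q_blocks, r_blocks):
        for i in range(re_ - rs):
            col_map[rs + i] = qs + i
    r_lo, r_hi = int(r_blocks[0][0]), int(r_blocks[-1][1])
    motif = []
    for col in reference.anchor_columns:
        if col < r_lo or col >= r_hi:
            raise ValueError(
                f"partial motif: anchor column {col} outside aligned exemplar "
                f"span [{r_lo},{r_hi}) for hit {hit.protein_id}:{hit.start}-{hit.end}"
            )
        if col in col_map:
            motif.append(sub[col_map[col]])
        else:  # exemplar column aligned to a query gap
            motif.append("-")
    return "".join(motif)


def classify_ks(motif: str) -> tuple[str, str]:
    """KS active-site call: Cys -> extension KS, Gln -> loading KSQ."""
    if motif == "C":
        return ("KS_extension", "exact")
    if motif == "Q":
        return ("KSQ_loading", "exact")
    return ("unknown", "unknown")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def classify_at(motif: str) -> tuple[str, str]:
    """AT substrate call from the 5-residue signature.

    Hamming distance 0 to YASHS/HAFHS gives an exact call; distance 1 to
    exactly one of the two gives a near call (this is what maps the
    observed RAFHS variant to malonyl-CoA); anything else — including a
    distance-1 tie or a gapped motif — is unknown.
    """
    if len(motif) != 5:
        raise ValueError(f"AT motif must be 5 residues, got {motif!r}")
    if "-" in motif:
        return ("unknown", "unknown")
    d_mm = _hamming(motif, AT_METHYLMALONYL)
    d_m = _hamming(motif, AT_MALONYL)
    if d_mm == 0:
        return ("methylmalonyl_CoA", "exact")
    if d_m == 0:
        return ("malonyl_CoA", "exact")
    near = [(d, c) for d, c in ((d_mm, "methylmalonyl_CoA"), (d_m, "malonyl_CoA")) if d == 1]
    if len(near) == 1:
        return (near[0][1], "near")
    return ("unknown", "unknown")


def _match_rules(
    motif: str, domain_class: str, rules: Sequence[tuple[str, str, str, str]]
) -> tuple[str, str, str]:
    """First matching rule wins; returns (call, confidence, rule_id)."""
    for rule_id, dclass, pattern, call in rules:
        if dclass != domain_class:
            continue
        if re.fullmatch(pattern, motif):
            return (call, "exact", rule_id)
    return ("unknown", "unknown", "")


def classify_kr(motif: str, references: ExemplarSet) -> tuple[str, str, str]:
    """KR stereochemistry fingerprint: A-type vs B-type, by rule table."""
    return _match_rules(motif, "KR", references.kr_er_rules)


def classify_er(motif: str, references: ExemplarSet) -> tuple[str, str, str]:
    """ER stereochemistry fingerprint: S vs R configuration, by rule table."""
    return _match_rules(motif, "ER", references.kr_er_rules)


def call_a_domain(
    motif: str, code_table: Mapping[str, str], tolerance: int = 1
) -> tuple[str, str]:
    """A-domain substrate by nearest binding-pocket code.

    Nearest code by Hamming distance; a unique nearest code within
    ``tolerance`` mismatches is called (exact at distance 0, near above);
    ties and gapped motifs are unknown.
    """
    lengths = {len(c) for c in code_table.values()}
    if len(motif) not in lengths:
        raise ValueError(
            f"A-domain motif length {len(motif)} does not match code table ({lengths})"
        )
    if "-" in motif:
        return ("unknown", "unknown")
    dists = sorted((_hamming(motif, code), sub) for sub, code in code_table.items())
    best_d, best_sub = dists[0]
    if best_d > tolerance:
        return ("unknown", "unknown")
    if len(dists) > 1 and dists[1][0] == best_d:
        return ("unknown", "unknown")
    return (best_sub, "exact" if best_d == 0 else "near")


def call_signatures(
    hits: Sequence[DomainHit],
    proteins: Mapping[str, SeqRecordLite],
    references: ExemplarSet,
) -> list[SignatureCall]:
    """Extract and classify signatures for every hit that has anchors.

    Hits of classes without an anchor definition (DH, MT, ACP, C, PCP, TE,
    tailoring classes) get an empty motif and the call ``present``.
    """
    calls: list[SignatureCall] = []
    for hit in hits:
        ex = references.by_class(hit.domain_class)
        if not ex.anchor_columns:
            calls.append(SignatureCall(hit, "", "present", "exact"))
            continue
        try:
            motif = extract_signature(hit, proteins[hit.protein_id], ex)
        except ValueError:
            calls.append(SignatureCall(hit, "", "unknown", "unknown"))
            continue
        if hit.domain_class == "KS":
            call, conf = classify_ks(motif)
            rule = ""
        elif hit.domain_class == "AT":
            call, conf = classify_at(motif)
            rule = ""
        elif hit.domain_class == "KR":
            call, conf, rule = classify_kr(motif, references)
        elif hit.domain_class == "ER":
            call, conf, rule = classify_er(motif, references)
        elif hit.domain_class == "A":
            call, conf = call_a_domain(motif, references.a_codes)
            rule = ""
        else:
            call, conf, rule = "present", "exact", ""
        calls.append(SignatureCall(hit, motif, call, conf, rule))
    return calls
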