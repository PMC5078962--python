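"""Module partitioning, assembly-line construction and precursor prediction.

An assembly line is read off an ordered domain string by a greedy
left-to-right grammar: each PKS module opens at a KS (KSQ for the loading
module), absorbs an AT and optional β-processing domains (DH/ER/KR/MT), and
closes at an ACP; an NRPS module is (C)–A–PCP.  A module left open at the
end of an ORF is completed by the leading domains of the next ORF (split
modules span at most two consecutive ORFs).  Genes annotated on the
complementary strand are excluded from the catalytic line but kept for the
tailoring inventory.

The β-keto processing combination of each extension module sets the
oxidation state of the unit it adds — no processing leaves a ketone, KR
alone a hydroxyl, DH/KR a double bond, DH/ER/KR a saturated carbon — and
the AT signature sets the extender (malonyl-CoA, a C2 unit; methylmalonyl-
CoA, a C3 unit with a methyl branch).  A KSQ loading module primes the
chain with the decarboxylated starter of its AT substrate.  The product is
the unit string, the unit counts, and a SMILES of the linear polyketide
precursor with the terminal amino acid appended as a C-terminal amide;
macrocyclization and post-assembly tailoring are inventoried but not
modeled as structure transformations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .domains import DomainHit, ExemplarSet, SignatureCall, call_signatures, detect_domains
from .seqio import SeqRecordLite, parse_orf_metadata

PKS_OPTIONAL = {"DH", "ER", "KR", "MT"}


class GrammarError(ValueError):
    """Domain order that no legal module structure can explain."""


@dataclass
class AssemblyModule:
    """One loading/extension/NRPS module of the assembly line."""

    index: int
    kind: str  # pks_loading | pks_extension | nrps
    domains: list[SignatureCall] = field(default_factory=list)
    extender: str = "unknown"  # C2_malonyl | C3_methylmalonyl | amino_acid:<name> | unknown
    reduction_state: str = "n/a"  # ketone | hydroxyl | double_bond | saturated | n/a
    kr_type: str = "none"
    er_config: str = "none"
    source_orfs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def domain_classes(self) -> list[str]:
        return [c.hit.domain_class for c in self.domains]

    @property
    def unit(self) -> str:
        """Short unit label: C2, C3, the amino-acid name, or ?."""
        if self.extender == "C2_malonyl":
            return "C2"
        if self.extender == "C3_methylmalonyl":
            return "C3"
        if self.extender.startswith("amino_acid:"):
            return self.extender.split(":", 1)[1]
        return "?"


@dataclass
class AssemblyLine:
    """The ordered module chain plus derived chain-level results."""

    modules: list[AssemblyModule]
    unit_string: str = ""
    counts: dict[str, int] = field(default_factory=dict)
    partial: bool = False
    precursor_smiles: str = ""
    tailoring_genes: list[dict] = field(default_factory=list)

    def pks_modules(self) -> list[AssemblyModule]:
        return [m for m in self.modules if m.kind.startswith("pks")]

    def nrps_modules(self) -> list[AssemblyModule]:
        return [m for m in self.modules if m.kind == "nrps"]


def partition_modules(calls: Sequence[SignatureCall]) -> list[AssemblyModule]:
    """Partition an ordered, signature-annotated domain string into modules.

    ``calls`` must be sorted by (gene_order_index, start) and restricted to
    forward-strand catalytic genes.  Raises :class:`GrammarError` for an AT
    with no module open; an ER without a DH is kept but flagged with a
    warning on its module.
    """
    modules: list[AssemblyModule] = []
    current: AssemblyModule | None = None
    current_start_orf: int | None = None

    def close(mod: AssemblyModule) -> None:
        modules.append(mod)

    for call in calls:
        cls = call.hit.domain_class
        if cls in ("P450", "MONOOX"):
            continue  # tailoring, not part of the catalytic line
        if current is not None and current_start_orf is not None:
            if call.hit.gene_order_index > current_start_orf + 1:
                raise GrammarError(
                    f"module {current.index} left open across more than two ORFs "
                    f"(opened in gene {current_start_orf}, now at "
                    f"{call.hit.gene_order_index})"
                )
        if cls == "KS":
            if current is not None:
                raise GrammarError(
                    f"KS at {call.hit.protein_id}:{call.hit.start} while module "
                    f"{current.index} is still open (missing carrier domain?)"
                )
            kind = "pks_loading" if call.call == "KSQ_loading" else "pks_extension"
            current = AssemblyModule(index=len(modules), kind=kind)
            current_start_orf = call.hit.gene_order_index
            _absorb(current, call)
        elif cls in ("AT", *PKS_OPTIONAL):
            if current is None or not current.kind.startswith("pks"):
                raise GrammarError(
                    f"{cls} at {call.hit.protein_id}:{call.hit.start} with no "
                    f"preceding KS in a PKS region"
                )
            _absorb(current, call)
        elif cls == "ACP":
            if current is None or not current.kind.startswith("pks"):
                raise GrammarError(
                    f"ACP at {call.hit.protein_id}:{call.hit.start} outside a PKS module"
                )
            _absorb(current, call)
            if "ER" in current.domain_classes() and "DH" not in current.domain_classes():
                current.warnings.append("ER without DH; domain kept but flagged")
            close(current)
            current = None
            current_start_orf = None
        elif cls in ("C", "A"):
            if current is None:
                current = AssemblyModule(index=len(modules), kind="nrps")
                current_start_orf = call.hit.gene_order_index
            elif current.kind != "nrps":
                raise GrammarError(
                    f"{cls} at {call.hit.protein_id}:{call.hit.start} inside an "
                    f"open PKS module"
                )
            _absorb(current, call)
        elif cls == "PCP":
            if current is None or current.kind != "nrps":
                raise GrammarError(
                    f"PCP at {call.hit.protein_id}:{call.hit.start} outside an NRPS module"
                )
            _absorb(current, call)
            close(current)
            current = None
            current_start_orf = None
        elif cls == "TE":
            if modules:
                _absorb(modules[-1], call)
            # a leading TE with no module is ignored
    if current is not None:
        raise GrammarError(
            f"module {current.index} left open at the end of the cluster "
            f"(domains {current.domain_classes()})"
        )
    return modules


def _absorb(mod: AssemblyModule, call: SignatureCall) -> None:
    mod.domains.append(call)
    pid = call.hit.protein_id
    if pid not in mod.source_orfs:
        mod.source_orfs.append(pid)


def reduction_state(module: AssemblyModule) -> str:
    """Oxidation state of the β-carbon set by the module's optional domains."""
    if module.kind != "pks_extension":
        return "n/a"
    present = {c for c in module.domain_classes() if c in ("DH", "ER", "KR")}
    if present == {"KR"}:
        return "hydroxyl"
    if present == {"DH", "KR"}:
        return "double_bond"
    if present == {"DH", "ER", "KR"}:
        return "saturated"
    if present == set():
        return "ketone"
    module.warnings.append(
        f"unexpected beta-processing combination {sorted(present)}; treated as ketone"
    )
    return "ketone"


def assign_extenders(modules: Sequence[AssemblyModule]) -> list[AssemblyModule]:
    """Set each module's extender (and stereo calls) from its signatures.

    PKS modules take the AT call (methylmalonyl-CoA -> C3, malonyl-CoA ->
    C2); the loading module's unit is the decarboxylated starter of its AT
    substrate, so a KSQ + malonyl-AT loads a C2 starter.  NRPS modules take
    the A-domain substrate.  Unknown calls propagate as ``unknown``.
    """
    for mod in modules:
        mod.reduction_state = reduction_state(mod)
        for call in mod.domains:
            if call.hit.domain_class == "KR" and call.call in ("A_type", "B_type"):
                mod.kr_type = call.call
            if call.hit.domain_class == "ER" and call.call in ("S_config", "R_config"):
                mod.er_config = call.call
        if mod.kind.startswith("pks"):
            at = next((c for c in mod.domains if c.hit.domain_class == "AT"), None)
            if at is None or at.call == "unknown":
                mod.extender = "unknown"
            elif at.call == "methylmalonyl_CoA":
                mod.extender = "C3_methylmalonyl"
            elif at.call == "malonyl_CoA":
                mod.extender = "C2_malonyl"
            else:
                mod.extender = "unknown"
        else:
            a = next((c for c in mod.domains if c.hit.domain_class == "A"), None)
            if a is None or a.call == "unknown":
                mod.extender = "unknown"
            else:
                mod.extender = f"amino_acid:{a.call}"
    return list(modules)


def build_chain(line: AssemblyLine) -> AssemblyLine:
    """Derive the unit string and unit counts from the module chain.

    Token 1 is the starter unit, tokens 2..n the extension units in module
    order; NRPS units are counted but are not ketide tokens.  Any unknown
    extender marks the chain partial; counts then cover known units only.
    """
    tokens: list[str] = []
    counts: dict[str, int] = {}
    partial = False
    for mod in line.modules:
        unit = mod.unit
        if mod.kind.startswith("pks"):
            tokens.append(unit)
        if unit == "?":
            partial = True
        else:
            counts[unit] = counts.get(unit, 0) + 1
    line.unit_string = "-".join(tokens)
    line.counts = counts
    line.partial = partial
    return line


_BETA = {  # reduction state -> beta-carbon SMILES fragment
    "ketone": "C(=O)",
    "hydroxyl": "C(O)",
    "saturated": "C",
}
_BETA_STEREO = {"A_type": "[C@H](O)", "B_type": "[C@@H](O)"}


def chain_to_smiles(line: AssemblyLine, trans_double_bonds: bool = True) -> str:
    """SMILES of the linear polyketide precursor (free acid / C-terminal amide).

    The chain is written from the starter ω-carbon to the carboxyl terminus.
    Each extension unit contributes an α-carbon (methyl branch iff C3) and
    assigns its β-state to the carbonyl carbon inherited from the previous
    unit.  Hydroxyl stereocentres are tagged when the module's KR type
    resolved, methyl-branch centres when its ER configuration resolved on a
    saturated C3 unit; double bonds are written trans by default.  A
    terminal NRPS amino acid (glycine in the canonical cluster) is appended
    as a C-terminal amide.  A partial chain is an error: no structure is
    emitted from unknown units.
    """
    if line.partial:
        raise ValueError("chain is partial (unknown extender); cannot emit a structure")
    pks = line.pks_modules()
    if not pks or pks[0].kind != "pks_loading":
        raise ValueError("chain must begin with a loading module")
    nrps = line.nrps_modules()
    if len(nrps) > 1:
        raise ValueError("at most one terminal NRPS module is supported")

    starter = pks[0]
    out: list[str] = ["C" if starter.unit == "C2" else "CC"]
    pending_dir = False  # previous unit ended inside a C=C pair
    for mod in pks[1:]:
        state = mod.reduction_state
        branch = mod.unit == "C3"
        bond = "/" if trans_double_bonds and (pending_dir or state == "double_bond") else ""
        if state == "double_bond":
            alpha = "C(C)" if branch else "C"
            out.append(f"{bond}C={alpha}")
            pending_dir = trans_double_bonds
        else:
            beta = _BETA_STEREO.get(mod.kr_type, _BETA["hydroxyl"]) if (
                state == "hydroxyl" and mod.kr_type in _BETA_STEREO
            ) else _BETA[state]
            if branch and state == "saturated" and mod.er_config in ("S_config", "R_config"):
                alpha = "[C@H](C)" if mod.er_config == "S_config" else "[C@@H](C)"
            else:
                alpha = "C(C)" if branch else "C"
            out.append(f"{bond}{beta}{alpha}")
            pending_dir = False
    tail_bond = "/" if pending_dir else ""
    if nrps:
        aa = nrps[0].unit
        if aa != "glycine":
            raise ValueError(f"no template for terminal amino acid {aa!r}")
        out.append(f"{tail_bond}C(=O)NCC(=O)O")
    else:
        out.append(f"{tail_bond}C(=O)O")
    return "".join(out)


def inventory_tailoring(
    orf_hits: Mapping[str, Sequence[DomainHit]],
    functions: Mapping[str, str] | None = None,
) -> list[dict]:
    """List ORFs with oxidative/tailoring roles (monooxygenases, P450s).

    Entries carry locus, deduced function and strand; no catalytic
    assignment is attempted — which enzyme performs which oxidation cannot
    be decided from sequence alone.
    """
    names = {"MONOOX": "monooxygenase", "P450": "cytochrome P450"}
    entries: list[dict] = []
    for orf_id, hits in orf_hits.items():
        for h in hits:
            if h.domain_class in names:
                entries.append({
                    "locus": orf_id,
                    "deduced_function": (functions or {}).get(orf_id, names[h.domain_class]),
                    "strand": h.strand,
                })
                break
    return entries


def mine_cluster(
    records: Sequence[SeqRecordLite],
    references: ExemplarSet,
    min_score: float | None = None,
) -> AssemblyLine:
    """End-to-end cluster mining: proteins in, assembly line out.

    ORF order and strand are read from ``order=``/``strand=`` tags in the
    FASTA descriptions (defaulting to file order, forward strand).
    Forward-strand domains feed the module grammar; every ORF feeds the
    tailoring inventory.
    """
    proteins = {r.id: r for r in records}
    per_orf: dict[str, list[DomainHit]] = {}
    ordered: list[tuple[int, SeqRecordLite, str]] = []
    for i, rec in enumerate(records):
        order, strand = parse_orf_metadata(rec, i)
        ordered.append((order, rec, strand))
    ordered.sort(key=lambda t: t[0])

    line_calls: list[SignatureCall] = []
    for order, rec, strand in ordered:
        hits = detect_domains(rec, references, min_score=min_score,
                              gene_order_index=order, strand=strand)
        per_orf[rec.id] = hits
        if strand == "+":
            line_calls.extend(call_signatures(hits, proteins, references))
    line_calls.sort(key=lambda c: (c.hit.gene_order_index, c.hit.start))
    modules = partition_modules(line_calls)
    assign_extenders(modules)
    line = AssemblyLine(modules=modules)
    build_chain(line)
    line.tailoring_genes = inventory_tailoring(per_orf)
    if not line.partial:
        line.precursor_smiles = chain_to_smiles(line)
    return line


def module_table(line: AssemblyLine) -> list[dict]:
    """Flat per-module rows for TSV output."""
    rows = []
    for m in line.modules:
        rows.append({
            "index": m.index,
            "kind": m.kind,
            "domains": ",".join(m.domain_classes()),
            "extender": m.extender,
            "unit": m.unit,
            "reduction_state": m.reduction_state,
            "kr_type": m.kr_type,
            "er_config": m.er_config,
            "source_orfs": ",".join(m.source_orfs),
            "warnings": ";".join(m.warnings),
        })
    return rows
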