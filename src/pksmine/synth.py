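"""Planted-truth synthetic data: clusters, genome pairs, 16S alignments.

Every input class the analysis consumes can be generated here with known
ground truth, so the whole pipeline is testable offline:

* ``make_cluster`` splices packaged exemplar domains into multi-ORF
  PKS/NRPS proteins with random linkers and planted signature residues
  (KS Cys/Gln, AT YASHS/HAFHS/RAFHS, KR/ER fingerprints, A-domain pocket
  code), honouring ORF breaks including mid-module splits;
* ``make_genome_pair`` produces a genome and a copy carrying i.i.d.
  substitutions at a controlled rate (plus optional block rearrangements),
  so the expected ANI is known by construction;
* ``evolve_16s`` evolves a gapless alignment along a given tree under
  Jukes-Cantor, so the true topology is known.

All generators are deterministic in their seed.  Linkers are plain random
amino-acid strings: with detection thresholds calibrated on shuffled-
composition nulls, random sequence cannot produce spurious domain hits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .domains import AT_MALONYL, AT_METHYLMALONYL, ExemplarSet, load_references
from .phylo import MsaLite, Node
from .seqio import SeqRecordLite, write_fasta

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NT4 = np.array(list("ACGT"))

# planted anchor residues per stereochemistry call (match the packaged
# kr_er_rules.tsv patterns; "none" deliberately matches no rule)
KR_ANCHORS = {"B_type": "LDDG", "A_type": "GSYW", "none": "AGSG"}
ER_ANCHORS = {"S_config": "Y", "R_config": "V", "none": "V"}

STATE_DOMAINS = {
    "ketone": [],
    "hydroxyl": ["KR"],
    "double_bond": ["DH", "KR"],
    "saturated": ["DH", "ER", "KR"],
}


class SpecError(ValueError):
    pass


@dataclass
class ClusterSpec:
    """Blueprint of a synthetic cluster: modules, ORF breaks, tailoring.

    ``orf_breaks`` are (module_index, domain_offset) pairs: a new ORF
    starts before that domain of that module; offset 0 breaks between
    modules, a positive offset splits a module across two ORFs.
    """

    modules: list[dict]
    orf_breaks: list[tuple[int, int]] = field(default_factory=list)
    tailoring: dict = field(default_factory=dict)
    seed: int = 0
    terminal_te: bool = True

    def __post_init__(self) -> None:
        if not self.modules:
            raise SpecError("a cluster needs at least one module")
        if self.modules[0]["kind"] != "pks_loading":
            raise SpecError("the first module must be pks_loading")
        breaks = [tuple(b) for b in self.orf_breaks]
        if breaks != sorted(breaks):
            raise SpecError("orf_breaks must be strictly increasing")
        self.orf_breaks = breaks
        for mod in self.modules:
            ext = mod.get("extender", "unknown")
            if ext not in ("C2_malonyl", "C3_methylmalonyl") and not ext.startswith(
                "amino_acid:"
            ):
                raise SpecError(f"unknown extender {ext!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterSpec":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            modules=data["modules"],
            orf_breaks=[tuple(b) for b in data.get("orf_breaks", [])],
            tailoring=data.get("tailoring", {}),
            seed=data.get("seed", 0),
            terminal_te=data.get("terminal_te", True),
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "modules": self.modules,
                    "orf_breaks": [list(b) for b in self.orf_breaks],
                    "tailoring": self.tailoring,
                    "seed": self.seed,
                    "terminal_te": self.terminal_te,
                },
                fh, indent=2,
            )
            fh.write("\n")

    # ---- generator-side truth (independent of the mining pipeline) ----

    def module_unit(self, mod: dict) -> str:
        ext = mod["extender"]
        if ext == "C2_malonyl":
            return "C2"
        if ext == "C3_methylmalonyl":
            return "C3"
        return ext.split(":", 1)[1]

    def truth(self) -> dict:
        units = [self.module_unit(m) for m in self.modules]
        pks_units = [u for m, u in zip(self.modules, units) if m["kind"].startswith("pks")]
        counts: dict[str, int] = {}
        for u in units:
            counts[u] = counts.get(u, 0) + 1
        return {
            "n_pks_modules": sum(m["kind"].startswith("pks") for m in self.modules),
            "n_nrps_modules": sum(m["kind"] == "nrps" for m in self.modules),
            "unit_string": "-".join(pks_units),
            "counts": counts,
            "modules": [
                {
                    "kind": m["kind"],
                    "extender": m["extender"],
                    "unit": u,
                    "reduction_state": m.get("reduction_state", "n/a")
                    if m["kind"] == "pks_extension" else "n/a",
                    "kr_type": m.get("kr_type", "none"),
                    "er_config": m.get("er_config", "none"),
                }
                for m, u in zip(self.modules, units)
            ],
            "tailoring": dict(self.tailoring),
            "seed": self.seed,
        }


@dataclass
class TruthBundle:
    """Generated records plus the truth JSON mirroring the spec."""

    records: list[SeqRecordLite]
    truth: dict
    seed: int

    def write(self, fasta_path: str | Path, truth_path: str | Path) -> None:
        write_fasta(self.records, fasta_path)
        with open(truth_path, "w") as fh:
            json.dump(self.truth, fh, indent=2)
            fh.write("\n")


def canonical_spec_path() -> Path:
    return Path(str(resources.files("pksmine").joinpath("data", "alchivemycin_canonical.json")))


def load_canonical_spec() -> ClusterSpec:
    """The packaged transcription of the alchivemycin-type hybrid cluster."""
    return ClusterSpec.from_json(canonical_spec_path())


def _linker(rng: np.random.Generator, lo: int = 20, hi: int = 60) -> str:
    return "".join(rng.choice(AA20, size=int(rng.integers(lo, hi + 1))))


def _domain_seq(cls: str, refs: ExemplarSet, overwrite: dict[int, str]) -> str:
    ex = refs.by_class(cls)
    s = list(ex.seq)
    for col, res in overwrite.items():
        s[col] = res
    return "".join(s)


def _module_domains(mod: dict, refs: ExemplarSet) -> list[tuple[str, str]]:
    """(domain_class, sequence) list for one module, anchors planted."""
    kind = mod["kind"]
    out: list[tuple[str, str]] = []
    if kind in ("pks_loading", "pks_extension"):
        ks_ex = refs.by_class("KS")
        ks_res = "Q" if kind == "pks_loading" else "C"
        out.append(("KS", _domain_seq("KS", refs, {ks_ex.anchor_columns[0]: ks_res})))
        at_ex = refs.by_class("AT")
        motif = mod.get("at_motif") or (
            AT_METHYLMALONYL if mod["extender"] == "C3_methylmalonyl" else AT_MALONYL
        )
        out.append(("AT", _domain_seq("AT", refs, dict(zip(at_ex.anchor_columns, motif)))))
        if kind == "pks_extension":
            for cls in STATE_DOMAINS[mod.get("reduction_state", "ketone")]:
                if cls == "KR":
                    anchors = KR_ANCHORS[mod.get("kr_type", "none")]
                    ex = refs.by_class("KR")
                    out.append(("KR", _domain_seq("KR", refs, dict(zip(ex.anchor_columns, anchors)))))
                elif cls == "ER":
                    ex = refs.by_class("ER")
                    res = ER_ANCHORS[mod.get("er_config", "none")]
                    out.append(("ER", _domain_seq("ER", refs, {ex.anchor_columns[0]: res})))
                else:
                    out.append((cls, _domain_seq(cls, refs, {})))
        out.append(("ACP", _domain_seq("ACP", refs, {})))
    elif kind == "nrps":
        out.append(("C", _domain_seq("C", refs, {})))
        aa = mod["extender"].split(":", 1)[1]
        if aa not in refs.a_codes:
            raise SpecError(f"no pocket code for substrate {aa!r}")
        ex = refs.by_class("A")
        out.append(("A", _domain_seq("A", refs, dict(zip(ex.anchor_columns, refs.a_codes[aa])))))
        out.append(("PCP", _domain_seq("PCP", refs, {})))
    else:
        raise SpecError(f"unknown module kind {kind!r}")
    return out


def make_cluster(spec: ClusterSpec, references: ExemplarSet | None = None) -> TruthBundle:
    """Build the multi-ORF protein FASTA of a synthetic cluster.

    Domain copies of the packaged exemplars (with planted anchor residues)
    are joined by random 20-60 aa linkers; ORF breaks from the spec are
    honoured, so a module can be split across two consecutive ORFs.
    Tailoring ORFs (monooxygenase / P450 exemplar copies) are appended,
    alternating strands.  Byte-identical for the same (spec, seed).
    """
    refs = references or load_references()
    rng = np.random.default_rng(spec.seed)

    domain_stream: list[tuple[int, int, str, str]] = []  # module, offset, class, seq
    for mi, mod in enumerate(spec.modules):
        for di, (cls, seq) in enumerate(_module_domains(mod, refs)):
            domain_stream.append((mi, di, cls, seq))
    if spec.terminal_te:
        domain_stream.append((len(spec.modules) - 1, 99, "TE", _domain_seq("TE", refs, {})))

    breaks = set(spec.orf_breaks)
    orf_seqs: list[list[str]] = [[]]
    for mi, di, cls, seq in domain_stream:
        if (mi, di) in breaks and orf_seqs[-1]:
            orf_seqs.append([])
        if not orf_seqs[-1]:
            orf_seqs[-1].append(_linker(rng))
        orf_seqs[-1].append(seq)
        orf_seqs[-1].append(_linker(rng))

    records: list[SeqRecordLite] = []
    order = 0
    for parts in orf_seqs:
        rid = f"orf{order:02d}"
        records.append(SeqRecordLite(
            id=rid, description=f"{rid} order={order} strand=+ role=catalytic",
            seq="".join(parts), alphabet="aa",
        ))
        order += 1
    strands = ["+", "-"]
    t_idx = 0
    for cls in ("MONOOX", "P450"):
        for _ in range(int(spec.tailoring.get(cls, 0))):
            rid = f"orf{order:02d}"
            seq = _linker(rng) + _domain_seq(cls, refs, {}) + _linker(rng)
            strand = strands[t_idx % 2]
            t_idx += 1
            records.append(SeqRecordLite(
                id=rid, description=f"{rid} order={order} strand={strand} role=tailoring",
                seq=seq, alphabet="aa",
            ))
            order += 1

    truth = spec.truth()
    truth["orfs"] = [r.id for r in records]
    truth["n_catalytic_orfs"] = len(orf_seqs)
    return TruthBundle(records=records, truth=truth, seed=spec.seed)


def random_cluster_spec(
    seed: int,
    min_modules: int = 3,
    max_modules: int = 16,
    allow_nrps: bool = True,
) -> ClusterSpec:
    """A random legal cluster blueprint (loading + extensions [+ NRPS])."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(min_modules, max_modules + 1))
    modules: list[dict] = [{
        "kind": "pks_loading",
        "extender": str(rng.choice(["C2_malonyl", "C3_methylmalonyl"])),
    }]
    with_nrps = allow_nrps and bool(rng.random() < 0.5)
    n_ext = n - 1 - int(with_nrps)
    for _ in range(max(1, n_ext)):
        state = str(rng.choice(["ketone", "hydroxyl", "double_bond", "saturated"]))
        mod = {
            "kind": "pks_extension",
            "extender": str(rng.choice(["C2_malonyl", "C3_methylmalonyl"])),
            "reduction_state": state,
        }
        if "KR" in STATE_DOMAINS[state]:
            mod["kr_type"] = str(rng.choice(["A_type", "B_type"]))
        if "ER" in STATE_DOMAINS[state]:
            mod["er_config"] = str(rng.choice(["S_config", "R_config"]))
        modules.append(mod)
    if with_nrps:
        modules.append({"kind": "nrps", "extender": "amino_acid:glycine"})

    # random ORF layout: break before ~ every third module, one optional split
    orf_breaks: list[tuple[int, int]] = []
    for mi in range(1, len(modules)):
        if rng.random() < 0.35:
            orf_breaks.append((mi, 0))
    split_candidates = [
        mi for mi, m in enumerate(modules)
        if m["kind"] == "pks_extension" and (mi, 0) not in orf_breaks and mi > 0
    ]
    if split_candidates and rng.random() < 0.5:
        mi = int(rng.choice(split_candidates))
        orf_breaks.append((mi, 2))  # split after KS+AT
        orf_breaks.sort()
    tailoring = {"MONOOX": int(rng.integers(0, 3)), "P450": int(rng.integers(0, 2))}
    return ClusterSpec(
        modules=modules, orf_breaks=orf_breaks, tailoring=tailoring, seed=seed
    )


# ---------------------------------------------------------------------------
# genome pairs for ANI

def make_genome_pair(
    length: int,
    divergence: float,
    rearrangements: int = 0,
    seed: int = 0,
    gc: float = 0.5,
) -> tuple[list[SeqRecordLite], list[SeqRecordLite], dict]:
    """A genome and a diverged copy with known expected ANI.

    The subject carries i.i.d. substitutions at rate ``divergence`` (each
    mutated base becomes one of the three other bases) and ``rearrangements``
    non-overlapping block swaps, which change order but not identity, so the
    expected ANI remains 100*(1 - divergence).
    """
    if not 0 <= divergence < 0.25:
        raise SpecError("divergence must be in [0, 0.25) for the ANI regime")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    query = rng.choice(NT4, size=length, p=p)
    subject = query.copy()
    mask = rng.random(length) < divergence
    n_mut = int(mask.sum())
    if n_mut:
        # shift by 1-3 positions in base order: always a different base
        base_idx = np.searchsorted(NT4, subject[mask])
        subject[mask] = NT4[(base_idx + rng.integers(1, 4, size=n_mut)) % 4]
    block = max(1000, length // 50)
    for k in range(rearrangements):
        a = int(rng.integers(0, max(1, length - 2 * block)))
        b = int(rng.integers(a + block, max(a + block + 1, length - block)))
        sa, sb = subject[a : a + block].copy(), subject[b : b + block].copy()
        subject[a : a + block], subject[b : b + block] = sb, sa
    q = [SeqRecordLite("query_genome", "query_genome", "".join(query), "nt")]
    s = [SeqRecordLite("subject_genome", "subject_genome", "".join(subject), "nt")]
    truth = {
        "length": length, "divergence": divergence,
        "expected_ani": 100.0 * (1.0 - divergence),
        "n_substitutions": n_mut, "rearrangements": rearrangements, "seed": seed,
    }
    return q, s, truth


# ---------------------------------------------------------------------------
# 16S-like alignments evolved on a known tree

def _dendropy_to_node(dnode) -> Node:
    node = Node(
        label=dnode.taxon.label if dnode.taxon else "",
        length=float(dnode.edge.length or 0.0),
    )
    for child in dnode.child_nodes():
        node.children.append(_dendropy_to_node(child))
    return node


def evolve_16s(
    tree_newick: str,
    sites: int,
    seed: int = 0,
    model: str = "jukes_cantor",
) -> tuple[MsaLite, Node, dict]:
    """Evolve a gapless alignment along a tree under Jukes-Cantor.

    The root sequence is uniform over ACGT; along each branch of length b
    (substitutions/site) every site changes with probability
    (3/4)(1 - exp(-4b/3)), uniformly to one of the other bases.  No indels:
    the alignment is positional.  Returns the alignment, the true topology
    and a truth dict.
    """
    if model != "jukes_cantor":
        raise SpecError(f"unsupported model {model!r}")
    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    for node in tree.preorder_node_iter():
        nch = len(node.child_nodes())
        if node is tree.seed_node:
            if nch not in (0, 2, 3):
                raise SpecError("root must have 2 or 3 children")
        elif nch not in (0, 2):
            raise SpecError("tree must be binary")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=sites)
    seqs: dict[str, np.ndarray] = {}

    def walk(dnode, seq: np.ndarray) -> None:
        for child in dnode.child_nodes():
            b = float(child.edge.length or 0.0)
            p_change = 0.75 * (1.0 - np.exp(-4.0 * b / 3.0))
            mask = rng.random(sites) < p_change
            out = seq.copy()
            n = int(mask.sum())
            if n:
                out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
            if child.is_leaf():
                seqs[child.taxon.label] = out
            else:
                walk(child, out)

    walk(tree.seed_node, root_seq)
    taxa = sorted(seqs)
    rows = ["".join(NT4[seqs[t]]) for t in taxa]
    msa = MsaLite(taxa=taxa, rows=rows)
    true_tree = _dendropy_to_node(tree.seed_node)
    truth = {"newick": tree_newick, "sites": sites, "seed": seed, "taxa": taxa}
    return msa, true_tree, truth
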