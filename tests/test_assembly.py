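import numpy as np
import pytest
from rdkit import Chem

import pksmine as pm
from pksmine.domains import AT_MALONYL, AT_METHYLMALONYL, DomainHit, SignatureCall
from pksmine.synth import STATE_DOMAINS


def _call(cls, call, order=0, pos=0, motif=""):
    hit = DomainHit("p%d" % order, cls, pos, pos + 50, 500.0, order)
    return SignatureCall(hit, motif, call, "exact" if call != "unknown" else "unknown")


def calls_from_spec(spec):
    """Signature-call stream a perfect detector would produce for a spec.

    Independent of the generator's sequence layer: built straight from the
    blueprint, with ORF indices advanced at the spec's break points.
    """
    breaks = set(spec.orf_breaks)
    calls, order, pos = [], 0, 0
    for mi, mod in enumerate(spec.modules):
        doms = []
        if mod["kind"] in ("pks_loading", "pks_extension"):
            doms.append(("KS", "KSQ_loading" if mod["kind"] == "pks_loading"
                         else "KS_extension"))
            at_call, _ = pm.classify_at(
                mod.get("at_motif") or (AT_METHYLMALONYL
                if mod["extender"] == "C3_methylmalonyl" else AT_MALONYL))
            doms.append(("AT", at_call))
            if mod["kind"] == "pks_extension":
                for cls in STATE_DOMAINS[mod.get("reduction_state", "ketone")]:
                    if cls == "KR":
                        doms.append(("KR", mod.get("kr_type", "unknown")))
                    elif cls == "ER":
                        doms.append(("ER", mod.get("er_config", "unknown")))
                    else:
                        doms.append((cls, "present"))
            doms.append(("ACP", "present"))
        else:
            doms.append(("C", "present"))
            doms.append(("A", mod["extender"].split(":", 1)[1]))
            doms.append(("PCP", "present"))
        for di, (cls, call) in enumerate(doms):
            if (mi, di) in breaks:
                order += 1
                pos = 0
            calls.append(_call(cls, call, order=order, pos=pos))
            pos += 100
    return calls


class TestPartition:
    def test_minimal_loading_plus_extension(self):
        calls = [_call("KS", "KSQ_loading", pos=0), _call("AT", "malonyl_CoA", pos=100),
                 _call("ACP", "present", pos=200), _call("KS", "KS_extension", pos=300),
                 _call("AT", "methylmalonyl_CoA", pos=400), _call("KR", "B_type", pos=500),
                 _call("ACP", "present", pos=600)]
        mods = pm.partition_modules(calls)
        assert [m.kind for m in mods] == ["pks_loading", "pks_extension"]
        assert mods[1].domain_classes() == ["KS", "AT", "KR", "ACP"]

    def test_at_without_ks_is_grammar_error(self):
        calls = [_call("AT", "malonyl_CoA", pos=0), _call("ACP", "present", pos=100)]
        with pytest.raises(pm.GrammarError, match="no\\s+preceding KS"):
            pm.partition_modules(calls)

    def test_er_without_dh_flagged_but_kept(self):
        calls = [_call("KS", "KS_extension", pos=0), _call("AT", "malonyl_CoA", pos=100),
                 _call("ER", "S_config", pos=200), _call("KR", "B_type", pos=300),
                 _call("ACP", "present", pos=400)]
        mods = pm.partition_modules(calls)
        assert "ER" in mods[0].domain_classes()
        assert any("ER without DH" in w for w in mods[0].warnings)

    def test_split_module_joins_across_two_orfs(self):
        calls = [_call("KS", "KS_extension", order=0, pos=0),
                 _call("AT", "malonyl_CoA", order=0, pos=100),
                 _call("KR", "B_type", order=1, pos=0),
                 _call("ACP", "present", order=1, pos=100)]
        mods = pm.partition_modules(calls)
        assert len(mods) == 1
        assert mods[0].source_orfs == ["p0", "p1"]

    def test_module_spanning_three_orfs_rejected(self):
        calls = [_call("KS", "KS_extension", order=0, pos=0),
                 _call("AT", "malonyl_CoA", order=1, pos=0),
                 _call("ACP", "present", order=2, pos=0)]
        with pytest.raises(pm.GrammarError, match="two ORFs"):
            pm.partition_modules(calls)

    def test_open_module_at_cluster_end_rejected(self):
        with pytest.raises(pm.GrammarError, match="open"):
            pm.partition_modules([_call("KS", "KS_extension", pos=0)])


class TestReductionState:
    @pytest.mark.parametrize("doms,state", [
        ([], "ketone"),
        (["KR"], "hydroxyl"),
        (["DH", "KR"], "double_bond"),
        (["DH", "ER", "KR"], "saturated"),
    ])
    def test_states(self, doms, state):
        calls = ([_call("KS", "KS_extension", pos=0), _call("AT", "malonyl_CoA", pos=100)]
                 + [_call(d, "present", pos=200 + 100 * i) for i, d in enumerate(doms)]
                 + [_call("ACP", "present", pos=900)])
        mods = pm.partition_modules(calls)
        assert pm.reduction_state(mods[0]) == state

    def test_odd_combination_is_ketone_with_warning(self):
        calls = [_call("KS", "KS_extension", pos=0), _call("AT", "malonyl_CoA", pos=100),
                 _call("DH", "present", pos=200), _call("ACP", "present", pos=300)]
        mods = pm.partition_modules(calls)
        assert pm.reduction_state(mods[0]) == "ketone"
        assert mods[0].warnings

    def test_loading_and_nrps_are_na(self):
        calls = [_call("KS", "KSQ_loading", pos=0), _call("AT", "malonyl_CoA", pos=100),
                 _call("ACP", "present", pos=200), _call("C", "present", pos=300),
                 _call("A", "glycine", pos=400), _call("PCP", "present", pos=500)]
        mods = pm.partition_modules(calls)
        assert [pm.reduction_state(m) for m in mods] == ["n/a", "n/a"]


class TestChain:
    def _line(self, calls):
        mods = pm.partition_modules(calls)
        pm.assign_extenders(mods)
        return pm.build_chain(pm.AssemblyLine(modules=mods))

    def test_loading_alone(self):
        line = self._line([_call("KS", "KSQ_loading", pos=0),
                           _call("AT", "malonyl_CoA", pos=100),
                           _call("ACP", "present", pos=200)])
        assert line.unit_string == "C2" and line.counts == {"C2": 1}

    def test_unknown_extender_marks_partial(self):
        line = self._line([_call("KS", "KSQ_loading", pos=0),
                           _call("AT", "malonyl_CoA", pos=100),
                           _call("ACP", "present", pos=200),
                           _call("KS", "KS_extension", pos=300),
                           _call("AT", "unknown", pos=400),
                           _call("ACP", "present", pos=500)])
        assert line.partial and line.unit_string == "C2-?"
        assert line.counts == {"C2": 1}
        with pytest.raises(ValueError, match="partial"):
            pm.chain_to_smiles(line)

    def test_acetoacetate_oracle(self):
        """Starter C2 + one unreduced C2 extension is acetoacetic acid."""
        line = self._line([_call("KS", "KSQ_loading", pos=0),
                           _call("AT", "malonyl_CoA", pos=100),
                           _call("ACP", "present", pos=200),
                           _call("KS", "KS_extension", pos=300),
                           _call("AT", "malonyl_CoA", pos=400),
                           _call("ACP", "present", pos=500)])
        assert pm.chain_to_smiles(line) == "CC(=O)CC(=O)O"

    def test_methyl_hydroxy_unit_oracle(self):
        """C3 extension with KR leaves 2-methyl-3-hydroxy, branch on the alpha carbon."""
        line = self._line([_call("KS", "KSQ_loading", pos=0),
                           _call("AT", "malonyl_CoA", pos=100),
                           _call("ACP", "present", pos=200),
                           _call("KS", "KS_extension", pos=300),
                           _call("AT", "methylmalonyl_CoA", pos=400),
                           _call("KR", "unknown", pos=500),
                           _call("ACP", "present", pos=600)])
        got = Chem.CanonSmiles(pm.chain_to_smiles(line))
        assert got == Chem.CanonSmiles("CC(O)C(C)C(=O)O")


def test_planted_truth_recovery_100_random_clusters():
    """Grammar + extender + state + chain reproduce generator truth exactly."""
    for seed in range(100):
        spec = pm.random_cluster_spec(seed)
        truth = spec.truth()
        mods = pm.partition_modules(calls_from_spec(spec))
        pm.assign_extenders(mods)
        line = pm.build_chain(pm.AssemblyLine(modules=mods))
        assert len(line.pks_modules()) == truth["n_pks_modules"]
        assert len(line.nrps_modules()) == truth["n_nrps_modules"]
        assert line.unit_string == truth["unit_string"]
        assert line.counts == truth["counts"]
        got = [(m.kind, m.extender, m.reduction_state) for m in line.modules]
        want = [(m["kind"], m["extender"], m["reduction_state"]) for m in truth["modules"]]
        assert got == want


def test_unit_count_conservation_property():
    """Tokens = PKS modules; counts sum to PKS + NRPS modules."""
    for seed in range(30):
        spec = pm.random_cluster_spec(seed + 1000)
        mods = pm.partition_modules(calls_from_spec(spec))
        pm.assign_extenders(mods)
        line = pm.build_chain(pm.AssemblyLine(modules=mods))
        assert len(line.unit_string.split("-")) == len(line.pks_modules())
        assert sum(line.counts.values()) == len(line.modules)


def test_smiles_heavy_atom_accounting():
    """Heavy atoms of the precursor match the per-unit closed form."""
    n_checked = 0
    for seed in range(40):
        spec = pm.random_cluster_spec(seed + 2000)
        mods = pm.partition_modules(calls_from_spec(spec))
        pm.assign_extenders(mods)
        line = pm.build_chain(pm.AssemblyLine(modules=mods))
        if line.partial:
            continue
        mol = Chem.MolFromSmiles(pm.chain_to_smiles(line))
        assert mol is not None
        units = line.unit_string.split("-")
        has_gly = bool(line.nrps_modules())
        states = [m.reduction_state for m in line.modules if m.kind == "pks_extension"]
        want_c = sum(2 if u == "C2" else 3 for u in units) + (2 if has_gly else 0)
        want_o = (1 if has_gly else 0) + 2 + states.count("ketone") + states.count("hydroxyl")
        want_n = 1 if has_gly else 0
        counts = {}
        for a in mol.GetAtoms():
            counts[a.GetSymbol()] = counts.get(a.GetSymbol(), 0) + 1
        assert counts.get("C", 0) == want_c
        assert counts.get("O", 0) == want_o
        assert counts.get("N", 0) == want_n
        n_checked += 1
    assert n_checked >= 20


class TestTailoringInventory:
    def test_counts_and_strands(self):
        hits = {
            "t1": [DomainHit("t1", "MONOOX", 0, 100, 500.0, 5, "+")],
            "t2": [DomainHit("t2", "MONOOX", 0, 100, 500.0, 6, "-")],
            "t3": [DomainHit("t3", "P450", 0, 100, 500.0, 7, "-")],
            "cat": [DomainHit("cat", "KS", 0, 100, 500.0, 0, "+")],
        }
        inv = pm.inventory_tailoring(hits)
        assert len(inv) == 3
        assert {e["strand"] for e in inv} == {"+", "-"}
        assert {e["deduced_function"] for e in inv} == {"monooxygenase", "cytochrome P450"}

    def test_empty(self):
        assert pm.inventory_tailoring({"x": []}) == []


class TestCanonicalCluster:
    """The worked example: the canonical hybrid cluster mined end to end."""

    def test_module_census(self, canonical_line):
        assert len(canonical_line.pks_modules()) == 14
        assert len(canonical_line.nrps_modules()) == 1

    def test_unit_string_and_counts(self, canonical_line):
        assert canonical_line.unit_string == \
            "C2-C3-C2-C2-C3-C2-C2-C3-C2-C2-C3-C3-C2-C2"
        assert canonical_line.counts == {"C2": 9, "C3": 5, "glycine": 1}

    def test_reduction_census(self, canonical_line):
        states = [m.reduction_state for m in canonical_line.modules
                  if m.kind == "pks_extension"]
        assert states.count("hydroxyl") == 3
        assert states.count("double_bond") == 5
        assert states.count("saturated") == 4

    def test_nrps_substrate_is_glycine(self, canonical_line):
        assert canonical_line.nrps_modules()[0].extender == "amino_acid:glycine"

    def test_split_module_spans_two_orfs(self, canonical_line):
        spans = [m for m in canonical_line.modules if len(m.source_orfs) == 2]
        assert len(spans) == 1

    def test_tailoring_inventory(self, canonical_line):
        funcs = [e["deduced_function"] for e in canonical_line.tailoring_genes]
        assert funcs.count("monooxygenase") == 3
        assert funcs.count("cytochrome P450") == 1

    def test_precursor_parses(self, canonical_line):
        assert Chem.MolFromSmiles(canonical_line.precursor_smiles) is not None
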