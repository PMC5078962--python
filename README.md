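# pksmine

Genome-mining and taxonomy toolkit for hybrid PKS/NRPS natural-product
clusters, built around the inference chain used to characterize
polyketide assembly lines in *Streptomyces*: locate catalytic domains on
cluster proteins, read their active-site signatures, reconstruct the
modular assembly line, and predict the linear polyketide precursor —
together with the genome-level computations used to place the producing
strain taxonomically (fragment-based ANI species assignment and 16S
neighbor-joining phylogeny with bootstrap supports).

It is aimed at natural-product bioinformaticians who want each step of
that chain as an inspectable, testable function rather than a web-service
black box. Every input class can be generated synthetically with planted
ground truth (`pksmine.synth`), so the full pipeline is verifiable offline.

## The science in brief

**Assembly-line logic.** A modular type I PKS elongates a polyketide chain
one ketide unit per module. Each extension module minimally carries
ketosynthase (KS), acyltransferase (AT) and acyl carrier protein (ACP)
domains; a loading module is recognized by the KSQ variant, in which the
KS active-site Cys is replaced by Gln (decarboxylative starter loading).
The AT's five signature residues select the extender: `YASHS` →
methylmalonyl-CoA (a C3 unit with a methyl branch), `HAFHS` →
malonyl-CoA (C2); one-mismatch variants such as `RAFHS` are called by a
nearest-motif rule. Optional β-processing domains set the oxidation state
of each unit — none → ketone, KR → hydroxyl, DH+KR → double bond,
DH+ER+KR → saturated — and KR/ER fingerprints predict the hydroxyl/methyl
stereochemistry. An NRPS module ((C)–A–PCP) contributes an amino acid
selected by its A-domain binding-pocket code. Reading the modules in gene
order (collinearity) yields the unit string, e.g.

```
C2-C3-C2-C2-C3-C2-C2-C3-C2-C2-C3-C3-C2-C2
```

for the canonical 14-PKS-module + 1-NRPS-module hybrid cluster shipped
with the package (5× methylmalonyl-CoA, 9× malonyl-CoA, 1× glycine), and
from it a SMILES of the linear precursor.

**Taxonomy.** ANIb fragments the query genome into 1,020 bp windows,
aligns each to the subject, retains hits at ≥30% identity and ≥70%
coverage, and averages identities; two genomes at or above the 95–96%
threshold (the genomic equivalent of 70% DNA–DNA relatedness) are
conspecific. The 16S workflow aligns sequences, removes all gap-containing
columns, computes Jukes–Cantor distances, joins neighbors (Saitou–Nei),
and attaches bootstrap supports from 1,000 column-resampled replicates,
showing only values above 50%.

## Worked example

```python
import pksmine as pm

refs = pm.load_references()                     # packaged exemplar bundle
spec = pm.load_canonical_spec()                 # canonical hybrid cluster
cluster = pm.make_cluster(spec, refs).records   # 11 ORFs, planted truth
line = pm.mine_cluster(cluster, refs)

print(len(line.pks_modules()), len(line.nrps_modules()))
print(line.unit_string)
print(line.counts)
print(line.precursor_smiles)
```

prints

```
14 1
C2-C3-C2-C2-C3-C2-C2-C3-C2-C2-C3-C3-C2-C2
{'C2': 9, 'C3': 5, 'glycine': 1}
C/C=C(C)/[C@@H](O)CCC/C=C(C)/CC/C=C/[C@H](O)C(C)CC/C=C/C(=O)C(C)[C@@H](O)C(C)/C=C/CCC(=O)NCC(=O)O
```

i.e. a C2 starter, thirteen extension units (five C3), a terminal glycine
amide, and per-unit oxidation states written into the SMILES (3 hydroxyls,
5 trans double bonds, 4 saturated positions, 1 ketone). The same run via
the CLI: `pksmine mine-cluster cluster.fasta` /
`pksmine predict-precursor cluster.fasta`; see also `pksmine anib`,
`pksmine tree16s` and `pksmine synth`.

The numbered drivers under `analysis/` run the four studies end to end
(cluster mining, ORF-by-ORF homolog comparison with synteny, ANI on
genomes with planted divergence, 16S phylogeny with 1,000 bootstraps) and
write their tables under `results/`.

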