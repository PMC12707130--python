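# amine-profiler

Structure-mining toolkit for **dual-donating exocyclic amines** in
RNA-containing 3D structures.

RNA is acceptor-rich: the four canonical ribonucleotides carry 62 acceptor
lone pairs against only 12 polar hydrogens, and the exocyclic amine of A, C
and G is the *only* functional group able to donate two H-bonds. This
package finds those amines in experimental structures (mmCIF/PDB), places
idealized sp2 hydrogens on them, calls H-bonds geometrically, and classifies
every amine as

* **non** — no H-bond donated,
* **single** — one hydrogen engaged (including bi/trifurcated bonds on a
  single H, which do not use the amine's second valence), or
* **dual** — both hydrogens donate to at least two distinct acceptor atoms.

Around that core it tabulates acceptor pairs (with backbone atoms
generalized to `N(...)`/`AA(O)` and OP1/OP2 merged to `NPO`), measures
burial (Shrake–Rupley SASA of the amine N; heavy-atom densities within
7.5 Å and in the 7.5–12.5 Å shell), measures conformation (glycosidic χ and
the η/θ backbone pseudotorsions with A-form and "Location" boxes), and
clusters 6×5-nt coarse-grained fragments by superposition RMSD to surface
recurrent motifs such as the S-motif.

## H-bond model

An acceptor within 4.1 Å of the amine nitrogen is measured against both
hydrogens; a bond passes when

```
d(H···acceptor) ≤ 2.5 Å   and   ∠(N–H···acceptor) ≥ 140°
```

Hydrogens are placed in the base plane at N–H = 1.01 Å, H–N–H = 120°. All
thresholds live in one `SurveyConfig` and are embedded (as a hash) in every
output.

## Worked example

Everything below runs offline — the `amine_profiler.fixtures` module
generates idealized structures (duplexes, noncanonical pairs, geometry
probes) rather than downloading them.

```python
from amine_profiler import pipeline
from amine_profiler.fixtures import make_helix, make_pair

result = pipeline.run_survey([
    (make_helix("GGCGCC"), None),          # 6-bp Watson-Crick duplex
    (make_pair("sheared_ga"), None),       # A(N6) dual donor
    (make_pair("trans_aa_hoogsteen"), None),
])
print(result.summary.per_base)
print(pipeline.rank_acceptor_pairs(result.records, base="A"))
```

prints

```
   non  single  dual
A    0       1     2
C    0       6     0
G    1       6     0
           pair  count same_residue_fraction
0  A(N7)/N(NPO)      1                   1.0
1  G(N3)/N(O2')      1                   1.0
```

(the table above shows counts for this 3-structure toy set): the 12 helix
amines are all single-donating (canonical pairing), the sheared-GA adenine
dual-donates to the N3 and O2' of one guanine — the signature of that pair —
and the *trans* AA adenine dual-donates to the Hoogsteen-edge N7 plus a
nonbridging phosphoryl oxygen.

The same survey is available from the shell:

```bash
amine-profiler fixtures --kind helix --sequence GGCGCC --out-dir fx
amine-profiler survey --inputs fx/helix_GGCGCC.cif --out-dir out
amine-profiler stats --records out/records.csv --metric sasa
```

To run on real data, point `amine-profiler survey --rep-set nrlist.csv
--local-dir structures/` at a representative-set CSV (IFE tokens of the
form `PDBID|model|chain`, chains joined by `+`) and a directory of
downloaded mmCIF files (`amine-profiler fetch` retrieves them when network
access is available).

## Chemistry tables

Donor/acceptor definitions ship as a versioned, human-readable YAML file
(`src/amine_profiler/data/chemistry.yaml`): per residue, the amine atom
names and placement anchors, donor hydrogens, and acceptor atoms with
lone-pair counts (two per oxygen, one per unprotonated ring nitrogen; the
amine nitrogen itself never accepts — its lone pair is delocalized into the
ring).

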