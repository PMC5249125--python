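# barcodeaudit

Tools for auditing DNA barcode reference libraries — the curation step
between "we sequenced COI from hundreds of field-identified specimens" and
"this library can be trusted to identify new specimens".

Field identification of morphologically conservative groups (the package
was designed around Mediterranean sharks, skates and rays, where juveniles
of congeneric species are routinely confused) produces reference libraries
whose species labels are partly wrong. `barcodeaudit` takes an aligned
~650 bp COI alignment plus a specimen table (species label, FAO fishing
division, optional voucher) and runs the standard battery of library
diagnostics:

* **QC** — reading-frame detection and stop-codon screening under the
  vertebrate mitochondrial code (stop codons in a COI barcode indicate
  NUMTs or sequencing artefacts), plus nucleotide-composition summaries.
* **Distances** — pairwise *p*-distances with pairwise deletion (a site
  contributes only where both sequences have an unambiguous A/C/G/T);
  per-species mean/maximum intraspecific distance and distance to the
  nearest heterospecific neighbour (NN). A species has a **barcoding
  gap** when max intra < NN, i.e. its point lies above the 1:1 line in
  the gap scatter.
* **Trees and OTUs** — neighbour joining (Saitou–Nei) on the *p*-distance
  matrix with non-parametric bootstrap over alignment columns;
  unrooted-monophyly ("cohesion") assessment per species; BIN-style OTU
  delimitation by refined single linkage (single-linkage components at
  2.2%, wide clusters re-partitioned by complete linkage).
* **The audit proper** — misidentification calls (a specimen whose OTU
  majority label disagrees with its field label *and* which is closer to
  the majority species than to its own), relabelling, post-review OTU
  concordance (interim "Genus sp." names folded into the congeneric
  binomial; one-or-two-record minorities treated as suspected
  misidentifications), A–E taxonomic-reliability grades, and splitting of
  deeply structured species into provisional taxa ("Species 1/2") that are
  graded separately.
* **Haplotype networks** — per-species haplotype collapsing (complete
  deletion of ambiguous columns), exact branch-and-bound maximum parsimony
  (≤ 10 haplotypes; NNI hill climbing above), conversion of the Fitch-
  annotated tree into a mutation-weighted network with frequency-0 median
  nodes, and detection of division-private haplotypes.

A synthetic-library simulator (`barcodeaudit.simulate`) generates
libraries with the statistical structure these analyses assume — species
clusters around 8% divergence, intraspecific variation around 0.3%,
sibling pairs below the OTU threshold, division-private lineages — and
injects label swaps, interim names and stop codons while recording every
artefact in a truth table, so the entire pipeline is testable offline.

## Worked example

```python
from barcodeaudit import AuditRunConfig, run_audit, summary_table, summarise_grades
from barcodeaudit.simulate import table1_scenario

library, truth = table1_scenario(seed=11)   # 246 specimens, 45 injected label swaps
report = run_audit(library, AuditRunConfig(bootstrap_reps=200, seed=1))

print(report.misid_table.to_string(index=False))
print(f"{len(report.misid_calls)} calls = {report.misid_percent:.2f}% "
      f"of {report.qc.n_passed} barcoded")
print(summary_table(report.summaries).to_string(index=False))
print(summarise_grades(report.grades).to_string(index=False))
```

prints

```
       barcode_label       morph_label division  n_misid  n_total
Mustelus punctulatus Mustelus mustelus   37.2.1       45      146
45 calls = 18.29% of 246 barcoded
              species mean_intra max_intra            nn_species nn_distance
    Mustelus mustelus       0.23      1.54 Scyliorhinus canicula        8.14
 Mustelus punctulatus       0.26      1.08 Scyliorhinus canicula        6.61
         Raja clavata       0.25      0.61  Mustelus punctulatus        6.91
Scyliorhinus canicula       0.23      0.77  Mustelus punctulatus        6.61
              Average       0.24      1.00                              7.07
grade  count  percent
    B      4    100.0
```

Reading this: the audit recovered all 45 smooth-hound specimens that the
scenario had mislabelled *Mustelus mustelus* in the Adriatic division
(45 of the 146 individuals carrying that field label there), with zero
false calls on the clean species. After relabelling, every species shows
the expected pattern — intraspecific distances well below 1% against
nearest-neighbour distances of 6–8% (a clear barcoding gap) — and all
four species earn grade B (internal concordance; grade A is unreachable
without an external reference-match table, which can be supplied via
`read_reference_table`).

The same pipeline is available from the shell:

```sh
audit simulate --config cfg.json --out sim/
audit qc   --fasta sim/library.fasta --meta sim/library.tsv --out qc/
audit full --fasta sim/library.fasta --meta sim/library.tsv \
           --seed 1 --bootstrap 1000 --out audit/
audit haplonet --fasta sim/library.fasta --meta sim/library.tsv \
               --species "Genus1 species1" --out net/
```

`audit full` writes TSV/JSON report tables (misidentifications by
division, the barcoding-gap table with its Average row, OTU discordance
before/after review, grades with rule traces), the bootstrap-annotated
tree in Newick, and per-species haplotype networks as edge/node TSVs and
GraphML.

## Layout

| module | contents |
| --- | --- |
| `barcodeaudit.io` | FASTA/TSV reading and writing, alignment validation, stop-codon QC, composition |
| `barcodeaudit.distance` | *p*-distance matrix, species summaries, gap scatter |
| `barcodeaudit.cluster` | neighbour joining, bootstrap, cohesion, refined single-linkage OTUs |
| `barcodeaudit.audit` | misidentification calls, OTU review, A–E grades, sub-cluster splits |
| `barcodeaudit.haplonet` | haplotype collapsing, parsimony trees, networks, private haplotypes |
| `barcodeaudit.simulate` | synthetic libraries with truth tables; canned scenarios |
| `barcodeaudit.report` | pipeline orchestration and publication-shaped tables |
| `barcodeaudit.cli` | the `audit` command |

See `docs/methods.md` for the models, parameter choices and known
limitations.
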