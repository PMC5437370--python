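# barcodeval

Chloroplast marker discovery and multi-method DNA-barcoding evaluation for
closely related plant species, built around the study design used for
Chinese oaks (*Quercus* subg. *Quercus*): compare two plastomes to find
variable regions and design universal primers, screen markers by
nucleotide diversity, then measure how well candidate barcodes and all of
their combinations discriminate species under four different analytical
frameworks.

## Who this is for

Researchers evaluating DNA barcodes in taxonomically difficult plant
groups — recently diverged species, hybridization, incomplete lineage
sorting — where no single marker separates species cleanly and the choice
of analytical method changes the answer.

## What it computes

**Genome comparison.** A circular plastome is partitioned into its
quadripartite structure (LSC / IRa / SSC / IRb) by locating the maximal
pair of reverse-complement segments; two genomes' single-copy regions are
compared through an anchor chain of unique shared k-mers with per-segment
global alignment, yielding SNP and gap-event counts; dispersed repeats of
8–50 bp are enumerated exactly. Conserved windows flanking variable
columns become primer candidates under standard constraints (18–24 nt,
Tm 50–65 °C, product 400–1,100 bp).

**Marker screening.** Per-species nucleotide diversity
π = mean pairwise p-distance among conspecifics (pairwise deletion),
screened at π > 0.0005 with amplification success as an observed input;
indel-bearing regions are scored with the multiallelic
deletion–insertion polymorphism diversity
*h* = n/(n−1) · (1 − Σ pᵢ²).

**Four barcoding methods** over every non-empty combination of markers:

1. *Distance*: ranked p-distance barcode-gap assessment, and a
   deterministic barcode-gap-discovery partition (widest-gap threshold
   above a prior maximum intraspecific divergence, single-linkage
   clustering, recursive refinement). A species is delimited when its
   individuals form exactly one pure group. Welch *t* and Wilcoxon
   rank-sum tests compare intra- vs interspecific divergences.
2. *Similarity*: leave-self-out top-hit classification by identity
   fraction; a species is identified when every individual's best hit is
   exclusively conspecific.
3. *Character*: per-species logic formulas (DNF over position=state
   literals) induced from diagnostic positions or by asymmetric-cost
   greedy search; an individual must satisfy its own species' formula and
   no other.
4. *Tree*: neighbor joining (Q-criterion, deterministic tie-breaks,
   negative branches clamped with sister compensation), column-bootstrap
   supports, and per-species monophyly scoring.

A seeded synthetic-data generator produces multi-species, multi-marker
datasets with controlled intra/interspecific divergence, planted
diagnostic columns, species-specific indels, plastid haplotype capture
(hybridization/ILS), and IUPAC heterozygous sites — with a ground-truth
record, so every stage is testable without downloads.

## Worked example

```sh
barcodeval simulate --preset clean --seed 3 --out data/
barcodeval evaluate --markers data/pm1.fasta --markers data/nm1.fasta \
    --map data/species_map.tsv --out report.tsv
head -4 report.tsv
```

```
method  markers n_identified  n_eligible  rate      identified_species                                 status
character  nm1      10          10        100.000000  sp01;sp02;sp03;sp04;sp05;sp06;sp07;sp08;sp09;sp10  ok
character  pm1      10          10        100.000000  sp01;sp02;sp03;sp04;sp05;sp06;sp07;sp08;sp09;sp10  ok
character  nm1+pm1  10          10        100.000000  sp01;sp02;sp03;sp04;sp05;sp06;sp07;sp08;sp09;sp10  ok
```

Each row is one method × marker-combination cell: the clean preset plants
a diagnostic column per species and keeps intraspecific divergence
(0.003/site) far below interspecific divergence (0.05/site), so every
species is identified by every method. Swap `--preset hybrid` (30% of
plastid haplotypes captured from another species) and the distance- and
tree-based rates collapse while the character-based method, anchored by
nuclear diagnostics, stays high — the method ordering seen in real oaks.

In Python:

```python
from barcodeval import simulate_dataset, preset_config, evaluate_all

alignments, species_map, truth = simulate_dataset(preset_config("hybrid", seed=17))
report = evaluate_all(alignments, species_map)
print({r.method: r.rate for r in report.rows
       if set(r.marker_set) == set(alignments)})
# {'distance': 0.0, 'similarity': 40.0, 'character': 100.0, 'tree': 40.0}
```

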