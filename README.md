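# cescore

Coevolution-based impact scoring for protein sequence variants.

Conservation-based predictors (SIFT-style scores, column-entropy
conservation) miss deleterious variants at poorly conserved sites —
allosteric residues, interaction interfaces, specificity-determining
positions — because compensatory substitutions keep such columns variable
across homologs. `cescore` targets exactly those sites by scoring variants
from the *evolutionary coupling structure* of a multiple sequence alignment
(MSA) instead of single-column conservation alone.

## The score

For a query protein of length *L* with an MSA of homologs:

1. **Covariation.** Every retained column pair gets a McLachlan-based
   substitution correlation (McBASC): for each pair of sequences (k, l) the
   McLachlan similarity of their residues is recorded per column, and the
   covariation of columns *i*, *j* is the Pearson correlation of those two
   similarity vectors over all sequence pairs.
2. **Couplings.** The top **2L** pairs by covariation are the protein's
   evolutionary couplings; C<sub>i</sub> is the set of partners coupled to
   residue *i*.
3. **CN (coupling number).** The per-residue count of selected couplings,
   percentile-rank normalized within the protein to [0, 1]
   (CN = (rank − 1)/(L − 1), average ranks for ties): 1 marks the most
   coupled residue.
4. **CC (cost of coupling).** For a variant α→γ at residue *i*, with β the
   wild-type residue at partner *j* and n<sub>i,j</sub>(·,·) the pair
   counts in columns *i*, *j*:

   ΔS<sub>i,j</sub>(α→γ) = −ln[(n<sub>i,j</sub>(γ,β) + 1) / n<sub>i,j</sub>(α,β)],  CC<sub>i</sub> = Σ<sub>j∈C<sub>i</sub></sub> ΔS<sub>i,j</sub> / |C<sub>i</sub>|

   High CC means the variant creates amino-acid pairings that are rare
   among homologs — an evolutionarily intolerant change.
5. **CE = CN × CC** — the combined impact score.

A single-column analog, **CS** = −ln[(n<sub>i</sub>(γ)+1)/n<sub>i</sub>(α)],
is provided as the conservation-only baseline, and an evaluation stack
covers ROC/AUC, accuracy-maximizing thresholds, the union rule for
integrating CE with a conservation score (predict intolerant when *either*
score reaches its threshold), and 100× Monte-Carlo 90/10 cross-validation.

MSA hygiene follows standard practice for covariation analysis: columns
with >20% gaps or a completely conserved residue are excluded from coupling
computation; homolog sets should keep sequences with <90% identity to the
query and 0.7–1.3× its length, and proteins with fewer than 10 homologs are
flagged as unsuitable.

## Worked example

Simulate a 50-residue, 200-sequence alignment with three planted
compensatory column pairs, then score one variant at a planted coupled
site (position 2) and two at independent background columns:

```sh
ce-score simulate --L 50 --N 200 --pairs 3 --seed 7 \
    --out sim.fasta --truth truth.json
ce-score compute --msa sim.fasta --variants vars.txt --out scores.tsv --with-cs
```

with `vars.txt` containing `S2W`, `C27W`, `L20W`. The output:

```
# ce-score v1.0.0 | cmd=compute msa=sim.fasta variants=vars.txt query=query multiplier=2.0 max_gap_frac=0.2 min_seq_pairs=10
protein_id  variant  position  wt  alt  coupling_count  n_partners  CN      CC      CE      CS
query       S2W      2         S   W    5               5           0.7449  3.7417  2.7872  4.5643
query       C27W     27        C   W    5               5           0.7449  2.7274  2.0316  3.8286
query       L20W     20        L   W    3               3           0.3571  2.8296  1.0106  3.8286
```

(CN/CC/CE/CS shown here to 4 decimals; the file carries full precision.)
The variant at the planted coupled site (S2W) breaks a compensatory pairing
and gets the highest CE (2.79): it is both at a highly coupled residue
(CN 0.74) and creates partner pairings never seen in the homologs
(CC 3.74). L20W sits at an ordinary background column — its CE is a third
of that despite a nearly identical CS, which is the point of the method:
CS alone cannot tell those sites apart. `ce-score evaluate` then fits
thresholds on training splits and reports cross-validated
sensitivity/precision/accuracy/balanced accuracy/MCC/F1 (and AUC) for a
single score or the CE+CS union rule.

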