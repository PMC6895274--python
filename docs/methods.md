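# Methods

## Model

`cescore` scores a single amino-acid substitution α→γ at residue *i* of a
query protein by combining two quantities derived from a query-anchored
MSA of its homologs.

**Covariation (McBASC).** For columns *i* and *j*, every unordered pair of
sequences (k, l) contributes one observation per column: the McLachlan
similarity of the two residues that pair shows there. The covariation of
(i, j) is the plain Pearson correlation of the two observation vectors.
The McLachlan table is the published 20×20 integer similarity matrix
(diagonals 8–9), loaded from Biopython's canonical copy
(`substitution_matrices.load("MCLACHLAN")`) and cross-checked in the test
suite against frozen entries of the original publication. This classic
substitution-correlation formulation uses no sequence weighting, no
average-product correction and no redundancy downweighting; it measures
raw covariation, which is what the coupling-number statistic is defined
over.

**Coupling selection.** The `budget = round(multiplier × L)` highest
covariation pairs are the protein's couplings; `multiplier` defaults to 2
(the systematically examined 2L cutoff for this family of analyses). Ties
at the cutoff break by (score desc, i asc, j asc) so outputs are
reproducible. Selection is monotone in the budget.

**CN.** coupling_count(i) = number of selected pairs touching *i*;
CN(i) = (average rank − 1)/(L − 1) with ranks ascending in count and
average ranks for ties. All L residues participate, including masked ones
(count 0), so CN endpoints are 1 (untied most-coupled) and 0 (untied
least-coupled) and a fully tied protein scores 0.5 everywhere.

**CC.** With β the query residue at partner *j* and n(·,·) the pair counts
over rows that are gap-free at both columns,
ΔS(α→γ) = −ln[(n(γ,β)+1)/n(α,β)] and CC is the mean of ΔS over all
partners in C_i. The +1 regularizes unseen variant pairings; the query row
itself always contributes, so the denominator n(α,β) ≥ 1 whenever the
declared wild type matches the query (a mismatch is reported as a
per-variant error). ΔS equals the difference of log-multinomial entropies
S = ln(N!/Π n!) between the table after moving one count from (α,β) to
(γ,β) and the table before — the test suite verifies this identity to
1e-9 against a log-gamma evaluation on random tables.

**CE = CN × CC** exactly, on every output row. **CS**, the conservation
baseline, is the single-column specialization of ΔS; its exact published
form is not fully specified in the literature this analog follows, so the
specialization is a documented package choice.

## Filtering and degenerate inputs

- Columns with gap fraction strictly > `max_gap_frac` (default 0.2) or
  with all non-gap residues identical are excluded from covariation.
  Variants at such columns are still scored (flagged `masked_site`): their
  coupling count is 0, they participate in the CN ranking, and CC/CE
  follow from whatever partners they have (none ⇒ CC = CE = 0, flagged
  `no_partners`). This keeps every variant scoreable while masked columns
  cannot poison coupling selection.
- A sequence pair contributes to covariation of (i, j) only if all four
  residues are non-gap; a column pair with fewer than `min_seq_pairs`
  (default 10) usable sequence pairs, or a zero-variance similarity
  vector, scores 0 rather than NaN.
- Homolog filtering keeps sequences with identity to the query strictly
  < 0.90 and length in [0.7, 1.3]× the query (inclusive); identity is
  matches / length-of-shorter under a simple global alignment
  (match 1 / mismatch −1 / gap open −2, extend −0.5) — a reproducible
  definition that needs no external search tool. Fewer than 10 survivors
  flags the protein as unsuitable instead of silently passing.
- A2M/Stockholm dialects: `.` and (in A2M) lowercase are insert states,
  treated as gap-equivalent; columns where the query is gapped are
  excluded from the coordinate map at read time, so L, the 2L budget and
  all variant positions refer to the query protein.

## Evaluation protocol

Intolerant (positive) = activity strictly below 50% of wild type.
Prediction at a threshold t is score ≥ t (configurable to strict >).
Metrics are the standard confusion-derived set; MCC and precision return 0
on 0/0 denominators. ROC uses the standard TPR = TP/(TP+FN),
FPR = FP/(FP+TN); AUC is computed by scikit-learn and equals the
Mann–Whitney concordance probability with ties counted ½ (asserted against
a brute-force pair count in the tests). `best_threshold` scans all
observed scores plus one point above the maximum and returns the smallest
accuracy-maximizing threshold. The union rule predicts intolerant when
either score reaches its own threshold. Monte-Carlo cross-validation
draws seeded random 90/10 splits (default 100 repeats), fits thresholds on
the training split only, and reports mean ± standard error
(sample SD/√repeats); a split missing a class in either half is redrawn
from the same seeded stream. The union rule has no continuous score, so
its per-repeat AUC is computed from the binary prediction and equals that
rule's balanced accuracy.

## Synthetic data

The generator emulates the one property the method depends on —
compensatory covariation — not real protein families. Planted pairs draw a
joint compatible state (e.g. A–K / S–E) with probability *w* per sequence
and independent residues from the two marginal alphabets otherwise;
conserved columns draw a dominant residue at a stated frequency (default
0.95); background columns are uniform over a per-column 4-letter
sub-alphabet, which keeps pair-count tables dense at desk-scale N; gaps
are sprinkled per column at `gap_rate` (≤ 0.5), never in the query row.
Defaults used throughout the tests: L = 50, N = 200 sequences (the scale
of a typical homolog search yielding ~180 usable sequences), w = 0.9,
gap_rate = 0.05. What passing tests show: the pipeline recovers planted
couplings and ranks pairing-breaking variants above background variants
under these conditions. What they do not show: performance on real MSAs
with phylogenetic correlation, sequence redundancy, and alignment error —
none of which the generator models.

The labeled-variant generator produces balanced classes with one Gaussian
informative score (positive mean shifted by `effect_size`, SD `noise_sd`)
and one pure-noise score; its expected AUC has the closed form
Φ(effect_size/(noise_sd·√2)), which the tests verify empirically at
n = 2000 within ±0.03.

## Numerical choices

- Natural logarithms throughout.
- The vectorized covariation matrix computes masked Pearson statistics via
  matrix products over per-column similarity vectors; it is asserted equal
  (1e-10) to a naive double-loop implementation. A 300-residue,
  200-sequence alignment completes in a few seconds on one CPU.
- Correlations are clipped to [−1, 1] to absorb last-ulp excursions.
- CLI TSV outputs use `%.17g` floats so identities like CE = CN × CC
  survive write/read cycles bit-for-bit (read back with pandas
  `float_precision="round_trip"` when exactness matters).
- All stochastic operations take an explicit integer seed through
  `numpy.random.default_rng`; there is no global RNG state.

## Known limitations

- The exact McBASC estimator has historical variants (weighting, gap
  conventions); this implementation fixes one defensible, fully documented
  instantiation. Absolute CE values depend on the MSA; comparisons are
  meaningful within a protein, which is why CN is percentile-normalized
  per protein.
- Published headline benchmarks for this family of methods rest on large
  curated MSAs and experimental variant sets; the desk-scale synthetic
  checks here validate the machinery, not field performance.
- No direct-coupling analysis (pseudo-likelihood) inference, no APC
  correction, no random-forest integration (the union rule and single
  scores are the supported schemes), and no nucleotide/codon support.
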