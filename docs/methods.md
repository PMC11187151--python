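# Methods

## Problem setting

Mismatch-repair-deficient (dMMR) tumors accumulate somatic insertions and
deletions in short tandem repeats. A diagnostic MSI panel is a small set of
repeat loci plus a decision rule that together reproduce the
immunohistochemistry (IHC) dMMR/pMMR call from sequencing alone. This
package implements the computational side of designing such a panel from
UMI-tagged amplicon sequencing of matched tumor/normal FFPE pairs, and of
applying it to tumors with no matched normal.

## Locus discovery

A microsatellite locus is a maximal tandem repeat tract whose primitive
unit is 1–5 bp long and occurs 7–13 whole times. Conventions:

- Copy counts are whole units; a trailing partial unit is excluded from the
  reported interval. This makes the copy-count window well defined.
- Tracts longer than 13 copies are excluded entirely rather than truncated
  (long homopolymers are noisy and are deliberately outside the marker
  class); `--no-upper-bound` relaxes this for exploration.
- Only the forward strand is scanned; a tract and its reverse complement
  are one genomic feature. The reported unit is the lexicographically
  smallest rotation, so equivalent descriptions ("TA" vs "AT") collapse.
- Non-ACGT characters terminate tracts (FFPE references may be masked).
- Primitivity of the observed unit guarantees, by the Fine–Wilf periodicity
  theorem at ≥ 7 copies, that each physical tract is reported under exactly
  one unit length; the scanner is verified against a brute-force enumerator
  on random and planted sequences.

The bound pair (7, 13) is treated as inclusive on both ends, with tracts
above the upper bound dropped; the discovery window itself is a fixed input
of the procedure, not a tuned parameter.

## Synthetic cohorts

The generator produces the inputs the analysis assumes, at repeat-length
resolution (no base-level reads, no alignment):

| parameter | default | meaning |
| --- | --- | --- |
| `n_paired_patients` | 93 | matched tumor/normal training pairs |
| `n_unmatched_tumors` | 32 | validation tumors without normals |
| `frac_dmmr` | 0.5 | fraction of tumors labeled dMMR |
| `n_loci` / `n_informative` | 200 / 8 | catalog size / planted informative mononucleotide loci |
| `p_unstable_dmmr` | 0.85 | per-informative-locus instability probability in dMMR tumors |
| `p_unstable_pmmr` | 0.02 | same in pMMR tumors |
| `p_decoy_unstable` | 0.01 | instability probability at non-informative loci |
| `purity` | 0.6 | fraction of tumor-derived molecules (UMI families) |
| `stutter_eps` | 0.08 | per-read probability of ±1-unit slippage (symmetric) |
| `families_per_locus` | 60 (Poisson) | UMI families per sample-locus |
| `reads_per_family_mean` | 4 (zero-truncated Poisson rate) | reads per family |
| `polymorphic_frac` | 0.05 | loci with patient-specific germline lengths (±1–2 units) |

The noise and purity values are stand-ins chosen to be realistic for FFPE
amplicon data (moderate tumor content, percent-scale polymerase slippage
per PCR+sequencing pass); no published per-locus noise rates back them,
and they should be treated as illustrative study conditions rather than
estimates.

Mechanics worth knowing:

- Every (sample, locus) cell draws from an independent RNG substream keyed
  by SHA-256 of the identifiers plus the master seed, so cohorts are fully
  reproducible and reads of one sample never depend on which other samples
  exist. dMMR/pMMR labels are assigned by an exact-count shuffle, so label
  *assignments* do change when the cohort size changes.
- When a tumor locus draws unstable, the somatic shift is sampled from
  {−3, −2, −1, +1, +2} and applied to each UMI family with probability
  `purity` (a family is one input molecule; it is tumor-derived or not).
- Stutter is ±1 unit, symmetric. Real stutter is contraction-biased and
  occasionally ±2; symmetry keeps the closed-form test oracles exact, and
  the calling statistic is insensitive to the direction of slippage.
- Germline-polymorphic loci are drawn from the non-informative loci only.
  The polymorphism filter exists precisely to remove such loci, and panel
  candidates in practice are pre-screened against known polymorphisms;
  coupling the two draws would make planted-locus recovery depend on the
  polymorphism lottery rather than on the pipeline.
- UMI collisions are not modeled; each family has a distinct UMI within its
  sample-locus cell.

What passing tests on this generator do **not** show about real data:
locus-specific stutter rates (homopolymer length dependence), contraction
bias, cross-locus coverage correlation, sample-quality variation, and
subclonal heterogeneity are all absent. The pipeline's thresholds would
need recalibration on real UMI-Seq data; the tests establish correctness of
the machinery, not clinical performance.

## UMI consensus

Families (reads sharing sample, locus and UMI) are collapsed to a
strict-majority consensus length; families with no strict majority are
dropped and tallied per sample, as are families below `min_family_size`
(default 1, so non-UMI data pass through unchanged; 3 is recommended for
real libraries — at size ≥ 3 a single stuttered read can no longer change
the consensus, which is the error-suppression mechanism). Strict majority
with tie-drop was chosen over plurality or rounded mean because it is
auditable and conservative; the suppression guarantee (consensus error <
raw read error at family size ≥ 3) is asserted by simulation in the tests.

## Instability calling

For tumor profile T and reference support S (allele lengths at ≥ 5% of the
reference's families), the statistic is

    novel(T, S) = (# consensus families of T with length ∉ S) / (# families of T).

- **Paired mode**: S comes from the matched normal; unstable ⇔
  novel ≥ τ (0.10) with ≥ `min_cov` (20) families on both sides.
- **Baseline mode** (no matched normal): S is the union of the supports of
  a panel of normals; additionally the statistic must exceed the normals'
  own novel-fraction distribution by `z_min` (3.0) standard deviations
  (floor `sd_floor` = 0.01, preventing a degenerate zero-variance null).
  Each normal is scored against the pooled support including itself
  (leave-one-in), a deliberately conservative null. The coverage rule
  applies to the tumor; the pooled normal depth is recorded as the
  reference coverage.

τ = 0.10 sits between the consensus noise floor (~1% of families at
`stutter_eps` = 0.08 after collapsing) and the smallest real signal
(purity × sensitivity of the shift, ~0.6 here), and every threshold is
config-exposed. A no-call (low coverage, missing baseline) is never
unstable and is excluded from frequency denominators; at classification
time no-calls count as stable, biasing toward specificity. Tumor-only
germline inference is intentionally not attempted.

## Selection cascade

1. **Polymorphism filter** — a locus is dropped when more than 5% of
   normal samples disagree with the majority modal consensus length
   (modal ties break toward the shorter length). Loci never observed in a
   normal are retained; with no normals the filter is skipped with a
   warning.
2. **dMMR enrichment filter** — keep loci with instability frequency
   ≥ 30% in dMMR and ≤ 5% in pMMR training tumors (no-calls excluded).
3. **Clustering** — per-locus feature vector (freq in dMMR, freq in pMMR,
   overall freq), standardized; Ward/Euclidean hierarchical clustering cut
   at six groups; K-means with k equal to the number of distinct
   hierarchical centroids, initialized at those centroids (deterministic
   given the seed). Frequency features, rather than raw per-sample binary
   vectors, make the clusters independent of sample ordering and cohort
   size; the binary representation remains available.
4. **Differential-cluster selection** — the gap of a cluster is the mean
   over its loci of freq(dMMR) − freq(pMMR). Retained: the argmax cluster,
   any cluster within 0.05 of it, **and any cluster whose gap reaches the
   absolute floor `min_gap` = 0.25** (the margin implied by the enrichment
   thresholds, 0.30 − 0.05). The absolute floor matters when the filtered
   set is small and uniformly differential: cutting a handful of
   equally-good loci into six groups produces noise-ranked singleton
   clusters, and keeping only those near the maximum would discard loci on
   sampling noise. A cluster uniformly above the enrichment margin is
   "pronounced differential abundance" in its own right.
5. **Panel optimization** — exhaustive enumeration of candidate subsets of
   size 2–8 (guarded by a 10^6-subset budget), scored by the
   ≥ 2-unstable ⇒ MSI-H rule; returns the subset maximizing training
   sensitivity subject to 100% training specificity, ties broken toward
   smaller panels then lexicographic locus ids; if no subset reaches full
   specificity the (specificity, sensitivity)-best subset is returned
   flagged `constraint_met=false`. The per-size best combination is logged.
   A greedy forward mode exists for large candidate sets and is checked
   against the exhaustive search on separable instances; exhaustive search
   is the reference algorithm (C(13, 2..8) ≈ 7 000 subsets is trivial).

Only mononucleotide (unit length 1) loci are panel-eligible by default —
the decision rule is defined over mononucleotide repeats — with a flag to
relax.

Note a consequence of the smaller-panel tie-break: when several subset
sizes reach the same training sensitivity, the smallest wins, and small
panels can generalize worse than the training estimate suggests (a
three-locus panel at per-locus sensitivity 0.85 passes the ≥ 2 rule with
probability ≈ 0.94 out of sample, versus ≈ 0.9998 for eight loci). The
per-size selection log exposes the larger alternatives.

## Classification and evaluation

MSI-H ⇔ at least `min_unstable` = 2 panel loci unstable; no-calls count as
stable; the negative class is reported as the combined label "MSS/MSI-L".
Confusion metrics (dMMR/MSI-H positive): sensitivity, specificity, PPV,
NPV, each ×100 and rounded to two decimals; zero-denominator metrics are
flagged undefined, never coerced to a number.

## Problem sizes and determinism

The default end-to-end exercise — also what `scripts/acceptance.py` runs —
uses 100 matched training pairs and a 60-tumor unmatched validation cohort
over 200 loci (~10⁷ simulated reads), chosen to give per-locus frequency
estimates at n = 50 per class while the whole pipeline completes in well
under a minute on one CPU. All randomness flows from explicit seeds
(master seed → hashed per-cell substreams; the clustering seed is passed
through); repeated runs are byte-identical.

## Known limitations

- The calling statistic ignores the magnitude of length shifts; a ±1 shift
  at high purity and a −3 shift count equally once above τ.
- Baseline mode can mis-call a tumor whose rare germline allele was never
  seen in the normal panel; paired mode does not have this failure mode.
- The consensus step drops tied families rather than modeling them; at
  family size 2 with one stuttered read this discards real molecules
  (conservative, and tallied in QC).
- The cascade's clustering stage adds little when the enrichment filter is
  already stringent; it matters when the filter is loosened to admit
  partially informative loci.
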