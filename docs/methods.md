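# Methods

## Scope

`srnase_screen` implements a desk-scale, fully deterministic
re-implementation of an S-RNase discovery analysis: sequence screening
of T2-RNase candidates, distance-based class/LPSC assignment, intron
inference, expression-specificity calls, and a GSI cross simulator with
a segregation/role-assignment engine. All data are synthetic and
generated programmatically with known ground truth; no sequence
databases, read-level simulation or assembly are involved.

## Biological model

- **GSI rule.** Pollen carrying an S allele present in the pistil is
  rejected; an `Sf` allele escapes rejection. `gsi_cross` draws the
  maternal allele uniformly and the paternal allele uniformly from the
  surviving pollen classes; a cross with no surviving class raises.
  `ProgenyTable` enforces the rejection rule as a construction-time
  invariant.
- **Semi-compatible design.** The default scenario is S1Sx × S1Sy with
  reciprocal crosses of n = 81 and 95 progeny. Five planted markers
  carry the canonical roles: shared-S (S1-linked), one unique-S marker
  per parent, an unlinked marker hemizygous in both parents (expected
  3:1), and a marker homozygous in one parent (always present).
- **Candidate definition.** A gene is designated an S-RNase candidate
  only if *every* line of evidence holds: class III and non-LPSC, basic
  pI, both CAS histidines, exactly one intron inside a hypervariable
  window, pistil-specific detection, and an S-linked marker role.

## Numerical methods

- **Pairwise alignment**: Needleman–Wunsch global alignment with linear
  gap penalty (defaults match/mismatch/gap = 1/0/−1), vectorised
  recurrence. The traceback compares recomputed cell scores with a
  relative tolerance of 1e−9 rather than exact float equality: the
  vectorised forward pass and the traceback sum terms in different
  orders, and on profile columns containing fractions such as 1/11 the
  exact comparison fails and degenerates the path into alternating
  insertions. The tolerant comparator restores the true optimal path;
  scores are unchanged.
- **Progressive MSA**: guide tree from pairwise identity, then
  profile–profile merges. Guide distances use the pairwise defaults
  (1/0/−1), but profile merging scores mismatch = −1 and gap = −2:
  with a zero mismatch penalty, deep merges have no columnar pressure
  and shred homologous columns into staggered gaps. This choice is
  fixed a priori, not tuned per dataset.
- **Neighbor joining**: Saitou–Nei with negative branch lengths clamped
  to zero and counted (`negative_branches_clamped`). On additive
  matrices the leaf-to-leaf distances are recovered exactly (tested to
  1e−9 against construction and against an independent NJ
  implementation's topology).
- **p-distance**: proportion of differing sites; pairwise deletion by
  default, complete deletion optional; identity = 1 − p.
- **pI**: bisection on the Henderson–Hasselbalch net charge, EMBOSS pKa
  set (N-term 8.6, C-term 3.6, D 3.9, E 4.1, C 8.5, Y 10.1, H 6.5,
  K 10.8, R 12.5); verified against a 1e−4 pH grid scan. Molecular
  weight from average residue masses minus one water per peptide bond.
- **Intron inference**: exact spliced CDS-to-genome mapping via
  Z-array matching. Preference order: fewest introns, then canonical
  GT..AG sites, then leftmost donors; surviving ties raise an ambiguity
  error rather than guessing. Coordinates are 0-based half-open
  internally and 1-based inclusive in GFF3 output.
- **Segregation statistics**: Pearson chi-square goodness of fit,
  df = 1, **no continuity correction** — the published-style P values
  (e.g. 58/23 vs 1:1 → 1.007e−4) are reproduced only without
  correction.
- **Marker role assignment** (`classify_marker`) is threshold-free.
  Each cross direction is labeled with the better-fitting ratio (the
  larger of the 1:1 and 3:1 chi-square P values); when the two
  directions disagree, the tie is broken by the pooled two-direction
  binomial log-likelihood, which uses all scored progeny. Unique-S
  calls rest on direction asymmetry itself (all present only when the
  carrying parent donates pollen, segregating the other way, carried by
  one parent): no unlinked marker model produces that pattern, so no
  ratio gate is applied. Rationale: a hard P ≥ 0.05 gate misclassifies
  a true 1:1 marker in at least one of two directions ~10% of the
  time, which is incompatible with a ≥99% recovery requirement; the
  likelihood rule was derived from that power analysis before
  measurement, then verified (300/300 scenario seeds). `alpha` is kept
  for threshold-style reporting only.
- **Differential expression**: permutation test with a pooled null on
  log2 median-of-ratios-normalised counts and a moderated difference
  statistic (3 vs 3 designs are enumerated exhaustively). This is
  **not equivalent** to a negative-binomial Wald test (DESeq2); every
  output carries `DE_TEST_LABEL` saying so. With 60 genes and exact
  3 vs 3 enumeration the smallest attainable q for a single hit is
  ~0.1 — a floor of the pooled null, not a bug. BH step-up controls
  FDR. Size factors use only genes with nonzero counts in every
  sample.

## Synthetic-data generator

All generators are deterministic in (parameters, seed); parameters are
recorded in the emitted truth objects.

- **Protein family** (`gen_family`): one random 230-aa ancestor
  (~25 kDa) per class, classes diverging at 0.6; class members
  substitute per site at rates solved analytically from target pairwise
  identity (`rate_for_pairwise_identity`). Class III composition is
  biased basic (K/R/H), classes I/II mildly acidic, so the class-wise
  pI ordering holds; the two CAS histidines are preserved except in
  flagged knockouts.
- **Domain separation.** Class III non-LPSC members (the S-allele pool)
  diverge at `s_allele_div` = 0.35 (~0.65 pairwise identity), while
  the planted LPSC targets 0.90 identity. S alleles are hypervariable,
  and a *detectable* low-polymorphic subcluster must sit clearly above
  the polymorphic background: 0.65 lies ~7σ below the 0.85 LPSC
  detection floor at length 230, and 0.90 sits ~2.7σ from both the
  0.85 floor and the 0.95 redundancy cutoff. These margins were chosen
  from the binomial site-count noise, not tuned against outcomes.
- **Transcripts** (`make_clean_transcript`): CDS from random synonymous
  codons, embedded in random UTRs with an in-frame upstream stop.
  Random coding occasionally leaves a longer stop-free stretch in
  another frame (typically the reverse complement of the CDS, ~2% of
  draws); codon and UTR choices are resampled until the planted protein
  is exactly the longest six-frame ORF, so the ORF caller's input is
  well-posed.
- **Genomic sequences** (`plant_gene`): introns (length 87–374,
  GT..AG) planted at chosen CDS offsets inside random flanks, returning
  the true gene model. Class III genes get one intron inside the HV2
  window; class I genes two introns; class II none.
- **Counts** (`gen_counts`): negative-binomial (dispersion 0.1),
  log-normal per-gene base means and library sizes; planted fold
  changes recorded in the truth map.
- **Tissue panels** (`gen_tissue_panel`): boolean detection rows
  guaranteed to read back as their truth label
  (`pistil_specific` / `pistil_plus_other` / `ubiquitous` /
  `not_detected`).

## Parameter defaults (units)

| Parameter | Default | Unit / note |
|---|---|---|
| protein length | 230 | residues (~25 kDa) |
| within-class divergence | 0.15 | per-site substitution fraction |
| S-allele divergence | 0.35 | per-site substitution fraction |
| between-class divergence | 0.6 | per-site substitution fraction |
| LPSC spec | (3, 0.90) | (members, target identity) |
| CAS residues | 45, 108 | 0-based backbone positions |
| cluster identity | 0.95 | redundancy collapse threshold |
| LPSC identity floor | 0.85 | detection threshold |
| class assignment floor | 0.30 | minimum support |
| pI basic cutoff | 7.5 | pH |
| intron length band | 87–374 | nt |
| cross sizes | 81 / 95 | forward / reciprocal progeny |
| alpha | 0.05 | reporting only (roles are threshold-free) |
| NB dispersion | 0.1 | negative-binomial 1/size |

## Limitations

- The MSA guarantees columnar alignment of the generated (indel-free)
  family only up to ~0.2 divergence; at deeper divergence only
  within-class columnar consistency is asserted and used.
- The DE test's pooled permutation null floors attainable q-values in
  small designs (see above) and is not a substitute for a count-model
  test on real data.
- `intron_in_hv` evaluates single-intron models only; multi-intron
  genes are reported but never satisfy the criterion.
- Marker role classification assumes reciprocal crosses of one focal
  pair; genotyping noise degrades the strict all-present and
  complementarity gates (homozygous, unique-S, shared-S) before it
  affects the ratio-based roles.
- The generator emits substitution-only families (no indels, no
  recombination within genes) and equal-frequency codon usage; these
  are conventions recorded in the truth objects, not biological
  claims.
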