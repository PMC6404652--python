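# Methods

## Model

`tastrain` treats a strain as a bag of chromosomal type-II toxin–antitoxin
(TA) genes, each a member of a homology *group* and, within its group, of
a sequence-identical *variant* class. Two layers of signal identify
strains in a metagenome: which groups are present, and which variant of
each group the reads support. The method is presence-oriented — it makes
no abundance estimates — and is explicitly conservative about resolution:
when read coverage cannot separate two reference strains, it reports the
set of strains the evidence is consistent with rather than picking one.

Assumptions worth stating plainly:

* TA genes are vertically inherited. The plasmid screen (removal of genes
  with a plasmid homolog at ≥ `plasmid_identity` local identity over
  ≥ `plasmid_min_coverage` of the gene) enforces this at database build
  time; it deliberately removes a gene's close homologs in other strains
  too, since they match the same plasmid.
* Reads are short relative to genes and are treated independently; no
  pairing or quality information is used (qualities are parsed and
  ignored at the default `min_base_quality = 0`).
* Evidence is aggregated per marker position, not per read haplotype:
  two markers covered by one read are treated as independent
  observations. This loses phasing information but matches the
  dropout-tolerant matrix formulation.

## Pipeline and definitions

1. **Grouping.** Single-linkage components of the graph joining gene pairs
   with global-alignment identity strictly above `grouping_identity`
   (default 0.88). Identity is matches / alignment columns, gaps counted
   in the denominator, computed on the canonically ordered pair so it is
   symmetric under tie-prone tracebacks. Groups are deterministic:
   ordered by smallest member gene id, labelled `<gene name>-<number>`.
   The representative is the longest member (ties: smallest gene id).
2. **Markers.** Each variant is globally aligned to the representative,
   giving a column string over representative positions plus insertion
   strings keyed to the preceding position. A marker is any column where
   ≥ 2 variants disagree (state: base or `-`) or any insertion key with
   ≥ 2 distinct inserted strings (state: the string, `""` if absent). A
   k-nt deletion therefore contributes k single-column gap markers rather
   than one k-long marker — a deliberate choice that keeps one stable
   coordinate frame and makes read projection per column well-defined.
   By construction of variant classes every variant pair is separated by
   at least one marker; the builder asserts this.
3. **Mapping.** Seeds are non-overlapping k-mers (k = 15, both strands);
   each candidate (gene, strand, diagonal) locus is extended by a banded
   semi-global alignment (read global, gene window free-ended; band
   ≈ 3 + read_length/25). A placement is accepted iff
   (mismatches + indel bases) / read_length ≤ `max_mismatch_frac` (0.1).
   All best-score placements are kept; reads whose best placements span
   more than one group are ambiguous and contribute no evidence.
4. **Evidence.** Per group: a breadth-of-coverage mask over representative
   positions, and per marker the read support for each observed state. A
   state matching no declared variant state (sequencing error or novel
   variant) increments a conflict counter only — the discard is per read,
   not permanent; `strict_marker_discard` switches to dropping any marker
   that saw a conflict.
5. **Detection.** Candidates of a group = variants whose state lies in the
   supported state set (support ≥ `min_support`) at every observed
   marker. Markers with two or more supported states flag the group
   *mixed* (co-occurring strains, not error). If evidence excludes every
   catalogued variant, the detection falls back to the full variant list
   and is flagged *inconsistent* rather than inventing an empty claim.
6. **Matrices.** `G(u,v) = 1` iff u, v are same-group candidates with
   equal states at every observed, supported marker (symmetric within a
   group by this definition; cross-group entries are 0).
   `St(i,j) = 0` iff some detected group supports a candidate variant of
   i's repertoire that j cannot account for (j lacks the group, or every
   variant j carries there is separated from i's supported candidates —
   a variant excluded by evidence counts as separated). St is asymmetric.
7. **Sets and report.** Indiscernible sets are connected components of
   `St ∧ Stᵀ`. The relation need not be transitive; components glued only
   through intermediaries are flagged `chained` instead of being split —
   the conservative reading. A set is reported iff some member passes:
   aggregate breadth over its detected repertoire genes > `min_coverage`
   (strictly), and observed supporting markers > `min_markers_abs`
   (strictly) *or* ≥ `min_markers_frac` of the strain's markers. A strain
   whose repertoire carries no markers at all (all its groups
   monovariant) degrades to presence/absence mode: the marker condition
   is waived and coverage alone decides.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `grouping_identity` | 0.88 | min pairwise identity (strict >) to join a group |
| `plasmid_identity` | 0.80 | local identity at which a plasmid hit removes a gene |
| `plasmid_min_coverage` | 0.50 | fraction of gene length the hit must span |
| `match/mismatch/gap_open/gap_extend` | +1/−1/−2/−1 | alignment scores; gap of L costs `gap_open + (L−1)·gap_extend` |
| `k` | 15 | seed k-mer length |
| `max_mismatch_frac` | 0.1 | mapping acceptance threshold |
| `min_support` | 1 | reads required before a state constrains candidates; ≥ 2 recommended with error-prone reads |
| `min_coverage` | 0.60 | reporting bar on aggregate breadth (strict >) |
| `min_markers_abs` / `min_markers_frac` | 2 / 0.50 | reporting bar on supported markers (> 2, or ≥ 50%) |
| `coverage_mode` | `breadth` | aggregate breadth over detected genes; `gene_fraction` counts detected repertoire genes instead |

The coverage figure is read as aggregate breadth (covered positions /
total positions of the strain's detected TA genes); the alternative
fraction-of-genes-detected reading is kept behind `coverage_mode`.

## Synthetic data

The generator emulates the statistical structure the method relies on,
with defaults chosen as the study conditions:

* Per gene-family slot, a genus-level ancestral sequence (length uniform
  in 200–400 nt); each species' homolog diverges from it at
  `inter_species_divergence` = 0.25 substitutions/site per species
  branch, which drives cross-species identity far below the 0.88
  grouping threshold — species therefore occupy disjoint groups (the
  species-specific presence pattern), unless `shared_groups` plants
  common ancestors for designated species pairs to mimic closely related
  species.
* Strains subsample their species' gene set (presence probability 0.8,
  at least one gene kept) and mutate it at 0.02 substitutions/site plus
  1–3 nt indels at 0.002/site — similar but not identical repertoires
  and variants, the strain-specific layer.
* Reads: per gene, Poisson(depth × L / read_length) fragments, uniform
  strand, i.i.d. base errors, constant Q30 qualities, read length 250 nt
  by default. Fragment starts may overhang gene boundaries (clipped,
  keeping at least half a read inside). This emulates reads drawn from a
  genome in which the gene is embedded; restricting starts to the gene
  interior would systematically undercover gene ends, and a marker near
  an end could then be "observed" by a single strain's lone read — an
  artifact of simulating bare genes, not a property of the method.

What the generator does **not** model: realistic error profiles
(quality-dependent, indel-rich), GC or positional bias, host or off-target
contamination, plasmid-borne reads, true paired-end geometry, within-gene
recombination. Passing tests therefore demonstrate the inference logic
under the stated statistical structure, not performance on real
sequencers' quirks.

## Numerical and degenerate-input choices

* All randomness flows from explicit seeds; every generator output and
  report is byte-identical across runs with the same seed.
* Alignment backend: `Bio.Align.PairwiseAligner` with the scores above;
  traceback ties are resolved by the library deterministically. Scores
  are verified against independent Gotoh/Smith–Waterman dynamic programs
  in the test suite; identity on tie-prone pairs is made symmetric by
  canonical argument ordering.
* Empty read set: a valid run — header-only report, exit 0.
* A read shorter than k, or mapping nowhere: silently unmapped.
* Reads longer than a gene are truncated to it (with a warning).
* Observing a deletion state requires the read to span both anchored
  flanks of the gap; observing an insertion state requires the anchors
  plus every inserted position. Partial spans contribute nothing.
* Zero-marker databases load and profile; detection then rests on
  presence/absence and the marker reporting condition is waived.

## Known limitations

* Candidate sets are defined per marker, not per read haplotype; with
  several co-occurring strains of one species, a reference variant whose
  per-position states coincide with the union of the planted variants'
  states can enter the candidate set even though no single read supports
  its joint pattern. Deep coverage of its private markers excludes it;
  thin coverage may not.
* The 0.88 grouping identity is applied to a fixed identity definition
  (global, gaps in the denominator); other definitions shift the
  effective threshold and are accommodated by changing
  `grouping_identity`, not the code.
* Marker coordinates are anchored to pairwise alignments against the
  representative; columns adjacent to indels may differ from what a full
  multiple alignment would give.
* The mapper is exact-seed based: reads whose every k-mer is hit by an
  error (error rate ≫ 5% at k = 15) lose sensitivity before the
  mismatch-fraction bound rejects them.
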