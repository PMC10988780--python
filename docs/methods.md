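# Methods

`clonotrack` implements an inference chain for calling antigen-reactive TCRβ
CDR3 clones from paired sorted repertoires, tracing them through unenriched
naive/memory compartments, and distilling them into shared CDR3 motifs. This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic cohorts do and do not establish.

## Data model

The unit of analysis is a repertoire: every TCRβ rearrangement sequenced
from one sorted compartment of one donor, with nucleotide and amino-acid
CDR3, V/D/J gene calls, a template count (number of sequenced genomic-DNA
molecules, a proxy for cell count because each αβ T cell carries one
rearranged TCRβ) and a frequency. Five compartments are modelled per donor:
antigen-reactive (AIM+) and matched non-reactive (AIM−) cells from an
activation-induced-marker sort, plus ex-vivo naive, central-memory (TCM) and
effector-memory (TEM) cells. Analyses operate on productive rearrangements
only; frequencies are always recomputed from template counts after
filtering, because any row removal invalidates a file's frequency column.
Clonotypes aggregate records by amino-acid CDR3 (the key under which clones
are tracked across samples); an amino-acid + V-gene key is available where a
stricter identity is wanted. Gene calls are collapsed to family level
(`TCRBV15-01*01` → `TRBV15`), the level at which usage preferences are
reported.

## Reactive-clone selection

1. **Frequency threshold.** The global threshold is the minimum over donors
   of the maximum AIM− clonotype frequency — the largest cutoff that removes
   every non-reactive clone in at least one donor. Selection applies a
   strict `>`. An optional `sig3_up` mode rounds the threshold up to three
   significant digits for reporting; the default is no rounding.
2. **Per-clone contingency test.** Each AIM+ clonotype above the threshold
   is tested on the 2×2 table of template counts (clone vs rest, AIM+ vs
   AIM−) with a two-sided Fisher exact test. Counts are templates, not
   unique-clone indicators, because compartment frequencies in this assay
   are template frequencies. The odds ratio uses the Haldane–Anscombe +0.5
   on all four cells whenever any cell is zero, keeping log odds finite.
3. **Decision rule.** A clone is selected when log10(odds) ≥ 1 and the
   Benjamini–Hochberg adjusted p is below 0.01, with adjustment spanning the
   donor's above-threshold candidates only. Both the sidedness of the test
   and the adjustment family are configurable; two-sided and per-donor are
   the defaults since neither choice is forced by the design.
4. **V-gene usage.** Per donor and gene, OR = (V+ selected / V+ control) /
   (V− selected / V− control) on unique clonotypes, +0.5 on all counts when
   any is zero, with control = the donor's AIM− clonotypes. Genes preferred
   (OR > 1) in at least five donors are tested across donors with a
   two-sided Mann–Whitney comparison of usage frequencies.

## Lineage tracking

Selected clones are matched into naive/TCM/TEM repertoires by exact
amino-acid CDR3 identity. A clone's memory copy number is its summed
template count over TCM and TEM (the two subsets are sorted separately, so
the sum is the donor's total memory support for the clone). Overlap is
reported as the percentage of selected clones found per compartment and
donor; naive vs memory percentages are compared with a two-sided
Mann–Whitney test. Clone-level publicity marks a CDR3 selected in two or
more donors.

## Motif discovery

CDR3s are trimmed to their interior before motif work (default: drop the
first three and last two residues, the germline-dominated ends). Offsets
are configurable and must match between discovery and any later pattern
matching.

* **Local convergence.** Interior k-mers (k = 2–4) enriched against a naive
  reference: fold = sample containment rate / reference containment rate
  (one pseudo-occurrence when absent from the reference), kept at fold ≥
  1000/100/10 for k = 2/3/4 with Fisher p < 0.05 and ≥ 3 distinct carrying
  CDR3s. The per-k folds fall with k because longer exact matches are
  rarer; all cuts are exposed in the API.
* **Global convergence.** Equal-length interiors differing at ≤ 1 position
  form a group whose pattern carries `%` (exactly one arbitrary residue) at
  the variable position. Implementation hashes every (sequence, position)
  single-mask key, which is exactly equivalent to all-pairs Hamming-≤1
  clustering and is tested against that brute force.
* **Group hygiene.** Groups need ≥ 2 distinct CDR3 members. Groups with
  identical member sets are collapsed, keeping the more specific pattern
  (longer, then fewer wildcards, then lexicographically smaller) — a
  house rule, stated here because some dedup rule is unavoidable and no
  canonical one exists.
* **Reference enrichment.** Each group's prevalence (distinct CDR3s
  matching the motif) is compared sample-vs-reference with a two-sided
  Fisher test; p < 0.05 passes. The reference is user-supplied; the package
  does not redistribute any proprietary naive panel, and tests use a
  synthetic reference drawn from the generator's background model (300,000
  CDR3s by default — roughly twice the pooled sample, so that small
  sample-only groups can reach significance). This is the main fidelity gap
  against analyses run with a tool's built-in reference panel.
* **Expansion score.** The statistic is the number of member clonotypes
  with ≥ 2 templates. The null resamples equally sized clonotype sets
  uniformly without replacement from the pooled dataset;
  p = (1 + #{null ≥ observed}) / (n_perm + 1) with n_perm = 1000. Null
  draws are cached per group size, and a fixed seed reproduces every p
  exactly.

## Reactive-motif calling, affiliation and public motifs

For each expansion-significant group, member template counts are summed per
compartment and compared as rates. The rate ("Poisson") test conditions on
the total: with n = c_A + c_B events and exposures T_A, T_B, c_A ~
Binomial(n, T_A/(T_A+T_B)) under equal rates — the standard exact two-rate
Poisson comparison, verified against an integer-exact binomial tail oracle.
The fold change is log2((rate_A + ε)/(rate_B + ε)) with ε = 1/max(T_A, T_B)
so one-sided groups stay finite. A group is a reactive (APOB+-style) motif
when expansion p < 0.05, log2 fold ≥ 2 **toward the reactive compartment**,
and −log10 p ≥ 5. The published volcano-plot cut is symmetric (|log2 fold| ≥
2) yet reads out reactive motifs; we require the reactive direction
explicitly and note the asymmetry as a deliberate interpretation.

Ex-vivo affiliation assigns naive/TCM/TEM CDR3s to the *fixed* reactive
motif set by pattern matching (LOCAL: substring containment; GLOBAL: equal
length + wildcard match) rather than re-clustering the ex-vivo pool —
re-clustering would produce groups incomparable with the reactive set.
Motifs found only among memory CDR3s are memory-affiliated by definition;
motifs found in both pools qualify when memory-vs-naive rates pass
|log2 fold| ≥ 1 in the memory direction with rate p < 0.05. Memory-affiliated
motifs span a sharing network over (donor, TCM/TEM) nodes; edge weight is
the number of distinct shared motifs, exported as GraphML plus a plain edge
list. A motif is public when its memory matches span more than 80% of
donors (5 of 6 at the default cohort size). Position-frequency matrices of
matching interiors (column-stochastic; GLOBAL motifs aligned directly,
LOCAL anchored at the motif occurrence) are emitted for any logo renderer.

## Synthetic cohorts

The generator emulates the structure of the study design so every stage is
testable against known truth:

* Background clones come from per-donor latent pools (60,000 clones for the
  AIM pair and naive, 30,000 for memory) with Zipf(3.5) weights truncated at
  the compartment total; template counts are multinomial draws of 20,000
  templates per compartment. AIM+ and AIM− draw from one shared pool, so an
  unplanted cohort is exchangeable between the two — the null used for
  calibration. Observed repertoires are dominated by singletons with a
  heavy expanded tail, matching the qualitative copy-number spectra of
  sorted non-reactive repertoires.
* Planted reactive clones (50 per donor) receive 80–200 AIM+ templates with
  AIM− counts capped so the AIM+:AIM− frequency ratio is ≥ 20. With
  probability 0.3 a planted clone is seeded into memory (TCM vs TEM split
  0.5, both-subsets probability 0.2, 1–16 copies); standalone planted
  clones leak into naive with probability 0.01 at one copy. The leak is
  restricted to standalone clones so that a motif family's naive/memory
  affiliation is a property of its seeding, not of a single leaked member.
* Ten motif families share an interior template with one wildcard position;
  members differ only at the wildcard, and cross-donor instantiations
  (probability 0.6 per non-owner donor) reuse the interior under a
  donor-specific two-residue flank — so motifs recur across donors while
  full clonotypes stay private, the regime observed for exact-sequence
  tracking. Family CDR3 lengths start at 12 (interior ≥ 7) so chance
  interior matches in 10^5-scale backgrounds are negligible.
* Ground truth is recorded from what was actually emitted (realised counts
  and placements), and non-productive filler rows (5%) exercise the
  productive filter.

What passing these tests shows: the statistics are computed exactly, the
decision rules are calibrated under the null, and the chain recovers planted
structure at realistic sizes. What it does not show: robustness to V(D)J
generation-probability structure, positional amino-acid biases, sequencing
artefacts, or cross-reactive background sharing — the background model is
deliberately neutral, and real repertoires are messier in all four ways.

## Problem sizes and defaults

Six donors, 20,000 productive templates per compartment (~10^4–10^5 scale
rearrangement tables), 1000 permutations per expansion score, 300,000
reference CDR3s. Null calibration in the test suite pools 20 independent
cohorts; the acceptance script uses 6 and reports every n it used. These
sizes were chosen so the whole chain exercises the same code paths as a
full-scale analysis while a complete run stays in the minutes range on one
CPU.

## Known limitations

* Exact reproduction of group counts from analyses run through GLIPH2's web
  tool is out of reach by construction: those depend on GLIPH2 internals
  (V-gene bias, length-distribution and network sub-scores are deliberately
  out of scope) and on its packaged reference panel.
* The local-motif defaults approximate published GLIPH2 behaviour but are
  not fitted to it.
* Tracking counts unique clonotypes, not templates, when reporting overlap
  percentages; the alternative reading of "frequency of overlap" would
  weight by clone size.
* The conditional-binomial rate test is exact but conditional; it does not
  model overdispersion between biological replicates.
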