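# clonotrack

Selection, lineage tracking and motif analysis of antigen-reactive TCRβ
CDR3 clones from paired sorted repertoires.

## The problem

Autoreactive CD4⁺ T-cell responses — for example against apolipoprotein B
(APOB), the core autoantigen of atherosclerosis — can be read out by
sorting antigen-reactive (AIM⁺) and non-reactive (AIM⁻) cells after peptide
restimulation and sequencing their TCRβ CDR3 repertoires. The analytical
questions that follow are the ones this package answers:

1. Which clones are *specifically* expanded in the reactive compartment,
   not just large? (bystander clones are large in both compartments)
2. Can those clones be found again in the donor's unenriched naive,
   central-memory (TCM) and effector-memory (TEM) repertoires — i.e. do
   they reflect an in-vivo recall response?
3. Do non-identical reactive CDR3s share conserved interior motifs
   (specificity groups), and are some motifs public — present in the memory
   compartment of most donors — even when every individual clone is private?

`clonotrack` implements this chain for immunoSEQ-style tab-separated CDR3
tables, and ships a first-class synthetic-cohort generator with planted
ground truth so every stage is testable end to end.

## The statistics at the core

* **Frequency threshold** t = min over donors d of max_c f_c(AIM⁻, d): the
  largest cutoff pruning all non-reactive clones in at least one donor;
  selection uses strict f > t.
* **Per-clone enrichment**: two-sided Fisher exact test on the template 2×2
  [a = clone templates in AIM⁺, b = in AIM⁻; c, d = remaining templates],
  OR = ad/bc with Haldane–Anscombe +0.5 on zero cells; a clone is selected
  when log₁₀(OR) ≥ 1 and Benjamini–Hochberg q < 0.01 within the donor's
  candidates.
* **V-gene usage**: OR = (V⁺ in selected / V⁺ in control)/(V⁻ in selected /
  V⁻ in control) on unique clonotypes; genes preferred in ≥ 5 donors tested
  by two-sided Mann–Whitney across donors.
* **Specificity groups** (GLIPH-style): local enriched k-mers (k = 2–4) and
  global groups of equal-length trimmed interiors differing at ≤ 1 position
  (pattern wildcard `%`); reference-enrichment Fisher test and a seeded
  permutation *expansion score* (members with ≥ 2 templates vs equal-size
  random draws).
* **Reactive-motif cut**: summed member template rates AIM⁺ vs AIM⁻; exact
  two-rate Poisson comparison via the conditional binomial
  c_A ~ Bin(c_A+c_B, T_A/(T_A+T_B)); keep expansion p < 0.05, log₂fold ≥ 2,
  −log₁₀p ≥ 5.
* **Memory affiliation & public motifs**: ex-vivo CDR3s are pattern-matched
  into the fixed motif set; memory-only motifs (or both-pool motifs with
  |log₂fold| ≥ 1, p < 0.05 toward memory) are memory-affiliated; motifs
  spanning > 80% of donors' memory compartments are public. Sharing is
  exported as a (donor × subset) graph.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from clonotrack import SimulationConfig, simulate_cohort
from clonotrack.pipeline import productive_cohort, run_selection, run_tracking

cfg = SimulationConfig(seed=1)          # 6 donors, 2e4 templates/compartment,
reps, truth = simulate_cohort(cfg)      # 50 planted reactive clones/donor
cohort = productive_cohort({(r.donor_id, r.compartment): r for r in reps})

sel = run_selection(cohort)
print(f"frequency threshold: {sel.threshold:.3g}")
print(f"candidates above threshold: {len(sel.enrichment)}; selected: {len(sel.selected)}")

tracked, per_donor, summary = run_tracking(cohort, sel.selected)
print(f"overlap: naive {summary['mean_pct_naive']:.2f}% vs memory "
      f"{summary['mean_pct_memory']:.2f}% (Mann-Whitney p = {summary['mannwhitney_p']:.4f})")
```

prints

```
frequency threshold: 0.00065
candidates above threshold: 302; selected: 300
overlap: naive 0.00% vs memory 26.33% (Mann-Whitney p = 0.0027)
```

The threshold (6.5×10⁻⁴) is the top non-reactive clonotype frequency of the
least-expanded donor; 300 of the 302 above-threshold AIM⁺ clonotypes pass
the odds/FDR cut — exactly the 6 × 50 planted reactive clones, none of the
background. Tracking finds ~26% of them in the memory compartments versus
none in naive (memory seeding was simulated at 30%, the naive leak at 1%),
and the per-donor Mann–Whitney confirms the memory bias. Motif discovery on
the same cohort (`pipeline.run_motif_discovery` /
`run_affiliation_and_network`, given a naive reference panel) recovers each
planted wildcard motif family as a global specificity group passing the
reactive-motif cut.

A command-line interface mirrors these stages on files:

```sh
clonotrack simulate --seed 1 --out cohort/
clonotrack select  --manifest cohort/manifest.yaml --out results/
clonotrack track   --manifest cohort/manifest.yaml --selected results/apob_pos_clones.tsv --out results/
clonotrack motifs  --manifest cohort/manifest.yaml --reference naive_ref.txt --out results/
clonotrack network --manifest cohort/manifest.yaml --reference naive_ref.txt --out results/
```

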