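"""End-to-end orchestration: selection -> tracking -> motifs -> network.

These functions wire the per-module operations into the full inference chain
on an in-memory cohort (a {(donor_id, compartment): Repertoire} map) and are
what the command-line interface and the acceptance script call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import enrichment, motifs as mo, network as net, tracking
from .errors import ConfigurationError
from .io import AIM_NEG, AIM_POS, NAIVE, TCM, TEM, Repertoire, filter_productive


def _donors(cohort: Mapping[tuple[str, str], Repertoire]) -> list[str]:
    return sorted({donor for donor, _ in cohort})


def _empty_enrichment() -> pd.DataFrame:
    cols = ["donor_id", "aa_seq", "v_gene", "j_gene", "freq_aim_pos",
            "freq_aim_neg", "templates_aim_pos", "templates_aim_neg",
            "odds_ratio", "log10_odds", "fisher_p", "fdr_q", "selected"]
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def productive_cohort(cohort: Mapping[tuple[str, str], Repertoire]) -> dict:
    return {k: filter_productive(rep) for k, rep in cohort.items()}


@dataclass
class SelectionResult:
    threshold: float
    enrichment: pd.DataFrame          # all candidates, all donors
    selected: pd.DataFrame            # selected rows only
    vgene_usage: pd.DataFrame
    vgene_report: pd.DataFrame | None


def run_selection(
    cohort: Mapping[tuple[str, str], Repertoire],
    rounding: str = "none",
    or_min_log10: float = 1.0,
    q_max: float = 0.01,
) -> SelectionResult:
    """Threshold derivation + per-donor clone enrichment + V-gene usage."""
    donors = _donors(cohort)
    neg_reps = [cohort[(d, AIM_NEG)] for d in donors]
    threshold = enrichment.derive_global_threshold(neg_reps, rounding=rounding)
    tables, usages = [], []
    for d in donors:
        res = enrichment.clone_enrichment_test(
            cohort[(d, AIM_POS)], cohort[(d, AIM_NEG)], threshold,
            or_min_log10=or_min_log10, q_max=q_max)
        tables.append(res)
        sel = res[res["selected"]]
        if len(sel):
            usages.append(enrichment.vgene_usage_odds(sel, cohort[(d, AIM_NEG)]))
    tables = [t for t in tables if len(t)]
    enr = pd.concat(tables, ignore_index=True) if tables else _empty_enrichment()
    usage = pd.concat(usages, ignore_index=True) if usages else pd.DataFrame()
    report = None
    if len(usage) and usage["donor_id"].nunique() >= 2:
        report = enrichment.cross_donor_usage_test(usage)
    selected = enr[enr["selected"]].reset_index(drop=True) if len(enr) else enr
    return SelectionResult(threshold=threshold, enrichment=enr, selected=selected,
                           vgene_usage=usage, vgene_report=report)


def run_tracking(
    cohort: Mapping[tuple[str, str], Repertoire],
    selected: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Trace selected clones into naive/TCM/TEM; per-donor overlap summary."""
    frames = []
    for d in _donors(cohort):
        sel_d = selected[selected["donor_id"] == d]
        if len(sel_d) == 0:
            continue
        frames.append(tracking.track_clones(
            sel_d, cohort[(d, NAIVE)], cohort[(d, TCM)], cohort[(d, TEM)]))
    if not frames:
        raise ConfigurationError("no selected clones to track")
    tracked = pd.concat(frames, ignore_index=True)
    per_donor, summary = tracking.overlap_fractions(tracked)
    return tracked, per_donor, summary


@dataclass
class MotifResult:
    sample: pd.DataFrame                      # pooled AIM+/AIM- motif sample
    groups: list = field(repr=False)          # all specificity groups
    group_table: pd.DataFrame = None
    apob_motifs: pd.DataFrame = None
    affiliations: list = field(default_factory=list)
    affiliation_table: pd.DataFrame = None
    exvivo_sample: pd.DataFrame = None
    sharing: net.SharingNetwork = None
    public: pd.DataFrame = None
    public_freqs: pd.DataFrame = None


def run_motif_discovery(
    cohort: Mapping[tuple[str, str], Repertoire],
    reference: mo.ReferenceSet,
    seed: int = 0,
    head: int = 3,
    tail: int = 2,
    n_perm: int = 1000,
    ref_p_max: float = 0.05,
    expansion_p_max: float = 0.05,
    log2_fold_min: float = 2.0,
    neg_log10_p_min: float = 5.0,
    min_unique: int = 2,
) -> MotifResult:
    """Discovery funnel on the pooled reactive/non-reactive sample.

    groups (>= 2 distinct members) -> reference-enriched (Fisher p <
    ``ref_p_max``) -> expansion-significant (permutation p <
    ``expansion_p_max``) -> reactive motif cut (fold + rate test).
    """
    donors = _donors(cohort)
    aim_reps = [cohort[(d, c)] for d in donors for c in (AIM_POS, AIM_NEG)]
    sample = mo.build_motif_sample(aim_reps, head=head, tail=tail)
    n_sample_cdr3s = int(sample[["aa_seq", "trimmed"]].drop_duplicates().shape[0])

    local = mo.local_motif_enrichment(sample, reference, min_unique=3)
    glob = mo.global_convergence(sample, min_unique=min_unique)
    groups = mo.build_specificity_groups(local, glob, sample, min_unique=min_unique)

    for g in groups:
        g.fisher_ref_p = mo.reference_enrichment_test(g, n_sample_cdr3s, reference)
    enriched = [g for g in groups if g.fisher_ref_p < ref_p_max]

    clonotypes = mo.dataset_clonotypes(sample)
    scorer = mo.ExpansionScorer(clonotypes, n_perm=n_perm, seed=seed)
    for g in enriched:
        g.expansion_p = scorer.score(sample.iloc[g.member_index]["aa_seq"])
    expanded = [g for g in enriched if g.expansion_p < expansion_p_max]

    totals = sample.groupby("compartment")["templates"].sum().to_dict()
    scored = net.score_groups(expanded, sample, AIM_POS, AIM_NEG, totals)
    apob = net.select_apob_motifs(
        scored, log2_fold_min=log2_fold_min,
        neg_log10_p_min=neg_log10_p_min, expansion_p_max=expansion_p_max)

    group_table = pd.DataFrame([{
        "pattern": g.motif.pattern, "kind": g.motif.kind,
        "n_unique_cdr3": g.n_unique_cdr3,
        "fisher_ref_p": g.fisher_ref_p, "expansion_p": g.expansion_p,
    } for g in groups])
    return MotifResult(sample=sample, groups=groups, group_table=group_table,
                       apob_motifs=apob)


def run_affiliation_and_network(
    result: MotifResult,
    cohort: Mapping[tuple[str, str], Repertoire],
    head: int = 3,
    tail: int = 2,
    donor_min_fraction: float = 0.8,
) -> MotifResult:
    """Classify reactive motifs ex vivo, build the sharing network, call public motifs."""
    donors = _donors(cohort)
    exvivo_reps = [cohort[(d, c)] for d in donors for c in (NAIVE, TCM, TEM)]
    affs, exvivo = net.classify_affiliation(result.apob_motifs, exvivo_reps,
                                            head=head, tail=tail)
    result.affiliations = affs
    result.affiliation_table = net.affiliation_table(affs)
    result.exvivo_sample = exvivo
    mem = [a for a in affs if net.is_memory_affiliated(a)]
    result.sharing = net.build_sharing_network(mem, exvivo)
    result.public, result.public_freqs = net.public_motifs(
        mem, exvivo, n_donors=len(donors), donor_min_fraction=donor_min_fraction)
    return result


def run_full_analysis(
    cohort: Mapping[tuple[str, str], Repertoire],
    reference: mo.ReferenceSet,
    seed: int = 0,
    rounding: str = "none",
    **motif_kwargs,
) -> tuple[SelectionResult, pd.DataFrame, pd.DataFrame, dict, MotifResult]:
    """Full chain on a productive-filtered cohort.

    Returns (selection, tracking table, per-donor overlap, overlap summary,
    motif result).
    """
    cohort = productive_cohort(cohort)
    selection = run_selection(cohort, rounding=rounding)
    tracked, per_donor, summary = run_tracking(cohort, selection.selected)
    motif = run_motif_discovery(cohort, reference, seed=seed, **motif_kwargs)
    motif = run_affiliation_and_network(motif, cohort)
    return selection, tracked, per_donor, summary, motif
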