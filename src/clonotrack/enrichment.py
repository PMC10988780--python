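"""Selection of antigen-reactive clones and V-gene usage preferences.

The selection chain mirrors the enrichment logic of an AIM-sorted paired
design: (1) a global clonal-frequency threshold is derived from the
non-reactive compartments — the smallest per-donor maximum AIM- clonotype
frequency, i.e. the largest cutoff that prunes every AIM- clone in at least
one donor; (2) AIM+ clonotypes above the threshold are tested clone-by-clone
with a two-sided Fisher exact test on template counts (AIM+ vs AIM-), with
Benjamini-Hochberg adjustment within donor, and kept when
log10(odds ratio) >= 1 and FDR-adjusted p < 0.01; (3) V-gene usage odds
ratios compare selected clones against the donor's non-reactive clonotypes.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, EmptyRepertoireError
from .io import Repertoire, aggregate_clonotypes

DEFAULT_BINS: tuple[tuple[int, float], ...] = ((1, 10), (11, math.inf))


def copy_number_spectrum(
    clonotypes: pd.DataFrame,
    bins: Sequence[tuple[int, float]] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Fraction of unique clonotypes per copy-number bin (bins are inclusive).

    The default bins reproduce the usual expanded/non-expanded dichotomy:
    1-10 copies versus more than 10 copies.
    """
    t = clonotypes["templates"].to_numpy()
    rows = []
    for lo, hi in bins:
        n = int(((t >= lo) & (t <= hi)).sum())
        label = f"{lo}-{int(hi)}" if math.isfinite(hi) else f">{lo - 1}"
        rows.append({"bin": label, "n_clonotypes": n, "fraction": n / len(t)})
    return pd.DataFrame(rows)


def round_up_sig3(x: float) -> float:
    """Round a positive number up to three significant digits (1.387e-3 -> 1.39e-3)."""
    if x <= 0:
        raise ConfigurationError("sig3_up rounding needs a positive value")
    exp = math.floor(math.log10(x))
    scale = 10.0 ** (exp - 2)
    return float(math.ceil(round(x / scale, 9)) * scale)


def derive_global_threshold(
    aim_neg_reps: Iterable[Repertoire],
    rounding: str = "none",
) -> float:
    """Largest frequency cutoff that removes all AIM- clones in at least one donor.

    This is the minimum over donors of the maximum AIM- clonotype frequency.
    Downstream selection applies a strict ``>``; with ``rounding="sig3_up"``
    the value is rounded up to three significant digits before use.
    """
    maxima = []
    for rep in aim_neg_reps:
        if rep.n_records == 0:
            raise EmptyRepertoireError(f"{rep.donor_id}/{rep.compartment}: empty AIM- repertoire")
        agg = aggregate_clonotypes(rep, key="aa")
        maxima.append(float(agg["frequency"].max()))
    if not maxima:
        raise EmptyRepertoireError("no AIM- repertoires supplied")
    threshold = min(maxima)
    if rounding == "sig3_up":
        threshold = round_up_sig3(threshold)
    elif rounding != "none":
        raise ConfigurationError(f"unknown rounding mode {rounding!r}")
    return threshold


def _odds_ratio(a: float, b: float, c: float, d: float) -> float:
    # Haldane-Anscombe: +0.5 on every cell whenever any cell is zero,
    # so log odds stay finite.
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def clone_enrichment_test(
    aim_pos: Repertoire,
    aim_neg: Repertoire,
    threshold: float,
    or_min_log10: float = 1.0,
    q_max: float = 0.01,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-clone AIM+ vs AIM- contingency testing above the frequency threshold.

    Candidates are AIM+ clonotypes with frequency strictly above ``threshold``.
    Each candidate's 2x2 table is [templates in AIM+, templates in AIM-;
    remaining AIM+ templates, remaining AIM- templates]; ``selected`` requires
    log10 odds >= ``or_min_log10`` and BH-adjusted Fisher p < ``q_max``
    (adjustment spans the donor's candidate set only).
    """
    if threshold <= 0:
        raise ConfigurationError("frequency threshold must be positive")
    pos = aggregate_clonotypes(aim_pos, key="aa")
    neg = aggregate_clonotypes(aim_neg, key="aa")
    total_pos = int(pos["templates"].sum())
    total_neg = int(neg["templates"].sum())
    neg_counts = dict(zip(neg["aa_seq"], neg["templates"]))

    cand = pos[pos["frequency"] > threshold].reset_index(drop=True)
    rows = []
    for r in cand.itertuples(index=False):
        a = int(r.templates)
        b = int(neg_counts.get(r.aa_seq, 0))
        c, d = total_pos - a, total_neg - b
        orr = _odds_ratio(a, b, c, d)
        p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative).pvalue
        rows.append({
            "donor_id": aim_pos.donor_id, "aa_seq": r.aa_seq,
            "v_gene": r.v_gene, "j_gene": r.j_gene,
            "freq_aim_pos": a / total_pos, "freq_aim_neg": b / total_neg,
            "templates_aim_pos": a, "templates_aim_neg": b,
            "odds_ratio": orr, "log10_odds": math.log10(orr), "fisher_p": float(p),
        })
    out = pd.DataFrame(rows, columns=[
        "donor_id", "aa_seq", "v_gene", "j_gene", "freq_aim_pos", "freq_aim_neg",
        "templates_aim_pos", "templates_aim_neg", "odds_ratio", "log10_odds",
        "fisher_p",
    ])
    if len(out):
        out["fdr_q"] = multipletests(out["fisher_p"], method="fdr_bh")[1]
        out["selected"] = (out["log10_odds"] >= or_min_log10) & (out["fdr_q"] < q_max)
    else:
        out["fdr_q"] = pd.Series(dtype=float)
        out["selected"] = pd.Series(dtype=bool)
    return out


def vgene_usage_odds(selected: pd.DataFrame, control: Repertoire) -> pd.DataFrame:
    """Per-V-gene odds ratio of usage in selected clones vs control clonotypes.

    OR = (V+ in selected / V+ in control) / (V- in selected / V- in control),
    computed on unique clonotypes, with +0.5 on all four counts when any is
    zero. ``selected`` must be non-empty and carry normalised ``v_gene``.
    """
    if len(selected) == 0:
        raise EmptyRepertoireError("no selected clones supplied for V-gene analysis")
    ctrl = aggregate_clonotypes(control, key="aa")
    donor = selected["donor_id"].iloc[0]
    n_sel, n_ctrl = len(selected), len(ctrl)
    sel_counts = selected["v_gene"].value_counts()
    ctrl_counts = ctrl["v_gene"].value_counts()
    genes = sorted(set(sel_counts.index) | set(ctrl_counts.index))
    rows = []
    for g in genes:
        a = int(sel_counts.get(g, 0))        # V+ in selected
        b = int(ctrl_counts.get(g, 0))       # V+ in control
        c, d = n_sel - a, n_ctrl - b         # V- counts
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) / (b + 0.5)) / ((c + 0.5) / (d + 0.5))
        else:
            orr = (a / b) / (c / d)
        rows.append({
            "donor_id": donor, "v_gene": g,
            "count_pos_with": a, "count_pos_without": c,
            "count_neg_with": b, "count_neg_without": d,
            "odds_ratio": orr,
            "freq_in_selected": a / n_sel, "freq_in_control": b / n_ctrl,
        })
    return pd.DataFrame(rows)


def cross_donor_usage_test(
    usages: pd.DataFrame,
    min_donors_preferred: int = 5,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Cohort-level V-gene preference report.

    Genes with OR > 1 in at least ``min_donors_preferred`` donors are tested
    with a two-sided Mann-Whitney comparison of per-donor usage frequencies
    (selected vs control); ``flagged`` marks genes passing both the donor
    count and ``p < p_max``.
    """
    donors = usages["donor_id"].unique()
    if len(donors) < 2:
        raise ConfigurationError("cross-donor test needs at least two donors")
    rows = []
    for g, sub in usages.groupby("v_gene", sort=True):
        n_pref = int((sub["odds_ratio"] > 1).sum())
        fs = sub["freq_in_selected"].to_numpy()
        fc = sub["freq_in_control"].to_numpy()
        if np.all(fs == fc):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(fs, fc, alternative="two-sided").pvalue)
        rows.append({
            "v_gene": g, "n_donors": len(sub), "n_donors_or_gt1": n_pref,
            "mean_freq_selected": float(fs.mean()), "mean_freq_control": float(fc.mean()),
            "mannwhitney_p": p,
            "flagged": (n_pref >= min_donors_preferred) and (p < p_max),
        })
    return pd.DataFrame(rows)
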