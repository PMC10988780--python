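"""Scoring pipeline output against simulation ground truth.

These helpers quantify how well the inference chain recovers what the
synthetic-cohort generator planted: clone-selection sensitivity and observed
false discovery rate, agreement of lineage-tracking flags, recovery of
planted motif families by discovered reactive motifs, and agreement of
memory-affiliation and public-motif calls.

A discovered motif is matched to a planted family when at least two of the
family's member CDR3s are members of the motif's specificity group — pattern
strings are not compared directly, since a family can legitimately surface
as a longer or shorter pattern covering the same clones.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .simulate import GroundTruth


def clone_selection_metrics(selected: pd.DataFrame, truth: GroundTruth) -> dict:
    """Sensitivity and observed FDR of clone selection vs planted reactive clones."""
    truth_keys = set(zip(truth.clones["donor_id"], truth.clones["aa_seq"]))
    sel_keys = (set(zip(selected["donor_id"], selected["aa_seq"]))
                if len(selected) else set())
    tp = len(sel_keys & truth_keys)
    return {
        "n_truth": len(truth_keys),
        "n_selected": len(sel_keys),
        "sensitivity": tp / len(truth_keys) if truth_keys else float("nan"),
        "fdr": (len(sel_keys) - tp) / len(sel_keys) if sel_keys else 0.0,
    }


def tracking_agreement(tracked: pd.DataFrame, truth: GroundTruth) -> dict:
    """Fraction of tracked planted clones whose naive/TCM/TEM flags equal the truth."""
    t = truth.clones.set_index(["donor_id", "aa_seq"])
    merged = tracked.set_index(["donor_id", "aa_seq"]).join(
        t[["in_naive", "in_tcm", "in_tem"]], how="inner", rsuffix="_truth")
    if len(merged) == 0:
        return {"n_compared": 0, "agreement": float("nan"), "exact": False}
    ok = ((merged["in_naive"] == merged["in_naive_truth"])
          & (merged["in_tcm"] == merged["in_tcm_truth"])
          & (merged["in_tem"] == merged["in_tem_truth"]))
    return {"n_compared": int(len(merged)), "agreement": float(ok.mean()),
            "exact": bool(ok.all())}


def group_member_sets(groups: Sequence, sample: pd.DataFrame) -> dict[str, set]:
    """pattern -> set of member CDR3 amino-acid sequences."""
    aa = sample["aa_seq"].to_numpy()
    return {g.motif.pattern: set(aa[g.member_index]) for g in groups}


def match_motifs_to_families(
    patterns: Sequence[str],
    member_sets: Mapping[str, set],
    truth: GroundTruth,
    min_shared: int = 2,
) -> tuple[dict[int, list[str]], list[str]]:
    """Map discovered motif patterns onto planted families by member overlap.

    Returns (family_id -> matching patterns, patterns matching no family).
    """
    fam_members = {
        int(fid): set(sub["aa_seq"])
        for fid, sub in truth.motif_members.groupby("family_id")
    }
    matched: dict[int, list[str]] = {fid: [] for fid in fam_members}
    unmatched: list[str] = []
    for pat in patterns:
        members = member_sets.get(pat, set())
        hit = False
        for fid, fam in fam_members.items():
            if len(members & fam) >= min_shared:
                matched[fid].append(pat)
                hit = True
        if not hit:
            unmatched.append(pat)
    return matched, unmatched


def motif_recovery(
    apob_patterns: Sequence[str],
    member_sets: Mapping[str, set],
    truth: GroundTruth,
) -> dict:
    """Fraction of planted families surfaced by at least one reactive motif."""
    matched, unmatched = match_motifs_to_families(apob_patterns, member_sets, truth)
    n_fam = len(matched)
    n_rec = sum(1 for pats in matched.values() if pats)
    return {
        "n_families": n_fam,
        "n_recovered": n_rec,
        "recovery": n_rec / n_fam if n_fam else float("nan"),
        "n_unmatched_motifs": len(unmatched),
        "matched": matched,
    }


def memory_affiliation_agreement(
    affiliation: pd.DataFrame,
    matched: Mapping[int, list[str]],
    truth: GroundTruth,
) -> dict:
    """Agreement of motif memory-affiliation calls with the planted truth.

    A family is predicted memory-affiliated when any of its matched reactive
    motifs is; comparison is restricted to recovered families.
    """
    flag = dict(zip(affiliation["pattern"], affiliation["memory_affiliated"]))
    truth_flag = dict(zip(truth.motifs["family_id"].astype(int),
                          truth.motifs["memory_affiliated"]))
    n, agree = 0, 0
    for fid, pats in matched.items():
        if not pats:
            continue
        predicted = any(bool(flag.get(p, False)) for p in pats)
        n += 1
        agree += int(predicted == bool(truth_flag[fid]))
    return {"n_compared": n, "agreement": agree / n if n else float("nan"),
            "exact": agree == n and n > 0}


def public_call_agreement(
    public: pd.DataFrame,
    matched: Mapping[int, list[str]],
    truth: GroundTruth,
    n_donors: int,
    donor_min_fraction: float = 0.8,
) -> dict:
    """Exact agreement of public-motif calls with the planted donor spans."""
    public_patterns = set(public["pattern"]) if len(public) else set()
    truth_public = {
        int(r.family_id)
        for r in truth.motifs.itertuples(index=False)
        if r.n_donors_memory > donor_min_fraction * n_donors
    }
    predicted_public = {
        fid for fid, pats in matched.items()
        if any(p in public_patterns for p in pats)
    }
    fam_patterns = {p for pats in matched.values() for p in pats}
    extra = sorted(public_patterns - fam_patterns)
    return {
        "truth_public": sorted(truth_public),
        "predicted_public": sorted(predicted_public),
        "n_extra_public_motifs": len(extra),
        "exact": predicted_public == truth_public and not extra,
    }
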