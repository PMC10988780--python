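"""Tracing selected reactive clones through unenriched naive/TCM/TEM repertoires.

Matching is exact on the clonotype key (amino-acid CDR3 by default, the key
under which T cells are tracked across samples; optionally CDR3 + V gene).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, EmptyRepertoireError
from .io import Repertoire, aggregate_clonotypes

TCM_ONLY = "TCM_ONLY"
TEM_ONLY = "TEM_ONLY"
BOTH = "BOTH"
NONE = "NONE"


def _clonotype_counts(rep: Repertoire, key: str) -> dict:
    agg = aggregate_clonotypes(rep, key=key)
    if key == "aa":
        return dict(zip(agg["aa_seq"], agg["templates"]))
    return dict(zip(zip(agg["aa_seq"], agg["v_gene"]), agg["templates"]))


def track_clones(
    selected: pd.DataFrame,
    naive: Repertoire,
    tcm: Repertoire,
    tem: Repertoire,
    key: str = "aa",
) -> pd.DataFrame:
    """Exact-match presence and memory copy numbers for each selected clone.

    ``selected`` needs columns ``donor_id, aa_seq`` (and ``v_gene`` for the
    ``aa_v`` key). Memory copy number of a clone is its summed template count
    over TCM and TEM. ``memory_partition`` is one of TCM_ONLY / TEM_ONLY /
    BOTH / NONE.
    """
    if key not in ("aa", "aa_v"):
        raise ConfigurationError(f"unknown tracking key {key!r}")
    lookups = {name: _clonotype_counts(rep, key)
               for name, rep in (("naive", naive), ("tcm", tcm), ("tem", tem))}
    rows = []
    for r in selected.itertuples(index=False):
        k = r.aa_seq if key == "aa" else (r.aa_seq, r.v_gene)
        t_naive = int(lookups["naive"].get(k, 0))
        t_tcm = int(lookups["tcm"].get(k, 0))
        t_tem = int(lookups["tem"].get(k, 0))
        if t_tcm and t_tem:
            part = BOTH
        elif t_tcm:
            part = TCM_ONLY
        elif t_tem:
            part = TEM_ONLY
        else:
            part = NONE
        rows.append({
            "donor_id": r.donor_id, "aa_seq": r.aa_seq,
            "in_naive": t_naive > 0, "in_tcm": t_tcm > 0, "in_tem": t_tem > 0,
            "templates_naive": t_naive, "templates_tcm": t_tcm, "templates_tem": t_tem,
            "memory_templates": t_tcm + t_tem, "memory_partition": part,
        })
    return pd.DataFrame(rows, columns=[
        "donor_id", "aa_seq", "in_naive", "in_tcm", "in_tem",
        "templates_naive", "templates_tcm", "templates_tem",
        "memory_templates", "memory_partition",
    ])


def overlap_fractions(tracking: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-donor percentages of selected clones found in naive vs memory pools.

    Returns the per-donor table and a cohort summary with means, SEMs and a
    two-sided Mann-Whitney p comparing the per-donor naive and memory
    percentages (NaN with fewer than two donors).
    """
    if len(tracking) == 0:
        raise EmptyRepertoireError("tracking table is empty")
    per_donor = tracking.groupby("donor_id", sort=True).agg(
        n_selected=("aa_seq", "size"),
        pct_naive=("in_naive", lambda s: 100.0 * s.mean()),
    )
    mem = tracking.assign(in_memory=tracking["in_tcm"] | tracking["in_tem"])
    per_donor["pct_memory"] = mem.groupby("donor_id", sort=True)["in_memory"].mean() * 100.0
    per_donor = per_donor.reset_index()

    nv = per_donor["pct_naive"].to_numpy()
    me = per_donor["pct_memory"].to_numpy()
    n = len(per_donor)
    if n >= 2 and not np.all(nv == me):
        p = float(stats.mannwhitneyu(nv, me, alternative="two-sided").pvalue)
    elif n >= 2:
        p = 1.0
    else:
        p = math.nan
    summary = {
        "mean_pct_naive": float(nv.mean()), "sem_pct_naive": float(nv.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan,
        "mean_pct_memory": float(me.mean()), "sem_pct_memory": float(me.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan,
        "mannwhitney_p": p,
    }
    return per_donor, summary


def memory_expansion_summary(tracking: pd.DataFrame, copies_cutoff: int = 6) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expanded fraction of memory-affiliated clones per donor, plus a top-clone table.

    A memory-affiliated clone is expanded when its summed memory copy number
    exceeds one; the top-clone table lists clones with memory copies strictly
    above ``copies_cutoff`` (default >6), ranked by copy number.
    """
    mem = tracking[tracking["memory_templates"] > 0]
    if len(mem) == 0:
        raise EmptyRepertoireError("no memory-affiliated clones to summarise")
    frac = mem.groupby("donor_id", sort=True).agg(
        n_memory_clones=("aa_seq", "size"),
        expanded_fraction=("memory_templates", lambda s: float((s > 1).mean())),
    ).reset_index()
    top = mem[mem["memory_templates"] > copies_cutoff].sort_values(
        ["memory_templates", "aa_seq"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return frac, top


def clone_publicity(selected_by_donor: dict[str, set], key: str = "aa") -> pd.DataFrame:
    """Public/private labels: a clone is public iff selected in >= 2 donors."""
    if len(selected_by_donor) < 2:
        raise ConfigurationError("publicity needs at least two donors")
    counts: dict = {}
    for donor, keys in sorted(selected_by_donor.items()):
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
    rows = [{"clone_key": k, "n_donors": n, "public": n >= 2}
            for k, n in sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))]
    return pd.DataFrame(rows, columns=["clone_key", "n_donors", "public"])
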