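"""AIM+ motif calling, ex-vivo affiliation, cross-donor sharing and public motifs.

A discovered specificity group becomes an antigen-reactive (APOB+ style)
motif when its members are clonally expanded (permutation expansion p <
0.05) and their summed template rate in the reactive compartment exceeds the
non-reactive compartment by at least log2 fold 2 with an exact two-rate
"Poisson" comparison p <= 1e-5. The rate test conditions on the total count:
with n = c_A + c_B events and exposures T_A, T_B, c_A ~ Binomial(n,
T_A/(T_A+T_B)) under equal rates — the standard exact two-rate Poisson
comparison.

Reactive motifs are then assigned to ex-vivo naive/TCM/TEM CDR3s by pattern
matching (no re-clustering: the motif set is held fixed), classified as
naive-only / memory-only / both / absent, and memory-affiliated motifs are
wired into a donor x subset sharing network whose most widely shared members
are the public motifs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, EmptyRepertoireError
from .io import NAIVE, TCM, TEM, Repertoire, write_table
from .motifs import (
    GLOBAL, LOCAL, MotifPattern, SpecificityGroup, build_motif_sample,
)

NAIVE_ONLY = "NAIVE_ONLY"
MEMORY_ONLY = "MEMORY_ONLY"
BOTH = "BOTH"
ABSENT = "ABSENT"


def motif_fold_and_poisson(
    count_a: int, count_b: int, total_a: int, total_b: int,
) -> tuple[float, float]:
    """log2 rate fold (A over B) and exact conditional-binomial rate-comparison p.

    A pseudo-rate eps = 1/max(total_a, total_b) keeps the fold finite when one
    side has no counts. A group with no counts on either side is degenerate:
    fold 0, p 1.
    """
    if total_a <= 0 or total_b <= 0:
        raise ConfigurationError("compartment totals must be positive")
    n = count_a + count_b
    if n == 0:
        return 0.0, 1.0
    eps = 1.0 / max(total_a, total_b)
    rate_a, rate_b = count_a / total_a, count_b / total_b
    log2_fold = math.log2((rate_a + eps) / (rate_b + eps))
    p_null = total_a / (total_a + total_b)
    p = stats.binomtest(count_a, n, p_null, alternative="two-sided").pvalue
    return float(log2_fold), float(min(p, 1.0))


def score_groups(
    groups: Sequence[SpecificityGroup],
    sample: pd.DataFrame,
    compartment_a: str,
    compartment_b: str,
    totals: Mapping[str, int],
) -> pd.DataFrame:
    """Fold and rate-test for every group between two compartments of the sample."""
    comp = sample["compartment"].to_numpy()
    templates = sample["templates"].to_numpy()
    in_a, in_b = comp == compartment_a, comp == compartment_b
    rows = []
    for g in groups:
        m = g.member_index
        c_a = int(templates[m[in_a[m]]].sum())
        c_b = int(templates[m[in_b[m]]].sum())
        fold, p = motif_fold_and_poisson(c_a, c_b, totals[compartment_a], totals[compartment_b])
        rows.append({
            "pattern": g.motif.pattern, "kind": g.motif.kind,
            "n_unique_cdr3": g.n_unique_cdr3,
            "sum_templates_a": c_a, "sum_templates_b": c_b,
            "log2_fold": fold, "poisson_p": p,
            "fisher_ref_p": g.fisher_ref_p, "expansion_p": g.expansion_p,
        })
    return pd.DataFrame(rows, columns=[
        "pattern", "kind", "n_unique_cdr3", "sum_templates_a", "sum_templates_b",
        "log2_fold", "poisson_p", "fisher_ref_p", "expansion_p",
    ])


def select_apob_motifs(
    scored: pd.DataFrame,
    log2_fold_min: float = 2.0,
    neg_log10_p_min: float = 5.0,
    expansion_p_max: float = 0.05,
) -> pd.DataFrame:
    """Reactive-direction motif cut: expansion-significant groups with
    log2 fold >= ``log2_fold_min`` toward compartment A and
    -log10(rate p) >= ``neg_log10_p_min``."""
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(scored["poisson_p"].to_numpy())
    keep = (
        (scored["expansion_p"] < expansion_p_max)
        & (scored["log2_fold"] >= log2_fold_min)
        & (neg_log10 >= neg_log10_p_min)
    )
    return scored[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# ex-vivo affiliation


def _match_exvivo(pattern: str, kind: str, exvivo: pd.DataFrame) -> np.ndarray:
    """Row mask of ex-vivo sample rows whose trimmed interior matches the motif."""
    trimmed = exvivo["trimmed"]
    if kind == LOCAL:
        return trimmed.str.contains(pattern, regex=False).to_numpy()
    rx = "".join("." if c == "%" else c for c in pattern)
    return trimmed.str.fullmatch(rx).to_numpy()


@dataclass
class MotifAffiliation:
    """Where an antigen-reactive motif lives in the unenriched repertoire."""

    pattern: str
    kind: str
    category: str              # NAIVE_ONLY / MEMORY_ONLY / BOTH / ABSENT
    memory_enriched: bool
    memory_log2_fold: float
    memory_poisson_p: float
    subset_detail: str         # TCM_ONLY / TEM_ONLY / BOTH / NA
    donors_memory: tuple[str, ...]
    match_index: np.ndarray = field(repr=False)  # rows of the ex-vivo sample


def classify_affiliation(
    apob_motifs: pd.DataFrame,
    exvivo_reps: Iterable[Repertoire],
    head: int = 3,
    tail: int = 2,
    mem_log2_fold_min: float = 1.0,
    mem_p_max: float = 0.05,
) -> tuple[list[MotifAffiliation], pd.DataFrame]:
    """Assign ex-vivo CDR3s to the fixed reactive-motif set and classify each motif.

    A motif found only among memory CDR3s is memory-affiliated by definition;
    one found in both pools is memory-affiliated when its memory-vs-naive
    template rates pass |log2 fold| >= ``mem_log2_fold_min`` in the memory
    direction with rate-test p < ``mem_p_max``. Trimming offsets must equal
    those used at discovery.
    """
    exvivo = build_motif_sample(exvivo_reps, head=head, tail=tail)
    totals = exvivo.groupby("compartment")["templates"].sum().to_dict()
    t_mem = int(totals.get(TCM, 0) + totals.get(TEM, 0))
    t_naive = int(totals.get(NAIVE, 0))
    comp = exvivo["compartment"].to_numpy()
    templates = exvivo["templates"].to_numpy()
    donors = exvivo["donor_id"].to_numpy()

    out: list[MotifAffiliation] = []
    for r in apob_motifs.itertuples(index=False):
        mask = _match_exvivo(r.pattern, r.kind, exvivo)
        idx = np.flatnonzero(mask)
        in_naive = comp[idx] == NAIVE
        in_tcm = comp[idx] == TCM
        in_tem = comp[idx] == TEM
        has_naive = bool(in_naive.any())
        has_mem = bool(in_tcm.any() or in_tem.any())
        if not has_naive and not has_mem:
            category, enriched, fold, p = ABSENT, False, math.nan, math.nan
        elif has_naive and not has_mem:
            category, enriched, fold, p = NAIVE_ONLY, False, math.nan, math.nan
        elif has_mem and not has_naive:
            category, enriched, fold, p = MEMORY_ONLY, False, math.nan, math.nan
        else:
            category = BOTH
            c_mem = int(templates[idx[in_tcm | in_tem]].sum())
            c_naive = int(templates[idx[in_naive]].sum())
            fold, p = motif_fold_and_poisson(c_mem, c_naive, t_mem, t_naive)
            enriched = (fold >= mem_log2_fold_min) and (p < mem_p_max)
        if has_mem:
            detail = ("BOTH" if (in_tcm.any() and in_tem.any())
                      else ("TCM_ONLY" if in_tcm.any() else "TEM_ONLY"))
            donors_mem = tuple(sorted(set(donors[idx[in_tcm | in_tem]])))
        else:
            detail, donors_mem = "NA", ()
        out.append(MotifAffiliation(
            pattern=r.pattern, kind=r.kind, category=category,
            memory_enriched=enriched, memory_log2_fold=fold, memory_poisson_p=p,
            subset_detail=detail, donors_memory=donors_mem, match_index=idx,
        ))
    return out, exvivo


def is_memory_affiliated(aff: MotifAffiliation) -> bool:
    return aff.category == MEMORY_ONLY or (aff.category == BOTH and aff.memory_enriched)


def affiliation_table(affiliations: Sequence[MotifAffiliation]) -> pd.DataFrame:
    rows = [{
        "pattern": a.pattern, "kind": a.kind, "category": a.category,
        "memory_enriched": a.memory_enriched,
        "memory_log2_fold": a.memory_log2_fold, "memory_poisson_p": a.memory_poisson_p,
        "subset_detail": a.subset_detail,
        "donors_memory": ",".join(a.donors_memory),
        "n_donors_memory": len(a.donors_memory),
        "memory_affiliated": is_memory_affiliated(a),
    } for a in affiliations]
    return pd.DataFrame(rows, columns=[
        "pattern", "kind", "category", "memory_enriched", "memory_log2_fold",
        "memory_poisson_p", "subset_detail", "donors_memory", "n_donors_memory",
        "memory_affiliated",
    ])


# ---------------------------------------------------------------------------
# sharing network


@dataclass
class SharingNetwork:
    """Donor x memory-subset nodes connected by shared motifs.

    ``graph``: networkx Graph with edge attribute ``weight`` (number of
    distinct shared motifs) and ``motifs`` (sorted tuple of their patterns);
    ``connections``: per-motif table of the node set it spans.
    """

    graph: nx.Graph
    connections: pd.DataFrame

    def edge_table(self) -> pd.DataFrame:
        rows = [{"node_a": a, "node_b": b, "weight": d["weight"],
                 "motifs": ";".join(d["motifs"])}
                for a, b, d in sorted(self.graph.edges(data=True))]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "motifs"])

    def write_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        for _, _, d in g.edges(data=True):
            d["motifs"] = ";".join(d["motifs"])
        nx.write_graphml(g, path)


def build_sharing_network(
    memory_affiliated: Sequence[MotifAffiliation],
    exvivo: pd.DataFrame,
) -> SharingNetwork:
    """Connect (donor, TCM/TEM) nodes that share memory-matching motifs.

    A motif's connection is the set of nodes holding >= 1 matching CDR3;
    connections of size one carry no edge but stay in the per-motif table.
    """
    comp = exvivo["compartment"].to_numpy()
    donors = exvivo["donor_id"].to_numpy()
    graph = nx.Graph()
    conn_rows = []
    edge_motifs: dict[tuple[str, str], list[str]] = {}
    for aff in memory_affiliated:
        idx = aff.match_index
        mem = idx[(comp[idx] == TCM) | (comp[idx] == TEM)]
        nodes = sorted({f"{d}_{c}" for d, c in zip(donors[mem], comp[mem])})
        for node in nodes:
            graph.add_node(node)
        conn_rows.append({"pattern": aff.pattern, "n_nodes": len(nodes),
                          "nodes": ";".join(nodes)})
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                edge_motifs.setdefault((nodes[i], nodes[j]), []).append(aff.pattern)
    for (a, b), motifs in sorted(edge_motifs.items()):
        graph.add_edge(a, b, weight=len(motifs), motifs=tuple(sorted(motifs)))
    return SharingNetwork(
        graph=graph,
        connections=pd.DataFrame(conn_rows, columns=["pattern", "n_nodes", "nodes"]),
    )


def public_motifs(
    memory_affiliated: Sequence[MotifAffiliation],
    exvivo: pd.DataFrame,
    n_donors: int,
    donor_min_fraction: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Motifs whose memory matches span more than ``donor_min_fraction`` of donors.

    Returns the ranked public-motif table and a per-motif, per-donor,
    per-subset table of summed matching-CDR3 frequencies in the memory pool.
    """
    if n_donors < 1:
        raise ConfigurationError("n_donors must be positive")
    comp = exvivo["compartment"].to_numpy()
    donors = exvivo["donor_id"].to_numpy()
    freqs = exvivo["frequency"].to_numpy()
    pub_rows, freq_rows = [], []
    for aff in memory_affiliated:
        span = len(aff.donors_memory)
        if span <= donor_min_fraction * n_donors:
            continue
        pub_rows.append({"pattern": aff.pattern, "kind": aff.kind,
                         "n_donors_memory": span,
                         "donors_memory": ",".join(aff.donors_memory)})
        idx = aff.match_index
        mem = idx[(comp[idx] == TCM) | (comp[idx] == TEM)]
        sub = pd.DataFrame({"donor_id": donors[mem], "subset": comp[mem],
                            "frequency": freqs[mem]})
        summed = sub.groupby(["donor_id", "subset"], sort=True)["frequency"].sum().reset_index()
        summed.insert(0, "pattern", aff.pattern)
        freq_rows.append(summed)
    pub = pd.DataFrame(pub_rows, columns=["pattern", "kind", "n_donors_memory", "donors_memory"])
    pub = pub.sort_values(["n_donors_memory", "pattern"], ascending=[False, True]).reset_index(drop=True)
    per_donor = (pd.concat(freq_rows, ignore_index=True) if freq_rows
                 else pd.DataFrame(columns=["pattern", "donor_id", "subset", "frequency"]))
    return pub, per_donor


def position_frequency_matrix(
    motif: MotifPattern,
    matching_trimmed: Sequence[str],
) -> pd.DataFrame:
    """Residue x position frequency matrix of motif-matching interiors.

    GLOBAL motifs align sequences directly (equal length by construction);
    LOCAL motifs anchor each sequence at its first motif occurrence, so
    position 0 is the motif start and flanking positions may be covered by a
    subset of sequences. Every covered column sums to one.
    """
    seqs = list(matching_trimmed)
    if not seqs:
        raise EmptyRepertoireError("no matching CDR3s for the position frequency matrix")
    if motif.kind == GLOBAL:
        offsets = [0] * len(seqs)
        if any(len(s) != motif.length for s in seqs):
            raise ConfigurationError("GLOBAL PFM needs equal-length matches")
        left = 0
    else:
        starts = [s.index(motif.pattern) for s in seqs]
        left = max(starts)
        offsets = [left - st for st in starts]
    width = max(off + len(s) for off, s in zip(offsets, seqs))
    residues = sorted({c for s in seqs for c in s})
    counts = pd.DataFrame(0.0, index=residues, columns=range(-left, width - left))
    for off, s in zip(offsets, seqs):
        for i, c in enumerate(s):
            counts.loc[c, off + i - left] += 1.0
    sums = counts.sum(axis=0)
    pfm = counts.loc[:, sums > 0].div(sums[sums > 0], axis=1)
    return pfm


def write_pfm(pfm: pd.DataFrame, path: str | Path) -> None:
    out = pfm.copy()
    out.insert(0, "residue", out.index)
    write_table(out, path)
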