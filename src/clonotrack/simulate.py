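"""Synthetic paired-compartment TCRbeta cohorts with planted ground truth.

The generator emulates the structure of an activation-induced-marker (AIM)
sorting study: for each donor it emits five repertoires — antigen-reactive
AIM+, matched non-reactive AIM-, and ex-vivo naive / central-memory (TCM) /
effector-memory (TEM) compartments — as immunoSEQ-style tables plus a
ground-truth ledger of every planted reactive clone and shared motif family.

Model sketch
------------
* Background clones. Each donor owns three latent clone pools (one shared by
  AIM+/AIM-, one for naive, one shared by TCM/TEM). Pool clone weights follow
  a discrete power law (Zipf, exponent ``clone_size_shape``) so observed
  repertoires are dominated by singletons and low-copy clones with a heavy
  expanded tail. Template counts per compartment are multinomial draws from
  the pool weights, which makes AIM+ and AIM- exchangeable when nothing is
  planted — the null case used for calibration checks.
* Planted reactive clones. ``planted_clones_per_donor`` clones per donor get
  large AIM+ template counts and AIM- counts capped so the AIM+ : AIM-
  frequency ratio is at least ``planted_enrichment_fold``. With probability
  ``memory_seeding_prob`` a planted clone is also placed in TCM and/or TEM
  (split by ``tcm_tem_mix`` / ``memory_both_prob``); standalone planted
  clones may leak into naive at ``naive_leak_prob`` with one copy.
* Planted motif families. ``n_planted_families`` families share an interior
  sequence template with one wildcard position; members within and across
  donors differ only at the wildcard (and in a donor-specific C-terminal
  flank, so full clonotypes stay private to each donor). A family recurs in
  each non-owner donor with probability ``publicity_prob``. Family members
  count toward the per-donor planted clone budget.

Identical seed and config give byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import io as rio
from ._genes import (
    TRBJ_NAMES, TRBJ_WEIGHTS, TRBV_NAMES, TRBV_WEIGHTS, reverse_translate,
)
from .errors import ConfigurationError
from .io import AIM_NEG, AIM_POS, COMPARTMENTS, NAIVE, TCM, TEM, Repertoire

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_ARR = np.frombuffer(AA_ALPHABET.encode(), dtype="S1")

# Donor-specific CDR3 C-terminal flanks keep planted family members private
# at the clone level while their trimmed interiors stay comparable.
_DONOR_SUFFIXES = ["YF", "QF", "EF", "TF", "GF", "AF", "SF", "NF", "DF", "HF", "LF", "PF"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the package's reference conditions: six donors, 2e4
    productive templates per compartment, 50 planted reactive clones per
    donor at twenty-fold AIM+ enrichment, ten shared motif families with 0.6
    cross-donor publicity and 0.3 memory seeding.
    """

    n_donors: int = 6
    templates_per_compartment: Mapping[str, int] = field(
        default_factory=lambda: {c: 20000 for c in COMPARTMENTS}
    )
    clone_size_shape: float = 3.5
    n_background_clones: int = 60000
    n_memory_background_clones: int = 30000
    cdr3_length_range: tuple[int, int] = (11, 18)
    n_planted_families: int = 10
    members_per_family: int = 3
    planted_clones_per_donor: int = 50
    planted_enrichment_fold: float = 20.0
    planted_templates_range: tuple[int, int] = (80, 200)
    memory_seeding_prob: float = 0.3
    tcm_tem_mix: float = 0.5
    memory_both_prob: float = 0.2
    memory_copies_range: tuple[int, int] = (1, 16)
    publicity_prob: float = 0.6
    naive_leak_prob: float = 0.01
    reactive_v_gene: str = "TRBV15"
    reactive_v_prob: float = 0.35
    nonproductive_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "memory_seeding_prob": self.memory_seeding_prob,
            "tcm_tem_mix": self.tcm_tem_mix,
            "memory_both_prob": self.memory_both_prob,
            "publicity_prob": self.publicity_prob,
            "naive_leak_prob": self.naive_leak_prob,
            "reactive_v_prob": self.reactive_v_prob,
            "nonproductive_rate": self.nonproductive_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} is not a probability")
        if self.clone_size_shape <= 1:
            raise ConfigurationError("clone_size_shape must exceed 1")
        if self.n_donors < 1:
            raise ConfigurationError("need at least one donor")
        if self.n_donors > len(_DONOR_SUFFIXES):
            raise ConfigurationError(f"at most {len(_DONOR_SUFFIXES)} donors supported")
        lo, hi = self.cdr3_length_range
        if lo < 8 or hi < lo:
            raise ConfigurationError("cdr3_length_range must be an interval with lower bound >= 8")
        if self.planted_enrichment_fold <= 1 and self.n_planted_families + self.planted_clones_per_donor > 0:
            raise ConfigurationError("planted_enrichment_fold must exceed 1")
        for c in COMPARTMENTS:
            if self.templates_per_compartment.get(c, 0) <= 0:
                raise ConfigurationError(f"templates_per_compartment[{c}] must be positive")


@dataclass
class GroundTruth:
    """Realised planted truth, recorded from what was actually emitted.

    ``clones``: one row per planted clone and donor with its template counts
    and presence flags in every compartment. ``motifs``: one row per planted
    family with its wildcard motif, full interior pattern, donors carrying it
    and donors where it reached the memory compartment. ``motif_members``:
    (family_id, donor_id, aa_seq) member list.
    """

    clones: pd.DataFrame
    motifs: pd.DataFrame
    motif_members: pd.DataFrame


# ---------------------------------------------------------------------------
# sequence generation helpers


def _random_fixed_length(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    codes = rng.integers(0, len(AA_ALPHABET), size=(n, length))
    return _AA_ARR[codes].view(f"S{length}").ravel().astype("U")


def random_cdr3s(
    rng: np.random.Generator,
    n: int,
    length_range: tuple[int, int],
    exclude: set[str] | None = None,
) -> np.ndarray:
    """Draw ``n`` unique CDR3s: Cys + uniform interior + Phe, lengths uniform in range."""
    exclude = exclude or set()
    out: list[str] = []
    seen: set[str] = set()
    lo, hi = length_range
    while len(out) < n:
        want = n - len(out)
        lengths = rng.integers(lo, hi + 1, size=int(want * 1.1) + 8)
        for length in range(lo, hi + 1):
            k = int((lengths == length).sum())
            if k == 0:
                continue
            interiors = _random_fixed_length(rng, k, length - 2)
            for s in interiors:
                seq = "C" + s + "F"
                if seq in seen or seq in exclude:
                    continue
                seen.add(seq)
                out.append(seq)
        del lengths
    return np.array(out[:n], dtype=object)


def _draw_genes(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    v = rng.choice(TRBV_NAMES, size=n, p=TRBV_WEIGHTS)
    j = rng.choice(TRBJ_NAMES, size=n, p=TRBJ_WEIGHTS)
    return v, j


@dataclass
class _Pool:
    seqs: np.ndarray
    weights: np.ndarray  # normalised sampling probabilities
    v: np.ndarray
    j: np.ndarray


def _make_pool(rng: np.random.Generator, n_clones: int, cap: int, shape: float,
               length_range: tuple[int, int], exclude: set[str]) -> _Pool:
    seqs = random_cdr3s(rng, n_clones, length_range, exclude)
    # heavy-tailed latent clone sizes, truncated at the compartment total
    sizes = np.minimum(rng.zipf(shape, size=n_clones), cap)
    v, j = _draw_genes(rng, n_clones)
    w = sizes / sizes.sum()
    return _Pool(seqs=seqs, weights=w, v=v, j=j)


# ---------------------------------------------------------------------------


def _plan_families(cfg: SimulationConfig, rng: np.random.Generator) -> list[dict]:
    """Lay out motif families: interior template, wildcard position, donor span."""
    lo, hi = cfg.cdr3_length_range
    fam_len_lo = max(lo + 1, 12)  # interior >= 7 keeps chance matches negligible
    families = []
    for f in range(cfg.n_planted_families):
        L = int(rng.integers(fam_len_lo, hi + 1))
        il = L - 5  # "CAS" prefix (3) + 2-residue flank
        template = str(_random_fixed_length(rng, 1, il)[0])
        wpos = int(rng.integers(0, il))
        mlen = int(rng.integers(4, 7))
        start_lo = max(0, wpos - mlen + 1)
        start_hi = min(il - mlen, wpos)
        mstart = int(rng.integers(start_lo, start_hi + 1))
        interior_pattern = template[:wpos] + "%" + template[wpos + 1:]
        motif = interior_pattern[mstart:mstart + mlen]
        owner = f % cfg.n_donors
        donors = [owner] + [
            d for d in range(cfg.n_donors)
            if d != owner and rng.random() < cfg.publicity_prob
        ]
        families.append({
            "family_id": f, "length": L, "template": template, "wildcard_pos": wpos,
            "motif": motif, "interior_pattern": interior_pattern,
            "donors": sorted(donors),
        })
    return families


def _plant_donor_clones(cfg, rng, donor_idx, families) -> list[dict]:
    """Per-donor planted clone specs with compartment template counts."""
    suffix = _DONOR_SUFFIXES[donor_idx]
    lo_t, hi_t = cfg.planted_templates_range
    t_pos = cfg.templates_per_compartment[AIM_POS]
    t_neg = cfg.templates_per_compartment[AIM_NEG]
    clones: list[dict] = []

    def _counts() -> tuple[int, int]:
        a = int(rng.integers(lo_t, hi_t + 1))
        # cap AIM- copies so freq_pos / freq_neg >= fold under the configured totals
        b_max = int(np.floor(a * t_neg / (t_pos * cfg.planted_enrichment_fold)))
        b = int(rng.integers(0, b_max + 1)) if b_max >= 0 else 0
        return a, b

    def _memory() -> tuple[int, int]:
        if rng.random() >= cfg.memory_seeding_prob:
            return 0, 0
        clo, chi = cfg.memory_copies_range
        if rng.random() < cfg.memory_both_prob:
            return int(rng.integers(clo, chi + 1)), int(rng.integers(clo, chi + 1))
        if rng.random() < cfg.tcm_tem_mix:
            return int(rng.integers(clo, chi + 1)), 0
        return 0, int(rng.integers(clo, chi + 1))

    def _vgene() -> str:
        if rng.random() < cfg.reactive_v_prob:
            return cfg.reactive_v_gene
        return str(rng.choice(TRBV_NAMES, p=TRBV_WEIGHTS))

    # family members first
    for fam in families:
        if donor_idx not in fam["donors"]:
            continue
        k = cfg.members_per_family
        residues = rng.choice(list(AA_ALPHABET), size=k, replace=False)
        for res in residues:
            interior = fam["template"][:fam["wildcard_pos"]] + str(res) + fam["template"][fam["wildcard_pos"] + 1:]
            aa = "CAS" + interior + suffix
            a, b = _counts()
            tcm, tem = _memory()
            clones.append({
                "aa_seq": aa, "family_id": fam["family_id"], "v_gene": _vgene(),
                "j_gene": str(rng.choice(TRBJ_NAMES, p=TRBJ_WEIGHTS)),
                AIM_POS: a, AIM_NEG: b, TCM: tcm, TEM: tem, NAIVE: 0,
            })
    n_standalone = max(0, cfg.planted_clones_per_donor - len(clones))
    standalone_seqs = random_cdr3s(rng, n_standalone, cfg.cdr3_length_range,
                                   exclude={c["aa_seq"] for c in clones})
    for aa in standalone_seqs:
        a, b = _counts()
        tcm, tem = _memory()
        naive = 1 if rng.random() < cfg.naive_leak_prob else 0
        clones.append({
            "aa_seq": str(aa), "family_id": -1, "v_gene": _vgene(),
            "j_gene": str(rng.choice(TRBJ_NAMES, p=TRBJ_WEIGHTS)),
            AIM_POS: a, AIM_NEG: b, TCM: tcm, TEM: tem, NAIVE: naive,
        })
    return clones


def _compartment_frame(bg_seqs, bg_v, bg_j, bg_counts, planted_rows, cfg, rng) -> pd.DataFrame:
    """Assemble one compartment table: background + planted + non-productive filler."""
    keep = bg_counts > 0
    parts = [pd.DataFrame({
        "aa_seq": bg_seqs[keep], "v_gene": bg_v[keep], "j_gene": bg_j[keep],
        "templates": bg_counts[keep],
    })]
    if planted_rows:
        parts.append(pd.DataFrame(planted_rows))
    df = pd.concat(parts, ignore_index=True)
    df["productive"] = True

    n_np = int(round(cfg.nonproductive_rate * len(df)))
    if n_np:
        seqs = random_cdr3s(rng, n_np, cfg.cdr3_length_range)
        # out-of-frame marker residue makes these visibly non-translatable
        marked = [s[: len(s) // 2] + "*" + s[len(s) // 2 + 1:] for s in seqs]
        v, j = _draw_genes(rng, n_np)
        parts_np = pd.DataFrame({
            "aa_seq": marked, "v_gene": v, "j_gene": j,
            "templates": np.ones(n_np, dtype=np.int64), "productive": False,
        })
        df = pd.concat([df, parts_np], ignore_index=True)

    df["d_gene"] = rio.UNRESOLVED
    df["templates"] = df["templates"].astype(np.int64)
    df["frequency"] = df["templates"] / df["templates"].sum()
    df["nucleotide_seq"] = [reverse_translate(s) for s in df["aa_seq"]]
    return df[["nucleotide_seq", "aa_seq", "v_gene", "d_gene", "j_gene",
               "templates", "frequency", "productive"]]


def simulate_cohort(config: SimulationConfig) -> tuple[list[Repertoire], GroundTruth]:
    """Generate the full cohort and its realised ground truth.

    Returns repertoires ordered by donor then compartment. Raises
    :class:`ConfigurationError` if the planted template demand exceeds any
    compartment's total.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    families = _plan_families(cfg, rng)

    reps: list[Repertoire] = []
    clone_rows: list[dict] = []
    member_rows: list[dict] = []
    fam_mem_donors: dict[int, set[str]] = {f["family_id"]: set() for f in families}
    fam_donor_ids: dict[int, list[str]] = {
        f["family_id"]: [f"D{d + 1}" for d in f["donors"]] for f in families
    }

    for d in range(cfg.n_donors):
        donor_id = f"D{d + 1}"
        planted = _plant_donor_clones(cfg, rng, d, families)
        planted_seqs = {c["aa_seq"] for c in planted}

        demand = {c: sum(cl[c] for cl in planted) for c in COMPARTMENTS}
        for comp in COMPARTMENTS:
            if demand[comp] >= cfg.templates_per_compartment[comp]:
                raise ConfigurationError(
                    f"planted template demand {demand[comp]} for {donor_id}/{comp} "
                    f"exceeds compartment total {cfg.templates_per_compartment[comp]}"
                )

        pools = {}
        pools["aim"] = _make_pool(rng, cfg.n_background_clones,
                                  cfg.templates_per_compartment[AIM_POS],
                                  cfg.clone_size_shape,
                                  cfg.cdr3_length_range, planted_seqs)
        pools["naive"] = _make_pool(rng, cfg.n_background_clones,
                                    cfg.templates_per_compartment[NAIVE],
                                    cfg.clone_size_shape,
                                    cfg.cdr3_length_range, planted_seqs)
        pools["mem"] = _make_pool(rng, cfg.n_memory_background_clones,
                                  max(cfg.templates_per_compartment[TCM],
                                      cfg.templates_per_compartment[TEM]),
                                  cfg.clone_size_shape,
                                  cfg.cdr3_length_range, planted_seqs)

        pool_of = {AIM_POS: "aim", AIM_NEG: "aim", NAIVE: "naive", TCM: "mem", TEM: "mem"}
        for comp in COMPARTMENTS:
            pool = pools[pool_of[comp]]
            n_bg = cfg.templates_per_compartment[comp] - demand[comp]
            counts = rng.multinomial(n_bg, pool.weights)
            planted_rows = [
                {"aa_seq": cl["aa_seq"], "v_gene": cl["v_gene"], "j_gene": cl["j_gene"],
                 "templates": cl[comp]}
                for cl in planted if cl[comp] > 0
            ]
            df = _compartment_frame(pool.seqs, pool.v, pool.j, counts, planted_rows, cfg, rng)
            reps.append(Repertoire(donor_id=donor_id, compartment=comp, df=df))

        for cl in planted:
            clone_rows.append({
                "donor_id": donor_id, "aa_seq": cl["aa_seq"], "v_gene": cl["v_gene"],
                "j_gene": cl["j_gene"], "family_id": cl["family_id"],
                "templates_aim_pos": cl[AIM_POS], "templates_aim_neg": cl[AIM_NEG],
                "templates_naive": cl[NAIVE], "templates_tcm": cl[TCM],
                "templates_tem": cl[TEM],
                "in_naive": cl[NAIVE] > 0, "in_tcm": cl[TCM] > 0, "in_tem": cl[TEM] > 0,
                "reactive": True,
            })
            if cl["family_id"] >= 0:
                member_rows.append({"family_id": cl["family_id"], "donor_id": donor_id,
                                    "aa_seq": cl["aa_seq"]})
                if cl[TCM] > 0 or cl[TEM] > 0:
                    fam_mem_donors[cl["family_id"]].add(donor_id)

    motif_rows = []
    for fam in families:
        mem_donors = sorted(fam_mem_donors[fam["family_id"]])
        motif_rows.append({
            "family_id": fam["family_id"], "motif": fam["motif"],
            "interior_pattern": fam["interior_pattern"], "cdr3_length": fam["length"],
            "wildcard_pos": fam["wildcard_pos"],
            "donors": ",".join(fam_donor_ids[fam["family_id"]]),
            "donors_memory": ",".join(mem_donors),
            "n_donors_memory": len(mem_donors),
            "memory_affiliated": len(mem_donors) > 0,
        })

    truth = GroundTruth(
        clones=pd.DataFrame(clone_rows),
        motifs=pd.DataFrame(motif_rows),
        motif_members=pd.DataFrame(member_rows, columns=["family_id", "donor_id", "aa_seq"]),
    )
    return reps, truth


def simulate_reference(n_seqs: int, seed: int,
                       length_range: tuple[int, int] = (11, 18)) -> np.ndarray:
    """Naive-like CDR3 reference cohort for motif enrichment testing.

    A stand-in, synthetic reference of unselected CDR3s drawn from the same
    background sequence model as the cohorts (the role played by a multi-donor
    naive reference panel in specificity-group analysis).
    """
    rng = np.random.default_rng(seed)
    return random_cdr3s(rng, n_seqs, length_range)


def write_fixture(reps: Iterable[Repertoire], truth: GroundTruth,
                  out_dir: str | Path) -> Path:
    """Write cohort TSVs, a manifest, and ground-truth tables; return the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rep in reps:
        fname = f"{rep.donor_id}_{rep.compartment}.tsv"
        rio.write_repertoire(rep, out_dir / fname)
        entries.append({"donor_id": rep.donor_id, "compartment": rep.compartment,
                        "path": fname})
    manifest = rio.write_manifest(entries, out_dir / "manifest.yaml")
    rio.write_table(truth.clones, out_dir / "truth_clones.tsv")
    rio.write_table(truth.motifs, out_dir / "truth_motifs.tsv")
    rio.write_table(truth.motif_members, out_dir / "truth_motif_members.tsv")
    return manifest
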