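"""Specificity-group discovery: local k-mer and global 1-mismatch CDR3 clustering.

CDR3s are first trimmed to their interior (default: drop the first three and
last two residues, the germline-dominated ends) so that motifs describe the
epitope-contact loop. Two convergence modes generate candidate groups:

* LOCAL — an enriched k-mer (k = 2..4) shared as an identical interior
  substring, kept when its sample/reference rate fold and Fisher p pass cuts
  and enough distinct CDR3s carry it;
* GLOBAL — equal-length interiors differing at no more than one position,
  grouped under a pattern with ``%`` at the variable position (``%`` matches
  exactly one arbitrary residue).

Each group is then scored for reference enrichment (Fisher on distinct-CDR3
counts vs a naive reference set) and for clonal expansion (a permutation
score: is the number of expanded member clonotypes higher than in random
same-size draws from the dataset?).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .io import Repertoire

logger = logging.getLogger(__name__)

LOCAL = "LOCAL"
GLOBAL = "GLOBAL"
WILDCARD = "%"

#: Default per-k minimum sample/reference fold for local k-mer enrichment.
DEFAULT_MIN_FOLD: Mapping[int, float] = {2: 1000.0, 3: 100.0, 4: 10.0}


# ---------------------------------------------------------------------------
# patterns


@dataclass(frozen=True)
class MotifPattern:
    """A motif: plain k-mer (LOCAL) or single-wildcard pattern (GLOBAL)."""

    pattern: str
    kind: str

    def __post_init__(self):
        n_wild = self.pattern.count(WILDCARD)
        if self.kind == LOCAL and n_wild != 0:
            raise ConfigurationError("LOCAL patterns carry no wildcard")
        if self.kind == GLOBAL and n_wild != 1:
            raise ConfigurationError("GLOBAL patterns carry exactly one wildcard")
        if self.kind not in (LOCAL, GLOBAL):
            raise ConfigurationError(f"unknown motif kind {self.kind!r}")

    @property
    def length(self) -> int:
        return len(self.pattern)

    def matches(self, trimmed: str) -> bool:
        """LOCAL: substring containment; GLOBAL: equal length + positional match."""
        if self.kind == LOCAL:
            return self.pattern in trimmed
        if len(trimmed) != len(self.pattern):
            return False
        return all(p == WILDCARD or p == c for p, c in zip(self.pattern, trimmed))


def wildcard_contains(pattern: str, s: str) -> bool:
    """Containment search for a pattern that may hold ``%`` wildcards."""
    rx = re.escape(pattern).replace(re.escape(WILDCARD), ".")
    return re.search(rx, s) is not None


def trim_cdr3(aa_seq: str, head: int = 3, tail: int = 2) -> str:
    """Interior of a CDR3: drop ``head`` leading and ``tail`` trailing residues.

    Raises ValueError for sequences too short to leave a non-empty interior;
    bulk callers exclude (and log) such sequences instead.
    """
    if len(aa_seq) < head + tail + 1:
        raise ValueError(f"CDR3 {aa_seq!r} too short to trim ({head},{tail})")
    return aa_seq[head: len(aa_seq) - tail] if tail else aa_seq[head:]


def build_motif_sample(
    reps: Iterable[Repertoire], head: int = 3, tail: int = 2,
) -> pd.DataFrame:
    """Pool repertoires into the motif-analysis sample table.

    One row per (donor, compartment, CDR3) with its trimmed interior,
    templates and frequency; too-short CDR3s are excluded and counted in the
    log.
    """
    frames = []
    for rep in reps:
        frames.append(pd.DataFrame({
            "donor_id": rep.donor_id, "compartment": rep.compartment,
            "aa_seq": rep.df["aa_seq"], "templates": rep.df["templates"],
            "frequency": rep.df["frequency"],
        }))
    sample = pd.concat(frames, ignore_index=True)
    lengths = sample["aa_seq"].str.len()
    short = lengths < head + tail + 1
    if short.any():
        logger.info("motif sample: excluded %d CDR3s shorter than %d residues",
                    int(short.sum()), head + tail + 1)
    sample = sample[~short].reset_index(drop=True)
    sample["trimmed"] = sample["aa_seq"].str.slice(head, None)
    if tail:
        sample["trimmed"] = sample["trimmed"].str.slice(0, -tail)
    return sample


# ---------------------------------------------------------------------------
# fast byte-matrix helpers


def _length_buckets(seqs: np.ndarray) -> dict[int, np.ndarray]:
    lengths = np.char.str_len(seqs.astype("U"))
    return {int(L): np.flatnonzero(lengths == L) for L in np.unique(lengths)}


def _byte_matrix(seqs: np.ndarray, L: int) -> np.ndarray:
    return seqs.astype(f"S{L}").view("S1").reshape(len(seqs), L).copy()


def _masked_keys(mat: np.ndarray, pos: int) -> np.ndarray:
    m = mat.copy()
    m[:, pos] = WILDCARD.encode()
    return m.view(f"S{mat.shape[1]}").ravel()


# ---------------------------------------------------------------------------
# reference sets


class ReferenceSet:
    """A naive CDR3 reference with k-mer and single-mask indices.

    Counts are over distinct input CDR3s: a sequence contributes once per
    k-mer or pattern no matter its copy number. ``sequences`` may be full
    CDR3s (trimmed internally with the same offsets as the sample) or
    pre-trimmed interiors.
    """

    def __init__(self, sequences: Iterable[str], head: int = 3, tail: int = 2,
                 already_trimmed: bool = False):
        seqs = pd.Series(pd.unique(np.asarray(list(sequences), dtype=object)))
        if not already_trimmed:
            keep = seqs.str.len() >= head + tail + 1
            seqs = seqs[keep]
            seqs = seqs.str.slice(head, None)
            if tail:
                seqs = seqs.str.slice(0, -tail)
        self.n_seqs = int(len(seqs))
        if self.n_seqs == 0:
            raise ConfigurationError("reference set is empty after trimming")
        # multiplicity: distinct input sequences per trimmed interior
        vc = seqs.value_counts()
        self._trimmed = vc.index.to_numpy(dtype=object)
        self._weights = vc.to_numpy(dtype=np.int64)
        self._buckets = _length_buckets(self._trimmed)
        self._kmer_counts: dict[int, pd.Series] = {}
        self._masked: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        self._masked_built = False

    def kmer_counts(self, k: int) -> pd.Series:
        """Series kmer -> number of distinct reference CDR3s containing it."""
        if k not in self._kmer_counts:
            self._kmer_counts[k] = _kmer_seq_counts(self._trimmed, self._weights, k)
        return self._kmer_counts[k]

    def count_containing(self, kmer: str) -> int:
        return int(self.kmer_counts(len(kmer)).get(kmer, 0))

    def _build_masked(self) -> None:
        for L, idx in self._buckets.items():
            mat = _byte_matrix(self._trimmed[idx], L)
            w = self._weights[idx]
            for i in range(L):
                keys = _masked_keys(mat, i)
                uniq, inv = np.unique(keys, return_inverse=True)
                counts = np.bincount(inv, weights=w).astype(np.int64)
                self._masked[(L, i)] = (uniq, counts)
        self._masked_built = True

    def count_matching_global(self, pattern: str) -> int:
        """Distinct reference CDR3s matching an equal-length one-wildcard pattern."""
        if not self._masked_built:
            self._build_masked()
        L, i = len(pattern), pattern.index(WILDCARD)
        entry = self._masked.get((L, i))
        if entry is None:
            return 0
        uniq, counts = entry
        key = np.bytes_(pattern.encode())
        j = np.searchsorted(uniq, key)
        if j < len(uniq) and uniq[j] == key:
            return int(counts[j])
        return 0

    def count_matching(self, motif: MotifPattern) -> int:
        if motif.kind == LOCAL:
            return self.count_containing(motif.pattern)
        return self.count_matching_global(motif.pattern)


def _kmer_seq_counts(trimmed: np.ndarray, weights: np.ndarray, k: int) -> pd.Series:
    """kmer -> weighted number of sequences containing it (distinct per sequence).

    (sequence, kmer) pairs are packed into uint64 codes so deduplication and
    counting stay in flat numpy: kmer bytes occupy the high bits, the
    sequence id the low bits.
    """
    if k > 5:
        # 8*k + log2(n_sequences) bits must fit in the uint64 packing
        raise ConfigurationError("k-mer length above 5 not supported")
    buckets = _length_buckets(trimmed)
    code_parts, seq_parts = [], []
    for L, idx in buckets.items():
        if L < k:
            continue
        mat = _byte_matrix(trimmed[idx], L).view(np.uint8)
        n_off = L - k + 1
        for off in range(n_off):
            window = mat[:, off:off + k].astype(np.uint64)
            code = np.zeros(len(idx), dtype=np.uint64)
            for j in range(k):
                code = code * np.uint64(256) + window[:, j]
            code_parts.append(code)
            seq_parts.append(idx)
    if not code_parts:
        return pd.Series(dtype=np.int64)
    codes = np.concatenate(code_parts)
    seqs = np.concatenate(seq_parts).astype(np.uint64)
    n_bits = int(np.ceil(np.log2(max(len(trimmed), 2))))
    packed = (codes << np.uint64(n_bits)) | seqs
    packed = np.unique(packed)  # dedup (sequence, kmer) pairs
    kmer_codes = packed >> np.uint64(n_bits)
    seq_ids = (packed & np.uint64((1 << n_bits) - 1)).astype(np.int64)
    uniq_codes, inverse = np.unique(kmer_codes, return_inverse=True)
    counts = np.bincount(inverse, weights=weights[seq_ids]).astype(np.int64)

    def _decode(code: int) -> str:
        bs = bytearray()
        while code:
            bs.append(code & 0xFF)
            code >>= 8
        return bytes(reversed(bs)).decode()

    index = [_decode(int(c)) for c in uniq_codes]
    return pd.Series(counts, index=index)


# ---------------------------------------------------------------------------
# discovery


@dataclass
class SpecificityGroup:
    """A motif plus its sample members (row positions in the sample table)."""

    motif: MotifPattern
    member_index: np.ndarray = field(repr=False)
    n_unique_cdr3: int
    fisher_ref_p: float | None = None
    expansion_p: float | None = None


def _sample_distinct(sample: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int]:
    """Unique trimmed interiors, their distinct-full-CDR3 multiplicities, total."""
    uniq_full = sample[["aa_seq", "trimmed"]].drop_duplicates()
    vc = uniq_full["trimmed"].value_counts()
    return vc.index.to_numpy(dtype=object), vc.to_numpy(np.int64), int(len(uniq_full))


def local_motif_enrichment(
    sample: pd.DataFrame,
    reference: ReferenceSet,
    k_values: Sequence[int] = (2, 3, 4),
    min_fold: Mapping[int, float] | None = None,
    p_max: float = 0.05,
    min_unique: int = 3,
) -> pd.DataFrame:
    """Reference-enriched interior k-mers.

    A k-mer is kept when (sample containment rate) / (reference containment
    rate, one pseudo-occurrence if absent) >= ``min_fold[k]``, its Fisher p
    on the containment 2x2 is below ``p_max``, and at least ``min_unique``
    distinct sample CDR3s carry it.
    """
    min_fold = dict(DEFAULT_MIN_FOLD) if min_fold is None else dict(min_fold)
    trimmed, weights, n_sample = _sample_distinct(sample)
    n_ref = reference.n_seqs
    rows = []
    for k in sorted(k_values):
        counts = _kmer_seq_counts(trimmed, weights, k)
        counts = counts[counts >= min_unique]
        if len(counts) == 0:
            continue
        ref_counts = reference.kmer_counts(k).reindex(counts.index, fill_value=0)
        fold = ((counts / n_sample) /
                (np.maximum(ref_counts, 1) / n_ref)).to_numpy()
        passing = np.flatnonzero(fold >= min_fold.get(k, 0.0))
        for i in passing:
            n_s, n_r = int(counts.iloc[i]), int(ref_counts.iloc[i])
            p = stats.fisher_exact(
                [[n_s, n_sample - n_s], [n_r, n_ref - n_r]], alternative="two-sided"
            ).pvalue
            if p < p_max:
                rows.append({"kmer": counts.index[i], "k": k, "n_sample": n_s,
                             "n_ref": n_r, "fold": float(fold[i]), "fisher_p": float(p)})
    return pd.DataFrame(rows, columns=["kmer", "k", "n_sample", "n_ref", "fold", "fisher_p"])


def global_convergence(sample: pd.DataFrame, min_unique: int = 2) -> list[dict]:
    """Group equal-length interiors differing at <= 1 position.

    Every (sequence, position) mask generates a candidate pattern; sequences
    sharing a masked key belong to the same group (a CDR3 can join several
    groups). Groups carrying fewer than ``min_unique`` distinct CDR3s are
    dropped. Returns dicts with ``pattern`` and ``trimmed`` member arrays.
    """
    trimmed, weights, _ = _sample_distinct(sample)
    buckets = _length_buckets(trimmed)
    groups: list[dict] = []
    for L in sorted(buckets):
        idx = buckets[L]
        mat = _byte_matrix(trimmed[idx], L)
        w = weights[idx]
        for i in range(L):
            keys = _masked_keys(mat, i)
            order = np.argsort(keys, kind="stable")
            sk = keys[order]
            boundaries = np.flatnonzero(np.concatenate(([True], sk[1:] != sk[:-1])))
            ends = np.concatenate((boundaries[1:], [len(sk)]))
            for b, e in zip(boundaries, ends):
                members = idx[order[b:e]]
                if int(w[order[b:e]].sum()) < min_unique:
                    continue
                groups.append({
                    "pattern": sk[b].decode(),
                    "trimmed": trimmed[members],
                })
    groups.sort(key=lambda g: g["pattern"])
    return groups


def build_specificity_groups(
    local_kmers: pd.DataFrame,
    global_groups: list[dict],
    sample: pd.DataFrame,
    min_unique: int = 2,
) -> list[SpecificityGroup]:
    """Materialise groups against the sample and deduplicate identical member sets.

    LOCAL members are all sample rows whose interior contains the k-mer;
    GLOBAL groups pass through. When two groups select the same distinct-CDR3
    member set, the more specific pattern wins (longer, then fewer wildcards,
    then lexicographically smaller).
    """
    trimmed_values = sample["trimmed"].to_numpy(dtype=object)
    row_index: dict[str, np.ndarray] = {
        t: np.asarray(ix) for t, ix in sample.groupby("trimmed", sort=False).indices.items()
    }
    uniq_trimmed = np.array(list(row_index.keys()), dtype=object)

    candidates: list[SpecificityGroup] = []

    if len(local_kmers):
        tser = pd.Series(uniq_trimmed)
        for r in local_kmers.itertuples(index=False):
            hit = tser[tser.str.contains(r.kmer, regex=False)]
            members = np.concatenate([row_index[t] for t in hit]) if len(hit) else np.array([], dtype=int)
            if len(members) == 0:
                continue
            n_uniq = sample.iloc[members]["aa_seq"].nunique()
            if n_uniq < min_unique:
                continue
            candidates.append(SpecificityGroup(
                motif=MotifPattern(r.kmer, LOCAL),
                member_index=np.sort(members), n_unique_cdr3=int(n_uniq)))

    for g in global_groups:
        members = np.concatenate([row_index[t] for t in g["trimmed"]])
        n_uniq = sample.iloc[members]["aa_seq"].nunique()
        if n_uniq < min_unique:
            continue
        candidates.append(SpecificityGroup(
            motif=MotifPattern(g["pattern"], GLOBAL),
            member_index=np.sort(members), n_unique_cdr3=int(n_uniq)))

    # dedup: identical distinct-CDR3 member sets collapse to one group
    best: dict[frozenset, SpecificityGroup] = {}
    for grp in candidates:
        key = frozenset(sample.iloc[grp.member_index]["aa_seq"])
        cur = best.get(key)
        if cur is None or _specificity_rank(grp.motif) < _specificity_rank(cur.motif):
            best[key] = grp
    out = list(best.values())
    out.sort(key=lambda g: (g.motif.kind, g.motif.pattern))
    return out


def _specificity_rank(motif: MotifPattern) -> tuple:
    return (-motif.length, motif.pattern.count(WILDCARD), motif.pattern)


def reference_enrichment_test(
    group: SpecificityGroup,
    n_sample_cdr3s: int,
    reference: ReferenceSet,
) -> float:
    """Two-sided Fisher p for group-motif prevalence: sample vs reference CDR3s."""
    n_g = group.n_unique_cdr3
    n_r = reference.count_matching(group.motif)
    table = [[n_g, n_sample_cdr3s - n_g], [n_r, reference.n_seqs - n_r]]
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# expansion score


def dataset_clonotypes(sample: pd.DataFrame) -> pd.DataFrame:
    """Collapse the motif sample to clonotypes (aa_seq, summed templates)."""
    return (sample.groupby("aa_seq", sort=True)["templates"].sum()
            .reset_index())


class ExpansionScorer:
    """Permutation expansion score over a fixed clonotype dataset.

    The statistic is the number of member clonotypes with >= 2 templates
    (expanded); the null draws equally sized clonotype sets uniformly without
    replacement from the whole dataset. ``p = (1 + #{null >= obs}) /
    (n_perm + 1)``; null draws are cached per group size, so scoring many
    groups against one dataset is cheap and reproducible for a fixed seed.
    """

    def __init__(self, clonotypes: pd.DataFrame, n_perm: int = 1000, seed: int = 0):
        if n_perm < 100:
            raise ConfigurationError("n_perm must be at least 100")
        self.n_perm = n_perm
        self._rng = np.random.default_rng(seed)
        self._expanded = (clonotypes["templates"].to_numpy() >= 2)
        self._aa_index = {aa: i for i, aa in enumerate(clonotypes["aa_seq"])}
        self._null_cache: dict[int, np.ndarray] = {}

    @property
    def n_clonotypes(self) -> int:
        return len(self._expanded)

    def _null_counts(self, m: int) -> np.ndarray:
        if m not in self._null_cache:
            N = self.n_clonotypes
            if m > N:
                raise ConfigurationError("group larger than the clonotype dataset")
            draws = self._rng.integers(0, N, size=(self.n_perm, m))
            # rejection-resample rows with repeats -> uniform without replacement
            while True:
                sorted_rows = np.sort(draws, axis=1)
                bad = (np.diff(sorted_rows, axis=1) == 0).any(axis=1)
                if not bad.any():
                    break
                draws[bad] = self._rng.integers(0, N, size=(int(bad.sum()), m))
            self._null_cache[m] = self._expanded[draws].sum(axis=1)
        return self._null_cache[m]

    def score(self, member_aa_seqs: Iterable[str]) -> float:
        members = sorted(set(member_aa_seqs))
        idx = np.array([self._aa_index[a] for a in members], dtype=int)
        observed = int(self._expanded[idx].sum())
        null = self._null_counts(len(idx))
        return float((1 + int((null >= observed).sum())) / (self.n_perm + 1))


def expansion_score(
    group: SpecificityGroup,
    sample: pd.DataFrame,
    clonotypes: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """One-off expansion score for a single group (see :class:`ExpansionScorer`)."""
    scorer = ExpansionScorer(clonotypes, n_perm=n_perm, seed=seed)
    return scorer.score(sample.iloc[group.member_index]["aa_seq"])
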