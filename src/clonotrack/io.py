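"""Reading, validation, filtering and aggregation of immunoSEQ-style CDR3 tables.

The unit of analysis is a :class:`Repertoire`: every productive and
non-productive TCRbeta rearrangement sequenced from one sorted T-cell
compartment (antigen-reactive AIM+, non-reactive AIM-, naive, central memory
TCM, or effector memory TEM) of one donor. Input files are tab-separated
exports with one row per rearrangement; column naming varies across platform
versions, so readers take a ``column_map`` that resolves logical field names
to file columns (a default for the common dialect is shipped).

Frequencies are always recomputed from template counts after any filtering
step: a file's frequency column is only trusted on raw pass-through reads,
because removing rows invalidates it.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    EmptyRepertoireError,
    RepertoireFormatError,
    RepertoireParseError,
)

# Compartment labels used throughout the package.
AIM_POS = "AIM_POS"
AIM_NEG = "AIM_NEG"
NAIVE = "NAIVE"
TCM = "TCM"
TEM = "TEM"
COMPARTMENTS = (AIM_POS, AIM_NEG, NAIVE, TCM, TEM)

UNRESOLVED = "unresolved"

#: Logical field -> column name in the common immunoSEQ export dialect.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "nucleotide_seq": "nucleotide",
    "aa_seq": "aminoAcid",
    "templates": "count (templates/reads)",
    "frequency": "frequencyCount",
    "v_gene": "vGeneName",
    "d_gene": "dGeneName",
    "j_gene": "jGeneName",
    "productive": "sequenceStatus",
}

_REQUIRED_FIELDS = ("nucleotide_seq", "aa_seq", "templates", "v_gene", "j_gene", "productive")
_OPTIONAL_FIELDS = ("frequency", "d_gene")

_INTERNAL_COLUMNS = [
    "nucleotide_seq", "aa_seq", "v_gene", "d_gene", "j_gene",
    "templates", "frequency", "productive",
]


class CDR3Record(NamedTuple):
    """One TCRbeta rearrangement: a row of a repertoire table."""

    nucleotide_seq: str
    aa_seq: str
    v_gene: str
    d_gene: str
    j_gene: str
    templates: int
    frequency: float
    productive: bool


@dataclass
class Repertoire:
    """All rearrangements for one (donor, compartment).

    The backing store is a DataFrame with columns
    ``nucleotide_seq, aa_seq, v_gene, d_gene, j_gene, templates, frequency,
    productive``; ``records`` materialises it as :class:`CDR3Record` tuples
    for small repertoires and tests.
    """

    donor_id: str
    compartment: str
    df: pd.DataFrame = field(repr=False)

    @property
    def total_templates(self) -> int:
        return int(self.df["templates"].sum())

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[CDR3Record]:
        return [CDR3Record(*row) for row in self.df[_INTERNAL_COLUMNS].itertuples(index=False)]

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.df)


def normalize_gene(name: object) -> str:
    """Collapse a platform gene call to family level, e.g. ``TCRBV15-01*01`` -> ``TRBV15``.

    Allele suffixes (``*NN``) and gene-duplicate suffixes (``-NN``) are
    stripped, the platform's ``TCRB`` prefix is rewritten to the IMGT ``TRB``,
    leading zeros in the family number are removed, and the result is
    upper-cased. Empty or unresolved calls map to ``"unresolved"``.
    """
    if name is None or (isinstance(name, float) and math.isnan(name)):
        return UNRESOLVED
    g = str(name).strip().upper()
    if g in ("", "NA", "UNRESOLVED", "UNKNOWN"):
        return UNRESOLVED
    g = g.split("*")[0]
    g = g.replace("TCRB", "TRB")
    g = g.split("-")[0]
    m = re.fullmatch(r"([A-Z]+)0*([0-9]+)", g)
    if m:
        g = f"{m.group(1)}{m.group(2)}"
    return g


def _parse_productive(values: pd.Series) -> pd.Series:
    """Interpret a sequenceStatus-style column: ``In`` (in-frame) means productive."""
    s = values.astype(str).str.strip().str.lower()
    return s.isin(("in", "true", "productive", "1"))


def read_repertoire(
    path: str | Path,
    donor_id: str,
    compartment: str,
    column_map: Mapping[str, str] | None = None,
    normalize_genes: bool = True,
) -> Repertoire:
    """Read one tab-separated repertoire export, unfiltered.

    Every row of the file is retained, including non-productive
    rearrangements (filtering is a separate, explicit step). If the file has
    no frequency column, frequencies are computed as templates / total
    templates; an unresolvable D gene column yields ``"unresolved"``.

    Raises
    ------
    RepertoireFormatError
        if a required column is missing (the message names it).
    RepertoireParseError
        if a template count is not a non-negative integer (names the row).
    EmptyRepertoireError
        if the file holds a header but no rows.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for fld in _REQUIRED_FIELDS:
        if cmap[fld] not in raw.columns:
            raise RepertoireFormatError(
                f"{path.name}: required column '{cmap[fld]}' (field '{fld}') not found"
            )
    if len(raw) == 0:
        raise EmptyRepertoireError(f"{path.name}: file contains no rearrangement rows")

    out = pd.DataFrame(index=raw.index)
    out["nucleotide_seq"] = raw[cmap["nucleotide_seq"]]
    out["aa_seq"] = raw[cmap["aa_seq"]]

    tmpl_raw = raw[cmap["templates"]].str.strip()
    bad = ~tmpl_raw.str.fullmatch(r"[0-9]+")
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise RepertoireParseError(
            f"{path.name}: non-integer template count {tmpl_raw.iloc[i]!r} at data row {i}"
        )
    out["templates"] = tmpl_raw.astype(np.int64)

    vg = raw[cmap["v_gene"]]
    jg = raw[cmap["j_gene"]]
    dg = raw[cmap["d_gene"]] if cmap["d_gene"] in raw.columns else pd.Series(UNRESOLVED, index=raw.index)
    if normalize_genes:
        out["v_gene"] = vg.map(normalize_gene)
        out["d_gene"] = dg.map(normalize_gene)
        out["j_gene"] = jg.map(normalize_gene)
    else:
        out["v_gene"], out["d_gene"], out["j_gene"] = vg, dg, jg

    if cmap["frequency"] in raw.columns:
        out["frequency"] = raw[cmap["frequency"]].astype(float)
    else:
        total = out["templates"].sum()
        out["frequency"] = out["templates"] / total

    out["productive"] = _parse_productive(raw[cmap["productive"]])
    out = out[_INTERNAL_COLUMNS]
    return Repertoire(donor_id=donor_id, compartment=compartment, df=out)


def write_repertoire(rep: Repertoire, path: str | Path,
                     column_map: Mapping[str, str] | None = None) -> Path:
    """Write a repertoire back to the tab-separated export dialect (UTF-8, LF)."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    path = Path(path)
    out = pd.DataFrame()
    out[cmap["nucleotide_seq"]] = rep.df["nucleotide_seq"]
    out[cmap["aa_seq"]] = rep.df["aa_seq"]
    out[cmap["templates"]] = rep.df["templates"]
    out[cmap["frequency"]] = rep.df["frequency"].map(lambda x: format(x, ".12g"))
    out[cmap["v_gene"]] = rep.df["v_gene"]
    out[cmap["d_gene"]] = rep.df["d_gene"]
    out[cmap["j_gene"]] = rep.df["j_gene"]
    out[cmap["productive"]] = np.where(rep.df["productive"], "In", "Out")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    return path


def filter_productive(rep: Repertoire) -> Repertoire:
    """Keep productive rearrangements only and renormalise frequencies.

    Raises :class:`EmptyRepertoireError` if nothing survives.
    """
    kept = rep.df[rep.df["productive"]].copy()
    if len(kept) == 0:
        raise EmptyRepertoireError(
            f"{rep.donor_id}/{rep.compartment}: no productive rearrangements remain"
        )
    total = kept["templates"].sum()
    kept["frequency"] = kept["templates"] / total
    kept = kept.reset_index(drop=True)
    return Repertoire(donor_id=rep.donor_id, compartment=rep.compartment, df=kept)


#: Valid clonotype aggregation keys: amino-acid CDR3 alone (the default used
#: for cross-sample tracking) or amino acid plus V gene.
AGGREGATION_KEYS = {"aa": ["aa_seq"], "aa_v": ["aa_seq", "v_gene"]}


def aggregate_clonotypes(rep: Repertoire, key: str = "aa") -> pd.DataFrame:
    """Collapse records into clonotypes under the given key.

    Templates and frequencies are summed per distinct key; the representative
    V/J call is taken from the largest-template record (ties broken by
    nucleotide sequence for determinism). Output is sorted by descending
    templates, ties broken lexicographically by ``aa_seq``.
    """
    if key not in AGGREGATION_KEYS:
        raise ConfigurationError(f"unknown aggregation key {key!r}; expected one of {sorted(AGGREGATION_KEYS)}")
    cols = AGGREGATION_KEYS[key]
    df = rep.df.sort_values(
        ["templates", "nucleotide_seq"], ascending=[False, True], kind="mergesort"
    )
    spec = {
        "templates": ("templates", "sum"),
        "frequency": ("frequency", "sum"),
        "j_gene": ("j_gene", "first"),
    }
    if "v_gene" not in cols:
        spec["v_gene"] = ("v_gene", "first")
    agg = df.groupby(cols, sort=False).agg(**spec).reset_index()
    agg = agg[cols + [c for c in ("v_gene", "j_gene", "templates", "frequency") if c not in cols]]
    agg = agg.sort_values(["templates", "aa_seq"], ascending=[False, True], kind="mergesort")
    return agg.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cohort manifests


def write_manifest(entries: Iterable[Mapping[str, str]], path: str | Path) -> Path:
    """Write a cohort manifest: a YAML list of {donor_id, compartment, path}."""
    path = Path(path)
    payload = {"entries": [dict(e) for e in entries]}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return path


def read_manifest(path: str | Path) -> list[dict[str, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not payload or "entries" not in payload:
        raise RepertoireFormatError(f"{path}: manifest has no 'entries' list")
    return list(payload["entries"])


def load_cohort(
    manifest_path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> dict[tuple[str, str], Repertoire]:
    """Read every repertoire named by a manifest into a {(donor, compartment): Repertoire} map.

    Paths in the manifest are resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    cohort: dict[tuple[str, str], Repertoire] = {}
    for entry in read_manifest(manifest_path):
        donor, comp = entry["donor_id"], entry["compartment"]
        if (donor, comp) in cohort:
            raise RepertoireFormatError(f"duplicate manifest entry for ({donor}, {comp})")
        p = Path(entry["path"])
        if not p.is_absolute():
            p = base / p
        cohort[(donor, comp)] = read_repertoire(p, donor, comp, column_map=column_map)
    return cohort


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy result table: UTF-8, LF line endings, fixed column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    return path
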