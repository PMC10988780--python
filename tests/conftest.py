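"""Shared fixtures: toy repertoires, a reference set, and one default cohort run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from clonotrack import pipeline, simulate as sim
from clonotrack import motifs as mo
from clonotrack._genes import reverse_translate
from clonotrack.io import Repertoire


def make_repertoire(donor_id: str, compartment: str, rows: list[dict]) -> Repertoire:
    """Toy repertoire from minimal row dicts (aa_seq + templates required)."""
    records = []
    for i, row in enumerate(rows):
        rec = {
            "aa_seq": row["aa_seq"],
            "templates": int(row["templates"]),
            "v_gene": row.get("v_gene", "TRBV5"),
            "d_gene": row.get("d_gene", "unresolved"),
            "j_gene": row.get("j_gene", "TRBJ1"),
            "productive": row.get("productive", True),
            "nucleotide_seq": row.get("nucleotide_seq", reverse_translate(row["aa_seq"])),
        }
        records.append(rec)
    df = pd.DataFrame(records)
    total = df["templates"].sum()
    df["frequency"] = df["templates"] / total
    cols = ["nucleotide_seq", "aa_seq", "v_gene", "d_gene", "j_gene",
            "templates", "frequency", "productive"]
    return Repertoire(donor_id=donor_id, compartment=compartment, df=df[cols])


@pytest.fixture(scope="session")
def reference():
    """Synthetic naive CDR3 reference panel shared by motif tests."""
    ref = mo.ReferenceSet(sim.simulate_reference(300000, seed=4242))
    for k in (2, 3, 4):
        ref.kmer_counts(k)
    return ref


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the package's reference study conditions."""
    cfg = sim.SimulationConfig(seed=1)
    reps, truth = sim.simulate_cohort(cfg)
    cohort = pipeline.productive_cohort({(r.donor_id, r.compartment): r for r in reps})
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def full_results(default_cohort, reference):
    """Full analysis chain on the default cohort (computed once per session)."""
    cfg, cohort, truth = default_cohort
    selection, tracked, per_donor, summary, motif = pipeline.run_full_analysis(
        cohort, reference, seed=cfg.seed)
    return {
        "cfg": cfg, "cohort": cohort, "truth": truth, "selection": selection,
        "tracked": tracked, "per_donor": per_donor, "summary": summary,
        "motif": motif,
    }
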