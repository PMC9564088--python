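"""Bundled clinical tables transcribed from the published study.

``load_cohort`` returns the 17-patient transplant cohort (demographics,
conditioning regimen, progression, PFS in months).  ``load_tumor_repertoires``
returns the kappa-chain tumor CDR3 signatures of the three patients with an
available tumor biopsy, as per-patient tumor repertoires whose pseudo-counts
preserve the published clone fractions.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import CohortRecord, Repertoire, read_cohort_table, tumor_signature_from_frame

__all__ = ["cohort_path", "load_cohort", "load_tumor_repertoires"]


def cohort_path():
    return resources.files("bcrnet.data") / "dlbcl_cohort.tsv"


def load_cohort() -> list[CohortRecord]:
    """The transplant cohort table (17 patients, 8 with progression)."""
    with resources.as_file(cohort_path()) as p:
        return read_cohort_table(p)


def load_tumor_repertoires() -> dict[str, Repertoire]:
    """Per-patient tumor CDR3 signatures as tumor repertoires."""
    ref = resources.files("bcrnet.data") / "tumor_cdr3_signatures.tsv"
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    out: dict[str, Repertoire] = {}
    for pid, sub in df.groupby("patient_no", sort=True):
        rep = tumor_signature_from_frame(sub.reset_index(drop=True), name=f"tumor_{pid}")
        rep.subject_id = str(pid)
        out[str(pid)] = rep
    return out
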