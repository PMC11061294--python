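"""Nucleus QC filtering and integrative HTO + genotype demultiplexing.

QC keeps nuclei with 2000-10,000 detected features and at most 5% of reads
mapping to mitochondrial genes (low-quality nuclei are those strictly
outside these bounds). Sample assignment consolidates two demultiplexing
calls: hashtag-oligonucleotide (HTO) calls take precedence when they name a
sample, the genotype call is used as confirmation or fallback, and
conflicting or doubly-uninformative nuclei are discarded.

Rule table (hto_call, genotype_call) -> assignment:

    R1  singlet S,        genotype S            -> S        (confirmed)
    R2  singlet S,        genotype S' != S      -> Discarded (conflict)
    R3  Doublet/Negative, genotype S            -> S        (genotype rescue)
    R4  Doublet/Negative, Doublet/Unassigned    -> Discarded
    R5  singlet S,        Doublet/Unassigned    -> Discarded by default;
        ``trust_hto=True`` keeps the HTO call instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._errors import ValidationError

HTO_SPECIAL = {"Doublet", "Negative"}
GENO_SPECIAL = {"Doublet", "Unassigned"}

FEATURES_MIN = 2000
FEATURES_MAX = 10_000
MITO_MAX = 5.0


def qc_filter(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep nuclei with features in [2000, 10000] and mito percentage <= 5.

    Returns the kept records and a removal report counting each reason
    (a nucleus can fail for more than one).
    """
    for col in ("n_features", "pct_mito"):
        if col not in records.columns:
            raise ValidationError(f"qc_filter: missing column {col!r}")
    bad_rows = records[
        (records["n_features"] < 0)
        | (records["pct_mito"] < 0)
        | (records["pct_mito"] > 100)
    ]
    if len(bad_rows):
        raise ValidationError(f"qc_filter: malformed record for barcode {bad_rows.index[0]!r}")

    low = records["n_features"] < FEATURES_MIN
    high = records["n_features"] > FEATURES_MAX
    mito = records["pct_mito"] > MITO_MAX
    kept = records[~(low | high | mito)]
    report = {
        "features_low": int(low.sum()),
        "features_high": int(high.sum()),
        "mito_high": int(mito.sum()),
        "removed": int((low | high | mito).sum()),
        "kept": int(len(kept)),
    }
    return kept, report


def consolidate_assignments(
    records: pd.DataFrame, sample_ids: set[str] | None = None, trust_hto: bool = False
) -> pd.DataFrame:
    """Apply the HTO-first, genotype-confirmation rule table per nucleus.

    ``sample_ids`` declares the valid sample vocabulary; by default it is
    inferred as every call token that is not a special token. Returns one
    row per input barcode with assigned_sample (or "Discarded") and the
    rule applied.
    """
    if sample_ids is None:
        tokens = set(records["hto_call"]) | set(records["genotype_call"])
        sample_ids = tokens - HTO_SPECIAL - GENO_SPECIAL
    else:
        unknown = (
            (set(records["hto_call"]) - sample_ids - HTO_SPECIAL)
            | (set(records["genotype_call"]) - sample_ids - GENO_SPECIAL)
        )
        if unknown:
            raise ValidationError(f"unknown call tokens: {sorted(unknown)}")

    hto = records["hto_call"].to_numpy(dtype=object)
    geno = records["genotype_call"].to_numpy(dtype=object)
    assigned = np.empty(len(records), dtype=object)
    rule = np.empty(len(records), dtype=object)

    hto_singlet = ~np.isin(hto, list(HTO_SPECIAL))
    geno_singlet = ~np.isin(geno, list(GENO_SPECIAL))

    match = hto_singlet & geno_singlet & (hto == geno)
    conflict = hto_singlet & geno_singlet & (hto != geno)
    rescue = ~hto_singlet & geno_singlet
    both_bad = ~hto_singlet & ~geno_singlet
    hto_only = hto_singlet & ~geno_singlet

    assigned[match], rule[match] = hto[match], "R1"
    assigned[conflict], rule[conflict] = "Discarded", "R2"
    assigned[rescue], rule[rescue] = geno[rescue], "R3"
    assigned[both_bad], rule[both_bad] = "Discarded", "R4"
    if trust_hto:
        assigned[hto_only] = hto[hto_only]
    else:
        assigned[hto_only] = "Discarded"
    rule[hto_only] = "R5"

    return pd.DataFrame(
        {"assigned_sample": assigned, "rule_applied": rule}, index=records.index
    )


def demultiplex(
    records: pd.DataFrame, trust_hto: bool = False
) -> tuple[pd.DataFrame, dict]:
    """QC filter then consolidate; returns assignments and a combined report."""
    kept, qc_report = qc_filter(records)
    assignments = consolidate_assignments(kept, trust_hto=trust_hto)
    rule_counts = assignments["rule_applied"].value_counts().to_dict()
    n_assigned = int((assignments["assigned_sample"] != "Discarded").sum())
    return assignments, {
        "qc": qc_report,
        "rules": rule_counts,
        "assigned": n_assigned,
        "discarded": int(len(assignments) - n_assigned),
    }
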