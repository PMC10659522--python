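"""Table I/O: one CSV per study holding metadata and concentrations.

Layout contract: samples as rows keyed by ``sample_id``; metadata columns
prefixed ``meta_``; every unprefixed column is a metabolite and must be
numeric. Missing cells are empty fields, read back as missing (never zero).
Numbers are serialized with full precision so a write/read round trip is
lossless for finite values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_tables", "write_tables"]


def write_tables(path, samples: pd.DataFrame, mets: pd.DataFrame) -> None:
    if not samples.index.equals(mets.index):
        raise ValueError("sample table and metabolite matrix must be aligned")
    meta = samples.add_prefix("meta_")
    combined = pd.concat([meta, mets], axis=1)
    combined.index.name = "sample_id"
    combined.to_csv(path, float_format="%.17g")


def read_tables(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, index_col="sample_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s): {dup[:5]}")
    meta_cols = [c for c in df.columns if c.startswith("meta_")]
    met_cols = [c for c in df.columns if not c.startswith("meta_")]
    samples = df[meta_cols].rename(columns=lambda c: c[len("meta_"):])
    mets = df[met_cols]
    bad = [c for c in met_cols if not np.issubdtype(mets[c].dtype, np.number)]
    if bad:
        raise ValueError(f"non-numeric metabolite column(s): {bad}")
    # restore integer/bool metadata dtypes where applicable
    for c in ("visit", "sex", "ethnicity", "smoking", "event"):
        if c in samples.columns and samples[c].notna().all():
            samples[c] = samples[c].astype(int)
    for c in ("fasting", "birth_cohort"):
        if c in samples.columns:
            samples[c] = samples[c].astype(bool)
    return samples, mets
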