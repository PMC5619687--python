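"""Shared TSV reading/writing.

All tabular artifacts are plain TSVs. Missing values are serialized as "NA";
lines beginning with '#' are provenance headers and are skipped on read.
"""

from __future__ import annotations

import os

import pandas as pd


def write_tsv(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a DataFrame as TSV, optionally prefixed with '# key=value' lines."""
    path = os.fspath(path)
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            for key, value in provenance.items():
                fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"],
                       keep_default_na=False, **kwargs)
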