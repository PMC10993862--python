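"""Dataset readers/writers and run manifests.

All tabular artifacts are delimited text. Ordinal response columns are
validated as integers within the declared category range; 1-based category
codes (the common survey coding) are shifted to the internal 0-based coding.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_dataset", "write_dataset", "write_manifest", "read_schema"]


def read_schema(path) -> dict:
    """Schema file (YAML/JSON): ``response_columns``, ``n_categories``,
    ``covariates`` (name -> kind)."""
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def read_dataset(path, schema: dict):
    """Read a delimited dataset and split into (responses, covariates).

    ``schema`` carries ``response_columns`` (list), ``n_categories`` (int or
    per-column dict; omit or null for numeric responses) and ``covariates``
    (name -> kind in {numeric, ordinal, categorical}).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad}; missing data are "
                         "not supported")
    resp_cols = list(schema["response_columns"])
    missing = [c for c in resp_cols if c not in df.columns]
    if missing:
        raise ValueError(f"response columns not in file: {missing}")
    ncat = schema.get("n_categories")
    data = df[resp_cols].copy()
    if ncat is not None:
        for col in resp_cols:
            k = int(ncat[col]) if isinstance(ncat, dict) else int(ncat)
            vals = df[col].to_numpy()
            if not np.allclose(vals, vals.astype(int)):
                raise ValueError(f"ordinal column {col!r} has non-integer values")
            vals = vals.astype(int)
            if vals.min() >= 1 and vals.max() <= k:
                vals = vals - 1  # accept 1-based coding and shift
            if vals.min() < 0 or vals.max() >= k:
                row = int(np.argmax((vals < 0) | (vals >= k)))
                raise ValueError(
                    f"category out of range in column {col!r} (row {row}): "
                    f"declared {k} categories")
            data[col] = vals
    covs = schema.get("covariates", {})
    zmissing = [c for c in covs if c not in df.columns]
    if zmissing:
        raise ValueError(f"covariate columns not in file: {zmissing}")
    z = df[list(covs.keys())].copy()
    for col, kind in covs.items():
        if kind == "ordinal":
            vals = z[col].to_numpy()
            if not np.allclose(vals, vals.astype(int)):
                raise ValueError(f"ordinal covariate {col!r} has non-integer "
                                 "values")
            z[col] = vals.astype(int)
        elif kind == "numeric":
            z[col] = z[col].astype(float)
    return data, z


def write_dataset(path, data, covariates=None, one_based: bool = True):
    """Write responses (and covariates) as tab-delimited text. Ordinal
    integer responses are emitted 1-based by default."""
    data = data.copy()
    if one_based:
        for col in data.columns:
            if np.issubdtype(data[col].dtype, np.integer):
                data[col] = data[col] + 1
    out = data if covariates is None else pd.concat(
        [data, covariates.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def write_manifest(path, payload: dict):
    """Run manifest: seeds, controls, versions -- enough to reproduce."""
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, frozenset):
            return sorted(o)
        return str(o)

    Path(path).write_text(json.dumps(payload, indent=2, default=default))
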