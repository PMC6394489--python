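"""Reading and writing: NONMEM-style CSV datasets and parameter configs.

The CSV dialect is comma-separated with a header row, case-insensitive
column names and ``.`` for missing values.  Parameter configurations are
YAML documents; the packaged default reproduces the published population
estimates together with their reported precision and bootstrap summary as
metadata.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimation import PKDataset
from .parameters import PopulationParameters

__all__ = [
    "read_nonmem_csv",
    "write_nonmem_csv",
    "parameters_to_yaml",
    "parameters_from_yaml",
    "load_default_parameters",
    "default_parameter_metadata",
]


def read_nonmem_csv(path) -> PKDataset:
    """Read a NONMEM-style rectangular dataset from CSV."""
    df = pd.read_csv(path, na_values=["."], skipinitialspace=True)
    df.columns = [str(c).strip().upper() for c in df.columns]
    return PKDataset(df)


def write_nonmem_csv(data: PKDataset | pd.DataFrame, path) -> None:
    """Write event records as CSV with '.' for missing values."""
    df = data.df if isinstance(data, PKDataset) else data
    df.to_csv(path, index=False, na_rep=".")


def parameters_to_yaml(pp: PopulationParameters, path) -> None:
    d = pp.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump({"parameters": d}, fh, sort_keys=False)


def parameters_from_yaml(path) -> PopulationParameters:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    block = doc.get("parameters", doc) if isinstance(doc, dict) else doc
    # percent-scale entries (omega_* given as e.g. 40.1) are accepted and
    # converted; the native scale is log-SD fractions
    clean = {}
    for k, v in block.items():
        if k.startswith("omega_") and k != "omega_cl_vc_cov" \
                and isinstance(v, (int, float)) and v > 10:
            clean[k] = v / 100.0
        elif k == "sigma_prop" and isinstance(v, (int, float)) and v > 5:
            clean[k] = v / 100.0
        else:
            clean[k] = v
    return PopulationParameters.from_dict(clean)


def _default_doc() -> dict:
    ref = resources.files("trastupk").joinpath("data/default_parameters.yaml")
    return yaml.safe_load(ref.read_text())


def load_default_parameters() -> PopulationParameters:
    """The packaged default parameter set (published final estimates)."""
    doc = _default_doc()
    return PopulationParameters.from_dict(doc["parameters"])


def default_parameter_metadata() -> dict:
    """Reported precision and bootstrap summary accompanying the default
    estimates (metadata only; never used in computation)."""
    return _default_doc()["metadata"]
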