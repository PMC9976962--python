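"""HDF5 and TSV readers/writers for the pipeline's standard layouts.

Beta/M matrices are stored in HDF5 with three datasets (``values``,
``probe_ids``, ``sample_ids``); tables (metadata, annotation, QC reports)
are tab-separated text with the id column first.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import BetaMatrix, MValueMatrix

_STR = h5py.string_dtype(encoding="utf-8")


def write_beta_h5(path, beta: BetaMatrix | MValueMatrix, **attrs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=beta.values, compression="gzip")
        f.create_dataset("probe_ids", data=np.asarray(beta.probe_ids, dtype=_STR))
        f.create_dataset("sample_ids", data=np.asarray(beta.sample_ids, dtype=_STR))
        f.attrs["matrix_kind"] = ("mvalue" if isinstance(beta, MValueMatrix)
                                  else "beta")
        for k, v in attrs.items():
            f.attrs[k] = v


def read_beta_h5(path) -> BetaMatrix | MValueMatrix:
    with h5py.File(path, "r") as f:
        values = f["values"][:]
        probe_ids = f["probe_ids"].asstr()[:].astype(object)
        sample_ids = f["sample_ids"].asstr()[:].astype(object)
        kind = f.attrs.get("matrix_kind", "beta")
    cls = MValueMatrix if kind == "mvalue" else BetaMatrix
    return cls(values, probe_ids, sample_ids)


def write_table(path, table: pd.DataFrame, index_label: str = "id") -> None:
    table.to_csv(path, sep="\t", index=True, index_label=index_label)


def read_table(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
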