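"""Shared I/O and seed-stream utilities.

All tabular artifacts are plain delimited text with a header row and a
sample-ID first column; matrices may be stored either orientation and are
normalized to samples-as-rows internally.  Randomness is organized around
one master seed: stage- and replicate-level child seeds are derived with
``numpy.random.SeedSequence(master, spawn_key=(stage, counter))`` so that
adding a stage never perturbs the draws of earlier stages.
"""

from __future__ import annotations

import hashlib
import pathlib

import numpy as np
import pandas as pd

__all__ = ["read_matrix", "write_matrix", "child_seed", "file_sha256"]

NA_VALUES = ["", "NA"]


def read_matrix(path, orientation: str = "samples_rows") -> pd.DataFrame:
    """Read a delimited matrix (CSV, or TSV by extension) with a header
    row and an ID first column; missing cells are empty or "NA"."""
    path = pathlib.Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=NA_VALUES, keep_default_na=False
    )
    if orientation == "features_rows":
        df = df.T
    elif orientation != "samples_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dups[:5]}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature IDs: {dups[:5]}")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    path = pathlib.Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep)


def child_seed(master: int, stage: int, counter: int = 0) -> int:
    """Deterministic per-stage child seed below 2**31."""
    state = np.random.SeedSequence(master, spawn_key=(stage, counter)).generate_state(1)
    return int(state[0] % (2**31 - 1))


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
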