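"""Loader for the packaged REBA / RULA / OWAS lookup tables.

The tables ship as long-format CSV data files inside the package (one row per
cell, 1-based indices) and are loaded into dense numpy arrays at import. The
CSVs are the single source of truth; tests compare them exhaustively against
a second, independently laid-out transcription of the published instruments.
"""

from __future__ import annotations

import csv
from importlib import resources

import numpy as np

_SPECS = {
    # name -> (index columns, shape)
    "reba_table_a": (("trunk", "neck", "legs"), (5, 3, 4)),
    "reba_table_b": (("upper_arm", "lower_arm", "wrist"), (6, 2, 3)),
    "reba_table_c": (("score_a", "score_b"), (12, 12)),
    "rula_table_a": (("upper_arm", "lower_arm", "wrist", "wrist_twist"), (6, 3, 4, 2)),
    "rula_table_b": (("neck", "trunk", "legs"), (6, 6, 2)),
    "rula_table_c": (("score_a", "score_b"), (8, 7)),
    "owas_categories": (("back", "arms", "legs", "load"), (4, 3, 7, 3)),
}


def _load(name: str) -> np.ndarray:
    index_cols, shape = _SPECS[name]
    value_col = "category" if name == "owas_categories" else "score"
    arr = np.full(shape, -1, dtype=int)
    ref = resources.files("ergopose.scales").joinpath(f"tables/{name}.csv")
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            idx = tuple(int(row[c]) - 1 for c in index_cols)
            arr[idx] = int(row[value_col])
    if (arr < 0).any():
        raise RuntimeError(f"table {name} has unfilled cells")
    return arr


REBA_TABLE_A = _load("reba_table_a")
REBA_TABLE_B = _load("reba_table_b")
REBA_TABLE_C = _load("reba_table_c")
RULA_TABLE_A = _load("rula_table_a")
RULA_TABLE_B = _load("rula_table_b")
RULA_TABLE_C = _load("rula_table_c")
OWAS_CATEGORIES = _load("owas_categories")
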