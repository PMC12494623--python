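"""Readers and writers for the package's plain-text formats.

Plate CSV (wide, canonical): one header row with ``sample_id, well_role``
followed by analyte identifiers, a second header-like row carrying the
analyte roles, then one row per well.  Clinical CSV: one header row keyed
by ``patient_id``.  Matrices: plain CSV with the patient id as index.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RawPlate

_ROLE_ROW_TAG = "#analyte_role"


def write_plate(plate: RawPlate, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "well_role", *plate.mfi.columns])
        writer.writerow([_ROLE_ROW_TAG, "", *plate.analyte_role.reindex(plate.mfi.columns)])
        for sid in plate.mfi.index:
            values = plate.mfi.loc[sid]
            writer.writerow(
                [sid, plate.well_role[sid], *[_fmt(v) for v in values]]
            )


def _fmt(v):
    f = float(v)
    return int(f) if f.is_integer() else f


def read_plate(path) -> RawPlate:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        role_row = next(reader)
        if role_row[0] != _ROLE_ROW_TAG:
            raise ValueError(f"{path}: second row must carry analyte roles")
        analytes = header[2:]
        roles = pd.Series(role_row[2:], index=analytes, name="analyte_role")
        sample_ids, well_roles, data = [], [], []
        for row in reader:
            if not row:
                continue
            sample_ids.append(row[0])
            well_roles.append(row[1])
            data.append([float(v) for v in row[2:]])
    mfi = pd.DataFrame(data, index=sample_ids, columns=analytes, dtype=float)
    return RawPlate(
        mfi=mfi,
        well_role=pd.Series(well_roles, index=sample_ids, name="well_role"),
        analyte_role=roles,
    )


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index=True, index_label="patient_id")


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id")


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index=True, index_label="patient_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id")


def write_edges(graph, path) -> None:
    """STRING-style ``protein1 protein2 combined_score`` list (0-1000 scale)."""
    import networkx as nx  # local import keeps io importable without graphs

    G = graph.graph if hasattr(graph, "graph") and not isinstance(graph, nx.Graph) else graph
    with Path(path).open("w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for u, v, d in G.edges(data=True):
            fh.write(f"{u} {v} {int(round(d['strength'] * 1000))}\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, tuple, set)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, list):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def write_json(payload: dict, path) -> None:
    with Path(path).open("w") as fh:
        json.dump(_jsonable(payload), fh, indent=2, sort_keys=True)


def read_json(path) -> dict:
    with Path(path).open() as fh:
        return json.load(fh)
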