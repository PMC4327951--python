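"""Packaged reference tables.

Two small delimited tables from the clinical validation study ship with
the package:

* ``cohort_rmsd`` — per-patient RMSD between the manual and automatic
  spine curves (frontal and sagittal planes) for the 24-patient scoliosis
  cohort, with anthropometric characteristics;
* ``interoperator_rmsd`` — the inter-operator assessment: 8 software
  operators, each analyzing the same scan three times.

The curve data behind these numbers (the raw patient scans) is not
publicly deposited; the tables serve as inputs for the summary-statistics
stage and as reference magnitudes for synthetic experiments.
"""

from __future__ import annotations

import csv
from importlib import resources

import numpy as np

__all__ = ["load_cohort_rmsd", "load_interoperator_rmsd"]


def _read_csv(name: str) -> tuple[list[str], list[list[str]]]:
    ref = resources.files("spinecurve.data").joinpath(name)
    with ref.open("r", newline="") as fh:
        rows = list(csv.reader(fh))
    return rows[0], rows[1:]


def load_cohort_rmsd() -> dict[str, np.ndarray]:
    """Per-patient cohort table as a dict of column arrays.

    Numeric columns are float arrays; ``sex`` stays a string array.
    """
    header, rows = _read_csv("cohort_rmsd.csv")
    cols = {h: [r[i] for r in rows] for i, h in enumerate(header)}
    out: dict[str, np.ndarray] = {}
    for name, vals in cols.items():
        if name == "sex":
            out[name] = np.array(vals)
        else:
            out[name] = np.array(vals, dtype=float)
    return out


def load_interoperator_rmsd() -> dict[str, np.ndarray]:
    """Inter-operator table (8 operators x 3 repeats) as column arrays."""
    header, rows = _read_csv("interoperator_rmsd.csv")
    return {h: np.array([r[i] for r in rows], dtype=float)
            for i, h in enumerate(header)}
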