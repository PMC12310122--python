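"""Cohort and configuration I/O.

Longitudinal cohorts travel in two equivalent containers:

* a long-format CSV with columns ``patient_id, age_years, variable,
  node_1..node_n`` — one row per (patient, visit, variable); the scalar
  cognitive score appears as variable ``"C"`` with its value in ``node_1``;
* an HDF5 container with one group per patient holding ``times``, the field
  matrices, scores, and (for synthetic patients) the noise-free truth and
  the generating progression rate.

Both round-trip losslessly to float64 and are written deterministically
(HDF5 object timestamps disabled), so identical cohorts yield identical
bytes.  Run configurations are YAML; every artifact records the
configuration hash and seed used to produce it.
"""

from __future__ import annotations

import hashlib
import json

import h5py
import numpy as np
import pandas as pd
import yaml

from .cohort import Trajectory

__all__ = ["cohort_to_frame", "frame_to_cohort", "write_cohort_csv",
           "read_cohort_csv", "write_cohort_h5", "read_cohort_h5",
           "load_graph_matrix", "load_yaml", "config_hash"]

_FIELD_VARS = ("A", "tau", "N")


def cohort_to_frame(cohort: list[Trajectory]) -> pd.DataFrame:
    """Long-format table of a cohort (observed values only)."""
    n = next(iter(cohort[0].fields.values())).shape[1]
    cols = [f"node_{i + 1}" for i in range(n)]
    rows = []
    for traj in cohort:
        for t_idx, age in enumerate(traj.times):
            for v in _FIELD_VARS:
                if v in traj.fields:
                    rows.append({"patient_id": traj.patient_id,
                                 "age_years": age, "variable": v,
                                 **dict(zip(cols, traj.fields[v][t_idx]))})
            rows.append({"patient_id": traj.patient_id, "age_years": age,
                         "variable": "C", "node_1": traj.C[t_idx]})
    return pd.DataFrame(rows)


def frame_to_cohort(df: pd.DataFrame) -> list[Trajectory]:
    node_cols = [c for c in df.columns if c.startswith("node_")]
    cohort = []
    for pid, sub in df.groupby("patient_id", sort=True):
        ages = np.sort(sub["age_years"].unique())
        fields = {}
        for v in _FIELD_VARS:
            rows = sub[sub["variable"] == v].sort_values("age_years")
            if len(rows):
                fields[v] = rows[node_cols].to_numpy(dtype=float)
        crows = sub[sub["variable"] == "C"].sort_values("age_years")
        C = crows["node_1"].to_numpy(dtype=float) if len(crows) \
            else np.full(len(ages), np.nan)
        cohort.append(Trajectory(patient_id=str(pid), times=ages,
                                 fields=fields, C=C))
    return cohort


def write_cohort_csv(cohort: list[Trajectory], path: str) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False, float_format="%.17g")


def read_cohort_csv(path: str) -> list[Trajectory]:
    return frame_to_cohort(pd.read_csv(path))


def write_cohort_h5(cohort: list[Trajectory], path: str,
                    meta: dict | None = None) -> None:
    with h5py.File(path, "w") as fh:
        if meta:
            for k, v in sorted(meta.items()):
                fh.attrs[k] = v
        for traj in cohort:
            g = fh.create_group(f"patients/{traj.patient_id}")
            g.create_dataset("times", data=traj.times, track_times=False)
            g.create_dataset("C", data=traj.C, track_times=False)
            g.attrs["gamma_true"] = traj.gamma_true
            for v, arr in traj.fields.items():
                g.create_dataset(v, data=arr, track_times=False)
            if traj.truth_fields is not None:
                for v, arr in traj.truth_fields.items():
                    g.create_dataset(f"truth_{v}", data=arr,
                                     track_times=False)
            if traj.truth_C is not None:
                g.create_dataset("truth_C", data=traj.truth_C,
                                 track_times=False)


def read_cohort_h5(path: str) -> list[Trajectory]:
    cohort = []
    with h5py.File(path, "r") as fh:
        for pid in sorted(fh["patients"]):
            g = fh[f"patients/{pid}"]
            fields = {v: g[v][()] for v in _FIELD_VARS if v in g}
            truth = {v: g[f"truth_{v}"][()] for v in _FIELD_VARS
                     if f"truth_{v}" in g}
            cohort.append(Trajectory(
                patient_id=pid, times=g["times"][()], fields=fields,
                C=g["C"][()], gamma_true=float(g.attrs.get("gamma_true", 1.0)),
                truth_fields=truth or None,
                truth_C=g["truth_C"][()] if "truth_C" in g else None))
    return cohort


def load_graph_matrix(path: str) -> np.ndarray:
    """Read a connectivity matrix from dense CSV or (i, j, weight) TSV.

    The delimiter decides the layout: comma-separated files are dense n x n
    matrices (header row optional), tab-separated files are 0-based edge
    lists, symmetrized on read.
    """
    with open(path) as fh:
        first_line = fh.readline()
    if "\t" in first_line:
        edges = pd.read_csv(path, sep="\t", header=None, comment="#")
        edges.columns = ["i", "j", "w"]
        n = int(max(edges["i"].max(), edges["j"].max())) + 1
        W = np.zeros((n, n))
        for _, row in edges.iterrows():
            i, j = int(row["i"]), int(row["j"])
            W[i, j] = W[j, i] = float(row["w"])
        return W
    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False
    has_header = not all(_numeric(t) for t in first_line.strip().split(","))
    df = pd.read_csv(path, header=0 if has_header else None)
    return df.to_numpy(dtype=float)


def load_yaml(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping (for provenance)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
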