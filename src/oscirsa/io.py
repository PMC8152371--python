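"""Readers and writers for every persisted artifact.

Conventions: square matrices (RDMs, maps) as tab-delimited text with 17
significant digits (lossless float round-trip); array containers (epochs,
stacks, TF coefficients) as NumPy ``.npz`` with a JSON sidecar carrying
labels, grids, seeds, and a schema tag; structured results (cluster
results, scores, reports, configs) as JSON/YAML.  Every loader validates
the schema tag and shape invariants instead of silently misparsing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .cluster import ClusterResult
from .rdm import RDM, RDMStack
from .simulate import EpochSet
from .tf import TFGrid

SCHEMA = "oscirsa-v1"
FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """Raised when a file was not written by this package's current schema."""


def _check_schema(meta: dict, path) -> None:
    tag = meta.get("schema")
    if tag != SCHEMA:
        raise SchemaError(f"{path}: expected schema {SCHEMA!r}, found {tag!r}")


# -- epochs -----------------------------------------------------------------

def save_epochs(path, epochs: EpochSet) -> None:
    """Write an EpochSet as ``<path>.npz`` plus ``<path>.json`` sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=epochs.data)
    sidecar = {
        "schema": SCHEMA,
        "kind": "epochs",
        "sfreq": epochs.sfreq,
        "tmin": epochs.tmin,
        "condition_labels": list(epochs.condition_labels),
        "meta": epochs.meta,
        "shape": list(epochs.data.shape),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_epochs(path) -> EpochSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    _check_schema(meta, path)
    if meta.get("kind") != "epochs":
        raise SchemaError(f"{path}: not an epochs container")
    data = np.load(path.with_suffix(".npz"))["data"]
    if list(data.shape) != meta["shape"]:
        raise SchemaError(f"{path}: array shape does not match sidecar")
    return EpochSet(data, meta["sfreq"], meta["tmin"],
                    meta["condition_labels"], meta.get("meta", {}))


# -- RDMs -------------------------------------------------------------------

def save_rdm(path, rdm: RDM) -> None:
    """Square delimited-text matrix with a header row of condition labels."""
    path = Path(path)
    header = "\t".join(str(l) for l in rdm.labels)
    np.savetxt(path, rdm.matrix, fmt=FLOAT_FMT, delimiter="\t",
               header=header, comments="# ")


def load_rdm(path) -> RDM:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("# "):
        raise SchemaError(f"{path}: missing label header row")
    labels = first[2:].rstrip("\n").split("\t")
    matrix = np.loadtxt(path, delimiter="\t", ndmin=2)
    if matrix.shape != (len(labels), len(labels)):
        raise SchemaError(f"{path}: matrix shape does not match header labels")
    return RDM(matrix, labels)


# -- RDM stacks -------------------------------------------------------------

def save_stack(path, stack: RDMStack) -> None:
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), vectors=stack.vectors,
                        valid=stack.valid, freqs=stack.freqs, times=stack.times)
    sidecar = {
        "schema": SCHEMA,
        "kind": "rdm_stack",
        "kinds": list(stack.kinds),
        "labels": list(stack.labels),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_stack(path) -> RDMStack:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    _check_schema(meta, path)
    if meta.get("kind") != "rdm_stack":
        raise SchemaError(f"{path}: not an RDM stack container")
    arr = np.load(path.with_suffix(".npz"))
    return RDMStack(arr["vectors"], meta["kinds"], arr["freqs"], arr["times"],
                    meta["labels"], arr["valid"])


# -- TF maps ----------------------------------------------------------------

def save_map(path, values: np.ndarray, grid: TFGrid, meta: dict | None = None) -> None:
    """A (freq x time) map as delimited text plus JSON metadata."""
    path = Path(path)
    np.savetxt(path.with_suffix(".tsv"), values, fmt=FLOAT_FMT, delimiter="\t")
    sidecar = {
        "schema": SCHEMA,
        "kind": "tf_map",
        "freqs": grid.freqs.tolist(),
        "times": grid.times.tolist(),
        "window_cycles": grid.window_cycles,
        "smoothing_factor": grid.smoothing_factor,
    }
    if meta:
        sidecar["meta"] = meta
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_map(path) -> tuple[np.ndarray, TFGrid, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    _check_schema(meta, path)
    if meta.get("kind") != "tf_map":
        raise SchemaError(f"{path}: not a TF map")
    values = np.loadtxt(path.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    grid = TFGrid(np.asarray(meta["freqs"]), np.asarray(meta["times"]),
                  meta["window_cycles"], meta["smoothing_factor"])
    if values.shape != (grid.n_freqs, grid.n_times):
        raise SchemaError(f"{path}: map shape does not match grid")
    return values, grid, meta.get("meta", {})


# -- cluster results --------------------------------------------------------

def save_cluster_result(path, result: ClusterResult) -> None:
    path = Path(path)
    payload = {
        "schema": SCHEMA,
        "kind": "cluster_result",
        "chosen_k": result.chosen_k,
        "replicates": result.replicates,
        "seed": result.seed,
        "rss_curve": {str(k): v for k, v in result.rss_curve.items()},
        "assignments": [
            {"kind": kind, "freq_idx": fi, "time_idx": ti, "cluster": c}
            for (kind, fi, ti), c in result.assignments.items()
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(payload, indent=1))
    np.savetxt(path.with_suffix(".centroids.tsv"), result.centroids,
               fmt=FLOAT_FMT, delimiter="\t")


def load_cluster_result(path) -> ClusterResult:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    _check_schema(meta, path)
    if meta.get("kind") != "cluster_result":
        raise SchemaError(f"{path}: not a cluster result")
    centroids = np.loadtxt(path.with_suffix(".centroids.tsv"),
                           delimiter="\t", ndmin=2)
    assignments = {(a["kind"], a["freq_idx"], a["time_idx"]): a["cluster"]
                   for a in meta["assignments"]}
    rss = {int(k): v for k, v in meta["rss_curve"].items()}
    index = [(a["kind"], a["freq_idx"], a["time_idx"]) for a in meta["assignments"]]
    return ClusterResult(assignments, centroids, rss, meta["chosen_k"],
                         meta["replicates"], meta["seed"], index)


# -- scores -----------------------------------------------------------------

def save_json(path, payload: dict) -> None:
    payload = {"schema": SCHEMA, **payload}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_json(path) -> dict:
    meta = json.loads(Path(path).read_text())
    _check_schema(meta, path)
    return meta
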