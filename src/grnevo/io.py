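"""Serialization: network JSON, population CSV, tidy time series, manifests.

Networks round-trip through JSON losslessly: Python's JSON float formatting
uses the shortest representation that reproduces the exact double, so weights
survive write/read bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional
from zlib import crc32

import numpy as np
import pandas as pd

from .core import RegulatoryNetwork, develop_batch
from .errors import GrnError
from .evolution import Population

FORMAT_VERSION = 1


def network_to_dict(net: RegulatoryNetwork) -> dict:
    ii, jj = np.nonzero(net.mask)
    return {
        "format": FORMAT_VERSION,
        "N": net.N,
        "c": net.c,
        "links": [[int(i), int(j)] for i, j in zip(ii, jj)],
        "weights": [float(w) for w in net.weights[ii, jj]],
    }


def network_from_dict(doc: dict) -> RegulatoryNetwork:
    N = int(doc["N"])
    mask = np.zeros((N, N), dtype=bool)
    weights = np.zeros((N, N))
    links = doc["links"]
    vals = doc["weights"]
    if len(links) != len(vals):
        raise GrnError("links and weights length mismatch")
    for (i, j), w in zip(links, vals):
        mask[i, j] = True
        weights[i, j] = w
    return RegulatoryNetwork(weights, mask)


def save_network(net: RegulatoryNetwork, path) -> None:
    Path(path).write_text(json.dumps(network_to_dict(net)))


def load_network(path) -> RegulatoryNetwork:
    return network_from_dict(json.loads(Path(path).read_text()))


def network_to_csv(net: RegulatoryNetwork, path) -> None:
    """Dense matrix export; zeros mark absent interactions."""
    pd.DataFrame(net.weights).to_csv(path, index=False, header=False)


def save_expression_state(s: np.ndarray, path) -> None:
    Path(path).write_text(json.dumps([float(x) for x in np.asarray(s, float)]))


def load_expression_state(path) -> np.ndarray:
    return np.asarray(json.loads(Path(path).read_text()), dtype=float)


def save_population(pop: Population, path) -> None:
    """Population as CSV (one member per row, one non-zero locus per column)
    with a JSON sidecar holding topology, s0 and generation."""
    path = Path(path)
    ii, jj = np.nonzero(pop.mask)
    cols = [f"w_{i}_{j}" for i, j in zip(ii, jj)]
    flat = pop.weights.reshape(pop.size, -1)[:, pop.mask.ravel()]
    pd.DataFrame(flat, columns=cols).to_csv(path, index=False, float_format=None)
    sidecar = {
        "format": FORMAT_VERSION,
        "N": int(pop.mask.shape[0]),
        "links": [[int(i), int(j)] for i, j in zip(ii, jj)],
        "s0": [float(x) for x in pop.s0],
        "generation": int(pop.generation),
    }
    path.with_suffix(path.suffix + ".manifest.json").write_text(json.dumps(sidecar))


def load_population(path, steps: int = 100, a: float = 1.0, threshold: float = 1e-4) -> Population:
    """Rebuild a population from CSV + sidecar; phenotypes are re-developed."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".manifest.json").read_text())
    N = sidecar["N"]
    mask = np.zeros((N, N), dtype=bool)
    for i, j in sidecar["links"]:
        mask[i, j] = True
    table = pd.read_csv(path, float_precision="round_trip")
    K = table.shape[0]
    weights = np.zeros((K, N, N))
    weights.reshape(K, -1)[:, mask.ravel()] = table.to_numpy(dtype=float)
    s0 = np.asarray(sidecar["s0"], dtype=float)
    phen, _, _, _ = develop_batch(weights, s0, steps=steps, a=a, threshold=threshold)
    return Population(
        weights=weights,
        mask=mask,
        s0=s0,
        phenotypes=phen,
        generation=int(sidecar.get("generation", 0)),
    )


def write_timeseries(records: pd.DataFrame, path, manifest: Optional[dict] = None) -> None:
    """Tidy metric time series to CSV plus an optional JSON sidecar manifest."""
    path = Path(path)
    df = pd.DataFrame(records, columns=["generation", "metric", "value"])
    df.to_csv(path, index=False)
    if manifest is not None:
        path.with_suffix(path.suffix + ".manifest.json").write_text(
            json.dumps(manifest, indent=2, default=_json_default)
        )


def read_timeseries(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["generation", "metric", "value"]
    if list(df.columns) != expected:
        raise GrnError(f"time series must have columns {expected}")
    return df


def _json_default(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def network_checksum(net: RegulatoryNetwork) -> str:
    """Stable content checksum of a genotype (topology + exact weights)."""
    payload = json.dumps(network_to_dict(net)).encode()
    return f"{crc32(payload):08x}"


@dataclass
class RunManifest:
    """Reproducibility record: config + seeds + founder checksum."""

    config: dict
    master_seed: Optional[int]
    derived_seeds: dict
    founder_checksum: str
    artifact_version: str = "0.1.0"
    started: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())
    finished: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "master_seed": self.master_seed,
            "derived_seeds": self.derived_seeds,
            "founder_checksum": self.founder_checksum,
            "artifact_version": self.artifact_version,
            "started": self.started,
            "finished": self.finished,
        }
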