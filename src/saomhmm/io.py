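"""File formats: panel manifests, adjacency CSVs, covariate tables,
effects configuration and estimator reports.

Conventions: adjacency matrices are plain 0/1 CSV without header, one
file per wave; a JSON manifest lists the wave files, observation times,
directedness and 1-based node labels.  Reports are self-describing JSON.
Node indexing is 0-based in memory and 1-based in every file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .effects import ActorCovariate, DyadCovariate, EffectSpec
from .estimation import EstimatorReport
from .networks import DirectedNetwork, NetworkPanel

__all__ = [
    "read_panel", "write_panel",
    "read_actor_covariates", "write_actor_covariates",
    "read_dyad_covariate", "write_dyad_covariate",
    "read_effects_config", "write_report", "read_report",
    "config_hash",
]


def _read_adjacency(path: Path, directed: bool) -> DirectedNetwork:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            vals = []
            for col, c in enumerate(cells, start=1):
                c = c.strip()
                if c not in ("0", "1"):
                    raise ValueError(
                        f"{path}:{ln}: cell {col} is {c!r}, expected 0 or 1")
                vals.append(int(c))
            rows.append(vals)
    lens = {len(r) for r in rows}
    if len(lens) != 1 or len(rows) not in lens:
        raise ValueError(f"{path}: adjacency matrix is ragged or non-square")
    return DirectedNetwork(np.array(rows, dtype=np.int8), directed)


def read_panel(manifest_path: str | Path) -> NetworkPanel:
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        man = json.load(fh)
    for key in ("waves", "times", "directed"):
        if key not in man:
            raise ValueError(f"{manifest_path}: manifest missing key {key!r}")
    times = np.asarray(man["times"], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{manifest_path}: times must be strictly increasing")
    base = manifest_path.parent
    nets = [_read_adjacency(base / w, bool(man["directed"]))
            for w in man["waves"]]
    return NetworkPanel(networks=nets, times=times,
                        role=man.get("role", "observed"))


def write_panel(panel: NetworkPanel, out_dir: str | Path,
                stem: str = "wave") -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wave_files = []
    for m, net in enumerate(panel.networks, start=1):
        fname = f"{stem}{m}.csv"
        np.savetxt(out_dir / fname, net.adjacency, fmt="%d", delimiter=",")
        wave_files.append(fname)
    manifest = {
        "waves": wave_files,
        "times": panel.times.tolist(),
        "directed": panel.directed,
        "role": panel.role,
        "node_labels": list(range(1, panel.n_nodes + 1)),
    }
    mpath = out_dir / "panel.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return mpath


def read_actor_covariates(path: str | Path,
                          n_nodes: int | None = None
                          ) -> dict[str, ActorCovariate]:
    """CSV with a 1-based ``node`` label column plus one column per
    covariate; every node must appear exactly once."""
    df = pd.read_csv(path)
    if "node" not in df.columns:
        raise ValueError(f"{path}: missing required 'node' column")
    labels = df["node"].astype(int).to_numpy()
    n = n_nodes if n_nodes is not None else labels.max()
    missing = sorted(set(range(1, n + 1)) - set(labels.tolist()))
    if missing:
        raise ValueError(f"{path}: missing node labels {missing}")
    order = np.argsort(labels)
    out = {}
    for col in df.columns:
        if col == "node":
            continue
        out[col] = ActorCovariate(col, df[col].to_numpy(dtype=float)[order])
    return out


def write_actor_covariates(covs: Mapping[str, ActorCovariate],
                           path: str | Path) -> None:
    n = len(next(iter(covs.values())).values)
    df = pd.DataFrame({"node": np.arange(1, n + 1)})
    for name, cov in covs.items():
        df[name] = cov.values
    df.to_csv(path, index=False)


def read_dyad_covariate(path: str | Path, name: str,
                        centered: bool = True) -> DyadCovariate:
    vals = np.loadtxt(path, delimiter=",", ndmin=2)
    return DyadCovariate(name, vals, centered=centered)


def write_dyad_covariate(cov: DyadCovariate, path: str | Path) -> None:
    np.savetxt(path, cov.values, fmt="%.10g", delimiter=",")


def read_effects_config(path: str | Path) -> tuple[list[EffectSpec], dict]:
    """YAML/JSON effects list: ``[{effect, covariate?, initial?, fixed?}]``.

    Returns the specs plus a dict of extra per-effect options (initial
    values, fixed flags) keyed by effect label."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, dict):
        entries = doc.get("effects")
        extra_keys = set(doc) - {"effects"}
        if extra_keys:
            raise ValueError(f"{path}: unknown top-level keys {sorted(extra_keys)}")
    else:
        entries = doc
    if not isinstance(entries, list) or not entries:
        raise ValueError(f"{path}: expected a non-empty list of effects")
    specs = []
    options = {}
    for k, ent in enumerate(entries):
        if not isinstance(ent, dict) or "effect" not in ent:
            raise ValueError(f"{path}: entry {k + 1} needs an 'effect' key")
        unknown = set(ent) - {"effect", "covariate", "initial", "fixed"}
        if unknown:
            raise ValueError(
                f"{path}: entry {k + 1} has unknown keys {sorted(unknown)}")
        spec = EffectSpec(ent["effect"], ent.get("covariate"))
        specs.append(spec)
        options[spec.label] = {"initial": float(ent.get("initial", 0.0)),
                               "fixed": bool(ent.get("fixed", False))}
    return specs, options


def write_report(report: EstimatorReport, path: str | Path,
                 seed: int | None = None, extra: dict | None = None) -> None:
    doc = {
        "labels": report.labels,
        "estimates": report.estimates.tolist(),
        "se": report.se.tolist() if report.se is not None else None,
        "t_ratios": (report.t_ratios.tolist()
                     if report.t_ratios is not None else None),
        "method": report.method,
        "converged": report.converged,
        "diverged": report.diverged,
        "iterations": report.iterations,
        "settings": report.settings,
        "diagnostics": report.diagnostics,
        "warnings": report.warnings,
        "seed": seed,
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_report(path: str | Path) -> EstimatorReport:
    with open(path) as fh:
        doc = json.load(fh)
    return EstimatorReport(
        labels=doc["labels"],
        estimates=np.asarray(doc["estimates"], dtype=float),
        se=(np.asarray(doc["se"], dtype=float)
            if doc.get("se") is not None else None),
        method=doc["method"],
        converged=doc["converged"],
        diverged=doc.get("diverged", False),
        iterations=doc["iterations"],
        settings=doc.get("settings", {}),
        diagnostics=doc.get("diagnostics", {}),
        warnings=doc.get("warnings", []),
    )


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
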