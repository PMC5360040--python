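"""Readers, writers and run manifests.

File conventions: gene identifiers in files are 1-based integer indices
(mapped to 0-based internally).  Tab-separated values are canonical; comma
delimiters are accepted on read.  Time-course files carry a header row whose
first cell is ``time`` followed by the strictly increasing sample times, then
one row per gene.  Edge lists carry (source, target, role[, K | frequency])
columns; SIF export writes ``source activates|inhibits target`` lines for
Cytoscape.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import CandidateSubnetwork, EnsembleResult, FitResult
from .model import TimeCourseDataset
from .netgen import Edge, NetworkTopology
from .stats import PredictionSet


class ParseError(ValueError):
    """Malformed input file; message carries the offending line."""


def _sniff_sep(path: Path) -> str:
    head = Path(path).read_text().splitlines()[0] if Path(path).stat().st_size else ""
    return "," if ("," in head and "\t" not in head) else "\t"


def read_timecourse(path, experiment_id: str | None = None) -> TimeCourseDataset:
    """Read a genes x timepoints matrix with a leading time header row."""
    path = Path(path)
    sep = _sniff_sep(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split(sep)
    try:
        times = np.array([float(v) for v in header[1:]])
    except ValueError as exc:
        raise ParseError(f"{path}, line 1: non-numeric time value ({exc})") from None
    if times.size < 2 or np.any(np.diff(times) <= 0):
        raise ParseError(f"{path}, line 1: times must be strictly increasing")
    rows: dict[int, np.ndarray] = {}
    for ln_no, line in enumerate(lines[1:], start=2):
        cells = line.split(sep)
        if len(cells) != times.size + 1:
            raise ParseError(f"{path}, line {ln_no}: expected {times.size + 1} columns, "
                             f"got {len(cells)}")
        try:
            gid = int(cells[0])
            vals = np.array([float(v) for v in cells[1:]])
        except ValueError:
            raise ParseError(f"{path}, line {ln_no}: non-numeric cell") from None
        if gid in rows:
            raise ParseError(f"{path}, line {ln_no}: duplicate gene identifier {gid}")
        rows[gid] = vals
    n = len(rows)
    if sorted(rows) != list(range(1, n + 1)):
        raise ParseError(f"{path}: gene identifiers must be 1..{n}")
    matrix = np.vstack([rows[g] for g in range(1, n + 1)])
    return TimeCourseDataset(timepoints=times, matrix=matrix,
                             experiment_id=experiment_id or path.stem)


def write_timecourse(dataset: TimeCourseDataset, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("time\t" + "\t".join(f"{t:g}" for t in dataset.timepoints) + "\n")
        for g in range(dataset.n_genes):
            fh.write(str(g + 1) + "\t"
                     + "\t".join(repr(float(v)) for v in dataset.matrix[g]) + "\n")


_ROLE_VERB = {"activator": "activates", "inhibitor": "inhibits"}
_VERB_ROLE = {v: k for k, v in _ROLE_VERB.items()}


def _sorted_edge_rows(obj) -> list[tuple[int, int, str, float]]:
    if isinstance(obj, NetworkTopology):
        rows = [(e.source, e.target, e.role, e.K) for e in obj.edges]
    elif isinstance(obj, PredictionSet):
        rows = [(r, t, role, float("nan")) for t, r, role in obj.edges]
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__} as a network")
    return sorted(rows, key=lambda r: (r[1], r[0], r[2]))


def write_network(obj, path, fmt: str = "tsv",
                  weights: Mapping[tuple[int, int, str], float] | None = None,
                  weight_col: str = "K") -> None:
    """Write a topology or prediction set as TSV or Cytoscape SIF.

    Rows are sorted by (target, source) so outputs are diffable.  ``weights``
    may override the per-edge value column, keyed by 0-based
    (source, target, role).
    """
    path = Path(path)
    rows = _sorted_edge_rows(obj)
    if fmt == "sif":
        with path.open("w") as fh:
            for s, t, role, _ in rows:
                fh.write(f"{s + 1}\t{_ROLE_VERB[role]}\t{t + 1}\n")
        return
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}")
    with path.open("w") as fh:
        fh.write(f"source\ttarget\trole\t{weight_col}\n")
        for s, t, role, k in rows:
            if weights is not None:
                k = weights.get((s, t, role), float("nan"))
            fh.write(f"{s + 1}\t{t + 1}\t{role}\t{k:g}\n")


def read_network(path, n_genes: int | None = None) -> NetworkTopology:
    """Read an edge-list TSV (or SIF) back into a topology."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    edges = []
    for ln_no, line in enumerate(lines, start=1):
        cells = line.split("\t") if "\t" in line else line.split(",")
        if ln_no == 1 and cells and cells[0] == "source":
            continue
        if len(cells) == 3 and cells[1] in _VERB_ROLE:  # SIF
            s, verb, t = cells
            role, k = _VERB_ROLE[verb], float("nan")
        elif len(cells) >= 3:
            s, t, role = cells[:3]
            k = float(cells[3]) if len(cells) > 3 and cells[3] not in ("", "nan") else float("nan")
        else:
            raise ParseError(f"{path}, line {ln_no}: expected >= 3 columns")
        try:
            edges.append(Edge(int(s) - 1, int(t) - 1, role, k))
        except ValueError:
            raise ParseError(f"{path}, line {ln_no}: bad edge row {line!r}") from None
    n = n_genes or (max((max(e.source, e.target) for e in edges), default=-1) + 1)
    return NetworkTopology(n_genes=n, edges=tuple(edges))


def topology_to_prediction(topology: NetworkTopology) -> PredictionSet:
    return PredictionSet(n_genes=topology.n_genes,
                         edges=frozenset((e.target, e.source, e.role) for e in topology.edges))


def write_ensembles(results: Mapping[int, EnsembleResult], path, *,
                    n_genes: int, p0_role: float, meta: dict | None = None) -> None:
    """Serialize per-gene ensembles (1-based gene ids) as JSON."""
    doc = {"n_genes": n_genes, "p0_role": p0_role, **(meta or {}), "genes": {}}
    for g, res in sorted(results.items()):
        doc["genes"][str(g + 1)] = {
            "experiment_id": res.experiment_id,
            "trials": res.trials,
            "error": res.error,
            "accepted": [
                {
                    "activators": [i + 1 for i in f.candidate.activators],
                    "inhibitors": [i + 1 for i in f.candidate.inhibitors],
                    "k_act": list(f.k_act), "k_inh": list(f.k_inh),
                    "r0": f.r0, "d": f.d, "e": f.e, "cost": f.cost,
                }
                for f in res.accepted
            ],
        }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_ensembles(path) -> tuple[dict[int, EnsembleResult], dict]:
    doc = json.loads(Path(path).read_text())
    results: dict[int, EnsembleResult] = {}
    for gid, entry in doc["genes"].items():
        g = int(gid) - 1
        res = EnsembleResult(target=g, experiment_id=entry.get("experiment_id", ""),
                             trials=entry["trials"], error=entry.get("error"))
        for a in entry["accepted"]:
            cand = CandidateSubnetwork(
                target=g,
                activators=tuple(i - 1 for i in a["activators"]),
                inhibitors=tuple(i - 1 for i in a["inhibitors"]),
            )
            res.accepted.append(FitResult(cand, tuple(a["k_act"]), tuple(a["k_inh"]),
                                          a["r0"], a["d"], a["e"], a["cost"], True))
        results[g] = res
    meta = {k: v for k, v in doc.items() if k != "genes"}
    return results, meta


def write_frequency_table(scores, path) -> None:
    """Edge-frequency TSV: target, regulator, role, count, frequency, p_value."""
    df = pd.DataFrame(
        [(s.target + 1, s.regulator + 1, s.role, s.count, s.frequency, s.p_value)
         for s in scores],
        columns=["target", "regulator", "role", "count", "frequency", "p_value"],
    ).sort_values(["target", "regulator", "role"])
    df.to_csv(path, sep="\t", index=False)


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, *, command: str, seed: int | None, config: Mapping,
                   inputs: Iterable = (), outputs: Iterable = ()) -> None:
    """Record everything needed to reproduce a run bit-for-bit."""
    from . import __version__

    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return clean(dataclasses.asdict(obj))
        if isinstance(obj, Mapping):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple, set, frozenset)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    doc = {
        "tool": "hillsemble",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config": clean(config),
        "inputs": {str(p): file_sha256(p) for p in inputs},
        "outputs": {str(p): file_sha256(p) for p in outputs},
    }
    Path(path).write_text(json.dumps(doc, indent=1))
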