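"""Readers and writers for the plain-text interchange formats.

- Network: TSV edge list with header ``source  target  sign  probability``
  (sign in {+, -, ?}; probability column optional/blank).  Node order is
  first-appearance order unless an explicit node-list file is supplied.
- Rule tables: a single JSON document ``{node: {"parents": [...],
  "p_on": [...]}}`` or a directory of per-node CSVs (one column per parent,
  last column the ON-probability; one row per parent combination) matching
  BooleaBayes-style lookup-table exports.
- States: JSON mapping state name -> {node: 0/1}; one file may hold several
  named attractors.
- Trees: TSV edge list plus a JSON sidecar with the objective values.
- Trajectory logs: TSV ``iteration  node  new_bit`` (optionally gzipped).
"""

from __future__ import annotations

import csv
import gzip
import json
from pathlib import Path

import numpy as np

from .boolean_sim import NetworkState, RuleTable, Trajectory
from .dst_search import MDST, ObjectiveValue, TreeArchive
from .graph_core import Edge, Network, SpanningTree, UndirectedGraph
from .dst_search import evaluate_tree

__all__ = [
    "load_network",
    "write_network",
    "load_rules",
    "write_rules",
    "load_states",
    "write_states",
    "write_archive",
    "load_archive",
    "write_trajectory",
    "load_trajectory",
]


class FormatError(ValueError):
    """Malformed input file; message carries the path and line number."""


def load_network(path, node_list: Path | None = None, name: str | None = None) -> Network:
    path = Path(path)
    nodes: list[str] = []
    seen: set[str] = set()
    if node_list is not None:
        for line in Path(node_list).read_text().splitlines():
            label = line.strip()
            if label and label not in seen:
                nodes.append(label)
                seen.add(label)
    edges = []
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [c.strip() for c in header[:3]] != ["source", "target", "sign"]:
            raise FormatError(f"{path}:1: expected header 'source\\ttarget\\tsign[\\tprobability]'")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise FormatError(f"{path}:{lineno}: expected at least 3 columns")
            src, tgt, sign = row[0].strip(), row[1].strip(), row[2].strip()
            prob = None
            if len(row) > 3 and row[3].strip():
                try:
                    prob = float(row[3])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: bad probability {row[3]!r}") from None
            for label in (src, tgt):
                if label not in seen:
                    if node_list is not None:
                        raise FormatError(
                            f"{path}:{lineno}: node {label!r} not in node list"
                        )
                    nodes.append(label)
                    seen.add(label)
            try:
                edges.append(Edge(src, tgt, sign, prob))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    try:
        return Network(nodes, edges, name=name or path.stem)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_network(net: Network, path, node_list: Path | None = None) -> None:
    """Write the TSV edge list; optionally also a node-list file preserving
    the canonical node order (otherwise a reader falls back to
    first-appearance order)."""
    path = Path(path)
    if node_list is not None:
        Path(node_list).write_text("\n".join(net.nodes) + "\n")
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["source", "target", "sign", "probability"])
        for e in net.edges:
            w.writerow(
                [e.source, e.target, e.sign,
                 "" if e.probability is None else repr(float(e.probability))]
            )


def load_rules(path) -> RuleTable:
    """Rule tables from a JSON document or a directory of per-node CSVs."""
    path = Path(path)
    if path.is_dir():
        return _load_rules_csv_dir(path)
    doc = json.loads(path.read_text())
    nodes = list(doc)
    parents = {}
    tables = {}
    for node, spec in doc.items():
        parents[node] = tuple(spec["parents"])
        tables[node] = np.asarray(spec["p_on"], dtype=float)
    try:
        return RuleTable(nodes, parents, tables)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def _load_rules_csv_dir(path: Path) -> RuleTable:
    nodes, parents, tables = [], {}, {}
    files = sorted(path.glob("*.csv"))
    if not files:
        raise FormatError(f"{path}: no per-node rule CSVs found")
    for f in files:
        node = f.stem
        with f.open() as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if not header or header[-1] != "p_on":
                raise FormatError(f"{f}:1: last column must be 'p_on'")
            plist = tuple(header[:-1])
            rows = {}
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                try:
                    bits = [int(x) for x in row[:-1]]
                    p = float(row[-1])
                except ValueError:
                    raise FormatError(f"{f}:{lineno}: bad row {row!r}") from None
                idx = 0
                for b in bits:
                    idx = (idx << 1) | b
                rows[idx] = p
            k = len(plist)
            if set(rows) != set(range(2**k)):
                raise FormatError(f"{f}: needs one row per parent combination (2^{k})")
            nodes.append(node)
            parents[node] = plist
            tables[node] = np.array([rows[i] for i in range(2**k)])
    try:
        return RuleTable(nodes, parents, tables)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_rules(rules: RuleTable, path) -> None:
    doc = {
        node: {
            "parents": list(rules.parents[node]),
            "p_on": [float(p) for p in rules.p_on[node]],
        }
        for node in rules.nodes
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_states(path, nodes: list[str]) -> dict[str, NetworkState]:
    path = Path(path)
    doc = json.loads(path.read_text())
    out = {}
    for name, mapping in doc.items():
        bad = {k: v for k, v in mapping.items() if v not in (0, 1)}
        if bad:
            raise FormatError(f"{path}: state {name!r} has non-binary entries {bad}")
        unknown = set(mapping) - set(nodes)
        if unknown:
            raise FormatError(f"{path}: state {name!r} references unknown nodes {sorted(unknown)}")
        try:
            out[name] = NetworkState.from_dict(nodes, mapping)
        except ValueError as exc:
            raise FormatError(f"{path}: state {name!r}: {exc}") from None
    return out


def write_states(states: dict[str, NetworkState], path) -> None:
    doc = {name: st.to_dict() for name, st in states.items()}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def write_archive(archive: TreeArchive, out_dir) -> None:
    """One TSV edge list per tree plus an ``archive.json`` manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "mode": archive.mode,
        "optimum": {
            "distance_total": archive.optimum.distance_total,
            "cost_total": archive.optimum.cost_total,
        },
        "count": len(archive),
        "evaluations": archive.evaluations,
        "trees": [],
    }
    for k, (sig, tree) in enumerate(sorted(archive.trees.items())):
        fname = f"tree_{k:06d}.tsv"
        g = tree.graph
        with (out / fname).open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["source", "target", "cost"])
            for i in sorted(tree.edge_indices):
                u, v = g.edge_labels(i)
                w.writerow([u, v, repr(float(g.costs[i]))])
        sidecar = {
            "objective_distance": evaluate_tree(tree, "DST").distance_total,
            "objective_cost": (
                evaluate_tree(tree, MDST).cost_total if g.weighted else None
            ),
            "edge_indices": list(sig),
        }
        (out / f"tree_{k:06d}.json").write_text(json.dumps(sidecar) + "\n")
        manifest["trees"].append(fname)
    (out / "archive.json").write_text(json.dumps(manifest, indent=1) + "\n")


def load_archive(archive_dir, graph: UndirectedGraph) -> TreeArchive:
    out = Path(archive_dir)
    manifest = json.loads((out / "archive.json").read_text())
    opt = manifest["optimum"]
    archive = TreeArchive(
        mode=manifest["mode"],
        optimum=ObjectiveValue(opt["distance_total"], opt["cost_total"]),
    )
    for k in range(manifest["count"]):
        sidecar = json.loads((out / f"tree_{k:06d}.json").read_text())
        archive.add(SpanningTree(frozenset(sidecar["edge_indices"]), graph))
    archive.evaluations = manifest.get("evaluations", 0)
    return archive


def write_trajectory(traj: Trajectory, path, compress: bool = False) -> None:
    path = Path(path)
    opener = gzip.open if compress else open
    nodes = traj.initial.nodes
    with opener(path, "wt", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["iteration", "node", "new_bit"])
        for t, (i, b) in enumerate(zip(traj.updated_nodes, traj.new_bits)):
            w.writerow([t, nodes[i], b])
    meta = {
        "initial": traj.initial.to_dict(),
        "converged": traj.converged,
        "iterations": traj.iterations,
        "seed": traj.seed,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta) + "\n")


def load_trajectory(path) -> Trajectory:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    init = NetworkState.from_dict(list(meta["initial"]), meta["initial"])
    index = init.index
    updated, bits = [], []
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            if not row:
                continue
            updated.append(index[row[1]])
            bits.append(int(row[2]))
    final = init.copy()
    for i, b in zip(updated, bits):
        final.bits[i] = b
    return Trajectory(
        initial=init,
        updated_nodes=updated,
        new_bits=bits,
        converged=meta["converged"],
        iterations=meta["iterations"],
        seed=meta["seed"],
        final=final,
    )
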