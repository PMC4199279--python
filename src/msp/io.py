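"""Reading and writing simulation artifacts.

Connectome snapshots are directed weighted edge lists — plain text lines
``src,dst,count`` with 0-based neuron ids and integer synapse
multiplicities — plus optional GraphML via networkx.  Time series go to
CSV through pandas.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .experiment import ExperimentResult
from .config import serialize_config


def write_edge_list(w: np.ndarray, path: str | Path) -> None:
    """Write ``W[i, j]`` (synapses j -> i) as ``src,dst,count`` lines."""
    path = Path(path)
    dst, src = np.nonzero(w)
    with open(path, "w") as fh:
        fh.write("src,dst,count\n")
        for s, t in zip(src.tolist(), dst.tolist()):
            fh.write(f"{s},{t},{int(w[t, s])}\n")


def read_edge_list(path: str | Path, n: int | None = None) -> np.ndarray:
    """Read an edge list back into a dense multiplicity matrix.

    ``n`` fixes the matrix size; by default it is inferred from the
    largest id present.
    """
    src, dst, cnt = [], [], []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "src,dst,count":
            raise ValueError(f"{path}: expected 'src,dst,count' header, got {header!r}")
        for line_no, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}:{line_no}: malformed line {line!r}")
            s, t, c = (int(p) for p in parts)
            if s < 0 or t < 0 or c < 0:
                raise ValueError(f"{path}:{line_no}: negative value")
            src.append(s)
            dst.append(t)
            cnt.append(c)
    size = n if n is not None else (max(src + dst) + 1 if src else 0)
    w = np.zeros((size, size), dtype=np.int64)
    for s, t, c in zip(src, dst, cnt):
        w[t, s] = c
    return w


def to_graphml(w: np.ndarray, path: str | Path) -> None:
    """Export the connectome as GraphML (edge attribute ``weight`` = count)."""
    g = nx.DiGraph()
    g.add_nodes_from(range(w.shape[0]))
    dst, src = np.nonzero(w)
    for s, t in zip(src.tolist(), dst.tolist()):
        g.add_edge(int(s), int(t), weight=int(w[t, s]))
    nx.write_graphml(g, str(path))


def write_result(result: ExperimentResult, out_dir: str | Path) -> None:
    """Persist an experiment: series.csv, snapshots/T*.edges, config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.series.to_csv(out / "series.csv", index=False)
    snap_dir = out / "snapshots"
    snap_dir.mkdir(exist_ok=True)
    for t, w in sorted(result.snapshots.items()):
        write_edge_list(w, snap_dir / f"T{t}.edges")
    (out / "config.resolved").write_text(serialize_config(result.config))
    pop = result.state.population
    np.savetxt(
        out / "population.csv",
        np.column_stack([pop.pos, pop.is_excitatory, pop.in_lpz]),
        delimiter=",",
        header="x_um,y_um,is_excitatory,in_lpz",
        comments="",
        fmt=["%.3f", "%.3f", "%d", "%d"],
    )
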