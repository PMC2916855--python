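"""File formats, JSON formatting, and fixture networks.

Edge lists are TSV with two integer columns ``source<TAB>target`` (0-based
patch ids, one row per directed link).  Header comment lines start with
``#``: ``# n=<int>`` fixes the number of patches (so isolated patches
survive a round trip) and ``# undirected`` marks symmetric networks, whose
files list each edge once.  Connectivity matrices are dense headerless CSV
with entries in [0, 1].
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .errors import EdgeListError, GenerationError
from .leslie import PatchDemography
from .network import (
    ConnectivityMatrix,
    DispersalNetwork,
    generate_config_model,
    generate_er,
    generate_regular,
)

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_connectivity_csv",
    "read_demography_json",
    "read_patches_json",
    "make_fixture",
    "json_dumps",
    "FIXTURE_NAMES",
]


# ----------------------------------------------------------------------
# edge lists


def read_edge_list(path: "str | Path") -> DispersalNetwork:
    """Parse a TSV edge list into a :class:`DispersalNetwork`.

    Malformed rows and self-loops are rejected with their line number.
    """
    path = Path(path)
    directed = True
    declared_n: int | None = None
    edges: list[tuple[int, int]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            flag = line.lstrip("#").strip().lower()
            if flag == "undirected":
                directed = False
            elif flag.startswith("n="):
                try:
                    declared_n = int(flag[2:])
                except ValueError as exc:
                    raise EdgeListError(f"{path}:{lineno}: bad n header {line!r}") from exc
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise EdgeListError(
                f"{path}:{lineno}: expected two tab-separated ids, got {raw!r}"
            )
        try:
            s, t = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise EdgeListError(f"{path}:{lineno}: non-integer patch id in {raw!r}") from exc
        if s < 0 or t < 0:
            raise EdgeListError(f"{path}:{lineno}: negative patch id in {raw!r}")
        if s == t:
            raise EdgeListError(
                f"{path}:{lineno}: self-loop {s}->{t}; self-loops are excluded"
            )
        edges.append((s, t))
    n = max((max(s, t) for s, t in edges), default=-1) + 1
    if declared_n is not None:
        if declared_n < n:
            raise EdgeListError(f"{path}: header n={declared_n} smaller than max id {n - 1}")
        n = declared_n
    return DispersalNetwork.from_edges(n, edges, directed=directed)


def write_edge_list(net: DispersalNetwork, path: "str | Path") -> None:
    """Write a network as TSV; undirected networks list each edge once."""
    lines = [f"# n={net.n}"]
    if not net.directed:
        lines.append("# undirected")
        pairs = net.undirected_edges
    else:
        pairs = net.edges
    lines.extend(f"{s}\t{t}" for s, t in pairs)
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# connectivity CSV


def read_connectivity_csv(path: "str | Path") -> ConnectivityMatrix:
    """Parse a dense headerless CSV into an explicit-scheme connectivity matrix."""
    path = Path(path)
    rows: list[list[float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        try:
            row = [float(tok) for tok in line.split(",")]
        except ValueError as exc:
            raise EdgeListError(f"{path}:{lineno}: non-numeric entry in {raw!r}") from exc
        if rows and len(row) != len(rows[0]):
            raise EdgeListError(
                f"{path}:{lineno}: ragged row of length {len(row)}, expected {len(rows[0])}"
            )
        rows.append(row)
    if not rows:
        raise EdgeListError(f"{path}: empty connectivity file")
    C = np.asarray(rows)
    if C.shape[0] != C.shape[1]:
        raise EdgeListError(f"{path}: matrix is {C.shape[0]}x{C.shape[1]}, must be square")
    if (C < 0).any() or (C > 1).any():
        raise EdgeListError(f"{path}: connectivity entries must lie in [0, 1]")
    return ConnectivityMatrix(C=C, scheme="explicit")


# ----------------------------------------------------------------------
# demography JSON


def read_demography_json(path: "str | Path") -> PatchDemography:
    """Read one demography record (keys m, survival, fertility, sigma)."""
    return PatchDemography.from_dict(json.loads(Path(path).read_text()))


def read_patches_json(path: "str | Path") -> "list[PatchDemography]":
    """Read a JSON array of per-patch demography records."""
    data = json.loads(Path(path).read_text())
    if not isinstance(data, list):
        raise EdgeListError(f"{path}: expected a JSON array of demography records")
    return [PatchDemography.from_dict(d) for d in data]


# ----------------------------------------------------------------------
# deterministic JSON formatting


def _round_sig(x: float, sig: int = 12) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def _round_tree(obj):
    if isinstance(obj, float):
        return _round_sig(obj)
    if isinstance(obj, dict):
        return {k: _round_tree(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_tree(v) for v in obj]
    return obj


def json_dumps(obj) -> str:
    """Deterministic JSON: floats at 12 significant digits, sorted keys."""
    return json.dumps(_round_tree(obj), indent=2, sort_keys=True)


# ----------------------------------------------------------------------
# fixture networks

FIXTURE_NAMES = (
    "fig2_regular",
    "fig2_er",
    "fig2_hetero",
    "fig3_lonely",
    "fig4_two_components",
    "fig5_all_to_all",
    "bootstrap_sinks",
)

#: demography shared by the network-topology fixtures: two age classes,
#: f = (0, 4), p2 = 0.5, so R = 2
_BASE_DEMOG = {"m": 2, "survival": [0.5], "fertility": [0.0, 4.0], "sigma": 0.3}


def _hetero_degree_sequence(n: int) -> "list[int]":
    """A right-skewed graphical sequence with mean degree 2: mostly degree-1
    leaves plus a few hubs."""
    assert n >= 12 and n % 4 == 0
    seq = [1] * (n // 2) + [2] * (n // 4) + [3] * (n // 8)
    hubs = n - len(seq)
    deficit = 2 * n - sum(seq)
    base, extra = divmod(deficit, hubs)
    seq += [base + (1 if i < extra else 0) for i in range(hubs)]
    return sorted(seq, reverse=True)


def make_fixture(name: str, seed: int) -> dict:
    """Build a named worked-example structure.

    Returns a dict with keys ``net`` (:class:`DispersalNetwork`), ``config``
    (demography/dispersal parameters as a JSON-ready dict), and ``notes``.
    All stochastic fixtures are fully determined by ``seed``.
    """
    if name == "fig2_regular":
        # every patch has exactly 2 links (ring)
        net = generate_regular(24, 2, seed)
        return _pack(net, "regular network, mean degree 2")
    if name == "fig2_er":
        # Erdos-Renyi with mean degree 2: p = 2/(n-1)
        net = generate_er(24, 2.0 / 23.0, seed)
        return _pack(net, "random network, mean degree ~2")
    if name == "fig2_hetero":
        net = generate_config_model(_hetero_degree_sequence(24), seed)
        return _pack(net, "heterogeneous network, mean degree 2, skewed degrees")
    if name == "fig3_lonely":
        # one directed 3-cycle; every other link is lonely
        cycle = [(0, 1), (1, 2), (2, 0)]
        lonely = [(2, 3), (3, 4), (4, 5), (1, 6), (6, 7), (0, 8), (8, 9), (10, 0)]
        net = DispersalNetwork.from_edges(11, cycle + lonely, directed=True)
        return _pack(net, "single simple cycle plus lonely-link appendages")
    if name == "fig4_two_components":
        # one simple 3-cycle component; one complex 6-patch/9-link component
        # of intersecting cycles; nine appendage patches on lonely links only
        simple = [(0, 1), (1, 2), (2, 0)]
        complex_comp = [
            (3, 4), (4, 5), (5, 6), (6, 7), (7, 8), (8, 3),  # outer 6-cycle
            (5, 3),  # chord: 3-cycle 3->4->5->3
            (7, 5),  # chord: 3-cycle 5->6->7->5
            (8, 6),  # chord: 3-cycle 6->7->8->6
        ]
        appendages = [
            (8, 9), (9, 10), (3, 11), (11, 12), (12, 13),
            (4, 14), (16, 15), (15, 5), (6, 17),
        ]
        net = DispersalNetwork.from_edges(18, simple + complex_comp + appendages, directed=True)
        return _pack(net, "two cyclic components (simple 3-cycle; complex 6-patch/9-link)")
    if name == "fig5_all_to_all":
        # complete undirected network on 4 nonidentical patches, patch 0
        # dominating elementwise and patch 3 subordinate: R0 > R1 > R2 > R3
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        net = DispersalNetwork.from_edges(4, edges, directed=False)
        patches = [
            {"m": 3, "survival": [0.8 - 0.1 * i, 0.7 - 0.1 * i],
             "fertility": [0.0, 3.0 - 0.4 * i, 5.0 - 0.6 * i],
             "sigma": 0.5 - 0.05 * i}
            for i in range(4)
        ]
        return {
            "net": net,
            "config": {"patches": patches, "epsilon": 0.1},
            "notes": "all-to-all network of 4 nonidentical patches, R0>R1>R2>R3",
        }
    if name == "bootstrap_sinks":
        # ring of 10 patches; each patch alone is a sink (sigma R = 0.6 < 1)
        # but subsidy recruitment lifts chi = R(sigma + eps rho(A))
        #                                  = 2 (0.3 + 0.3*2) = 1.8 > 1
        net = generate_regular(10, 2, seed)
        cfg = dict(_BASE_DEMOG)
        return {
            "net": net,
            "config": {"demography": cfg, "sigma": 0.3, "epsilon": 0.3},
            "notes": "all patches sinks in isolation, metapopulation persists",
        }
    raise GenerationError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def _pack(net: DispersalNetwork, notes: str) -> dict:
    return {
        "net": net,
        "config": {"demography": dict(_BASE_DEMOG), "sigma": 0.3, "epsilon": 0.1},
        "notes": notes,
    }
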