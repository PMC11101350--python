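"""Plain-text serialization of networks, equilibrium states and results.

A cell network is stored as two CSV tables plus a JSON header:

* ``<stem>_nodes.csv`` — id, x, y, kind, is_FA
* ``<stem>_bonds.csv`` — id, node_i, node_j, class, K_t, K_c, a, r0
* ``<stem>_header.json`` — format version, generation parameters, seed,
  geometry (polygon, nucleus), node/bond counts

Floats are written with ``repr`` (shortest round-trip), so a
write–read–write cycle is byte-identical.  An export to the LAMMPS
"data" file dialect (atoms + bonds, one bond type per fibre class) is
provided for interoperability with molecular-dynamics tooling.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .materials import FibreClass
from .mechanics import EquilibriumState
from .netgen import CellGenParams, CellGeometry, CellNetwork, Ellipse

FORMAT_VERSION = "cellnet-network-1"


def _network_frames(net: CellNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    is_fa = np.zeros(net.n_nodes, dtype=int)
    is_fa[net.fa_ids] = 1
    nodes = pd.DataFrame(
        {
            "id": np.arange(net.n_nodes),
            "x": net.positions[:, 0],
            "y": net.positions[:, 1],
            "kind": net.kinds,
            "is_FA": is_fa,
        }
    )
    bonds = pd.DataFrame(
        {
            "id": np.arange(net.n_bonds),
            "node_i": net.bonds[:, 0],
            "node_j": net.bonds[:, 1],
            "class": net.bond_class,
            "K_t": net.K_t,
            "K_c": net.K_c,
            "a": net.a,
            "r0": net.r0,
        }
    )
    return nodes, bonds


def save_network(net: CellNetwork, stem: str | Path) -> dict[str, Path]:
    """Write ``<stem>_nodes.csv``, ``<stem>_bonds.csv``,
    ``<stem>_header.json``; returns the paths."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    nodes, bonds = _network_frames(net)
    paths = {
        "nodes": stem.with_name(stem.name + "_nodes.csv"),
        "bonds": stem.with_name(stem.name + "_bonds.csv"),
        "header": stem.with_name(stem.name + "_header.json"),
    }
    nodes.to_csv(paths["nodes"], index=False)
    bonds.to_csv(paths["bonds"], index=False)
    geo = net.geometry
    header = {
        "format": FORMAT_VERSION,
        "params": None
        if net.params is None
        else dataclasses.asdict(net.params),
        "n_nodes": int(net.n_nodes),
        "n_bonds": int(net.n_bonds),
        "polygon": np.asarray(geo.polygon).tolist(),
        "nucleus": {
            "centre": list(geo.nucleus.centre),
            "semi_axes": list(geo.nucleus.semi_axes),
            "angle": geo.nucleus.angle,
        },
    }
    paths["header"].write_text(json.dumps(header, indent=1, sort_keys=True))
    return paths


def load_network(stem: str | Path) -> CellNetwork:
    """Load a network written by :func:`save_network`.

    Raises ``ValueError`` on version mismatch or on node/bond counts
    inconsistent with the header (truncated files)."""
    stem = Path(stem)
    header_path = stem.with_name(stem.name + "_header.json")
    header = json.loads(header_path.read_text())
    if header.get("format") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported network format {header.get('format')!r} in "
            f"{header_path} (expected {FORMAT_VERSION})"
        )
    nodes = pd.read_csv(
        stem.with_name(stem.name + "_nodes.csv"), float_precision="round_trip"
    )
    bonds = pd.read_csv(
        stem.with_name(stem.name + "_bonds.csv"), float_precision="round_trip"
    )
    for name, frame, expect in (
        ("nodes", nodes, header["n_nodes"]),
        ("bonds", bonds, header["n_bonds"]),
    ):
        if len(frame) != expect:
            raise ValueError(
                f"truncated {name} table: {len(frame)} rows read, header "
                f"says {expect} (last intact line {len(frame) + 1})"
            )
    params = header["params"]
    if params is not None:
        for key, val in params.items():
            if isinstance(val, list):
                params[key] = tuple(val)
        params = CellGenParams(**params)

    positions = nodes[["x", "y"]].to_numpy()
    kinds = nodes["kind"].to_numpy(dtype="<U16")
    nuc = header["nucleus"]
    nucleus = Ellipse(
        tuple(nuc["centre"]), tuple(nuc["semi_axes"]), nuc["angle"]
    )
    geometry = CellGeometry(
        polygon=np.asarray(header["polygon"], dtype=float),
        membrane_points=positions[kinds == "membrane"],
        nucleus=nucleus,
        nuclear_membrane_points=positions[kinds == "nuclear_membrane"],
    )
    return CellNetwork(
        positions=positions,
        kinds=kinds,
        bonds=bonds[["node_i", "node_j"]].to_numpy(dtype=int),
        bond_class=bonds["class"].to_numpy(dtype="<U16"),
        K_t=bonds["K_t"].to_numpy(),
        K_c=bonds["K_c"].to_numpy(),
        a=bonds["a"].to_numpy(),
        r0=bonds["r0"].to_numpy(),
        fa_ids=nodes.loc[nodes["is_FA"] == 1, "id"].to_numpy(dtype=int),
        geometry=geometry,
        params=params,
    )


def save_equilibrium(state: EquilibriumState, path: str | Path) -> Path:
    """Write an equilibrium state as CSV (id, ux, uy, fx, fy)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "id": np.arange(len(state.u)),
            "ux": state.u[:, 0],
            "uy": state.u[:, 1],
            "fx": state.forces[:, 0],
            "fy": state.forces[:, 1],
        }
    ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# LAMMPS data-file dialect
# ---------------------------------------------------------------------------

_BOND_TYPE_ORDER = [cls.value for cls in FibreClass]


def export_lammps_data(net: CellNetwork, path: str | Path, z: float = 0.0) -> Path:
    """Export the network in the LAMMPS "data" dialect (atoms + bonds).

    One atom per node (atom-style ``bond``: id mol type x y z) and one
    bond type per fibre class present in the network."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    present = [c for c in _BOND_TYPE_ORDER if (net.bond_class == c).any()]
    type_of = {c: t + 1 for t, c in enumerate(present)}
    lo = net.positions.min(axis=0) - 10.0
    hi = net.positions.max(axis=0) + 10.0
    lines = [
        "# cellnet discrete network export",
        "",
        f"{net.n_nodes} atoms",
        f"{net.n_bonds} bonds",
        "1 atom types",
        f"{len(present)} bond types",
        "",
        f"{lo[0]!r} {hi[0]!r} xlo xhi",
        f"{lo[1]!r} {hi[1]!r} ylo yhi",
        f"{-10.0!r} {10.0!r} zlo zhi",
        "",
        "Masses",
        "",
        "1 1.0",
        "",
        "Atoms # bond",
        "",
    ]
    for i, (x, y) in enumerate(net.positions):
        lines.append(f"{i + 1} 1 1 {x!r} {y!r} {z!r}")
    lines += ["", "Bonds", ""]
    for b, (i, j) in enumerate(net.bonds):
        lines.append(
            f"{b + 1} {type_of[net.bond_class[b]]} {i + 1} {j + 1}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_lammps_counts(path: str | Path) -> dict[str, int]:
    """Parse atom/bond counts and section sizes from a LAMMPS data file."""
    counts: dict[str, int] = {}
    section = None
    section_rows = {"Atoms": 0, "Bonds": 0}
    for line in Path(path).read_text().splitlines():
        bare = line.split("#")[0].strip()
        if not bare:
            continue
        if bare.endswith(" atoms"):
            counts["atoms"] = int(bare.split()[0])
        elif bare.endswith(" bonds"):
            counts["bonds"] = int(bare.split()[0])
        elif bare.split()[0] in ("Atoms", "Bonds", "Masses", "Velocities"):
            section = bare.split()[0]
        elif section in section_rows:
            section_rows[section] += 1
    counts["atom_rows"] = section_rows["Atoms"]
    counts["bond_rows"] = section_rows["Bonds"]
    return counts
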