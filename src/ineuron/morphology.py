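"""Neurite morphometry for traced 3-D neuron reconstructions.

A reconstruction is a soma plus a forest of rooted neurite trees. From it we
compute the quantities used to compare maturing induced neurons: total neurite
length, the axon (operationally the longest neurite), polarity class
(uni/bi/multipolar by the number of primary neurites), a Sholl profile
(crossings of concentric spheres centred on the soma), and the per-batch
normalisation of axon length against the ape-group mean.

Readers are provided for two interchange formats: standard 7-column SWC and
the HOC dialect produced by Imaris exports (``create``/``connect``/``pt3dadd``
statements only; anything else is ignored with a warning).
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MORPH_DAYS = (7, 14, 21, 35)

__all__ = [
    "Point3D",
    "Neurite",
    "NeuronMorphology",
    "ShollProfile",
    "MorphometryRecord",
    "MorphologyParseError",
    "MorphometryError",
    "parse_swc",
    "parse_hoc",
    "write_swc",
    "write_hoc",
    "total_neurite_length",
    "identify_axon",
    "classify_polarity",
    "sholl_profile",
    "batch_normalize",
    "morphometry_record",
    "records_to_frame",
    "sholl_long_frame",
]


class MorphologyParseError(ValueError):
    """Malformed SWC/HOC input (message names the offending line/section)."""


class MorphometryError(ValueError):
    """A metric is undefined for this morphology (e.g. no neurites)."""


@dataclass(frozen=True)
class Point3D:
    """A tracing node; coordinates in micrometres, radius in micrometres."""

    x: float
    y: float
    z: float
    radius: float = 0.2

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("Point3D coordinates must be finite")
        if self.radius < 0:
            raise ValueError("Point3D radius must be >= 0")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


class Neurite:
    """A rooted tree of 3-D nodes.

    ``nodes[0]`` is the origin on the soma; every other node has exactly one
    parent with a smaller index (topological order), so the tree is acyclic
    and connected by construction.
    """

    def __init__(self, nodes: np.ndarray, parents: np.ndarray,
                 radii: np.ndarray | None = None):
        nodes = np.asarray(nodes, dtype=float)
        parents = np.asarray(parents, dtype=int)
        if nodes.ndim != 2 or nodes.shape[1] != 3:
            raise ValueError("nodes must be an (n, 3) array")
        n = len(nodes)
        if n < 2:
            raise ValueError("a neurite needs at least 2 nodes (origin + 1)")
        if len(parents) != n or parents[0] != -1:
            raise ValueError("parents[0] must be -1 and match nodes length")
        if np.any(parents[1:] < 0) or np.any(parents[1:] >= np.arange(1, n)):
            raise ValueError("non-root parents must precede their children")
        if not np.all(np.isfinite(nodes)):
            raise ValueError("node coordinates must be finite")
        self.nodes = nodes
        self.parents = parents
        self.radii = (np.full(n, 0.2) if radii is None
                      else np.asarray(radii, dtype=float))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def segment_starts(self) -> np.ndarray:
        return self.nodes[self.parents[1:]]

    @property
    def segment_ends(self) -> np.ndarray:
        return self.nodes[1:]

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.segment_ends - self.segment_starts, axis=1)

    @property
    def total_length(self) -> float:
        return float(self.segment_lengths.sum())

    @property
    def n_branch_points(self) -> int:
        counts = np.bincount(self.parents[1:], minlength=self.n_nodes)
        return int(np.sum(counts > 1))


@dataclass
class NeuronMorphology:
    """One traced cell: soma centroid plus its neurite forest."""

    cell_id: str
    soma_centroid: np.ndarray
    neurites: list[Neurite]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.soma_centroid = np.asarray(self.soma_centroid, dtype=float)
        if self.soma_centroid.shape != (3,) or not np.all(
                np.isfinite(self.soma_centroid)):
            raise ValueError("soma_centroid must be a finite 3-vector")
        day = self.metadata.get("day")
        if day is not None and int(day) not in MORPH_DAYS:
            raise ValueError(
                f"morphology day must be one of {MORPH_DAYS}, got {day}")


@dataclass
class ShollProfile:
    """Sphere crossings at increasing radii around the soma centroid."""

    radii: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.radii) != len(self.counts):
            raise ValueError("radii and counts must align")
        if len(self.radii) and np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total_intersections(self) -> int:
        return int(self.counts.sum())


@dataclass
class MorphometryRecord:
    """Per-cell morphometric summary (lengths in µm)."""

    cell_id: str
    polarity_class: str
    n_primary: int
    total_neurite_length: float
    axon_length: float
    dendrite_length: float
    sholl: ShollProfile
    metadata: dict = field(default_factory=dict)
    normalized_axon_length: float | None = None

    def to_dict(self) -> dict:
        d = {
            "cell_id": self.cell_id,
            "polarity_class": self.polarity_class,
            "n_primary": self.n_primary,
            "total_neurite_length_um": self.total_neurite_length,
            "axon_length_um": self.axon_length,
            "dendrite_length_um": self.dendrite_length,
            "sholl_total_intersections": self.sholl.total_intersections,
            "normalized_axon_length": self.normalized_axon_length,
        }
        d.update(self.metadata)
        return d


# ---------------------------------------------------------------------------
# SWC reading / writing
# ---------------------------------------------------------------------------

def parse_swc(path: str | Path) -> NeuronMorphology:
    """Read a 7-column SWC file.

    Soma nodes (type 1) are collapsed to their centroid; each subtree of
    non-soma nodes rooted at the soma (or at -1) becomes one :class:`Neurite`
    whose origin is the soma centroid.
    """
    path = Path(path)
    entries: dict[int, tuple[int, np.ndarray, float, int]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 7:
            raise MorphologyParseError(
                f"{path.name}:{lineno}: expected 7 columns, got {len(fields)}")
        try:
            nid = int(fields[0])
            ntype = int(fields[1])
            xyz = np.array([float(v) for v in fields[2:5]])
            radius = float(fields[5])
            parent = int(fields[6])
        except ValueError as exc:
            raise MorphologyParseError(
                f"{path.name}:{lineno}: non-numeric field ({exc})") from None
        if nid in entries:
            raise MorphologyParseError(
                f"{path.name}:{lineno}: duplicate node id {nid}")
        entries[nid] = (ntype, xyz, radius, parent)

    for nid, (_, _, _, parent) in entries.items():
        if parent != -1 and parent not in entries:
            raise MorphologyParseError(
                f"{path.name}: node {nid} references undefined parent {parent}")

    soma_ids = {nid for nid, e in entries.items() if e[0] == 1}
    if soma_ids:
        centroid = np.mean([entries[i][1] for i in sorted(soma_ids)], axis=0)
    else:
        roots = [nid for nid, e in entries.items() if e[3] == -1]
        if not roots:
            raise MorphologyParseError(
                f"{path.name}: no soma node and no root node")
        centroid = entries[min(roots)][1]

    children: dict[int, list[int]] = {}
    root_ids: list[int] = []
    for nid in sorted(entries):
        ntype, _, _, parent = entries[nid]
        if ntype == 1:
            continue
        if parent == -1 or parent in soma_ids:
            root_ids.append(nid)
        else:
            children.setdefault(parent, []).append(nid)

    neurites: list[Neurite] = []
    visited: set[int] = set(soma_ids)
    for root in root_ids:
        nodes = [centroid]
        radii = [float(np.mean([entries[i][2] for i in sorted(soma_ids)]))
                 if soma_ids else entries[root][2]]
        parents = [-1]
        index_of: dict[int, int] = {}
        stack = [(root, 0)]
        while stack:
            nid, pidx = stack.pop()
            if nid in visited:
                raise MorphologyParseError(
                    f"{path.name}: cyclic parent chain at node {nid}")
            visited.add(nid)
            index_of[nid] = len(nodes)
            nodes.append(entries[nid][1])
            radii.append(entries[nid][2])
            parents.append(pidx)
            for child in reversed(children.get(nid, [])):
                stack.append((child, index_of[nid]))
        neurites.append(Neurite(np.array(nodes), np.array(parents),
                                np.array(radii)))

    unreached = set(entries) - visited
    if unreached:
        raise MorphologyParseError(
            f"{path.name}: nodes {sorted(unreached)[:5]} unreachable from any "
            "root (orphan or cyclic parent chain)")
    return NeuronMorphology(cell_id=path.stem, soma_centroid=centroid,
                            neurites=neurites)


def write_swc(m: NeuronMorphology, path: str | Path) -> None:
    """Serialize to SWC: node 1 is the soma centroid, neurite nodes type 3."""
    path = Path(path)
    lines = ["# generated by ineuron.morphology"]
    cx, cy, cz = m.soma_centroid
    lines.append(f"1 1 {cx:.6f} {cy:.6f} {cz:.6f} 1.000000 -1")
    next_id = 2
    for nr in m.neurites:
        # node 0 of each neurite is the soma centroid itself; skip it.
        ids = np.empty(nr.n_nodes, dtype=int)
        ids[0] = 1
        for i in range(1, nr.n_nodes):
            ids[i] = next_id
            x, y, z = nr.nodes[i]
            r = nr.radii[i]
            lines.append(
                f"{next_id} 3 {x:.6f} {y:.6f} {z:.6f} {r:.6f} "
                f"{ids[nr.parents[i]]}")
            next_id += 1
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# HOC (Imaris-export dialect) reading / writing
# ---------------------------------------------------------------------------

_CREATE_RE = re.compile(r"^\s*create\s+(.+?)\s*$")
_CONNECT_RE = re.compile(
    r"^\s*connect\s+(\S+?)\s*\(\s*([\d.]+)\s*\)\s*,\s*(\S+?)\s*\(\s*([\d.]+)\s*\)")
_PT3D_RE = re.compile(
    r"pt3dadd\(\s*([-\d.eE+]+)\s*,\s*([-\d.eE+]+)\s*,\s*([-\d.eE+]+)\s*,\s*([-\d.eE+]+)\s*\)")
_BLOCK_OPEN_RE = re.compile(r"^\s*(\S+)\s*\{")


def parse_hoc(path: str | Path) -> NeuronMorphology:
    """Read an Imaris-style HOC morphology.

    Only ``create``, ``connect`` and ``pt3dadd`` statements are honoured;
    other statements are ignored with a logged warning. Sections are linked
    into neurite trees by the connect graph; the section whose name contains
    ``soma`` (or the first section, when none does) supplies the soma
    centroid.
    """
    path = Path(path)
    order: list[str] = []
    points: dict[str, list[tuple[float, float, float, float]]] = {}
    connects: list[tuple[str, float, str, float]] = []

    current: str | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("//", 1)[0].strip()
        if not line:
            continue
        if current is not None:
            for m_ in _PT3D_RE.finditer(line):
                points[current].append(tuple(float(g) for g in m_.groups()))
            if "}" in line:
                current = None
            continue
        m_ = _CREATE_RE.match(line)
        if m_:
            for name in (n.strip() for n in m_.group(1).split(",")):
                arr = re.fullmatch(r"(\w+)\[(\d+)\]", name)
                if arr:  # NEURON-style array declaration
                    for i in range(int(arr.group(2))):
                        sec = f"{arr.group(1)}[{i}]"
                        order.append(sec)
                        points[sec] = []
                else:
                    order.append(name)
                    points[name] = []
            continue
        m_ = _CONNECT_RE.match(line)
        if m_:
            child, cpos, parent, ppos = m_.groups()
            connects.append((child, float(cpos), parent, float(ppos)))
            continue
        m_ = _BLOCK_OPEN_RE.match(line)
        if m_ and m_.group(1) in points:
            current = m_.group(1)
            rest = line.split("{", 1)[1]
            for p_ in _PT3D_RE.finditer(rest):
                points[current].append(tuple(float(g) for g in p_.groups()))
            if "}" in rest:
                current = None
            continue
        log.warning("%s:%d: ignoring HOC statement: %s", path.name, lineno,
                    line)

    if not order:
        raise MorphologyParseError(f"{path.name}: no sections declared")
    for child, _, parent, _ in connects:
        for name in (child, parent):
            if name not in points:
                raise MorphologyParseError(
                    f"{path.name}: connect references undeclared section "
                    f"'{name}'")
    for name in order:
        if len(points[name]) < 1:
            raise MorphologyParseError(
                f"{path.name}: section '{name}' has no 3-D points")

    soma_name = next((n for n in order if "soma" in n.lower()), order[0])
    soma_pts = np.array([p[:3] for p in points[soma_name]])
    centroid = soma_pts.mean(axis=0)

    children: dict[str, list[tuple[str, float, float]]] = {}
    parent_of: dict[str, str] = {}
    for child, cpos, parent, ppos in connects:
        children.setdefault(parent, []).append((child, cpos, ppos))
        parent_of[child] = parent

    roots = [n for n in order if n != soma_name
             and parent_of.get(n, soma_name) == soma_name]

    neurites: list[Neurite] = []
    for root in roots:
        nodes = [centroid]
        radii = [1.0]
        parents = [-1]
        sec_node_idx: dict[str, list[int]] = {}

        def add_section(sec: str, attach_idx: int) -> None:
            idxs: list[int] = [attach_idx]
            attach_xyz = nodes[attach_idx]
            for j, (x, y, z, d) in enumerate(points[sec]):
                xyz = np.array([x, y, z])
                if j == 0 and np.allclose(xyz, attach_xyz, atol=1e-7):
                    continue  # duplicated attachment point
                parents.append(idxs[-1])
                nodes.append(xyz)
                radii.append(d / 2.0)
                idxs.append(len(nodes) - 1)
            sec_node_idx[sec] = idxs
            for child, _cpos, ppos in children.get(sec, []):
                own = sec_node_idx[sec]
                at = own[int(round(ppos * (len(own) - 1)))]
                add_section(child, at)

        add_section(root, 0)
        if len(nodes) >= 2:
            neurites.append(Neurite(np.array(nodes), np.array(parents),
                                    np.array(radii)))
    return NeuronMorphology(cell_id=path.stem, soma_centroid=centroid,
                            neurites=neurites)


def write_hoc(m: NeuronMorphology, path: str | Path,
              diameter: float = 0.4) -> None:
    """Serialize to the Imaris-style HOC dialect.

    Each neurite is decomposed into unbranched sections; every section's
    first point repeats its parent's attachment point, which is the
    convention the reader expects.
    """
    path = Path(path)
    lines: list[str] = ["// generated by ineuron.morphology", "create soma"]
    cx, cy, cz = m.soma_centroid
    body: list[str] = [f"soma {{ pt3dadd({cx:.6f}, {cy:.6f}, {cz:.6f}, 1.000000) }}"]
    creates: list[str] = []
    connects: list[str] = []

    for i, nr in enumerate(m.neurites):
        kids: dict[int, list[int]] = {}
        for j in range(1, nr.n_nodes):
            kids.setdefault(int(nr.parents[j]), []).append(j)
        sec_count = 0
        # (first node of section, parent section name) stack; node 0 = soma
        stack = [(c, "soma") for c in reversed(kids.get(0, []))]
        while stack:
            start, parent_sec = stack.pop()
            name = f"n{i}s{sec_count}"
            sec_count += 1
            node_path = [start]
            while len(kids.get(node_path[-1], [])) == 1:
                node_path.append(kids[node_path[-1]][0])
            creates.append(f"create {name}")
            connects.append(f"connect {name}(0), {parent_sec}(1)")
            attach = (m.soma_centroid if parent_sec == "soma"
                      else nr.nodes[nr.parents[start]])
            pts = [attach] + [nr.nodes[j] for j in node_path]
            pt_lines = "\n".join(
                f"  pt3dadd({p[0]:.6f}, {p[1]:.6f}, {p[2]:.6f}, "
                f"{diameter:.6f})" for p in pts)
            body.append(f"{name} {{\n{pt_lines}\n}}")
            for c in reversed(kids.get(node_path[-1], [])):
                stack.append((c, name))
    path.write_text("\n".join(lines + creates + connects + body) + "\n")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def total_neurite_length(m: NeuronMorphology) -> float:
    """Sum of parent-child Euclidean segment lengths over all neurites (µm)."""
    if not m.neurites:
        raise MorphometryError(f"{m.cell_id}: no neurites, length undefined")
    return float(sum(nr.total_length for nr in m.neurites))


def identify_axon(m: NeuronMorphology) -> tuple[int, float]:
    """The longest neurite is taken to be the axon; ties break to the lowest
    index so the choice is deterministic."""
    if not m.neurites:
        raise MorphometryError(f"{m.cell_id}: no neurites, axon undefined")
    lengths = [nr.total_length for nr in m.neurites]
    idx = int(np.argmax(lengths))  # argmax returns the first maximum
    return idx, lengths[idx]


def classify_polarity(m: NeuronMorphology,
                      min_primary_length: float = 5.0) -> str:
    """Classify by the number of primary neurites (total length above
    ``min_primary_length``): 1 unipolar, 2 bipolar, >= 3 multipolar."""
    if not m.neurites:
        raise MorphometryError(f"{m.cell_id}: no neurites, polarity undefined")
    n = sum(1 for nr in m.neurites
            if nr.total_length >= min_primary_length)
    if n == 0:
        raise MorphometryError(
            f"{m.cell_id}: no neurite reaches {min_primary_length} µm; "
            "unclassifiable")
    return {1: "unipolar", 2: "bipolar"}.get(n, "multipolar")


def _count_primary(m: NeuronMorphology, min_primary_length: float) -> int:
    return sum(1 for nr in m.neurites
               if nr.total_length >= min_primary_length)


def sholl_profile(m: NeuronMorphology, step: float = 10.0,
                  max_radius: float | None = None) -> ShollProfile:
    """Count crossings of concentric spheres (3-D) centred on the soma.

    A straight segment crosses a sphere of radius ``r`` once when its
    endpoint distances straddle ``r`` (near endpoint inside, far endpoint at
    or beyond ``r``) and twice when both endpoints lie outside but its
    closest approach dips inside — the distance along a straight segment is
    convex, so 0/1/2 are the only possibilities.
    """
    if step <= 0:
        raise ValueError("Sholl step must be positive")
    c = m.soma_centroid
    if not m.neurites:
        return ShollProfile(np.array([]), np.array([], dtype=int))
    starts = np.vstack([nr.segment_starts for nr in m.neurites])
    ends = np.vstack([nr.segment_ends for nr in m.neurites])
    da = np.linalg.norm(starts - c, axis=1)
    db = np.linalg.norm(ends - c, axis=1)
    maxd = float(max(da.max(initial=0.0), db.max(initial=0.0)))
    if max_radius is None:
        max_radius = maxd
    n_rings = int(math.floor(max_radius / step + 1e-9))
    radii = step * np.arange(1, n_rings + 1)
    if n_rings == 0:
        return ShollProfile(radii, np.zeros(0, dtype=int))

    # closest approach of each segment to the centre
    d = ends - starts
    a2 = np.einsum("ij,ij->i", d, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstar = np.einsum("ij,ij->i", c - starts, d) / a2
    interior = (tstar > 0) & (tstar < 1) & (a2 > 0)
    closest = starts + np.clip(tstar, 0, 1)[:, None] * d
    dmin = np.where(interior, np.linalg.norm(closest - c, axis=1),
                    np.minimum(da, db))

    counts = np.zeros(n_rings, dtype=int)
    near = np.minimum(da, db)
    far = np.maximum(da, db)
    for i, r in enumerate(radii):
        straddle = (near < r) & (far >= r)
        dip = (near > r) & (dmin < r)
        counts[i] = int(straddle.sum() + 2 * dip.sum())
    return ShollProfile(radii, counts)


def batch_normalize(df: pd.DataFrame, value_col: str = "value",
                    group_col: str = "group", batch_col: str = "batch",
                    reference_group: str = "ape") -> pd.Series:
    """Divide each value by the mean of the reference (ape) group in its
    batch, so the reference group has per-batch mean 1."""
    out = pd.Series(np.nan, index=df.index, dtype=float)
    for batch, sub in df.groupby(batch_col, sort=False):
        ref = sub.loc[sub[group_col] == reference_group, value_col]
        if ref.empty:
            raise ValueError(
                f"batch {batch!r} has no {reference_group!r} values to "
                "normalise against")
        out[sub.index] = sub[value_col] / ref.mean()
    return out


def morphometry_record(m: NeuronMorphology, step: float = 10.0,
                       min_primary_length: float = 5.0) -> MorphometryRecord:
    """Compute the full per-cell morphometric summary."""
    total = total_neurite_length(m)
    _, axon = identify_axon(m)
    return MorphometryRecord(
        cell_id=m.cell_id,
        polarity_class=classify_polarity(m, min_primary_length),
        n_primary=_count_primary(m, min_primary_length),
        total_neurite_length=total,
        axon_length=axon,
        dendrite_length=total - axon,
        sholl=sholl_profile(m, step=step),
        metadata=dict(m.metadata),
    )


def records_to_frame(records: Iterable[MorphometryRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])


def sholl_long_frame(records: Iterable[MorphometryRecord]) -> pd.DataFrame:
    """Long-format companion table: cell_id, radius, count."""
    rows = []
    for r in records:
        for radius, count in zip(r.sholl.radii, r.sholl.counts):
            rows.append({"cell_id": r.cell_id, "radius_um": radius,
                         "count": int(count)})
    return pd.DataFrame(rows, columns=["cell_id", "radius_um", "count"])
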