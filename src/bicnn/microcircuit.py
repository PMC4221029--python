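"""Construction of one cerebellar hemisphere microcircuit.

Places neuron models in (and on top of) a 100 um cube of tissue, wires them
with a nearest-neighbour rule under fixed per-class convergence ratios,
draws normalized initial synaptic weights, and encodes the result in the
four-vector address-event representation (AER) used by the runtime.

Id layout is contiguous per population in the canonical order
``mf, gr, Go, ba, Pk`` so population membership is recoverable from ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "PopulationSpec",
    "NeuronPosition",
    "SynapseTable",
    "AerNetwork",
    "PackingError",
    "WiringError",
    "POPULATION_ORDER",
    "default_population_specs",
    "default_connection_ratios",
    "CONNECTION_NATURE",
    "allocate_positions",
    "wire_nearest_neighbor",
    "draw_initial_weights",
    "encode_aer",
    "decode_aer",
    "validate_network",
    "build_hemisphere",
    "save_network",
    "load_network",
    "export_edges_csv",
    "export_positions_csv",
]

POPULATION_ORDER = ("mf", "gr", "Go", "ba", "Pk")

GRANULAR = "granular"
MOLECULAR = "molecular"

#: Vertical extent of the molecular/Purkinje layer slab above the cube (um).
MOLECULAR_DEPTH = 40.0

EXCITATORY = 1
INHIBITORY = -1

#: (pre, post) -> synaptic nature. Inhibitory sources: Go->gr, ba->Pk,
#: Pk->ba, ba->Go; everything else excitatory.
CONNECTION_NATURE = {
    ("mf", "gr"): EXCITATORY,
    ("mf", "Go"): EXCITATORY,
    ("gr", "Go"): EXCITATORY,
    ("Go", "gr"): INHIBITORY,
    ("gr", "ba"): EXCITATORY,
    ("gr", "Pk"): EXCITATORY,
    ("ba", "Pk"): INHIBITORY,
    ("Pk", "ba"): INHIBITORY,
    ("ba", "Go"): INHIBITORY,
}


class PackingError(RuntimeError):
    """Raised when non-overlap placement cannot be satisfied."""


class WiringError(ValueError):
    """Raised when a convergence request exceeds the source population."""


@dataclass(frozen=True)
class PopulationSpec:
    """One population to instantiate in a hemisphere."""

    label: str
    count: int
    layer: str  # GRANULAR or MOLECULAR
    exclusion_radius: float  # um; centers kept >= sum of radii apart

    def __post_init__(self) -> None:
        if self.count <= 0:
            raise ValueError(f"count must be positive, got {self.count}")
        if self.layer not in (GRANULAR, MOLECULAR):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.exclusion_radius < 0:
            raise ValueError("exclusion_radius must be >= 0")


class NeuronPosition(NamedTuple):
    neuron_id: int
    population: str
    x: float
    y: float
    z: float


def default_population_specs() -> list[PopulationSpec]:
    """Per-hemisphere defaults: 281 mf glomeruli + 4413 cells = 4694 nodes.

    Exclusion radii for the granular layer follow the relative soma/glomerulus
    sizes; molecular-layer radii (ba 3, Pk 8) are the largest values for which
    rejection packing of 274 ba + 15 Pk in the 100x100x40 um slab stays
    feasible.
    """
    return [
        PopulationSpec("mf", 281, GRANULAR, 4.0),
        PopulationSpec("gr", 4096, GRANULAR, 2.0),
        PopulationSpec("Go", 28, GRANULAR, 8.0),
        PopulationSpec("ba", 274, MOLECULAR, 3.0),
        PopulationSpec("Pk", 15, MOLECULAR, 8.0),
    ]


def default_connection_ratios() -> dict[tuple[str, str], tuple[int, int]]:
    """(pre, post) -> (convergence, divergence) per-cell ratios.

    Convergence is binding (every post cell gets exactly that many distinct
    nearest sources); divergence is reported but not enforced.
    """
    return {
        ("mf", "gr"): (4, 59),
        ("mf", "Go"): (66, 7),
        ("gr", "Go"): (1639, 12),
        ("Go", "gr"): (4, 586),
        ("gr", "ba"): (41, 3),
        ("gr", "Pk"): (1024, 4),
        ("ba", "Pk"): (110, 7),
        ("Pk", "ba"): (3, 55),
        ("ba", "Go"): (28, 3),
    }


# ---------------------------------------------------------------------------
# placement


def _layer_bounds(layer: str, cube_edge: float) -> tuple[float, float]:
    if layer == GRANULAR:
        return 0.0, cube_edge
    return cube_edge, cube_edge + MOLECULAR_DEPTH


def allocate_positions(
    specs: list[PopulationSpec],
    cube_edge: float = 100.0,
    rng_seed: int = 0,
    max_attempts: int = 20_000,
) -> list[NeuronPosition]:
    """Place every neuron with rejection sampling under non-overlap.

    Granular-layer nodes get centers inside the cube, molecular-layer nodes
    in a slab of depth :data:`MOLECULAR_DEPTH` on top of it.  Two centers are
    never closer than the sum of their exclusion radii.  Populations are
    packed largest-radius first (easier feasibility); ids are assigned
    afterwards in canonical population order, contiguous per population.
    """
    if cube_edge <= 0:
        raise ValueError("cube_edge must be positive")
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate population labels")

    rng = np.random.default_rng(rng_seed)
    total = sum(s.count for s in specs)
    placed_xyz = np.empty((total, 3), dtype=np.float64)
    placed_r = np.empty(total, dtype=np.float64)
    n_placed = 0

    coords: dict[str, np.ndarray] = {}
    # deterministic pack order: big radii first, label as tie-break
    for spec in sorted(specs, key=lambda s: (-s.exclusion_radius, s.label)):
        zlo, zhi = _layer_bounds(spec.layer, cube_edge)
        pop_xyz = np.empty((spec.count, 3), dtype=np.float64)
        for i in range(spec.count):
            for _ in range(max_attempts):
                cand = rng.uniform(
                    (0.0, 0.0, zlo), (cube_edge, cube_edge, zhi)
                )
                if n_placed:
                    d2 = np.sum(
                        (placed_xyz[:n_placed] - cand) ** 2, axis=1
                    )
                    min_sep = placed_r[:n_placed] + spec.exclusion_radius
                    if np.any(d2 < min_sep**2):
                        continue
                pop_xyz[i] = cand
                placed_xyz[n_placed] = cand
                placed_r[n_placed] = spec.exclusion_radius
                n_placed += 1
                break
            else:
                raise PackingError(
                    f"could not place {spec.label} #{i} after "
                    f"{max_attempts} attempts; radii/counts incompatible "
                    f"with the {cube_edge} um cube"
                )
        coords[spec.label] = pop_xyz

    by_label = {s.label: s for s in specs}
    order = [lb for lb in POPULATION_ORDER if lb in by_label]
    order += [lb for lb in labels if lb not in POPULATION_ORDER]

    positions: list[NeuronPosition] = []
    nid = 0
    for lb in order:
        for x, y, z in coords[lb]:
            positions.append(NeuronPosition(nid, lb, float(x), float(y), float(z)))
            nid += 1
    return positions


# ---------------------------------------------------------------------------
# wiring


@dataclass
class SynapseTable:
    """Flat synapse list, canonically sorted by (post_id, pre_id)."""

    pre: np.ndarray  # int64 presynaptic ids
    post: np.ndarray  # int64 postsynaptic ids
    weight: np.ndarray  # float64 signed weights
    nature: np.ndarray  # int8, +1 excitatory / -1 inhibitory
    cls: np.ndarray  # int16 index into class_keys
    class_keys: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pre)

    def sort_canonical(self) -> None:
        order = np.lexsort((self.pre, self.post))
        for name in ("pre", "post", "weight", "nature", "cls"):
            setattr(self, name, getattr(self, name)[order])


def _positions_arrays(
    positions: list[NeuronPosition],
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Split positions into per-population id and coordinate arrays."""
    ids: dict[str, list[int]] = {}
    xyz: dict[str, list[tuple[float, float, float]]] = {}
    for p in positions:
        ids.setdefault(p.population, []).append(p.neuron_id)
        xyz.setdefault(p.population, []).append((p.x, p.y, p.z))
    return (
        {k: np.asarray(v, dtype=np.int64) for k, v in ids.items()},
        {k: np.asarray(v, dtype=np.float64) for k, v in xyz.items()},
    )


def wire_nearest_neighbor(
    positions: list[NeuronPosition],
    ratios: dict[tuple[str, str], tuple[int, int]] | None = None,
) -> SynapseTable:
    """Connect, per class, each target to its convergence-many nearest sources.

    Distance ties are broken by lower presynaptic id for determinism.
    """
    if ratios is None:
        ratios = default_connection_ratios()
    ids, xyz = _positions_arrays(positions)

    pre_parts: list[np.ndarray] = []
    post_parts: list[np.ndarray] = []
    nat_parts: list[np.ndarray] = []
    cls_parts: list[np.ndarray] = []
    class_keys = list(ratios.keys())

    for ci, (key, (conv, _div)) in enumerate(ratios.items()):
        src, dst = key
        if src not in ids or dst not in ids:
            raise WiringError(f"positions lack population for class {key}")
        n_src = len(ids[src])
        if conv > n_src:
            raise WiringError(
                f"class {src}->{dst}: convergence {conv} exceeds "
                f"source population size {n_src}"
            )
        src_ids, dst_ids = ids[src], ids[dst]
        # (n_dst, n_src) distances; small enough to hold densely
        d2 = np.sum(
            (xyz[dst][:, None, :] - xyz[src][None, :, :]) ** 2, axis=2
        )
        # lexsort per row: primary distance, secondary source id
        order = np.lexsort(
            (np.broadcast_to(src_ids, d2.shape), d2), axis=1
        )[:, :conv]
        pre_parts.append(src_ids[order].ravel())
        post_parts.append(np.repeat(dst_ids, conv))
        nat = CONNECTION_NATURE.get(key, EXCITATORY)
        nat_parts.append(np.full(order.size, nat, dtype=np.int8))
        cls_parts.append(np.full(order.size, ci, dtype=np.int16))

    table = SynapseTable(
        pre=np.concatenate(pre_parts),
        post=np.concatenate(post_parts),
        weight=np.zeros(sum(p.size for p in pre_parts), dtype=np.float64),
        nature=np.concatenate(nat_parts),
        cls=np.concatenate(cls_parts),
        class_keys=class_keys,
    )
    table.sort_canonical()
    return table


def _truncated_normal(
    rng: np.random.Generator,
    n: int,
    mu: float = 0.9,
    sigma: float = 0.1,
    lo: float = 0.8,
    hi: float = 1.0,
) -> np.ndarray:
    """Rejection-sample Normal(mu, sigma) truncated to [lo, hi]."""
    out = np.empty(n, dtype=np.float64)
    filled = 0
    while filled < n:
        draw = rng.normal(mu, sigma, size=max(n - filled, 64))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def draw_initial_weights(table: SynapseTable, rng_seed: int = 0) -> SynapseTable:
    """Fill |weights| ~ TruncNormal(0.9, 0.1, [0.8, 1]) * d, d = 1/in-degree.

    The normalizing constant d is computed per connection class and
    postsynaptic cell (a Go cell with 66 mf inputs and 1639 gr inputs gets
    d = 1/66 for the former and d = 1/1639 for the latter).  Inhibitory
    classes are stored with negative sign.
    """
    rng = np.random.default_rng(rng_seed)
    raw = _truncated_normal(rng, len(table))
    # in-degree per (class, post) pair
    key = table.cls.astype(np.int64) * (table.post.max() + 1) + table.post
    _uniq, inv, counts = np.unique(key, return_inverse=True, return_counts=True)
    d = 1.0 / counts[inv]
    table.weight = raw * d * table.nature
    return table


# ---------------------------------------------------------------------------
# AER codec


@dataclass
class AerNetwork:
    """Four-vector sparse-network encoding plus population id ranges.

    ``ID[i]`` is the i-th neuron id, ``N_P[i]`` its presynapse count, and the
    stacked ``P``/``W`` hold presynaptic ids and signed weights; neuron i's
    slice starts at ``offsets[i] = sum(N_P[:i])``.
    """

    ID: np.ndarray
    N_P: np.ndarray
    P: np.ndarray
    W: np.ndarray
    population_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def offsets(self) -> np.ndarray:
        return np.concatenate(([0], np.cumsum(self.N_P)))

    @property
    def n_neurons(self) -> int:
        return len(self.ID)

    @property
    def n_synapses(self) -> int:
        return len(self.P)

    def presynapses(self, neuron_id: int) -> tuple[np.ndarray, np.ndarray]:
        """Presynaptic ids and weights of one neuron."""
        idx = int(np.searchsorted(self.ID, neuron_id))
        if idx >= len(self.ID) or self.ID[idx] != neuron_id:
            raise KeyError(f"unknown neuron id {neuron_id}")
        off = self.offsets
        return self.P[off[idx] : off[idx + 1]], self.W[off[idx] : off[idx + 1]]


def encode_aer(
    table: SynapseTable,
    positions: list[NeuronPosition],
    population_ranges: dict[str, tuple[int, int]] | None = None,
) -> AerNetwork:
    """Encode a synapse table as the four AER vectors.

    Neurons appear in ID in ascending id order; presynapses of each neuron
    are stacked in ascending presynaptic-id order.
    """
    all_ids = np.asarray(sorted(p.neuron_id for p in positions), dtype=np.int64)
    if len(np.unique(all_ids)) != len(all_ids):
        raise ValueError("duplicate neuron ids in positions")
    if len(table) and not np.isin(
        np.concatenate([table.pre, table.post]), all_ids
    ).all():
        raise ValueError("synapse references an unknown neuron id")

    if population_ranges is None:
        population_ranges = {}
        for p in positions:
            lo, hi = population_ranges.get(p.population, (p.neuron_id, p.neuron_id + 1))
            population_ranges[p.population] = (
                min(lo, p.neuron_id),
                max(hi, p.neuron_id + 1),
            )

    order = np.lexsort((table.pre, table.post))
    post_sorted = table.post[order]
    n_p = np.zeros(len(all_ids), dtype=np.int64)
    idx_of = np.searchsorted(all_ids, post_sorted)
    np.add.at(n_p, idx_of, 1)
    return AerNetwork(
        ID=all_ids,
        N_P=n_p,
        P=table.pre[order].copy(),
        W=table.weight[order].copy(),
        population_ranges=dict(population_ranges),
    )


def decode_aer(net: AerNetwork) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`encode_aer`: (pre, post, weight) in canonical order."""
    post = np.repeat(net.ID, net.N_P)
    return net.P.copy(), post, net.W.copy()


# ---------------------------------------------------------------------------
# validation & convenience


def validate_network(
    net: AerNetwork,
    ratios: dict[tuple[str, str], tuple[int, int]] | None = None,
) -> dict:
    """Report realized per-class convergence/divergence against requests."""
    if ratios is None:
        ratios = default_connection_ratios()
    pre, post, _w = decode_aer(net)
    ranges = net.population_ranges

    def pop_of(arr: np.ndarray, label: str) -> np.ndarray:
        lo, hi = ranges[label]
        return (arr >= lo) & (arr < hi)

    report: dict = {"total_synapses": int(net.n_synapses), "classes": {}, "ok": True}
    for (src, dst), (conv, div) in ratios.items():
        mask = pop_of(pre, src) & pop_of(post, dst)
        lo_d, hi_d = ranges[dst]
        lo_s, hi_s = ranges[src]
        indeg = np.bincount(post[mask] - lo_d, minlength=hi_d - lo_d)
        outdeg = np.bincount(pre[mask] - lo_s, minlength=hi_s - lo_s)
        entry = {
            "requested_convergence": conv,
            "requested_divergence": div,
            "convergence_min": int(indeg.min()),
            "convergence_max": int(indeg.max()),
            "divergence_mean": float(outdeg.mean()),
            "divergence_max": int(outdeg.max()),
            "n_synapses": int(mask.sum()),
            "convergence_exact": bool((indeg == conv).all()),
        }
        if not entry["convergence_exact"]:
            report["ok"] = False
        report["classes"][f"{src}->{dst}"] = entry
    return report


def build_hemisphere(
    rng_seed: int,
    specs: list[PopulationSpec] | None = None,
    ratios: dict[tuple[str, str], tuple[int, int]] | None = None,
    cube_edge: float = 100.0,
) -> tuple[AerNetwork, SynapseTable, list[NeuronPosition]]:
    """Full pipeline: place, wire, weight, encode one hemisphere."""
    if specs is None:
        specs = default_population_specs()
    if ratios is None:
        ratios = default_connection_ratios()
    positions = allocate_positions(specs, cube_edge=cube_edge, rng_seed=rng_seed)
    table = wire_nearest_neighbor(positions, ratios)
    table = draw_initial_weights(table, rng_seed=rng_seed + 1)
    ranges: dict[str, tuple[int, int]] = {}
    cursor = 0
    order = [lb for lb in POPULATION_ORDER if lb in {s.label for s in specs}]
    by_label = {s.label: s for s in specs}
    for lb in order:
        ranges[lb] = (cursor, cursor + by_label[lb].count)
        cursor += by_label[lb].count
    net = encode_aer(table, positions, population_ranges=ranges)
    return net, table, positions


# ---------------------------------------------------------------------------
# persistence


def save_network(net: AerNetwork, path: str, build_seed: int | None = None) -> None:
    """Write the four AER vectors to an .npz plus a JSON sidecar."""
    path = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
    np.savez(path, ID=net.ID, N_P=net.N_P, P=net.P, W=net.W)
    sidecar = {
        "population_ranges": {k: list(v) for k, v in net.population_ranges.items()},
        "build_seed": build_seed,
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_network(path: str) -> AerNetwork:
    path = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
    with np.load(path) as z:
        arrays = {k: z[k] for k in ("ID", "N_P", "P", "W")}
    ranges: dict[str, tuple[int, int]] = {}
    try:
        with open(path + ".json") as fh:
            meta = json.load(fh)
        ranges = {k: tuple(v) for k, v in meta["population_ranges"].items()}
    except FileNotFoundError:
        pass
    return AerNetwork(population_ranges=ranges, **arrays)


def export_positions_csv(positions: list[NeuronPosition], path: str) -> None:
    """3D scatter export: one row per node (id, population, x, y, z in um)."""
    with open(path, "w") as fh:
        fh.write("neuron_id,population,x,y,z\n")
        for p in positions:
            fh.write(f"{p.neuron_id},{p.population},{p.x!r},{p.y!r},{p.z!r}\n")


def export_edges_csv(table: SynapseTable, path: str) -> None:
    """Tabular edge list (pre_id, post_id, class, weight)."""
    keys = [f"{a}->{b}" for a, b in table.class_keys]
    with open(path, "w") as fh:
        fh.write("pre_id,post_id,class,weight\n")
        for p, q, c, w in zip(table.pre, table.post, table.cls, table.weight):
            fh.write(f"{p},{q},{keys[c]},{w!r}\n")
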