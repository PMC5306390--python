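"""Model connectome of the protocerebral bridge / ellipsoid body circuit.

The model contains 60 neurons in four classes — 18 E-PGs, 16 P-ENs, 16 P-EGs
and 10 PB-intrinsic neurons (8 Δ7-type plus 2 P6-8–9-type) — each defined by
the anatomical compartments holding its dendritic and axonal arbors.  The PB
is divided into 18 glomeruli (L9..L1, R1..R9); the EB ring into 16 wedges
(w0..w15, azimuth increasing with index) grouped into 8 tiles (tile t = wedges
2t and 2t+1).  A synapse is postulated wherever an axonal arbor and a
dendritic arbor share a compartment, with a tile overlapping both of its
wedges; neurons make no autapses.

Wedge ↔ glomerulus correspondence (the azimuthal map): even wedges carry the
right-hemisphere E-PG dendrites in ascending glomerulus order (w = 2k ↔
R(k+1)) while odd wedges carry the left-hemisphere ones offset by one
azimuthal step (w = 2k+1 ↔ L(k+2), wrapping w15 ↔ L1).  The two G9 E-PGs
share the wrap-around wedges (G9R ↔ w0, G9L ↔ w15).  This mirrored
interleaving is what closes the ring: a P-EN returning to the tile of its
home wedge excites both its own E-PG and the E-PG one wedge over, so local
excitation spreads azimuthally in both directions (right-hemisphere P-ENs one
way, left the other) while the Δ7 pool provides glomerulus-wide inhibition.

Synapse strengths are uniform within each of the eight legal class pairs and
are measured in postsynaptic-current (PSC) equivalents per presynaptic action
potential; inhibitory classes carry negative sign.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "Compartment",
    "NeuronSpec",
    "SynapseClassParams",
    "ConnectivityMatrix",
    "N_NEURONS",
    "N_WEDGES",
    "N_TILES",
    "SYNAPSE_CLASSES",
    "enumerate_neurons",
    "infer_synapses",
    "build_matrix",
    "baseline_matrix",
    "bilateral_symmetry_map",
    "wedge_of_glomerulus",
    "tile_of_wedge",
    "tile_azimuth",
    "wedge_azimuth",
    "epg_channels_by_tile",
    "pen_tile_index",
    "class_indices",
    "subtype_indices",
    "write_matrix_csv",
    "read_matrix_csv",
]

N_NEURONS = 60
N_WEDGES = 16
N_TILES = 8

#: the eight legal (presynaptic class, postsynaptic class) pairs
SYNAPSE_CLASSES = (
    "PEN>EPG",
    "PEG>EPG",
    "EPG>PEN",
    "EPG>PEG",
    "EPG>Pintr",
    "Pintr>PEN",
    "Pintr>PEG",
    "Pintr>Pintr",
)

_CLASS_KEY = {"E-PG": "EPG", "P-EN": "PEN", "P-EG": "PEG", "Pintr": "Pintr"}


class Compartment(NamedTuple):
    """One anatomical compartment.

    ``neuropil`` is one of ``PB`` (index = glomerulus 1–9, hemisphere L/R),
    ``EB_wedge`` (index 0–15), ``EB_tile`` (index 0–7), ``Gall`` or
    ``Noduli`` (index 0, hemisphere L/R).  EB ring compartments carry
    hemisphere ``none``.
    """

    neuropil: str
    index: int
    hemisphere: str = "none"


def tile_of_wedge(w: int) -> int:
    return (w % N_WEDGES) // 2


def wedge_azimuth(w: int) -> float:
    """Center azimuth of wedge ``w`` in radians, in (−π, π]."""
    return -np.pi + (w % N_WEDGES + 0.5) * (2 * np.pi / N_WEDGES)


def tile_azimuth(t: int) -> float:
    """Center azimuth of tile ``t`` in radians, in (−π, π]."""
    return -np.pi + (t % N_TILES + 0.5) * (2 * np.pi / N_TILES)


def wedge_of_glomerulus(hemisphere: str, g: int) -> int:
    """EB wedge whose E-PG innervates PB glomerulus ``g`` of ``hemisphere``.

    Right glomeruli occupy even wedges in ascending order; left glomeruli the
    interleaved odd wedges shifted one azimuthal step.  G9 shares the
    wrap-around wedge of its side (G9R ↔ w0, G9L ↔ w15).
    """
    if hemisphere == "R":
        return 0 if g == 9 else 2 * (g - 1)
    if hemisphere == "L":
        if g == 9:
            return 15
        return (2 * (g - 2) + 1) % N_WEDGES if g >= 2 else 15
    raise ValueError(f"bad hemisphere {hemisphere!r}")


@dataclass(frozen=True)
class NeuronSpec:
    """One model neuron: a class/subtype, a hemisphere and two arbor sets."""

    id: int
    neuron_class: str  # E-PG | P-EN | P-EG | Pintr
    subtype: str  # E-PG | E-PG_tip | P-EN | P-EG | Pintr_D7 | Pintr_P6-8-9
    hemisphere: str  # L | R
    dendrite_compartments: frozenset
    axon_compartments: frozenset

    def pb_axon_glomeruli(self) -> set:
        return {
            (c.hemisphere, c.index)
            for c in self.axon_compartments
            if c.neuropil == "PB"
        }


@dataclass(frozen=True)
class SynapseClassParams:
    """Signed strengths of the eight synapse classes, in PSCs per spike.

    Baseline: excitatory classes +20; the Pintr pool is inhibitory, with the
    Pintr→P-EN and Pintr→P-EG classes at −15 and Pintr→Pintr at −20.
    """

    pen_epg: float = 20.0
    peg_epg: float = 20.0
    epg_pen: float = 20.0
    epg_peg: float = 20.0
    epg_pintr: float = 20.0
    pintr_pen: float = -15.0
    pintr_peg: float = -15.0
    pintr_pintr: float = -20.0

    _FIELDS = (
        "pen_epg",
        "peg_epg",
        "epg_pen",
        "epg_peg",
        "epg_pintr",
        "pintr_pen",
        "pintr_peg",
        "pintr_pintr",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self._FIELDS], dtype=float)

    @classmethod
    def from_array(cls, a) -> "SynapseClassParams":
        a = np.asarray(a, dtype=float)
        if a.shape != (8,):
            raise ValueError("expected 8 synapse-class strengths")
        return cls(**dict(zip(cls._FIELDS, a.tolist())))

    def strength(self, class_name: str) -> float:
        return getattr(self, _key_to_field(class_name))


def _key_to_field(class_name: str) -> str:
    try:
        pre, post = class_name.split(">")
    except ValueError:
        raise KeyError(f"unknown synapse class {class_name!r}") from None
    if class_name not in SYNAPSE_CLASSES:
        raise KeyError(f"unknown synapse class {class_name!r}")
    return f"{pre.lower()}_{post.lower()}"


@dataclass
class ConnectivityMatrix:
    """Signed 60×60 strength matrix; ``M[j, i]`` is the synapse j → i."""

    M: np.ndarray
    class_label: np.ndarray  # 60×60 array of '' or a SYNAPSE_CLASSES entry
    neurons: list = field(default_factory=list)


def _pb(hemisphere: str, g: int) -> Compartment:
    return Compartment("PB", g, hemisphere)


def enumerate_neurons() -> list:
    """Enumerate the 60 model neurons in canonical order.

    Order: E-PGs, P-ENs, P-EGs, Pintrs; within each class left hemisphere
    before right, ascending glomerulus index (Δ7 cells by azimuth index, then
    the two P6-8–9 cells L before R).
    """
    neurons: list[NeuronSpec] = []
    nid = 0

    # E-PGs: dendrite = one EB wedge, axon = one PB glomerulus + Gall.
    for hemi in ("L", "R"):
        for g in range(1, 10):
            w = wedge_of_glomerulus(hemi, g)
            subtype = "E-PG_tip" if g == 9 else "E-PG"
            neurons.append(
                NeuronSpec(
                    id=nid,
                    neuron_class="E-PG",
                    subtype=subtype,
                    hemisphere=hemi,
                    dendrite_compartments=frozenset({Compartment("EB_wedge", w)}),
                    axon_compartments=frozenset(
                        {_pb(hemi, g), Compartment("Gall", 0, hemi)}
                    ),
                )
            )
            nid += 1

    # P-ENs: dendrite = PB glomerulus G2–G9, axon = EB tile of the home wedge
    # (+ Noduli).
    for hemi in ("L", "R"):
        for g in range(2, 10):
            t = tile_of_wedge(wedge_of_glomerulus(hemi, g))
            neurons.append(
                NeuronSpec(
                    id=nid,
                    neuron_class="P-EN",
                    subtype="P-EN",
                    hemisphere=hemi,
                    dendrite_compartments=frozenset({_pb(hemi, g)}),
                    axon_compartments=frozenset(
                        {Compartment("EB_tile", t), Compartment("Noduli", 0, hemi)}
                    ),
                )
            )
            nid += 1

    # P-EGs: dendrite = PB glomerulus G1–G8, axon = EB tile of the home wedge
    # (+ Gall).
    for hemi in ("L", "R"):
        for g in range(1, 9):
            t = tile_of_wedge(wedge_of_glomerulus(hemi, g))
            neurons.append(
                NeuronSpec(
                    id=nid,
                    neuron_class="P-EG",
                    subtype="P-EG",
                    hemisphere=hemi,
                    dendrite_compartments=frozenset({_pb(hemi, g)}),
                    axon_compartments=frozenset(
                        {Compartment("EB_tile", t), Compartment("Gall", 0, hemi)}
                    ),
                )
            )
            nid += 1

    # Pintrs.  Dendrites span all 18 glomeruli (so every E-PG excites every
    # Pintr).  The 8 Δ7 cells place boutons in one bilateral glomerulus pair
    # {Ld, Rd}; the 2 P6-8–9 cells place boutons in G9 of one side, covering
    # the glomeruli the Δ7 pool misses.
    all_glomeruli = frozenset(
        _pb(h, g) for h in ("L", "R") for g in range(1, 10)
    )
    for d in range(1, 9):
        neurons.append(
            NeuronSpec(
                id=nid,
                neuron_class="Pintr",
                subtype="Pintr_D7",
                # midline-spanning cells; the L/R label is bookkeeping only
                hemisphere="L" if d % 2 else "R",
                dendrite_compartments=all_glomeruli,
                axon_compartments=frozenset({_pb("L", d), _pb("R", d)}),
            )
        )
        nid += 1
    for hemi in ("L", "R"):
        neurons.append(
            NeuronSpec(
                id=nid,
                neuron_class="Pintr",
                subtype="Pintr_P6-8-9",
                hemisphere=hemi,
                dendrite_compartments=all_glomeruli,
                axon_compartments=frozenset({_pb(hemi, 9)}),
            )
        )
        nid += 1

    assert nid == N_NEURONS
    return neurons


def _compartments_overlap(a: Compartment, b: Compartment) -> bool:
    """True if an axonal compartment ``a`` reaches a dendritic one ``b``."""
    if a == b:
        return True
    # a tile contacts dendrites in each of its two wedges, and vice versa
    if a.neuropil == "EB_tile" and b.neuropil == "EB_wedge":
        return tile_of_wedge(b.index) == a.index
    if a.neuropil == "EB_wedge" and b.neuropil == "EB_tile":
        return tile_of_wedge(a.index) == b.index
    return False


def _arbors_overlap(axons: Iterable, dendrites: Iterable) -> bool:
    return any(
        _compartments_overlap(a, d) for a in axons for d in dendrites
    )


def infer_synapses(neurons: list) -> tuple[np.ndarray, np.ndarray]:
    """Infer the boolean adjacency and per-entry synapse-class labels.

    ``adjacency[j, i]`` is True iff presynaptic neuron ``j``'s axonal arbor
    overlaps postsynaptic neuron ``i``'s dendritic arbor in some compartment
    and ``j != i``.  Raises ``ValueError`` if an inferred synapse falls
    outside the eight legal class pairs (a malformed compartment table).
    """
    n = len(neurons)
    adjacency = np.zeros((n, n), dtype=bool)
    labels = np.full((n, n), "", dtype=object)
    for j, pre in enumerate(neurons):
        for i, post in enumerate(neurons):
            if i == j:
                continue
            if _arbors_overlap(pre.axon_compartments, post.dendrite_compartments):
                cls = f"{_CLASS_KEY[pre.neuron_class]}>{_CLASS_KEY[post.neuron_class]}"
                if cls not in SYNAPSE_CLASSES:
                    raise ValueError(
                        f"illegal synapse class {cls} between neurons "
                        f"{pre.id} and {post.id}"
                    )
                adjacency[j, i] = True
                labels[j, i] = cls
    return adjacency, labels


def build_matrix(
    adjacency: np.ndarray,
    labels: np.ndarray,
    params: SynapseClassParams | None = None,
    neurons: list | None = None,
) -> ConnectivityMatrix:
    """Fill the adjacency with signed per-class strengths."""
    if params is None:
        params = SynapseClassParams()
    n = adjacency.shape[0]
    M = np.zeros((n, n), dtype=float)
    for cls in SYNAPSE_CLASSES:
        mask = adjacency & (labels == cls)
        if mask.any():
            M[mask] = params.strength(cls)
    return ConnectivityMatrix(M=M, class_label=labels, neurons=neurons or [])


def baseline_matrix(params: SynapseClassParams | None = None) -> ConnectivityMatrix:
    """Canonical neurons + inferred synapses + (baseline) strengths."""
    neurons = enumerate_neurons()
    adjacency, labels = infer_synapses(neurons)
    return build_matrix(adjacency, labels, params, neurons)


def _mirror_compartment(c: Compartment) -> Compartment:
    flip = {"L": "R", "R": "L", "none": "none"}
    if c.neuropil == "EB_wedge":
        return Compartment("EB_wedge", (15 - c.index) % N_WEDGES)
    if c.neuropil == "EB_tile":
        return Compartment("EB_tile", (7 - c.index) % N_TILES)
    if c.neuropil == "PB":
        # the reflection reverses azimuth, so glomerulus indices reflect too
        # (g ↔ 2−g mod 8 within G1–G8; the wrap glomerulus G9 is fixed)
        g = c.index if c.index == 9 else ((1 - c.index) % 8) + 1
        return Compartment("PB", g, flip[c.hemisphere])
    return Compartment(c.neuropil, c.index, flip[c.hemisphere])


def bilateral_symmetry_map(neurons: list) -> np.ndarray:
    """The left↔right involution π with M[π(j), π(i)] = M[j, i].

    The mirror swaps PB/Gall/Noduli hemispheres and reflects the EB ring
    (wedge w ↔ 15−w, tile t ↔ 7−t).  Found by matching each neuron's
    mirrored arbor sets against the population; raises ``ValueError`` if any
    neuron lacks a mirror partner (no valid involution).
    """
    index = {
        (nrn.neuron_class, nrn.dendrite_compartments, nrn.axon_compartments): nrn.id
        for nrn in neurons
    }
    pi = np.empty(len(neurons), dtype=int)
    for nrn in neurons:
        key = (
            nrn.neuron_class,
            frozenset(_mirror_compartment(c) for c in nrn.dendrite_compartments),
            frozenset(_mirror_compartment(c) for c in nrn.axon_compartments),
        )
        if key not in index:
            raise ValueError(f"neuron {nrn.id} has no bilateral mirror partner")
        pi[nrn.id] = index[key]
    if not np.array_equal(pi[pi], np.arange(len(neurons))):
        raise ValueError("bilateral map is not an involution")
    return pi


# ---------------------------------------------------------------------------
# bookkeeping helpers used by the stimulus and metrics modules


def class_indices(neurons: list, neuron_class: str) -> np.ndarray:
    return np.array(
        [n.id for n in neurons if n.neuron_class == neuron_class], dtype=int
    )


def subtype_indices(neurons: list, subtype: str) -> np.ndarray:
    ids = np.array([n.id for n in neurons if n.subtype == subtype], dtype=int)
    if ids.size == 0:
        raise KeyError(f"unknown subtype {subtype!r}")
    return ids


def _epg_wedge(nrn: NeuronSpec) -> int:
    (c,) = [c for c in nrn.dendrite_compartments if c.neuropil == "EB_wedge"]
    return c.index


def epg_channels_by_tile(neurons: list) -> list:
    """For each EB tile, the E-PG input channels (ids 0–17) it drives.

    A channel is attached to a tile when its dendritic wedge lies in it, so
    wrap-partner E-PGs (the G9 pair) share their tile's input.
    """
    epgs = [n for n in neurons if n.neuron_class == "E-PG"]
    out = []
    for t in range(N_TILES):
        out.append(
            np.array(
                [n.id for n in epgs if tile_of_wedge(_epg_wedge(n)) == t], dtype=int
            )
        )
    return out


def pen_tile_index(neurons: list) -> dict:
    """Map P-EN neuron id → axonal EB tile index, split by hemisphere."""
    out: dict[str, dict[int, int]] = {"L": {}, "R": {}}
    for n in neurons:
        if n.neuron_class != "P-EN":
            continue
        (t,) = [c.index for c in n.axon_compartments if c.neuropil == "EB_tile"]
        out[n.hemisphere][n.id] = t
    return out


# ---------------------------------------------------------------------------
# I/O


def write_matrix_csv(cm: ConnectivityMatrix, csv_path, sidecar_path=None) -> None:
    """Write M as CSV (header row/col = neuron ids) + JSON neuron metadata."""
    n = cm.M.shape[0]
    with open(csv_path, "w") as fh:
        fh.write("," + ",".join(str(i) for i in range(n)) + "\n")
        for j in range(n):
            fh.write(
                str(j) + "," + ",".join(f"{v:g}" for v in cm.M[j]) + "\n"
            )
    if sidecar_path is not None:
        meta = {
            "neurons": [
                {
                    "id": nrn.id,
                    "class": nrn.neuron_class,
                    "subtype": nrn.subtype,
                    "hemisphere": nrn.hemisphere,
                    "dendrites": sorted(map(list, nrn.dendrite_compartments)),
                    "axons": sorted(map(list, nrn.axon_compartments)),
                }
                for nrn in cm.neurons
            ],
            "synapse_classes": [
                {"from": int(j), "to": int(i), "class": cm.class_label[j, i]}
                for j in range(n)
                for i in range(n)
                if cm.class_label[j, i]
            ],
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def read_matrix_csv(csv_path) -> np.ndarray:
    rows = []
    with open(csv_path) as fh:
        header = fh.readline()
        for line in fh:
            rows.append([float(x) for x in line.strip().split(",")[1:]])
    return np.array(rows, dtype=float)
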