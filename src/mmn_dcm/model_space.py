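"""The eight-region mismatch-negativity network and its model space.

The network comprises bilateral primary auditory cortex (A1), superior
temporal gyrus (STG), inferior frontal gyrus (IFG) and inferior parietal
cortex (IPC).  The frontotemporal hierarchy IFG > STG > A1 is fixed; six
alternative architectures differ in how the parietal nodes attach to it and
whether they receive expectancy input:

=====  ============================  =====================
arch   IFG--IPC relation             expectancy input
=====  ============================  =====================
1      no fronto-parietal edge       IFG only
2      IPC above IFG                 IFG only
3      IFG above IPC                 IFG only
4      no fronto-parietal edge       IFG and IPC
5      IPC above IFG                 IFG and IPC
6      IFG above IPC                 IFG and IPC
=====  ============================  =====================

In every architecture STG sends forward connections to IPC (the parietal
node is always attached to the temporal hierarchy).  Each architecture comes
in two repetition-basis variants — exponential decay only (``E``) or
exponential decay plus phasic change (``EG``) — giving a 12-model space.

Forward connections run low -> high in the hierarchy, backward connections
are their reversals, and homologous inter-hemispheric (lateral) connections
between A1s and STGs are included symmetrically (configurable).

A reduced bilateral A1 + STG "demo" network is provided for fast,
fully-exercising runs of the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import numpy as np

from .parameters import ParameterLayout

__all__ = [
    "Region",
    "NetworkModel",
    "REGIONS8",
    "REGIONS_DEMO",
    "build_network",
    "build_full_network",
    "enumerate_model_space",
    "build_demo_network",
    "default_priors",
    "DEFAULT_PRIOR_VARIANCES",
]


@dataclass(frozen=True)
class Region:
    name: str
    mni: tuple[float, float, float]


#: The eight cortical sources with their MNI coordinates.
REGIONS8 = (
    Region("A1l", (-42.0, -22.0, 7.0)),
    Region("A1r", (46.0, -14.0, 8.0)),
    Region("STGl", (-61.0, -32.0, 8.0)),
    Region("STGr", (59.0, -25.0, 8.0)),
    Region("IFGl", (-46.0, 20.0, 8.0)),
    Region("IFGr", (46.0, 20.0, 8.0)),
    Region("IPCl", (-58.0, -27.0, 30.0)),
    Region("IPCr", (59.0, -41.0, 30.0)),
)

#: Reduced bilateral A1 + STG network for fast demonstration runs.
REGIONS_DEMO = REGIONS8[:4]


@dataclass
class NetworkModel:
    """One candidate network architecture with its repetition-basis kind.

    ``fwd_mask[i, j]`` is True when region ``j`` sends a forward connection
    to region ``i`` (target-major, so drives are ``mask @ rates``).
    """

    regions: tuple[Region, ...]
    fwd_mask: np.ndarray
    bwd_mask: np.ndarray
    auditory_input: tuple[int, ...]
    expectancy_input: tuple[int, ...]
    basis_kind: str  # "E" or "EG"
    model_id: str
    layout: ParameterLayout = field(repr=False)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.regions)

    def to_json(self) -> str:
        return json.dumps({
            "model_id": self.model_id,
            "regions": [{"name": r.name, "mni": list(r.mni)} for r in self.regions],
            "fwd_mask": self.fwd_mask.astype(int).tolist(),
            "bwd_mask": self.bwd_mask.astype(int).tolist(),
            "auditory_input": list(self.auditory_input),
            "expectancy_input": list(self.expectancy_input),
            "basis_kind": self.basis_kind,
        }, indent=2)


def _hemi_pairs(names):
    """Pair left/right homologues by their 'l'/'r' suffix."""
    pairs = []
    for i, n in enumerate(names):
        if n.endswith("l"):
            j = names.index(n[:-1] + "r")
            pairs.append((i, j))
    return pairs


def _edges_for(names, edge_names):
    idx = {n: i for i, n in enumerate(names)}
    return [(idx[s], idx[d]) for s, d in edge_names]


def _union_edges(names, lateral=True):
    """Forward-edge support (src, dst) of the union over architectures."""
    base = []
    for h in "lr":
        if f"A1{h}" in names and f"STG{h}" in names:
            base.append((f"A1{h}", f"STG{h}"))
        if f"STG{h}" in names and f"IFG{h}" in names:
            base.append((f"STG{h}", f"IFG{h}"))
        if f"STG{h}" in names and f"IPC{h}" in names:
            base.append((f"STG{h}", f"IPC{h}"))
        if f"IFG{h}" in names and f"IPC{h}" in names:
            base.append((f"IFG{h}", f"IPC{h}"))
            base.append((f"IPC{h}", f"IFG{h}"))
    if lateral:
        for pre in ("A1", "STG"):
            if f"{pre}l" in names and f"{pre}r" in names:
                base.append((f"{pre}l", f"{pre}r"))
                base.append((f"{pre}r", f"{pre}l"))
    return base


def _make_layout(regions, lateral=True):
    names = [r.name for r in regions]
    fwd = _edges_for(names, _union_edges(names, lateral))
    bwd = [(d, s) for (s, d) in fwd]  # backward support mirrors forward
    aud = [i for i, n in enumerate(names) if n.startswith("A1")]
    if any(n.startswith("IFG") for n in names):
        exp = [i for i, n in enumerate(names) if n.startswith(("IFG", "IPC"))]
    else:
        # demo network: expectancy input targets the top of its hierarchy
        exp = [i for i, n in enumerate(names) if n.startswith("STG")]
    return ParameterLayout(names, fwd, bwd, aud, exp)


def _masks_from_edges(n, edges):
    fwd = np.zeros((n, n), bool)
    for (s, d) in edges:
        fwd[d, s] = True
    return fwd, fwd.T.copy()


def build_network(architecture_id: int, basis_kind: str, lateral: bool = True) -> NetworkModel:
    """Construct one of the six parieto-frontal architectures.

    Parameters
    ----------
    architecture_id : int in 1..6
    basis_kind : {"E", "EG"}
        Repetition basis: exponential only, or exponential plus phasic.
    lateral : bool
        Include homologous A1--A1 and STG--STG inter-hemispheric connections.
    """
    if architecture_id not in range(1, 7):
        raise ValueError(f"architecture_id must be in 1..6, got {architecture_id}")
    if basis_kind not in ("E", "EG"):
        raise ValueError(f"basis_kind must be 'E' or 'EG', got {basis_kind!r}")

    regions = REGIONS8
    names = [r.name for r in regions]
    edge_names = []
    for h in "lr":
        edge_names += [(f"A1{h}", f"STG{h}"), (f"STG{h}", f"IFG{h}"), (f"STG{h}", f"IPC{h}")]
        if architecture_id in (2, 5):      # parietal above frontal
            edge_names.append((f"IFG{h}", f"IPC{h}"))
        elif architecture_id in (3, 6):    # frontal above parietal
            edge_names.append((f"IPC{h}", f"IFG{h}"))
    if lateral:
        for pre in ("A1", "STG"):
            edge_names += [(f"{pre}l", f"{pre}r"), (f"{pre}r", f"{pre}l")]

    fwd, bwd = _masks_from_edges(len(regions), _edges_for(names, edge_names))
    aud = tuple(i for i, n in enumerate(names) if n.startswith("A1"))
    if architecture_id <= 3:
        exp = tuple(i for i, n in enumerate(names) if n.startswith("IFG"))
    else:
        exp = tuple(i for i, n in enumerate(names) if n.startswith(("IFG", "IPC")))

    return NetworkModel(
        regions=regions, fwd_mask=fwd, bwd_mask=bwd,
        auditory_input=aud, expectancy_input=exp,
        basis_kind=basis_kind, model_id=f"{architecture_id}{basis_kind}",
        layout=_make_layout(regions, lateral),
    )


def build_full_network(lateral: bool = True) -> NetworkModel:
    """The superset model: union of all architectures, EG basis.

    Every candidate model's free-parameter set is nested in this model's, so
    each subject need only be inverted once and the 12 candidates scored by
    Bayesian model reduction.
    """
    regions = REGIONS8
    names = [r.name for r in regions]
    fwd, bwd = _masks_from_edges(len(regions), _edges_for(names, _union_edges(names, lateral)))
    aud = tuple(i for i, n in enumerate(names) if n.startswith("A1"))
    exp = tuple(i for i, n in enumerate(names) if n.startswith(("IFG", "IPC")))
    return NetworkModel(
        regions=regions, fwd_mask=fwd, bwd_mask=bwd,
        auditory_input=aud, expectancy_input=exp,
        basis_kind="EG", model_id="full",
        layout=_make_layout(regions, lateral),
    )


def build_demo_network(basis_kind: str = "EG", lateral: bool = True) -> NetworkModel:
    """Reduced bilateral A1 + STG network (hierarchy STG > A1).

    The demo network carries auditory input only: an expectancy input to its
    highest (STG) level would drive the same superficial-pyramidal
    populations whose gain is the quantity of interest and render that gain
    unidentifiable in so small a network.
    """
    regions = REGIONS_DEMO
    names = [r.name for r in regions]
    edge_names = [("A1l", "STGl"), ("A1r", "STGr")]
    if lateral:
        for pre in ("A1", "STG"):
            edge_names += [(f"{pre}l", f"{pre}r"), (f"{pre}r", f"{pre}l")]
    fwd, bwd = _masks_from_edges(len(regions), _edges_for(names, edge_names))
    aud = tuple(i for i, n in enumerate(names) if n.startswith("A1"))
    exp = ()
    return NetworkModel(
        regions=regions, fwd_mask=fwd, bwd_mask=bwd,
        auditory_input=aud, expectancy_input=exp,
        basis_kind=basis_kind, model_id=f"demo{basis_kind}",
        layout=_make_layout(regions, lateral),
    )


def enumerate_model_space(lateral: bool = True) -> list[NetworkModel]:
    """The 12-model space: architectures 1..6, each with E and EG bases.

    Ordering is stable: 1E..6E then 1EG..6EG.
    """
    return [build_network(a, kind, lateral)
            for kind in ("E", "EG") for a in range(1, 7)]


#: Default prior variances per parameter class ("default-v1" profile).
#: The scientific quantities (superficial-pyramidal gain, extrinsic weights,
#: repetition effects) are loosely constrained; conventional biophysical
#: nuisance quantities (rate constants, input/output gains, delays, slope)
#: are pinned tightly so they cannot absorb condition- and group-related
#: variance, which keeps the gain/connectivity parameters identifiable.
DEFAULT_PRIOR_VARIANCES = {
    "T": 1.0 / 128,
    "G_sp": 1.0 / 8,
    "A": 1.0 / 16,
    "B": 1.0 / 16,
    "C": 1.0 / 64,
    "D": 1.0 / 64,
    "S": 1.0 / 64,
    "L": 1.0 / 64,
}


def default_priors(network: NetworkModel,
                   profile: dict | None = None):
    """Default prior density for a network model.

    Zero means everywhere; diagonal variances by parameter class, with
    exactly zero variance on connections the architecture's masks forbid, on
    inputs the architecture does not receive, on phasic modulation entries of
    exponential-only models, and on the nine conventional intrinsic gains
    other than the superficial-pyramidal self-gain (which are treated as
    fixed constants of the microcircuit).
    """
    from .parameters import PriorDensity, SP_GAIN_INDEX, INTRINSIC_GAIN_LABELS

    prof = dict(DEFAULT_PRIOR_VARIANCES)
    if profile:
        prof.update(profile)

    lay = network.layout
    var = np.zeros(lay.size)
    names = lay.names
    sp_label = INTRINSIC_GAIN_LABELS[SP_GAIN_INDEX]
    rn = lay.region_names
    aud_names = {rn[i] for i in network.auditory_input}
    exp_names = {rn[i] for i in network.expectancy_input}

    fwd_allowed = {(s, d) for (s, d) in lay.fwd_edges if network.fwd_mask[d, s]}
    bwd_allowed = {(s, d) for (s, d) in lay.bwd_edges if network.bwd_mask[d, s]}
    fwd_name = {f"{rn[s]}->{rn[d]}" for (s, d) in fwd_allowed}
    bwd_name = {f"{rn[s]}->{rn[d]}" for (s, d) in bwd_allowed}

    for i, (name, cls) in enumerate(zip(names, lay.classes)):
        if cls == "T":
            var[i] = prof["T"]
        elif cls == "G":
            var[i] = prof["G_sp"] if name.endswith(sp_label) else 0.0
        elif cls == "A":
            edge = name[name.index("[") + 1:-1]
            ok = edge in (fwd_name if name.startswith("A_fwd") else bwd_name)
            var[i] = prof["A"] if ok else 0.0
        elif cls == "B":
            if name.startswith("B_sp"):
                reg = name[name.index("[") + 1:-1]
                var[i] = prof["B"] if network.basis_kind == "EG" else 0.0
            else:
                edge = name[name.index("[") + 1:-1]
                ok = edge in (fwd_name if name.startswith("B_fwd") else bwd_name)
                var[i] = prof["B"] if ok else 0.0
        elif cls == "C":
            reg = name[name.index("[") + 1:-1]
            ok = reg in (aud_names if name.startswith("C_aud") else exp_names)
            var[i] = prof["C"] if ok else 0.0
        elif cls == "D":
            var[i] = prof["D"]
        elif cls == "S":
            var[i] = prof["S"]
        elif cls == "L":
            var[i] = prof["L"]

    return PriorDensity(np.zeros(lay.size), var, names)
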