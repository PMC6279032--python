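"""Deterministic synthetic C-alpha structures for offline testing and demos.

The generators emulate, in miniature, the shapes a globin-style dataset
exercises: single helices, compact helix bundles (a globular-fold
surrogate), rigid multimers of those bundles (the quaternary-structure
effect testbed), perturbed near-duplicates, and heme-bearing chains.
All randomness flows through explicit seeds so every fixture is
bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .structure_io import (NodeModel, StructureModel, apply_assembly,
                           extract_nodes)

# canonical alpha-helix geometry
HELIX_RISE = 1.5       # Å per residue along the axis
HELIX_TWIST = 100.0    # degrees per residue
HELIX_RADIUS = 2.3     # Å, CA distance from the helix axis


class FixtureError(Exception):
    """A generated fixture violates its own postconditions."""


def helix_coords(n_res: int, rise: float = HELIX_RISE, twist: float = HELIX_TWIST,
                 radius: float = HELIX_RADIUS) -> np.ndarray:
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    k = np.arange(n_res)
    theta = np.deg2rad(twist) * k
    return np.column_stack([radius * np.cos(theta),
                            radius * np.sin(theta),
                            rise * k])


def make_helix(n_res: int, rise: float = HELIX_RISE, twist: float = HELIX_TWIST,
               radius: float = HELIX_RADIUS, chain_id: str = "A") -> NodeModel:
    """Ideal alpha-helical C-alpha trace as a node model (poly-ALA)."""
    coords = helix_coords(n_res, rise, twist, radius)
    return NodeModel(
        coords=coords,
        chain_ids=np.full(n_res, chain_id, dtype="U12"),
        res_labels=np.array([str(i + 1) for i in range(n_res)], dtype="U12"),
        res_names=np.full(n_res, "ALA", dtype="U8"),
        kinds=np.full(n_res, "CA", dtype="U12"),
        scope=chain_id,
    )


def make_bundle(n_helices: int, helix_len: int, packing_radius: float = 5.0,
                chain_id: str = "A") -> StructureModel:
    """Anti-parallel helices on a circle, as one chain of CA atoms.

    The bundle must form a single connected elastic network at the default
    15 Å cutoff; generation fails otherwise.
    """
    if n_helices < 1:
        raise ValueError("n_helices must be >= 1")
    base = helix_coords(helix_len)
    base = base - base.mean(axis=0)
    coords = []
    for h in range(n_helices):
        c = base.copy()
        if h % 2 == 1:  # anti-parallel: flip about the x axis
            c[:, 1] *= -1
            c[:, 2] *= -1
            c = c[::-1]
        phi = 2 * np.pi * h / max(n_helices, 1)
        c[:, 0] += packing_radius * np.cos(phi)
        c[:, 1] += packing_radius * np.sin(phi)
        coords.append(c)
    coords = np.concatenate(coords)
    n = len(coords)
    st = StructureModel(
        chain_ids=np.full(n, chain_id, dtype="U12"),
        res_ids=np.arange(1, n + 1),
        icodes=np.full(n, "", dtype="U1"),
        res_names=np.full(n, "ALA", dtype="U8"),
        atom_names=np.full(n, "CA", dtype="U8"),
        elements=np.full(n, "C", dtype="U4"),
        coords=coords,
        source_id=f"bundle{n_helices}x{helix_len}",
    )
    from .anm import check_connectivity
    labels = check_connectivity(extract_nodes(st), cutoff=15.0)
    if labels.max() != 0:
        raise FixtureError("bundle packing too sparse: network disconnected at 15 A")
    return st


def make_multimer(unit: StructureModel, copies: int = 2,
                  spacing: float = 18.0) -> StructureModel:
    """Rigid copies of a unit translated along x, chain ids disambiguated."""
    if copies < 2:
        raise ValueError("copies must be >= 2")
    eye = np.eye(3)
    transforms = [(eye, np.array([spacing * k, 0.0, 0.0])) for k in range(copies)]
    return apply_assembly(unit, transforms)


def perturb(structure: StructureModel, sigma: float, seed: int) -> StructureModel:
    """Add independent Gaussian displacement (sigma per axis) to every atom."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return structure
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=structure.coords.shape)
    from dataclasses import replace
    return replace(structure, coords=structure.coords + noise)


def add_heme(structure: StructureModel, chain_id: str,
             half_diagonal: float = 3.4) -> StructureModel:
    """Append a HEM residue (CHA..CHD on a planar square) near the chain centroid."""
    idx = structure.chain_atoms(chain_id)
    if len(idx) == 0:
        raise ValueError(f"chain {chain_id!r} not found")
    center = structure.coords[idx].mean(axis=0)
    offsets = half_diagonal * np.array(
        [[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]], dtype=float)
    res_id = int(structure.res_ids.max()) + 1
    n_new = 4
    return StructureModel(
        chain_ids=np.concatenate([structure.chain_ids,
                                  np.full(n_new, chain_id, dtype="U12")]),
        res_ids=np.concatenate([structure.res_ids, np.full(n_new, res_id)]),
        icodes=np.concatenate([structure.icodes, np.full(n_new, "", dtype="U1")]),
        res_names=np.concatenate([structure.res_names,
                                  np.full(n_new, "HEM", dtype="U8")]),
        atom_names=np.concatenate([structure.atom_names,
                                   np.array(["CHA", "CHB", "CHC", "CHD"], dtype="U8")]),
        elements=np.concatenate([structure.elements, np.full(n_new, "C", dtype="U4")]),
        coords=np.concatenate([structure.coords, center + offsets]),
        source_id=structure.source_id,
        model_number=structure.model_number,
    )


def make_family_structures(seed: int, n_per_family: int = 6, sigma: float = 0.3,
                           n_helices: int = 3, helix_len: int = 12,
                           spacing: float = 18.0):
    """Two planted families for the clustering testbed.

    Family A: perturbed copies of a monomeric helix bundle.  Family B: the
    same bundle dimerised and then perturbed, compared through its first
    chain — the quaternary-structure effect in miniature (the subunit is
    identical, its dynamic environment is not).

    Returns a list of (label, StructureModel, scope-chain-id) tuples.
    """
    base = make_bundle(n_helices, helix_len)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_per_family):
        st = perturb(base, sigma, int(rng.integers(2**31)))
        out.append((f"mono{i + 1}", st, "A"))
    dimer = make_multimer(base, copies=2, spacing=spacing)
    for i in range(n_per_family):
        st = perturb(dimer, sigma, int(rng.integers(2**31)))
        out.append((f"dimer{i + 1}", st, "A"))
    return out
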