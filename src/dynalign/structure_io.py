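"""Structure reading, assembly expansion, and coarse-grained node extraction.

Everything downstream operates on an ordered list of coarse-grained nodes:
one node per amino-acid residue placed at its C-alpha atom and, optionally,
four pseudo-nodes per heme group placed on the methine-bridge carbons
CHA, CHB, CHC and CHD.  Node order is strictly deterministic — chains in
file order; within a chain, C-alpha nodes in residue (file) order followed
by that chain's heme pseudo-nodes in CHA..CHD atom order — so that mode
vectors computed on the same structure always index the same residues.

Elastic-network modes should be computed on the biological unit even when a
single chain is compared afterwards.  The module does not fetch or infer
assemblies; :func:`apply_assembly` expands user-supplied transforms (e.g.
parsed from REMARK 350 with :func:`parse_biomt`), which makes the whole
pipeline runnable offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Chemical-component ids recognised as heme groups (configurable per call).
HEME_RESNAMES = ("HEM", "HEC", "HEA", "HEB")

#: Methine-bridge atoms used as heme pseudo-nodes, in node order.
HEME_ATOMS = ("CHA", "CHB", "CHC", "CHD")

#: Node-kind labels, matching HEME_ATOMS order for pseudo-nodes.
NODE_KINDS = ("CA", "HEME_CHA", "HEME_CHB", "HEME_CHC", "HEME_CHD")

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}


class StructureError(Exception):
    """Base class for structure-handling failures."""


class FormatError(StructureError):
    """The file could not be parsed under the named standard."""


class EmptyStructureError(StructureError):
    """The selected model contains no atoms."""


class EmptySelectionError(StructureError):
    """A scope or node selection resolved to zero nodes."""


class ValidationError(StructureError):
    """An input violates a documented contract (e.g. non-orthonormal rotation)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """Flat atom table for one model of a structure file.

    Arrays are parallel, one entry per atom, in file order.  Residue order
    within a chain follows file order, never author numbering.
    """

    chain_ids: np.ndarray
    res_ids: np.ndarray
    icodes: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    source_id: str = ""
    model_number: int = 1

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must be an (n_atoms, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")
        n = len(self.coords)
        for name in ("chain_ids", "res_ids", "icodes", "res_names",
                     "atom_names", "elements"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValidationError(f"{name} length {len(arr)} != n_atoms {n}")
            setattr(self, name, arr)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def chains(self) -> list[str]:
        """Chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for cid in self.chain_ids:
            seen.setdefault(str(cid), None)
        return list(seen)

    def chain_atoms(self, chain_id: str) -> np.ndarray:
        return np.flatnonzero(self.chain_ids == chain_id)

    def residues(self, chain_id: str) -> list[tuple[str, str, np.ndarray]]:
        """(residue label, residue name, atom indices) per residue in file order."""
        idx = self.chain_atoms(chain_id)
        out: list[tuple[str, str, np.ndarray]] = []
        groups: dict[tuple, list[int]] = {}
        order: list[tuple] = []
        for i in idx:
            key = (int(self.res_ids[i]), str(self.icodes[i]), str(self.res_names[i]))
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(int(i))
        for key in order:
            rid, icode, rname = key
            label = f"{rid}{icode}".strip()
            out.append((label, rname, np.array(groups[key], dtype=int)))
        return out


@dataclass
class NodeModel:
    """Ordered coarse-grained node list the ANM operates on."""

    coords: np.ndarray
    chain_ids: np.ndarray
    res_labels: np.ndarray
    res_names: np.ndarray
    kinds: np.ndarray
    scope: str = "all"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.chain_ids = np.asarray(self.chain_ids)
        self.res_labels = np.asarray(self.res_labels)
        self.res_names = np.asarray(self.res_names)
        self.kinds = np.asarray(self.kinds)
        triples = list(zip(self.chain_ids, self.res_labels, self.kinds))
        if len(set(triples)) != len(triples):
            raise ValidationError("duplicate (chain, residue, kind) node")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def ca_mask(self) -> np.ndarray:
        return self.kinds == "CA"

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for cid in self.chain_ids:
            seen.setdefault(str(cid), None)
        return list(seen)

    def chain_mask(self, chains) -> np.ndarray:
        chains = [chains] if isinstance(chains, str) else list(chains)
        return np.isin(self.chain_ids, chains)

    def subset(self, mask: np.ndarray, scope: str | None = None) -> "NodeModel":
        mask = np.asarray(mask)
        return NodeModel(
            coords=self.coords[mask],
            chain_ids=self.chain_ids[mask],
            res_labels=self.res_labels[mask],
            res_names=self.res_names[mask],
            kinds=self.kinds[mask],
            scope=scope if scope is not None else self.scope,
        )

    def sequence(self) -> str:
        """One-letter sequence over the C-alpha nodes (X for non-standard)."""
        return "".join(AA_3TO1.get(str(r), "X")
                       for r in self.res_names[self.ca_mask])

    def with_coords(self, coords: np.ndarray) -> "NodeModel":
        return replace(self, coords=np.asarray(coords, dtype=float))


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _from_atom_array(arr, source_id: str, model_number: int) -> StructureModel:
    if arr.array_length() == 0:
        raise EmptyStructureError(f"{source_id}: selected model contains no atoms")
    icodes = (arr.ins_code if "ins_code" in arr.get_annotation_categories()
              else np.full(arr.array_length(), "", dtype="U1"))
    return StructureModel(
        chain_ids=arr.chain_id.astype("U8"),
        res_ids=arr.res_id.astype(int),
        icodes=np.char.strip(icodes.astype("U4")),
        res_names=arr.res_name.astype("U8"),
        atom_names=arr.atom_name.astype("U8"),
        elements=arr.element.astype("U4"),
        coords=np.array(arr.coord, dtype=float),
        source_id=source_id,
        model_number=model_number,
    )


def read_structure(path, fmt: str = "auto", model: int = 1) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Multi-model files resolve to ``model`` (default 1).  Alternate locations
    are resolved to the highest-occupancy conformation (ties: first).
    """
    path = str(path)
    if fmt == "auto":
        low = path.lower()
        if low.endswith((".cif", ".mmcif", ".cif.gz")):
            fmt = "mmcif"
        elif low.endswith((".pdb", ".ent", ".pdb.gz")):
            fmt = "pdb"
        else:  # sniff: mmCIF files start with data_
            with open(path) as fh:
                head = fh.read(2048)
            fmt = "mmcif" if ("data_" in head or "_atom_site" in head) else "pdb"
    if fmt not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {fmt!r}")
    try:
        if fmt == "pdb":
            from biotite.structure.io.pdb import PDBFile
            pf = PDBFile.read(path)
            try:
                arr = pf.get_structure(model=model, altloc="occupancy")
            except (KeyError, TypeError):
                arr = pf.get_structure(model=model, altloc="first")
        else:
            from biotite.structure.io.pdbx import CIFFile, get_structure
            cf = CIFFile.read(path)
            try:
                arr = get_structure(cf, model=model, altloc="occupancy")
            except KeyError:
                arr = get_structure(cf, model=model, altloc="first")
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    return _from_atom_array(arr, source_id=path, model_number=model)


_CHAIN_ALPHABET = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                   "abcdefghijklmnopqrstuvwxyz0123456789")


def write_pdb(structure: StructureModel, path) -> None:
    """Write a minimal PDB file (fixtures and exports; 1e-3 Å precision).

    PDB chain ids hold one character; longer ids (e.g. assembly-copy
    suffixes) are remapped to single letters in order of first appearance.
    """
    import biotite.structure as bst
    from biotite.structure.io.pdb import PDBFile

    chains = structure.chains()
    if all(len(c) == 1 for c in chains):
        mapping = {c: c for c in chains}
    else:
        if len(chains) > len(_CHAIN_ALPHABET):
            raise ValidationError("too many chains for PDB output")
        mapping = {c: _CHAIN_ALPHABET[i] for i, c in enumerate(chains)}
    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.chain_id = np.array([mapping[str(c)] for c in structure.chain_ids],
                            dtype="U4")
    arr.res_id = structure.res_ids.astype(int)
    arr.ins_code = np.array([str(i)[:1] for i in structure.icodes], dtype="U1")
    arr.res_name = structure.res_names.astype("U5")
    arr.atom_name = structure.atom_names.astype("U6")
    arr.element = structure.elements.astype("U2")
    arr.coord = structure.coords.astype(np.float32)
    arr.hetero = np.array([str(r) in HEME_RESNAMES or str(r) == "HOH"
                           for r in structure.res_names])
    pf = PDBFile()
    pf.set_structure(arr)
    pf.write(str(path))


# ---------------------------------------------------------------------------
# assemblies
# ---------------------------------------------------------------------------

def _check_rotation(rot: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    rot = np.asarray(rot, dtype=float)
    if rot.shape != (3, 3):
        raise ValidationError("rotation must be 3x3")
    if not np.allclose(rot.T @ rot, np.eye(3), atol=tol):
        raise ValidationError("rotation is not orthonormal within 1e-6")
    return rot


def apply_assembly(structure: StructureModel, transforms) -> StructureModel:
    """Expand a structure by a list of (rotation, translation) transforms.

    One copy of the input per transform; chain ids of copies >= 2 get a
    deterministic ``-<copy index>`` suffix.  An identity first transform
    preserves coordinates bit-exactly.
    """
    if len(transforms) == 0:
        raise ValidationError("transforms list is empty")
    parts = []
    used: set[str] = set()
    for k, (rot, trans) in enumerate(transforms, start=1):
        rot = _check_rotation(rot)
        trans = np.asarray(trans, dtype=float).reshape(3)
        identity = np.array_equal(rot, np.eye(3)) and np.array_equal(trans, np.zeros(3))
        coords = structure.coords if identity else structure.coords @ rot.T + trans
        renames: dict[str, str] = {}
        for c in structure.chains():
            name = c if k == 1 else f"{c}-{k}"
            while name in used:  # pre-suffixed inputs can collide
                name = f"{name}-{k}"
            used.add(name)
            renames[c] = name
        chains = (structure.chain_ids if k == 1 else
                  np.array([renames[str(c)] for c in structure.chain_ids],
                           dtype="U16"))
        parts.append((chains, coords))
    return StructureModel(
        chain_ids=np.concatenate([p[0] for p in parts]),
        res_ids=np.tile(structure.res_ids, len(parts)),
        icodes=np.tile(structure.icodes, len(parts)),
        res_names=np.tile(structure.res_names, len(parts)),
        atom_names=np.tile(structure.atom_names, len(parts)),
        elements=np.tile(structure.elements, len(parts)),
        coords=np.concatenate([p[1] for p in parts]),
        source_id=structure.source_id,
        model_number=structure.model_number,
    )


def parse_biomt(path) -> list[tuple[np.ndarray, np.ndarray]]:
    """Parse REMARK 350 BIOMT transforms from a PDB file (helper).

    Returns a list of (rotation, translation) for the first assembly block.
    """
    rows: dict[int, list[list[float]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("REMARK 350") or "BIOMT" not in line:
                continue
            fields = line.split()
            # REMARK 350 BIOMT<r> <serial> r1 r2 r3 t
            tag = fields[2]
            serial = int(fields[3])
            vals = [float(v) for v in fields[4:8]]
            rows.setdefault(serial, [None, None, None])[int(tag[-1]) - 1] = vals
    transforms = []
    for serial in sorted(rows):
        mat = rows[serial]
        if any(r is None for r in mat):
            raise FormatError(f"incomplete BIOMT record {serial} in {path}")
        m = np.array(mat, dtype=float)
        transforms.append((_check_rotation(m[:, :3], tol=1e-4), m[:, 3].copy()))
    return transforms


# ---------------------------------------------------------------------------
# node extraction
# ---------------------------------------------------------------------------

def extract_nodes(structure: StructureModel, scope=None, include_heme: bool = True,
                  heme_resnames=HEME_RESNAMES) -> NodeModel:
    """Extract the ordered coarse-grained node model.

    One node per residue possessing a C-alpha atom; if ``include_heme``,
    four pseudo-nodes per heme residue having all four methine carbons.
    ``scope`` is None (all chains) or a chain id / list of chain ids.
    """
    chains = structure.chains()
    if scope is not None:
        wanted = [scope] if isinstance(scope, str) else list(scope)
        missing = [c for c in wanted if c not in chains]
        if missing:
            raise EmptySelectionError(f"chains not in structure: {missing}")
        chains = [c for c in chains if c in wanted]
    coords, cids, labels, rnames, kinds = [], [], [], [], []
    for cid in chains:
        heme_buffer = []
        for label, rname, atom_idx in structure.residues(cid):
            names = structure.atom_names[atom_idx]
            if rname in heme_resnames:
                if not include_heme:
                    continue
                pos = {}
                for n, i in zip(names, atom_idx):
                    if n in HEME_ATOMS and n not in pos:
                        pos[n] = structure.coords[i]
                if len(pos) < 4:
                    logger.warning("heme %s/%s missing CH atoms; skipped", cid, label)
                    continue
                for atom in HEME_ATOMS:
                    heme_buffer.append((pos[atom], cid, label, rname, f"HEME_{atom}"))
                continue
            ca = None
            for n, i in zip(names, atom_idx):
                if n == "CA" and structure.elements[i] in ("C", ""):
                    ca = structure.coords[i]
                    break
            if ca is None:
                if rname not in ("HOH", "DOD"):
                    logger.warning("residue %s/%s %s lacks CA; skipped",
                                   cid, label, rname)
                continue
            coords.append(ca)
            cids.append(cid)
            labels.append(label)
            rnames.append(rname)
            kinds.append("CA")
        for pos, c, label, rname, kind in heme_buffer:
            coords.append(pos)
            cids.append(c)
            labels.append(label)
            rnames.append(rname)
            kinds.append(kind)
    if not coords:
        raise EmptySelectionError("selection resolved to zero nodes")
    scope_desc = "all" if scope is None else ",".join(
        [scope] if isinstance(scope, str) else list(scope))
    return NodeModel(coords=np.array(coords), chain_ids=np.array(cids, dtype="U12"),
                     res_labels=np.array(labels, dtype="U12"),
                     res_names=np.array(rnames, dtype="U8"),
                     kinds=np.array(kinds, dtype="U12"), scope=scope_desc)


def nodes_to_structure(nodes: NodeModel, source_id: str = "nodes") -> StructureModel:
    """Represent a node model as a CA/heme-atom structure (for PDB export)."""
    atom_names, res_names, res_ids = [], [], []
    counter: dict[str, int] = {}
    last_res: dict[str, tuple] = {}
    for cid, label, rname, kind in zip(nodes.chain_ids, nodes.res_labels,
                                       nodes.res_names, nodes.kinds):
        key = (str(cid), str(label))
        if last_res.get(str(cid)) != key:
            counter[str(cid)] = counter.get(str(cid), 0) + 1
            last_res[str(cid)] = key
        res_ids.append(counter[str(cid)])
        res_names.append(rname)
        atom_names.append("CA" if kind == "CA" else str(kind)[5:])
    return StructureModel(
        chain_ids=nodes.chain_ids.copy(),
        res_ids=np.array(res_ids, dtype=int),
        icodes=np.full(len(nodes), "", dtype="U1"),
        res_names=np.array(res_names),
        atom_names=np.array(atom_names),
        elements=np.full(len(nodes), "C", dtype="U2"),
        coords=nodes.coords.copy(),
        source_id=source_id,
    )


def node_table(nodes: NodeModel):
    """Node model as a DataFrame (chain, residue, kind, x, y, z)."""
    import pandas as pd
    return pd.DataFrame({
        "chain": nodes.chain_ids,
        "residue": nodes.res_labels,
        "kind": nodes.kinds,
        "x": nodes.coords[:, 0],
        "y": nodes.coords[:, 1],
        "z": nodes.coords[:, 2],
    })


def write_node_table(nodes: NodeModel, path) -> None:
    node_table(nodes).to_csv(path, sep="\t", index=False, float_format="%.3f")
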