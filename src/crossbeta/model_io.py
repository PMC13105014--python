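"""Read, write, and organize atomic fibril models.

A :class:`FibrilModel` holds the atoms of a fibril segment (possibly a bundle
of refined models), organized into *subunits* (protofilaments -- stacks of
equivalent chains) and *layers* (axial position of a chain within its
subunit), together with an estimated growth axis.  Nothing is assumed about
the orientation of deposited coordinates: the growth axis is always fitted
from the screw transforms between equivalent chains.

File handling is delegated to gemmi (PDB and mmCIF).  Coordinates are in
angstroms throughout; nanometres appear only in reported cross-over and
strain quantities.  Author residue numbering (1-40 for Abeta40) is canonical
and never remapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .errors import EmptyInputError, InsufficientDataError, ParseError
from .geometry import RigidTransform, signed_rotation_about, superpose
from .helix import HelicalParams

__all__ = [
    "FibrilModel",
    "read_model",
    "write_model",
    "infer_layers_and_subunits",
    "fit_helical_params",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")

#: Abeta40 sequence, author numbering 1-40.
ABETA40_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV"


def _is_hydrogen(element: str, name: str) -> bool:
    el = element.strip()
    if el:
        return el.upper() in ("H", "D")
    return name.strip().upper().startswith(("H", "D")) and not name.strip().upper().startswith("HG")


@dataclass
class FibrilModel:
    """Atomic model of a fibril segment, organized into subunits and layers.

    ``atoms`` columns: ``model`` (1-based bundle member), ``chain``,
    ``resseq`` (author numbering), ``resname``, ``atom``, ``element``,
    ``x``/``y``/``z`` (angstroms).  ``subunit_assignment`` and
    ``layer_assignment`` map chain ids to a subunit label ("A"/"B") and an
    integer layer index increasing along the growth axis.
    """

    atoms: pd.DataFrame
    subunit_assignment: dict[str, str] = field(default_factory=dict)
    layer_assignment: dict[str, int] = field(default_factory=dict)
    growth_axis: np.ndarray | None = None  # unit vector
    axis_point: np.ndarray | None = None
    name: str = ""

    # -- basic accessors ---------------------------------------------------

    @property
    def bundle_size(self) -> int:
        return int(self.atoms["model"].nunique())

    @property
    def models(self) -> list[int]:
        return sorted(self.atoms["model"].unique().tolist())

    @property
    def chains(self) -> list[str]:
        first = self.atoms[self.atoms["model"] == self.models[0]]
        return list(dict.fromkeys(first["chain"].tolist()))

    @property
    def subunits(self) -> list[str]:
        return sorted(set(self.subunit_assignment.values()))

    def subunit_chains(self, label: str) -> list[str]:
        """Chains of one subunit, ordered by layer index."""
        chains = [c for c in self.chains if self.subunit_assignment.get(c) == label]
        return sorted(chains, key=lambda c: self.layer_assignment.get(c, 0))

    def chain_atoms(self, chain: str, model: int | None = None,
                    heavy_only: bool = True) -> pd.DataFrame:
        df = self.atoms
        if model is None:
            model = self.models[0]
        df = df[(df["model"] == model) & (df["chain"] == chain)]
        if heavy_only:
            mask = [not _is_hydrogen(e, a) for e, a in zip(df["element"], df["atom"])]
            df = df[np.asarray(mask, dtype=bool)]
        return df

    def coords(self, df: pd.DataFrame | None = None) -> np.ndarray:
        if df is None:
            df = self.atoms
        return df[["x", "y", "z"]].to_numpy(dtype=float)

    def matched_coords(self, chain_a: str, chain_b: str, model_a: int | None = None,
                       model_b: int | None = None,
                       resseq_range: tuple[int, int] | None = None,
                       atom_names: tuple[str, ...] | None = None,
                       ) -> tuple[np.ndarray, np.ndarray, list[tuple[int, str]]]:
        """Coordinates of atoms shared (by residue number + atom name) by two chains."""
        da = self.chain_atoms(chain_a, model_a)
        db = self.chain_atoms(chain_b, model_b)
        if resseq_range is not None:
            lo, hi = resseq_range
            da = da[(da["resseq"] >= lo) & (da["resseq"] <= hi)]
            db = db[(db["resseq"] >= lo) & (db["resseq"] <= hi)]
        if atom_names is not None:
            da = da[da["atom"].isin(atom_names)]
            db = db[db["atom"].isin(atom_names)]
        ia = {(int(r), a): k for k, (r, a) in enumerate(zip(da["resseq"], da["atom"]))}
        ib = {(int(r), a): k for k, (r, a) in enumerate(zip(db["resseq"], db["atom"]))}
        keys = [k for k in ia if k in ib]
        keys.sort()
        ca = self.coords(da)[[ia[k] for k in keys]]
        cb = self.coords(db)[[ib[k] for k in keys]]
        return ca, cb, keys

    def axial_coord(self, xyz: np.ndarray) -> np.ndarray:
        """Coordinate along the growth axis (angstroms)."""
        if self.growth_axis is None:
            raise InsufficientDataError("growth axis not set; run infer_layers_and_subunits")
        origin = self.axis_point if self.axis_point is not None else np.zeros(3)
        return (np.atleast_2d(xyz) - origin) @ self.growth_axis

    def chain_centroid(self, chain: str, model: int | None = None) -> np.ndarray:
        return self.coords(self.chain_atoms(chain, model)).mean(axis=0)

    def copy(self) -> "FibrilModel":
        return FibrilModel(
            atoms=self.atoms.copy(),
            subunit_assignment=dict(self.subunit_assignment),
            layer_assignment=dict(self.layer_assignment),
            growth_axis=None if self.growth_axis is None else self.growth_axis.copy(),
            axis_point=None if self.axis_point is None else self.axis_point.copy(),
            name=self.name,
        )


# ---------------------------------------------------------------------------
# File I/O


def read_model(path: str | Path, format: str | None = None,
               drop_hydrogens: bool = False) -> FibrilModel:
    """Read a PDB or mmCIF file into a :class:`FibrilModel`.

    All members of a multi-model bundle are retained.  ``format`` overrides
    extension-based detection ("pdb" or "mmcif"/"cif").
    """
    path = Path(path)
    try:
        if format is None:
            st = gemmi.read_structure(str(path))
        elif format.lower() == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format.lower() in ("cif", "mmcif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        else:
            raise ParseError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    rows = []
    for imodel, model in enumerate(st, start=1):
        for chain in model:
            for res in chain:
                for atom in res:
                    el = atom.element.name
                    if drop_hydrogens and _is_hydrogen(el, atom.name):
                        continue
                    rows.append((imodel, chain.name, res.seqid.num, res.name,
                                 atom.name, el, atom.pos.x, atom.pos.y, atom.pos.z))
    if not rows:
        raise EmptyInputError(f"{path} contains no atom records")
    atoms = pd.DataFrame(rows, columns=["model", "chain", "resseq", "resname",
                                        "atom", "element", "x", "y", "z"])
    return FibrilModel(atoms=atoms, name=path.stem)


def _to_gemmi(m: FibrilModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = m.name or "fibril"
    for imodel in m.models:
        gm = gemmi.Model(str(imodel))
        dfm = m.atoms[m.atoms["model"] == imodel]
        for chain_id in dict.fromkeys(dfm["chain"]):
            gc = gemmi.Chain(str(chain_id))
            dfc = dfm[dfm["chain"] == chain_id]
            for resseq in dict.fromkeys(dfc["resseq"]):
                dfr = dfc[dfc["resseq"] == resseq]
                res = gemmi.Residue()
                res.seqid = gemmi.SeqId(int(resseq), " ")
                res.name = str(dfr["resname"].iloc[0])
                for _, row in dfr.iterrows():
                    at = gemmi.Atom()
                    at.name = str(row["atom"])
                    at.element = gemmi.Element(str(row["element"]) or "X")
                    at.pos = gemmi.Position(float(row["x"]), float(row["y"]), float(row["z"]))
                    at.occ = 1.0
                    res.add_atom(at)
                gc.add_residue(res)
            gm.add_chain(gc)
        st.add_model(gm)
    st.setup_entities()
    return st


def write_model(m: FibrilModel, path: str | Path, format: str | None = None) -> None:
    """Write a model as PDB (default) or mmCIF, chosen by extension or ``format``."""
    path = Path(path)
    st = _to_gemmi(m)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("cif", "mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Geometry inference


def _pairwise_transforms(m: FibrilModel) -> dict[tuple[str, str], tuple[RigidTransform, float]]:
    """Best rigid transform and RMSD for every ordered chain pair (first model)."""
    out: dict[tuple[str, str], tuple[RigidTransform, float]] = {}
    chains = m.chains
    for i, a in enumerate(chains):
        for b in chains[i + 1:]:
            ca, cb, keys = m.matched_coords(a, b)
            if len(keys) < 3:
                continue
            t_ab, rmsd = superpose(ca, cb)
            out[(a, b)] = (t_ab, rmsd)
    return out


def infer_layers_and_subunits(m: FibrilModel, rmsd_tol: float = 1.0,
                              min_angle_deg: float = 0.2) -> FibrilModel:
    """Estimate the growth axis and assign chains to subunits and layers.

    The axis is extracted from the rotation axes of the best rigid
    superpositions between equivalent chains (pairs that superpose within
    ``rmsd_tol``): screw mates (rotations near 180 deg), same-subunit
    neighbours (small rotations), and C2 mates all rotate about the growth
    axis, so their axes are averaged.  Chains are then grouped into subunits
    (connected components of pairs related by a small rotation, i.e. pure
    stacking rather than a ~180 deg flip) and into layers by axial centroid
    order within each subunit.

    A single-chain model cannot be decomposed; it gets a trivial assignment
    and a warning.
    """
    m = m.copy()
    chains = m.chains
    if len(chains) < 2:
        warnings.warn("single-chain model: using trivial subunit/layer assignment")
        m.subunit_assignment = {c: "A" for c in chains}
        m.layer_assignment = {c: 0 for c in chains}
        m.growth_axis = np.array([0.0, 0.0, 1.0])
        m.axis_point = np.zeros(3)
        return m

    pairs = _pairwise_transforms(m)
    if not pairs:
        raise InsufficientDataError("no chain pair shares enough atoms to superpose")

    # Axis from well-superposing pairs with a well-defined rotation axis.
    best_rmsd = min(r for _, r in pairs.values())
    tol = max(rmsd_tol, 2.0 * best_rmsd + 1e-6)
    axes = []
    falls = []
    for (a, b), (t, rmsd) in pairs.items():
        if rmsd > tol:
            continue
        from .geometry import screw_decompose

        axis, angle, h, _ = screw_decompose(t)
        if abs(angle) >= min_angle_deg:
            axes.append(axis if (not axes or axis @ axes[0] >= 0) else -axis)
        else:
            tr = np.asarray(t.translation)
            if np.linalg.norm(tr) > 1e-6:
                falls.append(tr / np.linalg.norm(tr))
    if axes:
        u = np.mean(axes, axis=0)
    elif falls:
        falls = [f if (f @ falls[0] >= 0) else -f for f in falls]
        u = np.mean(falls, axis=0)
    else:
        raise InsufficientDataError("cannot infer growth axis: all chains coincide")
    u = u / np.linalg.norm(u)
    # Deterministic orientation: largest-magnitude component positive.
    k = int(np.argmax(np.abs(u)))
    if u[k] < 0:
        u = -u

    # Subunit grouping: edge when chains superpose well via a small rotation.
    parent = {c: c for c in chains}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for (a, b), (t, rmsd) in pairs.items():
        if rmsd > tol:
            continue
        angle, _ = signed_rotation_about(t, u)
        # Same-subunit neighbours are related by a small rotation (per-layer
        # twist); screw/C2 mates by a ~180 deg flip.
        if abs(angle) < 90.0:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

    groups: dict[str, list[str]] = {}
    for c in chains:
        groups.setdefault(find(c), []).append(c)
    # Label subunits deterministically by mean axial coordinate then chain id.
    m.growth_axis = u
    m.axis_point = np.zeros(3)
    order = sorted(groups.values(), key=lambda g: sorted(g)[0])
    labels = [chr(ord("A") + i) for i in range(len(order))]
    sub_assign: dict[str, str] = {}
    layer_assign: dict[str, int] = {}
    for label, group in zip(labels, order):
        zs = {c: float(m.axial_coord(m.chain_centroid(c))[0]) for c in group}
        for layer, c in enumerate(sorted(group, key=lambda c: zs[c])):
            sub_assign[c] = label
            layer_assign[c] = layer
    m.subunit_assignment = sub_assign
    m.layer_assignment = layer_assign
    return m


def _refine_axis(m: FibrilModel) -> np.ndarray:
    """Average screw axis over successive-layer transforms within subunits."""
    from .geometry import screw_decompose

    axes = []
    for label in m.subunits:
        chains = m.subunit_chains(label)
        for a, b in zip(chains, chains[1:]):
            ca, cb, keys = m.matched_coords(a, b)
            if len(keys) < 3:
                continue
            t, _ = superpose(ca, cb)
            axis, angle, h, _ = screw_decompose(t)
            if abs(angle) > 1e-6:
                axes.append(axis if (not axes or axis @ axes[0] >= 0) else -axis)
    if not axes:
        return m.growth_axis
    u = np.mean(axes, axis=0)
    u = u / np.linalg.norm(u)
    if u @ m.growth_axis < 0:
        u = -u
    return u


def fit_helical_params(m: FibrilModel, c1_rmsd_threshold: float = 1.5) -> HelicalParams:
    """Recover twist, rise, and symmetry class from coordinates.

    The screw transform between successive layers of each subunit gives the
    per-layer rotation and rise (averaged over layer pairs and bundle
    members).  The transform between the two subunits classifies the
    symmetry: subunits that fail to superpose within ``c1_rmsd_threshold``
    (Cα/heavy RMSD) are conformationally inequivalent (C1); otherwise a
    ~180 deg rotation with no axial offset is C2 and one with a half-rise
    offset is pseudo-2_1.

    Reported twist/rise follow the deposition conventions: per screw repeat
    for pseudo-2_1 (twist near +-180, rise = half the layer spacing), per
    layer for C2, per two-layer repeat for a two-subunit C1 fibril.  The sign
    of the twist is geometric (right-hand rule about the axis oriented so
    rise is positive); handedness stays "undetermined" since the deposition
    metadata convention cannot be inferred from a sign.
    """
    if not m.subunit_assignment or m.growth_axis is None:
        m = infer_layers_and_subunits(m)
    u = _refine_axis(m)

    angles, rises = [], []
    for label in m.subunits:
        chains = m.subunit_chains(label)
        if len(chains) < 2:
            continue
        for model in m.models:
            for a, b in zip(chains, chains[1:]):
                ca, cb, keys = m.matched_coords(a, b, model_a=model, model_b=model)
                if len(keys) < 3:
                    continue
                t, _ = superpose(ca, cb)
                angle, h = signed_rotation_about(t, u)
                angles.append(angle)
                rises.append(h)
    if not angles:
        raise InsufficientDataError("need at least 2 layers in one subunit to fit helix")
    theta = float(np.mean(angles))
    h = float(np.mean(rises))
    if h < 0:  # orient so rise is positive; flips the angle sign too
        theta, h = -theta, -h

    subs = m.subunits
    if len(subs) < 2:
        return HelicalParams(twist=theta, rise=h, symmetry="C1",
                             molecules_per_repeat=1, name=m.name)

    a0 = m.subunit_chains(subs[0])[0]
    b0 = m.subunit_chains(subs[1])[0]
    ca, cb, keys = m.matched_coords(a0, b0)
    if len(keys) < 3:
        inter_rmsd = np.inf
        offset = 0.0
    else:
        t_ab, inter_rmsd = superpose(ca, cb)
        _, offset = signed_rotation_about(t_ab, u)
    if inter_rmsd > c1_rmsd_threshold:
        # Two inequivalent subunits: repeat is two layers, two molecules.
        return HelicalParams(twist=2.0 * theta, rise=2.0 * h, symmetry="C1",
                             molecules_per_repeat=2, name=m.name)
    if abs(offset) < 0.25 * h:
        return HelicalParams(twist=theta, rise=h, symmetry="C2",
                             molecules_per_repeat=2, name=m.name)
    # Screw mate at half-rise: single-start helix, twist near +-180.
    f = theta / 2.0
    twist = f - 180.0 if f <= 0 else f + 180.0
    return HelicalParams(twist=twist, rise=h / 2.0, symmetry="pseudo-2_1",
                         molecules_per_repeat=1, name=m.name)
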