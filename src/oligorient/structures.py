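"""Ensemble containers, multi-model PDB I/O and ideal oligomer fixtures.

Conventions fixed package-wide:

* The laboratory frame has the static magnetic field B0 along +z, which is
  also taken as the membrane normal.
* Chains map to protomers in order of first appearance in the file; MODEL
  records map to replicas in file order.
* Backbone atoms handled per residue: N, H (amide proton), CA, C, O.
  The amide proton may be absent only for prolines and chain-initial
  residues; such residues carry no orientational observables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial import cKDTree

from .errors import ConfigError, DataError, GeometryError, ParseError, StructureError

# ---------------------------------------------------------------------------
# constants

ATOM_ORDER = ("N", "H", "CA", "C", "O")

#: Human phospholamban, 52 residues (pinwheel pentamer; no glycine, P21).
PLN_SEQUENCE = "MEKVQYLTRSAIRRASTIEMPQQARQKLQNLFINFCLILICLLLICIIVMLL"

_AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

# ideal backbone internal coordinates (lengths in Angstrom, angles in degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.02
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.0, 116.6, 121.9
_A_CA_C_O, _A_C_N_H = 120.5, 119.0
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0  # ideal alpha helix

_CLASH_CUTOFF = 1.0  # Angstrom, inter-protomer


# ---------------------------------------------------------------------------
# small linear algebra helpers

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-10:
        raise GeometryError("zero-length vector")
    return v / n


def rot_z(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_y(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector u onto unit vector v."""
    u, v = _unit(u), _unit(v)
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # pick any axis perpendicular to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        return _axis_angle(_unit(axis), 180.0)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    return _axis_angle(axis / s, np.degrees(np.arctan2(s, c)))


def _axis_angle(axis: np.ndarray, deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """Largest-variance direction of a point cloud (unit vector, sign free)."""
    x = points - points.mean(axis=0)
    _, vecs = np.linalg.eigh(x.T @ x)
    return vecs[:, -1]


# ---------------------------------------------------------------------------
# domain types

@dataclass
class BackboneResidue:
    """One residue's backbone; coordinates in the lab frame (Angstrom)."""

    index: int
    name: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    hn: Optional[np.ndarray] = None

    @property
    def has_amide_h(self) -> bool:
        return self.hn is not None


@dataclass
class Protomer:
    chain_id: str
    residues: list[BackboneResidue]

    def __post_init__(self):
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StructureError(
                f"chain {self.chain_id}: residue indices not strictly increasing"
            )

    @property
    def indices(self) -> list[int]:
        return [r.index for r in self.residues]

    def residue(self, index: int) -> BackboneResidue:
        for r in self.residues:
            if r.index == index:
                return r
        raise DataError(f"residue {index} not in chain {self.chain_id}")


@dataclass
class OrientedOligomer:
    """One P-protomer assembly in the lab frame (B0 = +z)."""

    protomers: list[Protomer]

    def __post_init__(self):
        if len(self.protomers) < 1:
            raise StructureError("oligomer needs at least one protomer")
        sig0 = [(r.index, r.name) for r in self.protomers[0].residues]
        for p in self.protomers[1:]:
            if [(r.index, r.name) for r in p.residues] != sig0:
                raise StructureError(
                    "homo-oligomer invariant violated: protomer sequences/"
                    "numbering differ between chains"
                )

    @property
    def n_protomers(self) -> int:
        return len(self.protomers)

    @property
    def residue_indices(self) -> list[int]:
        return self.protomers[0].indices


@dataclass
class ReplicaEnsemble:
    """M replicas of the same oligomer evolving in parallel."""

    replicas: list[OrientedOligomer]

    def __post_init__(self):
        if len(self.replicas) < 1:
            raise StructureError("ensemble needs at least one replica")
        p0 = self.replicas[0].n_protomers
        sig0 = [(r.index, r.name) for r in self.replicas[0].protomers[0].residues]
        for rep in self.replicas[1:]:
            if rep.n_protomers != p0:
                raise StructureError("replicas differ in protomer count")
            sig = [(r.index, r.name) for r in rep.protomers[0].residues]
            if sig != sig0:
                raise StructureError("replicas differ in sequence/numbering")

    @property
    def M(self) -> int:
        return len(self.replicas)

    @property
    def P(self) -> int:
        return self.replicas[0].n_protomers


@dataclass(frozen=True)
class PentamerBlueprint:
    """Recipe for an ideal pinwheel oligomer fixture.

    ``tm_range``/``cyto_range`` are inclusive residue-number ranges; when a
    cytoplasmic range is present it must immediately precede the TM range.
    ``tau_deg`` tilts each TM helix from +z, ``theta_deg`` orients the
    cytoplasmic helix relative to +z (values near 90-110 deg lie the helix on
    the membrane surface), ``bundle_radius`` sets the TM helix axis distance
    from the bundle axis, and each protomer sits at 360/P deg azimuthal
    spacing plus its entry in ``azimuth_offsets``.
    """

    n_protomers: int = 5
    sequence: str = PLN_SEQUENCE
    first_index: int = 1
    tm_range: tuple[int, int] = (31, 52)
    cyto_range: Optional[tuple[int, int]] = (1, 30)
    tau_deg: float = 12.8
    theta_deg: float = 98.8
    bundle_radius: float = 8.0
    azimuth_offsets: Optional[tuple[float, ...]] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_protomers < 1:
            raise ConfigError("n_protomers must be >= 1")
        if not (0.0 <= self.tau_deg <= 90.0):
            raise ConfigError("tau_deg must lie in [0, 90]")
        if self.bundle_radius <= 0:
            raise ConfigError("bundle_radius must be positive")
        last = self.first_index + len(self.sequence) - 1
        lo, hi = self.tm_range
        if lo > hi or lo < self.first_index or hi > last:
            raise ConfigError("tm_range outside the sequence")
        if self.cyto_range is not None:
            clo, chi = self.cyto_range
            if clo > chi or clo < self.first_index or chi > last:
                raise ConfigError("cyto_range outside the sequence")
            if not (chi < lo or clo > hi):
                raise ConfigError("tm_range and cyto_range overlap")
            if chi + 1 != lo:
                raise ConfigError(
                    "cyto_range must immediately precede tm_range"
                )
        if self.azimuth_offsets is not None and len(self.azimuth_offsets) != self.n_protomers:
            raise ConfigError("azimuth_offsets length must equal n_protomers")

    @property
    def residue_numbers(self) -> list[int]:
        return list(range(self.first_index, self.first_index + len(self.sequence)))

    @property
    def residue_names(self) -> list[str]:
        return [_AA1TO3[c] for c in self.sequence.upper()]

    @staticmethod
    def tm_only(n_protomers: int = 5, tau_deg: float = 12.8,
                bundle_radius: float = 8.0, seed: int = 0) -> "PentamerBlueprint":
        """Domain-II-only pentamer (residues 31-52), the desk-scale fixture."""
        return PentamerBlueprint(
            n_protomers=n_protomers, sequence=PLN_SEQUENCE[30:52],
            first_index=31, tm_range=(31, 52), cyto_range=None,
            tau_deg=tau_deg, bundle_radius=bundle_radius, seed=seed,
        )


# ---------------------------------------------------------------------------
# ideal helix construction (NeRF internal-coordinate chain build)

def _nerf(a, b, c, r, theta_deg, chi_deg):
    """Place atom D bonded to C given bond length r, angle B-C-D and
    torsion A-B-C-D."""
    theta = np.radians(theta_deg)
    chi = np.radians(chi_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = np.array([-r * np.cos(theta),
                  r * np.sin(theta) * np.cos(chi),
                  r * np.sin(theta) * np.sin(chi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_helix_coords(n_res: int) -> np.ndarray:
    """Ideal alpha-helical backbone (phi=-57, psi=-47), shape (R, 5, 3).

    Atom order follows ATOM_ORDER; the first residue's amide H is NaN.
    The resulting helix has a rise of ~1.5 A/residue and ~100 deg/residue
    twist, the textbook alpha-helix parameters.
    """
    x = np.full((n_res, 5, 3), np.nan)
    iN, iH, iCA, iC, iO = range(5)
    x[0, iN] = (0.0, 0.0, 0.0)
    x[0, iCA] = (_B_N_CA, 0.0, 0.0)
    a = np.radians(180.0 - _A_N_CA_C)
    x[0, iC] = x[0, iCA] + _B_CA_C * np.array([np.cos(a), np.sin(a), 0.0])
    for i in range(1, n_res):
        x[i, iN] = _nerf(x[i - 1, iN], x[i - 1, iCA], x[i - 1, iC],
                         _B_C_N, _A_CA_C_N, _PSI)
        x[i - 1, iO] = _nerf(x[i - 1, iN], x[i - 1, iCA], x[i - 1, iC],
                             _B_C_O, _A_CA_C_O, _PSI + 180.0)
        x[i, iCA] = _nerf(x[i - 1, iCA], x[i - 1, iC], x[i, iN],
                          _B_N_CA, _A_C_N_CA, _OMEGA)
        x[i, iH] = _nerf(x[i - 1, iO], x[i - 1, iC], x[i, iN],
                         _B_N_H, _A_C_N_H, 180.0)
        x[i, iC] = _nerf(x[i - 1, iC], x[i, iN], x[i, iCA],
                         _B_CA_C, _A_N_CA_C, _PHI)
    x[-1, iO] = _nerf(x[-1, iN], x[-1, iCA], x[-1, iC],
                      _B_C_O, _A_CA_C_O, _PSI + 180.0)
    return x


def _canonical_helix(n_res: int, axis_to: np.ndarray) -> np.ndarray:
    """Ideal helix rotated so its increasing-residue axis is ``axis_to``
    and its CA centroid sits at the origin."""
    x = _build_helix_coords(n_res)
    ca = x[:, 2, :]
    axis = _principal_axis(ca)
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    R = _rotation_between(axis, np.asarray(axis_to, float))
    x = x @ R.T
    x -= x[:, 2, :].mean(axis=0)
    return x


@lru_cache(maxsize=32)
def _templates(n_tm: int, n_cyto: int) -> tuple[np.ndarray, Optional[np.ndarray]]:
    # TM helix runs N->C downward (first residue at the top, where the
    # cytoplasmic domain attaches); cytoplasmic helix canonical along +z.
    tm = _canonical_helix(n_tm, np.array([0.0, 0.0, -1.0]))
    cyto = _canonical_helix(n_cyto, np.array([0.0, 0.0, 1.0])) if n_cyto else None
    return tm, cyto


def protomer_coords(bp: PentamerBlueprint, tau_deg: float, theta_deg: float,
                    azimuth_deg: float, spin_deg: float = 0.0,
                    displacement: Sequence[float] = (0.0, 0.0)) -> np.ndarray:
    """Realize one protomer of the pinwheel as a coordinate array (R, 5, 3).

    The TM helix is spun about its own axis by ``spin_deg``, tilted by
    ``tau_deg`` from +z, shifted to ``bundle_radius`` (+ in-plane
    displacement) and rotated to ``azimuth_deg`` about the bundle (+z) axis.
    The cytoplasmic helix, when present, is oriented at ``theta_deg`` from
    +z and attached ahead of the first TM residue.
    """
    n_tm = bp.tm_range[1] - bp.tm_range[0] + 1
    n_cyto = 0 if bp.cyto_range is None else bp.cyto_range[1] - bp.cyto_range[0] + 1
    tm_t, cyto_t = _templates(n_tm, n_cyto)

    R_tm = rot_y(tau_deg) @ rot_z(spin_deg)
    tm = tm_t @ R_tm.T
    parts = [tm]
    if cyto_t is not None:
        th = np.radians(theta_deg)
        a_c = np.array([-np.sin(th), 0.0, np.cos(th)])  # splays outward (+x after attach)
        cyto = cyto_t @ rot_y(-theta_deg).T
        # peptide bond from cytoplasmic C-terminal C to the first TM N
        p_n = tm[0, 0]
        cyto = cyto + (p_n - _B_C_N * a_c - cyto[-1, 3])
        # amide H of the junction residue from the actual cross-helix geometry
        c_prev, o_prev = cyto[-1, 3], cyto[-1, 4]
        tm[0, 1] = p_n + _B_N_H * _unit(c_prev - o_prev)
        parts = [cyto, tm]
    coords = np.concatenate(parts, axis=0)
    shift = np.array([bp.bundle_radius + displacement[0], displacement[1], 0.0])
    return (coords + shift) @ rot_z(azimuth_deg).T


def _coords_to_protomer(bp: PentamerBlueprint, coords: np.ndarray,
                        chain_id: str) -> Protomer:
    names = bp.residue_names
    numbers = bp.residue_numbers
    residues = []
    for i, (num, name) in enumerate(zip(numbers, names)):
        hn = coords[i, 1]
        if np.any(np.isnan(hn)) or name == "PRO":
            hn = None
        else:
            hn = hn.copy()
        residues.append(BackboneResidue(
            index=num, name=name, n=coords[i, 0].copy(), hn=hn,
            ca=coords[i, 2].copy(), c=coords[i, 3].copy(), o=coords[i, 4].copy(),
        ))
    return Protomer(chain_id=chain_id, residues=residues)


def build_ideal_pentamer(bp: PentamerBlueprint) -> OrientedOligomer:
    """Assemble the ideal pinwheel oligomer described by the blueprint.

    Deterministic: identical blueprints give bit-identical coordinates.
    Raises GeometryError if any two protomers come within 1 A of each other.
    """
    P = bp.n_protomers
    offsets = bp.azimuth_offsets or tuple(0.0 for _ in range(P))
    chains = []
    arrays = []
    for k in range(P):
        az = 360.0 * k / P + offsets[k]
        arr = protomer_coords(bp, bp.tau_deg, bp.theta_deg, az)
        arrays.append(arr)
        chains.append(_coords_to_protomer(bp, arr, chr(ord("A") + k)))
    if P > 1:
        flat = [a.reshape(-1, 3) for a in arrays]
        flat = [f[~np.isnan(f).any(axis=1)] for f in flat]
        trees = [cKDTree(f) for f in flat]
        for i in range(P):
            for j in range(i + 1, P):
                d, _ = trees[j].query(flat[i], k=1)
                if d.min() < _CLASH_CUTOFF:
                    raise GeometryError(
                        f"protomers {i} and {j} clash (min distance "
                        f"{d.min():.2f} A < {_CLASH_CUTOFF} A); increase "
                        "bundle_radius"
                    )
    return OrientedOligomer(protomers=chains)


# ---------------------------------------------------------------------------
# array views (used by restraint gradients and the sampler)

def oligomer_coords(olig: OrientedOligomer) -> np.ndarray:
    """Coordinates as an array (P, R, 5, 3); missing amide H is NaN."""
    P = olig.n_protomers
    R = len(olig.protomers[0].residues)
    out = np.full((P, R, 5, 3), np.nan)
    for p, prot in enumerate(olig.protomers):
        for i, res in enumerate(prot.residues):
            out[p, i, 0] = res.n
            if res.hn is not None:
                out[p, i, 1] = res.hn
            out[p, i, 2] = res.ca
            out[p, i, 3] = res.c
            out[p, i, 4] = res.o
    return out


def oligomer_with_coords(olig: OrientedOligomer, coords: np.ndarray) -> OrientedOligomer:
    """Copy of ``olig`` with coordinates replaced from a (P, R, 5, 3) array."""
    prots = []
    for p, prot in enumerate(olig.protomers):
        residues = []
        for i, res in enumerate(prot.residues):
            hn = None if res.hn is None else coords[p, i, 1].copy()
            residues.append(replace(
                res, n=coords[p, i, 0].copy(), hn=hn, ca=coords[p, i, 2].copy(),
                c=coords[p, i, 3].copy(), o=coords[p, i, 4].copy(),
            ))
        prots.append(Protomer(chain_id=prot.chain_id, residues=residues))
    return OrientedOligomer(protomers=prots)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)

def read_ensemble(path, model_policy: str = "all") -> ReplicaEnsemble:
    """Read a (possibly multi-model) PDB file into a ReplicaEnsemble.

    ``model_policy`` is "all" (one replica per MODEL) or "first".
    """
    if model_policy not in ("all", "first"):
        raise ConfigError(f"unknown model_policy {model_policy!r}")
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except Exception as exc:  # biotite raises assorted parse errors
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if model_policy == "first":
        n_models = 1
    replicas = []
    signature = None
    for m in range(n_models):
        try:
            atoms = pdb.get_structure(model=m + 1)
        except Exception as exc:
            raise ParseError(
                f"cannot parse model {m + 1} of {path}: {exc}") from exc
        olig = _model_to_oligomer(atoms, path)
        sig = [(p.chain_id, tuple((r.index, r.name, r.has_amide_h)
                                  for r in p.residues)) for p in olig.protomers]
        if signature is None:
            signature = sig
        elif sig != signature:
            raise StructureError(
                f"{path}: model {m + 1} differs in chain/residue composition "
                "from model 1"
            )
        replicas.append(olig)
    return ReplicaEnsemble(replicas=replicas)


def _model_to_oligomer(atoms: struc.AtomArray, path) -> OrientedOligomer:
    chain_order = []
    for cid in atoms.chain_id:
        if cid not in chain_order:
            chain_order.append(cid)
    protomers = []
    for cid in chain_order:
        sel = atoms[atoms.chain_id == cid]
        residues = []
        res_order = []
        for rid in sel.res_id:
            if rid not in res_order:
                res_order.append(int(rid))
        for rid in res_order:
            rsel = sel[sel.res_id == rid]
            byname = {}
            for i in range(rsel.array_length()):
                byname.setdefault(rsel.atom_name[i], rsel.coord[i].astype(float))
            name = str(rsel.res_name[0])
            missing = [a for a in ("N", "CA", "C", "O") if a not in byname]
            if missing:
                raise StructureError(
                    f"{path}: chain {cid} residue {rid} lacks backbone "
                    f"atom(s) {', '.join(missing)}"
                )
            hn = byname.get("H", byname.get("HN"))
            residues.append(BackboneResidue(
                index=rid, name=name, n=byname["N"], hn=hn,
                ca=byname["CA"], c=byname["C"], o=byname["O"],
            ))
        protomers.append(Protomer(chain_id=str(cid), residues=residues))
    return OrientedOligomer(protomers=protomers)


def write_ensemble(ens: ReplicaEnsemble, path, single_model_records: bool = False) -> None:
    """Write an ensemble as a multi-model PDB file.

    An M=1 ensemble is written without MODEL records unless
    ``single_model_records`` is set.
    """
    models = [_oligomer_to_atoms(rep) for rep in ens.replicas]
    pdb = PDBFile()
    if len(models) == 1 and not single_model_records:
        pdb.set_structure(models[0])
    else:
        pdb.set_structure(struc.stack(models))
        if len(models) == 1:
            # biotite omits MODEL records for depth-1 stacks; add them
            pdb.lines = (["MODEL        1"] + list(pdb.lines) + ["ENDMDL"])
    try:
        pdb.write(str(path))
    except OSError as exc:
        raise DataError(f"cannot write {path}: {exc}") from exc


def _oligomer_to_atoms(olig: OrientedOligomer) -> struc.AtomArray:
    rows = []
    for prot in olig.protomers:
        for res in prot.residues:
            coords = {"N": res.n, "CA": res.ca, "C": res.c, "O": res.o}
            if res.hn is not None:
                coords["H"] = res.hn
            for name in ATOM_ORDER:
                if name in coords:
                    rows.append((prot.chain_id, res.index, res.name, name,
                                 coords[name]))
    arr = struc.AtomArray(len(rows))
    arr.coord = np.array([r[4] for r in rows])
    arr.chain_id = np.array([r[0] for r in rows])
    arr.res_id = np.array([r[1] for r in rows])
    arr.res_name = np.array([r[2] for r in rows])
    arr.atom_name = np.array([r[3] for r in rows])
    arr.element = np.array([r[3][0] for r in rows])
    arr.hetero = np.zeros(len(rows), dtype=bool)
    return arr


# ---------------------------------------------------------------------------
# ensemble perturbation (reference-ensemble heterogeneity)

def perturb_ensemble(ens: ReplicaEnsemble, tilt_sigma: float,
                     jitter_sigma: float, seed: int) -> ReplicaEnsemble:
    """Per-replica rigid-body tilt (normal, width ``tilt_sigma`` deg, about a
    random in-membrane-plane axis through the replica centroid) plus
    per-atom Gaussian jitter of width ``jitter_sigma`` A. Seed-reproducible.
    """
    if tilt_sigma < 0 or jitter_sigma < 0:
        raise ConfigError("perturbation sigmas must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for rep in ens.replicas:
        coords = oligomer_coords(rep)
        angle = rng.normal(0.0, tilt_sigma)
        phi = rng.uniform(0.0, 360.0)
        axis = np.array([np.cos(np.radians(phi)), np.sin(np.radians(phi)), 0.0])
        flat = coords.reshape(-1, 3)
        rotated = flat
        if angle != 0.0:
            R = _axis_angle(axis, angle)
            center = np.nanmean(flat, axis=0)
            rotated = (flat - center) @ R.T + center
        if jitter_sigma > 0:
            rotated = rotated + rng.normal(0.0, jitter_sigma, size=flat.shape)
        # keep the same positions NaN (missing H) as the input
        rotated[np.isnan(flat).any(axis=1)] = np.nan
        out.append(oligomer_with_coords(rep, rotated.reshape(coords.shape)))
    return ReplicaEnsemble(replicas=out)
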