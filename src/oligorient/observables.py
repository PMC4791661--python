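"""Forward calculation of oriented-ssNMR observables from coordinates.

Two observables are computed for every amide nitrogen:

* **CSA** — the orientation-dependent 15N chemical shift. The shift tensor
  is diagonal in a principal axis frame anchored to the peptide plane, with
  principal values (delta11, delta22, delta33). The observed shift for a
  field direction ``b`` is ``b . sigma . b = sum_k delta_kk (e_k . b)^2``
  where ``e_k`` are the principal axes in the lab frame.
* **DC** — the 15N-1H dipolar coupling, ``zeta_DC (3 cos^2 theta - 1)/2``
  with ``theta`` the angle between the N-H bond and the field.

Principal-axis placement (standard amide 15N convention): the delta22 axis
is normal to the peptide plane (through C', N and H), the delta33 axis lies
in-plane, tilted ``pas_tilt_deg`` (default 17 deg) from the N-H bond toward
N->C', and delta11 completes the right-handed frame. Both the tilt and the
principal values are configurable.

Residues without an amide proton (prolines, chain-initial residues) carry
no observables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import GeometryError
from .structures import BackboneResidue, OrientedOligomer, ReplicaEnsemble

Z_AXIS = np.array([0.0, 0.0, 1.0])

#: 15N shift tensor principal values (ppm).
NONGLY_DELTAS = (64.0, 76.0, 216.9)
GLY_DELTAS = (46.5, 66.3, 211.6)

#: 15N-1H dipolar coupling constant (kHz) at the standard N-H bond length.
ZETA_DC = 10.52


@dataclass(frozen=True)
class TensorParameters:
    """15N CSA principal values (ppm) and in-plane tilt of the delta33 axis
    from the N-H bond (deg)."""

    delta11: float = NONGLY_DELTAS[0]
    delta22: float = NONGLY_DELTAS[1]
    delta33: float = NONGLY_DELTAS[2]
    delta11_gly: float = GLY_DELTAS[0]
    delta22_gly: float = GLY_DELTAS[1]
    delta33_gly: float = GLY_DELTAS[2]
    pas_tilt_deg: float = 17.0

    def __post_init__(self):
        if not (self.delta11 <= self.delta22 <= self.delta33):
            raise ValueError("principal values must satisfy d11 <= d22 <= d33")
        if not (self.delta11_gly <= self.delta22_gly <= self.delta33_gly):
            raise ValueError("glycine principal values must be ordered")

    def deltas_for(self, res_name: str) -> tuple[float, float, float]:
        if res_name.upper() == "GLY":
            return (self.delta11_gly, self.delta22_gly, self.delta33_gly)
        return (self.delta11, self.delta22, self.delta33)


@dataclass(frozen=True)
class DCParameters:
    """Dipolar coupling constant zeta_DC in kHz."""

    zeta_dc: float = ZETA_DC

    def __post_init__(self):
        if self.zeta_dc <= 0:
            raise ValueError("zeta_dc must be positive")


@dataclass(frozen=True)
class ComputedObservable:
    residue: int
    protomer: str
    kind: str  # "CSA" (ppm) or "DC" (kHz)
    value: float
    replica: int = 0


# ---------------------------------------------------------------------------
# geometry: peptide-plane principal axis frame

def _unit(v):
    n = np.linalg.norm(v)
    if n < 1e-8:
        raise GeometryError("degenerate geometry: zero-length vector")
    return v / n


def peptide_plane_frame(res: BackboneResidue, prev: BackboneResidue,
                        pas_tilt_deg: float = 17.0) -> np.ndarray:
    """Right-handed orthonormal principal-axis frame, rows (e1, e2, e3).

    e2 is normal to the plane through C'(prev), N and H; e3 is the N->H
    direction rotated in-plane by ``pas_tilt_deg`` toward N->C'(prev);
    e1 = e2 x e3.
    """
    if res.hn is None:
        raise GeometryError(f"residue {res.index} has no amide H")
    a = prev.c - res.n
    w = res.hn - res.n
    hu = _unit(w)
    au = _unit(a)
    nrm = np.cross(a, w)
    if np.linalg.norm(nrm) < 1e-8:
        raise GeometryError(
            f"residue {res.index}: C', N and H are collinear; peptide plane "
            "undefined"
        )
    e2 = _unit(nrm)
    x = np.cross(e2, hu)  # unit, in-plane, perpendicular to N-H
    s = 1.0 if np.dot(x, au) >= 0 else -1.0
    phi = np.radians(pas_tilt_deg)
    e3 = np.cos(phi) * hu + s * np.sin(phi) * x
    e1 = np.cross(e2, e3)
    return np.array([e1, e2, e3])


# ---------------------------------------------------------------------------
# scalar forward models

def compute_csa(res: BackboneResidue, prev: BackboneResidue,
                tp: TensorParameters = TensorParameters(),
                field: np.ndarray = Z_AXIS) -> float:
    """Back-calculated 15N shift (ppm) for field direction ``field``."""
    frame = peptide_plane_frame(res, prev, tp.pas_tilt_deg)
    b = _unit(np.asarray(field, float))
    deltas = tp.deltas_for(res.name)
    proj = frame @ b
    return float(np.dot(deltas, proj * proj))


def compute_dc(res: BackboneResidue, dp: DCParameters = DCParameters(),
               field: np.ndarray = Z_AXIS) -> float:
    """Back-calculated 15N-1H dipolar coupling (kHz), signed."""
    if res.hn is None:
        raise GeometryError(f"residue {res.index} has no amide H")
    u = _unit(res.hn - res.n)
    b = _unit(np.asarray(field, float))
    c = float(np.dot(u, b))
    return dp.zeta_dc * (3.0 * c * c - 1.0) / 2.0


# ---------------------------------------------------------------------------
# vectorized forward models over (R, 3) coordinate arrays

def _unit_rows(v, label="vector"):
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < 1e-8):
        raise GeometryError(f"degenerate geometry: zero-length {label}")
    return v / n


def csa_values(c_prev: np.ndarray, n: np.ndarray, h: np.ndarray,
               deltas: np.ndarray, pas_tilt_deg: float = 17.0,
               field: np.ndarray = Z_AXIS) -> np.ndarray:
    """Vectorized CSA over stacked residues.

    ``deltas`` has shape (R, 3) (per-residue principal values, so glycine
    rows can differ).
    """
    b = _unit(np.asarray(field, float))
    a = c_prev - n
    w = h - n
    hu = _unit_rows(w, "N-H bond")
    au = _unit_rows(a, "N-C' vector")
    e2 = _unit_rows(np.cross(a, w), "peptide-plane normal")
    x = np.cross(e2, hu)
    s = np.where(np.einsum("ij,ij->i", x, au) >= 0, 1.0, -1.0)[:, None]
    phi = np.radians(pas_tilt_deg)
    e3 = np.cos(phi) * hu + np.sin(phi) * s * x
    e1 = np.cross(e2, e3)
    p1, p2, p3 = e1 @ b, e2 @ b, e3 @ b
    d = np.asarray(deltas, float)
    return d[:, 0] * p1 * p1 + d[:, 1] * p2 * p2 + d[:, 2] * p3 * p3


def dc_values(n: np.ndarray, h: np.ndarray, zeta_dc: float = ZETA_DC,
              field: np.ndarray = Z_AXIS) -> np.ndarray:
    b = _unit(np.asarray(field, float))
    u = _unit_rows(h - n, "N-H bond")
    c = u @ b
    return zeta_dc * (3.0 * c * c - 1.0) / 2.0


# ---------------------------------------------------------------------------
# exact gradients (forward-mode Jacobian propagation)

def _skew(v):
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def _unit_jac(v, J):
    r = np.sqrt(v @ v)
    u = v / r
    return u, (np.eye(3) - np.outer(u, u)) @ J / r


def csa_value_grad(c_prev, n, h, deltas, pas_tilt_deg=17.0, field=Z_AXIS):
    """CSA value and its exact gradient w.r.t. (C'_prev, N, H).

    Returns ``(value, g_cprev, g_n, g_h)``; gradients in ppm/Angstrom.
    Input Jacobian ordering is the 9-vector [C'(3), N(3), H(3)].
    """
    b = _unit(np.asarray(field, float))
    I, Z = np.eye(3), np.zeros((3, 3))
    a = c_prev - n
    Ja = np.hstack([I, -I, Z])
    w = h - n
    Jw = np.hstack([Z, -I, I])
    cr = np.cross(a, w)
    if np.linalg.norm(cr) < 1e-8:
        raise GeometryError("collinear C', N, H: peptide plane undefined")
    Jcr = -_skew(w) @ Ja + _skew(a) @ Jw
    e2, J2 = _unit_jac(cr, Jcr)
    hu, Jhu = _unit_jac(w, Jw)
    au = a / np.linalg.norm(a)
    x = np.cross(e2, hu)
    Jx = -_skew(hu) @ J2 + _skew(e2) @ Jhu
    s = 1.0 if np.dot(x, au) >= 0 else -1.0
    phi = np.radians(pas_tilt_deg)
    e3 = np.cos(phi) * hu + s * np.sin(phi) * x
    J3 = np.cos(phi) * Jhu + s * np.sin(phi) * Jx
    e1 = np.cross(e2, e3)
    J1 = -_skew(e3) @ J2 + _skew(e2) @ J3
    val, g = 0.0, np.zeros(9)
    for d, e, J in ((deltas[0], e1, J1), (deltas[1], e2, J2), (deltas[2], e3, J3)):
        p = float(e @ b)
        val += d * p * p
        g += 2.0 * d * p * (b @ J)
    return val, g[:3], g[3:6], g[6:9]


def dc_value_grad(n, h, zeta_dc=ZETA_DC, field=Z_AXIS):
    """DC value and its exact gradient w.r.t. (N, H); kHz and kHz/Angstrom."""
    b = _unit(np.asarray(field, float))
    u = h - n
    r = np.linalg.norm(u)
    if r < 1e-8:
        raise GeometryError("zero-length N-H bond")
    c = float(u @ b) / r
    val = zeta_dc * (3.0 * c * c - 1.0) / 2.0
    dc_du = b / r - c * u / (r * r)
    g_h = 3.0 * zeta_dc * c * dc_du
    return val, -g_h, g_h


# ---------------------------------------------------------------------------
# whole-ensemble back-calculation

def eligible_residues(olig: OrientedOligomer) -> list[int]:
    """Residue numbers carrying observables: amide H present, not proline,
    and a preceding residue available for the peptide plane."""
    prot = olig.protomers[0]
    idx = {r.index for r in prot.residues}
    out = []
    for r in prot.residues:
        if r.hn is None or r.name.upper() == "PRO":
            continue
        if (r.index - 1) not in idx:
            continue
        out.append(r.index)
    return out


def backcalc_table(ens: ReplicaEnsemble,
                   tp: TensorParameters = TensorParameters(),
                   dp: DCParameters = DCParameters(),
                   field: np.ndarray = Z_AXIS) -> list[ComputedObservable]:
    """One CSA and one DC record per eligible residue per protomer per
    replica. Deterministic."""
    records = []
    for m, olig in enumerate(ens.replicas):
        elig = eligible_residues(olig)
        for prot in olig.protomers:
            bynum = {r.index: r for r in prot.residues}
            for i in elig:
                res, prev = bynum[i], bynum[i - 1]
                records.append(ComputedObservable(
                    residue=i, protomer=prot.chain_id, kind="CSA",
                    value=compute_csa(res, prev, tp, field), replica=m))
                records.append(ComputedObservable(
                    residue=i, protomer=prot.chain_id, kind="DC",
                    value=compute_dc(res, dp, field), replica=m))
    return records
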