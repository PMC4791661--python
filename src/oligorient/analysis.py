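"""Ensemble analyses: topology angles, order parameters, RMSF, pore
profile and principal component analysis.

Angle conventions (lab frame, B0 = membrane normal = +z):

* tau   — per-protomer transmembrane helix tilt vs +z, folded to [0, 90].
* theta — per-protomer cytoplasmic helix tilt vs +z, unfolded [0, 180]
          (values near 90-110 deg indicate adsorption on the membrane
          surface).
* gamma — tilt of the whole TM bundle axis vs +z, folded to [0, 90].
* omega — per-protomer angle between the TM helix axis and the bundle
          axis; computed entirely in the internal protein frame, hence
          invariant under any global rotation.

The pore profiler is a transparent axial-slab scan (not a Voronoi channel
finder): for each height z along the bundle axis the pore radius is the
smallest (axial distance - vdW radius) over atoms within a slab, floored
at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, GeometryError
from .structures import OrientedOligomer, ReplicaEnsemble

#: PLN domain boundaries (literature defaults, config-exposed everywhere).
DEFAULT_DOMAINS = {"Ia": (1, 16), "Ib": (17, 30), "II": (31, 52)}

VDW_RADII = {"N": 1.55, "C": 1.70, "O": 1.52, "H": 1.10}

Frames = Union[ReplicaEnsemble, Sequence[OrientedOligomer]]


def _as_frames(frames: Frames) -> list[OrientedOligomer]:
    if isinstance(frames, ReplicaEnsemble):
        return list(frames.replicas)
    frames = list(frames)
    if not frames:
        raise DataError("no frames supplied")
    return frames


def _fold90(angle_deg: float) -> float:
    return min(angle_deg, 180.0 - angle_deg)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# helix axis

def fit_helix_axis(ca_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares helix axis: principal direction of the centered CA
    cloud, sign chosen toward increasing residue index.

    Returns (unit axis, centroid). Requires >= 4 CA positions.
    """
    ca = np.asarray(ca_coords, float)
    if ca.ndim != 2 or ca.shape[0] < 4:
        raise DataError("helix axis fit needs at least 4 CA positions")
    centroid = ca.mean(axis=0)
    x = ca - centroid
    if np.allclose(x, 0.0, atol=1e-8):
        raise GeometryError("all CA positions coincide; axis undefined")
    _, vecs = np.linalg.eigh(x.T @ x)
    axis = vecs[:, -1]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis, centroid


def _domain_ca(prot, lo: int, hi: int) -> np.ndarray:
    ca = [r.ca for r in prot.residues if lo <= r.index <= hi]
    if not ca:
        raise ConfigError(f"domain {lo}-{hi} matches no residues")
    return np.array(ca)


# ---------------------------------------------------------------------------
# topology angles

def topology_angles(frames: Frames,
                    domains: Mapping[str, tuple[int, int]] = DEFAULT_DOMAINS
                    ) -> pd.DataFrame:
    """Per-frame, per-protomer tau/theta/gamma/omega angles (degrees).

    ``domains`` must define "II" (transmembrane); "Ia" (cytoplasmic) is
    required only when theta is computable. Returns a tidy DataFrame with
    columns frame, protomer, tau, theta, gamma, omega (theta NaN when no
    cytoplasmic domain is defined or present).
    """
    if "II" not in domains:
        raise ConfigError('domain "II" (transmembrane) must be defined')
    tm_lo, tm_hi = domains["II"]
    cyto = domains.get("Ia")
    z = np.array([0.0, 0.0, 1.0])
    rows = []
    for f, olig in enumerate(_as_frames(frames)):
        tm_axes = []
        all_tm_ca = []
        for prot in olig.protomers:
            ca = _domain_ca(prot, tm_lo, tm_hi)
            axis, _ = fit_helix_axis(ca)
            tm_axes.append(axis)
            all_tm_ca.append(ca)
        bundle_axis, _ = fit_helix_axis(np.concatenate(all_tm_ca))
        # orient the bundle axis with the mean protomer direction
        mean_dir = np.mean(tm_axes, axis=0)
        if np.dot(bundle_axis, mean_dir) < 0:
            bundle_axis = -bundle_axis
        gamma = _fold90(_angle_deg(bundle_axis, z))
        for p, prot in enumerate(olig.protomers):
            tau = _fold90(_angle_deg(tm_axes[p], z))
            omega = _angle_deg(tm_axes[p], bundle_axis)
            theta = np.nan
            if cyto is not None:
                try:
                    c_axis, _ = fit_helix_axis(_domain_ca(prot, *cyto))
                    theta = _angle_deg(c_axis, z)
                except (ConfigError, DataError):
                    theta = np.nan
            rows.append((f, prot.chain_id, tau, theta, gamma, omega))
    return pd.DataFrame(rows, columns=["frame", "protomer", "tau", "theta",
                                       "gamma", "omega"])


# ---------------------------------------------------------------------------
# order parameters

def order_parameters(frames: Frames, average_protomers: bool = True
                     ) -> pd.DataFrame:
    """Amide N-H order parameters S^2 per residue.

    S^2 = (3 sum_ab <mu_a mu_b>^2 - 1) / 2 with mu the unit N-H vector and
    the average over frames, computed per (residue, protomer); with
    ``average_protomers`` the per-protomer S^2 values are then averaged per
    residue. 1 for a rigid ensemble, -> 0 for isotropic N-H vectors.
    Requires at least 2 frames.
    """
    fr = _as_frames(frames)
    if len(fr) < 2:
        raise DataError("order parameters need at least 2 frames")
    vecs: dict = {}
    for olig in fr:
        for prot in olig.protomers:
            for res in prot.residues:
                if res.hn is None:
                    continue
                u = res.hn - res.n
                u = u / np.linalg.norm(u)
                vecs.setdefault((res.index, prot.chain_id), []).append(u)
    per_chain = {}
    for (residue, chain), mu in vecs.items():
        mu = np.array(mu)
        Q = mu.T @ mu / len(mu)  # <mu_a mu_b>, 3x3
        per_chain[(residue, chain)] = (3.0 * float(np.sum(Q * Q)) - 1.0) / 2.0
    if not average_protomers:
        rows = [(r, c, s2, len(vecs[(r, c)]))
                for (r, c), s2 in sorted(per_chain.items())]
        return pd.DataFrame(rows, columns=["residue", "protomer", "s2",
                                           "n_vectors"])
    byres: dict = {}
    for (residue, _), s2 in per_chain.items():
        byres.setdefault(residue, []).append(s2)
    rows = [(r, "", float(np.mean(v)), len(v)) for r, v in sorted(byres.items())]
    return pd.DataFrame(rows, columns=["residue", "protomer", "s2", "n_protomers"])


# ---------------------------------------------------------------------------
# superposition and RMSF

def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimizing |mobile@R.T + t - ref|."""
    mc, rc = mobile.mean(axis=0), ref.mean(axis=0)
    H = (mobile - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, rc - R @ mc


def _iterative_superpose(coords: np.ndarray, max_iter: int = 50,
                         tol: float = 1e-6) -> np.ndarray:
    """Superpose frames (F, N, 3) onto their iteratively refined mean."""
    x = coords.copy()
    ref = x[0]
    for _ in range(max_iter):
        for f in range(x.shape[0]):
            R, t = _kabsch(x[f], ref)
            x[f] = x[f] @ R.T + t
        new_ref = x.mean(axis=0)
        if np.abs(new_ref - ref).max() < tol:
            break
        ref = new_ref
    return x


def rmsf(frames: Frames, domain: tuple[int, int],
         average_protomers: bool = True) -> pd.DataFrame:
    """Per-residue CA root-mean-square fluctuation (Angstrom) within one
    domain, after iterative least-squares superposition of each protomer's
    domain CA onto the ensemble mean (rigid-body motion removed)."""
    fr = _as_frames(frames)
    if len(fr) < 2:
        raise DataError("RMSF needs at least 2 frames")
    lo, hi = domain
    P = fr[0].n_protomers
    per_protomer = []
    indices = None
    for p in range(P):
        coords = []
        for olig in fr:
            prot = olig.protomers[p]
            res = [r for r in prot.residues if lo <= r.index <= hi]
            if indices is None:
                indices = [r.index for r in res]
            coords.append([r.ca for r in res])
        coords = np.array(coords)
        if coords.shape[1] < 3:
            raise DataError("domain too small for superposition")
        sup = _iterative_superpose(coords)
        mean = sup.mean(axis=0)
        per_protomer.append(np.sqrt(np.mean(np.sum((sup - mean) ** 2, axis=2),
                                            axis=0)))
    arr = np.array(per_protomer)  # (P, R)
    if average_protomers:
        return pd.DataFrame({"residue": indices, "rmsf": arr.mean(axis=0)})
    rows = [(indices[i], fr[0].protomers[p].chain_id, arr[p, i])
            for p in range(P) for i in range(len(indices))]
    return pd.DataFrame(rows, columns=["residue", "protomer", "rmsf"])


# ---------------------------------------------------------------------------
# pore profile

@dataclass
class PoreProfile:
    z_grid: np.ndarray          # Angstrom, along the bundle axis
    radius: np.ndarray          # ensemble-mean pore radius per z
    sd: np.ndarray              # ensemble SD per z
    per_frame: np.ndarray       # (F, Z)
    bottlenecks: list           # [(residue, radius), ...] local minima
    mean_radius: float


def _frame_pore(olig: OrientedOligomer, tm_range: tuple[int, int],
                z_grid_rel: np.ndarray, slab_half: float,
                include_h: bool,
                axis_override: Optional[np.ndarray] = None
                ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Pore radii of one frame on a grid relative to the TM CA z-extent,
    in the bundle-axis frame. Also returns per-residue mean CA height."""
    lo, hi = tm_range
    tm_ca = np.concatenate([_domain_ca(p, lo, hi) for p in olig.protomers])
    if axis_override is not None:
        axis = np.asarray(axis_override, float)
        axis = axis / np.linalg.norm(axis)
        centroid = tm_ca.mean(axis=0)
    else:
        axis, centroid = fit_helix_axis(tm_ca)
    # build an orthonormal frame with the bundle axis as z
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    atoms, radii = [], []
    ca_heights: dict = {}
    for prot in olig.protomers:
        for res in prot.residues:
            coords = {"N": res.n, "CA": res.ca, "C": res.c, "O": res.o}
            if include_h and res.hn is not None:
                coords["H"] = res.hn
            for name, c in coords.items():
                atoms.append(c)
                radii.append(VDW_RADII[name[0]])
            if lo <= res.index <= hi:
                ca_heights.setdefault(res.index, []).append(
                    float(np.dot(res.ca - centroid, axis)))
    atoms = np.array(atoms) - centroid
    radii = np.array(radii)
    za = atoms @ axis
    ra = np.sqrt((atoms @ e1) ** 2 + (atoms @ e2) ** 2)
    ca_z = np.dot(tm_ca - centroid, axis)
    z0 = ca_z.min()
    out = np.empty(len(z_grid_rel))
    for i, zr in enumerate(z_grid_rel):
        z = z0 + zr
        mask = np.abs(za - z) <= slab_half
        if not mask.any():
            out[i] = np.nan
            continue
        out[i] = max(float(np.min(ra[mask] - radii[mask])), 0.0)
    heights = {k: float(np.mean(v)) - z0 for k, v in ca_heights.items()}
    return out, ca_z, heights


def pore_profile(frames: Frames, tm_range: tuple[int, int] = DEFAULT_DOMAINS["II"],
                 slab_half: float = 1.5, grid_step: float = 0.5,
                 include_h: bool = False,
                 axis: Optional[np.ndarray] = None) -> PoreProfile:
    """Axial pore-radius profile along the TM bundle axis.

    Per frame and grid height z the radius is min over slab atoms of
    (axial distance - vdW radius), floored at 0. The profile is averaged
    over frames; bottlenecks are local minima of the mean profile mapped to
    the residue whose mean CA height is nearest (ties toward the lower
    residue index). ``axis`` overrides the fitted bundle axis (useful for
    synthetic fixtures whose point cloud is too flat for a stable fit).
    """
    fr = _as_frames(frames)
    if fr[0].n_protomers < 3:
        raise GeometryError("pore profile needs an oligomer with P >= 3")
    # common grid from the first frame's CA extent
    lo, hi = tm_range
    tm_ca = np.concatenate([_domain_ca(p, lo, hi) for p in fr[0].protomers])
    if axis is not None:
        axis0 = np.asarray(axis, float)
        axis0 = axis0 / np.linalg.norm(axis0)
    else:
        axis0, _ = fit_helix_axis(tm_ca)
    extent = float(np.ptp(tm_ca @ axis0))
    z_grid = np.arange(0.0, extent + grid_step / 2, grid_step)
    profiles = []
    heights_acc: dict = {}
    for olig in fr:
        prof, _, heights = _frame_pore(olig, tm_range, z_grid, slab_half,
                                       include_h, axis)
        profiles.append(prof)
        for k, v in heights.items():
            heights_acc.setdefault(k, []).append(v)
    per_frame = np.array(profiles)
    mean = np.nanmean(per_frame, axis=0)
    sd = np.nanstd(per_frame, axis=0)
    mean_heights = {k: float(np.mean(v)) for k, v in heights_acc.items()}
    bottlenecks = _find_bottlenecks(z_grid, mean, mean_heights)
    return PoreProfile(z_grid=z_grid, radius=mean, sd=sd, per_frame=per_frame,
                       bottlenecks=bottlenecks,
                       mean_radius=float(np.nanmean(mean)))


def _find_bottlenecks(z_grid, profile, residue_heights) -> list:
    res_sorted = sorted(residue_heights)
    out = []
    for i in range(1, len(profile) - 1):
        if np.isnan(profile[i - 1:i + 2]).any():
            continue
        if profile[i] < profile[i - 1] and profile[i] <= profile[i + 1]:
            z = z_grid[i]
            best = min(res_sorted,
                       key=lambda r: (abs(residue_heights[r] - z), r))
            out.append((best, float(profile[i])))
    return out


def percentile_pore_contrast(frames: Frames, omega_series: Sequence[float],
                             percentile: float = 1.0,
                             tm_range: tuple[int, int] = DEFAULT_DOMAINS["II"],
                             min_frames: int = 5, **pore_kwargs):
    """Mean pore profiles of the bottom and top ``percentile`` intervals of
    the omega distribution and their difference (top - bottom) by z.

    Returns (low_profile, high_profile, difference array).
    """
    fr = _as_frames(frames)
    omega = np.asarray(omega_series, float)
    if len(omega) != len(fr):
        raise DataError("omega_series length must match the frame count")
    lo_cut = np.percentile(omega, percentile)
    hi_cut = np.percentile(omega, 100.0 - percentile)
    low_idx = [i for i, w in enumerate(omega) if w <= lo_cut]
    high_idx = [i for i, w in enumerate(omega) if w >= hi_cut]
    if len(low_idx) < min_frames or len(high_idx) < min_frames:
        raise DataError(
            f"each percentile bin needs >= {min_frames} frames "
            f"(got {len(low_idx)} low / {len(high_idx)} high)"
        )
    low = pore_profile([fr[i] for i in low_idx], tm_range, **pore_kwargs)
    high = pore_profile([fr[i] for i in high_idx], tm_range, **pore_kwargs)
    n = min(len(low.radius), len(high.radius))
    diff = high.radius[:n] - low.radius[:n]
    return low, high, diff


# ---------------------------------------------------------------------------
# principal component analysis

@dataclass
class PCAResult:
    eigenvalues: np.ndarray      # A^2, non-increasing
    eigenvectors: np.ndarray     # (3N, n_modes), columns orthonormal
    projections: np.ndarray      # (F, n_modes)
    mean_coords: np.ndarray      # (N, 3) superposed ensemble mean
    residues: list               # (residue, protomer) per CA

    def porcupine(self, mode: int = 0) -> np.ndarray:
        """Per-CA displacement vectors (N, 3) of one eigenvector."""
        return self.eigenvectors[:, mode].reshape(-1, 3)


def pca_domain(frames: Frames, residue_range: tuple[int, int]) -> PCAResult:
    """PCA of the CA coordinates of one residue range (all protomers),
    after iterative superposition onto the ensemble mean.

    Eigenvalues beyond the rank supported by the frame count are ~0.
    Requires >= 3 frames.
    """
    fr = _as_frames(frames)
    if len(fr) < 3:
        raise DataError("PCA needs at least 3 frames")
    lo, hi = residue_range
    coords, labels = [], None
    for olig in fr:
        xs, lab = [], []
        for prot in olig.protomers:
            for res in prot.residues:
                if lo <= res.index <= hi:
                    xs.append(res.ca)
                    lab.append((res.index, prot.chain_id))
        coords.append(xs)
        labels = labels or lab
    coords = np.array(coords)  # (F, N, 3)
    if coords.shape[1] < 3:
        raise DataError("residue range selects fewer than 3 CA atoms")
    sup = _iterative_superpose(coords)
    mean = sup.mean(axis=0)
    X = (sup - mean).reshape(len(fr), -1)
    cov = X.T @ X / len(fr)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    proj = X @ vecs
    return PCAResult(eigenvalues=vals, eigenvectors=vecs, projections=proj,
                     mean_coords=mean, residues=labels)
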