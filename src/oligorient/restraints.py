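"""Flat-bottom harmonic restraints under replica + internal averaging.

The restraint energy added to the sampling potential is, per observable i,

    E_i = ramp * alpha_kind * (|Delta_i| - eps_i)^2   if |Delta_i| > eps_i
    E_i = 0                                           otherwise

where ``Delta_i`` is the deviation of the *averaged* back-calculated value
from the experimental one and ``eps_i`` the experimental error (defaults
+-5 ppm for CSA, +-0.5 kHz for DC). No force acts while the disagreement is
within experimental error. Averaging is either

* ``replica`` — the arithmetic mean over the M replicas, per protomer
  (each protomer's replica-mean is restrained to the same experimental
  record), or
* ``replica_internal`` — the combined mean over all M*P protomer copies,
  the scheme appropriate for homo-oligomers whose NMR data are averaged
  over the protomers.

Force constants default to the published calibration table, keyed by
(number of replicas, averaging scheme); constants rise linearly from zero
over an equilibration ramp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .observables import (ComputedObservable, DCParameters, TensorParameters,
                          backcalc_table, csa_value_grad, dc_value_grad,
                          eligible_residues)
from .structures import ReplicaEnsemble, oligomer_coords

KINDS = ("CSA", "DC")

DEFAULT_ERROR = {"CSA": 5.0, "DC": 0.5}  # ppm / kHz

#: Calibrated force constants by replica count: columns are
#: (alpha_CSA, alpha_DC) for pure replica averaging and for combined
#: replica+internal averaging. Units J/(mol ppm^2) and J/(mol kHz^2).
FORCE_CONSTANT_TABLE = {
    1: ((4.5, 150.0), (12.5, 250.0)),
    2: ((12.0, 200.0), (12.5, 250.0)),
    3: ((12.5, 350.0), (12.5, 350.0)),
    4: ((12.5, 375.0), (12.5, 375.0)),
    8: ((20.0, 800.0), (20.0, 800.0)),
    16: ((25.0, 1000.0), (25.0, 1000.0)),
}

AVERAGING_SCHEMES = ("replica", "replica_internal")


# ---------------------------------------------------------------------------
# observable table

@dataclass
class ObservableTable:
    """Experimental (or synthetic) records: one row per (residue, kind)."""

    frame: pd.DataFrame  # columns: residue, kind, value, error

    def __post_init__(self):
        df = self.frame
        required = {"residue", "kind", "value"}
        if not required.issubset(df.columns):
            raise DataError(f"observable table needs columns {sorted(required)}")
        df = df.copy()
        df["residue"] = df["residue"].astype(int)
        df["kind"] = df["kind"].astype(str).str.upper()
        if not df["kind"].isin(KINDS).all():
            bad = sorted(set(df["kind"]) - set(KINDS))
            raise DataError(f"unknown observable kind(s): {bad}")
        if "error" not in df.columns:
            df["error"] = np.nan
        df["error"] = df["error"].astype(float)
        df.loc[df["error"].isna(), "error"] = df.loc[
            df["error"].isna(), "kind"].map(DEFAULT_ERROR)
        if (df["error"] < 0).any():
            raise DataError("observable errors must be >= 0")
        dup = df.duplicated(subset=["residue", "kind"])
        if dup.any():
            pairs = df.loc[dup, ["residue", "kind"]].to_records(index=False)
            raise DataError(f"duplicate observable records: {list(pairs)}")
        self.frame = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "ObservableTable":
        """records: iterables of (residue, kind, value[, error])."""
        rows = []
        for rec in records:
            rec = tuple(rec)
            rows.append(rec + (np.nan,) * (4 - len(rec)))
        return cls(pd.DataFrame(rows, columns=["residue", "kind", "value", "error"]))

    @classmethod
    def read_tsv(cls, path) -> "ObservableTable":
        try:
            df = pd.read_csv(path, sep=r"\s+", comment="#", header=0)
        except Exception as exc:
            raise DataError(f"cannot read observable table {path}: {exc}") from exc
        return cls(df)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# oriented ssNMR observables (CSA in ppm, DC in kHz)\n")
            self.frame.to_csv(fh, sep="\t", index=False)

    def lookup(self) -> dict:
        return {(int(r.residue), r.kind): (float(r.value), float(r.error))
                for r in self.frame.itertuples()}

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class RestraintConfig:
    alpha_csa: float = 25.0
    alpha_dc: float = 1000.0
    averaging: str = "replica_internal"
    M: int = 16
    ramp_steps: int = 0  # 0: fully ramped from the start

    def __post_init__(self):
        if self.alpha_csa < 0 or self.alpha_dc < 0:
            raise ConfigError("force constants must be >= 0")
        if self.M < 1:
            raise ConfigError("M must be >= 1")
        if self.averaging not in AVERAGING_SCHEMES:
            raise ConfigError(
                f"averaging must be one of {AVERAGING_SCHEMES}, "
                f"got {self.averaging!r}")
        if self.ramp_steps < 0:
            raise ConfigError("ramp_steps must be >= 0")

    @classmethod
    def from_table(cls, M: int, averaging: str = "replica_internal",
                   ramp_steps: int = 0) -> "RestraintConfig":
        """Default force constants for a given setup, from the published
        calibration table. For replica counts between table rows the nearest
        lower row is used."""
        if M < 1:
            raise ConfigError("M must be >= 1")
        key = max(k for k in FORCE_CONSTANT_TABLE if k <= M)
        col = 1 if averaging == "replica_internal" else 0
        a_csa, a_dc = FORCE_CONSTANT_TABLE[key][col]
        return cls(alpha_csa=a_csa, alpha_dc=a_dc, averaging=averaging,
                   M=M, ramp_steps=ramp_steps)

    def alpha(self, kind: str) -> float:
        return self.alpha_csa if kind == "CSA" else self.alpha_dc


def ramp_schedule(step: int, cfg: RestraintConfig) -> float:
    """Linear ramp: 0 at step 0, 1 at ``ramp_steps`` and beyond."""
    if step < 0:
        raise ConfigError("step must be >= 0")
    if cfg.ramp_steps == 0:
        return 1.0
    return min(float(step) / cfg.ramp_steps, 1.0)


# ---------------------------------------------------------------------------
# averaging (replica and combined replica+internal)

def average_observables(calc: Iterable[ComputedObservable],
                        scheme: str = "replica_internal") -> dict:
    """Average back-calculated observables.

    * ``replica_internal`` -> keys ``(residue, kind)``, mean over all
      replica*protomer copies.
    * ``replica`` -> keys ``(residue, kind, protomer)``, mean over replicas
      for each protomer separately.

    Raises DataError if the replicas do not all supply the same keys.
    """
    if scheme not in AVERAGING_SCHEMES:
        raise ConfigError(f"unknown averaging scheme {scheme!r}")
    sums: dict = {}
    counts: dict = {}
    per_replica_keys: dict = {}
    for rec in calc:
        if scheme == "replica_internal":
            key = (rec.residue, rec.kind)
        else:
            key = (rec.residue, rec.kind, rec.protomer)
        sums[key] = sums.get(key, 0.0) + rec.value
        counts[key] = counts.get(key, 0) + 1
        per_replica_keys.setdefault(rec.replica, set()).add(key)
    if not sums:
        raise DataError("no observables to average")
    keysets = list(per_replica_keys.values())
    if any(ks != keysets[0] for ks in keysets[1:]):
        raise DataError("replicas supply different observable keys")
    return {k: sums[k] / counts[k] for k in sums}


# ---------------------------------------------------------------------------
# energy and agreement statistics

@dataclass
class RestraintReport:
    total_energy: float
    per_observable: pd.DataFrame  # residue, kind, protomer, calc, obs, error, deviation, energy
    q_csa: Optional[float]
    q_dc: Optional[float]
    rmsd_csa: Optional[float]
    rmsd_dc: Optional[float]
    sd_csa: Optional[float]
    sd_dc: Optional[float]

    def as_dict(self) -> dict:
        return {
            "total_energy": self.total_energy,
            "q_csa": self.q_csa, "q_dc": self.q_dc,
            "rmsd_csa": self.rmsd_csa, "rmsd_dc": self.rmsd_dc,
            "sd_csa": self.sd_csa, "sd_dc": self.sd_dc,
            "per_observable": self.per_observable.to_dict(orient="records"),
        }


def flat_bottom_energy(deviation: float, error: float, alpha: float,
                       ramp_fraction: float) -> float:
    """Single-observable flat-bottom harmonic energy (J/mol)."""
    excess = abs(deviation) - error
    if excess <= 0.0:
        return 0.0
    return ramp_fraction * alpha * excess * excess


def restraint_energy(avg: Mapping, obs: ObservableTable, cfg: RestraintConfig,
                     ramp_fraction: float = 1.0) -> RestraintReport:
    """Evaluate the flat-bottom restraint for averaged values against the
    experimental table.

    ``avg`` maps ``(residue, kind)`` or ``(residue, kind, protomer)`` keys
    to averaged back-calculated values; every key must have a matching
    experimental record.
    """
    if ramp_fraction < 0:
        raise ConfigError("ramp_fraction must be >= 0")
    table = obs.lookup()
    rows = []
    total = 0.0
    for key, calc in avg.items():
        residue, kind = key[0], key[1]
        protomer = key[2] if len(key) > 2 else ""
        if (residue, kind) not in table:
            raise DataError(f"no experimental record for residue {residue} {kind}")
        value, error = table[(residue, kind)]
        dev = calc - value
        e = flat_bottom_energy(dev, error, cfg.alpha(kind), ramp_fraction)
        total += e
        rows.append((residue, kind, protomer, calc, value, error, dev, e))
    if not rows:
        raise DataError("no averaged observables supplied")
    df = pd.DataFrame(rows, columns=["residue", "kind", "protomer", "calc",
                                     "obs", "error", "deviation", "energy"])
    stats = {}
    for kind in KINDS:
        sub = df[df["kind"] == kind]
        if len(sub):
            stats[kind] = _agreement(sub["calc"].to_numpy(), sub["obs"].to_numpy())
        else:
            stats[kind] = (None, None, None)
    return RestraintReport(
        total_energy=total, per_observable=df,
        q_csa=stats["CSA"][0], q_dc=stats["DC"][0],
        rmsd_csa=stats["CSA"][1], rmsd_dc=stats["DC"][1],
        sd_csa=stats["CSA"][2], sd_dc=stats["DC"][2],
    )


def _agreement(calc: np.ndarray, obs: np.ndarray):
    denom = float(np.sum(obs * obs))
    if denom == 0.0:
        raise DataError("Q factor undefined: observed values are all zero")
    dev = calc - obs
    q = math.sqrt(float(np.sum(dev * dev))) / math.sqrt(denom)
    rmsd = math.sqrt(float(np.mean(dev * dev)))
    sd = float(np.std(dev))
    return q, rmsd, sd


def q_factor(calc: Mapping, obs: ObservableTable) -> dict:
    """Per-kind agreement of averaged values with the table.

    Returns ``{kind: {"q", "rmsd", "sd", "n"}}`` for kinds with at least one
    matched observable. Q = RMS(calc - obs) / RMS(obs).
    """
    table = obs.lookup()
    out = {}
    for kind in KINDS:
        pairs = [(v, table[(k[0], kind)][0]) for k, v in calc.items()
                 if k[1] == kind and (k[0], kind) in table]
        if not pairs:
            continue
        c = np.array([p[0] for p in pairs])
        o = np.array([p[1] for p in pairs])
        q, rmsd, sd = _agreement(c, o)
        out[kind] = {"q": q, "rmsd": rmsd, "sd": sd, "n": len(pairs)}
    if not out:
        raise DataError("no matched observables for any kind")
    return out


# ---------------------------------------------------------------------------
# analytic gradient of the total restraint energy

def ensemble_restraint_energy(ens: ReplicaEnsemble, obs: ObservableTable,
                              cfg: RestraintConfig,
                              tp: TensorParameters = TensorParameters(),
                              dp: DCParameters = DCParameters(),
                              ramp_fraction: float = 1.0) -> RestraintReport:
    """Back-calculate, average per ``cfg.averaging`` and score in one call."""
    calc = backcalc_table(ens, tp, dp)
    avg = average_observables(calc, cfg.averaging)
    return restraint_energy(avg, obs, cfg, ramp_fraction)


def restraint_gradient(ens: ReplicaEnsemble, obs: ObservableTable,
                       cfg: RestraintConfig,
                       tp: TensorParameters = TensorParameters(),
                       dp: DCParameters = DCParameters(),
                       ramp_fraction: float = 1.0) -> list[np.ndarray]:
    """Gradient of the total restraint energy w.r.t. every backbone atom.

    Returns one array of shape (P, R, 5, 3) per replica (atom order N, H,
    CA, C, O; only N, H and the preceding C' receive CSA/DC forces). Through
    the averaging each copy's contribution is scaled by 1/(M*P) (combined
    scheme) or 1/M (pure replica scheme).
    """
    if ramp_fraction < 0:
        raise ConfigError("ramp_fraction must be >= 0")
    M, P = ens.M, ens.P
    scheme = cfg.averaging
    calc = backcalc_table(ens, tp, dp)
    avg = average_observables(calc, scheme)
    table = obs.lookup()

    # d(total)/d(avg_key): zero inside the flat bottom
    coef = {}
    for key, value in avg.items():
        residue, kind = key[0], key[1]
        if (residue, kind) not in table:
            raise DataError(f"no experimental record for residue {residue} {kind}")
        target, error = table[(residue, kind)]
        dev = value - target
        excess = abs(dev) - error
        if excess > 0.0:
            coef[key] = (2.0 * ramp_fraction * cfg.alpha(kind)
                         * excess * math.copysign(1.0, dev))

    grads = [np.zeros((P, len(ens.replicas[0].protomers[0].residues), 5, 3))
             for _ in range(M)]
    if not coef:
        return grads

    weight = 1.0 / (M * P) if scheme == "replica_internal" else 1.0 / M
    pos = {idx: i for i, idx in enumerate(ens.replicas[0].residue_indices)}
    elig = eligible_residues(ens.replicas[0])
    for m, olig in enumerate(ens.replicas):
        for p, prot in enumerate(olig.protomers):
            bynum = {r.index: r for r in prot.residues}
            for ridx in elig:
                res, prev = bynum[ridx], bynum[ridx - 1]
                i, iprev = pos[ridx], pos[ridx - 1]
                key_extra = () if scheme == "replica_internal" else (prot.chain_id,)
                ck = (ridx, "CSA") + key_extra
                if ck in coef:
                    _, gc, gn, gh = csa_value_grad(
                        prev.c, res.n, res.hn, tp.deltas_for(res.name),
                        tp.pas_tilt_deg)
                    w = coef[ck] * weight
                    grads[m][p, iprev, 3] += w * gc
                    grads[m][p, i, 0] += w * gn
                    grads[m][p, i, 1] += w * gh
                dk = (ridx, "DC") + key_extra
                if dk in coef:
                    _, gn, gh = dc_value_grad(res.n, res.hn, dp.zeta_dc)
                    w = coef[dk] * weight
                    grads[m][p, i, 0] += w * gn
                    grads[m][p, i, 1] += w * gh
    return grads
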