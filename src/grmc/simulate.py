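"""Loop-anchored harmonic chain ("Generalized Rouse Model for Chromosomes").

The chromosome segment is a bead-spring chain of N loci with backbone springs
of constant ``kappa`` plus extra harmonic cross-links of constant ``omega``
between CTCF/cohesin loop-anchor pairs.  Because the model is harmonic (and
has no excluded volume — chain crossing is attributed to topoisomerase
activity), it is exactly solvable: the connectivity matrix A is diagonalized
into normal modes, each pair vector is an isotropic Gaussian, and the per-axis
variance of the m-n separation is

    sigma_mn^2 = sum_{p: lambda_p < 0} (V_pm - V_pn)^2 * kT / (-lambda_p),

with the single zero mode (uniform translation) contributing nothing.  The
mean distance follows as <R_mn> = 2*sqrt(2/pi)*sigma_mn.

The same system can be sampled by underdamped Langevin dynamics (BAOAB
splitting).  Two bond conventions are supported: ``rest_length_mode="zero"``
matches the analytic Gaussian theory exactly, while ``"a"`` uses finite rest
length ``a`` in both backbone and loop springs.  Trajectory estimators count
contacts within a threshold ``r_c`` and average pair distances over snapshots
and independent trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from numba import njit

from .theory import mean_from_sigma

__all__ = [
    "LoopSet",
    "GRMCSystem",
    "Trajectory",
    "TrajectoryStats",
    "build_connectivity",
    "analytic_pair_sigma",
    "analytic_mean_distance",
    "sample_equilibrium",
    "langevin_run",
    "estimate_stats",
    "binned_P_vs_R",
]


@dataclass(frozen=True)
class LoopSet:
    """Unordered set of loop-anchor index pairs {p, q}, 0-based, non-adjacent."""

    anchors: tuple

    def __init__(self, anchors: Iterable[Sequence[int]] = ()):
        pairs = set()
        for p, q in anchors:
            p, q = int(p), int(q)
            if p == q:
                raise ValueError(f"self-pair ({p}, {q}) is not a loop")
            lo, hi = min(p, q), max(p, q)
            if hi - lo <= 1:
                raise ValueError(
                    f"anchors ({p}, {q}) are adjacent; loops need |p - q| > 1"
                )
            pairs.add((lo, hi))
        object.__setattr__(self, "anchors", tuple(sorted(pairs)))

    def __len__(self):
        return len(self.anchors)

    def __iter__(self):
        return iter(self.anchors)

    def validate(self, N: int):
        for p, q in self.anchors:
            if not (0 <= p < N and 0 <= q < N):
                raise ValueError(f"loop anchor ({p}, {q}) out of range for N={N}")

    def counts(self, N: int) -> np.ndarray:
        """|Sigma_m|: number of loops attached to each locus."""
        c = np.zeros(N, dtype=int)
        for p, q in self.anchors:
            c[p] += 1
            c[q] += 1
        return c


@dataclass(frozen=True)
class GRMCSystem:
    """Physical definition of one loop-anchored chain.

    Lengths are in units of the bond length ``a`` and energies in ``kT`` by
    default (kT = 1, a = 1); real units work equally as long as they are
    consistent.  ``rest_length_mode="zero"`` gives the exactly Gaussian chain;
    ``"a"`` gives finite-rest-length springs.
    """

    N: int
    loops: LoopSet = field(default_factory=LoopSet)
    a: float = 1.0
    kappa: float = 100.0
    omega: float = 100.0
    xi: float = 0.1
    kT: float = 1.0
    mass: float = 1.0
    rest_length_mode: str = "zero"

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("need at least two loci")
        if min(self.kappa, self.omega, self.xi, self.mass) <= 0 or self.kT < 0:
            raise ValueError("kappa, omega, xi, mass must be positive and kT >= 0")
        if self.rest_length_mode not in ("zero", "a"):
            raise ValueError("rest_length_mode must be 'zero' or 'a'")
        self.loops.validate(self.N)

    def bonds(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Flat bond arrays (i, j, spring constant, rest length) for the integrator."""
        n_chain = self.N - 1
        i = np.concatenate([np.arange(n_chain), [p for p, _ in self.loops]]).astype(np.int64)
        j = np.concatenate([np.arange(1, self.N), [q for _, q in self.loops]]).astype(np.int64)
        k = np.concatenate(
            [np.full(n_chain, self.kappa), np.full(len(self.loops), self.omega)]
        )
        r0_val = 0.0 if self.rest_length_mode == "zero" else self.a
        r0 = np.full(i.size, r0_val)
        return i, j, k, r0


def build_connectivity(system: GRMCSystem) -> np.ndarray:
    """Connectivity matrix A: backbone couplings kappa, loop couplings omega.

    Off-diagonal entries are ``kappa`` for chain neighbors and ``omega`` for
    loop-anchor pairs; diagonal entries make every row sum to zero (interior
    loci get ``-2*kappa - |Sigma_m|*omega``, chain ends ``-kappa - |Sigma_m|*omega``).
    A is symmetric negative semidefinite with exactly one zero eigenvalue for
    a connected chain.
    """
    N = system.N
    A = np.zeros((N, N))
    idx = np.arange(N - 1)
    A[idx, idx + 1] = system.kappa
    A[idx + 1, idx] = system.kappa
    for p, q in system.loops:
        A[p, q] += system.omega
        A[q, p] += system.omega
    A[np.diag_indices(N)] = -A.sum(axis=1)
    return A


def _spectral(system: GRMCSystem) -> tuple[np.ndarray, np.ndarray]:
    A = build_connectivity(system)
    eigvals, eigvecs = np.linalg.eigh(A)  # columns of eigvecs are modes
    tol = 1e-9 * max(system.kappa, system.omega) * system.N
    n_zero = int(np.sum(np.abs(eigvals) < tol))
    if n_zero != 1:
        raise ValueError(
            f"connectivity has {n_zero} (near-)zero eigenvalues; "
            "the chain must be a single connected component"
        )
    return eigvals, eigvecs


def analytic_pair_sigma(system: GRMCSystem) -> np.ndarray:
    """Exact per-axis standard deviation sigma_mn for every locus pair.

    From the normal modes: ``sigma_mn^2 = sum_p (V_pm - V_pn)^2 kT/(-lambda_p)``
    over the negative modes (the zero translation mode has a uniform
    eigenvector, so its contribution vanishes identically).  Returns an (N, N)
    symmetric matrix with zero diagonal.
    """
    eigvals, eigvecs = _spectral(system)
    neg = eigvals < -1e-9 * max(system.kappa, system.omega) * system.N
    # rows of B are loci coordinates in the mode basis scaled by sqrt(kT/-lambda)
    B = eigvecs[:, neg] * np.sqrt(system.kT / (-eigvals[neg]))[None, :]
    sq = np.sum(B**2, axis=1)
    sigma2 = sq[:, None] + sq[None, :] - 2.0 * (B @ B.T)
    np.fill_diagonal(sigma2, 0.0)
    return np.sqrt(np.clip(sigma2, 0.0, None))


def analytic_mean_distance(system: GRMCSystem) -> np.ndarray:
    """Exact mean pair distances <R_mn> = 2*sqrt(2/pi)*sigma_mn."""
    return mean_from_sigma(analytic_pair_sigma(system))


def sample_equilibrium(system: GRMCSystem, rng: np.random.Generator) -> np.ndarray:
    """Draw one exact equilibrium configuration (rest-length-zero statistics).

    Mode amplitudes are independent Gaussians with variance kT/(-lambda_p);
    the zero (center-of-mass) mode is pinned at the origin.  For
    ``rest_length_mode="a"`` this is only an approximate starting point and a
    burn-in is still required.
    """
    eigvals, eigvecs = _spectral(system)
    neg = eigvals < -1e-9 * max(system.kappa, system.omega) * system.N
    std = np.sqrt(system.kT / (-eigvals[neg]))
    X = rng.normal(size=(neg.sum(), 3)) * std[:, None]
    return eigvecs[:, neg] @ X


@njit(cache=True)
def _forces(x, bond_i, bond_j, bond_k, bond_r0, f):
    f[:] = 0.0
    for b in range(bond_i.size):
        i = bond_i[b]
        j = bond_j[b]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        if bond_r0[b] == 0.0:
            fx = -bond_k[b] * dx
            fy = -bond_k[b] * dy
            fz = -bond_k[b] * dz
        else:
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < 1e-12:
                continue
            coef = -bond_k[b] * (r - bond_r0[b]) / r
            fx = coef * dx
            fy = coef * dy
            fz = coef * dz
        f[i, 0] += fx
        f[i, 1] += fy
        f[i, 2] += fz
        f[j, 0] -= fx
        f[j, 1] -= fy
        f[j, 2] -= fz


@njit(cache=True)
def _baoab(x, v, bond_i, bond_j, bond_k, bond_r0, mass, xi, kT, dt, n_snap, save_every, seed):
    """BAOAB Langevin integrator; returns (n_snap, N, 3) position snapshots."""
    np.random.seed(seed)
    N = x.shape[0]
    out = np.empty((n_snap, N, 3))
    vout = np.empty((n_snap, N, 3))
    f = np.empty((N, 3))
    _forces(x, bond_i, bond_j, bond_k, bond_r0, f)
    c1 = np.exp(-xi * dt / mass)
    c2 = np.sqrt(kT / mass * (1.0 - c1 * c1))
    half = 0.5 * dt
    for s in range(n_snap):
        for _ in range(save_every):
            for i in range(N):
                for d in range(3):
                    v[i, d] += half * f[i, d] / mass
                    x[i, d] += half * v[i, d]
            for i in range(N):
                for d in range(3):
                    v[i, d] = c1 * v[i, d] + c2 * np.random.normal()
                    x[i, d] += half * v[i, d]
            _forces(x, bond_i, bond_j, bond_k, bond_r0, f)
            for i in range(N):
                for d in range(3):
                    v[i, d] += half * f[i, d] / mass
        out[s] = x
        vout[s] = v
    return out, vout


@dataclass
class Trajectory:
    """Position and velocity snapshots (T, N, 3) of one Langevin run plus provenance."""

    positions: np.ndarray
    dt: float
    save_every: int
    seed: int
    system: GRMCSystem
    velocities: Optional[np.ndarray] = None

    def kinetic_temperature(self) -> float:
        """Per-axis kinetic temperature m<v_alpha^2> averaged over snapshots."""
        if self.velocities is None:
            raise ValueError("trajectory was saved without velocities")
        return float(self.system.mass * np.mean(self.velocities**2))

    @property
    def n_snapshots(self) -> int:
        return self.positions.shape[0]


def langevin_run(
    system: GRMCSystem,
    n_steps: int,
    dt: Optional[float] = None,
    save_every: int = 1000,
    seed: int = 0,
    n_equil_steps: int = 0,
    x0: Optional[np.ndarray] = None,
) -> Trajectory:
    """Run underdamped Langevin dynamics and return saved snapshots.

    ``dt`` defaults to ``0.01*sqrt(mass/max(kappa, omega))``, well inside the
    stability limit of the stiffest bond.  For rest-length-zero systems the
    initial configuration is drawn from the exact equilibrium ensemble (so no
    burn-in is needed); otherwise a random-walk start plus ``n_equil_steps``
    of discarded dynamics is used.  Runs with the same seed are bit-identical.
    """
    if dt is None:
        dt = 0.01 * np.sqrt(system.mass / max(system.kappa, system.omega))
    if n_steps < save_every:
        raise ValueError("n_steps must be at least save_every")
    rng = np.random.default_rng(seed)
    if x0 is not None:
        x = np.array(x0, dtype=float)
        if x.shape != (system.N, 3):
            raise ValueError(f"x0 must have shape ({system.N}, 3)")
    elif system.rest_length_mode == "zero":
        x = sample_equilibrium(system, rng)
    else:
        steps = rng.normal(size=(system.N - 1, 3))
        steps *= system.a / np.linalg.norm(steps, axis=1)[:, None]
        x = np.concatenate([np.zeros((1, 3)), np.cumsum(steps, axis=0)])
    v = rng.normal(size=(system.N, 3)) * np.sqrt(system.kT / system.mass)
    bi, bj, bk, br0 = system.bonds()
    # numba's legacy RNG takes 32-bit seeds
    nb_seed = int(rng.integers(0, 2**31 - 1))
    if n_equil_steps > 0:
        burn, _ = _baoab(
            x, v, bi, bj, bk, br0, system.mass, system.xi, system.kT, dt,
            1, int(n_equil_steps), nb_seed,
        )
        if not np.all(np.isfinite(burn)):
            raise FloatingPointError(
                f"burn-in diverged (dt={dt}, kappa={system.kappa}); reduce dt"
            )
        nb_seed = int(rng.integers(0, 2**31 - 1))
    n_snap = n_steps // save_every
    pos, vel = _baoab(
        x, v, bi, bj, bk, br0, system.mass, system.xi, system.kT, dt,
        n_snap, int(save_every), nb_seed,
    )
    if not np.all(np.isfinite(pos)):
        bad = int(np.argmax(~np.isfinite(pos).all(axis=(1, 2))))
        raise FloatingPointError(
            f"trajectory diverged at snapshot {bad} (dt={dt}, kappa={system.kappa}, "
            f"omega={system.omega}); reduce dt"
        )
    return Trajectory(
        positions=pos, dt=dt, save_every=save_every, seed=seed, system=system,
        velocities=vel,
    )


@dataclass
class TrajectoryStats:
    """Pairwise contact/distance estimators pooled over M independent trajectories.

    ``P[m, n]`` is the fraction of snapshots with |r_m - r_n| <= r_c;
    ``R_mean`` the average pair distance; ``R2_mean`` the average squared
    distance (so ``R2_mean/3`` estimates the per-axis variance sigma_mn^2 for
    rest-length-zero chains).  Per-trajectory matrices support standard-error
    estimates across independent runs.
    """

    M: int
    T: int
    r_c: float
    P: np.ndarray
    R_mean: np.ndarray
    R2_mean: np.ndarray
    per_traj_R_mean: np.ndarray
    per_traj_R2_mean: np.ndarray
    per_traj_P: np.ndarray

    def pairs_dataframe(self) -> pd.DataFrame:
        """Long-format (m, n, P_mn, R_mn_mean) table over the upper triangle."""
        N = self.P.shape[0]
        m, n = np.triu_indices(N, k=1)
        return pd.DataFrame(
            {"m": m, "n": n, "P_mn": self.P[m, n], "R_mn_mean": self.R_mean[m, n]}
        )


def _pairwise_accumulate(pos: np.ndarray, r_c: float, chunk: int = 64):
    """Sum over snapshots of contact indicators, distances, squared distances."""
    T, N, _ = pos.shape
    cnt = np.zeros((N, N))
    rsum = np.zeros((N, N))
    r2sum = np.zeros((N, N))
    for start in range(0, T, chunk):
        x = pos[start : start + chunk]
        d = x[:, :, None, :] - x[:, None, :, :]
        r2 = np.einsum("tmnk,tmnk->tmn", d, d)
        r = np.sqrt(r2)
        cnt += (r <= r_c).sum(axis=0)
        rsum += r.sum(axis=0)
        r2sum += r2.sum(axis=0)
    return cnt, rsum, r2sum


def estimate_stats(
    trajectories: Union[Trajectory, Sequence[Trajectory]], r_c: float
) -> TrajectoryStats:
    """Contact probability and mean-distance estimators over snapshots.

    ``P_mn = (1/TM) sum_a sum_t 1[|r_m - r_n| <= r_c]`` and
    ``<R_mn> = (1/TM) sum_a sum_t |r_m - r_n|`` over M trajectories of T
    snapshots each.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if len(trajectories) == 0:
        raise ValueError("need at least one trajectory")
    if not r_c > 0:
        raise ValueError("r_c must be positive")
    T = trajectories[0].n_snapshots
    N = trajectories[0].positions.shape[1]
    M = len(trajectories)
    P_t = np.empty((M, N, N))
    R_t = np.empty((M, N, N))
    R2_t = np.empty((M, N, N))
    for a, traj in enumerate(trajectories):
        if traj.n_snapshots != T or traj.positions.shape[1] != N:
            raise ValueError("all trajectories must share T and N")
        cnt, rsum, r2sum = _pairwise_accumulate(traj.positions, r_c)
        P_t[a] = cnt / T
        R_t[a] = rsum / T
        R2_t[a] = r2sum / T
    # identical diagonals (r=0) count as contacts; zero them for clarity
    for arr in (P_t, R_t, R2_t):
        arr[:, np.arange(N), np.arange(N)] = 0.0
    return TrajectoryStats(
        M=M,
        T=T,
        r_c=r_c,
        P=P_t.mean(axis=0),
        R_mean=R_t.mean(axis=0),
        R2_mean=R2_t.mean(axis=0),
        per_traj_R_mean=R_t,
        per_traj_R2_mean=R2_t,
        per_traj_P=P_t,
    )


def binned_P_vs_R(
    stats: TrajectoryStats,
    bin_width: float = 0.25,
    log: bool = True,
    min_count: int = 1,
    min_P: float = 0.0,
) -> pd.DataFrame:
    """Bin (P_mn, <R_mn>) points over P and average <R_mn> within each bin.

    Bins have width ``bin_width`` (in log10(P) by default, in P if
    ``log=False``), each centered at P and spanning [P - w/2, P + w/2].
    Returns a table with the bin center, the mean P and mean <R> of the
    members, and the member count; empty bins are omitted.
    """
    df = stats.pairs_dataframe()
    df = df[df.P_mn > max(min_P, 0.0)]
    if df.empty:
        raise ValueError("no pairs above min_P to bin")
    x = np.log10(df.P_mn.values) if log else df.P_mn.values
    lo = np.floor(x.min() / bin_width) * bin_width
    idx = np.floor((x - lo) / bin_width).astype(int)
    rows = []
    for b in np.unique(idx):
        sel = idx == b
        if sel.sum() < min_count:
            continue
        center = lo + (b + 0.5) * bin_width
        rows.append(
            {
                "P_center": 10**center if log else center,
                "P_mean": df.P_mn.values[sel].mean(),
                "R_mean": df.R_mn_mean.values[sel].mean(),
                "count": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)
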