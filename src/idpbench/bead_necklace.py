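"""One-bead-per-residue "bead-necklace" Monte Carlo model of an IDP.

The chain is a necklace of hard spheres (radius 2 A) joined by harmonic
bonds (equilibrium length 4.1 A, force constant 0.4 N/m).  Beads carry
fixed integer charges in {-1, 0, +1}; every chain charge is neutralized by
an explicit counterion (hard sphere, radius 2 A, charge -/+1).  Non-bonded
interactions are an extended Debye-Hueckel potential that accounts for the
particles' finite size,

    u_el(r) = lB * z_i * z_j * exp(-kappa (r - a_i - a_j))
              / ( r (1 + kappa a_i)(1 + kappa a_j) )        [kT]

plus, between chain beads only, a uniform soft short-range attraction
-eps (sigma_c / r)**6 that equals -0.6 kT at closest contact
(sigma_c = 4 A).  Added salt enters implicitly through the inverse Debye
length kappa; counterions are explicit.

Sampling is canonical-ensemble Metropolis Monte Carlo in a cubic box with
periodic boundaries and the minimum image convention.  Trial moves:
single-particle translation (chain beads and counterions, 17x more likely
than each of the other move classes), pivot rotation of the shorter chain
segment, rigid chain translation, and the slithering (reptation) move.
The regrown slither bond is drawn from the exact radial Boltzmann density
of the harmonic bond, and the corresponding bond-energy bias is divided
out of the Metropolis ratio, so the move satisfies detailed balance for a
flexible bond.  One cycle is one attempted move per mobile particle.
Coordinates are kept unwrapped; periodicity only enters through
minimum-image distances.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SimulationConfig",
    "SystemState",
    "Trajectory",
    "ConvergenceReport",
    "debye_parameters",
    "bond_force_constant_kT",
    "bond_energy",
    "pair_energy",
    "total_energy",
    "radius_of_gyration",
    "MonteCarloEngine",
    "run_simulation",
    "write_trajectory",
    "counterion_rdf",
    "statistical_inefficiency",
    "convergence_report",
]

# CODATA 2018
_E_CHARGE = 1.602176634e-19  # C
_EPS0 = 8.8541878128e-12  # F/m
_KB = 1.380649e-23  # J/K
_NA = 6.02214076e23  # 1/mol

MOVE_TYPES = ("single_bead", "pivot", "chain_translate", "slither", "ion_translate")


@dataclass
class SimulationConfig:
    """All bead-necklace parameters.  Lengths in Angstrom, energies in kT.

    ``bond_force_constant`` is in N/m (0.4 N/m ~ 0.97 kT/A^2 at 298 K).
    ``box_side`` of ``None`` means 1.1x the chain contour length, chosen at
    set-up.  ``move_weights`` gives the relative probability of each trial
    move *class*; the single-particle class covers chain beads and
    counterions alike, so every mobile particle is attempted with the same
    frequency.
    """

    bead_radius: float = 2.0
    ion_radius: float = 2.0
    bond_r0: float = 4.1
    bond_force_constant: float = 0.4  # N/m
    attraction_contact: float = 0.6  # kT, depth at closest chain-chain contact
    salt_mM: float = 150.0
    temperature_K: float = 298.0
    relative_permittivity: float = 78.4
    box_side: float | None = None
    move_weights: dict[str, float] = field(
        default_factory=lambda: {
            "single_bead": 17.0,
            "pivot": 1.0,
            "chain_translate": 1.0,
            "slither": 1.0,
        }
    )
    max_displacement: dict[str, float] = field(
        default_factory=lambda: {
            "bead": 1.5,
            "ion": 5.0,
            "chain": 2.0,
            "pivot_angle": math.pi / 2,
        }
    )
    n_equil_cycles: int = 200_000
    n_prod_cycles: int = 1_000_000
    sample_interval: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bead_radius", "ion_radius", "bond_r0", "temperature_K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.relative_permittivity <= 0:
            raise ValueError("relative_permittivity must be > 0")
        if self.salt_mM < 0:
            raise ValueError("salt_mM must be >= 0")
        if self.move_weights.get("single_bead", 0.0) <= 0:
            raise ValueError("single_bead move weight must be nonzero")
        if any(w < 0 for w in self.move_weights.values()):
            raise ValueError("move weights must be >= 0")


def debye_parameters(
    salt_mM: float, temperature_K: float = 298.0, relative_permittivity: float = 78.4
) -> tuple[float, float]:
    """Bjerrum length (A) and inverse Debye length kappa (1/A) for 1:1 salt.

    lB = e^2 / (4 pi eps0 eps_r kB T);  kappa^2 = 8 pi lB n_salt with
    n_salt the salt pair number density.  kappa is exactly 0 at 0 mM.
    """
    if relative_permittivity <= 0:
        raise ValueError("relative_permittivity must be > 0")
    if temperature_K <= 0:
        raise ValueError("temperature_K must be > 0")
    if salt_mM < 0:
        raise ValueError("salt_mM must be >= 0")
    lb_m = _E_CHARGE**2 / (4 * math.pi * _EPS0 * relative_permittivity * _KB * temperature_K)
    bjerrum = lb_m * 1e10  # Angstrom
    n_salt = salt_mM * 1e-3 * _NA * 1e-27  # pairs per A^3 (mM -> mol/L -> 1/A^3)
    kappa = math.sqrt(8 * math.pi * bjerrum * n_salt)
    return bjerrum, kappa


def bond_force_constant_kT(force_constant_N_per_m: float, temperature_K: float) -> float:
    """Convert a harmonic force constant from N/m to kT/A^2."""
    return force_constant_N_per_m * 1e-20 / (_KB * temperature_K)


def box_side_for(n_beads: int, config: SimulationConfig) -> float:
    """Effective cubic box side: configured value, or the default
    1.1x contour length with a floor of six bond lengths."""
    if config.box_side is not None:
        return config.box_side
    return max(1.1 * (n_beads - 1) * config.bond_r0, 6.0 * config.bond_r0)


def bond_energy(r, config: SimulationConfig):
    """Harmonic bond energy (k/2)(r - r0)^2 in kT."""
    k = bond_force_constant_kT(config.bond_force_constant, config.temperature_K)
    r = np.asarray(r, dtype=float)
    u = 0.5 * k * (r - config.bond_r0) ** 2
    return float(u) if u.ndim == 0 else u


def pair_energy(kind: str, z_i: int, z_j: int, r: float, config: SimulationConfig) -> float:
    """Non-bonded pair energy in kT; ``inf`` flags a hard-sphere overlap.

    ``kind`` selects the radii: "chain-chain", "chain-ion" or "ion-ion".
    The short-range attraction applies to chain-chain pairs only.
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    radii = {
        "chain-chain": (config.bead_radius, config.bead_radius),
        "chain-ion": (config.bead_radius, config.ion_radius),
        "ion-ion": (config.ion_radius, config.ion_radius),
    }
    try:
        a_i, a_j = radii[kind]
    except KeyError:
        raise ValueError(f"kind must be one of {sorted(radii)}, got {kind!r}") from None
    if r < a_i + a_j:
        return math.inf
    bjerrum, kappa = debye_parameters(
        config.salt_mM, config.temperature_K, config.relative_permittivity
    )
    u = 0.0
    if z_i and z_j:
        u += (
            bjerrum
            * z_i
            * z_j
            * math.exp(-kappa * (r - a_i - a_j))
            / (r * (1 + kappa * a_i) * (1 + kappa * a_j))
        )
    if kind == "chain-chain" and config.attraction_contact:
        sigma_c = a_i + a_j
        u -= config.attraction_contact * (sigma_c / r) ** 6
    return u


@dataclass
class SystemState:
    """One snapshot: chain and counterion coordinates plus the energy ledger."""

    chain_coords: np.ndarray  # (n_beads, 3), Angstrom, unwrapped
    counterion_coords: np.ndarray  # (n_ions, 3)
    counterion_charges: np.ndarray  # (n_ions,), +/-1
    per_bead_charge: np.ndarray  # (n_beads,)
    total_energy: float  # kT

    @property
    def n_beads(self) -> int:
        return len(self.chain_coords)

    @property
    def n_ions(self) -> int:
        return len(self.counterion_coords)


@dataclass
class Trajectory:
    """Sampled output of one Monte Carlo run."""

    frames: list[SystemState]
    cycles: np.ndarray  # production cycle index of each sample
    rg_series: np.ndarray  # Angstrom
    energy_series: np.ndarray  # kT
    acceptance_stats: dict[str, tuple[int, int]]  # move -> (attempted, accepted)
    config: SimulationConfig

    @property
    def mean_rg(self) -> float:
        return float(np.mean(self.rg_series))

    def acceptance_fraction(self, move: str) -> float:
        att, acc = self.acceptance_stats[move]
        return acc / att if att else float("nan")


def radius_of_gyration(chain_coords: np.ndarray) -> float:
    """Unweighted Rg over chain beads: sqrt(mean |r_i - r_mean|^2)."""
    centered = chain_coords - chain_coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotation_matrix(axis: np.ndarray, theta: float) -> np.ndarray:
    """Rodrigues rotation about ``axis`` (unit vector) by ``theta``."""
    x, y, z = axis
    c, s = math.cos(theta), math.sin(theta)
    cc = 1 - c
    return np.array(
        [
            [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
            [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
            [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
        ]
    )


class MonteCarloEngine:
    """Metropolis sampler for one chain plus its counterions.

    The engine keeps a running total energy updated from accepted
    incremental energy differences; ``full_energy()`` recomputes it from
    scratch for drift checks.  Pairwise interaction prefactors are
    precomputed as dense matrices, so per-move energies are vectorized
    array expressions.
    """

    def __init__(
        self,
        per_bead_charge: Sequence[int],
        config: SimulationConfig,
        rng: np.random.Generator | None = None,
    ):
        q = np.asarray(per_bead_charge, dtype=int)
        if q.ndim != 1 or len(q) < 2:
            raise ValueError("need at least 2 beads")
        if np.any(np.abs(q) > 1):
            raise ValueError("per-bead charges must be in {-1, 0, +1}")
        ion_q = -q[q != 0]  # one opposite unit charge per chain charge
        self._setup(q, ion_q, config)
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)

        weights = dict(config.move_weights)
        if self.n < 3:
            weights["pivot"] = 0.0
            weights["slither"] = 0.0
        self._move_names = [k for k, w in weights.items() if w > 0]
        w = [weights[k] for k in self._move_names]
        tot = sum(w)
        self._move_probs = [x / tot for x in w]
        self._move_cum = list(np.cumsum(self._move_probs))
        self.attempted = {k: 0 for k in MOVE_TYPES}
        self.accepted = {k: 0 for k in MOVE_TYPES}

        self.coords = np.empty((self.M, 3))
        self._place_initial()
        self.energy = self.full_energy()
        if not np.isfinite(self.energy):
            raise RuntimeError("initial configuration has a hard overlap")

    def _setup(self, q: np.ndarray, ion_q: np.ndarray, config: SimulationConfig) -> None:
        """Geometry, interaction matrices and bond-length sampler."""
        self.config = config
        self.n = len(q)
        self.m = len(ion_q)
        self.M = self.n + self.m
        self.charge = np.concatenate([q, ion_q]).astype(float)
        self.radius = np.concatenate(
            [np.full(self.n, config.bead_radius), np.full(self.m, config.ion_radius)]
        )
        self.is_chain = np.zeros(self.M, dtype=bool)
        self.is_chain[: self.n] = True

        contour = (self.n - 1) * config.bond_r0
        self.box = box_side_for(self.n, config)
        if self.box < contour:
            raise ValueError(
                f"box_side {self.box:.1f} A smaller than contour length {contour:.1f} A"
            )
        self.bjerrum, self.kappa = debye_parameters(
            config.salt_mM, config.temperature_K, config.relative_permittivity
        )
        self.bond_k = bond_force_constant_kT(config.bond_force_constant, config.temperature_K)
        self.eps_sr = config.attraction_contact

        # dense pair matrices: contact distance, screened-Coulomb prefactor
        # B_ij = lB z_i z_j / ((1+k a_i)(1+k a_j)), attraction numerator
        # A6_ij = eps (a_i + a_j)^6 for chain-chain pairs
        a = self.radius
        self._contact = a[:, None] + a[None, :]
        self._contact2 = self._contact**2
        np.fill_diagonal(self._contact2, 0.0)  # a particle never overlaps itself
        denom = 1.0 / ((1.0 + self.kappa * a)[:, None] * (1.0 + self.kappa * a)[None, :])
        self._B = self.bjerrum * np.outer(self.charge, self.charge) * denom
        np.fill_diagonal(self._B, 0.0)
        cc = self.is_chain[:, None] & self.is_chain[None, :]
        self._A6 = np.where(cc, self.eps_sr * self._contact**6, 0.0)
        np.fill_diagonal(self._A6, 0.0)
        self._nzB = [np.nonzero(self._B[i])[0] for i in range(self.M)]
        iu = np.triu_indices(self.M, k=1)
        self._triu = iu
        self._triu_contact2 = self._contact2[iu]
        self._triu_contact = self._contact[iu]
        self._triu_B = self._B[iu]
        self._triu_A6 = self._A6[iu]
        icu = np.triu_indices(self.n, k=1)
        self._ctriu = icu
        self._ctriu_contact2 = self._contact2[: self.n, : self.n][icu]
        self._ctriu_contact = self._contact[: self.n, : self.n][icu]
        self._ctriu_B = self._B[: self.n, : self.n][icu]
        self._ctriu_A6 = self._A6[: self.n, : self.n][icu]

        # inverse CDF of the radial bond density p(r) ~ r^2 exp(-k(r-r0)^2/2),
        # used by the slithering move
        width = 12.0 / math.sqrt(self.bond_k)
        grid = np.linspace(max(1e-6, config.bond_r0 - width), config.bond_r0 + width, 2048)
        pdf = grid**2 * np.exp(-0.5 * self.bond_k * (grid - config.bond_r0) ** 2)
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
        self._bond_cdf = cdf / cdf[-1]
        self._bond_grid = grid

    # ---------------- setup ----------------

    def _place_initial(self, max_restarts: int = 200) -> None:
        """Self-avoiding random walk for the chain, random insertion for ions."""
        r0 = self.config.bond_r0
        for _ in range(max_restarts):
            pts = np.empty((self.n, 3))
            pts[0] = 0.5 * self.box
            ok = True
            for i in range(1, self.n):
                for _ in range(200):
                    cand = pts[i - 1] + r0 * _random_unit(self.rng)
                    d = _min_image(pts[:i] - cand, self.box)
                    if np.all(np.einsum("ij,ij->i", d, d) >= (2 * self.config.bead_radius) ** 2):
                        pts[i] = cand
                        break
                else:
                    ok = False
                    break
            if not ok:
                continue
            self.coords[: self.n] = pts
            placed = 0
            tries = 0
            while placed < self.m and tries < 20000:
                cand = self.rng.uniform(0, self.box, size=3)
                existing = self.coords[: self.n + placed]
                d = _min_image(existing - cand, self.box)
                min_sep = self.radius[self.n + placed] + self.radius[: self.n + placed]
                if np.all(np.einsum("ij,ij->i", d, d) >= min_sep**2):
                    self.coords[self.n + placed] = cand
                    placed += 1
                tries += 1
            if placed == self.m:
                return
        raise RuntimeError(
            "failed to place a non-overlapping initial configuration; try a larger box_side"
        )

    # ---------------- energies ----------------

    def _u_particle(self, i: int, xi: np.ndarray) -> float:
        """Non-bonded energy of particle ``i`` at position ``xi`` vs everyone else."""
        d = self.coords - xi
        d -= self.box * np.round(d / self.box)
        r2 = np.einsum("ij,ij->i", d, d)
        r2[i] = math.inf
        if (r2 < self._contact2[i]).any():
            return math.inf
        u = 0.0
        nz = self._nzB[i]
        if nz.size:
            r = np.sqrt(r2[nz])
            u += float(
                (self._B[i, nz] * np.exp(-self.kappa * (r - self._contact[i, nz])) / r).sum()
            )
        if self.eps_sr and i < self.n:
            u -= float((self._A6[i, : self.n] / r2[: self.n] ** 3).sum())
        return u

    def _u_group(self, coords_a, idx_a, coords_b, idx_b) -> float:
        """Non-bonded energy between two disjoint particle groups."""
        d = coords_a[:, None, :] - coords_b[None, :, :]
        d -= self.box * np.round(d / self.box)
        r2 = np.einsum("abj,abj->ab", d, d)
        sub = np.ix_(idx_a, idx_b)
        if np.any(r2 < self._contact2[sub]):
            return math.inf
        u = 0.0
        B = self._B[sub]
        nz = B != 0
        if nz.any():
            r = np.sqrt(r2[nz])
            u += float(np.sum(B[nz] * np.exp(-self.kappa * (r - self._contact[sub][nz])) / r))
        if self.eps_sr:
            A6 = self._A6[sub]
            cc = A6 != 0
            if cc.any():
                u -= float(np.sum(A6[cc] / r2[cc] ** 3))
        return u

    def _bond_terms(self, chain: np.ndarray) -> float:
        b = np.linalg.norm(np.diff(chain, axis=0), axis=1)
        return float(0.5 * self.bond_k * np.sum((b - self.config.bond_r0) ** 2))

    def _bonds_of(self, i: int, xi: np.ndarray) -> float:
        u = 0.0
        r0 = self.config.bond_r0
        if i > 0:
            d = xi - self.coords[i - 1]
            u += 0.5 * self.bond_k * (math.sqrt(d @ d) - r0) ** 2
        if i < self.n - 1:
            d = xi - self.coords[i + 1]
            u += 0.5 * self.bond_k * (math.sqrt(d @ d) - r0) ** 2
        return u

    def _chain_total(self, chain: np.ndarray) -> float:
        """Bonds + chain-chain + chain-ion energy for a candidate chain geometry."""
        u = self._bond_terms(chain)
        d = chain[:, None, :] - chain[None, :, :]
        d -= self.box * np.round(d / self.box)
        r2 = np.einsum("abj,abj->ab", d, d)[self._ctriu]
        if np.any(r2 < self._ctriu_contact2):
            return math.inf
        nz = self._ctriu_B != 0
        if nz.any():
            r = np.sqrt(r2[nz])
            u += float(
                np.sum(self._ctriu_B[nz] * np.exp(-self.kappa * (r - self._ctriu_contact[nz])) / r)
            )
        if self.eps_sr:
            u -= float(np.sum(self._ctriu_A6 / r2**3))
        if self.m:
            u_ci = self._u_group(
                chain, np.arange(self.n), self.coords[self.n :], np.arange(self.n, self.M)
            )
            if not math.isfinite(u_ci):
                return math.inf
            u += u_ci
        return u

    def full_energy(self, coords: np.ndarray | None = None) -> float:
        """Total energy (bonds + all non-bonded pairs, minimum image), in kT."""
        c = self.coords if coords is None else coords
        u = self._bond_terms(c[: self.n])
        d = c[:, None, :] - c[None, :, :]
        d -= self.box * np.round(d / self.box)
        r2 = np.einsum("abj,abj->ab", d, d)[self._triu]
        if np.any(r2 < self._triu_contact2):
            return math.inf
        nz = self._triu_B != 0
        if nz.any():
            r = np.sqrt(r2[nz])
            u += float(
                np.sum(self._triu_B[nz] * np.exp(-self.kappa * (r - self._triu_contact[nz])) / r)
            )
        if self.eps_sr:
            u -= float(np.sum(self._triu_A6 / r2**3))
        return u

    # ---------------- trial moves ----------------

    def propose_move(self, move: str):
        """Generate a trial move.

        Returns ``(kind, payload, dU, dU_accept)``: ``dU`` is the true
        energy change of the candidate (for the ledger); ``dU_accept``
        additionally folds in the proposal-bias correction of the
        slithering move and is what the Metropolis rule must see.  For all
        other moves the two are identical.
        """
        if move in ("single_bead", "ion_translate"):
            if move == "ion_translate":
                if self.m == 0:
                    raise ValueError("no counterions to translate")
                i = int(self.n + self.rng.integers(self.m))
            else:
                i = int(self.rng.integers(self.M))
            amp = self.config.max_displacement["bead" if i < self.n else "ion"]
            xi_new = self.coords[i] + self.rng.uniform(-amp, amp, size=3)
            u_old = self._u_particle(i, self.coords[i])
            u_new = self._u_particle(i, xi_new)
            if i < self.n:
                u_old += self._bonds_of(i, self.coords[i])
                u_new += self._bonds_of(i, xi_new)
            du = u_new - u_old
            return ("particle", (i, xi_new), du, du)

        if move == "chain_translate":
            amp = self.config.max_displacement["chain"]
            shift = self.rng.uniform(-amp, amp, size=3)
            if self.m == 0:
                return ("chain", shift, 0.0, 0.0)
            chain_idx = np.arange(self.n)
            ion_idx = np.arange(self.n, self.M)
            ions = self.coords[self.n :]
            u_old = self._u_group(self.coords[: self.n], chain_idx, ions, ion_idx)
            u_new = self._u_group(self.coords[: self.n] + shift, chain_idx, ions, ion_idx)
            du = u_new - u_old
            return ("chain", shift, du, du)

        if move == "pivot":
            p = int(self.rng.integers(self.n))
            # rotate the shorter side; distances to the pivot bead are
            # preserved, so only segment-vs-rest cross terms change
            if p <= self.n - 1 - p:
                seg = np.arange(0, p)
                rest = np.concatenate([np.arange(p + 1, self.n), np.arange(self.n, self.M)])
            else:
                seg = np.arange(p + 1, self.n)
                rest = np.concatenate([np.arange(0, p), np.arange(self.n, self.M)])
            if len(seg) == 0:
                return ("noop", None, 0.0, 0.0)
            theta = self.rng.uniform(
                -self.config.max_displacement["pivot_angle"],
                self.config.max_displacement["pivot_angle"],
            )
            rot = _rotation_matrix(_random_unit(self.rng), theta)
            pivot_pt = self.coords[p]
            new_seg = (self.coords[seg] - pivot_pt) @ rot.T + pivot_pt
            u_old = self._u_group(self.coords[seg], seg, self.coords[rest], rest)
            u_new = self._u_group(new_seg, seg, self.coords[rest], rest)
            du = u_new - u_old
            return ("segment", (seg, new_seg), du, du)

        if move == "slither":
            head = bool(self.rng.integers(2))
            old_chain = self.coords[: self.n]
            new_chain = np.empty_like(old_chain)
            b_new = float(np.interp(self.rng.random(), self._bond_cdf, self._bond_grid))
            if head:  # drop bead 0, grow past the tail
                new_chain[:-1] = old_chain[1:]
                new_chain[-1] = old_chain[-1] + b_new * _random_unit(self.rng)
                b_old = float(np.linalg.norm(old_chain[1] - old_chain[0]))
            else:  # drop the tail bead, grow before the head
                new_chain[1:] = old_chain[:-1]
                new_chain[0] = old_chain[0] + b_new * _random_unit(self.rng)
                b_old = float(np.linalg.norm(old_chain[-1] - old_chain[-2]))
            du = self._chain_total(new_chain) - self._chain_total(old_chain)
            r0 = self.config.bond_r0
            bias = 0.5 * self.bond_k * ((b_new - r0) ** 2 - (b_old - r0) ** 2)
            return ("whole_chain", new_chain, du, du - bias)

        raise ValueError(f"unknown move type {move!r}")

    def metropolis_accept(self, du: float) -> bool:
        """Metropolis rule: overlap rejects, dU <= 0 accepts, else exp(-dU)."""
        if not math.isfinite(du):
            return False
        if du <= 0:
            return True
        return self.rng.random() < math.exp(-du)

    def _apply(self, kind: str, payload) -> None:
        if kind == "particle":
            i, xi = payload
            self.coords[i] = xi
        elif kind == "chain":
            self.coords[: self.n] += payload
        elif kind == "segment":
            seg, new_seg = payload
            self.coords[seg] = new_seg
        elif kind == "whole_chain":
            self.coords[: self.n] = payload

    def step(self) -> None:
        """One attempted move, drawn from the configured move-class weights."""
        move = self._move_names[bisect_right(self._move_cum, self.rng.random())]
        kind, payload, du, du_accept = self.propose_move(move)
        label = move
        if kind == "particle" and payload[0] >= self.n:
            label = "ion_translate"
        self.attempted[label] += 1
        if self.metropolis_accept(du_accept):
            self.accepted[label] += 1
            self._apply(kind, payload)
            self.energy += du

    def run_cycles(self, n_cycles: int) -> None:
        per_cycle = self.M
        for _ in range(n_cycles):
            for _ in range(per_cycle):
                self.step()

    def snapshot(self) -> SystemState:
        return SystemState(
            chain_coords=self.coords[: self.n].copy(),
            counterion_coords=self.coords[self.n :].copy(),
            counterion_charges=self.charge[self.n :].astype(int).copy(),
            per_bead_charge=self.charge[: self.n].astype(int).copy(),
            total_energy=self.energy,
        )


def total_energy(state: SystemState, config: SimulationConfig) -> float:
    """Total energy of a snapshot, recomputed from scratch (kT)."""
    eng = object.__new__(MonteCarloEngine)
    eng._setup(
        np.asarray(state.per_bead_charge, dtype=int),
        np.asarray(state.counterion_charges, dtype=int),
        config,
    )
    coords = np.vstack([state.chain_coords, state.counterion_coords.reshape(-1, 3)])
    return eng.full_energy(coords)


def run_simulation(per_bead_charge: Sequence[int], config: SimulationConfig) -> Trajectory:
    """Equilibrate then sample one chain; returns the sampled trajectory.

    The initial configuration is a self-avoiding random walk with bond
    length r0 plus uniformly inserted counterions.  After
    ``config.n_equil_cycles`` discarded cycles, Rg and energy are recorded
    every ``config.sample_interval`` cycles for ``config.n_prod_cycles``
    cycles.  Identical seed and config give a bit-identical trajectory.
    """
    eng = MonteCarloEngine(per_bead_charge, config)
    eng.run_cycles(config.n_equil_cycles)
    frames: list[SystemState] = []
    cycles = []
    rgs = []
    energies = []
    done = 0
    while done < config.n_prod_cycles:
        chunk = min(config.sample_interval, config.n_prod_cycles - done)
        eng.run_cycles(chunk)
        done += chunk
        frames.append(eng.snapshot())
        cycles.append(done)
        rgs.append(radius_of_gyration(eng.coords[: eng.n]))
        energies.append(eng.energy)
    stats = {k: (eng.attempted[k], eng.accepted[k]) for k in MOVE_TYPES}
    return Trajectory(
        frames=frames,
        cycles=np.asarray(cycles),
        rg_series=np.asarray(rgs),
        energy_series=np.asarray(energies),
        acceptance_stats=stats,
        config=config,
    )


def write_trajectory(trajectory: Trajectory, directory, name: str) -> None:
    """Write a trajectory as plain text: XYZ frames, CSV series, YAML config.

    ``<name>.xyz`` holds the sampled frames (chain beads first, then
    counterions, with the tag encoding the particle's charge: B0/B+/B- for
    beads, I+/I- for ions); ``<name>.csv`` is the per-sample series
    (cycle, Rg, energy); ``<name>.yaml`` echoes the configuration.
    """
    import io as _io
    from dataclasses import asdict
    from pathlib import Path

    import yaml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    for idx, fr in enumerate(trajectory.frames):
        buf.write(f"{fr.n_beads + fr.n_ions}\n")
        buf.write(f"frame {idx} cycle {trajectory.cycles[idx]} rg {trajectory.rg_series[idx]:.4f}\n")
        for q, (x, y, z) in zip(fr.per_bead_charge, fr.chain_coords):
            tag = "B+" if q > 0 else "B-" if q < 0 else "B0"
            buf.write(f"{tag} {x:.4f} {y:.4f} {z:.4f}\n")
        for q, (x, y, z) in zip(fr.counterion_charges, fr.counterion_coords):
            buf.write(f"{'I+' if q > 0 else 'I-'} {x:.4f} {y:.4f} {z:.4f}\n")
    (directory / f"{name}.xyz").write_text(buf.getvalue())
    lines = ["cycle,rg,energy\n"]
    lines += [
        f"{c},{r:.6f},{e:.6f}\n"
        for c, r, e in zip(trajectory.cycles, trajectory.rg_series, trajectory.energy_series)
    ]
    (directory / f"{name}.csv").write_text("".join(lines))
    meta = asdict(trajectory.config)
    meta["acceptance_stats"] = {k: list(v) for k, v in trajectory.acceptance_stats.items()}
    (directory / f"{name}.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def counterion_rdf(
    trajectory: Trajectory, bin_width: float = 1.0, charge: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distribution of each counterion's minimum-image distance to the chain.

    Returns ``(bin_edges, density, counts)`` where density is the
    normalized histogram of the minimum counterion-to-nearest-bead
    distance; it is identically zero below contact (4 A by default).
    ``charge`` restricts the analysis to counterions of that sign.
    """
    frames = trajectory.frames
    if len(frames) < 10:
        raise ValueError(f"need at least 10 frames, got {len(frames)}")
    if frames[0].n_ions == 0:
        raise ValueError("trajectory has no counterions")
    box = box_side_for(frames[0].n_beads, trajectory.config)
    dists = []
    for fr in frames:
        ions = fr.counterion_coords
        if charge is not None:
            ions = ions[fr.counterion_charges == charge]
        if len(ions) == 0:
            raise ValueError(f"no counterions of charge {charge}")
        d = _min_image(ions[:, None, :] - fr.chain_coords[None, :, :], box)
        r = np.sqrt(np.einsum("abj,abj->ab", d, d)).min(axis=1)
        dists.append(r)
    all_d = np.concatenate(dists)
    # minimum-image distances reach sqrt(3) * box/2 at the cube corners
    edges = np.arange(0.0, math.sqrt(3) * box / 2 + bin_width, bin_width)
    counts, edges = np.histogram(all_d, bins=edges)
    density = counts / (counts.sum() * bin_width)
    return edges, density, counts


def statistical_inefficiency(series: np.ndarray) -> float:
    """g = 1 + 2 sum (1 - t/n) rho_t, truncated at the first negative rho_t.

    g ~ the number of correlated samples per independent one; 1 for white
    noise and (1+phi)/(1-phi) for an AR(1) process with coefficient phi.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        return 1.0
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return 1.0
    g = 1.0
    for t in range(1, n):
        rho = np.dot(x[:-t], x[t:]) / ((n - t) * var)
        if rho < 0:
            break
        g += 2.0 * (1.0 - t / n) * rho
    return g


@dataclass
class ConvergenceReport:
    replicate_means: np.ndarray
    replicate_stderr: np.ndarray  # block-averaged standard errors
    inefficiency: np.ndarray
    pooled_mean: float
    pooled_stderr: float
    spread: float  # max |replicate mean - pooled mean|
    flagged: list[int]  # replicate indices deviating beyond the threshold


def convergence_report(
    rg_series_list: Sequence[np.ndarray], n_blocks: int = 10, flag_sigma: float = 3.0
) -> ConvergenceReport:
    """Block-average convergence diagnostics across replicate Rg series.

    Replicates whose mean deviates from the pooled mean by more than
    ``flag_sigma`` pooled standard errors are flagged as possibly trapped
    in distinct minima.
    """
    if len(rg_series_list) < 1:
        raise ValueError("need at least one replicate")
    means, errs, gs = [], [], []
    for s in rg_series_list:
        if isinstance(s, Trajectory):
            s = s.rg_series
        s = np.asarray(s, dtype=float)
        means.append(s.mean())
        nb = min(n_blocks, len(s))
        blocks = np.array_split(s, nb)
        bm = np.array([b.mean() for b in blocks])
        errs.append(bm.std(ddof=1) / math.sqrt(nb) if nb > 1 else 0.0)
        gs.append(statistical_inefficiency(s))
    means = np.asarray(means)
    errs = np.asarray(errs)
    pooled_mean = float(means.mean())
    pooled_err = float(np.sqrt(np.sum(errs**2)) / len(errs)) if len(errs) else 0.0
    spread = float(np.max(np.abs(means - pooled_mean))) if len(means) else 0.0
    if pooled_err > 0:
        flagged = [i for i, mu in enumerate(means) if abs(mu - pooled_mean) > flag_sigma * pooled_err]
    else:
        flagged = [i for i, mu in enumerate(means) if abs(mu - pooled_mean) > 0]
    return ConvergenceReport(
        replicate_means=means,
        replicate_stderr=errs,
        inefficiency=np.asarray(gs),
        pooled_mean=pooled_mean,
        pooled_stderr=pooled_err,
        spread=spread,
        flagged=flagged,
    )
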