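"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators: random IDP-like sequences hitting target composition
descriptors exactly at the residue-count level, ideal (phantom) harmonic
chains drawn from the exact bond-length Boltzmann density for use as a
simulator oracle, and noisy power-law (N, Rg) datasets for exercising the
scaling-law fitter.  All generators are pure functions of their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .bead_necklace import bond_force_constant_kT
from .scaling_law import ScalingLaw
from .sequence_props import load_kd_scale

__all__ = [
    "SequenceSpec",
    "make_sequence",
    "make_power_law_dataset",
    "make_phantom_chain",
    "harmonic_bond_moment",
]

#: charged residues used for composition targets; His excluded so targets
#: stay exact at pH 7
_POSITIVE = ("K", "R")
_NEGATIVE = ("D", "E")
#: neutral, non-titratable filler palette spanning the hydropathy scale
_FILLERS = ("I", "V", "L", "F", "M", "A", "G", "T", "S", "W", "N", "Q")


@dataclass(frozen=True)
class SequenceSpec:
    """Target composition for a generated sequence."""

    length: int
    target_fcr: float = 0.0
    target_ncpr: float = 0.0
    target_kd: float | None = None  # None: no hydropathy target
    proline_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        for name in ("target_fcr", "target_ncpr", "proline_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.target_ncpr > self.target_fcr:
            raise ValueError("target_ncpr cannot exceed target_fcr")


def make_sequence(spec: SequenceSpec) -> str:
    """A shuffled sequence whose descriptors match the spec within 1/length.

    The positive excess is assigned to f+ (net-positive chains); residue
    counts are the rounded targets, so FCR and NCPR are reproduced exactly
    up to the 1/length resolution of integer composition.
    """
    L = spec.length
    n_pos = round((spec.target_fcr + spec.target_ncpr) / 2 * L)
    n_neg = round((spec.target_fcr - spec.target_ncpr) / 2 * L)
    n_pro = round(spec.proline_fraction * L)
    n_fill = L - n_pos - n_neg - n_pro
    if n_fill < 0:
        raise ValueError(
            f"composition infeasible at length {L}: charged {n_pos + n_neg} "
            f"+ proline {n_pro} exceeds the chain; nearest achievable "
            f"fcr <= {(L - n_pro) / L:.3f} at this proline fraction"
        )
    got_fcr = (n_pos + n_neg) / L
    got_ncpr = abs(n_pos - n_neg) / L
    if abs(got_fcr - spec.target_fcr) > 1 / L or abs(got_ncpr - spec.target_ncpr) > 1 / L:
        raise ValueError(
            f"targets not achievable with integer counts at length {L}: "
            f"nearest fcr {got_fcr:.3f}, ncpr {got_ncpr:.3f}"
        )
    rng = np.random.default_rng(spec.seed)
    kd = load_kd_scale()
    residues = list(
        rng.choice(_POSITIVE, n_pos).tolist()
        + rng.choice(_NEGATIVE, n_neg).tolist()
        + ["P"] * n_pro
    )
    if spec.target_kd is None:
        residues += rng.choice(_FILLERS, n_fill).tolist()
    else:
        # greedy: each filler takes the palette value closest to the
        # remaining per-slot deficit of the target mean hydropathy
        needed = spec.target_kd * L - sum(kd[aa] for aa in residues)
        for slots_left in range(n_fill, 0, -1):
            per_slot = needed / slots_left
            pick = min(_FILLERS, key=lambda aa: abs(kd[aa] - per_slot))
            residues.append(pick)
            needed -= kd[pick]
    rng.shuffle(residues)
    return "".join(residues)


def make_power_law_dataset(
    law: ScalingLaw,
    n_points: int = 24,
    noise_sigma: float = 0.05,
    seed: int = 0,
    n_range: tuple[int, int] = (24, 441),
) -> tuple[np.ndarray, np.ndarray]:
    """(N, Rg) pairs from Rg = A N^nu exp(eps), eps ~ Normal(0, sigma).

    Chain lengths are drawn log-uniformly over ``n_range`` (default: the
    span of the packaged benchmark) and rounded to integers.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    rng = np.random.default_rng(seed)
    n = np.round(
        np.exp(rng.uniform(math.log(n_range[0]), math.log(n_range[1]), size=n_points))
    ).astype(int)
    eps = rng.normal(0.0, noise_sigma, size=n_points)
    rg = law.prefactor * n.astype(float) ** law.exponent * np.exp(eps)
    return n, rg


def harmonic_bond_moment(
    bond_r0: float, bond_force_constant: float, temperature_K: float, order: int = 2
) -> float:
    """<b^order> of the radial harmonic-bond Boltzmann density by quadrature.

    The density is p(r) ∝ r^2 exp(-beta k (r - r0)^2 / 2), the exact bond
    distribution of a free (phantom) harmonic chain.
    """
    k = bond_force_constant_kT(bond_force_constant, temperature_K)
    w = lambda r: r**2 * np.exp(-0.5 * k * (r - bond_r0) ** 2)
    hi = bond_r0 + 12.0 / math.sqrt(k)
    norm, _ = integrate.quad(w, 0.0, hi)
    mom, _ = integrate.quad(lambda r: r**order * w(r), 0.0, hi)
    return mom / norm


def make_phantom_chain(
    n_beads: int,
    bond_r0: float = 4.1,
    bond_force_constant: float = 0.4,
    temperature_K: float = 298.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Exact sample of a phantom harmonic chain (no non-bonded terms).

    Bond lengths are drawn from p(r) ∝ r^2 exp(-beta k (r-r0)^2/2) by
    inverse-CDF lookup; bond directions are uniform on the sphere.
    Returns (n_beads, 3) coordinates.
    """
    if n_beads < 2:
        raise ValueError("n_beads must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = bond_force_constant_kT(bond_force_constant, temperature_K)
    width = 12.0 / math.sqrt(k)
    grid = np.linspace(max(0.0, bond_r0 - width), bond_r0 + width, 4096)
    pdf = grid**2 * np.exp(-0.5 * k * (grid - bond_r0) ** 2)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
    cdf /= cdf[-1]
    lengths = np.interp(rng.random(n_beads - 1), cdf, grid)
    dirs = rng.normal(size=(n_beads - 1, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    coords = np.zeros((n_beads, 3))
    coords[1:] = np.cumsum(dirs * lengths[:, None], axis=0)
    return coords
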