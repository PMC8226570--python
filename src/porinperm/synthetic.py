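"""Synthetic compound tables and toy geometries for the analysis pipeline.

The real accumulation dataset (a ~189-compound screen with whole-cell
accumulation in E. coli) is not redistributable, so this module generates
tables with the same statistical structure: net charges between -2 and +2,
MPA means spanning roughly 40-75 A^2, lognormal total dipoles with a
Beta-distributed transversal fraction, alogP mostly below the 2.9
non-polarity cutoff, and accumulation log-linearly linked to the true
permeability score with Gaussian noise.  Planted subsets fall below the
45 nmol per 10^12 CFUs detection cutoff and above the alogP cutoff
(defaults: 35 below the detection cutoff and 18 above the alogP cutoff
with 1 compound failing both rules, i.e. 34 + 17 exclusive exclusions plus
one doubly-excluded compound, so 189 inputs leave 137 analysed rows), and
the noise level can be solved analytically from a target
Pearson correlation between ln(accumulation) and the score.

Toy molecules with closed-form descriptors (diatomics, rods, rings,
random clouds) support geometry-level testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensembles import ConformerEnsemble
from .pipeline import DEFAULT_ACCUMULATION_CUTOFF, DEFAULT_ALOGP_CUTOFF
from .pore import PoreModel, ScoringCoefficients
from .scoring import PorinPermeabilityModel

__all__ = [
    "GeneratorConfig",
    "generate_table",
    "make_toy_molecule",
    "solve_noise_sd",
]


def _default_charge_probs() -> dict[int, float]:
    return {-2: 0.05, -1: 0.17, 0: 0.30, 1: 0.36, 2: 0.12}


def _default_coefficients() -> ScoringCoefficients:
    return ScoringCoefficients(alpha=1.0, beta=-0.03, gamma=0.008, delta=0.0)


def _default_pore() -> PoreModel:
    return PoreModel()


@dataclass
class GeneratorConfig:
    """Distributions and link parameters of the synthetic table generator.

    ``target_r``, when set, overrides ``noise_sd`` with the value solved
    from ``r^2 = var(signal) / (var(signal) + noise_sd^2)`` on the
    surviving (analysed) subset, where the signal is
    ``slope * score``.
    """

    n_compounds: int = 189
    charge_probs: dict[int, float] = field(default_factory=_default_charge_probs)
    mpa_mean_range: tuple[float, float] = (40.0, 75.0)
    mpa_sd_range: tuple[float, float] = (0.5, 4.0)
    dipole_lognormal: tuple[float, float] = (np.log(9.0), 0.55)  # (mu, sigma)
    transversal_frac_beta: tuple[float, float] = (5.0, 2.0)
    alogp_params: tuple[float, float] = (0.9, 1.1)  # (mean, sd)
    true_coefficients: ScoringCoefficients = field(
        default_factory=_default_coefficients
    )
    pore: PoreModel = field(default_factory=_default_pore)
    link_slope: float = 0.30
    link_intercept: float = 5.86
    noise_sd: float = 0.5
    target_r: float | None = 0.74
    n_low_accumulation: int = 35
    n_nonpolar: int = 18
    n_overlap: int = 1
    accumulation_cutoff: float = DEFAULT_ACCUMULATION_CUTOFF
    alogp_cutoff: float = DEFAULT_ALOGP_CUTOFF

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        total = sum(self.charge_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"charge probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.charge_probs.values()):
            raise ValueError("charge probabilities must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.target_r is not None and not (0 < self.target_r <= 1):
            raise ValueError("target_r must lie in (0, 1]")
        if self.n_overlap > min(self.n_low_accumulation, self.n_nonpolar):
            raise ValueError("overlap exceeds a planted subset")
        planted = self.n_low_accumulation + self.n_nonpolar - self.n_overlap
        if planted > self.n_compounds:
            raise ValueError("planted subsets exceed the table size")
        for name in ("mpa_mean_range", "mpa_sd_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"invalid {name}: ({lo}, {hi})")


def solve_noise_sd(signal_sd: float, target_r: float) -> float:
    """Noise level giving Pearson ``target_r`` for signal + Gaussian noise.

    From ``r^2 = s^2 / (s^2 + n^2)``: ``n = s * sqrt(1/r^2 - 1)``.
    """
    if not (0 < target_r <= 1):
        raise ValueError("target_r must lie in (0, 1]")
    return float(signal_sd * np.sqrt(1.0 / target_r**2 - 1.0))


def generate_table(
    cfg: GeneratorConfig, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Draw one synthetic compound table; fully reproducible from ``seed``.

    Returns the table in the canonical CSV schema (plus a ``true_score``
    column) and a parameter dict recording every resolved setting,
    including the noise level actually used.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_compounds

    charges_support = np.array(sorted(cfg.charge_probs))
    probs = np.array([cfg.charge_probs[q] for q in charges_support])
    net_charge = rng.choice(charges_support, size=n, p=probs / probs.sum())

    mpa_mean = rng.uniform(*cfg.mpa_mean_range, size=n)
    mpa_sd = rng.uniform(*cfg.mpa_sd_range, size=n)
    total_dipole = rng.lognormal(*cfg.dipole_lognormal, size=n)
    frac = rng.beta(*cfg.transversal_frac_beta, size=n)
    transversal_dipole = total_dipole * frac
    alogp = rng.normal(*cfg.alogp_params, size=n)

    # planted exclusion subsets (low accumulation / nonpolar, with overlap)
    perm = rng.permutation(n)
    low_idx = perm[: cfg.n_low_accumulation]
    nonpolar_idx = np.concatenate(
        [
            perm[: cfg.n_overlap],
            perm[
                cfg.n_low_accumulation : cfg.n_low_accumulation
                + cfg.n_nonpolar
                - cfg.n_overlap
            ],
        ]
    )
    is_low = np.zeros(n, dtype=bool)
    is_low[low_idx] = True
    is_nonpolar = np.zeros(n, dtype=bool)
    is_nonpolar[nonpolar_idx] = True
    survivor = ~is_low & ~is_nonpolar

    # survivors stay at or below the polarity cutoff; planted rows above it
    alogp = np.clip(alogp, -2.0, None)
    alogp[~is_nonpolar] = np.minimum(alogp[~is_nonpolar], cfg.alogp_cutoff)
    alogp[is_nonpolar] = rng.uniform(
        cfg.alogp_cutoff + 0.05, cfg.alogp_cutoff + 1.1, size=is_nonpolar.sum()
    )

    table = pd.DataFrame(
        {
            "id": [f"cmpd{i + 1:04d}" for i in range(n)],
            "net_charge": net_charge.astype(int),
            "total_dipole": total_dipole,
            "transversal_dipole": transversal_dipole,
            "mpa_mean": mpa_mean,
            "mpa_sd": mpa_sd,
            "alogp": alogp,
        }
    )

    model = PorinPermeabilityModel(
        pore=cfg.pore, coefficients=cfg.true_coefficients
    )
    score = model.predict(table)
    table["true_score"] = score

    if cfg.target_r is not None and survivor.sum() >= 2:
        signal_sd = abs(cfg.link_slope) * float(np.std(score[survivor]))
        noise_sd = solve_noise_sd(signal_sd, cfg.target_r)
    else:
        noise_sd = cfg.noise_sd

    ln_acc = (
        cfg.link_intercept
        + cfg.link_slope * score
        + rng.normal(0.0, noise_sd, size=n)
    )
    accumulation = np.exp(ln_acc)
    # keep non-planted rows at/above the detection cutoff so the planted
    # exclusion counts determine the analysed n exactly
    accumulation = np.maximum(accumulation, cfg.accumulation_cutoff)
    accumulation[is_low] = rng.uniform(
        1.0, cfg.accumulation_cutoff - 1.0, size=is_low.sum()
    )
    table["accumulation"] = accumulation

    params = {
        "seed": int(seed),
        "n_compounds": int(n),
        "noise_sd": float(noise_sd),
        "target_r": cfg.target_r,
        "link_slope": cfg.link_slope,
        "link_intercept": cfg.link_intercept,
        "n_low_accumulation": int(cfg.n_low_accumulation),
        "n_nonpolar": int(cfg.n_nonpolar),
        "n_overlap": int(cfg.n_overlap),
        "n_survivors": int(survivor.sum()),
        "true_coefficients": list(cfg.true_coefficients.as_tuple()),
        "pore": {
            "name": cfg.pore.name,
            "v_pore": cfg.pore.v_pore,
            "e_pore": cfg.pore.e_pore,
            "pore_area_mean": cfg.pore.pore_area_mean,
            "pore_area_sd": cfg.pore.pore_area_sd,
        },
    }
    return table, params


# ---------------------------------------------------------------------------
# toy geometries


def make_toy_molecule(
    kind: str, params: dict | None = None, seed: int = 0
) -> ConformerEnsemble:
    """Toy geometries with closed-form or oracle-computable descriptors.

    Kinds
    -----
    ``diatomic``
        Two atoms with charges +-q at separation d along z: dipole
        ``q * d`` e*A.  Params: q=0.5, d=2.0, radius=1.5, mass=12.0.
    ``rod``
        Overlapping collinear spheres along z: MPA ~ pi r^2 down the axis.
        Params: n_atoms=5, spacing=1.0, radius=1.5, mass=12.0.
    ``ring``
        Regular polygon in the xy-plane: planar symmetry makes the two
        in-plane inertia moments degenerate (tie-break exercise).
        Params: n_atoms=8, ring_radius=2.0, radius=1.2, mass=12.0.
    ``random_cloud``
        Seed-reproducible random atoms; net charge exactly 0.
        Params: n_atoms=8, box=4.0, n_conformers=1.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "diatomic":
        q = params.get("q", 0.5)
        d = params.get("d", 2.0)
        radius = params.get("radius", 1.5)
        mass = params.get("mass", 12.0)
        positions = np.array([[[0.0, 0.0, -d / 2], [0.0, 0.0, d / 2]]])
        return ConformerEnsemble(
            compound_id=f"diatomic_q{q}_d{d}",
            positions=positions,
            charges=np.array([-q, q]),
            radii=np.full(2, radius),
            masses=np.full(2, mass),
        )
    if kind == "rod":
        n_atoms = params.get("n_atoms", 5)
        spacing = params.get("spacing", 1.0)
        radius = params.get("radius", 1.5)
        mass = params.get("mass", 12.0)
        z = (np.arange(n_atoms) - (n_atoms - 1) / 2) * spacing
        positions = np.zeros((1, n_atoms, 3))
        positions[0, :, 2] = z
        return ConformerEnsemble(
            compound_id=f"rod_{n_atoms}",
            positions=positions,
            charges=np.zeros(n_atoms),
            radii=np.full(n_atoms, radius),
            masses=np.full(n_atoms, mass),
        )
    if kind == "ring":
        n_atoms = params.get("n_atoms", 8)
        ring_radius = params.get("ring_radius", 2.0)
        radius = params.get("radius", 1.2)
        mass = params.get("mass", 12.0)
        theta = 2 * np.pi * np.arange(n_atoms) / n_atoms
        positions = np.zeros((1, n_atoms, 3))
        positions[0, :, 0] = ring_radius * np.cos(theta)
        positions[0, :, 1] = ring_radius * np.sin(theta)
        return ConformerEnsemble(
            compound_id=f"ring_{n_atoms}",
            positions=positions,
            charges=np.zeros(n_atoms),
            radii=np.full(n_atoms, radius),
            masses=np.full(n_atoms, mass),
        )
    if kind == "random_cloud":
        n_atoms = params.get("n_atoms", 8)
        box = params.get("box", 4.0)
        n_conformers = params.get("n_conformers", 1)
        positions = rng.uniform(-box / 2, box / 2, size=(n_conformers, n_atoms, 3))
        charges = rng.normal(0.0, 0.3, size=n_atoms)
        charges -= charges.mean()  # exactly neutral
        return ConformerEnsemble(
            compound_id=f"cloud_{seed}",
            positions=positions,
            charges=charges,
            radii=rng.uniform(1.2, 1.8, size=n_atoms),
            masses=rng.uniform(1.0, 16.0, size=n_atoms),
        )
    raise ValueError(f"unknown toy molecule kind: {kind!r}")
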