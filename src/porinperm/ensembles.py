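"""Conformer-ensemble container for descriptor calculation.

A :class:`ConformerEnsemble` holds one compound's sampled 3D geometries
together with the per-atom partial charges, van der Waals radii and masses
shared by all conformers.  The ensemble stands in for any source of
conformational sampling — a multi-conformer SDF, a trajectory subsample,
or library conformer embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConformerEnsemble"]

#: Tolerance (elementary charge) for the partial-charge sum to be accepted
#: as the compound's integral formal net charge.
CHARGE_SUM_TOLERANCE = 0.01


@dataclass
class ConformerEnsemble:
    """Sampled geometries of one compound with shared atomic properties.

    Parameters
    ----------
    compound_id:
        Identifier carried through to descriptor tables.
    positions:
        Array of shape ``(n_conformers, n_atoms, 3)`` in angstrom.
    charges:
        Per-atom partial charges in elementary charge units, shared by all
        conformers; must sum to an integer within 0.01 e.
    radii:
        Per-atom van der Waals radii in angstrom, strictly positive.
    masses:
        Per-atom masses in amu, strictly positive.
    """

    compound_id: str
    positions: np.ndarray
    charges: np.ndarray
    radii: np.ndarray
    masses: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError(
                f"positions must have shape (n_conformers, n_atoms, 3); "
                f"got {self.positions.shape}"
            )
        n_conf, n_atoms, _ = self.positions.shape
        if n_conf < 1:
            raise ValueError("ensemble needs at least one conformer")
        if n_atoms < 1:
            raise ValueError("ensemble needs at least one atom")
        for name, arr in (
            ("charges", self.charges),
            ("radii", self.radii),
            ("masses", self.masses),
        ):
            if arr.shape != (n_atoms,):
                raise ValueError(
                    f"{name} must have shape ({n_atoms},); got {arr.shape}"
                )
        if not np.all(self.radii > 0):
            raise ValueError("van der Waals radii must be strictly positive")
        if not np.all(self.masses > 0):
            raise ValueError("atomic masses must be strictly positive")
        total = float(self.charges.sum())
        residual = abs(total - round(total))
        if residual > CHARGE_SUM_TOLERANCE:
            raise ValueError(
                f"partial charges of {self.compound_id!r} sum to {total:.4f} e, "
                f"{residual:.4f} e away from the nearest integer "
                f"(tolerance {CHARGE_SUM_TOLERANCE} e)"
            )

    @property
    def n_conformers(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def formal_charge(self) -> int:
        """Nearest integer to the partial-charge sum."""
        return int(round(float(self.charges.sum())))
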