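"""Curvature-energy model of conical-lipid partitioning between vesicle leaflets.

A lipid whose polar head is small relative to its acyl-chain cross-section
prefers negatively curved monolayers: its spontaneous curvature ``c0`` (nm^-1)
is negative.  On a small vesicle of radius ``R`` the inner (concave) and outer
(convex) leaflets therefore cost such a lipid different bending energies.
For a binary mixture in which the host lipid is cylindrical (c0 = 0), and
ignoring the small area difference between the leaflets, the per-lipid
energies are

    e_i = 2 kappa a (c0 + 1/R)^2      (inner leaflet)
    e_o = 2 kappa a (c0 - 1/R)^2      (outer leaflet)

where ``kappa`` is the bending modulus in kBT and ``a`` the area per lipid in
nm^2.  The energy change on flipping a lipid from the inner to the outer
leaflet collapses to

    delta_e = e_o - e_i = -8 kappa a c0 / R        [kBT]

so at equilibrium the outer/inner number ratio is a Boltzmann factor,

    r = exp(-delta_e)                               (independent of f)

and, with an input molar fraction ``f`` of the conical species and equal
lipid counts on the two leaflets, the per-leaflet occupancies are

    f_o = 2 f r / (1 + r),     f_i = 2 f / (1 + r).

The inverse problem is also covered here: a two-step external/total labeling
experiment yields four fluorescence intensities whose ratio of ratios is the
fraction of the conical lipid sitting on the outer leaflets, from which the
occupancies (and an implied ratio r-hat) follow by arithmetic.

Note on the prefactor: the per-lipid energy is implemented verbatim with the
``2 kappa a`` prefactor conventional in this line of work, which
differs from the ``kappa a / 2`` one would write from a bare Helfrich
expansion per lipid.  Only ``delta_e`` matters for the partition, and the two
conventions differ by a constant factor that is absorbed in kappa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, InconsistentLabelingError

__all__ = [
    "LipidSpec",
    "MembraneSpec",
    "LeafletDistribution",
    "LeafletOccupancy",
    "leaflet_energies",
    "flip_energy",
    "partition_ratio",
    "leaflet_fractions",
    "predict_distribution",
    "partition_table",
    "external_fraction_from_labeling",
    "occupancy_from_external_fraction",
]


@dataclass(frozen=True)
class LipidSpec:
    """A lipid species: spontaneous curvature ``c0`` (nm^-1, signed) and
    area per lipid ``a`` (nm^2)."""

    c0: float
    a: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise DomainError(f"area per lipid must be positive, got {self.a}")


@dataclass(frozen=True)
class MembraneSpec:
    """Vesicle membrane: bending modulus ``kappa`` (kBT), local mean radius
    ``R`` (nm) and input fraction ``f`` of the conical lipid."""

    kappa: float
    R: float
    f: float = 0.0

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise DomainError(f"bending modulus must be positive, got {self.kappa}")
        if not self.R > 0:
            raise DomainError(f"vesicle radius must be positive, got {self.R}")
        if not 0.0 <= self.f < 1.0:
            raise DomainError(f"input fraction must lie in [0, 1), got {self.f}")


@dataclass(frozen=True)
class LeafletDistribution:
    """Full forward-model output for one (lipid, membrane, f) triple."""

    e_i: float
    e_o: float
    delta_e: float
    r: float
    f_i: float
    f_o: float


@dataclass(frozen=True)
class LeafletOccupancy:
    """Leaflet occupancies inferred from a labeling measurement, with the
    implied outer/inner ratio."""

    f_i: float
    f_o: float
    r_hat: float


def leaflet_energies(lipid: LipidSpec, mem: MembraneSpec) -> tuple[float, float]:
    """Per-lipid curvature energies (e_i, e_o) in kBT.

    The inner leaflet of a vesicle is concave, so the lipid there sees a
    curvature of +1/R relative to its own preference; the outer leaflet sees
    -1/R.
    """
    common = 2.0 * mem.kappa * lipid.a
    e_i = common * (lipid.c0 + 1.0 / mem.R) ** 2
    e_o = common * (lipid.c0 - 1.0 / mem.R) ** 2
    return e_i, e_o


def flip_energy(lipid: LipidSpec, mem: MembraneSpec) -> float:
    """Energy change delta_e = e_o - e_i (kBT) when a lipid flips from the
    inner to the outer leaflet; equals -8 kappa a c0 / R analytically."""
    return -8.0 * mem.kappa * lipid.a * lipid.c0 / mem.R


def partition_ratio(delta_e: float) -> float:
    """Boltzmann ratio r = exp(-delta_e) of outer to inner lipid counts.

    ``delta_e`` is already in kBT units, so no temperature appears. The ratio
    does not depend on the input fraction f.
    """
    if not np.isfinite(delta_e):
        raise DomainError(f"flip energy must be finite, got {delta_e}")
    return float(np.exp(-delta_e))


def leaflet_fractions(f: float, r: float) -> tuple[float, float]:
    """Occupancies (f_i, f_o) of the inner and outer leaflets.

    f_i = 2f / (1 + r) and f_o = 2fr / (1 + r); their average is f
    (conservation with equal lipid counts per leaflet).

    Raises
    ------
    DomainError
        If either occupancy would exceed 1 (the requested input fraction is
        infeasible at this partition ratio).
    """
    if f < 0:
        raise DomainError(f"input fraction must be non-negative, got {f}")
    if not r > 0:
        raise DomainError(f"partition ratio must be positive, got {r}")
    f_i = 2.0 * f / (1.0 + r)
    f_o = 2.0 * f * r / (1.0 + r)
    if f_i > 1.0:
        raise DomainError(
            f"inner-leaflet occupancy {f_i:.4f} exceeds 1 for f={f}, r={r}"
        )
    if f_o > 1.0:
        raise DomainError(
            f"outer-leaflet occupancy {f_o:.4f} exceeds 1 for f={f}, r={r}"
        )
    return f_i, f_o


def predict_distribution(lipid: LipidSpec, mem: MembraneSpec) -> LeafletDistribution:
    """Run the full forward model for one membrane composition."""
    e_i, e_o = leaflet_energies(lipid, mem)
    delta_e = flip_energy(lipid, mem)
    r = partition_ratio(delta_e)
    f_i, f_o = leaflet_fractions(mem.f, r)
    return LeafletDistribution(e_i=e_i, e_o=e_o, delta_e=delta_e, r=r, f_i=f_i, f_o=f_o)


def partition_table(
    lipid: LipidSpec, kappa: float, R: float, fractions: list[float]
) -> pd.DataFrame:
    """Tabulate model occupancies over a grid of input fractions.

    Values are also reported rounded half-even to 2 decimals, the precision
    at which such tables are customarily printed.
    """
    rows = []
    for f in fractions:
        dist = predict_distribution(lipid, MembraneSpec(kappa=kappa, R=R, f=f))
        rows.append(
            {
                "f": f,
                "f_i": dist.f_i,
                "f_o": dist.f_o,
                "r": dist.r,
                "f_i_2dp": float(np.round(dist.f_i, 2)),
                "f_o_2dp": float(np.round(dist.f_o, 2)),
                "r_2dp": float(np.round(dist.r, 2)),
            }
        )
    return pd.DataFrame(rows)


def external_fraction_from_labeling(
    i_alexa_ext: float,
    i_nbd1: float,
    i_alexa_tot: float,
    i_nbd2: float,
    tol: float = 1e-9,
) -> float:
    """Fraction of the conical lipid on the outer leaflets from a two-step
    labeling experiment.

    The first labeling reaches only external amine head groups; after
    solubilization and relabeling the second read reports the total pool.
    Each dye intensity is normalized by the co-read NBD intensity, which
    tracks total lipid, so

        frac_external = (I_ext / I_NBD1) / (I_tot / I_NBD2).

    Raises
    ------
    InconsistentLabelingError
        If the external read exceeds the total read beyond ``tol``.
    """
    for label, value in (
        ("I_Alexa_ext", i_alexa_ext),
        ("I_NBD1", i_nbd1),
        ("I_Alexa_tot", i_alexa_tot),
        ("I_NBD2", i_nbd2),
    ):
        if not value > 0:
            raise DomainError(f"intensity {label} must be positive, got {value}")
    ratio = (i_alexa_ext / i_nbd1) / (i_alexa_tot / i_nbd2)
    if ratio > 1.0 + tol:
        raise InconsistentLabelingError(
            f"external/total intensity ratio {ratio:.6f} exceeds 1: the external "
            "labeling read cannot exceed the total labeling read"
        )
    return float(min(ratio, 1.0))


def occupancy_from_external_fraction(f: float, frac_external: float) -> LeafletOccupancy:
    """Convert a measured external fraction into per-leaflet occupancies.

    With equal lipid counts per leaflet, an input fraction ``f`` of conical
    lipid of which ``frac_external`` sits outside gives

        f_o = 2 f frac_external,   f_i = 2 f (1 - frac_external)

    and an implied partition ratio r-hat = f_o / f_i (inf when f_i = 0).
    """
    if not 0.0 <= frac_external <= 1.0:
        raise DomainError(f"frac_external must lie in [0, 1], got {frac_external}")
    if not 0.0 < f < 1.0:
        raise DomainError(f"input fraction must lie in (0, 1), got {f}")
    f_o = 2.0 * f * frac_external
    f_i = 2.0 * f * (1.0 - frac_external)
    for name, value in (("inner", f_i), ("outer", f_o)):
        if value > 1.0:
            raise DomainError(f"{name}-leaflet occupancy {value:.4f} exceeds 1")
    r_hat = f_o / f_i if f_i > 0 else float("inf")
    return LeafletOccupancy(f_i=f_i, f_o=f_o, r_hat=r_hat)
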