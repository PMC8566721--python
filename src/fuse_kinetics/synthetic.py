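"""Synthetic inputs for every pipeline stage.

The package analyzes three kinds of raw data that normally come from a plate
reader or a molecular-dynamics engine: NBD dequenching traces, flat-bilayer
coordinate snapshots, and two-step labeling intensity quadruples.  This
module generates all of them with known ground truth so the downstream
estimators can be validated end to end.

Dequenching traces follow a saturating form

    F(t) = F0 + A * g(1 - exp(-nu t)),      nu = nu0 exp(-E_A T_ref / T)

whose normalized initial slope equals the fusion speed nu(T) in fusion
cycles per minute under the shared calibration map ``g`` (identity by
default).  Measurement noise is multiplicative lognormal per time point with
a configurable coefficient of variation.  Toy bilayers are flat rectangular
bead lattices: a polar head-bead layer with rectangular holes of known area
over a continuous hydrophobic tail layer, giving the defect detector an
exactly known ground truth.  Labeling experiments emit four intensities
whose NBD-normalized ratio of ratios equals the generating external fraction
exactly at zero noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box as _shapely_box
from shapely.ops import unary_union

from .calibration import IDENTITY, Calibration
from .defects import BilayerSnapshot
from .errors import DomainError
from .kinetics import T_REF, DequenchingTrace

__all__ = [
    "KineticParams",
    "ToyBilayerSpec",
    "LabelingTruth",
    "DEFAULT_TEMPERATURES",
    "simulate_dequenching_trace",
    "simulate_temperature_series",
    "build_toy_bilayer",
    "simulate_labeling_experiment",
    "collision_contact_time",
    "stokes_einstein_diffusion",
    "CONTACT_TIME_CONVENTIONS",
]

#: Boltzmann constant, J/K.
K_B = 1.380649e-23

#: Default assay temperature grid: 27-47 C in 5 C steps, in Kelvin.
DEFAULT_TEMPERATURES = (300.15, 305.15, 310.15, 315.15, 320.15)


@dataclass(frozen=True)
class KineticParams:
    """Generating parameters of a fusion-kinetics experiment.

    ``E_A`` is in kBT units at the 310.15 K reference, ``nu0`` in min^-1.
    ``labeled_fraction`` scales the absolute fluorescence amplitude (the
    labeled share of the vesicle population) without changing the normalized
    trace shape.  ``noise_cv`` is the coefficient of variation of the
    per-point multiplicative lognormal measurement noise.
    """

    E_A: float
    nu0: float
    temperatures: tuple = DEFAULT_TEMPERATURES
    labeled_fraction: float = 0.5
    noise_cv: float = 0.1
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.E_A > 0:
            raise DomainError(f"activation energy must be positive, got {self.E_A}")
        if self.nu0 < 0:
            raise DomainError(f"nucleation frequency must be >= 0, got {self.nu0}")
        if any(t <= 0 for t in self.temperatures):
            raise DomainError("all temperatures must be positive (Kelvin)")
        if self.noise_cv < 0:
            raise DomainError(f"noise CV must be >= 0, got {self.noise_cv}")
        if not 0 < self.labeled_fraction < 1:
            raise DomainError(
                f"labeled fraction must lie in (0, 1), got {self.labeled_fraction}"
            )
        if self.n_replicates < 1:
            raise DomainError(f"n_replicates must be >= 1, got {self.n_replicates}")

    def rate(self, T: float) -> float:
        """Arrhenius fusion speed nu(T) = nu0 exp(-E_A T_ref / T), cycles/min."""
        return self.nu0 * math.exp(-self.E_A * T_REF / T)


#: Raw-fluorescence shape of the emulated plate-reader signal (arbitrary
#: units): quenched baseline and full-dequenching amplitude before scaling
#: by the labeled fraction.
_BASELINE = 100.0
_AMPLITUDE = 900.0


def simulate_dequenching_trace(
    params: KineticParams,
    T: float,
    duration: float | None = None,
    dt: float | None = None,
    duration_cycles: float = 0.5,
    n_points: int = 2400,
    rng: np.random.Generator | None = None,
    replicate: int | str = 0,
    calibration: Calibration = IDENTITY,
) -> DequenchingTrace:
    """Simulate one NBD dequenching trace at temperature ``T`` (K).

    ``duration`` and ``dt`` are in minutes; when omitted they default to the
    time needed for ``duration_cycles`` fusion cycles (so the trace reaches
    ~40% of its plateau at the default 0.5) sampled at ``n_points`` points.
    The noiseless trace, normalized by its solubilization reference, has
    initial slope nu(T).
    """
    nu = params.rate(T)
    if duration is None:
        duration = duration_cycles / nu if nu > 0 else 60.0
    if dt is None:
        dt = duration / n_points
    if not dt > 0 or not duration > 0:
        raise DomainError(f"duration and dt must be positive, got {duration}, {dt}")
    if duration < 10 * dt:
        raise DomainError(
            f"duration ({duration}) must cover at least 10 sampling steps ({dt})"
        )
    if rng is None:
        rng = np.random.default_rng(params.seed)
    times = np.arange(int(round(duration / dt)) + 1) * dt
    cycles = -np.expm1(-nu * times)
    dequench = np.asarray(calibration.cycles_to_dequench(cycles), dtype=float)
    fluor = _BASELINE + params.labeled_fraction * _AMPLITUDE * dequench
    triton = _BASELINE + params.labeled_fraction * _AMPLITUDE
    if params.noise_cv > 0:
        sigma = math.sqrt(math.log1p(params.noise_cv**2))
        fluor = fluor * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=times.size)
    return DequenchingTrace(
        times=times,
        fluorescence=fluor,
        triton_reference=triton,
        temperature=float(T),
        label=f"{T:.2f}K/rep{replicate}",
        replicate=replicate,
    )


def simulate_temperature_series(
    params: KineticParams,
    duration: float | None = None,
    dt: float | None = None,
    duration_cycles: float = 0.5,
    n_points: int = 2400,
    calibration: Calibration = IDENTITY,
) -> list[DequenchingTrace]:
    """One trace per (temperature, replicate) over the parameter grid.

    Each trace draws from its own child random stream of ``params.seed``, so
    the full series is reproducible and traces are mutually independent.
    """
    temps = list(params.temperatures)
    if len(set(temps)) < 2:
        raise DomainError(
            "a temperature series needs >= 2 distinct temperatures for the "
            f"downstream Arrhenius fit, got {sorted(set(temps))}"
        )
    children = np.random.SeedSequence(params.seed).spawn(
        len(temps) * params.n_replicates
    )
    traces = []
    k = 0
    for T in temps:
        for rep in range(params.n_replicates):
            traces.append(
                simulate_dequenching_trace(
                    params,
                    T,
                    duration=duration,
                    dt=dt,
                    duration_cycles=duration_cycles,
                    n_points=n_points,
                    rng=np.random.default_rng(children[k]),
                    replicate=rep,
                    calibration=calibration,
                )
            )
            k += 1
    return traces


@dataclass(frozen=True)
class ToyBilayerSpec:
    """Geometry of a toy bead bilayer with constructed polar-cap holes.

    Head beads sit on a square lattice at ``head_z`` covering the box except
    inside ``hole_rects`` (axis-aligned ``(x0, y0, x1, y1)`` rectangles, A);
    a continuous hydrophobic tail lattice sits at ``tail_z``.  Overlapping
    holes are unioned.
    """

    box_x: float
    box_y: float
    head_z: float = 20.0
    tail_z: float = 17.0
    hole_rects: tuple = ()
    bead_radius: float = 0.9
    bead_spacing: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.box_x > 0 and self.box_y > 0):
            raise DomainError("box dimensions must be positive")
        if not self.bead_spacing > 0:
            raise DomainError(f"bead spacing must be positive, got {self.bead_spacing}")
        if not self.bead_radius > 0:
            raise DomainError(f"bead radius must be positive, got {self.bead_radius}")
        for rect in self.hole_rects:
            x0, y0, x1, y1 = rect
            if not (0 <= x0 < x1 <= self.box_x and 0 <= y0 < y1 <= self.box_y):
                raise DomainError(f"hole {rect} does not lie within the box")
        if not self.tail_z < self.head_z:
            raise DomainError("tail layer must sit below the head layer")

    def ground_truth_defect_fraction(self) -> float:
        """Exact hole area (after unioning overlaps) over box area."""
        if not self.hole_rects:
            return 0.0
        union = unary_union([_shapely_box(x0, y0, x1, y1) for x0, y0, x1, y1 in self.hole_rects])
        return float(union.area / (self.box_x * self.box_y))


def _in_any_hole(x: np.ndarray, y: np.ndarray, rects) -> np.ndarray:
    inside = np.zeros(x.shape, dtype=bool)
    for x0, y0, x1, y1 in rects:
        inside |= (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
    return inside


def build_toy_bilayer(spec: ToyBilayerSpec) -> BilayerSnapshot:
    """Construct the toy snapshot: a holed polar cap over a tail layer.

    All beads belong to the upper leaflet by construction.  The classifier
    returned by :func:`fuse_kinetics.defects.toy_classifier` (with matching
    ``bead_radius``) treats head beads as polar reference atoms and tail
    beads as hydrophobic.
    """
    s = spec.bead_spacing
    xs = (np.arange(int(np.floor(spec.box_x / s))) + 0.5) * s
    ys = (np.arange(int(np.floor(spec.box_y / s))) + 0.5) * s
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gx, gy = gx.ravel(), gy.ravel()

    keep = ~_in_any_hole(gx, gy, spec.hole_rects)
    head_xyz = np.column_stack([gx[keep], gy[keep], np.full(keep.sum(), spec.head_z)])
    tail_xyz = np.column_stack([gx, gy, np.full(gx.size, spec.tail_z)])

    xyz = np.vstack([head_xyz, tail_xyz])
    names = np.array(["HD"] * len(head_xyz) + ["TL"] * len(tail_xyz), dtype=object)
    resnames = np.full(len(xyz), "TOY", dtype=object)
    resids = np.arange(1, len(xyz) + 1)
    leaflets = np.full(len(xyz), "upper", dtype=object)
    return BilayerSnapshot(
        names=names,
        resnames=resnames,
        resids=resids,
        xyz=xyz,
        box=np.array([spec.box_x, spec.box_y, spec.head_z + 10.0]),
        leaflets=leaflets,
    )


@dataclass(frozen=True)
class LabelingTruth:
    """Ground truth of a two-step labeling experiment."""

    f: float
    frac_external: float
    intensity_scale: float = 1000.0
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f < 1:
            raise DomainError(f"input fraction must lie in (0, 1), got {self.f}")
        if not 0 <= self.frac_external <= 1:
            raise DomainError(
                f"frac_external must lie in [0, 1], got {self.frac_external}"
            )
        if not self.intensity_scale > 0:
            raise DomainError("intensity scale must be positive")
        if self.noise_cv < 0:
            raise DomainError(f"noise CV must be >= 0, got {self.noise_cv}")


#: Fluorescence yield of the dye per labeled lipid relative to the NBD
#: normalization signal, and the dilution factor between the two reads.
_LABEL_YIELD = 0.5
_SECOND_READ_DILUTION = 0.85


def simulate_labeling_experiment(
    truth: LabelingTruth, rng: np.random.Generator | None = None
) -> tuple[float, float, float, float]:
    """Four intensities (I_Alexa_ext, I_NBD1, I_Alexa_tot, I_NBD2).

    The first pair is read after external labeling, the second after total
    labeling; the second read is diluted by a fixed factor that the NBD
    normalization removes.  At zero noise the ratio of NBD-normalized
    intensities equals ``truth.frac_external`` exactly.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    s = truth.intensity_scale
    i_nbd1 = s
    i_ext = s * _LABEL_YIELD * truth.f * truth.frac_external
    i_nbd2 = s * _SECOND_READ_DILUTION
    i_tot = s * _SECOND_READ_DILUTION * _LABEL_YIELD * truth.f
    values = np.array([i_ext, i_nbd1, i_tot, i_nbd2])
    if truth.noise_cv > 0:
        sigma = math.sqrt(math.log1p(truth.noise_cv**2))
        values = values * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=4)
    return tuple(float(v) for v in values)


#: Contact-time conventions: (dimensionality factor c, diffusion multiplier m)
#: in t = d^2 / (c * m * D).  ``relative`` conventions use the relative
#: diffusion coefficient of the two vesicles (m = 2).
CONTACT_TIME_CONVENTIONS = {
    "single_1d": (2.0, 1.0),
    "relative_1d": (2.0, 2.0),
    "single_3d": (6.0, 1.0),
    "relative_3d": (6.0, 2.0),
}


def stokes_einstein_diffusion(radius_nm: float, T: float, viscosity: float) -> float:
    """Stokes-Einstein diffusion coefficient D = kB T / (6 pi eta r), m^2/s."""
    if not (radius_nm > 0 and T > 0 and viscosity > 0):
        raise DomainError("radius, temperature and viscosity must be positive")
    return K_B * T / (6.0 * math.pi * viscosity * radius_nm * 1e-9)


def collision_contact_time(
    gap_distance_nm: float,
    vesicle_radius_nm: float,
    T: float,
    viscosity: float = 1.0e-3,
    convention: str = "relative_3d",
) -> float:
    """Diffusive travel time (s) across the interaction gap of a collision.

    Two vesicles interact while less than a few nanometers apart; the time to
    diffuse across a gap ``d`` sets the window during which fusion must be
    nucleated.  The diffusion coefficient comes from Stokes-Einstein; the
    ``convention`` picks the mean-squared-displacement dimensionality factor
    and whether the relative diffusion of both vesicles (2D) or a single
    vesicle's D is used, t = d^2 / (c * m * D).  The default relative 3-D
    convention with eta = 1.0e-3 Pa s reproduces the conventional 60 ns-6 us
    window for gaps of 2-20 nm at 40 nm radius.
    """
    if gap_distance_nm < 0:
        raise DomainError(f"gap distance must be >= 0, got {gap_distance_nm}")
    try:
        c, m = CONTACT_TIME_CONVENTIONS[convention]
    except KeyError:
        raise DomainError(
            f"unknown convention {convention!r}; choose one of "
            f"{sorted(CONTACT_TIME_CONVENTIONS)}"
        ) from None
    d = gap_distance_nm * 1e-9
    diff = stokes_einstein_diffusion(vesicle_radius_nm, T, viscosity)
    return d * d / (c * m * diff)
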