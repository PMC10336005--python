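"""Seed-deterministic synthetic data generators for every pipeline stage.

The generators emulate the statistical structure of the study's inputs —
molecules on a hollow cylinder imaged by MINFLUX, multi-speed/-loading
sedimentation-equilibrium absorbance profiles, and mass-photometry-style
particle-mass samples drawn from the self-association equilibrium — so the
full analysis chain runs and is testable without any experimental data.
Every generator takes an integer seed and is byte-deterministic given
(seed, configuration); ground truth travels with the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import sedeq
from .thermo import DissociationConstants, species_distribution

__all__ = [
    "CylinderTruth",
    "ImagingModel",
    "gen_cylinder_molecules",
    "gen_localization_traces",
    "gen_sedeq_dataset",
    "gen_mass_histogram",
]


@dataclass(frozen=True)
class CylinderTruth:
    """Ground-truth hollow-cylinder geometry and occupancy.

    Defaults follow the wild-type pericentriolar Cep152 architecture: mean
    diameter 384 nm (mid radius 192), radial wall width 109 nm, height
    262 nm.  ``mode="clumped"`` emulates the assembly-deficient mutant
    phenotype: molecules concentrated into 1–2 angular lobes at a reduced
    density (``density_factor`` × n_molecules) and a broader radial/axial
    spread (``spread_factor`` × wall and height).
    """

    mid_radius_nm: float = 192.0
    wall_nm: float = 109.0
    height_nm: float = 262.0
    n_molecules: int = 500
    mode: str = "WT"
    clump_lobes: int = 2
    clump_kappa: float = 8.0  # von Mises concentration of each lobe
    density_factor: float = 0.5
    spread_factor: float = 1.5

    def __post_init__(self) -> None:
        if not self.wall_nm < 2.0 * self.mid_radius_nm:
            raise ValueError("wall width must be < cylinder diameter")
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be >= 0")
        if self.mode not in ("WT", "clumped"):
            raise ValueError("mode must be 'WT' or 'clumped'")


@dataclass(frozen=True)
class ImagingModel:
    """Stochastic single-molecule imaging model.

    Per molecule: labeled with probability ``labeling_efficiency``; a
    labeled molecule yields 1 + Bernoulli(``extra_trace_prob``) traces
    (blinking re-detection).  Per trace the localization count is
    1 + Poisson(``loc_mean - 1``) so real traces overwhelmingly pass the
    ≥5-localization filter; photons per localization are log-normal, and
    each localization scatters isotropically about the molecule with
    Gaussian σ ``loc_sigma_nm`` (the ~13 nm MINFLUX trace precision).
    Background traces are short by construction (mean length below the
    filter threshold) and uniform in the imaged volume.
    """

    labeling_efficiency: float = 1.0
    extra_trace_prob: float = 0.09
    loc_mean: float = 13.0
    loc_sigma_nm: float = 13.0
    photons_mu_log: float = math.log(500.0)
    photons_sigma_log: float = 0.5
    background_traces: int = 50
    background_loc_mean: float = 2.0
    dwell_s: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 <= self.labeling_efficiency <= 1.0:
            raise ValueError("labeling_efficiency must be in [0, 1]")
        if not 0.0 <= self.extra_trace_prob <= 1.0:
            raise ValueError("extra_trace_prob must be in [0, 1]")
        if self.loc_sigma_nm < 0 or self.loc_mean < 1:
            raise ValueError("invalid localization model")


def gen_cylinder_molecules(truth: CylinderTruth, seed: int) -> pd.DataFrame:
    """Sample ground-truth molecule positions on a hollow cylindrical shell.

    Radius is uniform in r² between the inner and outer wall (uniform areal
    density), z uniform over the height, and the angle uniform in WT mode
    or a von Mises mixture of ``clump_lobes`` lobes in clumped mode.
    Returns columns ``molecule_id, x_nm, y_nm, z_nm, r_nm, theta, mode``.
    """
    rng = np.random.default_rng(seed)
    n = truth.n_molecules
    wall, height = truth.wall_nm, truth.height_nm
    if truth.mode == "clumped":
        n = int(round(n * truth.density_factor))
        wall = min(wall * truth.spread_factor, 2.0 * truth.mid_radius_nm)
        height = height * truth.spread_factor
    if n == 0:
        return pd.DataFrame(
            columns=["molecule_id", "x_nm", "y_nm", "z_nm", "r_nm", "theta", "mode"]
        )
    r_in = max(truth.mid_radius_nm - wall / 2.0, 0.0)
    r_out = truth.mid_radius_nm + wall / 2.0
    r = np.sqrt(rng.uniform(r_in**2, r_out**2, size=n))
    if truth.mode == "WT":
        theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    else:
        centers = rng.uniform(0.0, 2.0 * math.pi, size=truth.clump_lobes)
        lobe = rng.integers(0, truth.clump_lobes, size=n)
        theta = rng.vonmises(centers[lobe], truth.clump_kappa) % (2.0 * math.pi)
    z = rng.uniform(-height / 2.0, height / 2.0, size=n)
    return pd.DataFrame(
        {
            "molecule_id": np.arange(n),
            "x_nm": r * np.cos(theta),
            "y_nm": r * np.sin(theta),
            "z_nm": z,
            "r_nm": r,
            "theta": theta,
            "mode": truth.mode,
        }
    )


def gen_localization_traces(
    molecules: pd.DataFrame, imaging: ImagingModel, seed: int
) -> pd.DataFrame:
    """Expand ground-truth molecules into a raw localization table.

    Output columns are the pipeline schema ``trace_id, t_s, x_nm, y_nm,
    z_nm, photons`` plus provenance columns ``molecule_id`` (−1 for
    background) and ``is_background``.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    trace_id = 0
    t = 0.0

    def emit(tid: int, n_loc: int, cx: float, cy: float, cz: float, mol: int, bg: bool):
        nonlocal t
        noise = rng.normal(0.0, imaging.loc_sigma_nm, size=(n_loc, 3))
        photons = rng.lognormal(
            imaging.photons_mu_log, imaging.photons_sigma_log, size=n_loc
        ).round()
        for i in range(n_loc):
            rows.append(
                (
                    tid,
                    t,
                    cx + noise[i, 0],
                    cy + noise[i, 1],
                    cz + noise[i, 2],
                    photons[i],
                    mol,
                    bg,
                )
            )
            t += imaging.dwell_s

    if len(molecules):
        labeled = rng.random(len(molecules)) < imaging.labeling_efficiency
        extra = rng.random(len(molecules)) < imaging.extra_trace_prob
        for (_, mol), lab, ext in zip(molecules.iterrows(), labeled, extra):
            if not lab:
                continue
            n_traces = 2 if ext else 1
            for _ in range(n_traces):
                n_loc = 1 + rng.poisson(imaging.loc_mean - 1.0)
                emit(
                    trace_id,
                    n_loc,
                    float(mol["x_nm"]),
                    float(mol["y_nm"]),
                    float(mol["z_nm"]),
                    int(mol["molecule_id"]),
                    False,
                )
                trace_id += 1

    if imaging.background_traces:
        if len(molecules):
            lo = molecules[["x_nm", "y_nm", "z_nm"]].min().to_numpy() - 50.0
            hi = molecules[["x_nm", "y_nm", "z_nm"]].max().to_numpy() + 50.0
        else:
            lo, hi = np.full(3, -250.0), np.full(3, 250.0)
        for _ in range(imaging.background_traces):
            c = rng.uniform(lo, hi)
            n_loc = 1 + rng.poisson(imaging.background_loc_mean - 1.0)
            emit(trace_id, n_loc, c[0], c[1], c[2], -1, True)
            trace_id += 1

    return pd.DataFrame(
        rows,
        columns=[
            "trace_id",
            "t_s",
            "x_nm",
            "y_nm",
            "z_nm",
            "photons",
            "molecule_id",
            "is_background",
        ],
    )


def gen_sedeq_dataset(
    k: DissociationConstants,
    loadings_m: tuple[float, ...] = (12.6e-6, 25e-6, 55e-6),
    speeds_rpm: tuple[float, ...] = (7000.0, 11000.0, 20000.0),
    wavelengths_nm: tuple[float, ...] = (280.0, 250.0),
    noise_sd_au: float = 0.005,
    seed: int = 0,
    cond: sedeq.SolutionConditions | None = None,
    ext250_ratio: float = 0.5,
    n_points: int = 200,
) -> tuple[list[sedeq.EquilibriumProfile], dict]:
    """Simulate a multi-speed/-loading/-wavelength equilibrium dataset.

    The default design mirrors the usable experimental cells: loadings
    12.6/25/55 μM at 7000/11000/20000 rpm and two wavelengths, with i.i.d.
    Gaussian absorbance noise.  Pathlength is 3 mm for loadings ≥ 50 μM and
    12 mm otherwise.  Returns (profiles, truth-dict).
    """
    rng = np.random.default_rng(seed)
    cond = cond or sedeq.SolutionConditions()
    model = sedeq.tet_oct_hexadecamer_model()
    log10_ks = np.array([math.log10(k.k8), math.log10(k.k16)])
    profiles = []
    for loading in loadings_m:
        path = 0.3 if loading >= 50e-6 else 1.2
        for speed in speeds_rpm:
            for wl in wavelengths_nm:
                run = sedeq.RotorRun(
                    speed_rpm=speed,
                    pathlength_cm=path,
                    wavelength_nm=wl,
                    n_points=n_points,
                )
                clean = sedeq.simulate_profile(
                    model,
                    log10_ks,
                    cond,
                    run,
                    loading,
                    ext250_ratio=ext250_ratio,
                    cell_id=f"L{loading:.3e}_S{int(speed)}_W{int(wl)}",
                )
                noisy = clean.absorbance + rng.normal(0.0, noise_sd_au, clean.absorbance.size)
                profiles.append(
                    sedeq.EquilibriumProfile(
                        run=run,
                        loading=loading,
                        radii=clean.radii,
                        absorbance=noisy,
                        cell_id=clean.cell_id,
                    )
                )
    truth = {
        "log10_k8": math.log10(k.k8),
        "log10_k16": math.log10(k.k16),
        "ext250_ratio": ext250_ratio,
        "noise_sd_au": noise_sd_au,
        "loadings_m": list(loadings_m),
        "speeds_rpm": list(speeds_rpm),
        "wavelengths_nm": list(wavelengths_nm),
        "conditions": asdict(cond),
        "seed": seed,
    }
    return profiles, truth


def gen_mass_histogram(
    k: DissociationConstants,
    total: float,
    unit_mass_da: float = sedeq.TETRAMER_MASS_DA,
    mass_sd_da: float = 15_000.0,
    n_particles: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mass-photometry-style particle masses from the equilibrium species.

    Particles are drawn with probability proportional to species *number*
    concentrations (each particle is one complex regardless of size); mass
    is stoichiometry × unit mass plus Gaussian measurement error.  Linear
    trimers-of-tetramers (3× unit mass) are absent by construction of the
    tetramer–octamer–hexadecamer model.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    rng = np.random.default_rng(seed)
    if n_particles == 0:
        return pd.DataFrame(columns=["stoichiometry", "mass_da"])
    state = species_distribution(total, k)
    number_conc = np.array([state.c4, state.c8, state.c16])
    probs = number_conc / number_conc.sum()
    stoich = rng.choice([1, 2, 4], size=n_particles, p=probs)
    mass = stoich * unit_mass_da + rng.normal(0.0, mass_sd_da, size=n_particles)
    return pd.DataFrame({"stoichiometry": stoich, "mass_da": mass})
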