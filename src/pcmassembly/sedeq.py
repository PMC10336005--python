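"""Sedimentation-equilibrium simulation and global fitting of self-association.

At sedimentation equilibrium each species adopts an exponential radial
profile set by its buoyant molar mass and the rotor speed,

    c_i(r) = c_i(r0) · exp[ σ_i (r² − r0²) / 2 ],
    σ_i   = M_i (1 − v̄ρ) ω² / (R T),

with r0 the meniscus.  When oligomer masses are integer multiples of the
free-unit mass, mass-action links imposed at the meniscus hold at every
radius, so a reversible self-association is simulated by (i) solving the
mass-conservation condition for the free-unit meniscus concentration and
(ii) propagating every species exponentially.  Conservation uses the
sector-shaped cell weighting ∝ r, for which the integral of each
exponential is available in closed form.

The global fitter estimates log10 dissociation constants jointly across
speeds, loadings and wavelengths.  Per-profile baselines and the unknown
250 nm extinction ratio enter the model linearly and are profiled out in
closed form (variable projection); the nonlinear search runs over the K's
only.  Confidence limits come from an F-statistic scan: each K is fixed on
a log grid, all other parameters are refit, and the interval bounds are the
crossings of the reduced-χ² threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.stats import f as f_dist

__all__ = [
    "GAS_CONSTANT_CGS",
    "TETRAMER_MASS_DA",
    "SpeciesSpec",
    "SolutionConditions",
    "RotorRun",
    "EquilibriumProfile",
    "SelfAssocModel",
    "FitResult",
    "ConfidenceInterval",
    "tet_oct_hexadecamer_model",
    "discrete_model",
    "isodesmic_model",
    "single_species_model",
    "simulate_profile",
    "global_fit",
    "fstat_confidence",
    "compare_models",
]

# cgs gas constant (g·cm²·s⁻²·mol⁻¹·K⁻¹) so that r in cm, M in g/mol work.
GAS_CONSTANT_CGS = 8.31446261815324e7

#: Calculated molar mass of the 2:2 heterotetramer building block (Da).
TETRAMER_MASS_DA = 51_800.0


@dataclass(frozen=True)
class SpeciesSpec:
    """One oligomeric species: stoichiometry n (tetramer units) and mass.

    Extinction is strictly proportional to stoichiometry, so only the
    free-unit extinction is carried by the model; ``molar_mass`` defaults to
    n × the tetramer mass.
    """

    stoichiometry: int
    molar_mass: float = 0.0

    def __post_init__(self) -> None:
        if self.stoichiometry < 1:
            raise ValueError("stoichiometry must be >= 1")
        if self.molar_mass == 0.0:
            object.__setattr__(
                self, "molar_mass", self.stoichiometry * TETRAMER_MASS_DA
            )
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")


@dataclass(frozen=True)
class SolutionConditions:
    """Solvent and sample properties entering the buoyancy factor."""

    vbar: float = 0.73  # partial specific volume, mL/g
    density: float = 1.02  # solvent density, g/mL
    temperature: float = 277.15  # K

    def __post_init__(self) -> None:
        if not 0.0 < self.vbar * self.density < 1.0:
            raise ValueError("buoyant factor 1 - vbar*rho must lie in (0, 1)")

    @property
    def buoyancy(self) -> float:
        return 1.0 - self.vbar * self.density


@dataclass(frozen=True)
class RotorRun:
    """One rotor-speed / cell / wavelength configuration."""

    speed_rpm: float
    meniscus_cm: float = 6.9
    base_cm: float = 7.2
    pathlength_cm: float = 1.2
    wavelength_nm: float = 280.0
    n_points: int = 200

    def __post_init__(self) -> None:
        if self.speed_rpm <= 0:
            raise ValueError("speed must be positive")
        if not self.meniscus_cm < self.base_cm:
            raise ValueError("meniscus must lie above (below in r) the base")

    @property
    def omega(self) -> float:
        """Angular velocity in rad/s."""
        return 2.0 * math.pi * self.speed_rpm / 60.0

    @property
    def radii(self) -> np.ndarray:
        return np.linspace(self.meniscus_cm, self.base_cm, self.n_points)


@dataclass(frozen=True)
class EquilibriumProfile:
    """Absorbance vs radius for one cell at one speed and wavelength."""

    run: RotorRun
    loading: float  # M, tetramer units
    radii: np.ndarray
    absorbance: np.ndarray
    baseline: float = 0.0
    cell_id: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radius grid must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")


@dataclass(frozen=True)
class SelfAssocModel:
    """Reversible self-association model built from one free unit.

    ``stoichiometries`` lists the species present (first entry must be 1,
    the free tetramer).  For a discrete model each higher species n carries
    its own overall dissociation constant K_n = c1ⁿ/c_n (units M^{n−1});
    the fit parameters are log10 K_n.  An isodesmic model instead uses one
    stepwise K_d for every addition, c_n = c1·(c1/K)^{n−1}, truncated at
    ``stoichiometries[-1]``.
    """

    stoichiometries: tuple[int, ...]
    isodesmic: bool = False
    name: str = ""
    extinction_280: float = 30_000.0  # M⁻¹cm⁻¹ per free unit

    def __post_init__(self) -> None:
        if self.stoichiometries[0] != 1:
            raise ValueError("first species must be the free unit (n = 1)")
        if len(set(self.stoichiometries)) != len(self.stoichiometries):
            raise ValueError("duplicate stoichiometries")

    @property
    def n_params(self) -> int:
        if self.isodesmic:
            return 1
        return len(self.stoichiometries) - 1

    def species_concentrations(
        self, c1: float, log10_ks: np.ndarray
    ) -> np.ndarray:
        """Concentrations of every species at free-unit concentration c1."""
        ns = np.asarray(self.stoichiometries, dtype=float)
        if self.isodesmic:
            kd = 10.0 ** log10_ks[0]
            with np.errstate(over="ignore"):
                out = c1 * (c1 / kd) ** (ns - 1.0)
            return out
        out = np.empty(len(ns))
        out[0] = c1
        for i, n in enumerate(self.stoichiometries[1:]):
            out[i + 1] = c1**n / 10.0 ** log10_ks[i]
        return out


def tet_oct_hexadecamer_model() -> SelfAssocModel:
    """The tetramer–octamer–hexadecamer model used for the real data."""
    return SelfAssocModel(
        stoichiometries=(1, 2, 4), name="tetramer-octamer-hexadecamer"
    )


def discrete_model(stoichiometries: tuple[int, ...], name: str = "") -> SelfAssocModel:
    return SelfAssocModel(
        stoichiometries=stoichiometries,
        name=name or "-".join(str(n) for n in stoichiometries),
    )


def isodesmic_model(n_max: int = 16) -> SelfAssocModel:
    return SelfAssocModel(
        stoichiometries=tuple(range(1, n_max + 1)),
        isodesmic=True,
        name="isodesmic",
    )


def single_species_model() -> SelfAssocModel:
    return SelfAssocModel(stoichiometries=(1,), name="single-species")


# ----------------------------------------------------------------- forward


def _sigmas(model: SelfAssocModel, cond: SolutionConditions, run: RotorRun) -> np.ndarray:
    """Reduced buoyant molar masses σ_i (cm⁻²) for every species."""
    ns = np.asarray(model.stoichiometries, dtype=float)
    masses = ns * TETRAMER_MASS_DA
    return (
        masses
        * cond.buoyancy
        * run.omega**2
        / (GAS_CONSTANT_CGS * cond.temperature)
    )


def _sector_average_factors(sigmas: np.ndarray, run: RotorRun) -> np.ndarray:
    """Cell-average of exp[σ(r²−r0²)/2] under the sector weight r dr.

    With u = (r² − r0²)/2 the integral is elementary:
    ⟨exp⟩ = (e^{σU} − 1)/(σU), U = (b² − r0²)/2.  σ → 0 gives 1.
    """
    U = (run.base_cm**2 - run.meniscus_cm**2) / 2.0
    x = sigmas * U
    out = np.empty_like(x)
    small = np.abs(x) < 1e-8
    out[small] = 1.0 + x[small] / 2.0
    out[~small] = np.expm1(x[~small]) / x[~small]
    return out


def _solve_meniscus_c1(
    model: SelfAssocModel,
    log10_ks: np.ndarray,
    cond: SolutionConditions,
    run: RotorRun,
    loading: float,
) -> float:
    """Free-unit meniscus concentration enforcing mass conservation.

    The sector-weighted cell average of total concentration (tetramer
    units) must equal the loading; the left side is strictly increasing in
    c1(r0), so a bracketed root solve is safe.
    """
    ns = np.asarray(model.stoichiometries, dtype=float)
    factors = _sector_average_factors(_sigmas(model, cond, run), run)

    def excess(c1: float) -> float:
        ci = model.species_concentrations(c1, log10_ks)
        return float(np.dot(ns * factors, ci)) - loading

    if loading == 0.0:
        return 0.0
    hi = loading
    if excess(hi) < 0:  # cannot happen for factors >= 1, defensive
        raise RuntimeError("conservation root not bracketed")
    # xtol must be far below molar concentration scales or it dominates rtol
    return brentq(excess, 0.0, hi, rtol=8.9e-16, xtol=1e-30, maxiter=300)


def simulate_profile(
    model: SelfAssocModel,
    log10_ks: np.ndarray | list[float],
    cond: SolutionConditions,
    run: RotorRun,
    loading: float,
    baseline: float = 0.0,
    ext250_ratio: float = 0.5,
    cell_id: str = "",
) -> EquilibriumProfile:
    """Noise-free equilibrium absorbance profile for one cell.

    ``loading`` is the cell-average concentration in molar tetramer units.
    Extinction of each oligomer is its stoichiometry times the free-unit
    extinction at 280 nm; at 250 nm this is scaled by ``ext250_ratio``.
    """
    log10_ks = np.asarray(log10_ks, dtype=float)
    if log10_ks.shape != (model.n_params,):
        raise ValueError(
            f"model {model.name!r} needs {model.n_params} log10 K value(s)"
        )
    signal = _signal_shape(model, log10_ks, cond, run, loading)
    if run.wavelength_nm == 250.0:
        signal = signal * ext250_ratio
    return EquilibriumProfile(
        run=run,
        loading=loading,
        radii=run.radii,
        absorbance=signal + baseline,
        baseline=baseline,
        cell_id=cell_id,
    )


def _signal_shape(
    model: SelfAssocModel,
    log10_ks: np.ndarray,
    cond: SolutionConditions,
    run: RotorRun,
    loading: float,
) -> np.ndarray:
    """Baseline-free absorbance at the 280 nm free-unit extinction."""
    sigmas = _sigmas(model, cond, run)
    c1_ref = _solve_meniscus_c1(model, log10_ks, cond, run, loading)
    ci_ref = model.species_concentrations(c1_ref, log10_ks)
    r = run.radii
    expo = np.exp(np.outer(sigmas, (r**2 - run.meniscus_cm**2) / 2.0))
    conc = ci_ref[:, None] * expo  # species × radius
    ns = np.asarray(model.stoichiometries, dtype=float)
    ext = ns * model.extinction_280
    return run.pathlength_cm * ext @ conc


def cell_average_concentration(profile_conc: np.ndarray, radii: np.ndarray) -> float:
    """Sector-weighted average ∫c·r dr / ∫r dr (numeric; used as an oracle)."""
    return float(np.trapezoid(profile_conc * radii, radii) / np.trapezoid(radii, radii))


# ---------------------------------------------------------------- tabular IO


def profiles_to_frame(profiles: list[EquilibriumProfile]):
    """Flatten profiles to the tabular schema used for CSV interchange.

    Columns: radius_cm, absorbance, speed_rpm, loading_M, wavelength_nm,
    cell_id, plus the cell geometry needed to reconstruct each run.
    """
    import pandas as pd

    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "radius_cm": p.radii,
                    "absorbance": p.absorbance,
                    "speed_rpm": p.run.speed_rpm,
                    "loading_M": p.loading,
                    "wavelength_nm": p.run.wavelength_nm,
                    "cell_id": p.cell_id,
                    "pathlength_cm": p.run.pathlength_cm,
                    "meniscus_cm": p.run.meniscus_cm,
                    "base_cm": p.run.base_cm,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_profiles(frame) -> list[EquilibriumProfile]:
    """Inverse of :func:`profiles_to_frame` (groups rows by cell_id)."""
    profiles = []
    for cell_id, grp in frame.groupby("cell_id", sort=False):
        first = grp.iloc[0]
        run = RotorRun(
            speed_rpm=float(first["speed_rpm"]),
            meniscus_cm=float(first["meniscus_cm"]),
            base_cm=float(first["base_cm"]),
            pathlength_cm=float(first["pathlength_cm"]),
            wavelength_nm=float(first["wavelength_nm"]),
            n_points=len(grp),
        )
        profiles.append(
            EquilibriumProfile(
                run=run,
                loading=float(first["loading_M"]),
                radii=grp["radius_cm"].to_numpy(dtype=float),
                absorbance=grp["absorbance"].to_numpy(dtype=float),
                cell_id=str(cell_id),
            )
        )
    return profiles


# ------------------------------------------------------------------ fitting


@dataclass(frozen=True)
class FitResult:
    """Converged global fit: log10 K's plus profiled linear parameters."""

    model: SelfAssocModel
    log10_ks: np.ndarray
    baselines: np.ndarray
    ext250_ratio: float
    chi2: float
    chi2_reduced: float
    n_obs: int
    n_params: int
    converged: bool
    message: str = ""
    confidence_intervals: dict = field(default_factory=dict)

    @property
    def dof(self) -> int:
        return self.n_obs - self.n_params


def _profiled_chi2(
    profiles: list[EquilibriumProfile],
    model: SelfAssocModel,
    cond: SolutionConditions,
    log10_ks: np.ndarray,
    fit_ext250: bool,
    ext250_ratio_fixed: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Residuals with baselines (and 250 nm ratio) profiled out linearly.

    For each profile the model is A = α·s(r) + b with α = 1 at 280 nm and
    α = ratio at 250 nm; b absorbs means, so the ratio is a one-parameter
    linear regression over the mean-centred 250 nm profiles.
    """
    shapes, is250 = [], []
    for p in profiles:
        s = _signal_shape(model, log10_ks, cond, p.run, p.loading)
        shapes.append(s)
        is250.append(p.run.wavelength_nm == 250.0)

    if fit_ext250 and any(is250):
        num = den = 0.0
        for p, s, w in zip(profiles, shapes, is250):
            if w:
                sc = s - s.mean()
                ac = p.absorbance - p.absorbance.mean()
                num += float(sc @ ac)
                den += float(sc @ sc)
        ratio = num / den if den > 0 else ext250_ratio_fixed
    else:
        ratio = ext250_ratio_fixed

    residuals, baselines = [], []
    for p, s, w in zip(profiles, shapes, is250):
        scaled = ratio * s if w else s
        b = float(np.mean(p.absorbance - scaled))
        baselines.append(b)
        residuals.append(p.absorbance - scaled - b)
    res = np.concatenate(residuals)
    return res, np.asarray(baselines), ratio


def global_fit(
    profiles: list[EquilibriumProfile],
    model: SelfAssocModel,
    cond: SolutionConditions,
    x0: np.ndarray | list[float] | None = None,
    fit_ext250: bool = True,
    ext250_ratio: float = 0.5,
    multistart_offsets: tuple[float, ...] = (-2.0, 0.0, 2.0),
    bounds_width: float = 6.0,
) -> FitResult:
    """Global nonlinear least squares over the model's log10 K's.

    Baselines (one per profile) and the 250 nm extinction ratio are linear
    and profiled out at every trial point, so the search space is just the
    K's.  Three starts spread ±2 log units guard against local minima.
    """
    if len(profiles) < 2:
        raise ValueError("global fit needs at least two profiles")
    n_k = model.n_params

    if n_k == 0:
        res, baselines, ratio = _profiled_chi2(
            profiles, model, cond, np.empty(0), fit_ext250, ext250_ratio
        )
        chi2 = float(res @ res)
        n_obs = res.size
        has250 = any(p.run.wavelength_nm == 250.0 for p in profiles)
        n_par = len(profiles) + (1 if fit_ext250 and has250 else 0)
        return FitResult(
            model=model,
            log10_ks=np.empty(0),
            baselines=baselines,
            ext250_ratio=ratio,
            chi2=chi2,
            chi2_reduced=chi2 / (n_obs - n_par),
            n_obs=n_obs,
            n_params=n_par,
            converged=True,
        )

    if x0 is None:
        # start every overall K at the scale set by the median loading
        med = float(np.median([p.loading for p in profiles]))
        if model.isodesmic:
            x0 = np.array([math.log10(med)])
        else:
            x0 = np.array(
                [(n - 1) * math.log10(med) for n in model.stoichiometries[1:]]
            )
    x0 = np.asarray(x0, dtype=float)

    def fun(x: np.ndarray) -> np.ndarray:
        return _profiled_chi2(profiles, model, cond, x, fit_ext250, ext250_ratio)[0]

    best = None
    message = ""
    for off in multistart_offsets:
        start = x0 + off
        try:
            sol = least_squares(
                fun,
                start,
                bounds=(x0 - bounds_width, x0 + bounds_width),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception as exc:  # pathological trial point
            message = str(exc)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return FitResult(
            model=model,
            log10_ks=x0,
            baselines=np.zeros(len(profiles)),
            ext250_ratio=ext250_ratio,
            chi2=math.inf,
            chi2_reduced=math.inf,
            n_obs=sum(p.absorbance.size for p in profiles),
            n_params=n_k + len(profiles) + (1 if fit_ext250 else 0),
            converged=False,
            message=message or "no start converged",
        )

    res, baselines, ratio = _profiled_chi2(
        profiles, model, cond, best.x, fit_ext250, ext250_ratio
    )
    chi2 = float(res @ res)
    n_obs = res.size
    has250 = any(p.run.wavelength_nm == 250.0 for p in profiles)
    n_par = n_k + len(profiles) + (1 if fit_ext250 and has250 else 0)
    return FitResult(
        model=model,
        log10_ks=best.x,
        baselines=baselines,
        ext250_ratio=ratio,
        chi2=chi2,
        chi2_reduced=chi2 / (n_obs - n_par),
        n_obs=n_obs,
        n_params=n_par,
        converged=bool(best.success),
        message=best.message,
    )


@dataclass(frozen=True)
class ConfidenceInterval:
    """Asymmetric F-statistic confidence interval for one K (in K units)."""

    lower: float
    upper: float
    level: float
    lower_open: bool = False
    upper_open: bool = False


def _refit_with_fixed(
    profiles, model, cond, fit: FitResult, param: int, value: float, fit_ext250: bool
) -> float:
    """χ² with one log10 K frozen and every other parameter refit."""
    n_k = model.n_params
    free_idx = [i for i in range(n_k) if i != param]

    def assemble(xfree: np.ndarray) -> np.ndarray:
        x = np.empty(n_k)
        x[param] = value
        for j, i in enumerate(free_idx):
            x[i] = xfree[j]
        return x

    if not free_idx:
        res = _profiled_chi2(
            profiles, model, cond, np.array([value]), fit_ext250, fit.ext250_ratio
        )[0]
        return float(res @ res)

    def fun(xfree: np.ndarray) -> np.ndarray:
        return _profiled_chi2(
            profiles, model, cond, assemble(xfree), fit_ext250, fit.ext250_ratio
        )[0]

    start = fit.log10_ks[free_idx]
    sol = least_squares(fun, start, xtol=1e-10, ftol=1e-10)
    return 2.0 * float(sol.cost)


def fstat_confidence(
    profiles: list[EquilibriumProfile],
    model: SelfAssocModel,
    cond: SolutionConditions,
    fit: FitResult,
    param: int = 0,
    level: float = 0.68,
    step_log10: float = 0.02,
    max_span_log10: float = 3.0,
    fit_ext250: bool = True,
) -> ConfidenceInterval:
    """F-statistic confidence limits by stepwise scanning of one K.

    The chosen log10 K is fixed on a grid above and below the best fit; all
    remaining parameters are refit at each step and the interval bounds are
    the crossings of χ²_crit = χ²_min·(1 + F(level; 1, ν)/ν).  Asymmetry is
    preserved — each side is scanned independently.  ``level → 0`` collapses
    the interval onto the point estimate.
    """
    if not fit.converged:
        raise ValueError("confidence scan requires a converged fit")
    nu = fit.dof
    if level <= 0.0:
        k_best = 10.0 ** fit.log10_ks[param]
        return ConfidenceInterval(lower=k_best, upper=k_best, level=level)
    threshold = fit.chi2 * (1.0 + f_dist.ppf(level, 1, nu) / nu)

    center = fit.log10_ks[param]

    def excess(x: float) -> float:
        return (
            _refit_with_fixed(profiles, model, cond, fit, param, x, fit_ext250)
            - threshold
        )

    bounds = {}
    open_flags = {}
    for side in (-1.0, +1.0):
        prev_x = center
        crossing = None
        steps = int(max_span_log10 / step_log10)
        for i in range(1, steps + 1):
            x = center + side * i * step_log10
            if excess(x) >= 0.0:
                # bracketed: refine the crossing of the χ² threshold
                crossing = brentq(excess, prev_x, x, xtol=step_log10 * 1e-3)
                break
            prev_x = x
        if crossing is None:
            bounds[side] = center + side * max_span_log10
            open_flags[side] = True
        else:
            bounds[side] = crossing
            open_flags[side] = False

    return ConfidenceInterval(
        lower=10.0 ** bounds[-1.0],
        upper=10.0 ** bounds[+1.0],
        level=level,
        lower_open=open_flags[-1.0],
        upper_open=open_flags[+1.0],
    )


def compare_models(
    profiles: list[EquilibriumProfile],
    models: list[SelfAssocModel],
    cond: SolutionConditions,
    fit_ext250: bool = True,
) -> list[tuple[SelfAssocModel, FitResult]]:
    """Fit every candidate model and rank by reduced χ² (best first).

    Individual non-convergence is recorded on the FitResult (infinite χ²),
    never fatal for the comparison as a whole.
    """
    if len(models) < 2:
        raise ValueError("model comparison needs at least two models")
    results = []
    for m in models:
        try:
            results.append((m, global_fit(profiles, m, cond, fit_ext250=fit_ext250)))
        except Exception as exc:
            results.append(
                (
                    m,
                    FitResult(
                        model=m,
                        log10_ks=np.empty(m.n_params),
                        baselines=np.zeros(len(profiles)),
                        ext250_ratio=1.0,
                        chi2=math.inf,
                        chi2_reduced=math.inf,
                        n_obs=sum(p.absorbance.size for p in profiles),
                        n_params=m.n_params,
                        converged=False,
                        message=str(exc),
                    ),
                )
            )
    return sorted(results, key=lambda mr: mr[1].chi2_reduced)
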