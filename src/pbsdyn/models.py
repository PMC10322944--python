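"""Global lifetime and target analysis of time-resolved surfaces.

``GlobalDecayModel`` fits a sum of IRF-convolved exponentials with
lifetimes shared across all wavelengths (variable projection: lifetimes are
the only nonlinear parameters, per-wavelength amplitudes are solved by
linear least squares at every step), yielding decay-associated spectra
(DAS).  ``TargetKineticModel`` fits a first-order compartmental scheme
directly, yielding species-associated spectra (SAS).  Both follow the
model/results pattern: construct from data, call :meth:`fit`, inspect the
returned results object (estimates, standard errors, diagnostics,
``summary()``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import ModelInconsistencyError
from .kinetics import (
    IRFModel,
    KineticScheme,
    TimeResolvedSurface,
    concentration_profiles,
    das_to_sas_matrices,
    exponential_basis,
    match_lifetimes,
    svd_rank,
)

__all__ = [
    "GlobalDecayModel",
    "DASResults",
    "SASResults",
    "TargetKineticModel",
    "TargetResults",
    "SchemeTemplate",
    "Transition",
    "das_to_sas",
    "rod_scheme_template",
]


def _solve_amplitudes(C: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Per-wavelength linear amplitudes A minimising ||Y - C A||."""
    A, *_ = np.linalg.lstsq(C, Y, rcond=None)
    return A


class GlobalDecayModel:
    """Multi-exponential global fit of a time x wavelength surface.

    Parameters
    ----------
    surface : TimeResolvedSurface
        The data; negative-time rows are kept and fitted through the IRF.
    n_components : int
        Number of shared lifetimes.  A value above the SVD rank estimate
        triggers a warning (overfitting risk), not a failure.
    irf : IRFModel, optional
        Gaussian instrument response convolved with every exponential.
    init_lifetimes : sequence of float or "auto"
        Starting lifetimes; "auto" spaces them logarithmically between the
        median time step and the time-axis span.
    """

    def __init__(
        self,
        surface: TimeResolvedSurface,
        n_components: int,
        irf: IRFModel | None = None,
        init_lifetimes: Sequence[float] | str = "auto",
    ) -> None:
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.surface = surface
        self.n_components = int(n_components)
        self.irf = irf
        _, rank = svd_rank(surface)
        if n_components > rank:
            warnings.warn(
                f"n_components={n_components} exceeds the SVD rank estimate "
                f"({rank}); extra components may fit noise",
                stacklevel=2,
            )
        self.svd_rank_estimate = rank
        if isinstance(init_lifetimes, str):
            if init_lifetimes != "auto":
                raise ValueError("init_lifetimes must be a sequence or 'auto'")
            t = surface.times
            lo = max(float(np.median(np.diff(t))), 1e-3)
            hi = max(float(t[-1] - t[0]), 10 * lo)
            self.init_lifetimes = np.geomspace(lo, hi, n_components)
        else:
            self.init_lifetimes = np.asarray(init_lifetimes, dtype=float)
            if len(self.init_lifetimes) != n_components:
                raise ValueError("init_lifetimes length must equal n_components")
            if np.any(self.init_lifetimes <= 0):
                raise ValueError("init lifetimes must be positive")

    # -- variable projection ------------------------------------------------

    def _residual(self, log_taus: np.ndarray) -> np.ndarray:
        C = exponential_basis(self.surface.times, np.exp(log_taus), self.irf)
        A = _solve_amplitudes(C, self.surface.signal)
        return (self.surface.signal - C @ A).ravel()

    def fit(self, xtol: float = 1e-12, ftol: float = 1e-12, max_nfev: int | None = None) -> "DASResults":
        """Trust-region least squares over log-lifetimes (positive by
        construction); amplitudes by linear projection at each step."""
        x0 = np.log(self.init_lifetimes)
        res = least_squares(
            self._residual, x0, method="trf", xtol=xtol, ftol=ftol,
            gtol=1e-12, max_nfev=max_nfev,
        )
        log_taus = res.x
        taus = np.exp(log_taus)
        order = np.argsort(taus)
        taus = taus[order]
        C = exponential_basis(self.surface.times, taus, self.irf)
        A = _solve_amplitudes(C, self.surface.signal)
        resid = self.surface.signal - C @ A
        rms = float(np.sqrt(np.mean(resid**2)))

        # standard errors of the nonlinear parameters from the Jacobian
        dof = max(resid.size - (len(taus) + A.size), 1)
        s2 = float(np.sum(resid**2)) / dof
        J = res.jac[:, order]
        try:
            cov_log = s2 * np.linalg.inv(J.T @ J)
            stderr = taus * np.sqrt(np.clip(np.diag(cov_log), 0, None))
        except np.linalg.LinAlgError:
            stderr = np.full_like(taus, np.nan)

        window = float(self.surface.times[-1] - self.surface.times[0])
        return DASResults(
            model=self,
            lifetimes=taus,
            lifetime_stderr=stderr,
            amplitude_spectra=A,
            fit_residual_rms=rms,
            converged=bool(res.status > 0),
            n_function_evals=int(res.nfev),
            poorly_determined=taus > 0.5 * window,
            optimizer_message=str(res.message),
        )


@dataclass
class DASResults:
    """Decay-associated spectra: shared lifetimes + amplitude spectra.

    A lifetime flagged in ``poorly_determined`` exceeds half the measurement
    window: the data constrain only a lower bound on it.
    """

    model: GlobalDecayModel
    lifetimes: np.ndarray                # (k,), ps, ascending
    lifetime_stderr: np.ndarray          # (k,), ps
    amplitude_spectra: np.ndarray        # (k, n_wavelengths)
    fit_residual_rms: float
    converged: bool
    n_function_evals: int = 0
    poorly_determined: np.ndarray = field(default_factory=lambda: np.array([]))
    optimizer_message: str = ""

    @property
    def wavelengths(self) -> np.ndarray:
        return self.model.surface.wavelengths

    def basis(self) -> np.ndarray:
        return exponential_basis(self.model.surface.times, self.lifetimes, self.model.irf)

    def reconstruction(self) -> np.ndarray:
        """Model surface C(t) @ A implied by the fit."""
        return self.basis() @ self.amplitude_spectra

    def summary(self) -> str:
        lines = [
            "Global decay fit (DAS)",
            "=" * 54,
            f"surface: {self.model.surface.shape[0]} times x "
            f"{self.model.surface.shape[1]} wavelengths",
            f"components: {len(self.lifetimes)}   "
            f"SVD rank estimate: {self.model.svd_rank_estimate}",
            f"converged: {self.converged}   residual RMS: {self.fit_residual_rms:.4g}",
            "-" * 54,
            f"{'component':>10} {'tau (ps)':>12} {'stderr':>10} {'note':>14}",
        ]
        for i, (tau, se) in enumerate(zip(self.lifetimes, self.lifetime_stderr)):
            note = "lower bound" if self.poorly_determined[i] else ""
            lines.append(f"{f'C{i+1}':>10} {tau:>12.4g} {se:>10.2g} {note:>14}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Amplitude spectra against wavelength, one line per lifetime."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for tau, amp in zip(self.lifetimes, self.amplitude_spectra):
            ax.plot(self.wavelengths, amp, label=f"{tau:.3g} ps")
        ax.axhline(0.0, color="0.6", lw=0.5)
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("DAS amplitude")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# DAS -> SAS under a fixed scheme
# ---------------------------------------------------------------------------


@dataclass
class SASResults:
    """Species-associated spectra under a first-order kinetic scheme."""

    scheme: KineticScheme
    species_spectra: np.ndarray          # (n, n_wavelengths)
    concentrations: np.ndarray           # (n_times, n)
    wavelengths: np.ndarray
    times: np.ndarray
    das: DASResults | None = None

    def reconstruction(self) -> np.ndarray:
        return self.concentrations @ self.species_spectra

    def summary(self) -> str:
        lines = [
            "Target analysis (SAS)",
            "=" * 54,
            "compartments: " + ", ".join(self.scheme.compartment_names),
            "eigen-lifetimes (ps): "
            + ", ".join(f"{t:.4g}" for t in self.scheme.lifetimes()),
        ]
        peaks = self.wavelengths[np.argmax(np.abs(self.species_spectra), axis=1)]
        for name, pk in zip(self.scheme.compartment_names, peaks):
            lines.append(f"  {name}: dominant band at {pk:.1f} nm")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, spec in zip(self.scheme.compartment_names, self.species_spectra):
            ax.plot(self.wavelengths, spec, label=name)
        ax.axhline(0.0, color="0.6", lw=0.5)
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("SAS amplitude")
        ax.legend()
        return ax


def das_to_sas(das: DASResults, scheme: KineticScheme, lifetime_rtol: float = 0.05) -> SASResults:
    """Impose a kinetic scheme on a DAS fit.

    The exponential amplitudes of a first-order scheme are a fixed linear
    mixture of the species spectra: with the eigen-basis E(t) ordered by
    ascending lifetime, ``c(t) = E(t) W`` and hence ``A_das = W A_sas``.
    Solving that linear relation converts the DAS into SAS; the
    reconstruction of the surface is unchanged by construction.

    Raises :class:`ModelInconsistencyError` when the DAS lifetimes do not
    match the scheme's eigen-lifetimes within ``lifetime_rtol``.
    """
    match_lifetimes(das.lifetimes, scheme, rtol=lifetime_rtol)
    _, W = das_to_sas_matrices(scheme)
    if abs(np.linalg.det(W)) < 1e-300:
        raise ModelInconsistencyError(
            "scheme mixing matrix is singular; compartments are kinetically "
            "indistinguishable from this initial condition"
        )
    A_sas = np.linalg.solve(W, das.amplitude_spectra)
    E = das.basis()
    return SASResults(
        scheme=scheme,
        species_spectra=A_sas,
        concentrations=E @ W,
        wavelengths=das.wavelengths,
        times=das.model.surface.times,
        das=das,
    )


# ---------------------------------------------------------------------------
# target (compartmental) fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Transition:
    """One first-order channel: ``source -> target`` (or loss if target is None).

    ``rate_param`` names the fitted rate; several transitions may share one
    parameter (e.g. the common relaxation of two parallel intermediates).
    ``weight`` scales the shared rate for branching.
    """

    source: str
    target: str | None
    rate_param: str
    weight: float = 1.0


@dataclass
class SchemeTemplate:
    """Fixed topology with free rate parameters for target fitting."""

    compartment_names: tuple[str, ...]
    transitions: tuple[Transition, ...]
    initial_populations: np.ndarray
    init_rates: Mapping[str, float]

    def __post_init__(self) -> None:
        self.compartment_names = tuple(self.compartment_names)
        self.transitions = tuple(self.transitions)
        self.initial_populations = np.asarray(self.initial_populations, dtype=float)
        names = set(self.compartment_names)
        for tr in self.transitions:
            if tr.source not in names or (tr.target is not None and tr.target not in names):
                raise ValueError(f"transition references unknown compartment: {tr}")
        missing = {tr.rate_param for tr in self.transitions} - set(self.init_rates)
        if missing:
            raise ValueError(f"no initial value for rate parameters {sorted(missing)}")

    @property
    def param_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for tr in self.transitions:
            if tr.rate_param not in seen:
                seen.append(tr.rate_param)
        return tuple(seen)

    def build(self, rates: Mapping[str, float]) -> KineticScheme:
        n = len(self.compartment_names)
        idx = {name: i for i, name in enumerate(self.compartment_names)}
        K = np.zeros((n, n))
        for tr in self.transitions:
            k = rates[tr.rate_param] * tr.weight
            i = idx[tr.source]
            K[i, i] -= k
            if tr.target is not None:
                K[idx[tr.target], i] += k
        return KineticScheme(self.compartment_names, K, self.initial_populations)


def rod_scheme_template(
    tau_p1: float = 3.6,
    tau_p2: float = 25.0,
    tau_r: float = 200.0,
    tau_t: float = 1999.0,
    branch: float = 0.5,
    p0_split: float = 0.5,
) -> SchemeTemplate:
    """Template for the branched rod scheme P1/P2 -> RS/RL -> T.

    RS and RL share one relaxation rate (their printed lifetimes coincide),
    which is the main source of degeneracy this topology carries; the fit
    reports per-parameter uncertainties so that degeneracy stays visible.
    """
    return SchemeTemplate(
        compartment_names=("P1", "P2", "RS", "RL", "T"),
        transitions=(
            Transition("P1", "RS", "k_p1", branch),
            Transition("P1", "RL", "k_p1", 1.0 - branch),
            Transition("P2", "RS", "k_p2", branch),
            Transition("P2", "RL", "k_p2", 1.0 - branch),
            Transition("RS", "T", "k_r"),
            Transition("RL", "T", "k_r"),
            Transition("T", None, "k_t"),
        ),
        initial_populations=np.array([p0_split, 1.0 - p0_split, 0.0, 0.0, 0.0]),
        init_rates={
            "k_p1": 1.0 / tau_p1,
            "k_p2": 1.0 / tau_p2,
            "k_r": 1.0 / tau_r,
            "k_t": 1.0 / tau_t,
        },
    )


class TargetKineticModel:
    """Direct compartmental fit: free rates, spectra by linear projection.

    Equivalent to :func:`das_to_sas` on noiseless data, but fits the scheme
    to the surface in one step — rates are the nonlinear parameters and the
    species spectra are solved linearly from the concentration profiles at
    each iteration.
    """

    def __init__(
        self,
        surface: TimeResolvedSurface,
        template: SchemeTemplate,
        irf: IRFModel | None = None,
    ) -> None:
        self.surface = surface
        self.template = template
        self.irf = irf

    def _profiles(self, log_rates: np.ndarray) -> tuple[KineticScheme, np.ndarray]:
        rates = dict(zip(self.template.param_names, np.exp(log_rates)))
        scheme = self.template.build(rates)
        C = concentration_profiles(scheme, self.surface.times, self.irf)
        return scheme, C

    def _residual(self, log_rates: np.ndarray) -> np.ndarray:
        _, C = self._profiles(log_rates)
        A = _solve_amplitudes(C, self.surface.signal)
        return (self.surface.signal - C @ A).ravel()

    def fit(self, xtol: float = 1e-12, ftol: float = 1e-12, max_nfev: int | None = None) -> "TargetResults":
        x0 = np.log([self.template.init_rates[p] for p in self.template.param_names])
        res = least_squares(
            self._residual, x0, method="trf", xtol=xtol, ftol=ftol,
            gtol=1e-12, max_nfev=max_nfev,
        )
        scheme, C = self._profiles(res.x)
        A = _solve_amplitudes(C, self.surface.signal)
        resid = self.surface.signal - C @ A
        rms = float(np.sqrt(np.mean(resid**2)))
        rates = dict(zip(self.template.param_names, np.exp(res.x)))

        dof = max(resid.size - (len(res.x) + A.size), 1)
        s2 = float(np.sum(resid**2)) / dof
        try:
            cov_log = s2 * np.linalg.inv(res.jac.T @ res.jac)
            se_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
        except np.linalg.LinAlgError:
            se_log = np.full(len(res.x), np.nan)
        rate_stderr = {
            p: rates[p] * se for p, se in zip(self.template.param_names, se_log)
        }

        window = float(self.surface.times[-1] - self.surface.times[0])
        sas = SASResults(
            scheme=scheme,
            species_spectra=A,
            concentrations=C,
            wavelengths=self.surface.wavelengths,
            times=self.surface.times,
        )
        return TargetResults(
            model=self,
            scheme=scheme,
            sas=sas,
            rates=rates,
            rate_stderr=rate_stderr,
            fit_residual_rms=rms,
            converged=bool(res.status > 0),
            n_function_evals=int(res.nfev),
            poorly_determined={
                p: (1.0 / k) > 0.5 * window for p, k in rates.items()
            },
            optimizer_message=str(res.message),
        )


@dataclass
class TargetResults:
    """Fitted compartmental scheme with its species spectra and diagnostics."""

    model: TargetKineticModel
    scheme: KineticScheme
    sas: SASResults
    rates: dict[str, float]
    rate_stderr: dict[str, float]
    fit_residual_rms: float
    converged: bool
    n_function_evals: int = 0
    poorly_determined: dict[str, bool] = field(default_factory=dict)
    optimizer_message: str = ""

    @property
    def lifetimes(self) -> dict[str, float]:
        """Fitted time constants 1/k per rate parameter, in ps."""
        return {p: 1.0 / k for p, k in self.rates.items()}

    def summary(self) -> str:
        lines = [
            "Target kinetic fit",
            "=" * 54,
            "compartments: " + ", ".join(self.scheme.compartment_names),
            f"converged: {self.converged}   residual RMS: {self.fit_residual_rms:.4g}",
            "-" * 54,
            f"{'rate':>8} {'k (1/ps)':>12} {'tau (ps)':>12} {'stderr(k)':>11} {'note':>12}",
        ]
        for p, k in self.rates.items():
            note = "lower bound" if self.poorly_determined.get(p) else ""
            lines.append(
                f"{p:>8} {k:>12.4g} {1.0 / k:>12.4g} "
                f"{self.rate_stderr.get(p, float('nan')):>11.2g} {note:>12}"
            )
        return "\n".join(lines)
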