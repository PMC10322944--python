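"""First-order compartmental kinetics for time-resolved spectroscopy.

Containers for time x wavelength surfaces and kinetic schemes, the
Gaussian-IRF-convolved exponential basis used throughout the global
analysis, closed-form and ODE concentration profiles, SVD rank estimation,
and the DAS -> SAS transform that imposes a kinetic scheme on a
multi-exponential fit.

Conventions
-----------
Rate matrix ``K``: ``K[j, i]`` is the transfer rate (1/ps) from compartment
``i`` to compartment ``j``; ``K[i, i]`` is minus the total outflow from
``i`` (transfers plus terminal loss), so ``dc/dt = K c``.  Lifetimes are the
negative reciprocal eigenvalues of ``K``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import erfcx

from .errors import ModelInconsistencyError

_SQRT2 = np.sqrt(2.0)
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class IRFModel:
    """Gaussian instrument response: centre ``t0`` and FWHM, both in ps."""

    t0: float = 0.0
    fwhm: float = 0.1

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise ValueError("IRF fwhm must be positive")

    @property
    def sigma(self) -> float:
        return self.fwhm * _FWHM_TO_SIGMA


@dataclass
class TimeResolvedSurface:
    """A transient-absorption or fluorescence surface over time x wavelength."""

    times: np.ndarray          # ps, strictly increasing
    wavelengths: np.ndarray    # nm, strictly increasing
    signal: np.ndarray         # (n_times, n_wavelengths)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.signal.shape != (len(self.times), len(self.wavelengths)):
            raise ValueError(
                f"signal shape {self.signal.shape} does not match axes "
                f"({len(self.times)}, {len(self.wavelengths)})"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.signal.shape

    def to_csv(self, path: str | Path) -> None:
        """Write as delimited text: first row wavelengths, first column times.

        A JSON sidecar ``<path>.meta.json`` carries the metadata.
        """
        path = Path(path)
        header = np.concatenate([[np.nan], self.wavelengths])
        body = np.column_stack([self.times, self.signal])
        np.savetxt(path, np.vstack([header, body]), delimiter=",", fmt="%.10g")
        if self.metadata:
            path.with_suffix(path.suffix + ".meta.json").write_text(
                json.dumps(self.metadata, indent=2, sort_keys=True)
            )

    @classmethod
    def from_csv(cls, path: str | Path, delimiter: str | None = None) -> "TimeResolvedSurface":
        path = Path(path)
        if delimiter is None:
            delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        raw = np.loadtxt(path, delimiter=delimiter)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            times=raw[1:, 0],
            wavelengths=raw[0, 1:],
            signal=raw[1:, 1:],
            metadata=metadata,
        )


# ---------------------------------------------------------------------------
# kinetic schemes
# ---------------------------------------------------------------------------


@dataclass
class KineticScheme:
    """Named compartments with a first-order rate matrix and initial state."""

    compartment_names: tuple[str, ...]
    rate_matrix: np.ndarray        # (n, n), ps^-1
    initial_populations: np.ndarray  # (n,), sums to 1

    def __post_init__(self) -> None:
        self.compartment_names = tuple(self.compartment_names)
        n = len(self.compartment_names)
        K = np.asarray(self.rate_matrix, dtype=float)
        p0 = np.asarray(self.initial_populations, dtype=float)
        if K.shape != (n, n):
            raise ValueError(f"rate matrix must be {n}x{n}, got {K.shape}")
        if not np.all(np.isfinite(K)):
            raise ValueError("rate matrix contains non-finite entries")
        off = K[~np.eye(n, dtype=bool)]
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal transfer rates must be non-negative")
        # each column's total outflow must cover its transfers (loss >= 0)
        if np.any(K.sum(axis=0) > 1e-9):
            raise ValueError("column sums of K must be <= 0 (no population creation)")
        if np.any(p0 < 0) or not np.isclose(p0.sum(), 1.0):
            raise ValueError("initial populations must be >= 0 and sum to 1")
        self.rate_matrix = K
        self.initial_populations = p0

    @property
    def n_compartments(self) -> int:
        return len(self.compartment_names)

    def eigen(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues and eigenvectors of K (real-valued for valid schemes)."""
        lam, V = np.linalg.eig(self.rate_matrix)
        if np.max(np.abs(lam.imag)) > 1e-9 * max(np.max(np.abs(lam.real)), 1e-30):
            raise ModelInconsistencyError(
                "rate matrix has complex eigenvalues; not a simple relaxation scheme"
            )
        order = np.argsort(lam.real)  # fastest (most negative) first
        return lam.real[order], V.real[:, order]

    def lifetimes(self) -> np.ndarray:
        """Decay lifetimes (ps) = -1/eigenvalues, sorted ascending; inf for 0."""
        lam, _ = self.eigen()
        with np.errstate(divide="ignore"):
            taus = np.where(lam < 0, -1.0 / lam, np.inf)
        return np.sort(taus)


def sequential_scheme(
    lifetimes: Sequence[float], names: Sequence[str] | None = None
) -> KineticScheme:
    """A -> B -> ... chain; the last compartment decays to the ground state."""
    taus = np.asarray(lifetimes, dtype=float)
    if np.any(taus <= 0):
        raise ValueError("lifetimes must be positive")
    n = len(taus)
    K = np.zeros((n, n))
    for i, tau in enumerate(taus):
        K[i, i] = -1.0 / tau
        if i + 1 < n:
            K[i + 1, i] = 1.0 / tau
    p0 = np.zeros(n)
    p0[0] = 1.0
    names = tuple(names) if names is not None else tuple(f"S{i + 1}" for i in range(n))
    return KineticScheme(names, K, p0)


def parallel_scheme(
    lifetimes: Sequence[float],
    names: Sequence[str] | None = None,
    populations: Sequence[float] | None = None,
) -> KineticScheme:
    """Independent compartments, each decaying straight to the ground state."""
    taus = np.asarray(lifetimes, dtype=float)
    n = len(taus)
    K = np.diag(-1.0 / taus)
    p0 = (
        np.asarray(populations, dtype=float)
        if populations is not None
        else np.full(n, 1.0 / n)
    )
    names = tuple(names) if names is not None else tuple(f"S{i + 1}" for i in range(n))
    return KineticScheme(names, K, p0)


def rod_energy_transfer_scheme(
    tau_p1: float = 3.6,
    tau_p2: float = 25.0,
    tau_r: float = 200.0,
    tau_t: float = 1999.0,
    branch: float = 0.5,
    p0_split: float = 0.5,
) -> KineticScheme:
    """The branched downhill scheme of a phycocyanin rod.

    Two donor pools P1 (peripheral alpha-84/beta-155 bilins) and P2 (interior
    beta-82 bilins) feed two intermediate red bilins RS and RL, which relax
    with a common lifetime into the terminal red bilin T:

        P1(3.6 ps) / P2(25 ps) -> RS/RL (200 ps) -> T (~2 ns)

    ``branch`` is the fraction of each donor's outflow routed to RS (the rest
    to RL); ``p0_split`` the initial excitation fraction on P1.
    """
    names = ("P1", "P2", "RS", "RL", "T")
    K = np.zeros((5, 5))
    for i, tau in enumerate((tau_p1, tau_p2)):
        k = 1.0 / tau
        K[i, i] = -k
        K[2, i] = branch * k
        K[3, i] = (1.0 - branch) * k
    for i in (2, 3):
        K[i, i] = -1.0 / tau_r
        K[4, i] = 1.0 / tau_r
    K[4, 4] = -1.0 / tau_t
    p0 = np.array([p0_split, 1.0 - p0_split, 0.0, 0.0, 0.0])
    return KineticScheme(names, K, p0)


# ---------------------------------------------------------------------------
# IRF-convolved exponential basis
# ---------------------------------------------------------------------------


def exp_conv_irf(times: np.ndarray, rate: float, irf: IRFModel | None) -> np.ndarray:
    """exp(-rate * t) * step(t), optionally convolved with a Gaussian IRF.

    The convolved form is the standard exponential x Gaussian closed form,
    evaluated through ``erfcx`` for numerical stability at large
    ``rate * sigma``::

        c(t) = 1/2 exp(-x^2 / 2 s^2) erfcx((k s - x/s) / sqrt(2)),  x = t - t0
    """
    t = np.asarray(times, dtype=float)
    k = float(rate)
    if irf is None:
        out = np.zeros_like(t)
        mask = t >= 0
        out[mask] = np.exp(-np.clip(k * t[mask], -700, 700))
        return out
    s = irf.sigma
    x = t - irf.t0
    z = (k * s - x / s) / _SQRT2
    out = np.empty_like(x)
    small = z < -6.0  # erfc(z) ~ 2: avoid erfcx overflow at large -z
    out[small] = np.exp(np.clip(k * (k * s * s / 2.0 - x[small]), -700, 700))
    zs = z[~small]
    out[~small] = 0.5 * np.exp(-x[~small] ** 2 / (2.0 * s * s)) * erfcx(zs)
    return out


def exponential_basis(
    times: np.ndarray, lifetimes: Sequence[float], irf: IRFModel | None
) -> np.ndarray:
    """Column-stacked IRF-convolved decays, one column per lifetime."""
    return np.column_stack(
        [exp_conv_irf(times, 1.0 / tau, irf) for tau in lifetimes]
    )


# ---------------------------------------------------------------------------
# concentration profiles
# ---------------------------------------------------------------------------


def _eigen_weights(scheme: KineticScheme) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues and the mixing matrix W with c(t) = E(t) @ W.

    ``E(t)`` holds the (convolved) exponentials of the eigenvalues and
    ``W[j, i] = V[i, j] * (V^-1 p0)[j]``.
    """
    lam, V = scheme.eigen()
    w = np.linalg.solve(V, scheme.initial_populations)
    W = (V * w).T
    return lam, W


def concentration_profiles(
    scheme: KineticScheme,
    times: np.ndarray,
    irf: IRFModel | None = None,
    method: str = "auto",
) -> np.ndarray:
    """Populations c(t) solving dc/dt = K c, c(0) = p0, IRF-convolved.

    ``method='analytic'`` uses the eigen-decomposition with closed-form
    exponential x erfc terms (requires a diagonalisable K); ``'ode'``
    integrates numerically (and convolves numerically when an IRF is given);
    ``'auto'`` prefers the analytic path and falls back on the ODE path when
    the eigenvector matrix is ill-conditioned.
    """
    t = np.asarray(times, dtype=float)
    if method not in {"auto", "analytic", "ode"}:
        raise ValueError(f"unknown method {method!r}")
    if method in {"auto", "analytic"}:
        lam, V = scheme.eigen()
        cond = np.linalg.cond(V)
        if cond < 1e8:
            _, W = _eigen_weights(scheme)
            E = np.column_stack([exp_conv_irf(t, -l, irf) for l in lam])
            return E @ W
        if method == "analytic":
            raise ModelInconsistencyError(
                f"rate matrix is not safely diagonalisable (cond={cond:.2g}); "
                "use method='ode'"
            )
    return _ode_profiles(scheme, t, irf)


def _ode_profiles(
    scheme: KineticScheme, times: np.ndarray, irf: IRFModel | None
) -> np.ndarray:
    K = scheme.rate_matrix
    p0 = scheme.initial_populations

    def rhs(_t, c):
        return K @ c

    if irf is None:
        pos = times[times > 0]
        out = np.zeros((len(times), scheme.n_compartments))
        out[times == 0] = p0
        if len(pos):
            sol = solve_ivp(
                rhs, (0.0, pos[-1]), p0, t_eval=pos, method="LSODA",
                rtol=1e-10, atol=1e-12,
            )
            out[times > 0] = sol.y.T
        return out
    # numerical convolution on a fine uniform grid, then interpolation
    s = irf.sigma
    lo = min(times.min() - irf.t0, -6 * s)
    hi = times.max() - irf.t0 + s
    dt = min(s / 10.0, np.min(np.diff(times)) / 4.0 if len(times) > 1 else s / 10.0)
    grid = np.arange(lo, hi + dt, dt)
    pos = grid[grid >= 0]
    base = np.zeros((len(grid), scheme.n_compartments))
    if len(pos):
        sol = solve_ivp(
            rhs, (0.0, pos[-1] + dt), p0, t_eval=pos, method="LSODA",
            rtol=1e-10, atol=1e-12,
        )
        base[grid >= 0] = sol.y.T
    kern_t = np.arange(-6 * s, 6 * s + dt, dt)
    kern = np.exp(-0.5 * (kern_t / s) ** 2)
    kern /= kern.sum()
    conv = np.column_stack(
        [np.convolve(base[:, i], kern, mode="same") for i in range(base.shape[1])]
    )
    out = np.column_stack(
        [np.interp(times - irf.t0, grid, conv[:, i]) for i in range(conv.shape[1])]
    )
    return out


# ---------------------------------------------------------------------------
# SVD rank
# ---------------------------------------------------------------------------


def svd_rank(
    surface: TimeResolvedSurface | np.ndarray,
    noise_factor: float = 5.0,
) -> tuple[np.ndarray, int]:
    """Singular values (descending) and the count above the noise floor.

    The floor is ``noise_factor`` times the median of the trailing half of
    the singular-value spectrum — the trailing values sample the noise.
    A zero matrix has rank 0.
    """
    signal = surface.signal if isinstance(surface, TimeResolvedSurface) else np.asarray(surface)
    if signal.size == 0:
        raise ValueError("empty signal matrix")
    s = np.linalg.svd(signal, compute_uv=False)
    if s[0] == 0.0:
        return s, 0
    floor = noise_factor * float(np.median(s[len(s) // 2:]))
    # numerical floor: values at relative machine precision are not signal
    floor = max(floor, s[0] * max(signal.shape) * np.finfo(signal.dtype).eps)
    rank = int(np.sum(s > floor))
    return s, max(rank, 1)


# ---------------------------------------------------------------------------
# DAS -> SAS
# ---------------------------------------------------------------------------


def match_lifetimes(
    das_lifetimes: np.ndarray, scheme: KineticScheme, rtol: float = 0.05
) -> np.ndarray:
    """Pair sorted DAS lifetimes with scheme eigen-lifetimes; error on mismatch."""
    taus_das = np.sort(np.asarray(das_lifetimes, dtype=float))
    taus_scheme = scheme.lifetimes()
    if len(taus_das) != len(taus_scheme):
        raise ModelInconsistencyError(
            f"{len(taus_das)} DAS components vs {len(taus_scheme)} compartments"
        )
    rel = np.abs(taus_das - taus_scheme) / taus_scheme
    if np.any(rel > rtol):
        raise ModelInconsistencyError(
            "DAS lifetimes inconsistent with scheme eigenvalues: "
            f"DAS {taus_das.round(4).tolist()} vs scheme "
            f"{taus_scheme.round(4).tolist()} (rtol={rtol})"
        )
    return taus_scheme


def das_to_sas_matrices(
    scheme: KineticScheme,
) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-lifetimes (ascending) and mixing matrix W ordered to match them.

    With the exponential basis E(t) ordered by ascending lifetime,
    ``c(t) = E(t) @ W`` and DAS amplitudes relate to species spectra by
    ``A_das = W @ A_sas``.
    """
    lam, V = scheme.eigen()
    w = np.linalg.solve(V, scheme.initial_populations)
    # eigen() sorts fastest first == ascending lifetime already
    W = (V * w).T
    with np.errstate(divide="ignore"):
        taus = np.where(lam < 0, -1.0 / lam, np.inf)
    return taus, W


# ---------------------------------------------------------------------------
# component annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComponentAssignment:
    component_label: str
    lifetime: float
    assigned_bilins: tuple[str, ...]
    rationale: str


def annotate_components(
    lifetimes: Sequence[float],
    ranking: "RankingReport",  # noqa: F821 - geometry import kept lazy
    component_labels: Sequence[str] | None = None,
    bulk_bilins: Sequence[str] = ("a84", "b155"),
) -> list[ComponentAssignment]:
    """Map kinetic components onto structural bilin classes.

    Deterministic rule mirroring the downhill energy-transfer picture:
    the fastest component belongs to the peripheral bilins with no linker
    contact (``bulk_bilins``); the slowest to the top-ranked red-bilin
    candidate; intermediate components to the remaining ranked candidates,
    least-flat first (they sit higher in the energy funnel).
    """
    taus = np.asarray(lifetimes, dtype=float)
    order = np.argsort(taus)
    labels = (
        list(component_labels)
        if component_labels is not None
        else [f"C{i + 1}" for i in range(len(taus))]
    )
    if len(labels) != len(taus):
        raise ValueError("component_labels length must match lifetimes")

    ranked = list(ranking.entries)  # flattest first
    top = ranked[0]
    middles = ranked[1:][::-1]  # least flat first

    assignments: list[ComponentAssignment] = []
    sorted_idx = list(order)
    for pos, idx in enumerate(sorted_idx):
        lbl, tau = labels[idx], float(taus[idx])
        if len(sorted_idx) > 1 and pos == 0:
            assignments.append(
                ComponentAssignment(
                    lbl, tau, tuple(bulk_bilins),
                    "fastest component: peripheral bilins without linker contact",
                )
            )
        elif pos == len(sorted_idx) - 1:
            assignments.append(
                ComponentAssignment(
                    lbl, tau, (top.bilin_label,),
                    "slowest component: flattest, most linker-engaged bilin "
                    "(terminal red bilin)",
                )
            )
        else:
            j = pos - 1
            if j < len(middles):
                assignments.append(
                    ComponentAssignment(
                        lbl, tau, (middles[j].bilin_label,),
                        "intermediate component: ranked red-bilin candidate "
                        f"(planarity rank {len(middles) - j} of {len(ranked)})",
                    )
                )
            else:
                warnings.warn(
                    f"component {lbl}: no structural class left to assign",
                    stacklevel=2,
                )
                assignments.append(
                    ComponentAssignment(lbl, tau, (), "unassigned: fewer structural "
                                        "classes than kinetic components")
                )
    return assignments
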