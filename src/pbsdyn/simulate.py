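"""Synthetic structures and spectroscopy surfaces with known ground truth.

Two generators:

* idealised open-chain tetrapyrroles whose adjacent pyrrole-plane angles are
  prescribed exactly, so plane fitting and angle recovery can be verified by
  round trip;
* time x wavelength surfaces built from Gaussian spectral bands evolving
  under a first-order kinetic scheme with a Gaussian IRF and additive
  noise, so SVD, global DAS fitting and target analysis can be verified
  against their generating parameters.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .kinetics import (
    IRFModel,
    KineticScheme,
    TimeResolvedSurface,
    concentration_profiles,
    rod_energy_transfer_scheme,
    sequential_scheme,
)
from .structure import Atom, BilinInstance, Chain, Residue, StructureModel

# ---------------------------------------------------------------------------
# tetrapyrrole geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TetrapyrroleSpec:
    """Prescription for one synthetic bilin.

    Angles in degrees within [0, 90]; ``ring_radius`` is the pentagon
    circumradius (a 1.38-Angstrom pyrrole bond gives ~1.17), and
    ``bridge_length`` the centroid-to-centroid spacing of adjacent rings.
    ``jitter_sigma`` adds isotropic Gaussian displacement to every atom.
    """

    theta_ab: float = 26.0
    theta_bc: float = 7.0
    theta_cd: float = 8.0
    ring_radius: float = 1.17
    bridge_length: float = 5.2
    jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("theta_ab", "theta_bc", "theta_cd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 90.0:
                raise ValueError(f"{name}={v} outside [0, 90]")
        if self.ring_radius <= 0 or self.bridge_length <= 0:
            raise ValueError("ring_radius and bridge_length must be positive")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


def _rot_x(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def make_tetrapyrrole(
    spec: TetrapyrroleSpec,
    label: str = "synthetic",
    chain_id: str = "X",
    residue_number: int = 201,
    residue_name: str = "CYC",
) -> BilinInstance:
    """Build a four-ring bilin whose fitted inter-plane angles equal the spec.

    Rings are planar pentagons strung along the x axis; each successive ring
    is rotated about that shared bridge axis by the prescribed angle
    increment.  Because the bridge axis lies in every ring plane, the angle
    between fitted adjacent planes equals the construction angle exactly at
    zero jitter (the round-trip property is the contract).
    """
    rng = np.random.default_rng(spec.seed)
    cumulative = np.cumsum([0.0, spec.theta_ab, spec.theta_bc, spec.theta_cd])
    atoms: list[Atom] = []
    pent = np.array(
        [
            [np.cos(2 * np.pi * j / 5), np.sin(2 * np.pi * j / 5), 0.0]
            for j in range(5)
        ]
    ) * spec.ring_radius
    for i, ring in enumerate("ABCD"):
        R = _rot_x(cumulative[i])
        center = np.array([i * spec.bridge_length, 0.0, 0.0])
        coords = pent @ R.T + center
        names = (f"N{ring}", f"C1{ring}", f"C2{ring}", f"C3{ring}", f"C4{ring}")
        for name, pos in zip(names, coords):
            if spec.jitter_sigma > 0:
                pos = pos + rng.normal(0.0, spec.jitter_sigma, 3)
            atoms.append(
                Atom(
                    name=name,
                    element="N" if name.startswith("N") else "C",
                    position=pos,
                    residue_name=residue_name,
                    residue_number=residue_number,
                    chain_id=chain_id,
                    is_hydrogen=False,
                )
            )
    return BilinInstance(label=label, host_chain_id=chain_id, atoms=atoms)


def _poly_ala_chain(
    chain_id: str, start: np.ndarray, n_res: int = 5, spacing: float = 3.8
) -> Chain:
    """A minimal C-alpha-only polyalanine chain (classified as polymer)."""
    residues = []
    for i in range(n_res):
        pos = start + np.array([0.0, 0.0, i * spacing])
        residues.append(
            Residue(
                name="ALA",
                number=i + 1,
                atoms=[
                    Atom("CA", "C", pos, "ALA", i + 1, chain_id, False)
                ],
            )
        )
    return Chain(chain_id=chain_id, residues=residues, is_polymer=True)


def _outward(atom_pos: np.ndarray, centroid: np.ndarray, dist: float) -> np.ndarray:
    """A point ``dist`` Angstrom beyond ``atom_pos`` along the ray from the
    centroid, so its nearest bilin atom is the chosen one."""
    u = atom_pos - centroid
    n = np.linalg.norm(u)
    u = u / n if n > 1e-9 else np.array([0.0, 1.0, 0.0])
    return atom_pos + dist * u


def _cys_anchor(chain_id: str, bilin: BilinInstance, number: int = 82) -> Residue:
    """A cysteine whose SG sits on the ring-A thioether position of ``bilin``."""
    centroid = bilin.coordinates().mean(axis=0)
    pos = _outward(bilin.atom("C3A").position, centroid, 1.9)
    return Residue(
        name="CYS",
        number=number,
        atoms=[Atom("SG", "S", pos, "CYS", number, chain_id, False)],
    )


def _arg_residue(
    chain_id: str, number: int, bilin: BilinInstance, ring: str, offset: float = 3.5
) -> Residue:
    """An arginine decoy ``offset`` Angstrom above the face of one pyrrole ring.

    Sitting on the ring normal keeps it within a 4-Angstrom contact cutoff
    of that ring while staying clear of the other rings and of the covalent
    cysteine anchor.
    """
    ring_atoms = np.array(
        [a.position for a in bilin.atoms if a.name.endswith(ring)]
    )
    center = ring_atoms.mean(axis=0)
    # plane normal from two in-plane edges
    n = np.cross(ring_atoms[1] - ring_atoms[0], ring_atoms[2] - ring_atoms[0])
    n /= np.linalg.norm(n)
    pos = center + offset * n
    return Residue(
        name="ARG",
        number=number,
        atoms=[Atom("CZ", "C", pos, "ARG", number, chain_id, False)],
    )


def make_toy_rod(
    specs: Sequence[TetrapyrroleSpec] | None = None,
    arg_signatures: Sequence[Sequence[int]] = ((178, 112, 181), (), (16, 163, 169)),
    linker_chain_id: str = "L",
    accession_label: str = "synthetic-rod",
) -> tuple[StructureModel, list[BilinInstance]]:
    """A synthetic bottom trimer: three beta-82-like bilins around a linker.

    Each bilin hangs on its own minimal host chain and is flanked by the
    arginine residues listed in ``arg_signatures`` (an empty tuple means a
    bilin with no arginine contact, the hallmark of monomer 2).  The model
    contains exactly the features the labelling and contact machinery looks
    at; it stands in for no particular deposition.
    """
    if specs is None:
        specs = (
            TetrapyrroleSpec(26.0, 7.0, 21.0, seed=1),
            TetrapyrroleSpec(26.0, 7.0, 8.0, seed=2),
            TetrapyrroleSpec(26.0, 7.0, 25.0, seed=3),
        )
    if len(specs) != len(arg_signatures):
        raise ValueError("one arginine signature per bilin required")

    chains: list[Chain] = []
    bilins: list[BilinInstance] = []
    linker_residues: list[Residue] = []
    for i, (spec, sig) in enumerate(zip(specs, arg_signatures)):
        host_id = chr(ord("A") + i)
        # spread the bilins azimuthally in the x-y plane around the rod axis
        angle = 2 * np.pi * i / max(len(specs), 1)
        shift = 18.0 * np.array([np.cos(angle), np.sin(angle), 0.0])
        bilin = make_tetrapyrrole(
            spec,
            label=f"toy-{i + 1}",
            chain_id=host_id,
            residue_number=201,
        )
        moved = [replace(a, position=a.position + shift) for a in bilin.atoms]
        bilin = BilinInstance(label=bilin.label, host_chain_id=host_id, atoms=moved)
        # a long backbone makes the principal axis of the toy the z axis
        host = _poly_ala_chain(host_id, shift + np.array([-5.0, -5.0, 3.0]), n_res=30)
        host.residues.append(_cys_anchor(host_id, bilin))
        host.residues.append(
            Residue(
                name=bilin.residue_name,
                number=bilin.residue_number,
                atoms=list(bilin.atoms),
            )
        )
        chains.append(host)
        bilins.append(bilin)
        for j, num in enumerate(sig):
            linker_residues.append(
                _arg_residue(linker_chain_id, num, bilin, ring="BCD"[j % 3])
            )
        if not sig:
            # the red bilin interacts with the linker without arginines:
            # put polar decoys (ASN/GLN) on rings C and D instead
            for j, (name, num) in enumerate((("ASN", 55), ("GLN", 57))):
                res = _arg_residue(linker_chain_id, num, bilin, ring="CD"[j])
                res.name = name
                res.atoms = [replace(a, residue_name=name) for a in res.atoms]
                linker_residues.append(res)

    # give the linker a polymer backbone below the trimer plus its arginines
    linker = _poly_ala_chain(linker_chain_id, np.array([0.0, 0.0, -40.0]), n_res=4)
    linker.residues.extend(linker_residues)
    chains.append(linker)
    model = StructureModel(accession_label=accession_label, chains=chains)
    return model, bilins


def toy_structure_model(
    spec: TetrapyrroleSpec,
    accession_label: str = "synthetic-bilin",
) -> StructureModel:
    """A single synthetic bilin wrapped in a one-chain structure model."""
    bilin = make_tetrapyrrole(spec, chain_id="A")
    chain = _poly_ala_chain("A", np.array([-6.0, -6.0, 0.0]))
    chain.residues.append(_cys_anchor("A", bilin))
    chain.residues.append(
        Residue(name=bilin.residue_name, number=bilin.residue_number,
                atoms=list(bilin.atoms))
    )
    return StructureModel(accession_label=accession_label, chains=[chain])


# ---------------------------------------------------------------------------
# spectroscopy surfaces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Band:
    """One Gaussian spectral component: centre (nm), width sigma (nm), amplitude."""

    center: float
    width: float
    amplitude: float = 1.0


@dataclass(frozen=True)
class SurfaceSpec:
    """Prescription for a synthetic time-resolved surface.

    ``bands`` holds one band list per scheme compartment; transient
    absorption compartments typically pair a negative ground-state bleach
    with a weaker positive excited-state-absorption lobe.
    """

    scheme: KineticScheme
    bands: tuple[tuple[Band, ...], ...]
    irf: IRFModel | None = field(default_factory=IRFModel)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.bands) != self.scheme.n_compartments:
            raise ValueError(
                f"{len(self.bands)} band sets for "
                f"{self.scheme.n_compartments} compartments"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def species_spectra(spec: SurfaceSpec, wavelengths: np.ndarray) -> np.ndarray:
    """The generating band matrix B (n_compartments x n_wavelengths)."""
    wl = np.asarray(wavelengths, dtype=float)
    B = np.zeros((spec.scheme.n_compartments, len(wl)))
    for i, bands in enumerate(spec.bands):
        for band in bands:
            B[i] += band.amplitude * np.exp(
                -0.5 * ((wl - band.center) / band.width) ** 2
            )
    return B


def make_surface(
    spec: SurfaceSpec, times: np.ndarray, wavelengths: np.ndarray
) -> TimeResolvedSurface:
    """signal = concentrations(scheme, IRF) x band matrix + Gaussian noise."""
    t = np.asarray(times, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    C = concentration_profiles(spec.scheme, t, spec.irf)
    B = species_spectra(spec, wl)
    signal = C @ B
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        scale = spec.noise_sigma * float(np.max(np.abs(signal)))
        signal = signal + rng.normal(0.0, scale, signal.shape)
    return TimeResolvedSurface(
        times=t,
        wavelengths=wl,
        signal=signal,
        metadata={
            "mode": "synthetic",
            "true_lifetimes_ps": [
                float(x) for x in spec.scheme.lifetimes() if np.isfinite(x)
            ],
            "noise_sigma": spec.noise_sigma,
            "seed": spec.seed,
        },
    )


def ta_surface_spec(noise_sigma: float = 0.01, seed: int = 0) -> SurfaceSpec:
    """Transient-absorption preset for the rod energy-transfer scheme.

    Bleach positions follow the five components resolved in CpcL-PBS
    transient absorption (631, 637, 644, 668 and 669 nm); each bleach is
    paired with a weaker positive excited-state-absorption lobe to the red,
    as observed for the donor pools (671 and 675 nm).
    """
    return SurfaceSpec(
        scheme=rod_energy_transfer_scheme(),
        bands=(
            (Band(631.0, 9.0, -1.0), Band(671.0, 12.0, 0.35)),
            (Band(637.0, 9.0, -1.0), Band(675.0, 12.0, 0.35)),
            (Band(644.0, 9.0, -1.0), Band(686.0, 13.0, 0.25)),
            (Band(668.0, 9.0, -1.0), Band(700.0, 13.0, 0.25)),
            (Band(669.0, 10.0, -1.2), Band(702.0, 14.0, 0.2)),
        ),
        irf=IRFModel(t0=0.0, fwhm=0.1),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def fluorescence_surface_spec(noise_sigma: float = 0.01, seed: int = 0) -> SurfaceSpec:
    """Streak-camera preset: three sequential emitting pools.

    Lifetimes 101 / 401 / 1999 ps; the middle pool emits a double band
    (651 and 669 nm), the terminal pool at 672 nm, matching the emission
    components of CpcL-PBS.
    """
    return SurfaceSpec(
        scheme=sequential_scheme([101.0, 401.0, 1999.0], names=("C645", "C651_669", "C672")),
        bands=(
            (Band(645.0, 11.0, 1.0),),
            (Band(651.0, 10.0, 0.7), Band(669.0, 10.0, 0.6)),
            (Band(672.0, 11.0, 1.0),),
        ),
        irf=IRFModel(t0=0.0, fwhm=30.0),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def default_ta_axes(
    n_times: int = 160, n_wavelengths: int = 80
) -> tuple[np.ndarray, np.ndarray]:
    """Axes emulating a pump-probe scan: dense early delays, log-spaced tail,
    a few pre-excitation rows, probe window 550-720 nm."""
    early = np.linspace(-1.0, 2.0, n_times // 4)
    late = np.geomspace(2.2, 6000.0, n_times - n_times // 4)
    times = np.concatenate([early, late])
    wavelengths = np.linspace(550.0, 720.0, n_wavelengths)
    return times, wavelengths


def default_fluorescence_axes(
    n_times: int = 140, n_wavelengths: int = 70
) -> tuple[np.ndarray, np.ndarray]:
    """Streak-camera-like axes: uniform 0-5 ns sweep, 600-760 nm window."""
    times = np.linspace(-100.0, 5000.0, n_times)
    wavelengths = np.linspace(600.0, 760.0, n_wavelengths)
    return times, wavelengths
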