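"""Quantitative bilin geometry: ring planes, inter-ring angles, superposition
RMSD and contact maps.

A phycocyanobilin's conformation is summarised by the acute angles between
the least-squares planes of its four pyrrole rings (A-B, B-C, C-D).  Smaller
angles mean a flatter, more conjugated, red-shifted chromophore; ranking
bilins by planarity together with their linker contacts identifies the
terminal-emitter-like "red" bilin of a rod.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, RingResolutionError, SelectionError
from .structure import Atom, BilinInstance, StructureModel

RING_LABELS = ("A", "B", "C", "D")

#: Default pyrrole-ring atom sets: the five-membered ring only (N + 4 ring
#: carbons), following the chemical-component definition of phycocyanobilin.
#: Exocyclic substituents are excluded; the mapping is configurable so the
#: sensitivity of the angles to the ring definition can be probed.
DEFAULT_RING_ATOMS: Mapping[str, tuple[str, ...]] = {
    X: (f"N{X}", f"C1{X}", f"C2{X}", f"C3{X}", f"C4{X}") for X in RING_LABELS
}


@dataclass(frozen=True)
class RingPlane:
    """Total-least-squares plane through a set of points."""

    centroid: np.ndarray
    normal: np.ndarray
    planarity_rms: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("plane normal must be unit length")
        if self.planarity_rms < 0:
            raise ValueError("planarity_rms must be >= 0")


@dataclass(frozen=True)
class BilinConformation:
    """The three adjacent inter-ring angles of one bilin, in degrees."""

    bilin_label: str
    theta_ab: float
    theta_bc: float
    theta_cd: float
    planes: Mapping[str, RingPlane] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name, v in (("theta_ab", self.theta_ab), ("theta_bc", self.theta_bc),
                        ("theta_cd", self.theta_cd)):
            if not 0.0 <= v <= 90.0:
                raise ValueError(f"{name}={v} outside [0, 90] degrees")

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.theta_ab, self.theta_bc, self.theta_cd)

    @property
    def planarity_score(self) -> float:
        """Negated angle sum: higher = flatter bilin."""
        return -(self.theta_ab + self.theta_bc + self.theta_cd)


@dataclass(frozen=True)
class ContactRecord:
    bilin_label: str
    partner_chain_id: str
    partner_residue_name: str
    partner_residue_number: int
    partner_atom: str
    bilin_atom: str
    distance: float


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid alignment of a mobile selection onto a reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_fit: float
    rmsd_target: float | None = None

    def transform(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# planes and angles
# ---------------------------------------------------------------------------


def fit_plane(points: np.ndarray, orient_toward: np.ndarray | None = None) -> RingPlane:
    """Fit the total-least-squares plane through ``points`` (n x 3, n >= 3).

    The plane minimises the sum of squared orthogonal distances; the normal
    is the singular vector of the smallest singular value of the centred
    coordinates.  ``orient_toward`` fixes the otherwise arbitrary sign of
    the normal (used only for deterministic reporting; angles take the
    absolute dot product anyway).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateGeometryError(
            f"plane fit needs >= 3 points in 3D, got shape {pts.shape}"
        )
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear: second singular value vanishes relative to the first
    if s[1] <= max(s[0], 1e-12) * 1e-8:
        raise DegenerateGeometryError("points are collinear; plane is undefined")
    normal = vt[2]
    if orient_toward is not None and normal @ (np.asarray(orient_toward) - centroid) < 0:
        normal = -normal
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return RingPlane(centroid=centroid, normal=normal, planarity_rms=rms)


def inter_ring_angle(p1: RingPlane, p2: RingPlane) -> float:
    """Acute angle between two planes in degrees: arccos(|n1 . n2|).

    Evaluated as atan2(|n1 x n2|, |n1 . n2|), which keeps full precision for
    near-parallel planes where arccos alone loses half the digits.
    """
    dot = abs(float(np.dot(p1.normal, p2.normal)))
    cross = float(np.linalg.norm(np.cross(p1.normal, p2.normal)))
    return float(np.degrees(np.arctan2(cross, dot)))


def _ring_atoms(bilin: BilinInstance, names: Sequence[str]) -> list[Atom]:
    lookup = {a.name: a for a in bilin.atoms}
    missing = [n for n in names if n not in lookup]
    if missing:
        raise RingResolutionError(
            f"bilin {bilin.label}: missing ring atoms {missing}"
        )
    return [lookup[n] for n in names]


def bilin_conformation(
    bilin: BilinInstance,
    ring_atoms: Mapping[str, Sequence[str]] = DEFAULT_RING_ATOMS,
) -> BilinConformation:
    """Fit the four pyrrole-ring planes and return the adjacent angles."""
    planes: dict[str, RingPlane] = {}
    centroids: dict[str, np.ndarray] = {}
    for X in RING_LABELS:
        atoms = _ring_atoms(bilin, ring_atoms[X])
        centroids[X] = np.mean([a.position for a in atoms], axis=0)
    for i, X in enumerate(RING_LABELS):
        atoms = _ring_atoms(bilin, ring_atoms[X])
        # orient each normal toward the next ring's centroid (reporting only)
        nxt = RING_LABELS[i + 1] if i + 1 < len(RING_LABELS) else RING_LABELS[i - 1]
        planes[X] = fit_plane(
            np.array([a.position for a in atoms]), orient_toward=centroids[nxt]
        )
    return BilinConformation(
        bilin_label=bilin.label,
        theta_ab=inter_ring_angle(planes["A"], planes["B"]),
        theta_bc=inter_ring_angle(planes["B"], planes["C"]),
        theta_cd=inter_ring_angle(planes["C"], planes["D"]),
        planes=planes,
    )


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


def superpose(
    reference_atoms: np.ndarray,
    mobile_atoms: np.ndarray,
    target_pairs: tuple[np.ndarray, np.ndarray] | None = None,
) -> SuperpositionResult:
    """Optimal least-squares rigid superposition (Kabsch).

    The rotation/translation minimise the RMSD between the fit selections;
    ``target_pairs`` = (reference_target, mobile_target) measures the RMSD of
    a *different* selection after applying the fitted transform — the fit is
    never repeated on the target (e.g. align on CpcB C-alpha, then measure
    ring-D atoms of the bilin).
    """
    ref = np.asarray(reference_atoms, dtype=float)
    mob = np.asarray(mobile_atoms, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise SelectionError(
            f"fit selections must be equal-shaped (n,3) arrays: {ref.shape} vs {mob.shape}"
        )
    if ref.shape[0] < 3:
        raise DegenerateGeometryError("superposition needs >= 3 fit pairs")
    ref_c, mob_c = ref.mean(axis=0), mob.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    # recompute the RMSD from residuals: the solver's reported rssd loses
    # precision by cancellation when the fit is near-exact
    moved_fit = mob @ R.T + t
    rmsd_fit = float(np.sqrt(np.mean(np.sum((ref - moved_fit) ** 2, axis=1))))
    rmsd_target = None
    if target_pairs is not None:
        tgt_ref = np.asarray(target_pairs[0], dtype=float)
        tgt_mob = np.asarray(target_pairs[1], dtype=float)
        if tgt_ref.shape != tgt_mob.shape:
            raise SelectionError("target selections must be equal-shaped")
        moved = tgt_mob @ R.T + t
        rmsd_target = float(np.sqrt(np.mean(np.sum((tgt_ref - moved) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd_fit=rmsd_fit,
                               rmsd_target=rmsd_target)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def contact_map(
    bilin: BilinInstance,
    model: StructureModel,
    cutoff: float = 4.0,
    exclude_hydrogens: bool = True,
) -> list[ContactRecord]:
    """All (bilin atom, environment atom) pairs within ``cutoff`` Angstrom.

    The distance criterion is inclusive (<= cutoff).  Atoms of the bilin
    residue itself are excluded; records are sorted by distance ascending.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    b_atoms = bilin.heavy_atoms if exclude_hydrogens else list(bilin.atoms)
    if not b_atoms:
        return []
    self_key = (bilin.chain_id, bilin.residue_number, bilin.residue_name)
    partners: list[Atom] = []
    for chain in model.chains:
        for res in chain.residues:
            if (chain.chain_id, res.number, res.name) == self_key:
                continue
            partners.extend(res.heavy_atoms if exclude_hydrogens else res.atoms)
    if not partners:
        return []
    tree = cKDTree(np.array([a.position for a in partners]))
    records: list[ContactRecord] = []
    for ba in b_atoms:
        for j in tree.query_ball_point(ba.position, cutoff):
            pa = partners[j]
            d = float(np.linalg.norm(ba.position - pa.position))
            records.append(
                ContactRecord(
                    bilin_label=bilin.label,
                    partner_chain_id=pa.chain_id,
                    partner_residue_name=pa.residue_name,
                    partner_residue_number=pa.residue_number,
                    partner_atom=pa.name,
                    bilin_atom=ba.name,
                    distance=d,
                )
            )
    records.sort(key=lambda r: (r.distance, r.bilin_atom, r.partner_atom))
    return records


def linker_contact_count(
    contacts: Iterable[ContactRecord], linker_chain_ids: Iterable[str]
) -> int:
    """Number of distinct linker residues contacting the bilin."""
    linkers = set(linker_chain_ids)
    return len(
        {
            (r.partner_chain_id, r.partner_residue_number)
            for r in contacts
            if r.partner_chain_id in linkers
        }
    )


# ---------------------------------------------------------------------------
# red-bilin ranking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankingEntry:
    bilin_label: str
    planarity_score: float
    linker_contacts: int


@dataclass(frozen=True)
class RankingReport:
    """Bilins ordered flattest-first, then by linker-contact count."""

    entries: tuple[RankingEntry, ...]
    ties: tuple[tuple[str, ...], ...] = ()

    @property
    def top_candidate(self) -> RankingEntry:
        return self.entries[0]


def rank_red_candidates(
    conformations: Sequence[BilinConformation],
    contacts: Mapping[str, Sequence[ContactRecord]] | None = None,
    linker_chain_ids: Iterable[str] = (),
    tie_tolerance: float = 1e-9,
) -> RankingReport:
    """Rank bilins as red-bilin candidates.

    Primary key: planarity score (flatter wins).  Secondary key: number of
    linker residues in contact (more interaction with the linker wins).
    Exact ties are reported, never broken silently.
    """
    if not conformations:
        raise ValueError("need at least one conformation to rank")
    contacts = contacts or {}
    linkers = tuple(linker_chain_ids)
    entries = [
        RankingEntry(
            bilin_label=c.bilin_label,
            planarity_score=c.planarity_score,
            linker_contacts=linker_contact_count(contacts.get(c.bilin_label, ()), linkers),
        )
        for c in conformations
    ]
    entries.sort(key=lambda e: (-e.planarity_score, -e.linker_contacts, e.bilin_label))
    ties: list[tuple[str, ...]] = []
    i = 0
    while i < len(entries):
        group = [entries[i]]
        j = i + 1
        while (
            j < len(entries)
            and abs(entries[j].planarity_score - entries[i].planarity_score) <= tie_tolerance
            and entries[j].linker_contacts == entries[i].linker_contacts
        ):
            group.append(entries[j])
            j += 1
        if len(group) > 1:
            ties.append(tuple(e.bilin_label for e in group))
        i = j
    if ties and entries[0].bilin_label in ties[0]:
        warnings.warn(
            f"top red-bilin candidates tied: {ties[0]}", stacklevel=2
        )
    return RankingReport(entries=tuple(entries), ties=tuple(ties))
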