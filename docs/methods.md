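# Methods

This note documents the models, conventions and numerical choices behind
`pbsdyn`, and what its synthetic-data tests do and do not demonstrate.

## Bilin conformation from coordinates

A phycocyanobilin (PCB) is an open-chain tetrapyrrole with four pyrrole
rings A–D; ring A is covalently bound to a cysteine of the phycobiliprotein.
Its effective conjugation — and hence the red shift of its absorption and
emission — grows as the four rings approach coplanarity. We summarise a
bilin's conformation by the three acute angles between the least-squares
planes of adjacent rings.

**Ring definition.** Each pyrrole plane is fitted to the five ring atoms
only (N + four ring carbons, atom names `N{X}`, `C1{X}`…`C4{X}` for
X ∈ {A,B,C,D}, following the wwPDB chemical-component definition of PCB).
Exocyclic substituents (methyls, vinyl, propionates, the ring-A/D carbonyl
oxygens) are excluded. Published angle figures rarely state their atom
convention, so the ring sets are a configurable argument of
`bilin_conformation`; with 5-atom rings, alternative reasonable conventions
move the angles by a few degrees at most, which is why a ±3° band is the
right expectation when comparing against integer-rounded printed values.

**Plane fit.** Total least squares: the normal is the right singular vector
of the smallest singular value of the centred coordinates, which minimises
the sum of squared orthogonal distances. Degeneracy (fewer than three
points, collinearity) raises an error rather than returning a junk plane.
The RMS orthogonal residual is reported as a per-ring planarity measure.
The normal's sign is fixed toward the next ring's centroid — reporting
cosmetics only, since the inter-plane angle uses the absolute dot product.

**Inter-ring angle.** θ = arccos |n₁·n₂| ∈ [0°, 90°], evaluated as
atan2(‖n₁×n₂‖, |n₁·n₂|) to keep full floating precision for near-parallel
planes (a plain arccos loses half the significant digits there, which is
visible at the micro-degree level the round-trip tests demand).

**Planarity score.** −(θ_AB + θ_BC + θ_CD); higher means flatter. The
field's usage is qualitative ("most flattened"); an angle sum is the
simplest aggregate that is monotone in every angle, and the raw angles are
always reported alongside it.

**Superposition.** Closed-form Kabsch alignment
(`scipy.spatial.transform.Rotation.align_vectors` on centred point sets).
The API separates the *fit* selection (typically Cα of a reference subunit,
e.g. CpcB when comparing the same bilin site across two rod structures)
from the *target* selection (e.g. all ring-D heavy atoms of the bilin); the
target RMSD is measured after applying the fit transform and is never
re-minimised. The RMSD is recomputed from residuals because the solver's
reported residual loses precision by cancellation when the fit is
near-exact.

**Contacts.** Plain heavy-atom distance with an inclusive cutoff
(default 4.0 Å), no angular hydrogen-bond criterion — matching how
bilin–protein interactions are usually quoted. Records exclude the bilin's
own residue and are sorted by distance.

**Rod-position labels.** Deposited PBS models do not encode the
rod-nomenclature (hexamer index, trimer layer, site, monomer index) in
chain identifiers, so labelling is necessarily operational:

- hexamer and layer come from the position along the rod's principal axis,
  oriented away from the CpcL linker (the membrane-proximal end), with a
  configurable hexamer height (default 55 Å ≈ one phycocyanin hexamer);
- the attachment site is named by the anchoring cysteine found nearest the
  ring-A thioether carbon: residue 84 → `a84` (α subunit), anything else →
  `b⟨num⟩` (β subunit, 82 or 152–155 depending on numbering);
- within the CpcL-proximal trimer, the three β82 bilins are distinguished
  by their CpcL arginine-contact signature: monomer 1 contacts
  R178/R112/R181, monomer 3 contacts R16/R163/R169, and monomer 2 contacts
  *no* arginine at all. The signature sets are configurable; a clash (two
  bilins claiming one index) raises a labelling error listing the
  candidates instead of guessing.

**Red-bilin ranking.** Candidates are ordered by planarity score, ties
broken by the number of distinct linker residues in contact; exact ties are
reported explicitly. The top candidate is the structural analogue of a
terminal emitter — in a CpcL rod, the flattened bottom-trimer β82 bilin of
monomer 2.

## Global lifetime and target analysis

**Data model.** A surface S(t, λ) of ΔA or fluorescence counts on strictly
increasing time (ps) and wavelength (nm) axes. Pre-excitation rows are kept
and fitted through the IRF, never discarded.

**IRF.** Gaussian with centre t₀ and FWHM (default 0.1 ps, a 100 fs pump).
An exponential decay convolved with it has the closed form

    c(t) = ½ exp(−x²/2s²) · erfcx((ks − x/s)/√2),   x = t − t₀, s = FWHM/2.355

evaluated through the scaled complementary error function for stability at
large k·s, with a plain-exponential branch where erfcx would overflow.
As FWHM → 0 this converges to the sharp exponential (verified to 1e-6 at
FWHM = 1e-4 ps).

**Kinetic schemes.** dc/dt = K c with K[j,i] the i→j transfer rate and
K[i,i] = −(total outflow of i); lifetimes are −1/eigenvalues. Validation
rejects negative transfer rates and population creation (column sums > 0).
Profiles use the eigen-decomposition with the convolved exponential basis;
if the eigenvector matrix is ill-conditioned (non-diagonalisable K), an
LSODA integration with numerical IRF convolution takes over. The analytic
path agrees with an independent ODE oracle to better than 1e-8.

**DAS (GlobalDecayModel).** Variable projection: the k shared lifetimes are
the only nonlinear parameters (fitted as log-lifetimes, so positivity holds
by construction, with scipy's trust-region reflective least squares); the
per-wavelength amplitudes are solved by ordinary linear least squares at
every iteration. The fit is deterministic given the data and starting
values; the default initialisation spaces lifetimes logarithmically across
the time window. Standard errors come from the Jacobian at the solution; a
lifetime exceeding half the measurement window is flagged as effectively a
lower bound. Requesting more components than the SVD rank estimate warns
but proceeds.

**SVD rank.** Singular values above 5× the median of the trailing half of
the spectrum (plus a machine-precision floor) count toward the rank; the
factor is configurable since no universal rule exists. Note that kinetic
rank and spectral rank differ: two pools with equal lifetimes and distinct
spectra raise the spectral rank but not the number of resolvable decay
components, and two pools with 1 nm-apart bands collapse spectrally while
remaining kinetically separable.

**SAS.** For a first-order scheme, the concentration profiles are a fixed
linear mixture of the eigen-decays: c(t) = E(t)·W with
W[j,i] = V[i,j]·(V⁻¹p₀)[j]. Hence DAS amplitudes and species spectra relate
linearly, A_das = W·A_sas, and `das_to_sas` solves that system after
checking the fitted lifetimes against the scheme's eigen-lifetimes
(default 5% relative tolerance; mismatch raises an error naming both sets).
The reconstruction C·A_sas equals the DAS reconstruction identically
(< 1e-10 observed), which is the defining invariant of the transform: a
scheme redistributes amplitude, it cannot improve the fit.

**Target fit (TargetKineticModel).** The same variable projection with the
scheme's free rates as nonlinear parameters: concentrations from the
scheme, spectra by linear solve. On noiseless data this is equivalent to
DAS + `das_to_sas`. The shipped rod template

    P1 --k_p1--> {RS, RL}   P2 --k_p2--> {RS, RL}   RS, RL --k_r--> T --k_t--> ground

ties RS and RL to one relaxation rate (their printed lifetimes coincide)
and splits each donor's outflow 50:50 by default. Two parallel donors and
two parallel intermediates with a common decay are intrinsically degenerate
to fit; the results object therefore reports a standard error for every
rate rather than pretending uniqueness, and the branching fraction and
initial-population split are explicit, fixed parameters of the template,
not fitted.

**Component annotation.** A deterministic rule connects kinetics to
structure: the fastest component is attributed to peripheral bilins with no
linker contact (α84/β155 pools), the slowest to the top-ranked red-bilin
candidate, intermediates to the remaining ranked candidates in ascending
planarity. With fewer structural classes than components the mapping is
partial and warns. The rationale string records which rule fired.

## Synthetic data: what it emulates, what it does not

**Tetrapyrroles.** Four planar pentagons strung along a shared bridge axis,
each rotated about that axis by the prescribed angle increment; because the
axis lies in every ring plane, the fitted inter-plane angles equal the
construction angles exactly at zero jitter. The round-trip property
(generator → conformation, error < 1e-6°) is the contract that makes the
angle pipeline trustworthy. The toy bottom trimer (`make_toy_rod`) adds
minimal host chains with cysteine anchors, a linker chain with
arginine-signature decoys, and the no-arginine flattest bilin in position 2
— the features the labelling and ranking machinery reads, nothing more. It
is synthetic and stands in for no particular deposition; real coordinate
files exercise the identical code path.

**Surfaces.** signal = C(t; scheme, IRF) × Gaussian-band matrix + white
noise scaled to the signal maximum, deterministic per seed. The
transient-absorption preset uses the rod scheme with lifetimes
3.6 / 25 / 200 / 200 / 1999 ps, bleach bands at 631, 637, 644, 668 and
669 nm, each paired with a weaker positive excited-state-absorption lobe to
the red, a 0.1 ps IRF, and 1% noise; the time axis mixes dense early delays
with a log-spaced tail out to 6 ns, as a delay-stage scan does. (One
caveat recorded here: the second donor pool's lifetime is quoted as 25 ps
in the transfer scheme but 40 ps in one figure caption of the source
experiment; the presets use 25 ps and the constructor exposes the
parameter.) The fluorescence preset is a sequential three-pool chain at
101 / 401 / 1999 ps with a 30 ps streak-camera IRF and a double band
(651/669 nm) on the middle pool.

Not emulated: probe chirp/dispersion, coherent artefacts around time zero,
detector saturation, scattering, anisotropy. Passing the recovery tests
therefore shows the estimator is correct and well-conditioned under the
stated noise model — it does not certify performance against those
systematic distortions, which real data carry.

**Recovery study sizes.** The acceptance checks use 160×80 surfaces and 20
noise realisations; at these sizes each DAS+target pair fits in well under
a second, and the median relative lifetime errors land near 1% — an
order of magnitude inside the 10% acceptance band, so the margin is robust,
not tuned.

## Known limitations

- Deposited-structure validation (inter-ring angles of specific bilins,
  cross-structure ring-D RMSD, chain counts) requires the user to supply
  the mmCIF files; nothing is downloaded.
- The rod-position labeller assumes a roughly linear rod with the linker at
  one end; exotic assemblies would need a user-supplied axis.
- Attachment-site naming trusts the host chain's cysteine numbering.
- `das_to_sas` requires as many DAS components as compartments; schemes
  with repeated eigenvalues should be fitted with `TargetKineticModel`
  instead, where the structure of K resolves what the exponential basis
  cannot.
- No excitonic-coupling or Förster-rate modelling: the structural and
  kinetic arms are connected by a ranking heuristic, deliberately not by a
  quantitative spectra-from-geometry model.
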