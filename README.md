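# pbsdyn

Quantitative analysis of **bilin chromophore conformation** and **ultrafast
energy-transfer kinetics** in phycobilisomes (PBS), the light-harvesting
antennae of cyanobacteria and red algae.

The package was built around the rod-type, core-less **CpcL-PBS**: a single
phycocyanin rod anchored to the thylakoid membrane by the CpcL linker that
feeds excitation energy directly to photosystem I. Its red-shifted terminal
emitter is an ordinary phycocyanobilin (PCB) made "red" by conformational
flattening under the linker protein — a structural fact that can be measured
from atomic coordinates and connected to the picosecond components seen in
transient-absorption and time-resolved fluorescence experiments. `pbsdyn`
implements both measurements as reusable, tested building blocks:

**Structural arm**

- mmCIF/PDB parsing (via `gemmi`), extraction of PCB residues
  (wwPDB component codes `CYC`/`PCB`), host-chain attachment and rod-position
  labelling `⟨hexamer⟩⟨trimer layer⟩-⟨site⟩-⟨monomer⟩` (e.g. `1I-b82-2`),
  with the three β82 bilins of the membrane-proximal trimer told apart by
  their CpcL arginine-contact signature.
- Total-least-squares pyrrole-ring planes; the bilin conformation is the
  triple of acute inter-plane angles θ_AB, θ_BC, θ_CD
  (θ = arccos|n₁·n₂|). Smaller angles = flatter, more conjugated,
  red-shifted chromophore.
- Kabsch superposition with separate fit/target selections (align on a
  reference subunit's Cα, measure e.g. ring-D heavy atoms), heavy-atom
  contact maps at a distance cutoff, and a red-bilin ranking
  (planarity first, linker contacts second).

**Spectroscopic arm** (statsmodels-style models and results)

- `GlobalDecayModel(surface, k, irf).fit()` — global lifetime analysis of a
  ΔA or fluorescence surface S(t, λ): variable-projection fit of
  S = Σᵢ Aᵢ(λ)·(exp(−t/τᵢ) ⊗ IRF) with lifetimes shared across wavelengths,
  returning decay-associated spectra (DAS) with standard errors and
  diagnostics.
- `das_to_sas(das, scheme)` / `TargetKineticModel(surface, template).fit()` —
  target analysis under a first-order compartmental scheme dc/dt = K c,
  giving species-associated spectra (SAS); the rod topology
  `P1/P2 → RS/RL → T` ships as a template.
- SVD rank estimation, closed-form exp×erfc Gaussian-IRF convolution, and
  an ODE path for non-diagonalisable schemes.

**Synthetic data** — generators for idealised tetrapyrroles with exactly
prescribed inter-ring angles and for time × wavelength surfaces evolving
under any scheme with Gaussian bands, IRF and noise, so every stage is
testable offline with known ground truth.

## Worked example

```sh
# a synthetic transient-absorption surface under the rod scheme
# P1(3.6 ps)/P2(25 ps) -> RS/RL(200 ps) -> T(1999 ps), 1% noise
pbsdyn simulate surface --preset rod-ta --noise 0.01 --seed 1 -o ta.csv
pbsdyn global-fit ta.csv --n 4 --irf-fwhm 0.1
```

prints (abridged):

```
SVD rank estimate: 3 (top singular values: 20, 16.8, 3.07, 0.29, 0.201, 0.193)
Global decay fit (DAS)
======================================================
surface: 160 times x 80 wavelengths
components: 4   SVD rank estimate: 3
converged: True   residual RMS: 0.009437
------------------------------------------------------
 component     tau (ps)     stderr           note
        C1        3.541      0.041
        C2        24.36       0.52
        C3        198.5        1.3
        C4         2001        5.7
```

The four shared lifetimes recover the generating scheme to ~1%. The rank
estimate of 3 is itself informative: the two intermediate pools decay with
the same 200 ps constant and the slowest two bleaches sit 1 nm apart, so
only three singular vectors clear the noise floor — the fourth component is
resolved kinetically, not spectrally. In python, the same fit is

```python
from pbsdyn import GlobalDecayModel, IRFModel, TimeResolvedSurface
surface = TimeResolvedSurface.from_csv("ta.csv")
das = GlobalDecayModel(surface, 4, irf=IRFModel(fwhm=0.1)).fit()
print(das.summary())
```

For the structural arm on a synthetic bottom trimer (angles prescribed at
θ_CD = 21°, 8°, 25°):

```sh
pbsdyn simulate structure --angles 26 7 8 -o toy.pdb
pbsdyn bilin-angles toy.pdb
```

```
bilin	theta_AB	theta_BC	theta_CD	planarity_score
A:201	26.00	7.01	7.98	-40.99
```

(the last-digit wiggle is the 3-decimal coordinate precision of the PDB
format).

The full pipeline (`pbsdyn run config.toml`) chains both arms: per-bilin
angle and contact tables, red-bilin ranking, DAS/SAS, and a component →
bilin annotation in which the slowest kinetic component is assigned to the
flattest, linker-engaged bilin — the terminal-emitter-like red PCB at the
bottom-trimer β82 position, monomer 2.

Deposited cryo-EM models are first-class inputs: point the config at local
mmCIF files (e.g. a CpcL-PBS rod and a comparison CpcG-PBS rod) to get real
inter-ring angles, CpcL contact maps and cross-structure ring-D RMSDs. No
coordinates are bundled and none are downloaded.

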