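# Methods

## Scope and model

`qsar3d` implements a grid-based 3D-QSAR analysis for a congeneric series
of small-molecule inhibitors, together with the conceptual-DFT reactivity
descriptors used to rationalise such models. The pipeline is:

1. **Dataset** — IC50 values (μM) are transformed to pIC50 =
   −log10(IC50 in mol/L) and partitioned into training and held-out test
   compounds. pIC50 is stored at full precision; the two-decimal figures
   of printed tables are produced by *truncation* (floor), which is a
   formatting option of the report writer, not a property of the data.
2. **Alignment** — every molecule is rigidly superposed onto a template
   conformation over the maximum common substructure (heavy atoms only),
   using least-squares (Kabsch) superposition. Among equal-size MCS atom
   mappings the mapping with the smallest post-superposition RMSD wins,
   with deterministic enumeration order breaking exact ties. A Gaussian
   volume-overlap score (atom-centred Gaussians, width tied to the
   van-der-Waals radius) is reported for diagnostics only. Flexible
   (conformer-searching, strain-penalised) alignment is deliberately out
   of scope: the series this package targets shares a scaffold, and the
   synthetic generator aligns by construction.
3. **Fields** — on a rectilinear grid enclosing the aligned series plus a
   margin, two families of descriptors are computed per compound:
   - *CoMFA*: a Lennard-Jones 12-6 steric probe energy and a Coulombic
     electrostatic probe energy (kcal/mol), probe = sp³ carbon, +1 e.
   - *CoMSIA*: Gaussian-attenuated similarity indices
     A(q) = −Σᵢ wᵢ exp(−α r²) for steric (w = r_vdW³), electrostatic
     (w = partial charge), hydrophobic (w = Wildman–Crippen atomic logP
     contribution), H-bond donor and acceptor (w = 0/1 indicator) fields.
4. **PLS** — grid columns are concatenated into one matrix, filtered by a
   minimum-sigma threshold, block-scaled, and regressed on pIC50 by PLS
   (NIPALS, `sklearn` backend, no autoscaling). Leave-one-out
   cross-validation gives q² = 1 − PRESS/TSS and SEP = √(PRESS/(n−c−1));
   the optimal number of components (ONC) maximises q², ties broken
   toward fewer components. Training statistics are r², SEE =
   √(RSS/(n−c−1)) and F = [r²/(1−r²)]·[(n−c−1)/c]; an exact fit reports
   F = +∞. Per-field contribution fractions are Σ|coefⱼ|·sdⱼ normalised
   over field blocks (empty blocks keep a zero slot). Residuals follow
   one convention everywhere: experimental − predicted. (The published
   prediction table this layout mirrors uses that convention in its
   CoMFA columns but the opposite sign in its CoMSIA columns; this
   package does not reproduce the inconsistency.)
5. **Contours** — per grid point the stdev·coefficient product is mapped
   back through the column mask (filtered columns → 0); favoured and
   disfavoured iso-levels are percentiles (default 80/20) of the nonzero
   value distribution, exported as two Gaussian cube files per field.
6. **Reactivity descriptors** — from frontier orbital energies via
   Koopmans' theorem (I = −E_HOMO, A = −E_LUMO): μ = −(I+A)/2, χ = −μ,
   η = I − A, S = 1/η, ω = μ²/(2η); all energies in eV, hartree inputs
   converted (1 Eh = 27.211386 eV). The derivative definitions
   (∂E/∂N at fixed external potential) are represented only through
   these finite-difference forms. Condensed Fukui functions are
   population differences f⁺(k) = q_k(N+1) − q_k(N),
   f⁻(k) = q_k(N) − q_k(N−1); q_k is an electron *population* — if NPA
   charges are supplied instead, a flag negates the differences. The
   atom with the largest f⁺ is flagged as the preferred site of
   nucleophilic attack, the largest f⁻ of electrophilic attack. Running
   the quantum-chemistry calculations themselves (DFT single points,
   population analysis) is out of scope; the module consumes their
   outputs.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| grid spacing | 0.6 | Å | the protocol value of the study this mirrors; unusually fine vs the conventional 2.0 Å, so it is a config knob and the test suite runs at 2.0 Å for speed |
| grid margin | 4.0 | Å | conventional extension beyond the union bounding box |
| steric cutoff | ±30 | kcal/mol | conventional CoMFA truncation; points at/inside an atom clamp to +30 rather than diverging |
| electrostatic handling | column-mean fill | — | at grid points where a compound's steric energy hit the +cutoff (inside its envelope), its electrostatic value is replaced by the column mean over the unaffected compounds — the conventional treatment; the bare Coulomb field itself is unclamped |
| dielectric | D(r) = r | — | distance-dependent dielectric; a constant dielectric is available |
| Coulomb constant | 332.0 | kcal·Å/(mol·e²) | standard electrostatics constant |
| probe | sp³ C, +1 e | — | conventional CoMFA probe (r_vdW 1.70 Å, ε 0.107 kcal/mol) |
| CoMSIA attenuation α | 0.3 | Å⁻² | conventional CoMSIA default |
| column filter (CoMFA) | 2.0 | kcal/mol | the protocol's minimum-sigma value; inclusive boundary; sample sd (ddof = 1) |
| column filter (CoMSIA) | 0.05 | — | similarity indices are dimensionless and an order of magnitude smaller than probe energies, so the energy threshold would delete every non-steric block; this value retains all five fields on the synthetic series |
| block scaling | equal total variance | — | each field block is scaled so its summed column variance is 1, preventing one field from dominating the latent decomposition by magnitude |
| filtering vs CV | fixed mask | — | the column filter is computed once on the full training matrix and held fixed across LOO folds (the conventional behaviour); per-fold refiltering is a flag |
| contour percentiles | 80 / 20 | % | conventional favoured/disfavoured levels |
| max components | 10 | — | ONC search bound, capped by min(n−2, retained columns, rank) |

Lennard-Jones parameters are a bundled per-element (radius, well-depth)
table in the Tripos style with Lorentz–Berthelot combining
(r_min = rᵢ + r_probe, ε = √(εᵢ ε_probe)); any table may be substituted.
Partial charges are taken from the input file when present, else computed
with the MMFF94 charge model (Gasteiger fallback for molecules outside
MMFF94 coverage); the provenance is recorded per molecule. Donor/acceptor
perception is a simple rule (donor: N/O/S bearing ≥1 H; acceptor: N/O
without positive formal charge), documented rather than sophisticated.

## Synthetic data: what it emulates and what it does not

The generator produces a congeneric series on a fused
thieno[2,3-b]pyridine-like bicyclic scaffold decorated at two positions
from a small substituent vocabulary. Each unique decoration is embedded
once (ETKDG, seeded; MMFF94-minimised) and superposed onto a shared
reference scaffold conformation, after which the scaffold atoms are
snapped *exactly* onto the reference coordinates — the series is aligned
by construction and duplicate decorations are bit-identical. Activity is
planted as a linear function of the series' own grid-field values
(highest-variance columns of one chosen field block), rescaled into the
pIC50 window 4.77–7.38 (the activity span of the series this package
models; the rescaling is cosmetic), plus seeded Gaussian noise
(default sd 0.1 log units). The default study conditions for recovery
experiments are n = 35 training compounds — the training-set size of the
mirrored study — with 2.0 Å grid spacing.

The fixtures therefore have: exact congenericity, perfect alignment, a
response that truly is linear in the fields, and homoscedastic noise.
Real series have none of these exactly — alignment error, activity
cliffs, measurement error correlated with assay, and field/activity
relationships that are at best locally linear. Passing recovery tests
shows the machinery is correct and statistically calibrated, not that
comparable q² values would be reached on experimental data. In
particular, the published model statistics of the mirrored study
(q² 0.671/0.646, r² 0.989/0.950, the 49/51 % and 13/25/22/20/20 % field
contributions) are not reproducible from public information — the 46
full 3D structures were never deposited and the commercial
implementation's internals are unpublished — so the package's acceptance
is property-based: oracle equivalence of the LOO loop, the
full-component-PLS = OLS limit, planted-structure recovery
(q² ≥ 0.8, dominant block identified), y-scrambling suppression
(q² ≤ 0.2 in ≥95 % of permutations), analytic field identities, and
conservation laws (Σ fractions = 1, Σf± = 1).

Orbital fixtures draw E_HOMO in (−8, −1) eV with a gap of 0.5–5 eV
(capped so E_LUMO ≤ 0), and Dirichlet-distributed f⁺/f⁻ so population
vectors conserve the electron count exactly; planted μ, η, S, ω are
emitted alongside. A fixture can also be planted at an exact (μ, η) pair
by inverting the finite-difference forms.

## Numerical choices and degenerate inputs

- Kabsch superposition uses SVD with a determinant correction, so the
  rotation is always proper; collinear point sets (second singular value
  ≈ 0) and k < 3 are rejected.
- `build_grid` uses points-per-axis = ceil(span/spacing) + 1 (with a
  1e-9 guard against float noise), so the last plane lies at or beyond
  the far face of the margin box.
- Grid points coincident with an atom: distance floored at 1e-12 Å and
  the steric value clamps to the cutoff; CoMSIA needs no guard (the
  Gaussian is finite everywhere).
- Rounding in the descriptor report is round-half-even at 4 decimals on
  full-precision values. Of the ten published (μ, η, S, ω) rows this
  report layout mirrors, recomputing ω from the printed (μ, η) disagrees
  with the printed ω at the 4th decimal for compounds 9, 29, 32 and 39
  (and S for 9, 29, 32) — the published figures were evidently rounded
  from unrounded upstream values. The package always reports values
  computed from its inputs.
- The bundled activity table stores compound 31 at 0.041 μM, the value
  consistent with its published pIC50 of 7.38 and the series' stated
  activity range (elsewhere printed rounded to 0.04).
- q² can be negative (PRESS > TSS); it is reported as computed.
  r² = 1 within 1e-12 reports F as +∞.
- Determinism: every generator is a pure function of (spec, seed); field
  assembly and PLS are deterministic, so repeated runs are bit-identical.

## Known limitations

- Rigid alignment only; no conformational search or strain term.
- Charges are force-field monopoles, not QM-derived (ESP/NPA) charges.
- H-bond fields are isotropic indicator Gaussians; no directionality.
- The qm-log orbital adapter is a minimal text parser for Gaussian-style
  logs (eigenvalue lines + natural-population summary); the native JSON
  schema is the supported interchange format.
- The MOL2 writer emits element symbols as atom types (no SYBYL atom
  typing).
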