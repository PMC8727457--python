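# Methods

## Model and assumptions

EE-GMFCC approximates a property of a large fluorophore–polymer complex by a
combination of small-fragment QM calculations, each embedded in the
point-charge field of everything outside its QM region. The scheme assumes
**local excitation**: the electronic reorganization on absorption is confined
to the chromophore and its immediate surroundings, so the response of residue
j is captured by one two-body fragment (chromophore + H-capped j) and
higher-order QM effects are absorbed by the embedding field. The assembled
excitation energy is exact for any strictly pairwise-additive energy model and
approximate otherwise; the mock-engine oracles below probe precisely that
split.

### Fragmentation and capping

Cuts happen only at the sugar C3'–O3' ester bond. Bookkeeping follows the
convention that the bridging O3' travels with the *downstream* fragmentation
unit: unit i is residue i minus its own O3' (when a 3' successor exists) plus
the O3' inherited from residue i−1. Every severed bond then has exactly one
end in any unit-contiguous fragment, and the dangling valence is saturated by
a hydrogen on the bond axis:

| kept atom | H distance | unit |
|-----------|-----------:|------|
| C3'       | 1.09       | Å    |
| O3'       | 0.96       | Å    |

Link placement is exact (1e-12 of the rule length in tests; the package-wide
invariant is 1e-9). A residue with no backbone linkage — the non-covalent
chromophore, any lone-chain ligand — is its own unit and is never severed. A
chromophore covalently grafted into the chain keeps its backbone bonds; its
boundary bonds are cut like any other, but the *chromophore atom set* used for
centroids and force reporting is pinned at fragment-build time to the
chromophore's unit, so it is identical in every fragment species.

### Combination formulas

Non-bonded chromophore: P = P_m + Σ_j (P_mj − P_m) for P ∈ {ω, μ, F}, with j
running over residues whose minimum interatomic distance to the chromophore is
≤ λ2B (closed threshold, matching the ≤ convention of the distance sums).
Bonded chromophore: the one-body part is replaced by
Σ_{i=m−1..m+1} ω(capped i) − Σ_{i=m−1..m} ω(concap i), and two-body
corrections skip the window [m−2, m+2] already covered by those local
fragments. Oscillator strength is f = (2/3)·ω·|μ|² in atomic units, ω
converted eV → hartree first (verified: the stored benchmark rows reproduce
their printed f only under this reading).

Ground state: E = Σ Ẽ(capped) − Σ Ẽ(concap) + Σ_pairs (Ẽij − Ẽi − Ẽj) − E_dc,
with "distant" pairs defined as j ≥ i+3 within one chain *or any cross-chain
pair* — the latter generalization is required so that a non-covalent ligand's
interactions with every residue are QM-corrected (the ligand never shares a
capped fragment with anything). Chains of one or two residues contribute a
single whole-chain term.

### The double-counting term

Expanding the assembly for a pairwise-additive energy shows that each distant
pair (i, j) enters the embedded one-body sums **twice** at MM level (once from
each side's background), while the QM pair correction Ẽij − Ẽi − Ẽj equals
V_QM(i,j) − 2·V_MM(i,j). QM-treated pairs therefore net exactly V_QM with no
further correction, and the doubly counted set is the distant pairs *not*
promoted to QM treatment, each needing one MM Coulomb copy removed. The
pipeline computes E_dc accordingly (over the complement of the QM pair list);
the `double_counting_correction` operation itself is pure arithmetic over
whatever pair list it is given, so an alternative convention is a one-line
change at the call site. At λ = ∞ the complement is empty, E_dc = 0, and the
assembly reproduces a pairwise full-system energy exactly — the ground-state
oracle.

### Embedding conventions

Background charges are one point charge per system atom outside the QM region.
Atoms *replaced* by link hydrogens (the removed bond partners) are excluded
outright and logged, not redistributed — the simplest defensible rule; charge
smearing near the boundary is a known alternative not implemented here.
Charge tables load either as force-field-style templates keyed by
(residue, atom name) — validated to integral per-residue totals — or as
per-atom (ESP-style) charges keyed by serial. Coulomb energies are
q·q/r with r in bohr (1 Å = 1.8897259886 bohr); energies are hartree
throughout, excitation energies reported in eV (1 hartree =
27.211386245988 eV), wavelengths via hc = 1239.84193 eV·nm.

## The mock engine and what the oracles do (and do not) show

The mock engine is a closed-form stand-in for a TD-HF/TD-DFT program, built so
the assembly identities are *exact* and every defect in the combinatorics is
detectable at 1e-10:

* ground energy: per-element self-energies + pairwise Coulomb among QM atoms +
  QM–background Coulomb (a genuine embedded pairwise energy — the intra-QM
  term is what makes the ground-state oracle non-trivial);
* excitation: ω₀ + α Σ_env q/d + β Σ_bg q/d + δ (Σ_env |q|/d)², d the distance
  to the chromophore centroid; α ≠ β models the QM-vs-MM treatment difference,
  δ an explicitly non-pairwise channel;
* TEDM: μ₀ + γ Σ_env q (r − r_c)/d²;
* forces: the analytic gradient of the excited-state energy with respect to
  chromophore positions (cross-checked against central differences at 1e-6
  hartree/bohr).

Link atoms carry self-energy (which cancels exactly between the capped,
concap and pair sums — their cut-bond multisets coincide) but zero model
charge. The **pairwise preset** draws coefficients from a seeded generator
with δ = 0 and assigns zero model charge to the cut-site atoms C3'/O3', so
dropping link-replaced background charges is energy-neutral: the preset
isolates the assembly combinatorics, which is the thing under test. The
**nonadditive preset** sets δ > 0 and ties α = β, so the assembly error equals
(ΣT)² − Σ_{j∈λ} T_j² with T_j = Σ_{unit j} |q|/d > 0 — positive and strictly
shrinking as the threshold admits residues, which is what the monotone
convergence check asserts. These identities validate the *bookkeeping*
(fragment enumeration, capping, charge complement, sign conventions), not the
physics of any real chromophore: real TD-DFT energies are not pairwise, real
charge models are not exactly consistent between QM and MM sides, and real
capping perturbs the density. Accuracy on real systems is an empirical
question the accompanying benchmark tables summarize.

## Synthetic structures

The toy generator builds chemically minimal residues — six atoms with the
backbone names the fragmenter needs (P, C3', O3') plus a jittered sidegroup —
and a rigid six-atom chromophore. Contact residues are placed radially around
the chromophore and slid along their radial direction until the *measured*
minimum distance equals the requested value (bracketed root find, verified to
0.05 Å); all other residues are parked on a row ≥ 10 Å away so requested
contacts are the only sub-threshold approaches. The intra-residue C3'–O3' bond
is 1.5 Å and chain neighbors abut at 1.6 Å. The standard benchmark complex is
8 nucleotides with contacts at 2.8, 3.6 and 4.5 Å (seeded), sized so the full
oracle suite runs in seconds; chain realism (sugar pucker, base stacking,
charge chemistry) is deliberately absent, so passing tests say nothing about
conformational realism — only about the scheme's arithmetic.

## Parameters that matter

| parameter | meaning | default | unit |
|-----------|---------|--------:|------|
| λ2B | two-body inclusion threshold (min interatomic distance) | 4.0 | Å |
| λFS | truncated-reference QM-region threshold | 4.0 | Å |
| H–C3' / H–O3' | link hydrogen bond lengths | 1.09 / 0.96 | Å |
| state_index | excited-state ordinal passed to the engine | 1 | – |

state_index is taken at face value per fragment; no attempt is made to track
"the same" excited state across fragments when state ordering changes — a
known limitation of the contract shared with any fragment scheme.

## Numerical choices

* Thresholds are closed (distance ≤ λ included).
* Assembly sums use compensated summation (`math.fsum`); the ground-state
  oracle holds to ~1e-12 hartree on the standard toy.
* PDB parsing keeps the first alternate conformer, treats insertion-coded
  residues as distinct residues in file order, and normalizes the cut-site
  name dialects C3/C3* → C3' and O3/O3* → O3'. Hydrogens present in the input
  are kept verbatim; none are added.
* Coordinates are PDB-native angstrom everywhere in the structure layer;
  bohr appears only inside Coulomb sums and force gradients.
* Degenerate inputs fail loudly: coincident charges raise a singularity error,
  zero-variance series refuse a correlation, the per-residue decomposition
  refuses electrostatically embedded inputs (the embedding field mixes
  many-body effects into each pair and obscures individual contributions).
* Presentation rounding (3 decimals eV, 4 decimals TEDM/f, 1 decimal nm) is
  applied only in formatted output; stored values keep full precision.

## Known limitations

Single-residue chromophores only (a multi-residue dye would need new capping
rules); no polarizable or self-consistently updated embedding; no three-body
QM corrections (the embedding is what keeps their neglect tolerable); the
benchmark tables record one printed inconsistency — one residue's tabulated
ΔEx disagrees with its own energy columns — and this package reports the value
recomputed from the energies.
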