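# Methods

## Decision problem

Each docking pose of an oxime inside organophosphate-inhibited AChE is an
alternative scored on four criteria: O(oxime)–P distance in Å (cost:
smaller is better), intermolecular energy in kcal/mol (cost), H-bond energy
in kcal/mol (cost; energies are negative, so "smaller" means more strongly
bound), and the number of active-site residues engaged in H-bonds (benefit).
Directions are fixed per criterion in `CriterionSpec` and drive the choice
of ideal/anti-ideal components in TOPSIS.

## Screening

Four elimination rules run in a fixed order, each pose recording only the
first rule that fired: (1) intermolecular energy > 0, (2) H-bond energy > 0,
(3) no contact with any active-site residue, (4) near-duplicate of an
earlier-kept pose. Positivity is strict — an energy of exactly 0 survives
rules 1–2. Rule 3 matches residue labels case-insensitively after stripping
and is disabled when no active-site list is supplied (an *empty* list is a
configuration error, since it would eliminate everything). Duplicate
detection compares the four criterion values component-wise against
per-criterion tolerances (defaults 0.01 Å, 0.01 kcal/mol, 0.01 kcal/mol, 0
residues) and is restricted to poses of the same ligand: agreement of
scores across different compounds is a coincidence, not a duplicate.
Geometry-based clustering (pose RMSD) is deliberately out of scope — only
tabulated criterion values are available to this stage.

Per-run pre-selection keeps one pose per (ligand, run): lexicographically
minimal (distance, intermolecular energy), remaining ties resolved by input
order. Distance is the primary key because reaching the phosphorus is the
mechanistic prerequisite for reactivation; a weighted combination here would
pre-empt the MCDM step. Whether the four rules run before or after the
per-run selection is configurable (`screen_poses(order=...)`, default
rules first); both orders produce at most one pose per run.

## AHP

Priorities come from the principal right eigenvector, computed by power
iteration started at the uniform vector and stopped when the relative
change falls below 1e-12 (cap 100 000 iterations; exceeding it raises a
numeric error). The row geometric mean is available as an alternative
(`method="row_geometric_mean"`); for the near-consistent matrices this
pipeline handles the two agree to several digits, and for exactly
consistent matrices to 1e-10. λmax is estimated as the mean of
`(A·w)_i / w_i`, which is exact at the eigenvector fixed point and the
standard estimator for the geometric-mean vector. CI = (λmax − n)/(n − 1),
CR = CI/RI with Saaty's random indices for n ≤ 10 (0, 0, 0.58, 0.90, 1.12,
1.24, 1.32, 1.41, 1.45, 1.49); n ≤ 2 is consistent by construction
(CI = CR = 0), and larger orders require a caller-supplied RI table.

Group judgments use AIJ: the element-wise geometric mean, the unique
aggregation that preserves reciprocity. Group weights are derived from the
exact (unrounded) aggregate by default; the bundled rounded group matrix is
also supported — its printed lower triangle is rounded to two decimals, so
the lenient reader accepts up to 5% relative reciprocity error and
`symmetrized()` restores exact reciprocity by keeping the upper triangle
verbatim. Both routes reproduce the reference weight vector
(0.633, 0.228, 0.044, 0.095) within 0.005 per component.

## TOPSIS

Vector normalisation (`r_ij = x_ij / ‖x_j‖₂`) is the default; it preserves
sign, so negative energies stay negative and the "min" direction correctly
selects the most negative weighted value as ideal. Min–max normalisation is
offered behind a flag for sensitivity analysis only. An all-zero column
cannot be normalised and is left at zero with a warning. Distances to A⁺/A⁻
use the Minkowski exponent `s ≥ 1` (default 2) on both sides; closeness is
`C = d⁻/(d⁺+d⁻)`, with the degenerate case d⁺+d⁻ = 0 (all alternatives
identical) defined as C = 0.5 plus a warning — symmetric and
division-free. Ranking sorts by decreasing C with stable ties (input
order); tied alternatives share a competition rank number in reports.
Weak dominance is preserved for any s ≥ 1, and positive per-column
rescaling of the raw matrix leaves the ranking unchanged — both properties
are enforced by the test suite on large random ensembles.

## Ellman arithmetic

`%I = (L0 − Li)/L0 × 100` and `%R = (Lr − Li)/(L0 − Li) × 100` from mean
412-nm absorbances. Values outside [0, 100] are returned unclamped with a
warning — reactivated wells occasionally overshoot the uninhibited control,
and clamping would hide that from QC. Plate reduction groups long-format
wells by (compound, concentration, time); each group needs L0 and Li roles
(Lr optional). Aggregation is mean-then-formula by default, with
formula-then-mean (replicates paired by id) as an option; replicate-level
percentages always feed the reported n and standard deviation. Blank or
background correction is not modelled. Enzyme kinetics (IC50, k_obs) are
out of scope.

## Synthetic data

The pose generator emulates the campaign scale the pipeline targets — by
default 3 ligands × 10 runs × 30 poses — with criterion values drawn
uniformly (normal optional) from ranges typical of oxime/AChE docking:
distance 3.5–6 Å, intermolecular energy −130 to −70 kcal/mol, H-bond energy
−12 to 0 kcal/mol, 1–4 active-site contacts. Clean poses always satisfy all
screening rules; requested fractions of violators (default 5% per rule) are
injected on disjoint index sets so each injected pose violates exactly one
rule, making screening verifiable by exact recovery. Duplicates are
near-copies of a clean same-ligand pose perturbed by ±0.005 on continuous
criteria — inside the default 0.01 similarity tolerance. All randomness
derives from one integer seed through spawned sub-streams (values /
violators / duplicates), so extending one stage cannot silently shift
another. What the generator does *not* emulate: correlated criteria (real
binding and H-bond energies co-vary), run-level clustering of poses, or any
physical energy model — passing tests demonstrate the decision pipeline's
correctness, not docking realism.

The PCM generator builds `a_ij = (w_i/w_j)·exp(t·e_ij)` with antisymmetric
Gaussian noise `e` (so reciprocity is exact at every noise scale) and
bisects `t` until the CR is within 0.005 of a target, bracketing by
doubling first; failure to bracket or converge raises a numeric error.

The plate generator produces triplicate wells around L0 ≈ 0.9, Li ≈ 0.1,
with reactivation rising saturably in concentration and time and 0.01
absorbance noise — enough structure to exercise grouping, replicate
pairing, and the warning paths.

## Command line

`poserank` exposes `ahp`, `screen`, `rank`, `ellman`, `generate`, and
`demo`. Configuration precedence is flags > YAML/JSON config > defaults;
exit codes are 0 (success), 1 (an enforced check such as `--enforce-cr`
failed), 2 (configuration error), 3 (data-format error), 4 (numeric
failure). `rank --log-file` records the configuration echo, resolved
weights, and SHA-256 of every input so a run can be re-executed exactly.
`demo` recomputes the bundled worked example — group-matrix entries,
weights, consistency ratios, and both ligands' rankings — and prints a
pass/fail table; it also states explicitly how the computed isatin-3-oxime
ranking compares with the bundled published selection. With the reference
weights the computed isatin ranking places Dock7 first (closeness 0.697)
just ahead of Dock3 (0.687), in agreement with that selection: Dock3 is
better on distance and intermolecular energy, but Dock7's stronger H-bond
energy decides the narrow margin.

## Numerical and degenerate-case summary

- Fraction literals in PCM files are parsed exactly before float
  conversion; typeset minus signs and single-character vulgar fractions are
  normalised.
- Strict reciprocity tolerance 1e-6 relative; lenient 0.05 (rounded
  published matrices).
- Weight vectors must sum to 1 within 1e-6 at the TOPSIS interface (1e-9
  when carried on criteria); weights must be strictly positive.
- Ties everywhere resolve to input order (stable), never arbitrarily.
- Problem sizes in the test suite and acceptance script: the bundled 10×4
  decision matrices, 4×4 judgment matrices, synthetic campaigns of 900
  poses, and property ensembles of 1000 random 5×3 matrices — sizes chosen
  to match the scale of the scientific problem itself.

## Known limitations

- Only tabulated criterion values are consumed; native docking outputs and
  structures are not parsed.
- The AHP hierarchy is a single criteria level; fuzzy/interval extensions
  and incomplete judgments are unsupported.
- TOPSIS is the only MCDM family implemented; closeness values from
  different normalisations are not comparable with each other.
- Reported wet-lab reactivation percentages cannot be recomputed without
  the raw absorbances, which are not published; the Ellman module therefore
  validates against algebraic identities and synthetic plates only.
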