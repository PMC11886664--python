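# Methods

## The charge model and the inverse problem

MMFF94 assigns the partial charge of atom *j* as its formal type charge
plus the sum of bond charge increments over its bonds:

    q_j = q0_j + Σ_{bonds j–k} ω(I_k, I_j),      ω(I,J) = −ω(J,I).

Antisymmetry means each unordered pair of atom types carries exactly one
unknown and homotype pairs (I,I) carry none. For a structure with known
charges this is a linear system

    B ω = q − q0

with one row per atom and one column per non-degenerate bond type. Each
bond contributes +1 to the row of one endpoint and −1 to the other, so
every column of **B** sums to zero. Two consequences follow directly:

* the forward map conserves charge — `apply_bci` output sums to Σq0
  exactly, for any increment table;
* a net-charge mismatch Σq − Σq0 ≠ 0 cannot be absorbed by any ω. The
  residual sum of squares is then bounded below by (Σq − Σq0)²/n_atoms
  (the mismatch projected onto the constant vector, which is orthogonal
  to the column space). `diagnostics` reports this bound and warns when
  |Σq − Σq0| > 1e-3 e.

### Orientation convention

Stored increments are keyed by the lexicographically ordered type pair
(type_lo, type_hi); the stored ω is the increment *received by the
type_lo atom*, and the type_hi atom receives −ω. For the platinum keys
(Cl,Pt), (N,Pt), (H,N) this is the increment received by the ligand-side
atom, which is the orientation in which the field quotes "bci Pt–N".
Negating the convention globally negates every ω and leaves residuals
unchanged (covered by a test). `.par` files document the convention in
their header; a row written with a non-canonical pair ("Pt Cl w") is
interpreted as the increment received by its first-named type and
reoriented on read.

### Solver

`scipy.linalg.lstsq` with the SVD driver (`gelsd`) and a relative
singular-value cutoff of 1e-10 for rank determination. Rank-deficient
systems (symmetric molecules, repeated columns) deterministically return
the minimum-norm minimizer, with a rank warning in the diagnostics. The
normal-equations solution (BᵀB)⁻¹Bᵀ(q − q0) serves as an independent
oracle in the tests, never as the implementation. Batch solving defaults
to per-structure fits with aggregation of per-key statistics (n, mean,
sample sd with sd≡0 for n=1, min, max), matching how per-structure
variability across charge methods is usually reported; pooled solving
(stacking all atom rows over the union of keys) is an explicit option.
No atom or structure weighting is applied: unweighted least squares is
the stated method and weights would be an undocumented extension.

### Formal charges

`q0` defaults to zero for every atom type, including ions. This
reproduces the published increment ranges for the neutral and ionic
complexes alike, at the cost of the (surfaced) inconsistency for ions;
a `FormalChargeScheme` file ("atom_type q0" rows) can assign ionic
charges instead, which removes the mismatch and changes the fitted ω
accordingly. A strict scheme errors on unlisted types; the default
falls back to zero.

## Deviation metrics

* RD = 100 (calc − ref)/ref, signed — a calculated value below the
  reference is negative (the orientation fixed by the published
  lattice-parameter table).
* MAPE = mean |RD| over a series (used for structural parameters).
* MAD = mean |calc − ref| in input units (used for vibrational
  frequencies, where percentages would mix scales across modes).

Reports round to 3 decimals for percent metrics; full precision is kept
internally. The module always reports the value it computes from the
pairs it is given — a summary quoted alongside a table elsewhere is
never trusted over recomputation — and it computes over whatever series
the caller passes, leaving any pooling across units to the caller.

## Fixtures and the synthetic generator

Packaged fixtures are the published platinum-complex tables: cisplatin
gas-phase charges at two levels of theory × three charge methods
(CHELPG/Hirshfeld/Mulliken), [PtCl₄]²⁻ at two basis-set choices × three
methods, α-cisplatin solid-phase Bader/Hirshfeld/Mulliken charges, and
the experimental/calculated lattice parameters of both polymorphs. Atom
types in the fixture mol2 files are element symbols, so increments are
fitted at the chemical-identity level (Pt–Cl, Pt–N, N–H) — MMFF94 has no
platinum type to use instead. For the solid-phase unit cell the exact
N↔H bond pairing is not published, but the incidence rows depend only on
per-atom bond-type counts (each N binds 1 Pt + 3 H, each H binds 1 N),
so any valid pairing yields the identical system.

The synthetic generator draws a uniform-attachment random spanning tree
(guaranteed connected) plus optional extra edges, types atoms from an
alphabet, and sets charges by the forward rule from a prescribed
ground-truth table plus independent zero-mean Gaussian per-atom noise.
Defaults: 8 atoms, alphabet {A,B,C}, ground-truth increments of
alternating sign and magnitude 0.1–0.3 e (comparable to the fitted
platinum–ligand values), noise sd 0.05 e for noisy experiments — a
scale chosen to mimic the spread of charges across charge methods and
levels of theory. The Gaussian model is deliberately simple: real
charge-method variation is systematic (Mulliken consistently
overestimates magnitudes, for instance), so passing recovery tests shows
the estimator is correct and unbiased under idealized noise, not that
any particular charge method is accurate. `recovery_experiment` scores
per-key bias and RMSE over an ensemble (200 structures by default in the
examples; 10–1000 in tests — small enough to run in seconds, large
enough that the Monte-Carlo bias check is meaningful). Keys are scored
only over structures whose systems have full column rank, because
minimum-norm solutions of rank-deficient systems shrink toward zero and
would contaminate the bias of an otherwise unbiased estimator.

## Numerical choices and edge cases

* SVD cutoff 1e-10 (relative); exact-recovery and oracle-equivalence
  tests assert at 1e-10 absolute.
* Homotype bonds contribute no unknown; their charge imbalance goes to
  the residuals. A molecule with only homotype bonds yields a valid
  0-column system solved trivially (empty ω, rss = ‖q − q0‖²).
* `.par` values are written with fixed 5 decimals (bit-stable reruns);
  a solve→write→apply round trip is therefore exact to ~1e-5 e, not
  machine precision.
* mol2 charges are written with 6 decimals (round trip to 1e-6 e);
  `NO_CHARGES` is preserved as an explicit "no data" flag rather than
  silently reading zeros.
* Charge tables accept ASCII and typographic minus signs, since values
  are often pasted from typeset tables.

## Limitations

* No quantum chemistry: charges are inputs, never computed.
* No MMFF94 atom-type perception (rings, aromaticity); types are taken
  as given, optionally collapsed to element symbols.
* No joint fitting of ω with formal charges, no regularized or weighted
  variants, no angle/dihedral increments.
* Coordinates are carried through mol2 I/O but never used.
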