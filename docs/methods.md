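# Methods

## The prediction problem

A DNA-binding protein's sequence specificity is summarized by an L×4
position weight matrix (PWM).  Structure-based PWM prediction threads
every base identity through a fixed protein–DNA complex geometry and
converts the resulting per-position energies to probabilities.  This
package extends that idea to proteins *without* a co-crystallized DNA:
a synthetic complex is built by rigidly superposing the unbound query
protein onto a homologue's protein–DNA complex (the template), after
which threading proceeds exactly as for a native complex.

The rigid-body assumption is the method's central approximation: the
query is kept in its unbound conformation.  Conformational change on
DNA binding is therefore the dominant error source, and predictions
degrade gracefully (not catastrophically) when the unbound and bound
forms differ.  The method can only assess positions the protein
physically reaches; columns outside the contact span carry no signal
and are reported as uniform with an explicit flag.

## The knowledge-based potential

Counts `N_obs(i, j, r)` record how often protein heavy-atom type `i`
(167 types: every heavy atom of the 20 standard amino acids, OXT
excluded) and DNA heavy-atom type `j` (82 types: every heavy atom of
DA/DC/DG/DT including the sugar–phosphate backbone) co-occur at a
distance within bin `r ∈ {3,…,10}` Å, width 3 for the first bin and 1
for the rest, interval convention `(r−Δr, r]` (a distance of exactly
3.0 Å falls in bin 3, exactly 10.0 Å in bin 10).  Each protein–DNA
atom pair is counted once, with the protein atom always in the first
role; intra-molecular pairs never count.  Atoms outside the vocabulary
(solvent, ions, modified residues, terminal variants) are skipped and
logged.

The potential is the inverse-Boltzmann log-ratio to a volume-corrected
reference state,

    u(i,j,r) = −ln[ P(i,j,r) / P_ref(r) ],   P_ref(r) ∝ r^α Δr,

so enriched contacts score negative (favorable).  Parameters:

| parameter | default | meaning |
|---|---|---|
| `alpha` | 1.61 | reference-state volume exponent |
| `r_cut` | 10 Å | interaction cutoff (= last bin edge) |
| `pseudocount` | 0.1 | additive per-bin count, keeps logs finite |
| `weighting` | `none` | or `power:γ`, w(r) = (r/r_cut)^γ before normalizing |
| `beta` | 15 | temperature-like divisor for PWM emission |

Type pairs never observed at any distance are *uninformative* and
contribute exactly zero in every bin, regardless of pseudocount — a
deliberate choice so that absence of evidence is not treated as
repulsion.  The distance weighting is exposed as a pluggable scheme
because several variants of this potential family differ only there;
the default (`none`) is the plain log-ratio form.

## Complex admission filters

Two presets exist.  The knowledgebase profile demands an X-ray
structure with resolution better than 3.0 Å, exactly one
double-stranded DNA, ≥ 6 Watson–Crick base pairs with < 30% unpaired
DNA residues, a protein chain with ≥ 5 contact residues (heavy atom
within 4.5 Å of DNA) and a protein chain of ≥ 40 residues.  The
template profile drops the single-duplex requirement and tolerates
missing experiment metadata.  "Exactly one dsDNA" is operationalized
as exactly one maximal duplex with ≥ 2 pairs found by the pairing
detector.  Watson–Crick pairing itself is complementarity plus an
N1(purine)–N3(pyrimidine) distance ≤ 3.5 Å with greedy
closest-first matching; no angular criterion is applied, which is
reliable for near-ideal duplexes but would over-pair heavily distorted
DNA.  "Paired bases" counts base *pairs*, and the unpaired fraction is
unpaired residues over all DNA residues.

## Superposition and threading

The synthetic complex keeps the template DNA bitwise untouched,
removes all template protein chains and appends the query protein
transformed by one rigid motion `x' = t + U·x`, read from the
alignment tool's three-row matrix file or computed by least-squares
(SVD) superposition of a user-supplied residue correspondence.  Query
chain identifiers are renamed on collision.

Base substitution rebuilds the base moiety of both nucleotides of a
Watson–Crick pair from an idealized base library expressed in the
standard base-pair reference frame, anchored via the glycosidic frame
(C1′, glycosidic N, one ring anchor: N9/C4 for purines, N1/C2 for
pyrimidines), with the transform pinned so that the library C1′ maps
exactly onto the observed C1′.  All four library bases share a single
canonical C1′ position (the mean of the per-base values, which differ
by < 0.06 Å); this makes substitution closed under composition — any
chain of substitutions at a position yields the same placement — so
the emitted PWM provably cannot depend on which sequence happened to
sit in the template.  Backbone coordinates are never moved; residue
names are updated so backbone atom *types* follow the new identity.

Per-position energies sum the pair potentials between every protein
heavy atom and every heavy atom (base + backbone) of the two
substituted nucleotides, within r_cut.  Including the backbone keeps
the per-position decomposition consistent with the whole-complex ΔG; a
`base-moiety-only` variant was considered and rejected because the
82-type scheme deliberately distinguishes backbone types by base.
Columns are `p ∝ exp(−ΔG/β)` with a max-shift for stability; β → 0
concentrates on the argmin base, β → ∞ gives uniform columns.

## PWM comparison

The Ψ-score is the mean per-position Kullback–Leibler divergence
D(annotated ‖ predicted), natural log, with both matrices floored at
ε = 1e-3 and renormalized.  This direction treats the annotation as
truth and punishes predictions that zero out truly favored bases; the
opposite and symmetrized directions are available as options.  Because
predicted matrices are usually shorter than annotated ones, alignment
scans every offset placing the shorter matrix fully inside the longer,
in both the forward and reverse-complement orientation of the
prediction, keeping the minimal Ψ (ties: smaller offset, forward).
Significance uses dummy PWMs with columns drawn uniformly from the
probability simplex (flat Dirichlet — the maximum-entropy choice, the
source procedure says only "randomly generated"), aligned identically,
with the add-one estimator p = (1 + #{Ψ_dummy ≤ Ψ}) / (n + 1) so p is
never zero; the reference procedure uses n = 100,000 dummies (the
bundled evaluation uses 10,000, which resolves p down to 1e-4).

## Synthetic data

The fixture generator emulates the *inputs* of the pipeline, not real
biophysics: idealized B-form DNA (uniform rise 3.38 Å, twist 36°/step,
rigid library bases, a stylized sugar–phosphate backbone with correct
atom names but approximate internal geometry) and a poly-alanine
protein chain arcing at 23 Å radius — outside the 10 Å cutoff — with
designated atoms relocated to planted distances from designated DNA
atoms.  Planted-preference corpora put a probe atom type (default
ARG.NH1) 3.2–3.8 Å from the preferred base's discriminating
major-groove atom (N6/O6/N4/O4) at the center of a 5-base run, with
random flanks of the other bases keeping competing reference-sense
discriminators ≥ 8 Å away, plus five CB–phosphate contacts so every
complex clears the admission filters.  Generators are bit-deterministic
under their seed.

What passing tests on these fixtures shows: the counting, potential,
substitution, threading and scoring machinery is exact and internally
consistent, and the pipeline recovers a planted atomic preference end
to end.  What it does not show: predictive accuracy on real complexes,
which depends on a PDB-scale knowledgebase and on how well the rigid
superposition approximates the bound state.

## Numerical choices

Binning uses exact `ceil` arithmetic so boundary distances are
assigned per the half-open-left convention with no epsilon.  Altloc
resolution keeps the highest occupancy (ties: file order); only the
first model of multi-model files is read; hydrogens are dropped at
parse time.  Kabsch superposition enforces a proper rotation via the
SVD determinant correction and rejects collinear point sets.  The
Boltzmann column uses a max-shift; Ψ flooring precedes
renormalization.  Degenerate inputs fail loudly: empty structures,
empty knowledgebases, unpaired threading positions and non-orthogonal
matrices raise typed errors.

## Problem sizes

The bundled evaluation runs at desk scale, chosen to exercise every
code path with comfortable statistical margins: corpora of 30–50
complexes (each ~750 heavy atoms), 10–20 replicate seeds, 2,000–10,000
dummy PWMs per null.  The same code paths scale to PDB-sized corpora;
only the inputs change.

## Known limitations

* No modeling of unbound→bound conformational change (rigid splice).
* Positional independence: no dinucleotide or higher-order coupling.
* mmCIF input, modified nucleotides and NMR ensembles beyond model 1
  are out of scope.
* The fixture geometry is idealized; its backbone is not
  stereochemically exact and should not be used as a structural model.
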