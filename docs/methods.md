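# Methods

## Model class and conventions

A model is specified by an ordered alphabet (α ≥ 2 characters; the order is
contractual and the *last* character is the simplex reference), a sequence
length L, an encoding flavor, and an ordered family of position sets
A₁, …, A_J ⊆ {1, …, L}.  The embedding is the direct sum over j of the
Kronecker product, over the positions of A_j in ascending order, of the
single-position encoding; the empty set contributes the constant feature.
Duplicate position sets are allowed and produce duplicated feature blocks.
Positions are 1-based in all user-facing labels.

Two single-position encodings are supported.  The one-hot encoding of
character c is the α-dimensional indicator vector.  The simplex encoding
maps character c_i (i < α) to the i-th standard basis vector of dimension
α−1 and the last character to the all-(−1) vector, so the encodings of all
characters sum to zero.  Feature labels are `theta_0` for the constant,
`theta_<positions>:<characters>` for one-hot blocks and
`theta_<positions>:<indices>` (indices 1…α−1) for simplex blocks, with a
`#<ordinal>` suffix disambiguating repeated position sets.  No canonical
feature order exists in the literature for these models; the order used
here — blocks in listed order, Kronecker factors by ascending position,
characters in alphabet order — is a package convention and is what the TSV
and MatrixMarket outputs mean.

Sequence enumeration is lexicographic in alphabet-character order and fixes
the design-matrix row order.  Enumeration (and everything built on it: the
design matrix, the brute-force oracle, exhaustive gauge-vector tests) is
guarded by a cap, 10⁶ sequences by default.

A family with J = 0 (no blocks at all) is accepted as the degenerate
zero-dimensional model so that the enumeration of equivariant model classes
is closed under taking sub-families; it cannot be embedded or evaluated.

## Symmetry and representations

The group of position-specific character permutations acts on sequences by
applying an independent alphabet permutation at each position; elements are
stored as character-to-character mappings, so they are independent of
alphabet order.  The one-hot encoding transforms under the permutation
(defining) representation; the simplex encoding under the standard
representation.  The simplex representation matrix of a permutation is
computed by solving the linear system against the α−1 independent simplex
vectors — *not* by conjugating the permutation matrix with the similarity
transformation T — so the single-position Maschke identity
T·R_ohe(h)·T⁻¹ = (1) ⊕ R_sim(h) remains an independent cross-check rather
than a tautology.  That identity is verified in exact integer arithmetic in
the rearranged form T·R_ohe(h) = ((1) ⊕ R_sim(h))·T, avoiding the
fractional T⁻¹.

Parameters transform contragrediently, θ ↦ (R(h)⁻¹)ᵀθ, which is the unique
linear transform that compensates the sequence transformation in all
predictions; the inverse matrix is obtained exactly as R(h⁻¹).  For one-hot
models R(h) is a permutation matrix and the transform permutes parameters
along with their alleles; for simplex models it genuinely mixes parameters
(for α = 3 and the transposition of the first and last characters, the
additive block maps (θ¹, θ²) to (−θ¹−θ², θ²)), which is exactly why simplex
parameters cannot be read as intrinsic allelic effects.

## Distillation

The similarity matrix T (first row all ones; row i+1 equal to e_i − e_α)
satisfies T·onehot(c) = (1) ⊕ simplex(c).  Its inverse is closed-form, with
entries that are integer multiples of 1/α.

`Tdecom` is block-diagonal over position sets.  For each A_j the Kronecker
product of T factors is composed with a permutation that groups output
coordinates by the subset B ⊆ A_j of positions carrying a simplex
component, ordering sub-blocks by |B| then lexicographically by positions;
within a sub-block, coordinates follow the Kronecker order of the simplex
components (ascending position, indices in order), so the sub-block for B
literally equals the simplex product embedding over B on every sequence.
The supplement-level formulas published for this construction may differ
from ours by a permutation; any ±1-sparse factorization satisfying the
distillation certificate is equally valid, and ours is fixed by the
ordering above.

`Tthin` keeps the first copy of each distinct subset (first in the global
block order: smallest j, then the within-j order) and replaces every later
copy by (copy − kept copy).  Since copies are *equal* on sequence
embeddings — the proportionality constant between copies is +1 for
generalized one-hot models, and the certificate asserts this equality —
the later copies become identically zero.  `Tthin` is unit-triangular-like:
its inverse simply re-adds the kept copy.  `Tsort` is the permutation
placing kept sub-blocks on top, ordered by subset size then position
lexicography, with the zeroed coordinates following in their original
order.

`Tdist = Tsort·Tthin·Tdecom` then maps every sequence embedding to the
distilled simplex embedding over the distinct subsets followed by γ zeros.
Its entries are in {−1, 0, +1}: the only additive mixing (thinning)
combines rows from different block-diagonal blocks, whose column supports
are disjoint.  The inverse is assembled from the three factors'
closed-form inverses, never by dense numerical inversion; it is fractional
(denominators divide α^max|A_j|) and the product Tdist·Tdist⁻¹ is checked
to machine precision.

Simplex-flavor inputs are already sums of irreducible blocks, so `Tdecom`
is the identity for them and distillation reduces to thinning repeated
position sets and sorting; families with distinct sets come back unchanged
with γ = 0.

## Counting

M = Σ_j base^|A_j| (base α for one-hot, α−1 for simplex) and γ are computed
by exact integer arithmetic with no matrices: the distinct subsets are the
union of the power sets of the A_j (for one-hot) or the distinct A_j (for
simplex), the multiplicity Q_k of subset B_k is the number of A_j containing
it, and the two equivalent expressions for γ (dimension deficit and
multiplicity sum) are both evaluated and required to agree.  This scales to
pairwise models with L in the thousands; the all-order family at large L is
out of reach of the subset enumeration, as its distinct-subset count itself
is 2^L.

## Gauge fixing

The gauge basis is the last γ rows of Tdist.  The projection
P = Tdistᵀ·D·(Tdist⁻¹)ᵀ, with D the diagonal selector of the first M−γ
coordinates, is idempotent, annihilates the gauge space, and satisfies
Pᵀx(s) = x(s), hence preserves every prediction.  Its image — the
"distilled gauge" — is one valid linear gauge; it is *not* claimed to be
the zero-sum gauge.  The zero-sum conditions (additive parameters summing
to zero over characters at each position, pairwise blocks summing to zero
over either margin) are provided as a separate structural check for the
pairwise one-hot preset, and the relationship between the two gauges is
left empirical.

## Oracle

The brute-force oracle computes M − rank of the enumerated design matrix
(rank via SVD with a 1e-9 relative cutoff — design entries are in
{−1, 0, 1} and the singular values are well separated at these sizes), an
orthonormal null-space basis, and column-span equality by mutual projection
residuals.  It shares no code with the distillation path; independence is
the point.  Gauge-vector membership tests are exact for integer vectors and
use an absolute tolerance of 1e-9 otherwise.

## Test problem sizes

Certificate-style checks run exhaustively over all sequences for every
structured preset at α ∈ {2, 3, 4} and L ∈ {2, 3}, plus the all-order model
at α = 3, L = 3 (27 sequences, M = 64, γ = 37) — sizes at which the oracle
is exact and instant.  Equivariance checks use 10 seeded random group
elements and parameter vectors per model; class enumeration is tested to
L = 3 (256 classes).  Sparsity of Tdist is checked only as a non-exploding
nonzero count for pairwise models at L = 4, 8, 16 (α = 4), consistent with
O(L²) growth; no asymptotic claim is tested.

## Known limitations

Only the PSCP symmetry group is implemented; the global character
permutation, position permutation and full Hamming-isometry groups are out
of scope, as are wild-type (reference-relative) and physicochemical
feature encodings, model fitting, and the enumeration of allelic orbits for
arbitrary generalized alleles.  The multi-orbit lower bound γ ≥ J−1 is
exercised on random position-set families only.  All inputs are synthetic:
model specifications, parameters and sequences are generated or written by
hand — the package analyzes model structure, not data, so nothing about
fit quality on real assays is implied by the tests passing.
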