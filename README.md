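# seqgauge

Gauge freedoms of linear sequence-function models, analyzed through the
symmetry group of position-specific character permutations.

## The problem

Quantitative models of sequence-function relationships — Potts-style models
of proteins, additive and pairwise-interaction models fit to deep mutational
scanning or massively parallel reporter data — are usually written as linear
models over one-hot features:

    f(s; θ) = θᵀ x(s),

where the embedding x(s) is a direct sum, over position sets A₁, …, A_J, of
Kronecker products of single-position one-hot encodings.  These features are
linearly dependent (the indicators at a position sum to one), so the models
carry **gauge freedoms**: directions g in parameter space with
f(s; θ+g) = f(s; θ) for every sequence s.  Individual parameter values are
then meaningless until the gauge is fixed, and the gauge space G — the null
space of the α^L × M design matrix — is too large to compute by elimination
once α^L explodes.

`seqgauge` is for modelers who need to know, for a given model family, how
many gauge freedoms there are, a basis for them, and a projection that fixes
the gauge — without ever forming the design matrix.

## The method: embedding distillation

Sequence space carries the symmetry group H = H₁ × ⋯ × H_L of
position-specific character permutations (PSCP), which preserves Hamming
distances.  One-hot models are *equivariant*: x(hs) = R(h) x(s) for a
permutation representation R, and parameters co-transform by (R(h)⁻¹)ᵀ.
The single-position one-hot representation splits into the trivial and the
standard ("simplex") irreducible representations of the symmetric group;
the splitting is realized by the integer similarity matrix T with
T·onehot(c) = (1) ⊕ simplex(c).

Applying T factor-by-factor turns each Kronecker block over A_j into 2^|A_j|
irreducible sub-blocks, one per subset B ⊆ A_j, and every sub-block with the
same B is *equal* on all sequence embeddings.  The distillation

    T_dist = T_sort · T_thin · T_decom

subtracts redundant copies and sorts the survivors, so that for every s

    T_dist · x(s) = x_dist(s) ⊕ 0_γ,

where x_dist is the full-rank simplex embedding over the distinct subsets
B₁, …, B_K and

    γ = M − Σ_k (α−1)^|B_k| = Σ_k (Q_k − 1)(α−1)^|B_k|,

with Q_k = #{j : B_k ⊆ A_j}.  The last γ rows of T_dist are a sparse basis
of G with entries in {−1, 0, +1}, and P = T_distᵀ D (T_dist⁻¹)ᵀ (D keeping
the first M−γ coordinates) is an idempotent, prediction-preserving
gauge-fixing projection.  Both counts are pure integer combinatorics and
scale to L in the thousands; a brute-force design-matrix oracle certifies
everything on small instances.

## Worked example

A pairwise-interaction one-hot model on DNA 3-mers (α = 4, L = 3):

```python
import seqgauge as sg

spec = sg.model_preset("pairwise", "ACGT", 3)
print("M     =", sg.count_params(spec))
print("gamma =", sg.count_gauge(spec))

res = sg.distill(spec)
print("distilled dim =", res.distilled_dim)
print("nnz(Tdist)    =", res.Tdist.nnz)

basis = sg.gauge_basis(res)
print("basis shape   =", basis.vectors.shape)
print("oracle gamma  =", sg.nullspace_dim(spec))
```

prints

```
M     = 61
gamma = 24
distilled dim = 37
nnz(Tdist)    = 373
basis shape   = (24, 61)
oracle gamma  = 24
```

The model has M = 1 + Lα + C(L,2)α² = 61 parameters, of which
γ = L + C(L,2)(2α−1) = 24 are gauge freedoms — the familiar per-position
and per-pair marginal constraints of Potts models.  The distilled model has
37 = 1 + L(α−1) + C(L,2)(α−1)² parameters (the matched simplex model, which
has no gauge freedoms), the 24 × 61 basis consists of sparse ±1 vectors each
annihilating all 64 sequence embeddings, and the brute-force rank of the
64 × 61 design matrix confirms the count.

The same operations are available from the shell:

```
seqgauge count --config model.json
seqgauge distill --config model.json --out out/model
seqgauge gauge-basis --config model.json --out out/model
seqgauge project --config model.json --theta theta.tsv --out fixed.tsv
seqgauge evaluate --config model.json --theta theta.tsv --fasta seqs.fasta --out preds.tsv
seqgauge verify --config model.json
seqgauge enumerate-classes -L 2 --out classes.json
```

with `model.json` like `{"alphabet": "ACGT", "L": 3, "preset": "pairwise"}`
(or an explicit `"position_sets": [[], [1], [2], [1, 2]]`).  Matrices are
written in MatrixMarket coordinate format, parameters and predictions as
TSV.

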