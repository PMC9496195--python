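# anchorgda

Anchor-gene co-expression screening and gene-signature deconvolution for
bulk transcriptomes.

## The problem

In case/control expression studies of neurodegeneration (the motivating
setting is spinal-cord tissue of ALS patients vs non-diseased controls), a
single gene of interest — the *anchor*, e.g. `GJA1`, which encodes the
gap-junction protein connexin 43 — can be used to stratify the whole
transcriptome: which genes rise and fall with the anchor, and what cell
types or processes do those genes represent? `anchorgda` implements that
workflow end to end for analysts working from a genes × samples expression
matrix and a library of curated gene signatures:

1. **Screen** — Pearson-correlate every gene to the anchor within one sample
   group. Genes with r ≥ 0.50 (and two-sided p < 0.05, from
   t = r·√((n−2)/(1−r²)) with n−2 df) form the significantly positively
   correlated set (GSPC); genes with r ≤ −0.50 the negatively correlated set
   (GSNC). Both criteria are configurable and either can be disabled.
2. **Deconvolve** — intersect a gene list of size *n* with each signature of
   size *D* in a universe of *N* genes (default N = 20,203, the annotated
   RefSeq count). For an observed overlap *x*:

   - expected overlap  E = n·D / N
   - representation factor  RF = x / E  (RF > 1: more overlap than chance)
   - exact hypergeometric tail  p = P(X ≥ x),  with
     P(X = x) = C(D, x)·C(N−D, n−x) / C(N, n)
   - percent of signature  100·x / D

3. **ROC** — evaluate the anchor (or any marker) as a two-group
   discriminator: AUC = U/(n₁n₂) (Mann–Whitney, midranks), Hanley–McNeil
   95% CI, normal-approximation p against AUC = 0.5.
4. **Drugs** — rank candidate signature-reversing compounds by the combined
   score C = z·log₁₀(p); strongly negative C flags candidate reversers.

Supporting modules handle probe collapse (highest-variance probe per gene),
per-gene z-scoring, ANOVA + Benjamini–Hochberg differential screening, and a
fully seeded synthetic-data generator that plants known correlation blocks
and signature memberships so every stage is testable without any download.

## Worked example

```python
from anchorgda import (
    SimulationConfig, generate_dataset, correlate_to_anchor,
    deconvolve, roc_auc, expected_overlap, representation_factor,
    hypergeom_upper_tail,
)

# enrichment arithmetic on published intersection counts:
# n = 2542 anchor-correlated genes vs the D = 118 microglia signature
print("expected =", round(expected_overlap(2542, 118, 20203), 2))
print("RF       =", round(representation_factor(70, 2542, 118, 20203), 2))
print("p_tail   =", f"{hypergeom_upper_tail(70, 2542, 118, 20203):.2e}")

# end-to-end on a synthetic two-group study with planted structure
cfg = SimulationConfig(seed=0)          # 10 NDC + 13 ALS, 2000 genes
matrix, signatures, truth = generate_dataset(cfg)
screen = correlate_to_anchor(matrix, "GJA1", "ALS")
print("GSPC/GSNC sizes:", len(screen.gspc), len(screen.gsnc))
for rec in deconvolve(screen.gspc, signatures):
    print(f"{rec.signature_name:15s} x={rec.x:3d} RF={rec.rf:5.2f} "
          f"-log10 p={rec.neglog10_p:6.2f} enriched={rec.enriched}")

neg = matrix.values.loc["GJA1", matrix.samples_in_group("NDC")]
pos = matrix.values.loc["GJA1", matrix.samples_in_group("ALS")]
res = roc_auc(neg.to_numpy(), pos.to_numpy(), marker="GJA1")
print(f"AUC = {res.auc:.4f}  95% CI [{res.ci_low:.3f}, {res.ci_high:.3f}]  p = {res.p:.3f}")
```

Output:

```
expected = 14.85
RF       = 4.71
p_tail   = 2.67e-33
GSPC/GSNC sizes: 329 438
microglia_like  x= 74 RF=37.87 -log10 p=102.82 enriched=True
neuron_like     x= 13 RF= 0.89 -log10 p=  0.15 enriched=False
AUC = 0.7846  95% CI [0.597, 0.973]  p = 0.024
```

Reading the output: a random 2542-gene list would share ~14.85 genes with a
118-gene signature in a 20,203-gene universe, so an observed overlap of 70
is 4.71-fold enriched with tail probability ~10⁻³³. On the synthetic study,
the screen recovers the planted positively correlated block into GSPC, the
immune-like signature planted inside that block is flagged as enriched
while the neural-like signature is not, and the anchor discriminates cases
from controls at AUC ≈ 0.78 — the discrimination level its default
group-shift (δ = 1.1 sd) is designed to produce.

The same pipeline runs from the shell on TSV/GMT files:

```bash
anchorgda simulate --out sim --seed 42
anchorgda screen --expression sim/expression.tsv --annotation sim/annotation.tsv \
    --anchor GJA1 --group ALS --out screen_out
anchorgda deconv --genes gspc.txt --gmt sim/signatures.gmt --out deconv_out
anchorgda roc --expression sim/expression.tsv --annotation sim/annotation.tsv \
    --gene GJA1 --neg-group NDC --pos-group ALS --out roc_out
anchorgda drugs --table drugs.tsv --out drugs_out
```

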