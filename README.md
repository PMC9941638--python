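# panicleqtl

Quantitative description of **organ distribution patterns along the rice
panicle**, and QTL mapping of those patterns in backcross inbred line (BIL)
populations.

## The problem

Rice yield depends not only on how many spikelets a panicle carries but on
*where* along the rachis its organs sit — distally laid panicles fill grain
differently from proximally laid ones.  Organ *numbers* are easy to count;
organ *distribution patterns* have lacked an objective, heritable phenotype.
This package implements such a phenotype and the genetics around it, for
plant geneticists and breeders working with inbred-line mapping populations.

## The method

For one panicle, measure each primary branch (length, secondary branch
count, spikelet count), index branches from the distal end, and map rank
*i* of *n* to position *x = (i−1)/(n−1)* on [0, 1].  Fit a cubic spline

&nbsp;&nbsp;&nbsp;&nbsp; *y<sub>i</sub> = α + Σ<sub>k=1..K</sub> β<sub>k</sub> b<sub>k</sub>(x<sub>i</sub>) + ε<sub>i</sub>*

with **knots fixed across panicles** so coefficients are comparable, choose
the model dimension *K* ∈ {3,4,5} per trait by the summed GCV score
*n·RSS/(n−edf)²* over all lines, and rescale the fitted curve to integrate
to one.  The rescaled coefficients (α′, β′₁…β′<sub>K</sub>) are a
size-free descriptor of the distribution pattern; principal components of
the per-line descriptor matrix are the pattern phenotypes.  Downstream:

* narrow-sense heritability *h² = σ²<sub>G</sub>/(σ²<sub>G</sub>+σ²<sub>ε</sub>)*
  by REML under *V = Gσ²<sub>G</sub> + Iσ²<sub>ε</sub>* with a VanRaden
  marker relationship matrix *G*;
* a single-QTL genome scan: Kosambi map, two-state hidden Markov genotype
  probabilities for BC1-derived inbred lines (class prior 3/4 : 1/4), a
  normal-mixture EM fit at every cM, LOD = log₁₀ likelihood ratio,
  1,000-permutation genome-wide thresholds, −2-LOD support intervals,
  allele effects and PVE = 1 − 10^(−2·LOD/n);
* a simulator that plants independent "organ number" and "organ pattern"
  QTLs in BC1F7 genomes, so the whole pipeline is testable end to end.

## Worked example

Simulate a 75-line BIL panel with a number QTL on c1 and a pattern QTL on
c2, then describe and scan it:

```bash
python - <<'PY'
import yaml, pathlib
cfg = {"simulate": {"seed": 3, "n_lines": 75,
                    "chromosomes": {"c1": 60.0, "c2": 60.0},
                    "qtls": [{"chromosome": "c1", "position_cm": 30.0,
                              "kind": "number", "effect": 1.45},
                             {"chromosome": "c2", "position_cm": 30.0,
                              "kind": "pattern"}]}}
pathlib.Path("demo.yaml").write_text(yaml.safe_dump(cfg))
PY
panicleqtl simulate --config demo.yaml --out demo
panicleqtl describe --phenotype demo/phenotype.csv --out demo/desc
panicleqtl scan --phenotype demo/phenotype.csv --genotype demo/genotype.csv \
    --map demo/map.csv --out demo/scan --n-perm 1000 --step 2 --seed 1
```

`describe` prints the per-trait PCA report (variance proportions in %):

```
                  trait  df  PC1  PC2  PC3  PC4  PC5
  primary_branch_length   4 79.5 19.1  1.2  0.2  0.0
secondary_branch_number   3 93.3  5.7  1.0  0.0  NaN
        spikelet_number   3 97.0  2.3  0.7  0.0  NaN
```

PC1 and PC2 carry nearly all pattern variance.  `scan` reports
`6 QTL peak(s) above threshold`; in its `peaks.csv` the organ totals peak
only on c1, the planted number locus (total spikelet number: LOD 29.1,
PVE 0.83, class means 161.4 ± 1.6 vs 237.7 ± 4.6 — the planted 1.45
ratio), and the descriptor PCs peak only on c2, the planted pattern locus
(primary-branch-length PC1: LOD 56.8), every support interval covering
the true 30 cM position.  Organ number and organ pattern segregate
independently — exactly the dissociation the method is built to expose.

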