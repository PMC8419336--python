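# vaftree

Exhaustive reconstruction of clonal hierarchies from bulk variant allele
frequencies.

Acute myeloid leukemia (and many other cancers) consists of several clones
related by a rooted mutation tree: each clone differs from its parent by one
newly acquired heterozygous mutation. Single-cell sequencing reveals that
tree directly but is rarely available in the clinic; bulk sequencing only
reports, for each mutation *i*, the variant allele frequency *b*<sub>i</sub>
— the mixture-weighted fraction of cells carrying it. `vaftree` answers the
question: **which clonal hierarchies are compatible with the measured bulk
VAFs, and how ambiguous is that reconstruction?**

## The model

Number the clones from the root in nondecreasing depth and let
*a*<sub>ij</sub> = 1 if clone *j* carries mutation *i*. The resulting
genotype matrix **A** is unit upper triangular (det **A** = 1), so the clone
frequencies **x** solve

&nbsp;&nbsp;&nbsp;&nbsp;**A x** = **b**

uniquely by back-substitution. A hierarchy is *compatible* with the data iff
that solution is componentwise non-negative. VAFs are rescaled so the most
abundant mutation reads 100%; the founder row of **A** is all ones, so
compatible founder-rooted solutions satisfy Σ*x*<sub>i</sub> = 100.

All candidate hierarchies are generated exhaustively through the Prüfer
bijection (*n*<sup>*n*−2</sup> labeled trees per fixed root,
*n*<sup>*n*−1</sup> rooted trees overall). Under measurement error each
candidate is instead fit by constrained weighted least squares

&nbsp;&nbsp;&nbsp;&nbsp;min ‖**W**(**A x** − **b**)‖₂ s.t. *x*<sub>i</sub> ≥ 0, Σ*x*<sub>i</sub> = 100,

and all candidates are ranked by residual. The robustness of a
reconstruction is quantified by multinomial resampling of single-cell clone
counts, Gaussian perturbation of the VAFs, and an exhaustive uniqueness
experiment on exact data. Samples with several founding clones (or an
unsequenced common founder) are handled by rooting at a healthy reference
allele, optionally *relaxing* the data (scaling mutated VAFs by
(100 − *x*)/100 to admit *x*% healthy cells).

## Worked example

```python
import numpy as np
from vaftree import VAFSample, reconstruct, write_newick

diagnosis = VAFSample(("DNMT3A", "NPM1", "FLT3"),
                      np.array([100.0, 60.0, 30.0]), timepoint="diagnosis")
report = reconstruct([diagnosis])
print(f"{report.n_trees_enumerated} candidate hierarchies, "
      f"{len(report.exact_fits)} exact")
for fit in report.exact_fits:
    print(f"rank {fit.rank}  residual {fit.combined_residual:.3f}  "
          f"clone frequencies {fit.x_as_dict('diagnosis')}")
    print("  ", write_newick(fit.tree))
```

prints

```
3 candidate hierarchies, 2 exact
rank 1  residual 0.000  clone frequencies {'DNMT3A': 10.0, 'FLT3': 30.0, 'NPM1': 60.0}
   (FLT3,NPM1)DNMT3A;
rank 1  residual 0.000  clone frequencies {'DNMT3A': 40.0, 'NPM1': 30.0, 'FLT3': 30.0}
   ((FLT3)NPM1)DNMT3A;
```

Two hierarchies explain these VAFs exactly: the branched tree
DNMT3A → {NPM1, FLT3} mixing clones at 10/60/30%, and the chain
DNMT3A → NPM1 → FLT3 at 40/30/30%. The third candidate
(DNMT3A → FLT3 → NPM1) would need a negative clone frequency and is ruled
out. A second timepoint typically removes the remaining ambiguity.

The same pipeline is available from the shell:

```sh
vaftree reconstruct --vaf diagnosis.csv --vaf relapse.csv \
        --mode founder --out report.json --newick trees/
vaftree --seed 1 simulate --n 4 --cells 500 --out patient
vaftree --seed 1 perturb --sc patient.sc.tsv --truth patient.truth.nwk \
        --reps 1000 --sd 0.5 --out experiment/
vaftree --seed 1 uniqueness --n 4 --datasets 10000 --timepoints 2
```

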