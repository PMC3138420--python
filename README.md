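# aainterp

Fixed-width numeric feature matrices from variable-length protein sequences.

Most classifiers and regressors require inputs of a fixed dimension, but
biological sequences vary in length through insertions and deletions.
`aainterp` bridges that gap in two steps:

1. **Descriptor encoding.** Each residue of an amino-acid sequence is mapped
   to a real number by a physicochemical *descriptor scale* — a function
   `d: {A,R,N,D,…,V} → ℝ` such as Kyte–Doolittle hydropathy, net charge or
   molecular weight. A sequence `s = s₁…s_L` becomes the vector
   `y = (d(s₁), …, d(s_L))`. A bundled database ships 532 scales: 531
   all-numeric AAindex1 entries plus one synthetic alphabet-rank scale,
   addressed by 1-based index (index 151, the default, is Kyte–Doolittle
   hydropathy; 146 is net charge). Optionally a scale's 20 values are
   affinely normalized onto [0, 1] or [−1, 1] before encoding.

2. **Length normalization by interpolation.** The encoded vector is treated
   as samples of a function at knots x = 1…L and resampled to a target
   length D on the uniform grid `x_j = 1 + (j−1)(L−1)/(D−1)`, using one of
   five interpolants: `linear` (straight segments), or a cubic spline with
   `natural` (zero end curvature), `periodic` (equal first and second
   derivatives at the two endpoints; requires equal endpoint values) or
   `fmm` (Forsythe–Malcolm–Moler: end conditions taken from the exact cubic
   through the outermost four points at each end) boundary conditions;
   `spline` is an alias of `fmm`. The spline systems are solved in
   second-derivative (moment) form with the Thomas algorithm, the periodic
   one by Sherman–Morrison cyclic reduction. All interpolants pass through
   every knot, so the first and last output values always equal the first
   and last input values.

Applying both steps to every sequence of a dataset yields an
`n_sequences × D` feature matrix ready for any standard learner. The
motivating use case is HIV-1 coreceptor-usage prediction from V3-loop
sequences (33–38 residues, length varying by indels), where hydropathy
encoding plus length normalization makes fixed-dimension classifiers
applicable; the package also ships a synthetic V3-like two-class generator
so the whole pipeline can be exercised and tested without external data.

## Worked example

```python
import numpy as np
from aainterp import (SequenceRecord, NormalizationMode, encode,
                      load_bundled_database, resample)

db = load_bundled_database()
scale = db.get(151)
print(f"descriptor 151: {scale.accession} — {scale.description}")

v3 = SequenceRecord(
    id="v3_example",
    residues="CTRPNNNTRKSIHIGPGRAFYTTGEIIGDIRQAHCNIC",
)
enc = encode(v3, db, descriptor_index=151, mode=NormalizationMode.UNIT)
print(f"encoded length: {enc.source_length}")
np.set_printoptions(precision=3, suppress=True)
print("first five encoded values:", enc.values[:5])

out = resample(enc.values, 35, "spline")
print(f"normalized length: {len(out)}")
print("first five normalized values:", out[:5])
```

prints

```
descriptor 151: KYTJ820101 — Hydropathy index (Kyte-Doolittle, 1982)
encoded length: 38
first five encoded values: [0.778 0.422 0.    0.322 0.111]
normalized length: 35
first five normalized values: [0.778 0.369 0.029 0.312 0.086]
```

The 38-residue loop is encoded residue-by-residue with [0, 1]-normalized
hydropathy (C → 0.778, T → 0.422, R → 0, …) and squeezed to 35 values by a
cubic spline; interior values shift slightly as the sampling grid moves,
while the two endpoint values are preserved exactly.

The same pipeline from the shell:

```
aainterp synth --n0 1151 --n1 200 --signal 0.6 --seed 42 \
    --out synth.fasta --labels synth_labels.txt
aainterp encode-matrix --fasta synth.fasta --descriptor 151 \
    --dims 35 --method linear --normalize 2 --out matrix.csv
aainterp demo --fasta synth.fasta --labels synth_labels.txt \
    --dims 35 --folds 5 --seed 1
```

The `demo` subcommand reports the cross-validated area under the ROC curve,
`AUC = 0.9140 (5-fold cross-validation)` for the generated set above
(a 200-vs-1151 imbalanced two-class problem whose minority class has a
hydrophobic-shifted residue composition). `aainterp list-descriptors`
prints the full bundled scale table.

## Layout

- `aainterp.descriptors` — AAindex1 parsing, the bundled 532-scale
  database, interval normalization of scales
- `aainterp.encode` — sequence → descriptor-value vector
- `aainterp.interpolate` — the five resampling methods and their solvers
- `aainterp.pipeline` — dataset → feature matrix; cross-validated demo
  classifier
- `aainterp.synth` — synthetic V3-like two-class sequence generator
- `aainterp.io` — FASTA, label-file and matrix CSV/TSV readers/writers
- `aainterp.cli` — the `aainterp` command

See `docs/methods.md` for the model details, parameter choices and known
limitations.
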