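# molarbovw

Bag-of-visual-words classification of third-molar complications on
panoramic dental radiographs.

Impacted or tilted third molars (wisdom teeth, "R8") are a common
finding on panoramic radiographs, and triaging hundreds of images is
tedious even for experienced dentists.  `molarbovw` implements a
classical computer-vision pipeline for sorting such radiographs into
three groups — `R8_Lower` (lower molars affected), `R8_Upper_Lower`
(upper and lower affected) and `R8_Null` (no affected molar) — without
any bounding-box annotation or deep learning:

```
radiograph → median(3×3) → bilateral(d=9, σ_c=σ_s=75) → Sobel |G_x|,|G_y| blend
          → fixed third-molar ROI mask (rows 300:900, cols 490:2200 @ 1200×2400)
          → ORB/SIFT keypoint descriptors → K-means visual vocabulary (K words)
          → BoVW histogram h ∈ ℝ^K,  h_j = #{descriptors nearest to word j}
          → 6 classifiers × stratified 10-fold CV (paired folds)
```

The library is organised as sklearn-style estimators —
`KeypointDescriptorExtractor` (images → descriptor bags) and
`BagOfVisualWords` (bags → histograms, `fit`/`transform`, fitted
attributes `cluster_centers_`, `inertia_`) — that compose with any
sklearn classifier or `Pipeline`, plus a `molarbovw` CLI for running the
stages from a shell.  Since clinical datasets cannot be redistributed,
a seeded synthetic radiograph generator (`molarbovw.synthetic`)
produces labeled phantoms with the statistical structure the pipeline
assumes; see `docs/methods.md` for what it does and does not emulate.

## Worked example

Generate a small synthetic dataset and benchmark all six classifiers:

```sh
molarbovw generate --n 150 --seed 42 --out data/
molarbovw evaluate data/manifest.csv --out run/ --k 200 --seed 42
```

The evaluation prints a table like (accuracy as `mean±std` over ten
folds; numbers from the run above):

```
                             ORB
logistic_regression  0.953±0.043
svm_rbf              1.000±0.000
mlp                  0.940±0.055
decision_tree        0.827±0.095
gradient_boosting    0.907±0.061
random_forest        1.000±0.000
```

Every classifier sits far above the three-class chance level (~0.33),
i.e. the BoVW histograms carry the class signal; a shuffled-label
control on the same histograms lands at 0.35.  On synthetic phantoms
the separations are cleaner than clinical imaging would allow — the
absolute numbers characterise the pipeline, not clinical performance.

`run/` then contains `report.json` (per-fold detail), `report.csv`
(the table above), `vocabulary.bovw` and `run_record.json` (config
snapshot, manifest hash, timings).  Single-image prediction:

```sh
molarbovw extract data/manifest.csv run/train.desc
molarbovw build-vocab run/train.desc run/vocab.bovw --k 200 --seed 42
molarbovw encode run/train.desc run/vocab.bovw run/hist.csv
molarbovw train run/hist.csv data/manifest.csv run/model.joblib \
    --classifier decision_tree --vocabulary run/vocab.bovw
molarbovw predict run/model.joblib data/img_0000.png
# data/img_0000.png: R8_Null (low evidence: 0 keypoints)
```

(An `R8_Null` phantom has no affected-molar texture, so the edge image
carries almost no corner structure inside the ROI — the all-zero
histogram is itself the class signature, and the prediction is flagged
accordingly.)

As a library:

```python
from sklearn.pipeline import Pipeline
from sklearn.tree import DecisionTreeClassifier
from molarbovw import BagOfVisualWords, KeypointDescriptorExtractor

pipe = Pipeline([
    ("features", KeypointDescriptorExtractor(method="ORB")),
    ("bovw", BagOfVisualWords(n_words=200, seed=42)),
    ("clf", DecisionTreeClassifier(random_state=0)),
])
pipe.fit(images, labels)          # images: list of uint8 arrays
```

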