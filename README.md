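# subwave

**2D microwave head-scattering simulation and nearest-subspace
classification of subdural hematoma.**

Traumatic subdural hematoma (SDH) is routinely detected by CT, which is not
available in ambulances; broadband microwave technology — an antenna helmet
measuring multiport scattering parameters across 0.1–3 GHz — is a candidate
for prehospital detection.  `subwave` implements the computational arm of
that idea for researchers in biomedical electromagnetics and
machine-learning diagnostics: a parameterized 2D finite-element model of a
human head inside an 8-antenna helmet, simulation of the complex
S-parameters over randomized "patients" (head size, helmet rotation, CSF
thickness, bleeding size and position), and a multi-class SVD subspace
classifier with the full evaluation protocol (grouped fivefold
cross-validation, learning curves, and a binary validation set drawn with
unseen parameter values).

## The model in brief

* **Physics.**  Frequency-domain scalar Helmholtz equation for the
  out-of-plane magnetic field (TM polarization),
  `div((1/eps_r) grad H) + k0^2 H = 0`, on an unstructured triangle mesh;
  complex tissue permittivities from Debye / 4-term Cole–Cole dispersion
  models (`eps = eps' − j eps''`, `e^{+j omega t}`).  Antennas are
  parallel-plate waveguide ports (`eps_r = 20`) carrying a cutoff-free TEM
  mode; water bags couple the apertures to the skull.  One sparse LU
  factorization per frequency yields the full 8×8 S matrix; reciprocity
  holds to round-off and left-side lesions reuse right-side solves through
  the port reflection permutation.
* **Features.**  The unique channels `S_ij (j ≥ i)` of every frequency are
  concatenated into one complex vector `x` — 36 channels for 8 antennas,
  55 channels (22,055 elements at 401 frequencies) for the 10-antenna
  instrument — with no further preprocessing.
* **Classifier.**  Each class `c` is modeled as `x = U_c α + e`; `U_c` holds
  leading left singular vectors of the class data matrix, and an observation
  is assigned to the class with the smallest projection residual
  `d_c = ||x − U_c U_c^H x||`.  `NearestSubspaceModel.fit()` returns a
  results object with the bases, retained singular values, `summary()`,
  `distances()` and `predict()`.

## Worked example

Simulate a scaled-down study (30 observations per class, 8 frequencies over
0.7–1.7 GHz; about two minutes on one CPU) and look at bleeding detection
and the subspace-distance trend:

```python
import numpy as np
from subwave import (HeadModelConfig, sample_scenarios, build_dataset,
                     cross_validate, confusion_metrics)

config = HeadModelConfig()
scenarios = sample_scenarios(30, config=config, seed=7)   # 180 scenarios
data = build_dataset(scenarios, np.linspace(0.7e9, 1.7e9, 8), config,
                     elements_per_wavelength=6)

cm, dists = cross_validate(data, k=5, seed=0, return_distances=True)
metrics = confusion_metrics(cm)
print(f"binary detection: sensitivity {metrics['tpr_pct']:.1f} %, "
      f"specificity {metrics['tnr_pct']:.1f} %")
for c, name in enumerate(data.class_names):
    print(f"median distance to the no-bleeding subspace, {name:12s}: "
          f"{np.median(dists[data.y == c, 0]):.4f}")
```

prints

```
binary detection: sensitivity 82.0 %, specificity 66.7 %
median distance to the no-bleeding subspace, no_bleeding : 0.0097
median distance to the no-bleeding subspace, 0.2cm       : 0.0146
median distance to the no-bleeding subspace, 0.5cm       : 0.0237
median distance to the no-bleeding subspace, 1cm         : 0.0287
median distance to the no-bleeding subspace, 2cm         : 0.0424
median distance to the no-bleeding subspace, 2.5cm       : 0.0441
```

The held-out distance to the no-bleeding subspace grows monotonically with
bleeding thickness — the behavioral signature of the method — and detection
improves steeply with training-set size: at the full design (250
observations per class) fivefold CV reaches 100 % sensitivity and
specificity with ~82 % six-class accuracy (see below).

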