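# chromodyn

Quantitative analysis of MeCP2 chromatin binding and clustering, and its
relationship to clinical severity in Rett syndrome, as a tested and
reusable Python pipeline.

MeCP2 binds methylated DNA through its methyl-CpG-binding domain (MBD) and
accumulates at chromocenters — the DAPI-bright pericentromeric
heterochromatin foci of mouse interphase nuclei — where it drives their
clustering into fewer, larger foci. Missense mutations in the MBD impair
this in graded ways: some abolish binding outright, some leave binding but
abolish or impair clustering. `chromodyn` implements the image- and
kinetics-level quantities used to score these phenotypes:

- **Segmentation** — nuclei by global thresholding plus distance-transform
  watershed; chromocenters within each nucleus by a nucleoplasm-relative
  intensity threshold (mean + *k*·sd) and an h-maxima-seeded watershed on
  inverted intensity (descending-threshold "water" region splitting),
  yielding per-cell chromocenter number **CN** and mean size **CS**.
- **Co-localization** — per-nucleus Pearson coefficient *r*<sub>p</sub>
  between the DAPI and GFP channels, banded as *r*<sub>p</sub> ≥ 0.6
  positive, 0.5 < *r*<sub>p</sub> < 0.6 weak positive, *r*<sub>p</sub> ≤ 0.5
  negligible, and combined with morphometry into four binding/clustering
  patterns (normal, impaired clustering, abolished clustering, abolished
  binding).
- **Morphometry statistics** — per-construct CN/CS means ± SEM and
  two-tailed Mann–Whitney U tests against wild type (exact enumeration for
  small untied samples, tie-corrected normal approximation otherwise), with
  significance tiers *p* ≤ 0.005 and *p* ≤ 0.05.
- **FRAP kinetics** — easyFRAP-style double normalization
  *I*<sub>dn</sub>(t) = (*T*<sub>pre</sub>/*T*(t))·(*I*(t)/*I*<sub>pre</sub>)
  and full-scale normalization, then least-squares fitting of
  *f*(t) = *A*·(1 − e<sup>−kt</sup>) (or a double exponential), giving the
  half-time of recovery t<sub>1/2</sub> = ln 2/k, the mobile fraction
  (fitted amplitude, normalized to one) and R².
- **Severity scoring** — a Functional Severity Score
  FSS = w<sub>cn</sub>·|CN<sub>mut</sub>/CN<sub>WT</sub> − 1| +
  w<sub>cs</sub>·|CS<sub>mut</sub>/CS<sub>WT</sub> − 1| correlated
  (Pearson/Spearman) against the per-mutation Clinical Severity Score (CSS),
  packaged from published hemizygous-male case reports.

Raw micrographs for the original experiments are not publicly deposited, so
the package ships a first-class **synthetic-data module**: two-channel
nucleus scenes with Gaussian-profile chromocenters, configurable
co-localization state and a ground-truth sidecar, plus FRAP traces from the
single-exponential recovery model with acquisition photobleaching and
noise. Every downstream stage is tested against this known truth.

## Worked example

```python
from chromodyn import *
from chromodyn.synthetic import SceneParams, FrapSimParams

scene = generate_nucleus_image(SceneParams(coloc_mode="colocalized",
                                           noise_sd=0.02, seed=8))
nucleus = segment_nuclei(scene.dapi, min_nucleus_area=1000)[0]
foci = detect_chromocenters(scene.dapi, nucleus, pixel_size_um=0.1)
r_p = pearson_coloc(scene.dapi, scene.gfp, nucleus)
print(f"CN = {foci.cn}, CS = {foci.cs_um2:.3f} um^2")
print(f"r_p = {r_p:.3f} ({classify_localization(r_p)})")

trace = generate_frap_trace(FrapSimParams(mobile_fraction=0.59, t_half_s=64.16,
                                          n_post=2000, dt_s=0.2,
                                          noise_sd=0.02, seed=1))
fit = fit_recovery(normalize_trace(trace))
print(f"t_half = {fit.t_half_s:.2f} s, mobile fraction = "
      f"{fit.mobile_fraction:.3f}, R^2 = {fit.r_squared:.3f}")
```

prints

```
CN = 11, CS = 1.148 um^2
r_p = 0.955 (positive)
t_half = 65.12 s, mobile fraction = 0.565, R^2 = 0.968
```

The scene carried 11 chromocenters of ~1.1 µm² and a GFP channel tracking
the DAPI foci, so the construct classifies as positively co-localized; the
FRAP trace was generated with a 64.16 s half-time and 0.59 mobile fraction,
and the normalize-and-fit step recovers both within the noise.

The same stages run from the shell:

```sh
chromodyn simulate image --seed 2 --out scene/
chromodyn segment --in scene/scene.tif --out seg/
chromodyn run                 # full synthetic panel + severity correlation
```

`chromodyn run` executes simulate → segment → coloc → morpho → frap →
severity on a configurable construct panel and writes per-stage CSVs plus a
reproducibility manifest (seed, config hash, package version).

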