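# bonechron

Does young sedimentary ancient DNA (eDNA) of an extinct species mean the
species was still alive, or only that its remains were still decaying on the
landscape?  `bonechron` implements the inference chain needed to ask that
question quantitatively, motivated by the debate over Middle-Holocene mammoth
eDNA in Arctic sediments:

1. **Taphonomic persistence regression** — how long exposed bone survives on a
   landscape falls log-linearly with local mean annual temperature (MAT):
   `log10(persistence, yr) = a + b·MAT`, fitted by OLS separately for bones
   that were confidently never buried and for the broader set whose
   post-mortem history is ambiguous (possible exhumation).  Predictions
   back-transform to years with a 95% confidence (or prediction) bound.
2. **Extinction-date estimation (GRIWM)** — from a dated occurrence series
   sorted oldest to youngest, each older sighting *i* implies a sighting rate
   λᵢ = kᵢ/(tᵢ − t_last); the extinction offset beyond the last sighting is
   ln(α)/ln(1 − λᵢ) (α = 0.05 by default), and the single-reference estimates
   are combined with inverse-distance weights 1/(tᵢ − t_last).  Dating errors
   (2σ) are propagated by Gaussian Monte-Carlo resampling; the 2.5th/97.5th
   percentiles of the resampled estimates form the reported interval, which
   may extend past the present day (negative yr BP).
3. **Temporal-mixing window test** — for each region, the window from the
   median fossil-based extinction estimate down to that median minus the
   predicted bone persistence is where eDNA from dead tissue is *expected*.
   Every eDNA age is classified against three nested windows (mean
   persistence, upper 95% bound for never-buried bones, upper 95% bound for
   potentially-never-buried bones); ages younger than all three are flagged
   `outside`.

A synthetic-data generator produces bone tables and fossil/eDNA series with
known ground truth (true regression coefficients, true extinction date, true
persistence duration), so every stage has a parameter-recovery and coverage
test surface without downloading anything.

## Worked example

```python
import bonechron as bc

bones = bc.gen_bone_table(bc.BoneGenConfig(n=40, seed=1))
model = bc.fit_persistence(bones, bc.BurialClass.NEVER_BURIED)
print(f"slope {model.slope:.4f} log10-yr/degC, intercept {model.intercept:.3f}, "
      f"R^2 {model.r_squared:.3f}, p {model.p_value:.2e}, n {model.n}")

pred = bc.predict_persistence(model, mat=-13.3)
print(f"persistence at -13.3 C: mean {pred.mean_persistence/1000:.2f} kyr, "
      f"upper 95% {pred.upper_ci/1000:.2f} kyr")

series = bc.gen_occurrence_series(bc.SeriesGenConfig(seed=2), region="siberia_nw")
fossils = [r for r in series if r.source is bc.Source.FOSSIL]
est = bc.estimate_extinction(fossils, bc.EstimatorConfig(seed=3))
print(f"fossil extinction estimate: median {est.median/1000:.2f} kyr BP, "
      f"95% CI [{est.ci_lower/1000:.2f}, {est.ci_upper/1000:.2f}] kyr BP "
      f"(truth 11.00)")
```

prints

```
slope -0.0614 log10-yr/degC, intercept 2.576, R^2 0.978, p 3.18e-17, n 21
persistence at -13.3 C: mean 2.47 kyr, upper 95% 3.02 kyr
fossil extinction estimate: median 10.93 kyr BP, 95% CI [11.19, 10.67] kyr BP (truth 11.00)
```

The fitted slope (−0.0614) recovers the generating value (−0.06) within its
standard error; at −13.3 °C the model expects bones to persist roughly 2.5
kyr, so eDNA that much younger than the last fossil needs no surviving
population.  The extinction estimate's interval brackets the true simulated
extinction (11 kyr BP); its median sits slightly young of the last true
sighting, as the offset construction intends.

The same operations are available from a shell:

```sh
bonechron simulate bones --seed 1 --out bones.csv
bonechron fit-persistence bones.csv --class never --out model.json
bonechron predict --model model.json --mat -13.3
bonechron estimate-extinction occ.csv --region siberia_nw --source fossil --seed 1 --out est.json
bonechron mixing-report --bones bones.csv --occ occ.csv --sites sites.csv --out report.json
```

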