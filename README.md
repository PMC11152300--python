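# magbird

Circular statistics for migratory-bird headings and the geomagnetic field.

Migratory birds appear to use the Earth's magnetic field as a navigational
cue. A natural statistical question follows: do the *direction changes*
along a bird's migration track co-vary with the local geomagnetic
declination and inclination (or their changes along the route)? Answering
it properly requires directional statistics — headings and field angles
live on the circle, where ordinary correlation and regression are invalid.

`magbird` is a tested, reusable implementation of that analysis for
movement ecologists and biostatisticians working with Movebank-style
tracking tables:

* **geodesy** — great-circle central angles (haversine form), initial
  bearings, and per-segment direction-change series from timed
  (lat, lon) fixes;
* **geomag** — evaluation of the main geomagnetic field from Gauss
  coefficients (WMM.COF-style files): Schmidt semi-normalized spherical
  harmonics, secular variation, field components X/Y/Z, declination
  D = atan2(Y, X) and inclination I = atan2(Z, √(X²+Y²));
* **circular_stats** — the von Mises distribution
  f(θ; μ, κ) = e^{κ cos(θ−μ)} / (2π I₀(κ)) with cdf, sampler and MLE;
  Watson's U² goodness-of-fit statistic with Monte-Carlo / parametric
  bootstrap critical values; the circular correlation coefficient
  r = Σ sin(θᵢ−θ̄) sin(Mᵢ−M̄) / √(Σ sin²(θᵢ−θ̄) Σ sin²(Mᵢ−M̄))
  with its asymptotic normal test of H₀: ρ_c = 0;
* **circular_regression** — circular-circular regression via
  trigonometric-polynomial conditional expectations of
  (cos β, sin β) given the covariate angle, with von Mises error
  interpretation and a BIC-like degree selector;
* **synthetic_data** — ground-truth simulators: dipole/randomized
  coefficient sets and spherical random-walk tracks whose headings are
  von Mises distributed and, optionally, coupled to the local field
  angles with a known strength;
* **pipeline** / CLI — the end-to-end per-species workflow with
  deterministic seeding and JSON/CSV reporting.

## Worked example

Simulate a track whose headings are steered by the local magnetic
inclination (coupling 0.6), then run the full analysis:

```bash
magbird simulate --kind randomized --coupling 0.6 --covariate inclination \
    --covariate-mode point --n-points 300 --kappa 6 --seed 3 --out-dir demo
magbird analyze demo/tracks.csv demo/coefficients.cof \
    --seed 42 --covariate-mode point --out demo/results.json
magbird report demo/results.json
```

which prints

```
synthetic: n=299 U2=0.0219 (crit 0.1024) | inc r=+0.324 p=0.000 | dec r=+0.289 p=0.000
```

Reading: the direction series has 299 segments; Watson's U² (0.0219)
stays below its parametric-bootstrap 5% critical value (0.1024), so the
von Mises model for the headings is not rejected. The circular
correlation between headings and the inclination covariate is clearly
positive (r = +0.32, p < 0.001), recovering the planted coupling;
declination co-varies with inclination along this track and correlates
too. With `--coupling 0` both p-values are non-significant at close to
the nominal 95% rate.

The same machinery is available as a library; see the module docstrings
and `docs/methods.md` for the model details.

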