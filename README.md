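# tunaforage

Visual foraging and bioenergetics of Atlantic bluefin tuna (*Thunnus
thynnus*) larvae in warm oligotrophic spawning grounds.

Bluefin tuna spawn in some of the warmest, most food-poor waters in the
ocean — in the western Mediterranean, larvae grow in a mixed layer holding
only a few hundred copepod nauplii per cubic metre. `tunaforage` asks
whether that prey field can actually sustain the larvae's exceptionally
high growth potential. It couples a visual prey-encounter model to an
energy budget, derives the **critical prey density** — the concentration of
a single prey type at which a larva exactly meets a growth target — for
each developmental stage, temperature and prey type, and scores
zooplankton-survey stations for food limitation under different diet
scenarios. A synthetic survey generator reproduces the statistical
structure of the field data so the whole pipeline runs without any
download.

Intended users: larval-fish ecologists and ichthyoplankton-survey analysts
who want stage- and temperature-resolved food-limitation thresholds from
standard station tables.

## Model

For a larva of standard length *L* (mm) and dry weight
*W* = 0.0008·e^(0.9052·L) mg, the hourly daylight budget is

```
SGR·W = α·Σ_prey i_prey − R(W, T)
i_prey = P_prey · β_prey · N_prey · W_prey          (linear functional response)
β_prey = ½ π R_det² V_L                              (half-field visual search, m³ h⁻¹)
R(W,T) = 0.404·W^0.994 · 32 · 0.88 · (12/34) · (100/45000) · 2^((T−26)/10)
```

with assimilation efficiency α = 0.77, swimming speed V_L = 3 body lengths
s⁻¹, capture probability P = 1 for nauplii and an ontogenetic 0→1 ramp for
larger, evasive prey. Larvae feed only during the 15 daylight hours, and
the daily rate is capped at the ad-libitum ceiling SGR_T = 0.0418·T − 0.8355
day⁻¹ measured in rearing experiments. Detection distance is proportional
to prey length × larval length, R_det = c·l_prey·L; the single optical
constant *c* is calibrated from one anchor threshold (stage F0, nauplii
only, 22 °C, 4000 m⁻³), after which every other prediction is
out-of-sample. Because ingestion is linear in density, the critical density
has the closed form `N* = i_req / (P·β·W_prey)`.

The food-limitation index **FLI** = realized SGR / ad-libitum SGR flags a
station-stage-diet combination as limited when FLI < 1 and as starving when
the realized SGR is negative.

## Worked example

```python
import tunaforage as tf

params = tf.calibrate_detection(tf.ModelParams())   # c = 7.3367
F0 = tf.default_stages()[0]                          # pre-flexion, 4.8 mm

# survey-average prey field at the mean mixed-layer temperature
diet = [(tf.NAUPLIUS, 506.0), (tf.CLADOCERAN, 653.0), (tf.COPEPOD, 258.0)]
b = tf.growth_budget(F0, diet, temp=24.4, params=params)
print(b.daily_sgr, b.fli)        # 0.1844 /d, FLI = 1.000  -> unlimited

b_naup = tf.growth_budget(F0, [(tf.NAUPLIUS, 506.0)], 24.4, params)
print(b_naup.daily_sgr)          # -0.0981 /d  -> starving on nauplii alone
```

On the average prey field the full diet supports the ad-libitum ceiling
(0.1844 day⁻¹ at 24.4 °C, FLI = 1), while nauplii alone do not even cover
metabolism (−0.098 day⁻¹): the occasional larger cladoceran or copepod is
what breaks food limitation. The nauplii-only thresholds for full growth at
22 °C rise from ≈4000 m⁻³ (F0) to ≈12000 m⁻³ (F3):

```python
table = tf.critical_density_table(params=params.with_(assume_full_capture=True))
```

The same analyses are available from a shell:

```bash
tunaforage calibrate
tunaforage critical-densities --temps 22,25,28 --out critical_densities.csv
tunaforage gen-synthetic --year 2020 --n 17 --seed 42 --out stations.csv
tunaforage assess-stations --input stations.csv --out station_assessment.csv
tunaforage curves --stage F0 --prey nauplius --png curves.png
```

Every run writes a JSON manifest (config hash, seed, calibrated constant)
next to its outputs.

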