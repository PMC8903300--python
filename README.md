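# soilscape

Passive acoustic monitoring of soil biodiversity: compute the acoustic
complexity of soil soundscapes recorded by buried contact microphones,
model its diurnal, seasonal and microclimatic drivers, and relate it to
the diversity and composition of the soil fauna.

Soil mesofauna and macrofauna — mites, springtails, fly larvae, ants,
earthworms and their predators — produce movement, feeding and
stridulation sounds in the litter and uppermost soil layers, mostly
between 100 Hz and 10 kHz.  A richer community produces a more complex
soundscape, so an acoustic complexity index measured continuously and
non-invasively can stand in for destructive soil coring.  This package
implements that analysis chain end to end, with seeded synthetic
generators for every data stream (audio, microclimate, community counts)
so the whole pipeline is testable without field data.

## The index and the model

**Adapted Acoustic Complexity Index.**  From a magnitude spectrogram
(512-sample rectangular windows, no overlap, DC dropped; a ~20.68-s clip
at 50 kHz gives a 256-band x 2020-block matrix), per frequency band *k*
and 1-s clump:

```
d_k = |I_k − I_{k+1}|        D = Σ d_k        ACI = D / Σ I_k
```

averaged (not summed) over all band x clump cells, which bounds the value.
Stationary Gaussian noise gives `2 − √2 ≈ 0.586`; only values in
[0.55, 0.90] are treated as biophony (below: amplifier noise floor;
above: rain or irrigation hitting the sensor).

**Hierarchical gamma autoregressive model.**  With `y = ACI − 0.55`,

```
η_it = α_i + X_it β + Σ_{l=1}^{L} φ_l · ln y_{i,t−l}
y_it ~ Gamma(k, e^{η_it})          α_i ~ N(μ_α, σ_α²),  β_j ~ N(0, σ_β²)
```

fit by ensemble MCMC (4 chains x 1000 post-warm-up draws by default,
R-hat for every parameter), with daytime x season or microclimate designs
(soil moisture + quadratic, soil and surface temperature, positive 30-min
surface heating, covariates at lag −1) and scenario predictions reported
as kernel-density MAP points with 95 % highest-density intervals.

**Community analyses.**  Hill numbers `⁰D, ¹D, ²D` (richness,
exp-Shannon, inverse Simpson), Bray–Curtis distances, non-metric
multidimensional scaling (Kruskal stress-1), sensor-stratified PERMANOVA,
and linear mixed models linking ACI at three temporal resolutions around
each soil-sampling event to standardized community attributes.

## Worked example

```python
import pandas as pd
from soilscape import (SoundscapeConfig, generate_recording,
                       aci_of_recording, filter_aci)

cfg = SoundscapeConfig(seed=42)            # 50 kHz, ~20.68 s clips
rows = []
for minutes, richness in [(0, 2), (10, 5), (20, 8)]:
    t = pd.Timestamp("2019-06-20 12:00") + pd.Timedelta(minutes=minutes)
    rec = generate_recording(t, cfg, None, richness=richness, sensor_id="B1")
    rows.append({"sensor_id": "B1", "time": t,
                 "aci": aci_of_recording(rec).value, "richness": richness})
print(filter_aci(pd.DataFrame(rows)).to_string(index=False))
```

```
sensor_id                time      aci  richness  valid
       B1 2019-06-20 12:00:00 0.602509         2   True
       B1 2019-06-20 12:10:00 0.654617         5   True
       B1 2019-06-20 12:20:00 0.680209         8   True
```

Three synthetic noon clips with 2, 5 and 8 acoustically active taxa: the
averaged ACI climbs from 0.603 to 0.680 — above the 0.586 noise floor,
inside the [0.55, 0.90] validity band (`valid=True`), and increasing with
the planted richness.  Diversity of the dominance profile reported for
the sampled cores (63 % mites, 28 % flies, 7 % springtails plus two
singletons, as counts `63, 28, 7, 1, 1`):

```python
from soilscape import hill_number
[round(hill_number([63, 28, 7, 1, 1], q), 3) for q in (0, 1, 2)]
# [5.0, 2.524, 2.082]
```

Richness 5, but only ~2.5 equally-abundant-equivalent taxa once abundance
is weighted — the community is strongly dominance-structured.

## Command-line pipeline

```sh
soilscape all --config run.yaml --seed 3      # simulate → aci → fits → diversity → link
soilscape simulate --config run.yaml          # individual stages; rerun is a no-op
soilscape validate --config run.yaml          # config schema + cross-field checks
```

Stages exchange plain CSV/WAV/JSON artifacts in the run directory and
record manifests (config hash + seed), so every output is reproducible
from config + seed and reruns skip up-to-date stages unless `--force`.

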