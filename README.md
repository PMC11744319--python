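# stomaspec

Modelling and simulation toolkit for stomatopod (mantis shrimp) colour
vision. Stomatopods sample the spectrum with up to 12 photoreceptor classes
stacked in four midband ommatidial rows, and two competing ideas describe how
that information is read out:

* **multi-dichromatic opponency** — each row *n* acts as an independent
  two-receptor colour channel comparing its distal and proximal tiers;
* **binning ("barcode") coding** — colour is the activation pattern across
  all channels, dominated by the strongest one, with no fine within-row
  comparison.

The decisive behavioural assay is a von Frisch grey-card experiment under
coloured illumination: flat greys of different brightness are exact metamers
of one another in both readouts, so discriminating a colour from all greys
under a restricted spectrum requires within-row opponency. `stomaspec`
implements the full computational chain of that argument: spectral fixtures,
quantum catches, both readouts, a simulator of the three-choice experiment,
and the statistics used to analyse it.

## The model

For a receptor with spectral sensitivity *S*(λ) viewing a stimulus with
reflectance *R*(λ) under an illuminant photon distribution *I*(λ), the
quantum catch is

    Q = ∫ S(λ) R(λ) I(λ) dλ      (trapezoid rule, 300–750 nm, 1 nm)

Each midband row *n* (1–4) pairs a distal and a proximal tier; its opponent
**activity profile** for stimulus X is the log-ratio

    Aₙ(X) = ln Q_distal − ln Q_proximal

and the **contrast difference** between stimuli X and Y under one illuminant
is

    CDₙ = Aₙ(X) − Aₙ(Y)

|CD| > 0.5 is flagged as high contrast. Rows whose normalized catches fall
below an activation threshold (default 0.05 of the reference catch, R2P
viewing the brightest grey under natural light) are treated as silenced:
numerically defined but carrying no usable signal. The binning readout is
the unit-max-rescaled catch vector compared by Chebyshev distance. Both
readouts are invariant to rescaling the illuminant — intensity alone carries
no chromatic signal, which is the logic of the grey-card design.

The behavioural simulator links contrast to choice through a Luce/softmax
chooser: each presented stimulus is scored by the negative of its largest
per-row deviation from the learned target signature, and choices follow
softmax(β·score) mixed with lapse and no-choice rates. The analysis stage
provides the protocol's stage-progression rules, Pearson chi-square
goodness-of-fit against the 1/3 chance level, and a binomial logit mixed
model (random intercept per individual) fitted by Gauss–Hermite maximum
likelihood.

## Worked example

```python
from stomaspec import default_retina, spectral_library, contrast_between

retina = default_retina()
lib = spectral_library()
ill, refl = lib["illuminants"], lib["reflectances"]

for illum in ("natural", "green-tent"):
    ct = contrast_between(retina, refl["green"], refl["grey0.15"], ill[illum],
                          stimulus_x="green", stimulus_y="grey0.15",
                          illuminant_id=illum)
    print(f"green vs grey (OD 0.15) under {illum}:")
    for row in sorted(ct.cd):
        tag = "active" if row in ct.active_rows else "silenced"
        print(f"  row {row}: CD = {ct.cd[row]:+.3f}  ({tag})")
```

prints

```
green vs grey (OD 0.15) under natural:
  row 1: CD = -2.755  (silenced)
  row 2: CD = -1.368  (active)
  row 3: CD = +1.873  (silenced)
  row 4: CD = +0.242  (active)
green vs grey (OD 0.15) under green-tent:
  row 1: CD = -1.804  (silenced)
  row 2: CD = -0.965  (active)
  row 3: CD = +0.502  (silenced)
  row 4: CD = +0.108  (active)
```

Row 2 keeps a high contrast (|CD| ≈ 0.97 > 0.5) between the green target and
any grey even inside the green tent, so an opponent observer can still find
the target there; rows whose receptors catch almost no photons under the
restricted spectrum are marked silenced and excluded from the judgement. The
same computation for the blue target under the blue tent leaves no activated
row above 0.5 — the model's explanation for why discrimination collapses
under blue illumination while surviving under green and red.

A full simulated study (fixtures → contrasts → trials → statistics) runs
from one config:

```
stomaspec run-all --seed 42 --out run/
```

or in Python via `stomaspec.pipeline.run_all(RunConfig(...))`; outputs are
tidy CSV/JSON tables plus a manifest with the config hash and seed, and are
byte-identical for identical config + seed.

## Layout

| module | contents |
| --- | --- |
| `stomaspec.spectral` | wavelength grids, spectra, filter algebra, CSV I/O |
| `stomaspec.retina` | pigment templates, the 12-channel midband retina |
| `stomaspec.visual` | quantum catches, activity profiles, contrast differences, binning |
| `stomaspec.fixtures` | synthetic daylight, tent/stimulus/ND filters, reflectances |
| `stomaspec.experiment` | trial scheduling, the softmax chooser, the 3-stage simulator |
| `stomaspec.stats` | success rates, inclusion rules, chi-square, the mixed logit model |
| `stomaspec.pipeline` / `stomaspec.cli` | config, validation, end-to-end runs, `stomaspec` CLI |

The default retina's λmax table is an explicitly documented placeholder (the
species' measured sensitivity curves are not published in tabular form);
supply your own `lambda_max_nm` values or digitized `sensitivity_file`
curves via a retina config for fidelity — see
`src/stomaspec/data/default_retina.yaml` and `docs/methods.md`.
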