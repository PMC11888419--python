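# ehtmech

Regional strain, stiffness and fluorescence analysis of cryowounded
engineered heart tissues (EHTs).

## The problem

Engineered heart tissues — rectangular hydrogel constructs of
cardiomyocytes and cardiac fibroblasts cultured under pacing — can be
given a controlled, localized freezing injury (a cryowound) at their
midline to model myocardial infarction *in vitro*. The question is how
the injury changes the tissue regionally: does the wound stop
contracting and get stretched by the surviving muscle, does it stiffen
like scar, and how do the fibroblast and cardiomyocyte populations
redistribute across the wound, border and remote zones?

`ehtmech` implements the quantitative side of that experiment as a
tested, reusable pipeline:

- **DIC** — subset-based 2D digital image correlation between grayscale
  video frames, yielding displacement fields and Green–Lagrange strains
  (axial component `Exx = ∂u/∂x + ½[(∂u/∂x)² + (∂v/∂x)²]`).
- **Systolic strain** — automatic diastole/systole frame selection and
  the median `Exx` profile over the central 0.5 mm transverse band,
  restricted to the central 90% of the long axis.
- **Geometry** — widths measured at the middle and ends of the
  unstretched gel, linearly interpolated between them; compaction
  factor = width / 4 mm cast width; thickness = compaction × 3.25 mm
  well height; cross-sectional area A(x) = width × thickness.
- **Ramp stiffness** — a stepped electromagnet ramp (0.0–0.8 A in 0.1 A
  increments, 5 s holds) is converted to force through a configurable
  calibration, to stress σ(x) = F / A(x), and paired with the median
  subregion strain at every step. Each subregion's (ε, σ) series is
  averaged within seven uniform-width strain bins and fit by ordinary
  least squares; the slope is the modulus E (kPa). Subregions are
  0.3 mm long with 0.2 mm gaps over the central 2.3 mm: the central one
  is the wound zone, its flanks the border, the outermost the remote.
- **Fluorescence intensity** — long-axis traces of DAPI / FSP-1 / cTn-1
  channels, normalized to a 10-pixel band at the tissue's outer edge,
  integrated (AUC) per zone and expressed as fold-change
  (AUC − AUC_prewound) / AUC_prewound.
- **Statistics** — repeated-measures ANOVA across the three zones,
  post-hoc paired t-tests, and one-sample t-tests against a
  hypothetical mean of zero, at p < 0.05.
- **Synthetic data** — a fully seeded generator producing speckle
  images, beat and ramp sequences, and fluorescence maps with known
  per-zone ground truth, so every stage is validated by parameter
  recovery without any external data.

## Worked example

Recover known zone moduli ({wound 30, border 20, remote 10} kPa) from a
synthetic nine-step force ramp, then measure systolic strains of a
wounded cohort:

```python
from ehtmech.pipeline import ramp_recovery_study, systolic_replicates

stiff = ramp_recovery_study(seed=0)
for zone, E in stiff.zone_moduli.items():
    print(f"{zone:>7s} modulus: {E:5.1f} kPa")

beats = systolic_replicates(n=3, base_seed=0, wounded=True)
print(beats.round(4))
```

```
  wound modulus:  29.8 kPa
 border modulus:  19.5 kPa
 remote modulus:   9.7 kPa
         wound  border  remote
sample                        
0       0.0437  0.0059 -0.0299
1       0.0378  0.0051 -0.0268
2       0.0424  0.0065 -0.0283
```

The moduli come back within a few percent of the generator's ground
truth, and the wounded tissues show the characteristic sign pattern:
positive (tensile) strain in the wound — the dead region is stretched
by each beat — and negative (contractile) strain in the remote zone.

The same analyses are available from the shell:

```bash
ehtmech simulate --kind ramp --out data/ --seed 0
ehtmech stiffness --frames data/ramp.tif --protocol data/protocol.csv --out results/
ehtmech validate --out results/
```

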