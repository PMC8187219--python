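# toricratio

How much cylinder must a toric intraocular lens (tIOL) carry to fully
correct a given corneal astigmatism? Many calculation services sidestep a
proper optical calculation and multiply the corneal astigmatism by a fixed
"translation factor" (typically ≈ 1.4). This package quantifies how wrong
that shortcut can be: it implements a paraxial vergence model of the
pseudophakic eye, back-solves the effective lens position (ELP) of the
capsular-bag lens from each eye's postoperative refraction — independent of
any established IOL power formula — computes the tIOL that fully corrects
the cornea meridian by meridian, and analyzes the resulting
**translation ratio**

> ρ = torus of the fully correcting tIOL / corneal astigmatism

over a Monte-Carlo cohort of synthetic eyes. It is written for researchers
in ophthalmic optics and for anyone evaluating toric-IOL calculation
schemes.

## Model

Per principal meridian, a vergence `V` (in dioptres) crosses an axial gap
`d` in a medium of index `n` as `V' = V / (1 − (d/n) V)` and gains the
power of each thin lens it meets. The eye is: spectacle plane → 12 mm air
gap → thin cornea (power `K = (n_k − 1)/r` from the keratometer index
`n_k = 1.332`) → ELP of aqueous (n = 1.336) → thin tIOL → vitreous path of
`AL − ELP` to the retina. Chaining the lane's object vergence (−1/6 D for a
6 m lane) through this system:

* **forward**: predict the postoperative spherical equivalent for a given
  IOL power and lens position;
* **inverse**: find the unique ELP at which the forward model reproduces
  the measured refraction (the forward SE is strictly monotone in ELP, so a
  bracketed root solve on [0.5, 8] mm is exact);
* **per meridian**: the emmetropizing IOL powers `P(K_flat)` and
  `P(K_steep)` at that common ELP give the torus
  `T = P(K_flat) − P(K_steep)` and the ratio `ρ = T / (K_steep − K_flat)`.

Because no raw clinical cohort is distributable, a seeded generator
produces synthetic eyes (axial length, corneal radii, right-skewed
astigmatism, an ELP that rises linearly with axial length), simulates
surgery with a 0.5 D IOL power grid, and observes the refraction through
0.25 D measurement noise and 0.25 D chart quantization.

## Worked example

```python
from toricratio import ToricTranslationModel, PopulationParams

model = ToricTranslationModel.from_synthetic(PopulationParams(n=16744, seed=1))
results = model.fit()
print(results.summary())
```

```
Toric translation-ratio analysis
================================
cases: 16744 in, 16735 valid, 9 excluded {'elp_out_of_range': 9}
translation ratio: mean 1.3960 +/- 0.0651  median 1.3911  range [1.1828, 1.8718]
fixed factor 1.4: undercorrection up to 25.2 %, overcorrection up to 18.4 %

model                         intercept              slope(s)   adjR2    |R|  class
-----------------------------------------------------------------------------------
ratio_on_k_eq                    0.8882               +0.0118   0.068  0.261  small
ratio_on_astigmatism             1.3975               -0.0012   0.000  0.011  negligible
ratio_on_elp                     0.8857               +0.1074   0.924  0.961  large
ratio_on_axial_length            1.0101               +0.0163   0.201  0.448  moderate
elp_on_axial_length              1.1645               +0.1517   0.217  0.466  moderate
p_eq_on_axial_length           101.9538               -3.4483   0.877  0.937  large
p_eq_on_elp                     37.3494               -3.5730   0.100  0.316  moderate
p_eq_on_k_eq                    79.5267               -1.3707   0.090  0.300  small
p_eq_on_elp_axial_length        99.9337      +1.7347, -3.7113   0.896  0.946  large
```

Reading this: the translation ratio is anything but constant — it spans
roughly 1.2 to 1.9 here with mean ≈ 1.40. Its dominant driver is the lens
position (ρ ≈ 0.886 + 0.107·ELP, adj R² ≈ 0.92): the more posterior the
lens, the more torus each dioptre of corneal astigmatism needs. Axial
length acts only indirectly, through its correlation with ELP, and the
corneal astigmatism itself has no effect on the ratio. The equivalent
power of the emmetropizing lens falls by ≈ 3.7 D per mm of axial length
and rises by ≈ 1.7 D per mm of posterior lens shift (multiple regression),
which is why misjudging the lens position matters clinically. Applying a
fixed factor of 1.4 across a ratio range of 1.2–1.6 undercorrects the
refractive cylinder by up to 12.5 % or overcorrects it by up to ~17 %
(`toricratio.misestimation_bounds(1.4, 1.2, 1.6)`).

The same pipeline is scriptable from a shell:

```sh
toric-ratio full --n 16744 --seed 1 -o out/   # cohort.csv, cases.csv, report.json
toric-ratio generate --n 1000 --seed 7 -o cohort.csv
toric-ratio analyze -i cohort.csv -o report.json
```

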