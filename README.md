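# ulfmt — on-resonance MT imaging simulation at ultra-low field

`ulfmt` is a desk-scale simulator and analysis toolkit for **on-resonance
magnetization-transfer (MT) imaging with non-balanced steady-state free
precession (SSFP) at ultra-low field (64 mT)**. It is aimed at MR physicists
designing or validating MT protocols on point-of-care scanners, where the
MT weighting is generated not by an off-resonance prepulse but by the RF
energy of the imaging pulse itself.

## The method

Tissue is modelled as two proton pools: a *free* water pool (T1f, T2f) and a
*bound* macromolecular pool (fraction *f*, T1b, T2b ~ microseconds) coupled
by magnetization exchange (fundamental rate *k*; forward rate *k·f*, reverse
*k·(1−f)*). A hard RF pulse of flip angle α and width τ has mean amplitude
ω₁ = α/τ and saturates the bound pool at rate

    W = π ω₁² G(0),       per-pulse attenuation exp(−W τ),

where G(0) is the bound-pool absorption lineshape on resonance (Gaussian by
default, G(0) = T2b/√(2π); a cutoff-evaluated super-Lorentzian is
available). Raising α (or shortening τ) deposits more RF energy and
saturates the bound pool harder, which drains free-pool signal through
exchange — the MT contrast.

The steady-state signal is computed with an extended phase graph (EPG)
engine with exchange: configuration states F±k, Zk for the free pool plus
the bound-pool longitudinal orders, ideal gradient spoiling (one
configuration shift per TR), and exact matrix-exponential longitudinal
propagation. Both non-balanced SSFP observables are returned:

* **FISP / SSFP-FID** — |F₀| just after the pulse,
* **PSIF / SSFP-Echo** — the F₋₁ pathway just before the next pulse.

A brute-force **isochromat oracle** (time-stepped Bloch–McConnell over N
spins spanning 2π of spoiler dephasing) validates the EPG engine to better
than 1e-3 relative on a grid of tissues and flip angles.

Two images with equal non-MT weighting but different RF energy (flip angles
α_low/α_high mirror-symmetric about the PSIF symmetry point at 180°) give
the MT ratio

    MTR = (MT_low − MT_high) / MT_low × 100 %.

For a single-pool material the PSIF response is symmetric about 180°, so
MTR ≡ 0 regardless of T1/T2 — any nonzero MTR isolates the bound pool.

The package also ships digital phantoms (a six-vial water / dairy-cream /
hair-conditioner MT phantom and a T1/T2 relaxometry array), multi-coil
noisy acquisition simulation, root-sum-of-squares combination, optional
non-local-means denoising, and the reproducibility statistics used to
assess the protocol: ROI means, histograms, Bland–Altman agreement and the
bias-corrected two-scan coefficient of variation
CoV = SD/mean × 1.125 × 100 % (1.125 = 1 + 1/(4n) at n = 2 scans).

## Worked example

```python
from ulfmt import load_presets, predict_mtr, scan_rescan_cov

presets = load_presets()          # literature-informed 64 mT presets
protocol = presets.protocol       # TR 12.03 ms, tau 220 us, PSIF

wm = presets.tissues["wm_like"]
print(predict_mtr((60.0, 300.0), protocol, wm))   # 19.48  (% MTR)

print(scan_rescan_cov(23.0, 23.2))                # 0.689  (% CoV)
```

Simulating the six-vial phantom noise-free at the (60°, 300°) pair and
taking ROI means over each vial prints:

```
water_1        0.00
water_2        0.00
cream_1       13.37
cream_2       13.37
conditioner_1 31.32
conditioner_2 31.32
```

i.e. MTR ordering conditioner > cream > water ≈ 0, following the bound-pool
fractions of the materials, while the water vials show that T1/T2 contrast
alone produces no MT signal.

The same chain is scriptable from the shell:

```bash
ulfmt phantom --out ph --kind vials
ulfmt sweep --phantom-dir ph --out sw --seed 1 --angles 60,300 --noise-sigma 0.002
ulfmt mtr --low low.nii.gz --high high.nii.gz --out mtr.nii.gz --labels ph/labels.nii.gz
ulfmt cov --scan roi1.csv --rescan roi2.csv --out cov.csv
ulfmt bland-altman --pairs pairs.csv --out ba.json --plot ba.png
```

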