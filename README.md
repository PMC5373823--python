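# phasecorr

Pair-correlation analysis for two-color single-molecule localization
microscopy (SMLM) of membrane proteins, and a conserved-order-parameter Ising
simulator of how clustering a receptor stabilizes an ordered lipid domain
that sorts kinases in, phosphatases out, and drives receptor phosphorylation.

## Who this is for

Labs doing STORM/PALM imaging of membrane components (e.g. a clustered B-cell
receptor against minimal lipid-anchor peptides) face two artifacts that break
naive co-localization analysis: a single photoswitchable fluorophore is
detected 10–50 times ("overcounting", which makes monomers look like
clusters in single-channel data), and probes are sampled sparsely
(2–20 µm⁻²), so real co-enrichment of a few tens of percent is invisible by
eye. The statistics implemented here quantify weak co-distribution robustly:

- **Cross-correlation** `C(r)`: fold enrichment of channel-B localizations at
  distance `r` from channel-A localizations relative to a random
  co-distribution. `C > 1` co-clustering, `C < 1` exclusion, `C = 1` random.
  Computed equivalently by an explicit pair histogram (`crosscorr_direct`)
  or by FFTs on reconstructed 25 nm images (`crosscorr_fft`); both normalize
  expected pair counts with the ROI-mask autocorrelation, so arbitrary mask
  shapes (including holes over detached membrane) do not bias `C(r)`.
  Cross-correlation is immune to overcounting.
- **Surface density** from the single-channel autocorrelation
  `G(r) = 1 + A exp(−r²/2σ²)`: the area under the overcounting peak is
  inversely proportional to the density of independent emitters,
  `ρ = 1/(2π σ² A)` (grouped localizations, fit window 50–500 nm).
- **Variance model** for single-cell error bars: the angular-average SEM of
  the 2D correlogram `dC(r,⟨θ⟩)` is corrected for the finite localization
  precision (σ_PSF = 30 nm), `dC1 = (1 + 2σ_PSF/Δr)(1 + e^{−r²/4σ_PSF²}) dC_raw`,
  and for finite sampling of the super-resolved PSF (`dC2`).
- **Potential of mean force** `PMF(r) = −ln C(r)` (k_BT), the effective
  interaction free energy between the labeled species.
- **Live-cell steady-state correlation**: frame-pair correlations averaged
  over time delays up to 50 frames, divided by the correlation of the 1 µm
  Gaussian-blurred average images to remove cell-scale labeling gradients;
  plus a conservative single-particle tracker (500 nm linking radius,
  ambiguous links terminated) and reference-proximal step-size analysis
  (100 nm) to detect binding-induced slowing.
- **Membrane model**: a 256×256 (2 nm/pixel) Ising lattice at T = 1.05 T_C
  with Kawasaki (exchange) dynamics; receptors and kinases are ordered (+1)
  components, phosphatases disordered (−1). A receptor-only circular trap
  clusters receptors; reactions fire on accepted moves (kinase contact
  phosphorylates at 0.1%, phosphatase contact dephosphorylates at 100%,
  phosphorylated receptors optionally act as receptor-bound kinases).

## Worked example

```python
import numpy as np
from phasecorr.loc_data import RoiMask, reconstruct_image, group_sequential
from phasecorr.pair_correlation import (
    crosscorr_fft, variance_dc1, variance_dc2, density_from_autocorr, pmf_from_corr)
from phasecorr.synthetic_data import (
    SceneSpec, BlinkModel, generate_scene, sample_localizations)

# two co-clustered species: 20 shared discs (50 nm) in a 5x5 um field,
# each molecule observed ~15 times with 15 nm localization noise
scene = generate_scene(SceneSpec(mode="co_clustered", fov_nm=(5000, 5000),
                                 n_discs=20, disc_radius_nm=50,
                                 molecules_per_disc=10, seed=11))
locs = sample_localizations(scene, BlinkModel(mean_observations=15,
                                              localization_sigma=15), seed=42)
mask = RoiMask.rectangle(5000, 5000)
a, b = locs.select_channel("a"), locs.select_channel("b")
res = crosscorr_fft(reconstruct_image(a, mask), reconstruct_image(b, mask),
                    mask, r_max=500)
variance_dc1(res)
na = density_from_autocorr(group_sequential(a), mask)
nb = density_from_autocorr(group_sequential(b), mask)
variance_dc2(res, na.n_emitters, nb.n_emitters)
print(f"C(r<25nm) = {res.c[0]:.1f}")
print(f"rho_a = {na.rho_um2:.1f} /um^2 "
      f"(~{na.diagnostics['observations_per_emitter']:.0f} obs/emitter)")
pmf = pmf_from_corr(res)
print(f"PMF at r=37.5 nm: {pmf.pmf_kt[1]:.2f} kT")
```

Output:

```
C(r<25nm) = 99.6
rho_a = 0.8 /um^2 (~140 obs/emitter)
PMF at r=37.5 nm: -4.40 kT
```

`C ≈ 100` in the first bin says channel-B density within 25 nm of a
channel-A localization is ~100× the random expectation — the strong
co-clustering built into the scene. The density estimate illustrates its
documented caveat: for a *clustered* species it reports the density of
independent structures, and 0.8 µm⁻² is exactly the 20 discs / 25 µm² of the
ground truth (each "emitter" here is a 10-molecule disc observed ~140
times). On randomly distributed molecules the same estimator recovers the
molecular density within ~10% across 2–20 µm⁻² (see the test suite). The
PMF expresses the second-bin enrichment as an effective attraction of
~4.4 k_BT.

A command-line interface wraps the same stages
(`phasecorr synth | xcorr | density | live-xcorr | track | simulate | report`);
every run writes a `provenance.json` with the resolved configuration and seed.

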