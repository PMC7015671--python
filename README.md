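# mtrecon

Desk-scale, fully testable implementation of a microtubule (MT) cryo-EM
reconstruction-and-refinement pipeline and the quantitative statistics of
the kinesin-5 motor assays that accompany such structural work. Every
input is produced by the package's own synthetic-data generators with
known ground truth, so each stage — from projection matching to censored
run-length fitting — can be verified quantitatively on one CPU in
minutes.

It is aimed at structural biologists and methods developers who want a
transparent, inspectable model of how helical MT reconstruction works
(IHRSR-style refinement, protofilament signal subtraction, FSC-based
validation), and at quantitative biologists who need the standard
single-molecule fitters with honest handling of censoring and model
selection.

## What's inside

**Lattice model** (`mtrecon.lattice`). The MT monomer lattice as an
N-start helix: for an N-protofilament (PF), S-start lattice with monomer
spacing *a*, the per-subunit helical parameters are

    twist = ±360°/N        rise = S·a/N

(e.g. N=14, S=3, a=40.95 Å → 25.714°, 8.775 Å; the dimer repeat is
2a ≈ 82 Å). The seam is modeled as one PF column with swapped α/β
register.

**Synthetic data** (`mtrecon.simulate`). Gaussian-blob decorated MT
volumes (α/β-tubulin, motor, tail species with Bernoulli occupancies),
projected segment stacks extracted every 80 Å along in-plane filaments
with exact ground-truth Euler angles/shifts, optional phase-contrast CTF
and calibrated footprint SNR; plus the four assay dataset families
(Michaelis–Menten ATPase curves, Gaussian-mixture velocities with
right-censored exponential run lengths, force-vs-overlap pairs,
two-compartment cell images).

**Reconstruction core** (`mtrecon.recon`). Exhaustive projection
matching by normalized cross-correlation with sub-pixel shifts,
ramp-filtered real-space back-projection with hit-count normalization,
grid-search estimation of helical rise/twist from map self-correlation,
N-fold symmetrized averaging, the full IHRSR iteration, multi-reference
13/14/15-PF sorting with per-filament majority vote, and per-filament
polynomial smoothing of alignments with MAD outlier replacement.

**Protofilament refinement** (`mtrecon.pfrefine`). Soft wedge masks that
partition the annulus exactly; signal subtraction of all other PFs by a
single complement projection; extraction of one re-centered particle per
PF per segment (19,128 segments × 14 PFs → 267,792 particles); local
constrained refinement; and focused occupancy classification built on a
matched-filter statistic against the consensus volume.

**Validation** (`mtrecon.validation`). FSC with the 0.143 criterion
(by-filament half-sets — segment-level splits overlap and inflate FSC),
B-factor sharpening `exp(−B·s²/4)`, and blocres-style sliding-window
local resolution.

**Assay statistics** (`mtrecon.assays`). scikit-learn-style estimators:
`MichaelisMentenEstimator` (v = kcat·S/(Km+S)), `GaussianMixture1D`
(EM on raw samples, BIC selection between k=1 and 2),
`CensoredExponentialFitter` (mean = Σ lengths / # uncensored,
half-length = mean·ln 2), `OverlapForceRegressor` (least-squares slope
with a seeded pair-resampling bootstrap CI), and the background-
subtracted spindle:cytoplasm intensity ratio.

## Worked example

```python
import numpy as np
from mtrecon.lattice import LatticeSpec, helical_params_from_spec
from mtrecon.simulate import DensitySpec, simulate_segment_stack, build_volume
from mtrecon.recon import ihrsr_refine
from mtrecon.lattice import HelicalParams

lat = LatticeSpec(n_pf=14, radius_A=80.0)           # desk-scale radius
dens = DensitySpec(voxel_size_A=4.0, box_px=64, motor_occupancy=0.0)
sim = simulate_segment_stack(lat, dens, n_filaments=4,
                             filament_len_A=880.0, snr=np.inf, seed=5)

hp = helical_params_from_spec(lat)                  # -25.714 deg, 8.775 A
init, _ = build_volume(lat, dens, seed=99)          # wrong rot register
start = HelicalParams(hp.twist_deg + 0.6, hp.rise_A - 0.3)
res = ihrsr_refine(sim.images, init, start, 14, n_iter=3,
                   angular_step_deg=4.0, shift_range_A=8.0,
                   r_min_A=30.0, r_max_A=110.0, meta=sim.meta)
print(res.log[["iteration", "twist_deg", "rise_A", "mean_cc"]])
```

prints (per iteration: refined twist/rise and mean alignment score)

```
 iteration  twist_deg   rise_A  mean_cc
         0 -25.772890 8.684635 0.996239
         1 -25.706375 8.736642 0.965616
         2 -25.710287 8.740577 0.965451
```

i.e. starting 0.6° / 0.3 Å off, the refinement returns to the generating
lattice parameters (−25.714°, 8.775 Å) within the search grid step in
two iterations, and the refined map correlates with the generating
volume at NCC = 0.989 inside the MT mask.

On the assay side:

```python
from mtrecon.simulate import gen_mm_dataset
from mtrecon.assays import fit_michaelis_menten

d = gen_mm_dataset(7.1, 680.0, np.geomspace(68, 13600, 8),
                   noise_cv=0.03, seed=1)
fit = fit_michaelis_menten(d.mt_conc_nM, d.rate_per_s)
print(f"kcat = {fit.kcat_:.2f} ± {fit.kcat_se_:.2f} 1/s, "
      f"Km = {fit.km_:.0f} ± {fit.km_se_:.0f} nM")
# kcat = 7.15 ± 0.08 1/s, Km = 689 ± 31 nM
```

recovering the generating kinetics (7.1 s⁻¹, 680 nM) within error.

A `mtrecon` console script exposes the stages
(`simulate`/`recon`/`pfrefine`/`validate`/`assays` subcommands); run
`mtrecon --help`.

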