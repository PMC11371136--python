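# sita — salt-induced tilting assay analysis

`sita` is a Python toolkit for quantifying how salinity modifies root
gravitropism in plate-grown seedlings, and for mapping the natural
variation of that response with a mixed-model genome-wide association
scan.

In a salt-induced tilting assay (SITA), agar plates are rotated 90° at
the moment seedlings are transferred to a treatment (e.g. 100 mM NaCl),
gravistimulating every root, and root growth is imaged every 20 min.
Under control conditions the root tip re-bends toward the gravity
vector; under NaCl the tip settles at a deflected angle. `sita` takes
the traced root polylines (RSML, as exported by SmartRoot, or long CSV)
and computes:

- **RTD** (root tip direction): the signed angle between gravity and
  the growth direction of the last 10% of the traced root,
- **RVA** (root vector angle): the signed angle of the straight vector
  from the root's position at transfer to its current tip,
- per-frame root length and growth rate (cm/h),
- a fitted re-bending kinetic model
  `y(t) = y0 + L·e^(−k·t)` (lower asymptote `y0`, initial decrease `L`,
  decay rate `k` in 1/h; a logistic variant is available),
- the salt-response traits **K^N/C** = k_NaCl / k_control,
  **RTD^N−C** at 5 h, and **RVA^N−C** at 23 h,
- broad-sense heritability **H²** from one-way ANOVA mean squares over
  replicated accessions,
- an **EMMAX-style mixed-model GWAS** over a biallelic SNP panel
  (minimal VCF or dosage CSV): MAF filter (strict `maf > 0.05`),
  VanRaden kinship, one REML fit of
  `y = Xb + u + e, u ~ N(0, σ_g²K)` under the null, per-SNP
  generalized-least-squares tests, a Bonferroni threshold
  `T = −log10(α/m)`, and haplotype grouping of accessions by the
  alleles at the significant SNPs with a trait comparison between the
  groups.

Because raw assay data for a real accession panel is typically not
shippable, the package includes a fully tested synthetic-data module
(`sita.simgen`) that generates time-lapse root traces from a
first-order heading-relaxation process and structured genotype panels
(Balding–Nichols subpopulations) with a planted causal SNP, so the
whole chain runs end-to-end against known ground truth.

## Worked example

```python
from sita.simgen import RootSimConfig, simulate_root
from sita.traits import trait_timeseries
from sita.kinetics import fit_decay, response_traits

cfg = RootSimConfig(g_rate=0.3, theta_set_salt_deg=45.0,
                    sigma_theta=3.0, seed=7)
ctrl = simulate_root(cfg, "control", seed=1)
salt = simulate_root(cfg, "NaCl", seed=2)
tc, ts = trait_timeseries(ctrl), trait_timeseries(salt)
fc = fit_decay(tc["time_h"], tc["rtd_deg"])
fs = fit_decay(ts["time_h"], ts["rtd_deg"])
rt = response_traits(fs, fc, ts, tc)
print(f"control fit: y0={fc.y0:+.1f} deg  L={fc.L:.1f} deg  k={fc.k:.3f} /h")
print(f"NaCl fit:    y0={fs.y0:+.1f} deg  L={fs.L:.1f} deg  k={fs.k:.3f} /h")
print(f"K_ratio={rt.K_ratio:.3f}  RTD_diff(5h)={rt.rtd_diff_deg:+.1f} deg  "
      f"RVA_diff(23h)={rt.rva_diff_deg:+.1f} deg")
```

prints

```
control fit: y0=-2.0 deg  L=91.3 deg  k=0.290 /h
NaCl fit:    y0=+46.4 deg  L=42.7 deg  k=0.318 /h
K_ratio=1.094  RTD_diff(5h)=+35.1 deg  RVA_diff(23h)=+40.5 deg
```

The control root re-bends from 90° (the post-tilt heading) down to an
asymptote near 0° (gravity) at ≈0.3 h⁻¹ — recovering the simulator's
relaxation rate — while the salt-treated root settles near the 45°
setpoint, giving large positive RTD/RVA differences: the salt-response
phenotype the GWAS stage maps.

A full synthetic run — panel simulation, per-accession root pairs,
trait extraction, kinetic fits, kinship-corrected scan and haplotype
follow-up — is one command:

```sh
sita run-all --seed 1 --out-dir my_run
```

which writes `genotypes.vcf`, `response_traits.csv`,
`association.csv`, `haplotypes.csv` and a `manifest.json` that is
sufficient to reproduce the run byte-for-byte. Individual stages are
exposed as `sita simulate-roots`, `simulate-panel`, `extract-traits`,
`fit-kinetics`, `gwas` and `haplotype`.

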