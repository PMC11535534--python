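# ovastereo

Fractionator stereology for ovarian follicle counting: a virtual-tissue
simulator and Monte-Carlo validation harness for the standard histological
procedure used to estimate the ovarian reserve (the number of primordial
follicles housed in the ovarian cortex).

## Who this is for

Reproductive biologists and biostatisticians who count follicles on
systematically sampled H&E sections and scale the raw counts up to
whole-ovary totals — and who want to know, quantitatively, when that
scale-up is unbiased, how precise it is at a given sampling intensity, and
why large (secondary and antral) follicles must not be counted with the
same rule as primordial ones.

## The method

The ovary is cut into 1-mm slabs perpendicular to its long axis.  A
systematic uniform random third of the slabs is selected (fixed interval,
uniformly random start — fraction f2).  Each selected slab is cut into
5-µm sections, and five serial sections out of every 50 are collected
(fraction f3).  If part of the ovary was removed beforehand (e.g. for
pathology), the weight fraction that remained is f1.  A primordial or
primary follicle enters the raw count Q only in a section where its oocyte
nucleolus is clearly seen, and a follicle counted once is excluded from
subsequent adjacent sections.  The total follicle number is then estimated
by the fractionator:

    N̂ = ΣQ × 1 / (f1 × f2 × f3)

Because systematic uniform random sampling examines every counting unit
with probability f1·f2·f3, N̂ is design-unbiased — *provided* the counting
unit (the nucleolus) is tallied in exactly one section.  `ovastereo`
simulates the entire chain against synthetic 3D ovaries with known
follicle numbers:

- **`synthetic_ovary`** — prolate-ellipsoid ovary, follicles as nested
  spheres (follicle ⊃ oocyte ⊃ nucleus ⊃ nucleolus) placed uniformly in a
  cortical shell; every size and count is a configurable simulator
  parameter.
- **`sectioning`** — slabs, systematic slab selection, serial-run section
  sampling, and sphere–section intersection geometry (profile chords at
  the section mid-plane; sections are 3-D slices, not planes).
- **`counting`** — the nucleolus-gated rule with adjacent-section
  exclusion; the naive profile-presence rule (for bias studies); the
  relative secondary-follicle scheme (1-of-50 sections, no scale-up); the
  per-section growing-follicle raw count; profile-diameter morphometry.
- **`estimation`** — the fractionator scale-up with *realized* sampling
  fractions, bilateral averaging, age-group summaries and the
  primary:primordial ratio.
- **`mc_study`** — replicate harness reporting relative bias, CV and
  standard errors per stage and counting mode, plus the brute-force
  exhaustive oracle and the object-size overcounting experiment.

## Worked example

```python
import ovastereo as ov

cfg = ov.OvaryConfig(stages={"primordial": ov.StageConfig(
    1000, ov.SizeDist(35, 3), ov.SizeDist(30, 2.5),
    ov.SizeDist(18, 1.5), ov.SizeDist(3, 0.3))})
model = ov.generate_ovary(cfg, seed=1)               # ground truth: 1000 follicles
res = ov.section_ovary(model, ov.SamplingPlan(), seed=2)
cr = ov.apply_counting_rule(res)                     # nucleolus-gated counts
n_hat = ov.estimate_total(cr.counts_by_stage["primordial"],
                          cr.realized_f1, cr.realized_f2, cr.realized_f3)
print(f"slabs selected: {res.selected_slabs} of {res.n_slabs_total}")
print(f"realized fractions: f1={res.realized_f1}, "
      f"f2={res.realized_f2:.4f}, f3={res.realized_f3}")
print(f"raw count sum(Q) = {cr.counts_by_stage['primordial']}")
print(f"N_hat = {n_hat:.1f}  (true N = 1000)")
```

prints

```
slabs selected: [2, 5, 8, 11, 14, 17, 20, 23, 26, 29] of 30
realized fractions: f1=1.0, f2=0.3333, f3=0.1
raw count sum(Q) = 26
N_hat = 780.0  (true N = 1000)
```

26 of the 1000 follicles were counted on the sampled sections; dividing by
the overall sampling probability 1/3 × 1/10 scales this up to 780.  A
single ovary is noisy (the CV at this design is ≈ 17%); averaging over
replicates recovers the truth — `ov.run_replicates` with 500 replicates of
this configuration puts the relative bias within a fraction of a percent,
inside its Monte-Carlo error band.

The same pipeline is available from the shell (`ovastereo generate`,
`section`, `count`, `estimate`, `report`, `mc-study`); all subcommands are
deterministic given a config and seed.  See the module docstring of
`ovastereo/cli.py` for the YAML config layout.

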