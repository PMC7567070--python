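# trajmetrics

Conformational metrics and work-based free-energy estimation for protein
molecular-dynamics trajectories, built around the comparative analysis of a
small GTPase (KRAS) and its guanine nucleotide-exchange factor (GEF): how do
point mutations at an acetylation-mimicking site (K104A, K104Q on a G12D
background) change the orientation of the α2/α3 helices that form the
GEF-binding surface, and how much do they change the binding free energy?

The package is for computational structural biologists who have (or want to
emulate) trajectory and nonequilibrium-work data and need the standard
readouts as tested, scriptable building blocks rather than one-off scripts.

## What it computes

**RMSD(t)** after weighted least-squares (Kabsch) superposition onto a
reference conformation:

    RMSD(t) = [ (1/M) Σᵢ mᵢ |rᵢ(t) − rᵢ_ref|² ]^½ ,   M = Σᵢ mᵢ

**RMSF and B-factor** over a time window, with the window-mean positions as
reference and the Debye–Waller conversion

    B = (8/3) π² · RMSF²

**Pseudo-dihedral helix orientation**: the torsion over four Cα atoms
(default Met67–Thr74–Lys104–Thr87 by author numbering, spanning the α2 and
α3 helices), with windowed histograms, circular means/stds, and pairwise
distribution-shift summaries.

**ΔΔG from bidirectional work samples** by the Crooks–Gaussian Intersection
(CGI): fit a Gaussian to the forward (λ 0→1) work and to the negated
backward (λ 1→0) work; their crossing point is the free-energy difference.
In a double-system/single-box setup this is directly the binding ΔΔG of a
mutation (ΔΔG = ΔG1 − ΔG2; positive values destabilize binding).  A Bennett
acceptance-ratio (BAR) estimator and seeded bootstrap errors are included as
cross-checks.

**Synthetic generators** produce seeded stand-ins with the statistical
structure the analysis assumes — helical Cα geometry, Gaussian atomic
fluctuations with optional rigid-body drift, von Mises angle ensembles,
Crooks-consistent Gaussian work samples — so the full pipeline runs and is
validated without MD engine output.

## Worked example

Generate 100 forward + 100 backward Crooks-consistent work samples around a
planted ΔΔG of 6.14 kJ/mol, then estimate it back:

```sh
$ trajmetrics simulate work --dg 6.14 --dissipation 3 --n 100 --seed 42 --out works.txt
$ trajmetrics cgi --in works.txt --n-boot 1000 --seed 1 --bar
dG = 6.553 kJ/mol (CGI, n=100+100, T=298.15 K) +/- 0.252
dG = 6.351 kJ/mol (BAR cross-check)
```

The CGI point estimate (6.55 kJ/mol) recovers the planted 6.14 kJ/mol within
two bootstrap standard errors at this sample size; the independent BAR
estimate agrees, and the positive sign marks the mutation as destabilizing
GEF binding.

The same works from Python:

```python
from trajmetrics import WorkSpec, simulate_work, cgi_estimate

ws = simulate_work(WorkSpec(dg_true=6.14, dissipation=3.0, seed=42))
est = cgi_estimate(ws, n_boot=1000, seed=1)
print(est.dg, est.ci95)        # 6.55 (6.05, 7.08)
```

A full comparative run (four systems, WT reference, angle ensembles at the
published means plus per-system ΔΔG) is driven by a flat INI config:

```ini
[run]
reference = WT

[WT]
angle_mu = -55.3
seed = 4

[G12D_K104Q]
angle_mu = -62.0
seed = 3
work_dg_true = 6.14
```

```sh
trajmetrics report --config run.ini --out out/
```

which writes per-system TSV tables (RMSD series, RMSF/B-factor profiles,
angle histograms) and one deterministic `report.json` with the pairwise
shifts (`left_shifted` flags, circular-std ratios) and the ΔΔG table with
stabilizing/destabilizing calls.

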