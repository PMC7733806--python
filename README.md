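# pumpgeom

Structural and kinetic analysis of P-type ATPase conformations, built around
the comparison of wild-type SERCA1a (the sarco/endoplasmic-reticulum
Ca²⁺-ATPase) with its interdomain-communication mutant E340A.

SERCA pumps two Ca²⁺ ions per ATP across the SR/ER membrane by cycling
through E1/E2 conformations of a 10-helix transmembrane domain (M1–M10)
coupled to a cytosolic headpiece of three domains (A, N, P). Glu340, in the
short P1 helix at the membrane-facing side of the P domain, sits at the hub
connecting the P domain to M3, to the L6-7 loop, and — through headpiece
packing — to the Ca²⁺-gating helices M1–M3. This package implements the
quantitative analyses used to characterise what its removal does:

- **segment-decomposed structural comparison** — Kabsch least-squares
  superposition on a named segment (e.g. the M5–M10 bundle, residues
  750–994), then per-segment RMSDs evaluated in that fitted frame;
- **named geometric observables** — headpiece-inclination angle
  (Cα Leu13–Thr86–Leu98), M1 kink angle (Cα Trp50–Arg63–Val74),
  P1-to-M4 anchor distance (Pro337–Pro312 Cα), Leu249–residue-340 distance,
  and the in-line phosphoryl-transfer geometry at Asp351 (Oδ–Pγ distance
  and Oδ–Pγ–bridge angle);
- **polar-contact / hydrogen-bond accounting** between domains, including
  single-water bridges, with a heavy-atom criterion for crystal structures
  and a D–H···A criterion for MD frames;
- **trajectory analyses** — per-frame observable time series, KDE/histogram
  densities with mode finding, Pearson trace correlation, medians, and a
  hysteretic two-state classifier for one-way switching events such as the
  Arg822 in→out swing;
- **functional-assay computations** — two-phase association fits
  F(t) = F₀ + A₁(1−e^(−k₁t)) + A₂(1−e^(−k₂t)) of Ca²⁺-binding fluorescence
  traces with a numerically solved half-time, enzyme-coupled ATPase specific
  activity from NADH A340 slopes (ε = 6.22 mM⁻¹cm⁻¹), and free-Ca²⁺
  speciation in Ca/EGTA buffers from the 1:1 binding quadratic;
- **seeded synthetic-data generators** for every one of these analyses, each
  emitting machine-readable ground truth.

## Worked example

Free Ca²⁺ after the final CaCl₂ addition of the fluorescence protocol
(105 µM adjusted + ~4 µM contaminating + 12.5 mM added Ca, 5 mM EGTA):

```
$ pumpgeom caegta --ca 12.609e-3 --egta 5e-3 --kd 1e-7
{
  "bound_ca": 0.0049999342897738015,
  "free_ca": 0.007609065710226199,
  "free_egta": 6.571022619864669e-08,
  "kd_app": 1e-07
}
```

With Ca in 2.5-fold excess over EGTA, essentially every chelator site is
occupied and 7.61 mM Ca²⁺ remains free — the Kd only decides the last
fraction of a percent.

Segment-decomposed comparison of a synthetic structure pair related by a
known 30° rigid rotation plus 0.3 Å-per-coordinate Gaussian noise:

```python
from pumpgeom.synthetic_data import make_rigid_pair
from pumpgeom.report import run_compare_report

ref, mob, truth = make_rigid_pair(n_atoms=1000, rotation_deg=30.0,
                                  noise_sd=0.3, seed=11)
report = run_compare_report(ref, mob)
print(truth["expected_fit_rmsd"])                      # 0.519
print(report.rmsd_fit_segment["segments"]["M5M10"])    # [0.542, 245]
print(report.rmsd_global)   # {'rmsd': 0.5188, 'n_atoms': 1000, ...}
```

The motion is global, so after fitting on any segment every segment sits at
the noise floor σ·√((3n−6)/n) ≈ 0.52 Å recorded by the generator; with the
real WT/E340A pair the same report instead separates the rigid transmembrane
core from the rotated headpiece.

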