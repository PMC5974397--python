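# oligoscope

Determining how many protomers a membrane protein ring contains is
surprisingly contentious: crystallography, gel filtration and
spectroscopy regularly disagree about the same protein. For microbial
rhodopsins two independent observables settle it — the ring geometry
seen by atomic force microscopy in a lipid membrane, and the sign of the
exciton-coupled circular dichroism (CD) couplet produced by the retinal
chromophores. `oligoscope` implements the computational side of both:

- **AFM topograph simulation** from atomic coordinates with a hard-sphere
  sample and a blended sphere/cone tip (5° half angle, 0.5 nm apex by
  default), low-pass filtered at the instrument's ~2 nm lateral
  resolution. The simulated map is exactly the grayscale dilation of the
  union-of-spheres surface by the reflected tip, and is verified against
  an independent brute-force contact oracle.
- **Ring metrology** on height maps: subunit peaks by topographic
  prominence (persistence), rotational-autocorrelation symmetry order,
  least-squares peak-circle diameter plus a half-height outer diameter,
  a central protrusion/pore score that assigns the membrane face (a
  central His-tag bump marks the C-side, an open pore the N-side), and
  per-patch statistics (counts, mean ± s.d., class fractions).
- **Exciton CD prediction** from retinal geometry: point-dipole coupling
  Hamiltonian V_ij = μ²κ_ij/d³, rotational strengths
  R_k = −(π/λ̄) Σ c_ik c_jk [R_ij·(μ_i×μ_j)] that obey the zero-sum rule,
  Gaussian band synthesis with an intrinsic monomer band, and couplet
  classification: blue-positive/red-negative = *normal* (the trimer
  signature), the reverse = *inverted* (the pentamer signature).
- **A synthetic-structure generator** producing ground-truth ring
  oligomers (n = 3, 5, 6; diameters 2.8–4.9 nm), head-to-tail vs
  tail-to-tail dipole packings, central protrusion/pore variants, packed
  lipid-patch scenes and AFM-like noise — so the entire chain is testable
  without downloading anything.

See `docs/methods.md` for the models, defaults and their limits.

## Worked example

```python
from oligoscope import (FilterSpec, NoiseSpec, ScanGrid, SyntheticOligomerSpec,
                        TipModel, analyze_heightmap, corrupt_heightmap,
                        make_ring_oligomer, predict_cd, simulate_topograph)

spec = SyntheticOligomerSpec(n=6, ring_radius=2.3, seed=5)
structure, chromophores, truth = make_ring_oligomer(spec)
hm = simulate_topograph(structure, TipModel(), ScanGrid.centered(0.1, 101, 101))
noisy = corrupt_heightmap(hm, NoiseSpec(sigma=0.05, line_offset_sigma=0.02, seed=6))
call = analyze_heightmap(noisy, presmooth=FilterSpec(2.0))
print(call.cls, call.measurement.diameter, call.measurement.central_feature)
```

Running `examples/02_ring_analysis.py` (the same computation, annotated)
prints:

```
ground truth: hexamer, peak-circle diameter 4.60 nm
recovered:    hexamer (6 subunit peaks, C6 autocorrelation, confidence 0.42)
peak-circle diameter 4.60 nm, outer (half-height) diameter 7.28 nm
central feature -3.33 nm -> face 'N-side'
```

The analysis recovered the planted symmetry order and the 4.60 nm
peak-circle diameter exactly; the larger outer diameter reflects tip
broadening of the ring footprint, and the deeply negative central
feature is the open pore of the tag-free face. On the CD side,
`examples/03_exciton_cd.py` shows the packing-to-couplet mapping:

```
C3 head_to_tail -> normal_couplet   (blue +, red -); exciton bands at 548, 513, 513 nm
C5 tail_to_tail -> inverted_couplet (blue -, red +); exciton bands at 538, 538, 525, 525, 498 nm
weak couplet + intrinsic CD: apparent peak 525.8 nm vs lambda_max 524 nm (minimum -1.1e-09, never negative)
```

— the same ring geometry flips its couplet sign when the retinal azimuth
pattern flips, and a couplet too weak to cross zero still betrays itself
by pushing the apparent CD peak red of the absorption maximum.

The other examples cover topograph simulation (`01`), patch mixture
statistics (`04`) and running the full chain on a real downloaded
crystal structure (`05`).

## Command line

```bash
oligoscope synth --n 5 --radius 2.15 --azimuth tail_to_tail --out fix/
oligoscope simulate --in structure.pdb --side N --cutoff 2 --out map.tsv
oligoscope analyze --in map.tsv --orders 3,5,6
oligoscope cd --in structure.pdb --site-lambda 524 --out spectrum.tsv
oligoscope run --config run.yaml      # full pipeline, JSON report
```

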