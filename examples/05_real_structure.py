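"""Run the full chain on a real crystal structure (requires a download).

With the KR2 pentamer coordinates (PDB 4XTN) saved to data/4XTN.pdb —
e.g. `curl -O https://files.rcsb.org/download/4XTN.pdb` — this script
orients the oligomer, simulates both membrane faces, measures the ring
and predicts the CD couplet from the five retinals.
"""

from pathlib import Path

import numpy as np

from oligoscope import (
    FilterSpec,
    ScanGrid,
    TipModel,
    analyze_heightmap,
    extract_retinal_chromophores,
    lowpass_filter,
    orient_oligomer,
    predict_cd,
    read_structure,
    simulate_topograph,
)

path = Path(__file__).resolve().parent.parent / "data" / "4XTN.pdb"
if not path.exists():
    raise SystemExit(
        f"{path} not found.\nDownload the KR2 pentamer coordinates first:\n"
        f"  mkdir -p {path.parent}\n"
        f"  curl -o {path} https://files.rcsb.org/download/4XTN.pdb"
    )

structure = read_structure(str(path))
print(f"read {path.name}: {len(structure)} heavy atoms, "
      f"{structure.n_chains} chains")

for side in ("N", "C"):
    oriented = orient_oligomer(structure, side=side)
    half = float(np.max(np.abs(oriented.positions[:, :2]))) + 2.0
    n = 2 * int(np.ceil(half / 0.1)) + 1
    hm = simulate_topograph(oriented, TipModel(5.0, 0.5),
                            ScanGrid.centered(0.1, n, n))
    hm = lowpass_filter(hm, FilterSpec(2.0))
    call = analyze_heightmap(hm)
    m = call.measurement
    print(f"{side}-side: {call.cls}, {m.n_subunits} subunits, "
          f"peak-circle diameter {m.diameter:.2f} nm, "
          f"central feature {m.central_feature:+.2f} nm")

chrom = extract_retinal_chromophores(structure, site_wavelength=524.0)
system, spectrum, couplet = predict_cd(chrom)
print(f"{len(chrom)} retinals -> {couplet.label} "
      f"(blue {couplet.blue_lobe_sign}, red {couplet.red_lobe_sign})")
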