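# capsipy

Structural analysis of icosahedral viral capsids, built around the yeast
L-A virus (a *Totiviridae* dsRNA virus whose T = 1 shell packs 120
chemically identical Gag protomers as 60 asymmetric dimers):

- **Cation-π detection** — geometric identification of interactions between
  cationic side-chain moieties (Arg guanidinium, Lys ammonium, optionally
  His imidazolium) and aromatic π faces (Phe/Tyr six-rings, both Trp rings,
  optionally His). A contact is recorded when the charge center lies within
  `d_max` (default 5 Å) of the ring centroid *and* the centroid→cation
  vector falls within `theta_max` (default 45°) of the ring normal.
- **Interaction networks** — connected components of the residue graph whose
  edges are contacts, with per-structure summaries (side chains, networks)
  and a batch prevalence survey across capsid structures.
- **Icosahedral symmetry** — the 60 proper rotations of the icosahedral
  group (532 orientation, two-fold axes along the coordinate axes) and
  asymmetric-unit → full-capsid expansion.
- **Interface energetics** — enumeration of the capsomere's unique
  protomer–protomer interface classes and a decomposable rigid-body score
  `E_total = E_vdw + E_es + E_ds` (truncated 12-6 van der Waals,
  constant-dielectric Coulomb over formal charges, buried-surface-area
  desolvation).
- **Greedy assembly simulation** — starting from one protomer, repeatedly
  dock the neighbor with the most favorable summed interface energy until
  the 120-subunit shell is complete.
- **Community statistics** — nearest-neighbor distances, single-linkage
  community clustering, box-plot statistics (1.5·IQR whiskers), and genome
  packaging efficiency from full/empty capsid counts of micrograph particle
  picks.

A deterministic synthetic-fixture generator (planted cation-π pairs, toy
capsids, random structures, particle fields) makes every module testable
without downloading any deposited structure.

## Worked example

```python
import numpy as np
from capsipy import fixtures, detect_contacts, expand_assembly, \
    icosahedral_operators, packaging_efficiency

# plant a cation-pi pair at exactly 4.2 A / 20 deg and detect it
s = fixtures.make_planted_pair(fixtures.PlantedPairSpec(4.2, 20.0, "ARG", "TYR"))
c = detect_contacts(s)[0]
print(f"{c.cation.res_name} -> {c.ring.ring_label} d={c.distance:.2f} A, "
      f"theta={c.theta:.1f} deg, {c.scope}")

# expand a 2-chain asymmetric unit into the full T=1 shell
unit = fixtures.make_random_structure(8, box_size=15.0, seed=1, chain_ids=("A", "B"))
capsid = expand_assembly(unit, icosahedral_operators())
print(f"{len(unit.chains)} chains -> {len(capsid.chains)} protomers")

# packaging efficiency from counted full/empty mature capsids
raw, rounded = packaging_efficiency(400, 661)
print(f"packaging efficiency: {raw:.2f}% (~{rounded}%)")
```

prints

```
ARG -> TYR6 d=4.20 A, theta=20.0 deg, inter_chain
2 chains -> 120 protomers
packaging efficiency: 37.70% (~40%)
```

The planted pair comes back at exactly the geometry it was built with; the
60 icosahedral rotations turn the two-protein asymmetric unit into the 120
protomer chains of the T = 1 capsid; and of 1061 counted mature capsids,
400 full ones give a ~40% genome packaging efficiency.

## Documentation

See `docs/methods.md` for the underlying models, parameter defaults,
numerical conventions, and known limitations.
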