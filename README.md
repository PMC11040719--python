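# ifacesearch

Alignment and similarity assessment of protein–protein interfaces from 3-D
structure, for structural biologists who want to ask: *which known
interfaces look like this one?* Typical uses are finding interface mimicry
between unrelated folds, screening a structure collection for potential
interaction partners, and ranking docking poses by interface similarity to
a reference complex — all without any sequence information.

## Method

An interface is modelled atom-wise: every heavy atom of one chain within
4.5 Å of any heavy atom of the partner chain belongs to that chain's side
of the interface. Each side is reduced to a typed point cloud — by default
one Cα per interface residue; optionally a "restricted" set (O/N/S
heteroatoms, aromatic ring centres of His/Phe/Trp/Tyr, hydrophobic
side-chain carbons of Ala/Ile/Leu/Lys/Met/Pro/Val) or all heavy atoms,
both filtered to atoms solvent-exposed on the unbound chain.

Searching works by tetrahedral geometric hashing. Over one side's points,
all tetrahedra whose six edge lengths lie in [*minDist*, *maxDist*]
(defaults 1–14 Å) are enumerated, sorted by decreasing total edge length,
and greedily selected so every point is covered, topping up to
*noffilters* (default 30). Each selected tetrahedron becomes a database
filter: four property-constrained corners (at the default hierarchy level,
chemical element plus interaction type, with Cα as its own atom type) and
six distance intervals of width ±*distTolerance*. A filter match is any
ordered 4-point mapping in a stored interface satisfying all constraints;
symmetric and overlapping mappings are all kept, since each implies a
different alignment.

Every match is superposed by the Kabsch–Umeyama closed-form solution,
giving a candidate rigid transform of the target onto the query.
Candidates are ranked by a cheap Cα shape score (6 Å radius) and, per
target, the best ⌈√n⌉ of the n candidates are fully scored:

- **shape score** — the fraction of query points with a transformed
  target point within *scoringRadius* (default 1.5 Å),
- **pharma score** — the same matches weighted by a pharmacophore
  compatibility matrix over the types {Acc/Don, Acc, Don, Aro, HyPhob,
  Cα, Pos/Don, Neg/Acc},
- **SP-score** — their equally weighted combination,

each normalized by the point count of the larger of the two compared
sides, so only complete two-way overlap scores 1. A protein–protein
interface has one side per chain, so four chain pairings (AA′, AB′, BA′,
BB′) are evaluated and the best SP-score reported; one-sided queries
(a residue list on a single chain, no partner needed) use two pairings.

Two published parameter presets are built in: *runtime-optimized*
(minDist 1, maxDist 14, scoringRadius 1.5, distTolerance 1.0 — the
default) and *accuracy-optimized* (minDist 2, distTolerance 1.5).

## Worked example

The package ships a deterministic generator of small two-chain complexes
(compact helix bundles with realistic contact geometry), so everything
below runs without downloading any structure:

```python
import numpy as np
from ifacesearch import (SyntheticComplexSpec, make_toy_complex,
                         model_interface, compare_pair, transform_structure)
from ifacesearch.synthetic import random_rigid_transform

base = make_toy_complex(SyntheticComplexSpec(seed=1))
pair = model_interface(base, "A", "B")
print(len(pair.side_a.points), len(pair.side_b.points))   # 14 17

moved = transform_structure(base, random_rigid_transform(np.random.default_rng(8)))
hit = compare_pair(pair, model_interface(moved, "A", "B"))
print(hit.chain_pairing, round(hit.shape, 3), round(hit.pharma, 3), round(hit.sp, 3))
# AA' 1.0 1.0 1.0   -- the rigidly moved copy is recognised perfectly

decoy = make_toy_complex(SyntheticComplexSpec(seed=99))
hit = compare_pair(pair, model_interface(decoy, "A", "B"))
print(round(hit.sp, 3))
# 0.625             -- an unrelated complex scores clearly lower
```

The reported `hit.transform` maps the target onto the query; for the moved
copy it inverts the planted motion to numerical precision.

From the shell, the same pipeline is:

```bash
ifacesearch build-db --in structures/ --out db/
ifacesearch search --db db/ --query complex.pdb --chains A,B --out hits.tsv
ifacesearch compare --query a.pdb --target b.pdb --aligned-out aligned.pdb
ifacesearch bench --scores scored_panel.tsv --out metrics.tsv
```

`hits.tsv` holds one row per database interface — best chain pairing,
shape/pharma/SP scores, corner RMSD — sorted by the chosen score.

## Layout

- `ifacesearch.structures` — PDB/mmCIF parsing (gemmi), heavy-atom model, aligned-PDB output
- `ifacesearch.interface` — interface extraction, Shrake–Rupley exposure, point reduction, pharmacophore typing
- `ifacesearch.tetrascan` — tetrahedron enumeration/selection and filter annotation
- `ifacesearch.matchdb` — SQLite-backed interface database and filter matching
- `ifacesearch.align_score` — superposition, hit selection, shape/pharma/SP scoring
- `ifacesearch.bench`, `ifacesearch.synthetic` — benchmark metrics and the complex/decoy generator
- `ifacesearch.cli` — the `ifacesearch` command

See `docs/methods.md` for modelling assumptions, parameter rationale and
known limitations.
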