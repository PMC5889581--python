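# dockzones

Headless analysis of protein–protein docking ensembles. Given a set of
candidate poses (decoys) of one two-protein complex, `dockzones` identifies
each pose's **contact zone** (residue pairs within an interaction window,
default 3–5 Å), aggregates the ensemble into a **contact frequency matrix**,
filters poses by required interactions, **ranks** them against a trusted
primary structure (e.g. a crystal) with a +1/+4/−1 similarity score, builds
comparative **list-view** models, and computes rigid-body transforms for
**exploded** (non-overlapping parabolic grid of paired proteins) and
**open-book** (both contact surfaces facing the viewer) layouts. Outputs are
machine-readable TSV/JSON plus static SVG graphics and transformed PDB files
— no GUI, no renderer.

## Library overview

| module | what it does |
| --- | --- |
| `structures_io` | PDB in/out; `Configuration` = reference + paired protein unit; chain selectors, altloc/water/HETATM policy |
| `synth_fixtures` | synthetic two-protein ensembles with planted contacts at exact distances + ground-truth manifest |
| `contacts` | minimum heavy-atom residue distances, contact zones, collisions (< 3 Å), closest pair |
| `matrix_filter` | ensemble frequency matrix, marginals, conjunctive pair filtering |
| `ranking` | similarity scores against the primary configuration, stable ordering |
| `listview` | left/right list-view models, hydrophobicity / distance / frequency sorting, compare & compact modes |
| `geometry_views` | Kabsch superposition, ensemble alignment, zone centroids & normals, exploded grid, open-book transforms |
| `export_cli` | TSV/JSON/SVG exports, pipeline runner, `dockzones` CLI |

## CLI

```sh
# make a synthetic 6-pose ensemble with two planted contacts per pose
dockzones --out ens synth --n-configs 6 --residues-per-unit 8 \
    --plant A:2-B:3@4.0 --plant A:4-B:6@3.5

# full pipeline: contacts, matrix + heat map, filter, rank vs primary,
# list-views, exploded layout, open-book transforms
dockzones --out results --primary ens/conf_001.pdb \
    run ens/conf_00[2-6].pdb --pair A:2-B:3

# individual stages
dockzones --out results contacts ens/*.pdb
dockzones --out results matrix ens/*.pdb
dockzones filter ens/*.pdb --pair A:2-B:3 --filter-dmax 4.0
dockzones --out results --primary ens/conf_001.pdb rank ens/*.pdb
dockzones --out results explode ens/*.pdb --margin 10
dockzones --out results openbook ens/*.pdb --gap 10
```

Global flags: `--dmin/--dmax` (contact window), `--ref-chains/--paired-chains`
(comma-separated chain ids), `--primary`, `--out`, `--seed`, `--include-het`,
`-v`. A single input path containing MODEL records is treated as a
multi-model ensemble; multiple paths are one pose per file.

All outputs embed the serialized run configuration for provenance and are
byte-deterministic for identical inputs.

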