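# meaobond

Quantitative chemical-bonding analysis through orbital entanglement.

`meaobond` constructs atom-localized orbitals that maximize the inter-atomic
two-orbital coherences of the 2-particle reduced density matrix ("maximally
entangled atomic orbitals"), groups them into bonds via a mutual-information
correlation graph, and scores

* **two-center bonds** by the normalized mutual information `I/(2 log 4)` and
  the relative entropy of entanglement `E/log 4` of the two-orbital reduced
  state, and
* **multicenter bonds and aromatic rings** by genuine multipartite
  entanglement (GME, the minimum bipartition entropy of the cluster's CAS
  wavefunction, normalized by `log 4`).

The package is self-contained: it ships a compact electronic-structure
engine (McMurchie–Davidson Gaussian integrals with numba kernels,
density-fitted restricted Hartree–Fock, determinant full CI), basis-set data
(cc-pVDZ, aug-cc-pVDZ, 6-311++G(d,p), STO-3G, MINAO, def2-universal-JKFIT
for H–F) and reference geometries as plain text.  The `chem_backend` module
is a thin adapter over plain arrays, so an external engine can be swapped in.

## Layout

| module | role |
|---|---|
| `model_systems` | analytic fixtures: idealized bond state, symmetric orthogonalization, GHZ/W registers, covalent-to-ionic family |
| `chem_backend` | engine adapter: mean field, CAS/FCI solutions, thermal ensembles |
| `atomic_partition` | IAO / projected-minimal atom-blocked orthonormal orbital bases |
| `fock_rdm` | one-/two-orbital reduced density matrices, entropies, mutual information |
| `meao` | coherence objective, analytic gradient, safeguarded Newton optimizer over block rotations |
| `bonding_graph` | correlation graph, bond clustering, active-space construction |
| `entanglement` | pure bipartite entropy, relative entropy of entanglement (Frank–Wolfe over separable states), GME |
| `cli_report` | end-to-end workflow, JSON reports, CLI |
| `engine` | bundled integrals / SCF / FCI backend |

## CLI

```sh
meao-bond run   --geometry mol.xyz --basis cc-pvdz --partition iao-minimal \
                --threshold 0.10 --solver fci --seed 1 --out outdir
meao-bond graph --geometry mol.xyz --out outdir      # JSON + GraphML export
meao-bond cubes --geometry mol.xyz --out cubes       # orbital cube files
meao-bond report --report outdir/report.json --csv bonds.csv
```

`run` executes the four-stage workflow (partition → orbital optimization →
clustering → per-bond entanglement) and writes `report.json` with per-bond
normalized `I`/`E`, per-cluster GME, active-space sizes and provenance.

Python API example:

```python
from meaobond.cli_report import RunConfig, run_bonding_analysis
from meaobond.geometries import geometry_path

report = run_bonding_analysis(RunConfig(geometry=geometry_path("benzene-exp"),
                                        basis="cc-pvdz", seed=1))
print(report.multicenter[0]["GME_normalized"])   # 0.970 (six-orbital pi ring)
```

## Notes

* All entropies are natural-log; every reported quantity is normalized
  (`I/(2 log 4)`, `E/log 4`, `GME/log 4`), which is base-independent.
* The mixed-state entanglement defaults to a separable set with local
  particle-number superselection (the physically meaningful choice for
  fermionic orbital subsystems); `separable_set="unrestricted"` is available.
* The bundled engine is restricted Hartree–Fock only; density-functional
  references require wiring an external engine into `chem_backend`.
  Geometry optimization is likewise external: optimized reference geometries
  are bundled as data with their provenance recorded in the XYZ comments.
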