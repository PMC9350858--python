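# sdfmc

Meshless Monte Carlo radiation transfer for light transport in turbid
media.  All geometry is represented by signed distance functions (SDFs)
combined with constructive solid geometry (union / smooth union /
intersection / subtraction) and rigid transforms; photon packets are
advanced by sphere tracing, so smooth curved surfaces are handled
exactly: refractive-index boundaries are located on the implicit
surface, normals come from central differences of the SDF, and packets
are Fresnel-reflected or Snell-refracted there.  Fluence is recorded on
a voxel grid with an exact path-length estimator (3D DDA segment
splitting).

Units are cm throughout, in a right-handed world frame.

## Library overview

| module      | contents |
|-------------|----------|
| `geometry`  | `Sphere`, `Box`, `Capsule`, `Cylinder`, CSG combinators, `Transform`, `Scene` (nearest-surface and medium queries), `surface_normal`, `rasterize` |
| `optics`    | free-path sampling (`-ln u`), Henyey-Greenstein cosine, unpolarized Fresnel reflectance, vector reflect/refract, counter-based per-photon RNG substreams |
| `transport` | sphere-tracing propagation loop (`propagate` reference implementation and the jitted batch driver `run_simulation`), boundary handling, terminal events |
| `recording` | `FluenceGrid` path-length accumulator, fluence normalization, `absorption_map` |
| `sources`   | isotropic point, uniform rectangle, collimated strip launches |
| `scenarios` | packaged experiments: isotropic-sphere scattering law, semi-infinite slab two-exponential fluence fit, glass sphere, glass bottle, capsule-network vessels, synthetic network generator |
| `io_cli`    | YAML run configs, capsule tables, raw+JSON volumes, CLI |

Example:

```python
from sdfmc import (OpticalMedium, Scene, Sphere, FluenceGrid, GridSpec,
                   isotropic_point, run_simulation)

medium = OpticalMedium(mu_s=20.0, mu_a=0.5, g=0.9, n=1.38)
scene = Scene([Sphere(0.5, medium=medium)],
              bbox_center=(0, 0, 0), bbox_half_extents=(1, 1, 1))
grid = FluenceGrid(GridSpec(dims=(64, 64, 64), origin=(-1, -1, -1),
                            spacing=(1 / 32,) * 3))
result = run_simulation(scene, isotropic_point((0, 0, 0)),
                        n_photons=100_000, seed=1, grid=grid)
fluence = grid.finalize_fluence(100_000)   # cm^-2 per photon
print(result.counts)
```

Runs are bit-reproducible for a given seed: every photon index owns an
independent counter-derived RNG substream, so results do not depend on
scheduling.

## Command line

```sh
sdfmc run config.yaml -o out/            # simulate a YAML scene config
sdfmc scenario sphere --tau 10 -n 100000 # packaged experiments
sdfmc scenario slab --wavelength 630 -n 200000
sdfmc scenario glass-sphere|bottle|vessels
sdfmc make-vessels --seed 1 --n 50 -o vessels.txt
sdfmc rasterize config.yaml -o labels.raw
```

Exit code 2 marks configuration errors, 1 runtime failures.  See
`tests/test_io.py::CANONICAL_CONFIG` for the config schema; capsule
tables are plain text rows `x1 y1 z1 x2 y2 z2 radius` (cm).

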