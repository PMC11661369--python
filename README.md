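# phantomforge

Digital tooling for designing, slicing-adjacent post-processing, and
optically characterizing multi-filament 3-D-printed tissue-mimicking
phantoms.

A mixing extruder blends gray, white and translucent PLA filament into one
nozzle at programmable per-channel fractions; the resulting material's
absorption coefficient (`mua`) and reduced scattering coefficient (`musp`,
both mm^-1 at 635 nm) follow an affine model in the gray/white percentages:

```
mu = A * Rg + B * Rw + C        (Rt = 100 - Rg - Rw)
```

This package implements the full digital half of that workflow:

| module | what it does |
|---|---|
| `phantomforge.mixing` | fit the linear-mixing model from titration data, forward prediction, constrained inverse design on the mixing simplex, relative-error and ROI summaries |
| `phantomforge.wmc` | White Monte Carlo photon transport in a semi-infinite medium (numba kernel), similarity rescaling, Hankel projection to spatial frequencies, `(mua, musp, fx)` reflectance lookup tables, diffusion closed-form oracle |
| `phantomforge.sfdi` | 3-phase demodulation, reference-phantom calibration, per-pixel LUT inversion to `mua`/`musp` maps |
| `phantomforge.gcode` | multi-material G-code post-processing: purge-tower planning/insertion, 0.3 mm z-hop on tower transitions, x/y-rectilinear travel rewriting, per-channel mixing commands (M163/M164), filament usage accounting |
| `phantomforge.designs` | parametric phantom generators (titration rulers, three benchmarks, the QA slab with 8 thin inclusions, the 16-inclusion tomography slab, a three-mixture anatomical stand-in) with watertight STL export |
| `phantomforge.synth` | seeded synthetic inputs: titration tables, SFDI frame sets with ground truth, toy multi-region G-code |
| `phantomforge.cli` | `phantomforge` command-line entry point |

## CLI examples

```bash
# calibrate a mixing model from a titration CSV
phantomforge synth titration --out titration.csv --seed 1 --noise 0.05
phantomforge fit --titration titration.csv --out fitted.json

# forward / inverse design
phantomforge predict --model fitted.json --Rg 100 --Rw 0
phantomforge invert --model fitted.json --mua 0.01 --musp 0.5

# build a White-MC reflectance LUT (slow: runs the photon transport)
phantomforge lut build --out lut.npz --photons 1000000 --seed 1

# synthesize an SFDI acquisition and recover property maps
phantomforge synth sfdi --out frames/ --seed 1 --size 90
phantomforge sfdi recover --sample frames/sample --reference frames/reference \
    --ref-mua 0.0064 --ref-musp 1.42 --lut lut.npz --out maps/

# generate phantom geometry (STL meshes + JSON manifest)
phantomforge design qa --out qa/ --model fitted.json

# post-process toy multi-region G-code
phantomforge synth gcode --out toy.gcode --pattern checkerboard
phantomforge gcode post --in toy.gcode --plan toy.plan.json --out print.gcode
```

Exit codes: 0 success, 1 internal error, 2 usage error, 3 infeasible design
(a region's target optical properties outside the mixing model's range).

## Notes

- Meshes are vertical prisms (slab + box/cylinder inclusions); the
  background solid is produced by conforming polygon-with-holes
  triangulation (hole bridging + ear clipping), watertight by
  construction and verified by an edge-pairing check. Binary STL by
  default, `--ascii-stl` for text output.
- The white-MC run stores per-photon exit records so one simulation serves
  the entire `(mua, musp)` grid: absorption is applied as `exp(-mua * L)`
  and scattering is spanned by similarity rescaling of lengths.
- The tomography slab is generated as 10 x 5 x 1.5 cm (the thickness
  carries the partial-depth cylinder inclusions).
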