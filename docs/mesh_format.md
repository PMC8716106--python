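# Mesh JSON dialect

`rootsim` reads and writes segmented 2D cellular meshes as JSON — the
interchange stand-in for a confocal segmentation pipeline's output.  A
file round-trips bit-exactly through `load_mesh`/`save_mesh`.

```jsonc
{
 "version": 1,
 "vertices": [[x, y], ...],          // micrometres, y pointing shootward
 "cells": [
  {
   "id": 0,
   "type": "Vascular",               // one of the 15 documented cell types
   "vertex_ring": [3, 4, 9, 8],      // CCW ring of vertex indices
   "center": 120,                    // fan-triangulation center vertex (-1 if absent)
   "state": {
    "IAA": 0.0,                      // cytoplasmic auxin, nM
    "PIN": 0.0, "AUX1": 0.0,         // cytoplasmic carrier pools, nM
    "REG": 0.0, "POL": 0.0,          // regulator/polarizer pools, nM
    "af": [0.0, 0.0],                // anisotropy vector, |af| <= 1
    "A_max": 96.0,                   // division area threshold, um^2
    "A_min": 32.0,                   // turgor floor area, um^2
    "parity": 0,                     // alternating-division bookkeeping
    "knockdown": {},                 // expression multipliers per species
    "region": "BPE",                 // mechanics-only region label
    "growth_factor": 1.0,
    "b_IAA": null                    // per-cell synthesis override, nM/h
   }
  }
 ],
 "walls": [
  {
   "id": 0,
   "v": [3, 4],                      // vertex pair (sorted)
   "cells": [0, 5],                  // 1 (organ surface) or 2 adjoining cells
   "IAA": 0.0,                       // shared apoplast pool, nM
   "rest_length": 8.0,               // um
   "strain": 0.0,
   "no_flux": false,                 // carrier fluxes disabled on this wall
   "sides": [                        // one record per adjoining cell
    {"cell": 0, "PIN": 0.0, "AUX1": 0.0, "REG": 0.0, "POL": 0.0, "kE": 1.0}
   ]
  }
 ]
}
```

Validation on load enforces: every ring simple and counter-clockwise;
every ring edge backed by exactly one wall; every wall adjoining one or
two cells whose rings list it (adjacency is an involution); a side record
for exactly the adjoining cells; known cell types.  Violations raise a
parse/validation error naming the offending record.

Cell types: `QC, ColumellaInitial, Columella, EpidermisLRCInitial, CEI,
CEID, LRC, Epidermis, Endodermis, Cortex, Pericycle, Vascular,
VascularInitial, Source, Sink`.

`rootsim template -o mesh.json` writes the synthetic embryonic template
in this dialect; `rootsim validate mesh.json` checks an edited file.
A legacy-ASCII VTK export of the geometry with auxin and |af| scalars is
available through `rootsim.cell_complex.export_vtk`.
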