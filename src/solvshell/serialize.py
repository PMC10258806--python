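"""Plain-text writers for analysis products (TSV curves, JSON, DX grids)."""

from __future__ import annotations

import json

import numpy as np


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and (obj != obj):  # NaN
        return None
    return obj


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_tsv(path, header, columns) -> None:
    """Write equal-length columns as a tab-separated table with a # header."""
    cols = [np.asarray(c) for c in columns]
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(header) + "\n")
        for row in zip(*cols):
            fh.write("\t".join(f"{v:.8g}" if isinstance(v, (float, np.floating))
                               else str(v) for v in row) + "\n")


def write_dx_grid(path, grid) -> None:
    """Write a SpatialDensityGrid as an OpenDX volumetric file."""
    nx, ny, nz = grid.density.shape
    o = grid.origin
    s = grid.spacing
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}\n")
        fh.write(f"delta {s:.6f} 0 0\ndelta 0 {s:.6f} 0\ndelta 0 0 {s:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {nx * ny * nz} "
                 "data follows\n")
        flat = grid.density.ravel()
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
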