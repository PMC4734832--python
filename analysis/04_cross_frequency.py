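#!/usr/bin/env python
"""Theta-gamma comodulograms with surrogate z-scores: coupled vs null.

Computes the normalized-entropy MI matrix and its 100-surrogate z-scores
for a strongly coupled synthetic signal (c = 0.8 at 8 Hz / 60 Hz) and for
an uncoupled control, writing both matrices as CSV. The coupled matrix
should peak at the generator's cell with a large z; the null matrix should
show no systematically significant cells.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mazelfp.crossfreq import BandGrid, surrogate_zscores
from mazelfp.synthetic import CouplingSpec, generate_coupled_process

FS = 1000.0


def _write(matrix, grid, path):
    pd.DataFrame(matrix, index=list(grid.amp_freqs), columns=list(grid.phase_freqs)).to_csv(path)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    grid = BandGrid()
    args.out.mkdir(parents=True, exist_ok=True)
    for name, c in (("coupled", 0.8), ("null", 0.0)):
        spec = CouplingSpec(coupling_strength=c, f_theta=8.0, f_gamma=60.0)
        x = generate_coupled_process(spec, 60.0, FS, seed=args.seed).samples[0]
        zc = surrogate_zscores(x, x, FS, grid, n_surrogates=100, seed=args.seed + 1)
        _write(zc.mi, grid, args.out / f"comodulogram_{name}.csv")
        _write(zc.z, grid, args.out / f"zscores_{name}.csv")
        a, p = np.unravel_index(int(np.argmax(zc.mi)), zc.mi.shape)
        print(
            f"{name} (c={c}): max MI {zc.mi[a, p]:.4f} at theta {grid.phase_freqs[p]:g} Hz / "
            f"gamma {grid.amp_freqs[a]:g} Hz, z there {zc.z[a, p]:.1f}; "
            f"{(np.abs(zc.z) > 1.96).mean() * 100:.1f}% of cells |z| > 1.96"
        )
    print(f"wrote MI and z matrices under {args.out}")


if __name__ == "__main__":
    main()
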