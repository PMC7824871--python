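"""Regenerate the bundled synthetic 1471-neuron reservoir template.

The reservoir places one neuron at the centre of each 1-cm^3 voxel of a
brain-sized volume.  The original atlas-derived coordinate list is not
redistributable, so this script builds a synthetic stand-in: centres of a
10 mm grid that fall inside a brain-shaped ellipsoid (semi-axes 70 x 85 x
62 mm, centred 5 mm above the axial origin), trimmed to exactly 1471 points
by keeping those with the smallest ellipsoidal norm.

Deterministic; writes src/arisnn/data/talairach_1471_synthetic.csv.
"""
from __future__ import annotations

import pathlib

import numpy as np

N_NEURONS = 1471
SEMI_AXES = np.array([70.0, 85.0, 62.0])
CENTER = np.array([0.0, 0.0, 5.0])


def build_coords() -> np.ndarray:
    # voxel centres at odd multiples of 5 mm, covering the ellipsoid
    axis = np.arange(-95.0, 100.0, 10.0)
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    norm = np.sum(((pts - CENTER) / SEMI_AXES) ** 2, axis=1)
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], norm))
    inside = order[norm[order] <= 1.0 + 1e-12]
    if inside.size < N_NEURONS:
        raise RuntimeError(f"ellipsoid too small: {inside.size} voxels")
    return pts[np.sort(inside[:N_NEURONS])]


def main() -> None:
    coords = build_coords()
    out = (
        pathlib.Path(__file__).resolve().parents[1]
        / "src"
        / "arisnn"
        / "data"
        / "talairach_1471_synthetic.csv"
    )
    with out.open("w") as fh:
        fh.write("x,y,z\n")
        for x, y, z in coords:
            fh.write(f"{x:.1f},{y:.1f},{z:.1f}\n")
    print(f"wrote {out} ({len(coords)} neurons)")


if __name__ == "__main__":
    main()
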