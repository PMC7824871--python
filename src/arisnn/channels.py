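"""Canonical 64-channel montage: labels, 3D positions, and scalp-site grouping.

The recording montage is the 64-channel BioSemi layout with extended 10/20
names.  Channel order below is canonical throughout the package; files read
from disk are reordered to it.
"""
from __future__ import annotations

import re
from functools import lru_cache

import numpy as np

#: Canonical channel order (BioSemi 64, extended 10/20 names).
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

#: The eight temporal-region electrodes analysed for responder/non-responder
#: weight changes.
TEMPORAL_CHANNELS: tuple[str, ...] = (
    "F7", "F8", "FT7", "FT8", "T7", "T8", "TP7", "TP8",
)

SITES: tuple[str, ...] = (
    "frontal", "temporal", "frontocentral", "centroparietal", "occipitoparietal",
)

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(\d+)$")

# prefix -> site for lateral channels outside the fixed temporal set; order
# matters (two-letter prefixes must win over their one-letter heads)
_PREFIX_SITES = (
    ("Fp", "frontal"),
    ("AF", "frontal"),
    ("FT", "temporal"),
    ("FC", "frontocentral"),
    ("CP", "centroparietal"),
    ("PO", "occipitoparietal"),
    ("TP", "temporal"),
    ("F", "frontal"),
    ("C", "frontocentral"),
    ("P", "centroparietal"),
    ("O", "occipitoparietal"),
    ("T", "temporal"),
)


def site_of(label: str) -> tuple[str, str] | None:
    """Return ``(hemisphere, site)`` for a lateral channel, ``None`` for midline.

    Hemisphere follows 10/20 parity (odd = left, even = right).  The eight
    temporal electrodes are a fixed set; remaining lateral channels are
    assigned by label prefix.  Unknown labels raise ``ValueError``.
    """
    if label.endswith("z"):
        return None
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"unrecognized channel label: {label!r}")
    prefix, num = m.group(1), int(m.group(2))
    hemisphere = "left" if num % 2 == 1 else "right"
    if label in TEMPORAL_CHANNELS:
        return hemisphere, "temporal"
    for p, site in _PREFIX_SITES:
        if prefix == p:
            return hemisphere, site
    raise ValueError(f"unrecognized channel label: {label!r}")


@lru_cache(maxsize=1)
def electrode_positions_mm() -> dict[str, np.ndarray]:
    """3D electrode positions (mm, head frame: +x right, +y anterior, +z up).

    Taken from the standard BioSemi-64 montage shipped with :mod:`mne` and
    converted from metres to millimetres.
    """
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    pos = montage.get_positions()["ch_pos"]
    out = {}
    for label in CHANNELS_64:
        if label not in pos:
            raise KeyError(f"electrode {label!r} missing from montage")
        out[label] = np.asarray(pos[label], dtype=float) * 1000.0
    return out


def fit_electrodes_to_extent(
    electrodes: dict[str, np.ndarray], coords: np.ndarray
) -> dict[str, np.ndarray]:
    """Affine-rescale an electrode cloud onto the extent of a coordinate set.

    Centres the electrode cloud on the centroid of ``coords`` and scales each
    axis so the electrode half-ranges match the coordinate half-ranges.  Used
    to place scalp electrodes over a reservoir template whose coordinates are
    in a different frame/scale; nearest-neighbour mapping then operates in the
    template frame.
    """
    labels = list(electrodes)
    elec = np.array([electrodes[c] for c in labels], dtype=float)
    e_center = (elec.max(axis=0) + elec.min(axis=0)) / 2.0
    e_half = (elec.max(axis=0) - elec.min(axis=0)) / 2.0
    t_center = (coords.max(axis=0) + coords.min(axis=0)) / 2.0
    t_half = (coords.max(axis=0) - coords.min(axis=0)) / 2.0
    scale = np.where(e_half > 0, t_half / np.where(e_half > 0, e_half, 1.0), 1.0)
    fitted = (elec - e_center) * scale + t_center
    return {c: fitted[i] for i, c in enumerate(labels)}
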