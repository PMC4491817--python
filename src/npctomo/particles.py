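"""Per-particle metadata tables.

A particle table is a pandas ``DataFrame`` with one row per particle and the
columns below; it is serialized as UTF-8 TSV.  ``phi/theta/psi/dx/dy/dz``
describe the rigid transform that maps the raw particle volume into the
current reference frame (see :mod:`npctomo.transforms` for the convention).

Columns
-------
particle_id : int        unique id
tomo_id : int            source tomogram id
x, y, z : float          particle position in the tomogram (voxels)
phi, theta, psi : float  Euler angles (degrees, intrinsic Z-X-Z)
dx, dy, dz : float       translation (voxels)
keep : bool              particle still in play
reason : str             exclusion reason code ("" while kept)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .transforms import RigidTransform

PARTICLE_COLUMNS = [
    "particle_id", "tomo_id", "x", "y", "z",
    "phi", "theta", "psi", "dx", "dy", "dz", "keep", "reason",
]

#: exclusion reason codes are exhaustive and mutually exclusive per particle
REASON_CODES = ("angle_at_limit", "normal_mismatch", "view_balance", "boundary")


def new_particle_table(n: int = 0) -> pd.DataFrame:
    """Empty table with *n* default rows (identity transforms, keep=True)."""
    return pd.DataFrame({
        "particle_id": np.arange(n, dtype=int),
        "tomo_id": np.zeros(n, dtype=int),
        "x": np.zeros(n), "y": np.zeros(n), "z": np.zeros(n),
        "phi": np.zeros(n), "theta": np.zeros(n), "psi": np.zeros(n),
        "dx": np.zeros(n), "dy": np.zeros(n), "dz": np.zeros(n),
        "keep": np.ones(n, dtype=bool),
        "reason": [""] * n,
    })


def transform_of(row) -> RigidTransform:
    return RigidTransform(row["phi"], row["theta"], row["psi"],
                          (row["dx"], row["dy"], row["dz"]))


def set_transform(table: pd.DataFrame, index, t: RigidTransform) -> None:
    table.loc[index, ["phi", "theta", "psi"]] = [t.phi, t.theta, t.psi]
    table.loc[index, ["dx", "dy", "dz"]] = list(t.shift)


def write_particles(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_particles(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in PARTICLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"particle table missing columns: {missing}")
    table["keep"] = table["keep"].astype(bool)
    table["reason"] = table["reason"].fillna("").astype(str)
    return table
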