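"""Particle metadata tables (plain TSV with a named-column header).

Columns: stack_index, defocus_A, diameter_A, pixel_size_A, euler_phi,
euler_theta, euler_psi (radians, ZYZ intrinsic), voltage_kev, cs_A.
Defocus may be supplied in micrometres via a ``defocus_um`` column instead;
it is converted and stored internally in Angstrom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

REQUIRED_COLUMNS = (
    "stack_index",
    "defocus_A",
    "diameter_A",
    "pixel_size_A",
    "euler_phi",
    "euler_theta",
    "euler_psi",
    "voltage_kev",
    "cs_A",
)

_POSITIVE = ("defocus_A", "diameter_A", "pixel_size_A", "voltage_kev")


def validate_particle_table(table: pd.DataFrame) -> pd.DataFrame:
    """Normalise and sanity-check a particle table (returns a copy)."""
    df = table.copy()
    if "defocus_A" not in df.columns and "defocus_um" in df.columns:
        df["defocus_A"] = df.pop("defocus_um") * 1e4
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"particle table is missing column(s): {', '.join(missing)}")
    for col in _POSITIVE:
        if (df[col] <= 0).any():
            raise ValueError(f"column {col} must be strictly positive")
    if (df["cs_A"] < 0).any():
        raise ValueError("column cs_A must be non-negative")
    if df["stack_index"].duplicated().any():
        raise ValueError("stack_index values must be unique")
    return df[list(REQUIRED_COLUMNS)]


def read_particle_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_particle_table(df)


def write_particle_table(table: pd.DataFrame, path) -> None:
    validate_particle_table(table).to_csv(path, sep="\t", index=False)


def euler_to_matrix(phi: float, theta: float, psi: float) -> np.ndarray:
    """ZYZ intrinsic Euler angles (radians) -> rotation matrix."""
    return Rotation.from_euler("ZYZ", [phi, theta, psi]).as_matrix()


def matrix_to_euler(rot: np.ndarray):
    """Rotation matrix -> ZYZ intrinsic Euler angles (radians)."""
    phi, theta, psi = Rotation.from_matrix(np.asarray(rot)).as_euler("ZYZ")
    return float(phi), float(theta), float(psi)


def records_from_table(table: pd.DataFrame):
    """Particle table -> list of :class:`ssbctf.reconstruct.ParticleRecord`."""
    from .reconstruct import ParticleRecord

    df = validate_particle_table(table)
    records = []
    for _, row in df.iterrows():
        records.append(
            ParticleRecord(
                defocus=float(row["defocus_A"]),
                orientation=euler_to_matrix(
                    row["euler_phi"], row["euler_theta"], row["euler_psi"]
                ),
                diameter=float(row["diameter_A"]),
                pixel_size=float(row["pixel_size_A"]),
                stack_index=int(row["stack_index"]),
            )
        )
    return records


def table_from_records(records, voltage_kev: float, cs: float = 0.0) -> pd.DataFrame:
    rows = []
    for rec in records:
        phi, theta, psi = matrix_to_euler(rec.orientation)
        rows.append(
            {
                "stack_index": rec.stack_index,
                "defocus_A": rec.defocus,
                "diameter_A": rec.diameter,
                "pixel_size_A": rec.pixel_size,
                "euler_phi": phi,
                "euler_theta": theta,
                "euler_psi": psi,
                "voltage_kev": voltage_kev,
                "cs_A": cs,
            }
        )
    return pd.DataFrame(rows)
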