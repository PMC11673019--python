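"""File formats: cohort/peak/modulus/accuracy CSVs, VTK export, YAML config.

Cohorts are stored as a long-format measurement table (one row per
``eye_id, frequency_hz, weighted_displacement``) plus a sidecar label
table (``eye_id, species, group, stage, location``).  FEM fields export
to legacy ASCII VTK (biquadratic quadrilateral cells) and flat CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fem import DeflectionField
from .localization import FrequencyScanResult
from .spectra import ResonantPeak, VibrationalSpectrum

__all__ = [
    "cohort_to_frames",
    "frames_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "peaks_to_frame",
    "curve_to_frame",
    "write_vtk",
    "field_to_frame",
    "load_yaml",
    "dump_yaml",
]


def cohort_to_frames(
    cohort: list[VibrationalSpectrum],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long measurement table + sidecar label table for a cohort."""
    meas = pd.DataFrame(
        {
            "eye_id": np.repeat(
                [s.eye_id for s in cohort], [s.frequencies.size for s in cohort]
            ),
            "frequency_hz": np.concatenate([s.frequencies for s in cohort]),
            "weighted_displacement": np.concatenate(
                [s.displacements for s in cohort]
            ),
        }
    )
    labels = pd.DataFrame(
        {
            "eye_id": [s.eye_id for s in cohort],
            "species": [s.species for s in cohort],
            "group": [s.group for s in cohort],
            "stage": [s.stage if s.stage is not None else "" for s in cohort],
            "location": [s.location for s in cohort],
            "normalization_state": [s.normalization_state for s in cohort],
        }
    )
    return meas, labels


def frames_to_cohort(
    meas: pd.DataFrame, labels: pd.DataFrame
) -> list[VibrationalSpectrum]:
    """Inverse of :func:`cohort_to_frames`, preserving eye order."""
    lab = labels.set_index("eye_id")
    cohort = []
    for eye_id in labels["eye_id"]:
        sub = meas[meas["eye_id"] == eye_id].sort_values("frequency_hz")
        row = lab.loc[eye_id]
        stage = row["stage"]
        stage = None if stage in ("", None) or pd.isna(stage) else int(float(stage))
        cohort.append(
            VibrationalSpectrum(
                sub["frequency_hz"].to_numpy(),
                sub["weighted_displacement"].to_numpy(),
                eye_id=str(eye_id),
                species=str(row["species"]),
                group=str(row["group"]),
                stage=stage,
                location=str(row["location"]),
                normalization_state=str(row.get("normalization_state", "raw")),
            )
        )
    return cohort


def write_cohort_csv(
    cohort: list[VibrationalSpectrum], measurements_path, labels_path
) -> None:
    meas, labels = cohort_to_frames(cohort)
    meas.to_csv(measurements_path, index=False)
    labels.to_csv(labels_path, index=False)


def read_cohort_csv(measurements_path, labels_path) -> list[VibrationalSpectrum]:
    meas = pd.read_csv(measurements_path)
    labels = pd.read_csv(labels_path, keep_default_na=False)
    return frames_to_cohort(meas, labels)


def peaks_to_frame(peaks_by_eye: dict[str, list[ResonantPeak]]) -> pd.DataFrame:
    rows = [
        {"eye_id": eye, "frequency_hz": p.frequency, "height": p.height, "band": p.band}
        for eye, plist in peaks_by_eye.items()
        for p in plist
    ]
    return pd.DataFrame(rows, columns=["eye_id", "frequency_hz", "height", "band"])


def curve_to_frame(curve: list[FrequencyScanResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frequency_hz": [r.frequency for r in curve],
            "mean_accuracy": [r.mean_accuracy for r in curve],
            "accuracy_sd": [r.accuracy_sd for r in curve],
            "method": [r.method for r in curve],
        }
    )


# VTK legacy cell type 28 = biquadratic quadrilateral; node order: corners,
# edge midpoints, centre.
_VTK_Q9_ORDER = [0, 2, 8, 6, 1, 5, 7, 3, 4]


def write_vtk(field: DeflectionField, path) -> None:
    """Legacy ASCII VTK unstructured grid with nodal displacement vectors
    and the axial deflection map."""
    mesh = field.mesh
    lines = [
        "# vtk DataFile Version 3.0",
        "axisymmetric corneal deflection field (r-z meridian section)",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [f"{r:.9e} {z:.9e} 0.0" for r, z in mesh.nodes]
    lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * 10}")
    for elem in mesh.elements:
        ordered = " ".join(str(elem[k]) for k in _VTK_Q9_ORDER)
        lines.append(f"9 {ordered}")
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines += ["28"] * mesh.n_elements
    lines.append(f"POINT_DATA {mesh.n_nodes}")
    lines.append("VECTORS displacement double")
    lines += [f"{u:.9e} {w:.9e} 0.0" for u, w in field.displacement]
    lines.append("SCALARS axial_deflection double 1")
    lines.append("LOOKUP_TABLE default")
    lines += [f"{v:.9e}" for v in field.axial_deflection]
    Path(path).write_text("\n".join(lines) + "\n")


def field_to_frame(field: DeflectionField) -> pd.DataFrame:
    mesh = field.mesh
    return pd.DataFrame(
        {
            "r_m": mesh.nodes[:, 0],
            "z_m": mesh.nodes[:, 1],
            "u_r_m": field.displacement[:, 0],
            "u_z_m": field.displacement[:, 1],
            "magnitude_m": field.magnitude,
            "axial_deflection_m": field.axial_deflection,
        }
    )


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
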