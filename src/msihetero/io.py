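"""Readers and writers for the plain-text interchange formats.

Datacubes travel as TSV with columns ``patient_id, x, y, mz_<value>...``;
metadata, labels, compositions and results are plain TSV/JSON. imzML input
is supported when ``pyimzml`` is installed (optional dependency).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from msihetero.types import PatientDatacube, SurvivalRecord, derive_response

MZ_PREFIX = "mz_"


def write_datacubes_tsv(cubes: Sequence[PatientDatacube], path: str) -> None:
    frames = []
    for cube in cubes:
        df = pd.DataFrame(
            cube.intensities,
            columns=[f"{MZ_PREFIX}{mz:.6f}" for mz in cube.channels],
        )
        df.insert(0, "y", cube.coords[:, 1])
        df.insert(0, "x", cube.coords[:, 0])
        df.insert(0, "patient_id", cube.patient_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_datacubes_tsv(path: str) -> list[PatientDatacube]:
    df = pd.read_csv(path, sep="\t")
    mz_cols = [c for c in df.columns if c.startswith(MZ_PREFIX)]
    if not mz_cols:
        raise ValueError(f"no {MZ_PREFIX}* intensity columns in {path}")
    channels = np.array([float(c[len(MZ_PREFIX):]) for c in mz_cols])
    order = np.argsort(channels)
    channels = channels[order]
    cubes = []
    for pid, grp in df.groupby("patient_id", sort=True):
        coords = grp[["x", "y"]].to_numpy(dtype=int)
        inten = grp[mz_cols].to_numpy(dtype=float)[:, order]
        cube = PatientDatacube(str(pid), coords, channels, inten)
        cube.validate()
        cubes.append(cube)
    return cubes


def write_survival_tsv(records: Sequence[SurvivalRecord], path: str) -> None:
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "time_months": [r.time for r in records],
            "event": [r.event for r in records],
            "response": [r.response for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_survival_tsv(path: str, response_cutoff: float = 13.8) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        if "response" in df.columns and not pd.isna(row["response"]):
            resp = int(row["response"])
        else:
            resp = derive_response(float(row["time_months"]), int(row["event"]), response_cutoff)
        records.append(
            SurvivalRecord(str(row["patient_id"]), float(row["time_months"]), int(row["event"]), resp)
        )
    return records


def write_labels_tsv(
    labels_by_k: dict[int, dict[str, np.ndarray]],
    coords: dict[str, np.ndarray],
    path: str,
) -> None:
    """Per-pixel label maps, one column per K: patient_id, x, y, label_K<k>..."""
    ks = sorted(labels_by_k)
    rows = []
    for pid in sorted(coords):
        xy = coords[pid]
        block = {"patient_id": pid, "x": xy[:, 0], "y": xy[:, 1]}
        for k in ks:
            block[f"label_K{k}"] = labels_by_k[k][pid]
        rows.append(pd.DataFrame(block))
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_labels_tsv(path: str, k: int) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    col = f"label_K{k}"
    if col not in df.columns:
        raise ValueError(f"{path} has no column {col}")
    return {
        str(pid): grp[col].to_numpy(dtype=int) for pid, grp in df.groupby("patient_id", sort=True)
    }


def read_mass_table(path: str) -> pd.DataFrame:
    """Metabolite table: columns ``id``, optional ``formula``, ``monoisotopic_mass``.

    If the mass column is absent it is computed from the formula.
    """
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise ValueError(f"mass table {path} lacks an 'id' column")
    if "monoisotopic_mass" not in df.columns:
        if "formula" not in df.columns:
            raise ValueError(f"mass table {path} needs 'monoisotopic_mass' or 'formula'")
        from msihetero.annotation import monoisotopic_mass

        df["monoisotopic_mass"] = df["formula"].map(monoisotopic_mass)
    if not np.all(df["monoisotopic_mass"] > 0):
        raise ValueError("monoisotopic masses must be positive")
    return df


def read_gmt(path: str) -> dict[str, set[str]]:
    """GMT pathway sets: name <tab> description <tab> member..."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            pathways[parts[0]] = {m for m in parts[2:] if m}
    return pathways


def read_imzml(path: str) -> PatientDatacube:  # pragma: no cover - optional dep
    """Read an imzML file (continuous or processed mode) as one datacube.

    Processed-mode per-pixel m/z axes are binned onto the axis of the first
    pixel by nearest channel. Requires the optional ``pyimzml`` package.
    """
    try:
        from pyimzml.ImzMLParser import ImzMLParser
    except ImportError as exc:
        raise ImportError(
            "reading imzML requires the optional 'pyimzml' package"
        ) from exc
    parser = ImzMLParser(path)
    mzs0, _ = parser.getspectrum(0)
    channels = np.asarray(mzs0, dtype=float)
    coords = []
    inten = np.zeros((len(parser.coordinates), channels.size))
    for i, (x, y, *_z) in enumerate(parser.coordinates):
        mzs, ints = parser.getspectrum(i)
        mzs = np.asarray(mzs, dtype=float)
        ints = np.asarray(ints, dtype=float)
        if mzs.shape == channels.shape and np.allclose(mzs, channels):
            inten[i] = ints
        else:  # processed mode: nearest-channel binning
            idx = np.clip(np.searchsorted(channels, mzs), 0, channels.size - 1)
            left = np.clip(idx - 1, 0, channels.size - 1)
            idx = np.where(
                np.abs(channels[left] - mzs) < np.abs(channels[idx] - mzs), left, idx
            )
            np.add.at(inten[i], idx, ints)
        coords.append((int(x) - 1, int(y) - 1))  # imzML coordinates are 1-based
    pid = os.path.splitext(os.path.basename(path))[0]
    cube = PatientDatacube(pid, np.array(coords), channels, inten)
    cube.validate()
    return cube


def read_cohort_dir(path: str) -> list[PatientDatacube]:
    """Read every pixel-format TSV (and imzML, if readable) in a directory."""
    cubes: list[PatientDatacube] = []
    for name in sorted(os.listdir(path)):
        full = os.path.join(path, name)
        if name.endswith(".tsv") and "pixel" in name:
            cubes.extend(read_datacubes_tsv(full))
        elif name.endswith(".imzML"):
            cubes.append(read_imzml(full))
    if not cubes:
        raise ValueError(f"no pixel TSV or imzML files found in {path}")
    return cubes


def write_truth_tsv(cohort, path_labels: str, path_composition: str) -> None:
    rows = []
    for cube in cohort.datacubes:
        lab = cohort.truth_labels[cube.patient_id]
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": cube.patient_id,
                    "x": cube.coords[:, 0],
                    "y": cube.coords[:, 1],
                    "subpop": lab,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path_labels, sep="\t", index=False)
    comp = pd.DataFrame(
        cohort.truth_composition,
        columns=[f"share_{i + 1}" for i in range(cohort.truth_composition.shape[1])],
    )
    comp.insert(0, "patient_id", cohort.patient_ids)
    comp.to_csv(path_composition, sep="\t", index=False)
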