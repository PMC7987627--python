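"""Cumulative dose-volume histograms and the mean absolute dose deviation.

A cumulative DVH gives, for each dose level ``D``, the structure volume
receiving at least ``D``.  The mean absolute dose deviation (MADD) of a
structure against a reference dose ``A`` is the volume-weighted mean of
``|D - A|``:

    M = (1/V0) * integral_0^V0 |D - A| dV

computed here by rectangular strips on the tabulated DVH points: each point
``j`` (except the last) contributes the volume step ``dV_j = V_j - V_{j+1}``
at dose ``D_j``; the terminal point carries its whole remaining volume at the
maximum tabulated dose.  With ``A = 0`` the MADD reduces to the mean dose;
for a target volume ``A`` is the prescription and the MADD measures coverage
deviation in either direction.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, TextIO

import numpy as np
import pandas as pd

from .errors import (
    DegenerateStructureError,
    InvalidDVHError,
    UnitError,
)

GY = "Gy"
PERCENT = "percent"
ML = "mL"
FRACTION = "fraction"

#: canonical structure names used throughout the pipeline
STRUCTURES = (
    "heart",
    "lung_right",
    "lung_left",
    "tumor_bed",
    "breast_left",
    "breast_right",
    "body",
)

#: role of each structure for a left-sided breast treatment: the ipsilateral
#: breast and tumor bed are targets (reference dose = prescription), all other
#: structures are organs at risk or the external contour (reference dose = 0).
STRUCTURE_ROLES: Mapping[str, str] = {
    "heart": "OAR",
    "lung_right": "OAR",
    "lung_left": "OAR",
    "tumor_bed": "PTV",
    "breast_left": "PTV",
    "breast_right": "OAR",
    "body": "BODY",
}

_V0_RELTOL = 1e-6


@dataclass(frozen=True)
class ReferenceDose:
    """Reference dose A for a MADD: 0 for an OAR / body, the prescription for a PTV."""

    value: float
    dose_unit: str = PERCENT

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"reference dose must be >= 0, got {self.value}")


def reference_for_role(role: str, prescribed: float = 100.0) -> ReferenceDose:
    """Reference dose by structure role: prescription for PTV, zero otherwise."""
    if role == "PTV":
        return ReferenceDose(prescribed)
    return ReferenceDose(0.0)


@dataclass(frozen=True)
class StructureDVH:
    """One structure's cumulative dose-volume curve.

    ``doses`` are strictly increasing, ``volumes`` non-increasing, and the
    first volume equals the total structure volume ``total_volume`` (the whole
    structure receives at least the lowest tabulated dose).
    """

    structure_name: str
    role: str
    doses: np.ndarray
    volumes: np.ndarray
    total_volume: float
    dose_unit: str = PERCENT
    volume_unit: str = FRACTION

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "volumes", v)
        if self.role not in ("OAR", "PTV", "BODY"):
            raise InvalidDVHError(f"unknown role {self.role!r}")
        if d.ndim != 1 or v.ndim != 1 or d.size != v.size or d.size == 0:
            raise InvalidDVHError("doses and volumes must be equal-length 1-D arrays")
        if np.any(d < 0) or np.any(v < 0):
            raise InvalidDVHError("doses and volumes must be non-negative")
        if np.any(np.diff(d) <= 0):
            raise InvalidDVHError("doses must be strictly increasing")
        if np.any(np.diff(v) > 0):
            raise InvalidDVHError("cumulative volumes must be non-increasing")
        v0 = float(self.total_volume)
        if v0 < 0:
            raise InvalidDVHError("total volume must be non-negative")
        if v0 > 0 and abs(v[0] - v0) > _V0_RELTOL * v0:
            raise InvalidDVHError(
                f"first cumulative volume {v[0]} does not match V0={v0} "
                "(use StructureDVH.from_points to normalize truncated exports)"
            )

    @classmethod
    def from_points(
        cls,
        structure_name: str,
        doses: Iterable[float],
        volumes: Iterable[float],
        *,
        role: str | None = None,
        total_volume: float | None = None,
        dose_unit: str = PERCENT,
        volume_unit: str = FRACTION,
    ) -> "StructureDVH":
        """Build a DVH from raw export points, normalizing common defects.

        Duplicate dose rows are merged keeping the smaller cumulative volume
        (cumulative DVHs are step functions and exports sometimes repeat a
        dose).  If the first tabulated volume is below ``total_volume`` the
        curve is anchored by prepending ``(0, V0)``, since a cumulative DVH
        equals V0 at dose 0 by definition.
        """
        d = np.asarray(list(doses), dtype=float)
        v = np.asarray(list(volumes), dtype=float)
        if d.size == 0:
            raise InvalidDVHError("empty DVH")
        order = np.argsort(d, kind="stable")
        d, v = d[order], v[order]
        # merge duplicate doses keeping the smaller volume
        keep_d, keep_v = [], []
        for di, vi in zip(d, v):
            if keep_d and di == keep_d[-1]:
                keep_v[-1] = min(keep_v[-1], vi)
            else:
                keep_d.append(di)
                keep_v.append(vi)
        d, v = np.asarray(keep_d), np.asarray(keep_v)
        if role is None:
            role = STRUCTURE_ROLES.get(structure_name, "OAR")
        if total_volume is None:
            total_volume = float(v[0])
        if total_volume > 0 and v[0] < total_volume * (1 - _V0_RELTOL) :
            if d[0] > 0:
                d = np.concatenate([[0.0], d])
                v = np.concatenate([[total_volume], v])
            else:
                v = v.copy()
                v[0] = total_volume
        return cls(
            structure_name=structure_name,
            role=role,
            doses=d,
            volumes=v,
            total_volume=float(total_volume),
            dose_unit=dose_unit,
            volume_unit=volume_unit,
        )

    @property
    def n_points(self) -> int:
        return int(self.doses.size)


def to_relative(dvh: StructureDVH, prescribed_dose: float) -> StructureDVH:
    """Convert a DVH from absolute dose (Gy) to percent of the prescription."""
    if prescribed_dose <= 0:
        raise ValueError(f"prescribed dose must be positive, got {prescribed_dose}")
    if dvh.dose_unit != GY:
        raise UnitError(f"expected a DVH in Gy, got {dvh.dose_unit!r}")
    return replace(dvh, doses=100.0 * dvh.doses / prescribed_dose, dose_unit=PERCENT)


def to_absolute(dvh: StructureDVH, prescribed_dose: float) -> StructureDVH:
    """Inverse of :func:`to_relative`: percent of prescription back to Gy."""
    if prescribed_dose <= 0:
        raise ValueError(f"prescribed dose must be positive, got {prescribed_dose}")
    if dvh.dose_unit != PERCENT:
        raise UnitError(f"expected a DVH in percent, got {dvh.dose_unit!r}")
    return replace(dvh, doses=dvh.doses * prescribed_dose / 100.0, dose_unit=GY)


def differential_volumes(dvh: StructureDVH) -> tuple[np.ndarray, np.ndarray]:
    """Rectangular volume strips (D_j, dV_j) of a cumulative DVH.

    For points ``j = 1..n-1`` the strip is ``dV_j = V_j - V_{j+1}`` anchored at
    ``D_j`` (no interpolation beyond tabulated doses); the last point carries
    its remaining volume ``V_n`` at ``D_n``.  The strips conserve volume:
    ``sum(dV) == V0``.
    """
    v = dvh.volumes
    dv = np.empty_like(v)
    dv[:-1] = v[:-1] - v[1:]
    dv[-1] = v[-1]
    return dvh.doses, dv


def madd(dvh: StructureDVH, ref: ReferenceDose) -> float:
    """Mean absolute dose deviation of a structure against reference dose A.

    Discrete form ``sum_j |D_j - A| * dV_j / V0`` over the rectangular strips
    of :func:`differential_volumes`.  The result shares the DVH's dose unit
    and is independent of the volume unit.
    """
    if ref.dose_unit != dvh.dose_unit:
        raise UnitError(
            f"reference dose unit {ref.dose_unit!r} does not match DVH unit {dvh.dose_unit!r}"
        )
    if dvh.total_volume <= 0:
        raise DegenerateStructureError(
            f"structure {dvh.structure_name!r} has zero volume"
        )
    doses, dv = differential_volumes(dvh)
    return float(np.sum(np.abs(doses - ref.value) * dv) / dvh.total_volume)


def mean_dose(dvh: StructureDVH) -> float:
    """DVH-derived mean dose (the MADD against a zero reference)."""
    return madd(dvh, ReferenceDose(0.0, dvh.dose_unit))


def madd_for_structure(dvh: StructureDVH, prescribed: float = 100.0) -> float:
    """MADD using the role-appropriate reference (prescription for PTVs, 0 else)."""
    ref = reference_for_role(dvh.role, prescribed)
    return madd(dvh, replace(ref, dose_unit=dvh.dose_unit))


# ---------------------------------------------------------------------------
# DVH cohort table I/O
# ---------------------------------------------------------------------------

DVH_CSV_COLUMNS = ["patient_id", "setup", "structure", "dose", "volume"]
SETUPS = ("prone", "supine")


def dvhs_to_frame(dvhs: Mapping[tuple[str, str], Mapping[str, StructureDVH]]) -> pd.DataFrame:
    """Flatten a {(patient_id, setup): {structure: DVH}} mapping to a long table."""
    parts = []
    for (pid, setup), structs in dvhs.items():
        for name, dvh in structs.items():
            parts.append(
                pd.DataFrame(
                    {
                        "patient_id": pid,
                        "setup": setup,
                        "structure": name,
                        "dose": dvh.doses,
                        "volume": dvh.volumes,
                    }
                )
            )
    return pd.concat(parts, ignore_index=True)


def write_dvh_csv(
    dvhs: Mapping[tuple[str, str], Mapping[str, StructureDVH]],
    path,
    dose_unit: str = PERCENT,
) -> None:
    """Write the cohort DVH table with its dose-unit metadata line."""
    frame = dvhs_to_frame(dvhs)
    with open(path, "w") as fh:
        fh.write(f"# dose_unit={dose_unit}\n")
        frame.to_csv(fh, index=False)


def read_dvh_csv(path) -> tuple[dict[tuple[str, str], dict[str, StructureDVH]], str]:
    """Read a cohort DVH table; returns ({(patient, setup): {structure: DVH}}, dose_unit).

    The file carries a ``# dose_unit=Gy|percent`` metadata line before the
    header; rows are grouped per structure with dose ascending.
    """
    dose_unit = PERCENT
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("#"):
            m = re.search(r"dose_unit\s*=\s*(\w+)", line)
            if m:
                dose_unit = m.group(1)
        else:
            break
    frame = pd.read_csv(io.StringIO(text), comment="#")
    missing = set(DVH_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise InvalidDVHError(f"DVH CSV missing columns: {sorted(missing)}")
    out: dict[tuple[str, str], dict[str, StructureDVH]] = {}
    for (pid, setup, structure), grp in frame.groupby(
        ["patient_id", "setup", "structure"], sort=False
    ):
        dvh = StructureDVH.from_points(
            str(structure),
            grp["dose"].to_numpy(),
            grp["volume"].to_numpy(),
            dose_unit=dose_unit,
        )
        out.setdefault((pid, str(setup)), {})[str(structure)] = dvh
    return out, dose_unit


_TPS_STRUCTURE_RE = re.compile(r"^\s*Structure\s*:\s*(.+?)\s*$", re.IGNORECASE)
_TPS_NUMBER_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def read_tps_export(
    source: TextIO | str,
    dose_unit: str = GY,
) -> dict[str, StructureDVH]:
    """Parse a treatment-planning-system DVH text export.

    Expects blocks introduced by ``Structure: <name>`` followed by a
    two-column dose/volume table; other header lines are skipped.  Volume
    columns may be absolute (mL) or relative (% / fraction); relative
    percentage columns (first value near 100) are rescaled to fractions.
    """
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = source.read().splitlines()
    blocks: dict[str, list[tuple[float, float]]] = {}
    current: str | None = None
    for line in lines:
        m = _TPS_STRUCTURE_RE.match(line)
        if m:
            current = m.group(1)
            blocks[current] = []
            continue
        if current is None:
            continue
        nums = _TPS_NUMBER_RE.findall(line)
        if len(nums) >= 2 and not re.search(r"[A-Za-z]{3,}", line):
            blocks[current].append((float(nums[0]), float(nums[1])))
    out = {}
    for name, pts in blocks.items():
        if not pts:
            continue
        d = [p[0] for p in pts]
        v = [p[1] for p in pts]
        volume_unit = ML
        if v[0] <= 1.0 + 1e-9:
            volume_unit = FRACTION
        elif 95.0 <= v[0] <= 105.0 and max(v) <= 105.0:
            # relative percentage column
            v = [x / 100.0 for x in v]
            volume_unit = FRACTION
        out[name] = StructureDVH.from_points(
            name, d, v, dose_unit=dose_unit, volume_unit=volume_unit
        )
    return out
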