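"""Plan penalty scores: priority-weighted sums of structure MADDs.

A treatment plan is summarized by ``score = sum_i w_i * M_i`` where ``M_i``
is the MADD of structure ``i`` (percent of prescribed dose) and the weights
``w_i`` sum to 1, so the score is a convex combination — a weighted average
of all OAR and PTV dose deviations, on the same scale as the dose
prescription.  Named weight sets ("priority types") express clinical
emphasis: heart sparing, lung sparing, target coverage, or whole-body low
dose.  The body external contour contains the OARs and PTVs, so it carries
weight 0 in every priority type except the dedicated ``body`` type (where it
flags integral-dose / second-cancer concern); giving it weight elsewhere
would doubly penalize the structures inside it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
import yaml

from .dvh import PERCENT, STRUCTURES, StructureDVH, madd_for_structure, to_relative
from .errors import ConfigError, MissingStructureError

logger = logging.getLogger(__name__)

_WEIGHT_SUM_TOL = 1e-9


@dataclass(frozen=True)
class WeightSet:
    """Named per-structure weights summing to 1."""

    name: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        w = dict(self.weights)
        object.__setattr__(self, "weights", w)
        if any(v < 0 for v in w.values()):
            raise ConfigError(f"weight set {self.name!r} has negative weights")
        total = sum(w.values())
        if abs(total - 1.0) > _WEIGHT_SUM_TOL:
            raise ConfigError(
                f"weights of {self.name!r} sum to {total!r}, expected 1"
            )

    @property
    def structures(self) -> list[str]:
        """Structures with strictly positive weight."""
        return [s for s, w in self.weights.items() if w > 0]


# Priority types.  Order of values: heart, right lung, left lung, tumor bed,
# left breast, right breast, body.  Type 1 encodes the ordinal priority
# heart > lungs > tumor bed > contralateral breast > ipsilateral breast used
# for low-risk breast treatment; the other four shift emphasis to a single
# clinical concern.
_BUILTIN_TABLE = {
    "type1": (0.40, 0.16, 0.14, 0.11, 0.09, 0.10, 0.0),
    "heart": (0.65, 0.08, 0.07, 0.10, 0.05, 0.05, 0.0),
    "lungs": (0.20, 0.30, 0.35, 0.07, 0.04, 0.04, 0.0),
    "ptvs": (0.15, 0.08, 0.07, 0.35, 0.30, 0.05, 0.0),
    "body": (0.10, 0.15, 0.15, 0.08, 0.07, 0.15, 0.30),
}
_BUILTIN_ORDER = (
    "heart",
    "lung_right",
    "lung_left",
    "tumor_bed",
    "breast_left",
    "breast_right",
    "body",
)

BUILTIN_WEIGHT_NAMES = tuple(_BUILTIN_TABLE)


def builtin_weights(name: str) -> WeightSet:
    """Return one of the five built-in priority types by name."""
    try:
        values = _BUILTIN_TABLE[name]
    except KeyError:
        raise KeyError(
            f"unknown weight set {name!r}; built-ins are {sorted(_BUILTIN_TABLE)}"
        ) from None
    return WeightSet(name, dict(zip(_BUILTIN_ORDER, values)))


def load_weight_set(path) -> WeightSet:
    """Load a user-defined weight set from a YAML or JSON config file."""
    with open(path) as fh:
        text = fh.read()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = json.loads(text)
    if not isinstance(data, dict) or "weights" not in data:
        raise ConfigError("weight-set file must define 'name' and 'weights'")
    return WeightSet(str(data.get("name", "custom")), dict(data["weights"]))


@dataclass(frozen=True)
class PlanPenalty:
    """Per-structure MADDs plus the weighted penalty score for one plan."""

    patient_id: str
    setup: str
    madds: Mapping[str, float]
    score: float
    weight_set_name: str


def penalty_score(
    madds: Mapping[str, float],
    ws: WeightSet,
    *,
    patient_id: str = "",
    setup: str = "",
    renormalize_missing: bool = False,
) -> PlanPenalty:
    """Weighted penalty score ``sum_i w_i * M_i`` for one plan.

    Every structure with positive weight must have a MADD; with
    ``renormalize_missing`` the weights of absent structures are dropped and
    the remainder rescaled to sum to 1 (logged), for exports that lost a
    contour.
    """
    weights = {s: w for s, w in ws.weights.items() if w > 0}
    missing = [s for s in weights if s not in madds or pd.isna(madds[s])]
    if missing:
        if not renormalize_missing:
            raise MissingStructureError(
                f"MADD missing for weighted structure(s) {missing} "
                f"under weight set {ws.name!r}"
            )
        logger.warning(
            "renormalizing weight set %r without structures %s", ws.name, missing
        )
        weights = {s: w for s, w in weights.items() if s not in missing}
        total = sum(weights.values())
        if total <= 0:
            raise MissingStructureError("all weighted structures missing")
        weights = {s: w / total for s, w in weights.items()}
    score = sum(w * float(madds[s]) for s, w in weights.items())
    return PlanPenalty(
        patient_id=patient_id,
        setup=setup,
        madds={s: float(madds[s]) for s in weights},
        score=float(score),
        weight_set_name=ws.name,
    )


def score_cohort(
    dvhs: Mapping[tuple[str, str], Mapping[str, StructureDVH]],
    weight_set: WeightSet,
    *,
    prescriptions: Mapping[str, float] | float | None = None,
    renormalize_missing: bool = False,
) -> pd.DataFrame:
    """Score every paired plan of a cohort under one weight set.

    ``dvhs`` maps (patient_id, setup) to per-structure DVHs.  DVHs in Gy are
    converted to percent of the prescription (a per-patient mapping or a
    single value) before MADD computation; all downstream math is in percent
    of prescribed dose.  Patients missing one of the two setups are excluded
    with a logged warning.  Returns one row per (patient, setup) with the
    score and the per-structure MADDs.
    """
    patients: dict[str, dict[str, Mapping[str, StructureDVH]]] = {}
    for (pid, setup), structs in dvhs.items():
        patients.setdefault(str(pid), {})[setup] = structs
    rows = []
    for pid in patients:
        setups = patients[pid]
        if not {"prone", "supine"} <= set(setups):
            logger.warning(
                "patient %s excluded: missing %s setup",
                pid,
                sorted({"prone", "supine"} - set(setups)),
            )
            continue
        for setup in ("supine", "prone"):
            structs = setups[setup]
            madds = {}
            for name, dvh in structs.items():
                if dvh.dose_unit != PERCENT:
                    if prescriptions is None:
                        raise ConfigError(
                            "DVHs are in Gy but no prescription was given"
                        )
                    rx = (
                        float(prescriptions)
                        if not isinstance(prescriptions, Mapping)
                        else float(prescriptions[pid])
                    )
                    dvh = to_relative(dvh, rx)
                madds[name] = madd_for_structure(dvh, prescribed=100.0)
            plan = penalty_score(
                madds,
                weight_set,
                patient_id=pid,
                setup=setup,
                renormalize_missing=renormalize_missing,
            )
            row = {
                "patient_id": pid,
                "setup": setup,
                "weight_set": weight_set.name,
                "score": plan.score,
            }
            row.update({f"{s}_madd": madds.get(s) for s in STRUCTURES})
            rows.append(row)
    return pd.DataFrame(rows)
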