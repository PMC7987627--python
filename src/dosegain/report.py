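"""Pipeline composition and report rendering.

Chains the stages — synthetic or external cohort, MADD/penalty scoring under
one or more priority weight sets, paired gain analysis with subgroup split,
and predictor screening — into a single reproducible run that writes
machine-readable outputs (CSV/JSON) plus optional charts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import gain as gain_mod
from . import predictors as pred_mod
from .cohort import CohortData, GeneratorConfig, generate_cohort
from .dvh import StructureDVH
from .errors import ConfigError, EmptySubgroupError
from .penalty import BUILTIN_WEIGHT_NAMES, builtin_weights, score_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "results/pipeline"
    weight_sets: Sequence[str] = BUILTIN_WEIGHT_NAMES
    split_at: float = 2.0  # supine-penalty threshold of the subgroup split
    alpha: float = 0.05
    level: float = 0.95
    exclude_outliers: Sequence[str] = ()
    seed: int = 12345
    n_patients: int = 116
    charts: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 0.5:
            raise ConfigError(f"alpha must be in (0, 0.5], got {self.alpha}")


def fmt_median_range(values: np.ndarray) -> str:
    """``median(min–max)`` at two decimals, e.g. ``2.36(1.33–4.26)``."""
    return (
        f"{np.median(values):.2f}({np.min(values):.2f}–{np.max(values):.2f})"
    )


def render_table4(pairs_by_set: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Median (range) penalty per setup and priority type, plus the delta.

    One row per weight set with the supine, prone, and prone-minus-supine
    medians formatted at two decimals.
    """
    rows = []
    for name, pairs in pairs_by_set.items():
        rows.append(
            {
                "priority_type": name,
                "supine": fmt_median_range(pairs["supine_score"].to_numpy()),
                "prone": fmt_median_range(pairs["prone_score"].to_numpy()),
                "delta": fmt_median_range(pairs["delta"].to_numpy()),
                "median_supine": float(pairs["supine_score"].median()),
                "median_prone": float(pairs["prone_score"].median()),
                "median_delta": float(pairs["delta"].median()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ReportBundle:
    """In-memory results of one pipeline run."""

    penalties: pd.DataFrame
    pairs_by_set: dict[str, pd.DataFrame]
    gain_by_set: dict[str, gain_mod.GainSummary]
    subgroup: dict
    table4: pd.DataFrame
    bullet: pd.DataFrame
    predictor_table: pd.DataFrame | None
    manifest: dict


def run_pipeline(
    config: RunConfig,
    cohort: CohortData | None = None,
    *,
    dvhs: Mapping[tuple[str, str], Mapping[str, StructureDVH]] | None = None,
    characteristics: pd.DataFrame | None = None,
    write: bool = True,
) -> ReportBundle:
    """Run cohort → penalties → gain analysis → predictor screen.

    Without an explicit cohort or DVH table, a synthetic cohort is generated
    under the default study conditions with ``config.seed``.  Outputs under
    ``config.outdir``: per-patient penalty CSV (all weight sets), gain
    summary JSON (with the subgroup split at ``split_at``), priority-type
    median table, bullet-arrow CSV (type-1 weights), and the predictor
    screen CSV when characteristics are available.
    """
    if cohort is None and dvhs is None:
        cohort = generate_cohort(
            GeneratorConfig(n_patients=config.n_patients, seed=config.seed)
        )
    if cohort is not None:
        dvhs = cohort.dvhs
        characteristics = cohort.characteristics
        manifest = dict(cohort.manifest)
    else:
        manifest = {}

    frames = []
    pairs_by_set: dict[str, pd.DataFrame] = {}
    gain_by_set: dict[str, gain_mod.GainSummary] = {}
    for name in config.weight_sets:
        ws = builtin_weights(name) if isinstance(name, str) else name
        scored = score_cohort(dvhs, ws)
        frames.append(scored)
        pairs = gain_mod.pair_scores(scored)
        pairs_by_set[ws.name] = pairs
        gain_by_set[ws.name] = gain_mod.count_gains(pairs, level=config.level)
    penalties = pd.concat(frames, ignore_index=True)

    primary = pairs_by_set[
        "type1" if "type1" in pairs_by_set else next(iter(pairs_by_set))
    ]
    subgroup: dict = {"split_at": config.split_at}
    try:
        low = gain_mod.count_gains(
            primary, lambda p: p["supine_score"] < config.split_at, level=config.level
        )
        high = gain_mod.count_gains(
            primary, lambda p: p["supine_score"] >= config.split_at, level=config.level
        )
        subgroup.update(
            below=low.to_dict(),
            at_or_above=high.to_dict(),
            p_value=gain_mod.two_proportion_test(
                (low.n_gain, low.n), (high.n_gain, high.n)
            ),
        )
    except EmptySubgroupError:
        logger.warning(
            "subgroup split at %s leaves one side empty; skipped", config.split_at
        )
        subgroup.update(below=None, at_or_above=None, p_value=None)

    table4 = render_table4(pairs_by_set)
    bullet = gain_mod.bullet_arrow(primary)

    predictor_table = None
    if characteristics is not None:
        records = characteristics.merge(
            primary.rename(
                columns={"supine_score": "supine_score", "prone_score": "prone_score"}
            ),
            on="patient_id",
            how="inner",
        )
        records["delta_penalty"] = records["delta"]
        if len(records) >= 10:
            predictor_table = pred_mod.screen_all(
                records, alpha=config.alpha, exclude=config.exclude_outliers
            )

    bundle = ReportBundle(
        penalties=penalties,
        pairs_by_set=pairs_by_set,
        gain_by_set=gain_by_set,
        subgroup=subgroup,
        table4=table4,
        bullet=bullet,
        predictor_table=predictor_table,
        manifest=manifest,
    )
    if write:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: ReportBundle, config: RunConfig) -> None:
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.penalties.to_csv(outdir / "penalties.csv", index=False)
    summary = {
        "gain_by_weight_set": {k: v.to_dict() for k, v in bundle.gain_by_set.items()},
        "subgroup": bundle.subgroup,
        "manifest": bundle.manifest,
        "config": dataclasses.asdict(config),
    }
    with open(outdir / "gain_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    bundle.table4.to_csv(outdir / "priority_medians.csv", index=False)
    bundle.bullet.to_csv(outdir / "bullet_arrow.csv", index=False)
    if bundle.predictor_table is not None:
        bundle.predictor_table.to_csv(outdir / "predictor_screen.csv", index=False)
    if config.charts:
        _render_charts(bundle, outdir)
    logger.info("report written to %s", outdir)


def _render_charts(bundle: ReportBundle, outdir: pathlib.Path) -> None:
    """Optional bullet-arrow chart; numeric outputs never depend on this."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    b = bundle.bullet
    gain = b["direction"] == "down"
    ax.scatter(b["rank"], b["supine_score"], s=12, color="black", zorder=3)
    for _, row in b.iterrows():
        color = "tab:blue" if row["delta"] < 0 else "tab:red"
        ax.annotate(
            "",
            xy=(row["rank"], row["prone_score"]),
            xytext=(row["rank"], row["supine_score"]),
            arrowprops=dict(arrowstyle="->", color=color, lw=0.8),
        )
    ax.set_xlabel("patients sorted by supine penalty")
    ax.set_ylabel("penalty score (% of prescribed dose)")
    ax.set_title(f"prone reduces the penalty in {int(gain.sum())}/{len(b)} patients")
    fig.tight_layout()
    fig.savefig(outdir / "bullet_arrow.svg")
    plt.close(fig)
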