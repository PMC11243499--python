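"""CSV input/output, row validation and report building.

participants.csv is a wide UTF-8 comma-separated file ('.' decimal
separator — worth stating because the study population writes decimal
commas), one row per participant, with a required header. Mandatory
columns: identifiers and demographics, the breastfeeding group, lactation
frequency/duration, the ten beverage columns, activity hours and sweat
points, and the excretion scale points. Dietary columns are optional and
either wide (``food_<id>_g_day``) or supplied via a long-format companion
diary file with ``participant_id, food_id, amount_g_day`` rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import ValidationError

from .config import PipelineConfig, ScoringConfig, StatsOptions
from .foods import FoodTable, default_food_table
from .records import (
    ActivityProfile,
    BreastfeedingGroup,
    ExcretionReport,
    FoodDiaryEntry,
    LactationReport,
    LiquidIntake,
    ParticipantRecord,
)
from . import scoring as sc
from . import stats as st

logger = logging.getLogger("wbqn")

MANDATORY_COLUMNS: tuple[str, ...] = (
    "participant_id", "group", "age", "weight", "height",
    "feeds_per_day", "minutes_per_feed",
    *LiquidIntake.model_fields,
    "hours_intensive", "hours_moderate", "hours_sedentary",
    "sweat_points_intensive", "sweat_points_moderate", "sweat_points_sedentary",
    "urine_points", "fecal_points",
)


class SchemaError(ValueError):
    """The input file's header does not match the participant schema."""


@dataclass
class ValidationReport:
    """Row-level validation outcome: every rejected row appears exactly once."""

    n_accepted: int = 0
    n_rejected: int = 0
    errors: list[dict] = field(default_factory=list)

    def reject(self, row: int, field_name: str, message: str) -> None:
        self.n_rejected += 1
        self.errors.append({"row": row, "field": field_name, "message": message})

    @property
    def n_input(self) -> int:
        return self.n_accepted + self.n_rejected


def _record_from_row(row: dict, food_cols: list[str]) -> ParticipantRecord:
    diary = [
        FoodDiaryEntry(food_id=c[len("food_"):-len("_g_day")], amount=row[c])
        for c in food_cols
        if not pd.isna(row[c]) and row[c] != 0
    ]
    edu = row.get("education_years")
    return ParticipantRecord(
        participant_id=str(row["participant_id"]),
        age=row["age"], weight=row["weight"], height=row["height"],
        education_years=None if pd.isna(edu) else edu,
        lactation=LactationReport(
            group=row["group"],
            feeds_per_day=row["feeds_per_day"],
            minutes_per_feed=row["minutes_per_feed"],
        ),
        diary=diary,
        liquids=LiquidIntake(**{f: row[f] for f in LiquidIntake.model_fields}),
        activity=ActivityProfile(
            hours_intensive=row["hours_intensive"],
            hours_moderate=row["hours_moderate"],
            hours_sedentary=row["hours_sedentary"],
            sweat_points_intensive=int(row["sweat_points_intensive"]),
            sweat_points_moderate=int(row["sweat_points_moderate"]),
            sweat_points_sedentary=int(row["sweat_points_sedentary"]),
        ),
        excretion=ExcretionReport(
            urine_points=int(row["urine_points"]),
            fecal_points=int(row["fecal_points"]),
        ),
    )


def read_participants(
    path: Union[str, Path],
    foods: Optional[FoodTable] = None,
    diary_path: Optional[Union[str, Path]] = None,
) -> tuple[list[ParticipantRecord], ValidationReport]:
    """Load and validate participants.csv.

    Returns the validated records and a :class:`ValidationReport` itemising
    every rejected row with the offending field and message. Missing
    mandatory columns raise :class:`SchemaError` listing them all.
    """
    if foods is None:
        foods = default_food_table()
    frame = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    food_cols = [c for c in frame.columns
                 if c.startswith("food_") and c.endswith("_g_day")]
    long_diary: dict[str, list[FoodDiaryEntry]] = {}
    if diary_path is not None:
        ddf = pd.read_csv(diary_path, dtype={"participant_id": str,
                                             "food_id": str})
        for c in ("participant_id", "food_id", "amount_g_day"):
            if c not in ddf.columns:
                raise SchemaError(f"diary file missing column: {c}")
        for r in ddf.itertuples(index=False):
            long_diary.setdefault(r.participant_id, []).append(
                FoodDiaryEntry(food_id=r.food_id, amount=r.amount_g_day))

    records: list[ParticipantRecord] = []
    report = ValidationReport()
    for i, row in enumerate(frame.to_dict(orient="records")):
        try:
            rec = _record_from_row(row, food_cols)
            if long_diary:
                rec = rec.model_copy(update={
                    "diary": rec.diary + long_diary.get(rec.participant_id, [])})
            unknown = [e.food_id for e in rec.diary if e.food_id not in foods]
            if unknown:
                report.reject(i, "diary",
                              f"unknown food_id(s): {sorted(set(unknown))}")
                continue
            records.append(rec)
            report.n_accepted += 1
        except ValidationError as exc:
            first = exc.errors()[0]
            loc = ".".join(str(p) for p in first["loc"]) or "record"
            report.reject(i, loc, first["msg"])
        except (ValueError, TypeError, KeyError) as exc:
            report.reject(i, "record", str(exc))
    return records, report


def write_scored(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a scored cohort; full float precision so read-back is exact."""
    # repr() emits the shortest string that round-trips the float64 exactly
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_scored(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str},
                       float_precision="round_trip")


# ---------------------------------------------------------------------------
# analysis report


SUMMARY_VARIABLES: tuple[str, ...] = (
    "age", "weight", "bmi", "education_years",
    "intake_total", "intake_drinking_water", "intake_liquids_excl_water",
    "intake_foods", "intake_juice", "intake_soft_drink", "intake_tea",
    "intake_coffee", "intake_milk",
    "loss_total", "loss_urine", "loss_feces", "loss_sweat",
    "balance_observed",
)


def build_analysis_report(
    scored: pd.DataFrame, options: Optional[StatsOptions] = None
) -> dict:
    """All analytical tables for a scored cohort, machine-readable.

    Contents: group sizes; per-variable group summaries (trimmed mean, IQR,
    Kruskal-Wallis); BMI-class and adequacy proportions with chi-square
    tests; the water-balance quartile table; and per-predictor
    proportional-odds fits of the balance quartile, including the
    breastfeeding-group contrasts against the non-breastfeeding reference.
    """
    if options is None:
        options = StatsOptions()
    variables = [v for v in SUMMARY_VARIABLES if v in scored.columns]
    summary = st.group_summaries(scored, variables,
                                 adjust=options.benjamini_hochberg)
    group_counts = scored["group"].value_counts().to_dict()

    categorical = {}
    for var in ("bmi_class", "adequacy_flag", "negative_flag"):
        if var in scored.columns and scored[var].nunique() > 1:
            cs = st.categorical_group_summary(scored, var)
            categorical[var] = {
                "counts": {str(k): v.to_dict()
                           for k, v in cs["counts"].iterrows()},
                "statistic": cs["statistic"],
                "p_value": cs["p_value"],
            }

    qtable = st.build_quartile_table(scored)

    reg = scored.copy()
    dummies = st.group_dummies(reg, reference=BreastfeedingGroup.none.value)
    reg = pd.concat([reg, dummies], axis=1)
    predictors = [*dummies.columns, *st.DEFAULT_REGRESSION_PREDICTORS]
    regression = st.per_predictor_fits(reg, predictors)

    return {
        "n_total": int(len(scored)),
        "group_counts": {str(k): int(v) for k, v in group_counts.items()},
        "alpha": options.alpha,
        "group_summaries": summary.to_dict(orient="records"),
        "categorical": categorical,
        "quartile_table": qtable.to_dict(),
        "ordinal_regression": regression.to_dict(orient="records"),
    }


def report_to_markdown(report: dict) -> str:
    """Human-readable rendering of :func:`build_analysis_report` output."""
    lines = ["# Water-balance analysis report", ""]
    lines.append(f"Participants: {report['n_total']} "
                 f"({', '.join(f'{k}: {v}' for k, v in report['group_counts'].items())})")
    lines += ["", "## Group summaries (5% trimmed mean, IQR; Kruskal-Wallis p)",
              ""]
    groups = list(report["group_counts"])
    header = "| variable | " + " | ".join(groups) + " | p |"
    lines += [header, "|" + "---|" * (len(groups) + 2)]
    for row in report["group_summaries"]:
        cells = [
            f"{row[f'{g}_trimmed_mean']:.2f} ({row[f'{g}_iqr']:.2f})"
            for g in groups
        ]
        lines.append(f"| {row['variable']} | " + " | ".join(cells)
                     + f" | {row['p_value']:.4g} |")
    lines += ["", "## Proportions by group (chi-square)", ""]
    for var, block in report["categorical"].items():
        lines.append(f"- **{var}**: chi2 = {block['statistic']:.3f}, "
                     f"p = {block['p_value']:.4g}")
    qt = report["quartile_table"]
    c1, c2, c3 = qt["cutoffs"]
    lines += ["", "## Water-balance quartiles",
              f"Cut-points (mL/day): Q1 < {c1:.2f} <= Q2 < {c2:.2f} "
              f"<= Q3 < {c3:.2f} <= Q4", ""]
    lines.append("| group | Q1 | Q2 | Q3 | Q4 |")
    lines.append("|---|---|---|---|---|")
    for g, row in qt["counts"].items():
        lines.append(f"| {g} | " + " | ".join(
            str(row[q]) for q in ("Q1", "Q2", "Q3", "Q4")) + " |")
    lines += ["", "## Ordinal regression of balance quartile "
                  "(per-predictor proportional-odds fits)", ""]
    lines.append("| predictor | estimate (95% CI) | p | parallel-lines p |")
    lines.append("|---|---|---|---|")
    for row in report["ordinal_regression"]:
        lines.append(
            f"| {row['predictor']} | {row['estimate']:.4f} "
            f"({row['ci_lower']:.3f}, {row['ci_upper']:.3f}) "
            f"| {row['p_value']:.4g} | {row['parallel_lines_p']:.4g} |"
        )
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# pipeline driver


class PipelineError(RuntimeError):
    pass


def run_pipeline(
    config: PipelineConfig,
    simulate_if_missing: bool = True,
) -> dict[str, Path]:
    """Run simulate (if no input file is configured) -> score -> analyze.

    Writes scored.csv, report.json, report.md and wbqn.log into the output
    directory; deterministic given inputs and seed. On any stage failure the
    partially written artifacts are removed and the error re-raised.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    handler = logging.FileHandler(out / "wbqn.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("config hash %s", config.config_hash())
        logger.info("milk-loss term: %s; quartile cutoffs: %s",
                    "on" if config.scoring.milk_loss.enabled else "off",
                    config.scoring.quartile_cutoffs or "auto")
        foods = (FoodTable.from_csv(config.foods) if config.foods
                 else default_food_table())
        if config.participants is not None:
            records, vreport = read_participants(config.participants, foods)
            logger.info("read %d rows: %d accepted, %d rejected",
                        vreport.n_input, vreport.n_accepted, vreport.n_rejected)
            for err in vreport.errors:
                logger.warning("rejected row %(row)s field %(field)s: "
                               "%(message)s", err)
            if not records:
                raise PipelineError("no valid participant rows")
            scored = sc.score_records(records, foods, config.scoring)
        elif simulate_if_missing:
            from .simulate import default_cohort_config, generate_cohort
            cohort = generate_cohort(default_cohort_config(seed=config.seed),
                                     foods)
            cohort.write_csv(out / "participants.csv")
            artifacts["participants"] = out / "participants.csv"
            logger.info("simulated cohort of %d participants (seed %d)",
                        len(cohort), config.seed)
            scored = sc.score_frame(cohort.frame, foods, config.scoring)
        else:
            raise PipelineError("no participants file configured")

        write_scored(scored, out / "scored.csv")
        artifacts["scored"] = out / "scored.csv"
        report = build_analysis_report(scored, config.stats)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, default=_jsonable), encoding="utf-8")
        artifacts["report_json"] = out / "report.json"
        (out / "report.md").write_text(report_to_markdown(report),
                                       encoding="utf-8")
        artifacts["report_md"] = out / "report.md"
        logger.info("pipeline complete: %s", sorted(artifacts))
        return artifacts
    except Exception:
        for p in artifacts.values():
            p.unlink(missing_ok=True)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
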