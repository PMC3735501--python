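"""Experimental data model: conditions, wells, study design, plate-file I/O.

The experiment crosses an inflammatory challenge (0 or 1 ug/ml LPS) with
carbohydrate supplementation — galacto-oligosaccharides alone (GOS), a 9:1
GOS/FOS blend, a 9:1:2 GOS/FOS/AOS blend, or glucose/lactose controls matched
to the sugar content of the GOS product — at total oligosaccharide
concentrations of 0.5, 1 and 2% w/v.  Outcomes are TNF-alpha and IL-10
(ELISA, pg/ml, left-censored at the assay detection limits) and cell
viability (CCK-8 absorbance relative to blank).

The plate CSV dialect is one row per well:

    horse_id,condition,analyte,replicate,value,below_detection

``below_detection`` is ``true``/``false``; censored rows carry the detection
limit in the ``value`` column as the censoring bound.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .formulation import IncubationComposition, compose_incubation, dilute

logger = logging.getLogger(__name__)

__all__ = [
    "ANALYTES",
    "DETECTION_LIMITS",
    "IncubationCondition",
    "WellMeasurement",
    "StudyDesign",
    "default_condition_catalogue",
    "default_study_design",
    "condition_by_label",
    "read_plate_csv",
    "write_plate_csv",
    "write_summary_csv",
    "read_summary_csv",
]

ANALYTES = ("TNFa", "IL10", "viability")

#: ELISA lower detection limits in pg/ml; viability has none.
DETECTION_LIMITS: dict[str, float] = {"TNFa": 15.625, "IL10": 156.25}

#: Nominal oligosaccharide blend ratios (parts GOS : FOS : AOS).
BLEND_RATIOS: dict[str, tuple[float, float, float]] = {
    "GOS": (1.0, 0.0, 0.0),
    "GOS/FOS": (9.0, 1.0, 0.0),
    "GOS/FOS/AOS": (9.0, 1.0, 2.0),
}

CONCENTRATIONS_PCT = (0.5, 1.0, 2.0)
LPS_DOSE_UG_PER_ML = 1.0

_RATIO_TOL = 1e-9


@dataclass(frozen=True)
class IncubationCondition:
    """One experimental arm: LPS dose plus carbohydrate doses.

    Oligosaccharide doses are % w/v of each component (GOS, FOS, AOS
    separately, so a "GOS/FOS/AOS 2.0%" condition has gos_pct=1.5,
    fos_pct=0.1667, aos_pct=0.3333).  Accompanying glucose and lactose are in
    mg/ml of medium.
    """

    label: str
    lps_ug_per_ml: float = 0.0
    gos_pct: float = 0.0
    fos_pct: float = 0.0
    aos_pct: float = 0.0
    glucose_mg_per_ml: float = 0.0
    lactose_mg_per_ml: float = 0.0
    arm: str = "blank"

    def __post_init__(self) -> None:
        for name in ("lps_ug_per_ml", "gos_pct", "fos_pct", "aos_pct",
                     "glucose_mg_per_ml", "lactose_mg_per_ml"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.label}: {name} must be >= 0")
        if self.arm not in ("oligosaccharide", "sugar_control", "blank"):
            raise ValueError(f"{self.label}: unknown arm {self.arm!r}")
        # blend-ratio invariants: FOS:GOS = 1:9 whenever FOS is present,
        # AOS:GOS = 2:9 whenever AOS is present
        if self.fos_pct > 0:
            if abs(self.fos_pct / self.gos_pct - 1.0 / 9.0) > _RATIO_TOL:
                raise ValueError(f"{self.label}: FOS/GOS ratio must be 1/9")
        if self.aos_pct > 0:
            if abs(self.aos_pct / self.gos_pct - 2.0 / 9.0) > _RATIO_TOL:
                raise ValueError(f"{self.label}: AOS/GOS ratio must be 2/9")

    @property
    def total_oligo_pct(self) -> float:
        return self.gos_pct + self.fos_pct + self.aos_pct

    @property
    def has_lps(self) -> bool:
        return self.lps_ug_per_ml > 0

    def to_composition(self) -> IncubationComposition:
        """Per-10-ml masses implied by the doses (oligosaccharides only)."""
        oligo = {}
        if self.gos_pct > 0:
            oligo["GOS"] = self.gos_pct * 100.0
        if self.fos_pct > 0:
            oligo["FOS"] = self.fos_pct * 100.0
        if self.aos_pct > 0:
            oligo["AOS"] = self.aos_pct * 100.0
        return compose_incubation(oligo) if oligo else IncubationComposition()


@dataclass(frozen=True)
class WellMeasurement:
    """One well's observation.

    ``value`` is pg/ml for cytokines and relative absorbance for viability;
    for censored wells it holds the detection limit (the censoring bound).
    """

    horse_id: str
    condition: str
    analyte: str
    replicate: int
    value: float
    below_detection: bool = False

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if not self.below_detection and self.value <= 0:
            raise ValueError(
                f"well {self.horse_id}/{self.condition}: non-positive value "
                f"{self.value} without below_detection flag"
            )
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")


@dataclass
class StudyDesign:
    """Horses with arm membership, the condition catalogue, detection limits."""

    horses: dict[str, str]  # horse_id -> arm
    conditions: list[IncubationCondition]
    detection_limits: dict[str, float] = field(
        default_factory=lambda: dict(DETECTION_LIMITS)
    )

    def horses_in_arm(self, arm: str) -> list[str]:
        return [h for h, a in self.horses.items() if a == arm]

    def condition(self, label: str) -> IncubationCondition:
        return condition_by_label(self.conditions, label)

    def conditions_for_arm(self, arm: str) -> list[IncubationCondition]:
        """Conditions incubated for one arm's horses.

        Both cytokine arms include the shared blank and LPS-alone references;
        the viability arm runs the unchallenged conditions only.
        """
        if arm == "oligosaccharide":
            return [c for c in self.conditions if c.arm in ("blank", "oligosaccharide")]
        if arm == "sugar_control":
            return [c for c in self.conditions if c.arm in ("blank", "sugar_control")]
        if arm == "viability":
            return [c for c in self.conditions if not c.has_lps]
        raise ValueError(f"unknown arm {arm!r}")


def _blend_label(fraction: str, conc: float, lps: bool) -> str:
    base = f"{fraction} {conc:.1f}%"
    return f"LPS + {base}" if lps else base


def default_condition_catalogue() -> list[IncubationCondition]:
    """The full condition catalogue implied by the study layout.

    Returns the cross of {no LPS, 1 ug/ml LPS} x {GOS, GOS/FOS, GOS/FOS/AOS,
    glucose/lactose control} x {0.5, 1, 2}% plus the blank and LPS-alone
    references (26 conditions).  Doses are derived through the formulation
    arithmetic so the catalogue stays consistent with the published per-10-ml
    composition table.
    """
    conditions: list[IncubationCondition] = [
        IncubationCondition(label="blank", arm="blank"),
        IncubationCondition(label="LPS", lps_ug_per_ml=LPS_DOSE_UG_PER_ML, arm="blank"),
    ]
    # 2% stock compositions per blend, then serial dilution
    total_2pct_mg = 200.0  # 20 mg/ml oligosaccharide in 10 ml
    for fraction, ratio in BLEND_RATIOS.items():
        parts = sum(ratio)
        targets = {
            comp: total_2pct_mg * r / parts
            for comp, r in zip(("GOS", "FOS", "AOS"), ratio)
            if r > 0
        }
        stock = compose_incubation(targets)
        for conc in CONCENTRATIONS_PCT:
            comp = dilute(stock, 2.0 / conc)
            for lps in (False, True):
                conditions.append(
                    IncubationCondition(
                        label=_blend_label(fraction, conc, lps),
                        lps_ug_per_ml=LPS_DOSE_UG_PER_ML if lps else 0.0,
                        gos_pct=comp.oligo_masses_mg.get("GOS", 0.0) / 100.0,
                        fos_pct=comp.oligo_masses_mg.get("FOS", 0.0) / 100.0,
                        aos_pct=comp.oligo_masses_mg.get("AOS", 0.0) / 100.0,
                        glucose_mg_per_ml=comp.co_masses_mg.get("glucose", 0.0) / 10.0,
                        lactose_mg_per_ml=comp.co_masses_mg.get("lactose", 0.0) / 10.0,
                        arm="oligosaccharide",
                    )
                )
    # glucose/lactose controls matched to the sugar content of the GOS product
    gos_stock = compose_incubation({"GOS": total_2pct_mg})
    for conc in CONCENTRATIONS_PCT:
        comp = dilute(gos_stock, 2.0 / conc)
        for lps in (False, True):
            conditions.append(
                IncubationCondition(
                    label=_blend_label("glucose/lactose", conc, lps),
                    lps_ug_per_ml=LPS_DOSE_UG_PER_ML if lps else 0.0,
                    glucose_mg_per_ml=comp.co_masses_mg["glucose"] / 10.0,
                    lactose_mg_per_ml=comp.co_masses_mg["lactose"] / 10.0,
                    arm="sugar_control",
                )
            )
    return conditions


def condition_by_label(
    conditions: list[IncubationCondition], label: str
) -> IncubationCondition:
    for cond in conditions:
        if cond.label == label:
            return cond
    raise KeyError(f"no condition labelled {label!r}")


def default_study_design(
    n_oligo: int = 5, n_sugar: int = 4, n_viability: int = 3
) -> StudyDesign:
    """Study design with the default arm sizes (5 / 4 / 3 horses)."""
    horses: dict[str, str] = {}
    horses.update({f"O{i}": "oligosaccharide" for i in range(1, n_oligo + 1)})
    horses.update({f"S{i}": "sugar_control" for i in range(1, n_sugar + 1)})
    horses.update({f"V{i}": "viability" for i in range(1, n_viability + 1)})
    return StudyDesign(horses=horses, conditions=default_condition_catalogue())


# ---------------------------------------------------------------------------
# plate CSV I/O

PLATE_COLUMNS = ("horse_id", "condition", "analyte", "replicate", "value", "below_detection")

_BOOL = {"true": True, "1": True, "false": False, "0": False}


class PlateParseError(ValueError):
    pass


def read_plate_csv(
    path: str | Path,
    catalogue: list[IncubationCondition] | None = None,
) -> tuple[list[WellMeasurement], StudyDesign]:
    """Read and validate a plate CSV; infer the study design from its rows.

    Rows are validated against the condition catalogue and the detection-limit
    rule: a cytokine value below its analyte's detection limit must carry the
    ``below_detection`` flag (and censored rows retain the limit as bound).
    Horses are assigned arms by the conditions/analytes they appear with.
    """
    path = Path(path)
    if catalogue is None:
        catalogue = default_condition_catalogue()
    labels = {c.label: c for c in catalogue}
    measurements: list[WellMeasurement] = []
    horse_conditions: dict[str, set[str]] = {}
    horse_analytes: dict[str, set[str]] = {}
    n_censored = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise PlateParseError(f"{path}: empty file")
        missing = set(PLATE_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise PlateParseError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                cond = row["condition"]
                if cond not in labels:
                    raise ValueError(f"unknown condition label {cond!r}")
                analyte = row["analyte"]
                flag_raw = row["below_detection"].strip().lower()
                if flag_raw not in _BOOL:
                    raise ValueError(f"bad below_detection value {row['below_detection']!r}")
                flag = _BOOL[flag_raw]
                value = float(row["value"])
                limit = DETECTION_LIMITS.get(analyte)
                if not flag and limit is not None and value < limit:
                    raise ValueError(
                        f"value {value} below the {analyte} detection limit "
                        f"{limit} must be flagged below_detection"
                    )
                well = WellMeasurement(
                    horse_id=row["horse_id"],
                    condition=cond,
                    analyte=analyte,
                    replicate=int(row["replicate"]),
                    value=limit if (flag and limit is not None) else value,
                    below_detection=flag,
                )
            except (KeyError, ValueError) as exc:
                raise PlateParseError(f"{path}:{lineno}: {exc}") from exc
            measurements.append(well)
            n_censored += well.below_detection
            horse_conditions.setdefault(well.horse_id, set()).add(cond)
            horse_analytes.setdefault(well.horse_id, set()).add(well.analyte)
    if not measurements:
        raise PlateParseError(f"{path}: no data rows")
    horses: dict[str, str] = {}
    for horse, conds in horse_conditions.items():
        if horse_analytes[horse] == {"viability"}:
            horses[horse] = "viability"
        elif any(labels[c].arm == "sugar_control" for c in conds):
            horses[horse] = "sugar_control"
        else:
            horses[horse] = "oligosaccharide"
    logger.info(
        "read %d wells (%d censored) from %s; %d horses",
        len(measurements), n_censored, path, len(horses),
    )
    design = StudyDesign(horses=horses, conditions=catalogue)
    return measurements, design


def write_plate_csv(measurements: list[WellMeasurement], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PLATE_COLUMNS)
        for m in measurements:
            writer.writerow(
                [m.horse_id, m.condition, m.analyte, m.replicate,
                 repr(m.value), "true" if m.below_detection else "false"]
            )


# ---------------------------------------------------------------------------
# summary CSV (tables of point estimates and credible intervals, contrasts)

_SUMMARY_HEADER = ["condition", "analyte", "point_estimate", "lower", "upper"]
_CONTRAST_HEADER = [
    "numerator", "denominator", "analyte",
    "percent_change", "ratio_lower", "ratio_upper", "significant",
]


def write_summary_csv(summaries, contrasts, path: str | Path) -> None:
    """Write condition summaries (and optionally contrasts) as a sectioned CSV.

    Summaries are written at 1 decimal (the reporting precision); contrasts
    carry the signed integer percent change and the significance mark.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("summaries must be non-empty")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SUMMARY_HEADER)
        for s in summaries:
            writer.writerow(
                [s.condition, s.analyte, f"{s.point_estimate:.1f}",
                 f"{s.lower:.1f}", f"{s.upper:.1f}"]
            )
        if contrasts:
            writer.writerow([])
            writer.writerow(_CONTRAST_HEADER)
            for c in contrasts:
                writer.writerow(
                    [c.numerator, c.denominator, c.analyte, f"{c.percent_change:+d}",
                     f"{c.ratio_bci[0]:.4f}", f"{c.ratio_bci[1]:.4f}",
                     "true" if c.significant else "false"]
                )


def read_summary_csv(path: str | Path):
    """Read back a summary CSV written by :func:`write_summary_csv`."""
    from .inference import ConditionSummary, Contrast  # avoid import cycle

    summaries: list = []
    contrasts: list = []
    section = "summary"
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != _SUMMARY_HEADER:
            raise PlateParseError(f"{path}: unexpected summary header {header}")
        for row in reader:
            if not row or not any(row):
                section = "contrast_header"
                continue
            if section == "contrast_header":
                if row != _CONTRAST_HEADER:
                    raise PlateParseError(f"{path}: unexpected contrast header {row}")
                section = "contrast"
                continue
            if section == "summary":
                summaries.append(
                    ConditionSummary(
                        condition=row[0], analyte=row[1],
                        point_estimate=float(row[2]), lower=float(row[3]),
                        upper=float(row[4]),
                    )
                )
            else:
                contrasts.append(
                    Contrast(
                        numerator=row[0], denominator=row[1], analyte=row[2],
                        percent_change=int(row[3]),
                        ratio_bci=(float(row[4]), float(row[5])),
                        significant=row[6] == "true",
                    )
                )
    return summaries, contrasts
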