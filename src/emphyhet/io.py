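"""Cohort table I/O, schema validation, and the end-to-end pipeline.

The cohort lives in a flat CSV, one row per subject: comma-separated,
UTF-8, "." decimal, empty string = missing.  ``read_cohort`` sniffs the
delimiter (overridable) and returns a DataFrame plus a cell-level
validation report; it hard-fails only on missing required columns.

``run_pipeline`` chains simulation → exclusions → statistics and writes
the five result tables plus a JSON provenance log (seed, parameters,
subject counts after each exclusion, stage timings).
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("emphyhet")


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str  # identifier | years | liters | percent | signed_percent | indicator | category
    required: bool = True
    dtype: str = "float64"
    bounds: tuple[float, float] | None = None
    categories: tuple[str, ...] | None = None


@dataclass
class CohortSchema:
    columns: tuple[ColumnSpec, ...]

    def required_names(self) -> list[str]:
        return [c.name for c in self.columns if c.required]

    def __iter__(self):
        return iter(self.columns)


COHORT_SCHEMA = CohortSchema(columns=(
    ColumnSpec("subject_id", "identifier", dtype="object"),
    ColumnSpec("copd", "indicator", bounds=(0, 1)),
    ColumnSpec("age", "years", bounds=(0, 120)),
    ColumnSpec("male", "indicator", bounds=(0, 1)),
    ColumnSpec("pack_years", "years", required=False, bounds=(0, 400)),
    ColumnSpec("fev1_pre_l", "liters", required=False, bounds=(0, 10)),
    ColumnSpec("fev1_post_l", "liters", required=False, bounds=(0, 10)),
    # lung-function percents are model outcomes: checked finite, not range-bound
    ColumnSpec("fev1_pct_pred", "percent"),
    ColumnSpec("fev1_fvc_pct", "percent"),
    ColumnSpec("rv_tlc_pct", "percent", required=False),
    ColumnSpec("dlco_pct_pred", "percent", required=False),
    ColumnSpec("cb", "category", required=False, dtype="object",
               categories=("yes", "no", "")),
    ColumnSpec("laa_pct", "percent", bounds=(0, 100)),
    ColumnSpec("hi_pct", "signed_percent", bounds=(-100, 100)),
    ColumnSpec("hi_left_pct", "signed_percent", required=False, bounds=(-100, 100)),
    ColumnSpec("hi_right_pct", "signed_percent", required=False, bounds=(-100, 100)),
    ColumnSpec("gold_stage", "category", dtype="object",
               categories=("none", "I", "II", "III", "IV")),
))


@dataclass
class ValidationReport:
    n_rows: int
    issues: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_cohort(df: pd.DataFrame, schema: CohortSchema = COHORT_SCHEMA) -> ValidationReport:
    """Collect out-of-range / malformed cells; does not mutate or raise."""
    report = ValidationReport(n_rows=len(df))
    for col in schema:
        if col.name not in df.columns:
            if col.required:
                report.issues.append({"column": col.name, "row": None,
                                      "problem": "required column missing"})
            continue
        series = df[col.name]
        if col.categories is not None:
            vals = series.fillna("").astype(str).str.strip()
            bad = ~vals.isin(col.categories)
            for idx in series.index[bad]:
                report.issues.append({"column": col.name, "row": int(idx),
                                      "problem": f"not one of {col.categories}",
                                      "value": series.loc[idx]})
        elif col.kind != "identifier":
            numeric = pd.to_numeric(series, errors="coerce")
            malformed = numeric.isna() & series.notna() & (series.astype(str).str.strip() != "")
            bad = malformed | np.isinf(numeric.fillna(0.0))
            problem = "malformed or non-finite"
            if col.bounds is not None:
                lo, hi = col.bounds
                bad = bad | (numeric < lo) | (numeric > hi)
                problem = f"outside [{lo}, {hi}] or malformed"
            for idx in series.index[bad]:
                report.issues.append({"column": col.name, "row": int(idx),
                                      "problem": problem,
                                      "value": series.loc[idx]})
    return report


def read_cohort(
    path: "str | Path",
    schema: CohortSchema = COHORT_SCHEMA,
    delimiter: str | None = None,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a cohort CSV.

    Raises on an empty file or missing required columns; everything else
    (range violations, malformed cells) goes in the returned report.
    """
    path = Path(path)
    text_head = path.read_text(encoding="utf-8")[:4096]
    if not text_head.strip():
        raise ValueError(f"{path}: empty cohort file")
    if delimiter is None:
        try:
            delimiter = csv.Sniffer().sniff(text_head, delimiters=",;\t").delimiter
        except csv.Error:
            delimiter = ","
    df = pd.read_csv(path, sep=delimiter, dtype={
        c.name: c.dtype for c in schema if c.dtype == "object"
    })
    missing = [name for name in schema.required_names() if name not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df, validate_cohort(df, schema)


def write_cohort(df: pd.DataFrame, path: "str | Path") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Result tables and the pipeline driver
# ---------------------------------------------------------------------------


def _fit_to_frame(fit) -> pd.DataFrame:
    t = fit.table.reset_index().rename(columns={"index": "term"})
    t.insert(0, "outcome", fit.outcome)
    t["n"] = fit.n
    return t


def _comparisons_to_frame(comparisons) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        row = {"variable": c.variable, "test": c.test, "p_value": c.p_value}
        for g, st in c.group_stats.items():
            tag = "le0" if g == "HI<=0" else "gt0"
            for k, v in st.items():
                row[f"{tag}_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_cohort(records: pd.DataFrame, yates: bool = False) -> dict[str, pd.DataFrame]:
    """Run the full statistical pipeline on an already-filtered cohort.

    Produces the characteristics table, dominance-stratified comparisons,
    adjusted linear models (COPD and non-COPD strata) and the logistic
    GOLD-severity model; COPD and non-COPD subgroups are analysed
    separately throughout.
    """
    from . import stats as st

    copd = records[records["copd"].astype(int) == 1]
    noncopd = records[records["copd"].astype(int) == 0]

    tables: dict[str, pd.DataFrame] = {}
    pieces = []
    for label, part in (("all", records), ("copd", copd), ("noncopd", noncopd)):
        if len(part):
            s = st.summarize_cohort(part)
            s.insert(0, "group", label)
            pieces.append(s)
    tables["table1"] = pd.concat(pieces, ignore_index=True)

    comp = []
    for label, part in (("copd", copd), ("noncopd", noncopd)):
        if len(part):
            c = _comparisons_to_frame(st.compare_groups(part, yates=yates))
            c.insert(0, "group", label)
            comp.append(c)
    tables["table2"] = pd.concat(comp, ignore_index=True) if comp else pd.DataFrame()

    if len(copd):
        tables["table3"] = pd.concat(
            [_fit_to_frame(st.fit_adjusted_linear(copd, o)) for o in st.PF_OUTCOMES],
            ignore_index=True,
        )
        tables["table4"] = _fit_to_frame(st.fit_logistic_gold(copd))
    if len(noncopd):
        tables["table5"] = pd.concat(
            [_fit_to_frame(st.fit_adjusted_linear(noncopd, o)) for o in st.PF_OUTCOMES],
            ignore_index=True,
        )
    return tables


def run_pipeline(config: dict, out_dir: "str | Path", seed: int | None = None) -> dict:
    """Execute the configured stages and write artifacts plus a run log.

    ``config`` keys: ``cohort`` (CohortSpec field overrides or a ``path``
    to an existing CSV), ``phantom`` (PhantomSpec overrides; optional),
    ``analysis`` ({"yates": bool}).  Any stage error propagates after
    being recorded in the log.
    """
    from . import laa, synth

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": _jsonable(config), "seed": seed, "stages": {}}
    t0 = time.perf_counter()

    def stage(name):
        log["stages"][name] = {"t_start_s": round(time.perf_counter() - t0, 3)}
        return log["stages"][name]

    try:
        phantom_cfg = config.get("phantom")
        if phantom_cfg is not None:
            rec = stage("phantom")
            pspec = synth.PhantomSpec(**{**phantom_cfg, **({"seed": seed} if seed is not None else {})})
            vol = synth.generate_phantom(pspec)
            vol.save(str(out / "phantom_image.nii.gz"), str(out / "phantom_lobes.nii.gz"))
            quant = laa.quantify_volume(vol)
            quant.to_frame().to_csv(out / "phantom_quant.csv", index=False)
            rec["whole_lung_laa_pct"] = quant["whole"].laa_pct

        rec = stage("cohort")
        cohort_cfg = dict(config.get("cohort", {}))
        if "path" in cohort_cfg:
            df, report = read_cohort(cohort_cfg["path"])
            if not report.ok:
                rec["validation_issues"] = len(report.issues)
        else:
            if seed is not None:
                cohort_cfg["seed"] = seed
            df = synth.generate_cohort(synth.CohortSpec(**cohort_cfg))
        write_cohort(df, out / "cohort.csv")
        rec["n"] = len(df)

        rec = stage("exclusions")
        from .stats import apply_exclusions

        kept, disposition = apply_exclusions(df)
        rec["disposition"] = disposition
        write_cohort(kept, out / "cohort_analytic.csv")

        rec = stage("analyze")
        tables = analyze_cohort(kept, **config.get("analysis", {}))
        for name, table in tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        rec["tables"] = sorted(tables)
    except Exception as exc:
        log["error"] = {"stage": list(log["stages"])[-1] if log["stages"] else None,
                        "message": str(exc)}
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
        raise

    log["elapsed_s"] = round(time.perf_counter() - t0, 3)
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    logger.info("pipeline complete: %s", out)
    return log


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
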