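"""File schemas, run configuration, and the end-to-end pipeline.

All tables are UTF-8 comma-separated text with a header row. The plot
table holds one row per plot; multi-valued measurements (stem heights,
cores, CO2 readings, litter masses) are semicolon-packed within a cell and
accretion poles are pipe-separated lists of semicolon-packed readings, so
a full experiment round-trips losslessly through a single delimited file.
Synthetic and deposited field tables use the same schemas and are
interchangeable pipeline inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import effects as eff
from . import inference as inf
from .functions import RawPlotMeasurements, FUNCTION_COLUMNS, build_function_matrix
from .multifun import DEFAULT_Q_GRID, multifunctionality_table
from .synthetic import (
    TREATMENTS,
    ExperimentConfig,
    SyntheticDataset,
    generate_experiment,
)

__all__ = [
    "RunConfig",
    "read_plot_table",
    "write_plot_table",
    "read_series",
    "write_series",
    "run_pipeline",
]

log = logging.getLogger("marshcascade")

_LIST_FIELDS = ("stem_heights_cm", "belowground_biomass_g", "co2_flux",
                "litter_mass_g")
_SCALAR_FIELDS = ("plant_density_per_m2", "macrofauna_wet_g",
                  "gene_copies_per_g", "gypsum_initial_g", "gypsum_final_g",
                  "gypsum_days", "drain_time_h", "sin_t0", "sin_t30",
                  "soc_pct", "tn_pct", "bulk_core_dry_g", "bulk_core_cm3")

_SERIES_SCHEMAS = {
    "birds": ("year", "month", "camera", "group", "count"),
    "burrows": ("plot_id", "treatment", "year", "month", "burrows"),
    "plants": ("plot_id", "treatment", "day", "count"),
    "tethering": ("plot_id", "treatment", "n_tethered", "n_eaten"),
}


class SchemaError(ValueError):
    """Raised when an input table does not match its declared schema."""


def _pack(values: Sequence[float]) -> str:
    return ";".join(repr(float(v)) for v in values)


def _unpack(cell: str, where: str) -> list[float]:
    try:
        return [float(v) for v in str(cell).split(";") if v != ""]
    except ValueError as exc:
        raise SchemaError(f"non-numeric value in {where}: {cell!r}") from exc


def write_plot_table(raws: Sequence[RawPlotMeasurements], path) -> None:
    """Write raw plot measurements as a single delimited table."""
    rows = []
    for r in raws:
        row = {"plot_id": r.plot_id, "treatment": r.treatment}
        for name in _SCALAR_FIELDS:
            row[name] = repr(float(getattr(r, name)))
        for name in _LIST_FIELDS:
            row[name] = _pack(getattr(r, name))
        row["pole_marks_cm"] = "|".join(_pack(p) for p in r.pole_marks_cm)
        for metal, conc in r.metal_conc.items():
            row[f"metal_{metal}"] = repr(float(conc))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plot_table(path) -> list[RawPlotMeasurements]:
    """Read a plot table back into :class:`RawPlotMeasurements` records."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty input file") from exc
    if df.empty:
        raise SchemaError(f"{path}: empty plot table")
    required = ["plot_id", "treatment", *_SCALAR_FIELDS, *_LIST_FIELDS,
                "pole_marks_cm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    metal_cols = [c for c in df.columns if c.startswith("metal_")]
    raws = []
    for i, row in df.iterrows():
        where = f"{path} row {i}"
        treatment = row["treatment"]
        if treatment not in TREATMENTS:
            raise SchemaError(f"{where}: unknown treatment label "
                              f"{treatment!r}")
        kwargs = {"plot_id": row["plot_id"], "treatment": treatment}
        for name in _SCALAR_FIELDS:
            vals = _unpack(row[name], f"{where} column {name}")
            if len(vals) != 1:
                raise SchemaError(f"{where} column {name}: expected one value")
            kwargs[name] = vals[0]
        for name in _LIST_FIELDS:
            kwargs[name] = _unpack(row[name], f"{where} column {name}")
        kwargs["pole_marks_cm"] = [
            _unpack(p, f"{where} column pole_marks_cm")
            for p in str(row["pole_marks_cm"]).split("|")]
        kwargs["metal_conc"] = {
            c.removeprefix("metal_"):
                _unpack(row[c], f"{where} column {c}")[0]
            for c in metal_cols}
        raws.append(RawPlotMeasurements(**kwargs))
    return raws


def write_series(df: pd.DataFrame, kind: str, path) -> None:
    """Write a monthly/daily series table of the named kind."""
    cols = _SERIES_SCHEMAS.get(kind)
    if cols is None:
        raise ValueError(f"unknown series kind {kind!r}")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"series {kind!r}: missing columns {missing}")
    df[list(cols)].to_csv(path, index=False)


def read_series(path, kind: str) -> pd.DataFrame:
    """Read a series table and validate its schema."""
    cols = _SERIES_SCHEMAS.get(kind)
    if cols is None:
        raise ValueError(f"unknown series kind {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty input file") from exc
    if df.empty:
        raise SchemaError(f"{path}: empty {kind} table")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for c in cols:
        if c in ("plot_id", "treatment", "group"):
            continue
        if not pd.api.types.is_numeric_dtype(df[c]):
            bad = df[pd.to_numeric(df[c], errors="coerce").isna()].index
            raise SchemaError(f"{path}: non-numeric values in column {c!r} "
                              f"(rows {list(bad[:5])})")
    return df


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    simulate: bool = True
    input_dir: str | None = None
    out_dir: str = "marshcascade_out"
    standardization: str = "percent_of_max"
    q_grid: tuple[float, ...] = DEFAULT_Q_GRID
    top_k: int = 3
    alpha: float = 0.05
    adjustment: str = "bonferroni"
    seed: int = 0
    reference_treatment: str = "planting_control"

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if any(q < 0 for q in self.q_grid):
            raise ValueError("q grid must be non-negative")
        if not self.simulate and not self.input_dir:
            raise ValueError("input_dir required when simulate is off")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys {sorted(unknown)}")
        if "q_grid" in data:
            data["q_grid"] = tuple(data["q_grid"])
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analytical configuration (output location excluded)."""
        data = dataclasses.asdict(self)
        data.pop("out_dir", None)
        blob = json.dumps(data, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _load_inputs(config: RunConfig) -> SyntheticDataset:
    if config.simulate:
        return generate_experiment(ExperimentConfig(seed=config.seed))
    d = Path(config.input_dir)
    raws = read_plot_table(d / "plots.csv")
    return SyntheticDataset(
        raw=raws,
        birds=read_series(d / "birds.csv", "birds"),
        burrows=read_series(d / "burrows.csv", "burrows"),
        plants=read_series(d / "plants.csv", "plants"),
        tethering=read_series(d / "tethering.csv", "tethering"),
        truth={},
        config=ExperimentConfig(seed=config.seed),
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    """Write a dataset in the pipeline's input schemas."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    write_plot_table(dataset.raw, d / "plots.csv")
    write_series(dataset.birds, "birds", d / "birds.csv")
    write_series(dataset.burrows, "burrows", d / "burrows.csv")
    write_series(dataset.plants, "plants", d / "plants.csv")
    write_series(dataset.tethering, "tethering", d / "tethering.csv")


def percent_changes(values: pd.Series, treatments: pd.Series,
                    reference: str = "planting_control") -> dict[str, float]:
    """Percent change of each treatment mean relative to the reference:
    100 * (mean_T - mean_ref) / mean_ref."""
    means = values.groupby(treatments).mean()
    if reference not in means.index:
        raise ValueError(f"reference treatment {reference!r} absent")
    ref = means[reference]
    if ref == 0:
        raise ValueError("reference mean is zero; percent change undefined")
    return {t: float(100.0 * (m - ref) / ref) for t, m in means.items()
            if t != reference}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and write the result tables.

    Stages: load-or-simulate, function derivation, multifunctionality,
    per-function and index treatment comparisons, monthly exclusion effect
    sizes with bird-abundance meta-regression, and tethering proportion
    tests. Returns the machine-readable summary (also written to
    ``summary.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("run config hash=%s seed=%d simulate=%s",
                 config.config_hash(), config.seed, config.simulate)
        dataset = _load_inputs(config)
        if config.simulate:
            write_dataset(dataset, out / "dataset")

        matrix = build_function_matrix(dataset.raw, top_k=config.top_k)
        matrix.to_csv(out / "function_matrix.csv")

        mfn = multifunctionality_table(matrix, q_grid=config.q_grid,
                                       index_mode=config.standardization)
        mfn.to_csv(out / "multifunctionality.csv")

        comparisons, letters = _compare_all(matrix, mfn, config.alpha)
        comparisons.to_csv(out / "comparisons.csv", index=False)

        effect_rows, moderator = _trophic(dataset)
        effect_rows.to_csv(out / "effects_monthly.csv", index=False)

        tether = _tether_test(dataset, config.alpha)

        summary = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_plots": len(dataset.raw),
            "treatment_means": {
                col: {t: float(v) for t, v in
                      mfn.groupby("treatment")[col].mean().items()}
                for col in ("avg_index", "N_q1", "M_ef_q1")
                if col in mfn.columns},
            "pct_change_vs_control": {
                "avg_index": percent_changes(mfn["avg_index"],
                                             mfn["treatment"],
                                             config.reference_treatment),
                **{f: percent_changes(matrix[f], matrix["treatment"],
                                      config.reference_treatment)
                   for f in FUNCTION_COLUMNS},
            },
            "avg_index_anova": _anova_summary(mfn),
            "letters_avg_index": letters,
            "exclusion_effect": {
                "n_months": int(len(effect_rows)),
                "mean_lrr": float(effect_rows["lrr"].mean()),
                "moderator_slope": moderator.slope,
                "moderator_p": moderator.p,
            },
            "tethering": tether,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        log.info("pipeline complete: %s", out)
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()


def _anova_summary(mfn: pd.DataFrame) -> dict:
    groups = {t: sub["avg_index"].to_numpy()
              for t, sub in mfn.groupby("treatment")}
    cmp = inf.anova_tukey(groups)
    return {"F": cmp.statistic, "df": list(cmp.df), "p": cmp.p}


def _compare_all(matrix: pd.DataFrame, mfn: pd.DataFrame,
                 alpha: float) -> tuple[pd.DataFrame, dict]:
    """Per-function and per-index treatment comparisons.

    Primary and secondary production use rank-based pairwise tests (their
    field distributions are strongly skewed); every other response uses
    ANOVA + Tukey HSD.
    """
    rank_based = {"primary_production", "secondary_production"}
    rows = []
    letters_index: dict[str, str] = {}
    responses = [(f, matrix) for f in FUNCTION_COLUMNS]
    responses += [(c, mfn) for c in mfn.columns if c != "treatment"]
    for name, table in responses:
        groups = {t: sub[name].to_numpy()
                  for t, sub in table.groupby("treatment")}
        if name in rank_based:
            cmp = inf.wilcoxon_pairwise(groups, alpha=alpha)
        else:
            cmp = inf.anova_tukey(groups, alpha=alpha)
        if name == "avg_index":
            letters_index = cmp.letters
        rows.append({
            "response": name, "method": cmp.method,
            "statistic": cmp.statistic,
            "df1": cmp.df[0] if cmp.df else np.nan,
            "df2": cmp.df[1] if cmp.df else np.nan,
            "p": cmp.p,
            "letters": ";".join(f"{g}={l}" for g, l in cmp.letters.items()),
        })
    return pd.DataFrame(rows), letters_index


def _trophic(dataset: SyntheticDataset):
    monthly = eff.exclusion_effect_on_crabs(dataset.burrows)
    birds = dataset.birds
    shore = (birds[birds["group"] == "shorebird"]
             .groupby(["year", "month"])["count"].sum())
    moderator = []
    keep = []
    for e in monthly:
        year, month = (int(x) for x in e.group.split("-"))
        if (year, month) in shore.index:
            keep.append(e)
            moderator.append(float(shore.loc[(year, month)]))
    fit = eff.moderator_regression(keep, moderator)
    rows = pd.DataFrame([{
        "month": e.group, "lrr": e.lrr, "var": e.var,
        "n_exclusion": e.n_p, "n_control": e.n_e,
        "orientation": e.orientation,
    } for e in keep])
    return rows, fit


def _tether_test(dataset: SyntheticDataset, alpha: float) -> dict:
    agg = dataset.tethering.groupby("treatment")[["n_eaten", "n_tethered"]].sum()
    cmp = inf.pairwise_proportions(agg["n_eaten"].to_dict(),
                                   agg["n_tethered"].to_dict(), alpha=alpha)
    return {
        "intensity_pct": {
            t: eff.predation_intensity(r["n_eaten"], r["n_tethered"])
            for t, r in agg.iterrows()},
        "chi2": cmp.statistic,
        "p": cmp.p,
        "letters": cmp.letters,
    }
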