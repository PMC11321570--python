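"""Readers, writers, configuration and descriptive cohort summaries.

The canonical on-disk format is tidy CSV with the column schema of
:class:`memkin.datasets.LabellingDataset` (fractions as decimals in [0, 1],
days as floats, counts as non-negative reals).  A best-effort adapter reads
spreadsheet exports laid out with the same columns on the first sheet.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .datasets import REQUIRED_COLUMNS, LabellingDataset
from .chimerism import ReplacementCurve
from .priors import Prior, prior_from_dict

__all__ = ["read_labelling_table", "write_labelling_table",
           "read_replacement_curve", "write_replacement_curve",
           "load_config", "save_priors", "load_priors", "summarize_cohort"]

logger = logging.getLogger("memkin")

_CURVE_COLUMNS = ["population", "mouse_id", "days_post_bmt",
                  "donor_count", "host_count"]


def read_labelling_table(path, dialect: str = "tidy-csv",
                         max_day: float = 35.0) -> LabellingDataset:
    """Read and validate a labelling timecourse table.

    ``dialect="tidy-csv"`` expects the canonical CSV schema;
    ``"study-xlsx"`` reads the first sheet of a spreadsheet with the same
    columns.  Out-of-range fractions and missing columns raise with the
    offending rows/columns named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tidy-csv":
        df = pd.read_csv(path)
    elif dialect == "study-xlsx":
        df = pd.read_excel(path, sheet_name=0)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for col in ("day", "n_cells"):
        if col in df.columns and not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()].tolist()
            if bad:
                raise ValueError(f"non-numeric values in {col!r}, rows {bad}")
            df[col] = coerced
    ds = LabellingDataset(df, max_day=max_day)
    logger.info("read %d rows from %s", len(ds), path)
    return ds


def write_labelling_table(dataset: LabellingDataset, path) -> None:
    dataset.data.to_csv(path, index=False, columns=list(REQUIRED_COLUMNS))
    logger.info("wrote %d rows to %s", len(dataset), path)


def read_replacement_curve(path) -> dict[str, ReplacementCurve]:
    """Read donor-replacement observations; one curve per population."""
    df = pd.read_csv(path)
    missing = [c for c in _CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    out = {}
    for pop, grp in df.groupby("population"):
        out[str(pop)] = ReplacementCurve(
            population=str(pop),
            data=grp.drop(columns="population").reset_index(drop=True))
    logger.info("read replacement curves for %s", sorted(out))
    return out


def write_replacement_curve(curves: dict[str, ReplacementCurve], path) -> None:
    frames = []
    for pop, c in curves.items():
        d = c.data.copy()
        d.insert(0, "population", pop)
        frames.append(d)
    pd.concat(frames).to_csv(path, index=False)


_CONFIG_KEYS = {"structure", "priors_file", "design_file", "seed",
                "rtol", "atol_scale", "out_dir", "n_walkers", "n_steps",
                "burn", "schedule"}


def load_config(path) -> dict:
    """Load a run configuration; unknown keys are rejected, and the
    resolved configuration (with the seed) is logged."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.setdefault("seed", 0)
    logger.info("resolved config: %s", cfg)
    return cfg


def save_priors(priors: dict[str, Prior], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: p.to_dict() for k, p in priors.items()}, fh)


def load_priors(path) -> dict[str, Prior]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return {k: prior_from_dict(v) for k, v in raw.items()}


# ---------------------------------------------------------------------------
# descriptive summaries (convenience only; standard rank tests)


def summarize_cohort(dataset: LabellingDataset,
                     min_group: int = 2) -> dict[str, pd.DataFrame]:
    """Medians and rank tests for cohort-level comparisons.

    Returns ``{"medians": ..., "tests": ...}``: per (cohort, subset,
    lineage) medians of the Ki67-high fraction and cell counts; two-sided
    Mann-Whitney tests between cohorts (per subset) and paired Wilcoxon
    tests between host and donor (per cohort and subset, paired on mouse
    and day).  Groups below ``min_group`` observations are skipped with a
    note.  These are descriptive conveniences, not the package's inference.
    """
    df = dataset.data
    medians = (df.groupby(["cohort", "subset", "lineage"])
               [["f_ki67hi", "n_cells"]].median().reset_index())

    tests = []
    for subset, grp in df.groupby("subset"):
        cohorts = sorted(grp["cohort"].unique())
        if len(cohorts) == 2:
            for var in ("f_ki67hi", "n_cells"):
                a = grp.loc[grp["cohort"] == cohorts[0], var].dropna()
                b = grp.loc[grp["cohort"] == cohorts[1], var].dropna()
                row = {"subset": subset, "comparison":
                       f"{cohorts[0]} vs {cohorts[1]}", "variable": var,
                       "test": "mann-whitney"}
                if len(a) < min_group or len(b) < min_group:
                    row.update(p_value=np.nan, note="group too small")
                else:
                    method = "exact" if max(len(a), len(b)) <= 8 else "auto"
                    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                             method=method)
                    row.update(statistic=float(res.statistic),
                               p_value=float(res.pvalue), note="")
                tests.append(row)
        for cohort, cgrp in grp.groupby("cohort"):
            wide = cgrp.pivot_table(index=["mouse_id", "day"],
                                    columns="lineage", values="f_ki67hi")
            if {"host", "donor"} <= set(wide.columns):
                pairs = wide.dropna(subset=["host", "donor"])
                row = {"subset": subset, "comparison":
                       f"host vs donor ({cohort})", "variable": "f_ki67hi",
                       "test": "wilcoxon"}
                diffs = pairs["donor"] - pairs["host"]
                if len(pairs) < min_group or np.allclose(diffs, 0):
                    row.update(p_value=np.nan if len(pairs) < min_group else 1.0,
                               note="group too small"
                               if len(pairs) < min_group else "identical")
                else:
                    res = stats.wilcoxon(pairs["donor"], pairs["host"])
                    row.update(statistic=float(res.statistic),
                               p_value=float(res.pvalue), note="")
                tests.append(row)
    return {"medians": medians, "tests": pd.DataFrame(tests)}
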