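"""Accuracy measures for synthetic-population validation.

Relative bias  RB = 100 * (estimate - actual) / actual  per area and
characteristic, and the median relative bias (MRB) of each characteristic
across areas.  Cells with a zero actual count have no defined RB; they are
reported separately, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import HH_TYPES, Population, tabulate_age_sex, tabulate_hh_types


class UndefinedBiasError(ValueError):
    """RB requested for a zero actual count."""


def relative_bias(actual: float, estimate: float) -> float:
    """Percent deviation of an estimate from the actual quantity."""
    if actual == 0:
        raise UndefinedBiasError("relative bias is undefined for actual = 0")
    return 100.0 * (estimate - actual) / actual


def median_relative_bias(pairs) -> float:
    """Median of the defined RBs over (actual, estimate) pairs.

    For an even number of defined RBs the mean of the two central order
    statistics is used.  Zero-actual pairs are skipped (they have no RB);
    at least one defined RB is required.
    """
    rbs = [relative_bias(a, e) for a, e in pairs if a != 0]
    if not rbs:
        raise UndefinedBiasError("no defined relative biases")
    return float(np.median(rbs))


@dataclass
class BiasReport:
    """Per-cell RBs, per-characteristic MRBs, and undefined/flagged cells."""

    cells: pd.DataFrame  # area_id, characteristic, actual, estimate, rb
    mrb: pd.Series  # characteristic -> MRB (%)
    undefined: pd.DataFrame = field(default_factory=pd.DataFrame)
    outside_interval: pd.DataFrame = field(default_factory=pd.DataFrame)


def compare_populations(
    predicted: Population,
    reference: Population,
    age_bands: list[tuple[int, int]],
    intervals: pd.DataFrame | None = None,
) -> BiasReport:
    """Cell-level bias report between a predicted and a reference population.

    Characteristics: male and female totals, the five household-type
    totals, and person totals per age band, each per shared area.  When a
    bootstrap ``intervals`` frame (area_id, characteristic, lower, upper)
    is supplied, reference values falling outside their interval are
    flagged.
    """
    pred_areas = set(predicted.households["area_id"])
    ref_areas = set(reference.households["area_id"])
    areas = sorted(pred_areas & ref_areas)
    if not areas:
        raise ValueError("no shared area ids to compare")

    rows = []
    for area in areas:
        p = predicted.subset_areas([area])
        r = reference.subset_areas([area])
        for name, est, act in _characteristics(p, r, age_bands):
            rows.append((area, name, act, est))
    cells = pd.DataFrame(rows, columns=["area_id", "characteristic", "actual", "estimate"])
    defined = cells["actual"] != 0
    cells["rb"] = np.where(
        defined, 100.0 * (cells["estimate"] - cells["actual"]) / cells["actual"].replace(0, np.nan), np.nan
    )
    undefined = cells[~defined].drop(columns="rb").reset_index(drop=True)
    mrb = cells[defined].groupby("characteristic")["rb"].median()

    outside = pd.DataFrame()
    if intervals is not None:
        merged = cells.merge(intervals, on=["area_id", "characteristic"], how="inner")
        mask = (merged["actual"] < merged["lower"]) | (merged["actual"] > merged["upper"])
        outside = merged[mask].reset_index(drop=True)
    return BiasReport(cells, mrb, undefined, outside)


def _characteristics(pred: Population, ref: Population, age_bands):
    pred_sex = pred.persons["sex"].value_counts()
    ref_sex = ref.persons["sex"].value_counts()
    yield "males_total", int(pred_sex.get("M", 0)), int(ref_sex.get("M", 0))
    yield "females_total", int(pred_sex.get("F", 0)), int(ref_sex.get("F", 0))
    pred_hh = tabulate_hh_types(pred.households)
    ref_hh = tabulate_hh_types(ref.households)
    for t in HH_TYPES:
        yield f"hh:{t}", pred_hh[t], ref_hh[t]
    pred_age = tabulate_age_sex(pred.persons, age_bands)
    ref_age = tabulate_age_sex(ref.persons, age_bands)
    for lo, hi in age_bands:
        est = pred_age[f"F:{lo}-{hi - 1}"] + pred_age[f"M:{lo}-{hi - 1}"]
        act = ref_age[f"F:{lo}-{hi - 1}"] + ref_age[f"M:{lo}-{hi - 1}"]
        yield f"age:{lo}-{hi - 1}", est, act
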