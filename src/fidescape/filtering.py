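"""Exclusion cascade producing the per-species analysis table.

Encounters are filtered in a fixed order before modelling:

1. non-responses (the bird never reacted before the observer reached it);
2. responses by walking or running rather than flight;
3. flights whose refuge location could not be determined in the field;
4. species left with 20 or fewer FIDs after the row-level filters
   (the species rule is strict: a species needs more than 20).

Every record lands in exactly one bin, so the report partitions the input
and the narrative percentages can be audited at each stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPECIES_MIN_FIDS = 20          # retained species need strictly more than this
MAX_PERCH_HEIGHT_M = 10.0
RESAMPLING_RADIUS_M = 50.0

REQUIRED_COLUMNS = ("species", "park_id", "std_m", "fid_m", "responded",
                    "escape_mode", "x0", "y0", "x1", "y1", "distance_fled_m")

ESCAPE_MODES = ("fly", "walk_run", "none")


class SchemaError(ValueError):
    """Raised when encounter rows violate the schema; carries per-row messages."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems[:5]) +
                         (f" (+{len(problems) - 5} more)" if len(problems) > 5 else ""))


@dataclass
class ExclusionReport:
    n_input: int = 0
    n_non_response: int = 0
    n_non_flight: int = 0
    n_refuge_unknown: int = 0
    n_dropped_species_threshold: int = 0
    n_retained: int = 0
    species_retained: dict[str, int] = field(default_factory=dict)

    def percentages(self) -> dict[str, float]:
        """Stage percentages rounded to one decimal, on the bases field
        studies quote them:
        non-response and non-flight against all approaches, refuge-unknown
        against flight responses."""
        n_flight = self.n_input - self.n_non_response - self.n_non_flight
        def pct(k, base):
            return round(100.0 * k / base, 1) if base else 0.0
        return {
            "non_response_pct_of_input": pct(self.n_non_response, self.n_input),
            "non_flight_pct_of_input": pct(self.n_non_flight, self.n_input),
            "refuge_unknown_pct_of_flight": pct(self.n_refuge_unknown, n_flight),
            "retained_pct_of_input": pct(self.n_retained, self.n_input),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input), ("non_response", self.n_non_response),
                ("non_flight", self.n_non_flight),
                ("refuge_unknown", self.n_refuge_unknown),
                ("dropped_species_threshold", self.n_dropped_species_threshold),
                ("retained", self.n_retained)]
        return pd.DataFrame(rows, columns=["stage", "count"])


def validate_schema(records: pd.DataFrame) -> None:
    problems = []
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            problems.append(f"missing column {col!r}")
    if problems:
        raise SchemaError(problems)
    mode = records["escape_mode"]
    responded = records["responded"].astype(bool)
    for i in records.index[~mode.isin(ESCAPE_MODES)]:
        problems.append(f"row {i}: unknown escape_mode {records.loc[i, 'escape_mode']!r}")
    for i in records.index[(mode == "none") != ~responded]:
        problems.append(f"row {i}: escape_mode/responded mismatch")
    # fid_m > std_m is a field-protocol warning (validate_sampling_criteria),
    # not a schema failure: such rows stay analysable.
    if problems:
        raise SchemaError(problems)


def refuge_known(records: pd.DataFrame) -> pd.Series:
    """A refuge is known when its coordinates are finite (short flights store
    the initial coordinates) or a measured flight distance exists."""
    if "refuge_known" in records.columns:
        return records["refuge_known"].astype(bool)
    coords = np.isfinite(records["x1"].astype(float)) & \
        np.isfinite(records["y1"].astype(float))
    measured = np.isfinite(records["distance_fled_m"].astype(float))
    return coords | measured


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Run the exclusion cascade; returns (analysis table, report)."""
    validate_schema(records)
    report = ExclusionReport(n_input=len(records))
    responded = records["responded"].astype(bool)
    report.n_non_response = int((~responded).sum())
    stage = records[responded]

    flew = stage["escape_mode"] == "fly"
    report.n_non_flight = int((~flew).sum())
    stage = stage[flew]

    known = refuge_known(stage)
    report.n_refuge_unknown = int((~known).sum())
    stage = stage[known]

    counts = stage.groupby("species")["fid_m"].apply(
        lambda s: int(np.isfinite(s.astype(float)).sum()))
    keep_species = set(counts[counts > SPECIES_MIN_FIDS].index)
    in_kept = stage["species"].isin(keep_species)
    report.n_dropped_species_threshold = int((~in_kept).sum())
    retained = stage[in_kept]
    report.n_retained = len(retained)
    report.species_retained = {sp: int(counts[sp]) for sp in sorted(keep_species)}
    return retained.copy(), report


def validate_sampling_criteria(records: pd.DataFrame) -> list[str]:
    """Field-protocol checks. These emit warnings only — no row is excluded.

    Checks: perch height above the 10 m sampling ceiling, FID exceeding StD,
    and same-species samples within 50 m of an earlier sample of that
    species (repeat-sampling risk). Rows are scanned in order, so the first
    sample at a location never warns.
    """
    warnings: list[str] = []
    if "perch_height_m" in records.columns:
        high = records.index[records["perch_height_m"].astype(float) > MAX_PERCH_HEIGHT_M]
        warnings.extend(
            f"row {i}: perch height above {MAX_PERCH_HEIGHT_M:.0f} m sampling criterion"
            for i in high)
    fid = records["fid_m"].astype(float)
    std = records["std_m"].astype(float)
    bad = records.index[np.isfinite(fid) & np.isfinite(std) & (fid > std)]
    warnings.extend(f"row {i}: FID exceeds starting distance" for i in bad)
    for sp, sub in records.groupby("species"):
        xs = sub["x0"].astype(float).to_numpy()
        ys = sub["y0"].astype(float).to_numpy()
        idx = sub.index.to_numpy()
        for j in range(1, len(sub)):
            d = np.hypot(xs[:j] - xs[j], ys[:j] - ys[j])
            d = d[np.isfinite(d)]
            if len(d) and d.min() < RESAMPLING_RADIUS_M:
                warnings.append(
                    f"row {idx[j]}: {sp} sampled {d.min():.1f} m from a "
                    f"previous {sp} sample (< {RESAMPLING_RADIUS_M:.0f} m)")
    return warnings
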