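"""Schema-validated CSV input and output.

All files are UTF-8, comma-separated, with a mandatory header row; missing
values are empty cells.  Deltas are permil relative to the fixed reference
ratios in :mod:`tracerbudget.isotope`; pools are umol, volumes litres,
durations days.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "MEASUREMENT_COLUMNS",
    "CHAMBER_COLUMNS",
    "FOOD_COLUMNS",
    "read_measurements",
    "read_chambers",
    "read_foods",
    "load_reference_budget_means",
]

MEASUREMENT_COLUMNS = (
    "treatment",
    "composition",
    "replicate",
    "taxon",
    "pool",
    "element",
    "delta_sample",
    "pool_umol",
)
CHAMBER_COLUMNS = (
    "treatment",
    "composition",
    "replicate",
    "volume_l",
    "dic_umol_per_l",
    "incubation_days",
    "delta_dic_start",
    "delta_dic_end",
    "feeding_days",
)
FOOD_COLUMNS = (
    "treatment",
    "name",
    "labeled_element",
    "enrichment",
    "cn_ratio",
    "added_c_umol",
    "added_n_umol",
)


def _read(path, required: tuple[str, ...], kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{kind} file not found: {path}")
    table = pd.read_csv(path)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return table


def _check_finite(table: pd.DataFrame, columns: tuple[str, ...], path) -> None:
    for col in columns:
        bad = table.index[table[col].isna()]
        if len(bad):
            raise ValueError(
                f"{path}: column {col!r} has missing value(s) at row(s) "
                f"{[int(i) + 2 for i in bad[:5]]} (1-based, incl. header)"
            )


def read_measurements(path) -> pd.DataFrame:
    """Per-pool isotope measurements: one row per
    (treatment, replicate, taxon, pool, element)."""
    table = _read(path, MEASUREMENT_COLUMNS, "measurements")
    _check_finite(table, ("delta_sample", "pool_umol"), path)
    bad_pool = set(table["pool"]) - {"tissue", "total"}
    if bad_pool:
        raise ValueError(f"{path}: unknown pool value(s) {sorted(bad_pool)}")
    bad_el = set(table["element"]) - {"C", "N"}
    if bad_el:
        raise ValueError(f"{path}: unknown element value(s) {sorted(bad_el)}")
    return table


def read_chambers(path) -> pd.DataFrame:
    """Per-chamber incubation records (volume, DIC, start/end DIC deltas)."""
    table = _read(path, CHAMBER_COLUMNS, "chambers")
    _check_finite(
        table,
        ("volume_l", "dic_umol_per_l", "incubation_days", "delta_dic_start",
         "delta_dic_end", "feeding_days"),
        path,
    )
    return table


def read_foods(path) -> pd.DataFrame:
    """Food-source descriptors, one row per treatment x labeled element."""
    table = _read(path, FOOD_COLUMNS, "foods")
    _check_finite(table, ("enrichment", "cn_ratio", "added_c_umol"), path)
    return table


def load_reference_budget_means() -> pd.DataFrame:
    """Published mean carbon-budget terms (umol C per chamber over the
    10-day experiment) for the coral-sponge feeding study this package
    models; used by the budget-reproduction entry point."""
    with resources.files("tracerbudget.data").joinpath(
        "reference_budget_means.csv"
    ).open() as fh:
        return pd.read_csv(fh)
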