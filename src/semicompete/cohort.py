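"""Semi-competing-risks cohort container, I/O, validation and accounting.

A cohort row records two (time, indicator) pairs per subject — time to the
non-terminal event (dementia diagnosis) or censoring, and time to the
terminal event (death) or censoring — plus baseline covariates.  Observation
of the non-terminal event ends at death or censoring, so the data live on
the wedge ``y1 <= y2``: if the non-terminal event was not observed the two
follow-up times must coincide exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortError",
    "CohortSchemaError",
    "CohortParseError",
    "EmptyCohortError",
    "CohortTable",
    "FlowCounts",
    "BaselineSummary",
    "CORE_COLUMNS",
    "read_cohort",
    "write_cohort",
    "validate_rows",
    "flow_counts",
    "baseline_table",
    "pct",
]

CORE_COLUMNS = ("id", "y1", "delta1", "y2", "delta2")


class CohortError(ValueError):
    """Base class for cohort-level failures."""


class CohortSchemaError(CohortError):
    """A required column is missing from the input file."""


class CohortParseError(CohortError):
    """A time or indicator failed to parse; carries the offending row index."""


class EmptyCohortError(CohortError):
    """The input contains no subject rows."""


@dataclass
class CohortTable:
    """Validated semi-competing-risks dataset.

    Attributes
    ----------
    data : pandas.DataFrame
        One row per subject with columns ``id, y1, delta1, y2, delta2`` plus
        the encoded covariates.  Times are positive floats (days from
        baseline); indicators are 0/1 integers.
    covariate_names : list of str
        Covariate columns, in model order.
    encoding_map : dict
        How categorical source variables were expanded into indicator
        columns (level list + reference level), so reports are reproducible.
    n_excluded_invalid : int
        Rows dropped at read time for violating the wedge invariants.
    """

    data: pd.DataFrame
    covariate_names: list[str]
    encoding_map: dict = field(default_factory=dict)
    n_excluded_invalid: int = 0

    def __post_init__(self) -> None:
        if self.data["id"].duplicated().any():
            dup = self.data.loc[self.data["id"].duplicated(), "id"].iloc[0]
            raise CohortError(f"duplicate subject id {dup!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def p(self) -> int:
        return len(self.covariate_names)

    @property
    def X(self) -> np.ndarray:
        return self.data[self.covariate_names].to_numpy(dtype=float)

    def arrays(self) -> dict[str, np.ndarray]:
        """Numeric views used by the likelihood code."""
        d = self.data
        return {
            "y1": d["y1"].to_numpy(dtype=float),
            "delta1": d["delta1"].to_numpy(dtype=int),
            "y2": d["y2"].to_numpy(dtype=float),
            "delta2": d["delta2"].to_numpy(dtype=int),
            "X": self.X,
        }


@dataclass(frozen=True)
class FlowCounts:
    """Study-flow accounting: who developed the non-terminal event, who died."""

    n_total: int
    n_nonterminal: int
    n_no_nonterminal: int
    n_death_given_nonterminal: int
    n_death_given_no_nonterminal: int
    n_excluded_invalid: int = 0

    def __post_init__(self) -> None:
        if self.n_nonterminal + self.n_no_nonterminal != self.n_total:
            raise CohortError(
                "flow counts inconsistent: "
                f"{self.n_nonterminal} + {self.n_no_nonterminal} != {self.n_total}"
            )
        if self.n_death_given_nonterminal > self.n_nonterminal:
            raise CohortError("more deaths than subjects in the event group")
        if self.n_death_given_no_nonterminal > self.n_no_nonterminal:
            raise CohortError("more deaths than subjects in the event-free group")


@dataclass
class BaselineSummary:
    """Per-covariate baseline characteristics split by non-terminal outcome.

    ``table`` holds machine-readable numbers; :meth:`formatted` renders the
    conventional "n (pct%)" / "mean (SD)" presentation.
    """

    table: pd.DataFrame
    n_group0: int
    n_group1: int
    group_labels: tuple[str, str] = ("no_nonterminal", "nonterminal")

    EMPTY_MARK = "(empty group)"

    def formatted(self) -> pd.DataFrame:
        rows = []
        for _, r in self.table.iterrows():
            out = {"variable": r["variable"]}
            for g, ng in (("0", self.n_group0), ("1", self.n_group1)):
                if ng == 0:
                    out[f"group{g}"] = self.EMPTY_MARK
                elif r["type"] == "binary":
                    out[f"group{g}"] = f"{int(r[f'n{g}'])} ({r[f'stat{g}']:.1f}%)"
                else:
                    out[f"group{g}"] = f"{r[f'stat{g}']:.1f} ({r[f'sd{g}']:.2f})"
            rows.append(out)
        return pd.DataFrame(rows)


def pct(k: int, n: int) -> float:
    """Percentage ``100*k/n`` rounded to one decimal, the table convention."""
    if n == 0:
        raise ZeroDivisionError("percentage of an empty group")
    return round(100.0 * k / n, 1)


def validate_rows(df: pd.DataFrame) -> np.ndarray:
    """Boolean mask of rows satisfying the semi-competing-risks invariants.

    Valid rows have positive times, 0/1 indicators, ``y1 <= y2``, and
    ``y1 == y2`` whenever the non-terminal event was not observed.
    """
    y1, y2 = df["y1"].to_numpy(float), df["y2"].to_numpy(float)
    d1, d2 = df["delta1"].to_numpy(float), df["delta2"].to_numpy(float)
    ok = np.isfinite(y1) & np.isfinite(y2) & (y1 > 0) & (y2 > 0)
    ok &= np.isin(d1, (0.0, 1.0)) & np.isin(d2, (0.0, 1.0))
    ok &= y1 <= y2
    ok &= ~((d1 == 0) & (y1 < y2))
    return ok


def read_cohort(path, schema: dict | None = None) -> CohortTable:
    """Read a delimited-text cohort, validate it, and drop invalid rows.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row.
    schema : dict, optional
        Mapping from the canonical keys ``id, y1, delta1, y2, delta2`` to the
        column names used in the file.  Unmapped columns are covariates.

    Raises
    ------
    CohortSchemaError
        A mapped or canonical core column is absent.
    CohortParseError
        A time or indicator fails numeric parsing (reports the row index).
    EmptyCohortError
        The file holds no subject rows.
    """
    raw = pd.read_csv(path)
    if len(raw) == 0:
        raise EmptyCohortError(f"no subject rows in {path}")
    schema = schema or {}
    rename = {v: k for k, v in schema.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in CORE_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s) {missing} in {path}")

    for col in ("y1", "delta1", "y2", "delta2"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortParseError(
                f"non-numeric value {raw[col].iloc[idx]!r} in column {col!r} at row {idx}"
            )
        raw[col] = coerced

    covariates = [c for c in raw.columns if c not in CORE_COLUMNS]
    mask = validate_rows(raw)
    kept = raw.loc[mask].reset_index(drop=True)
    kept = kept.astype({"y1": float, "y2": float, "delta1": int, "delta2": int})
    kept[covariates] = kept[covariates].astype(float)
    return CohortTable(
        data=kept[list(CORE_COLUMNS) + covariates],
        covariate_names=covariates,
        n_excluded_invalid=int((~mask).sum()),
    )


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort back to CSV with full float precision (round-trip safe)."""
    cohort.data.to_csv(path, index=False, float_format="%.17g")


def flow_counts(cohort: CohortTable) -> FlowCounts:
    """Tabulate the study flow: event-group sizes and deaths within each."""
    d1 = cohort.data["delta1"].to_numpy()
    d2 = cohort.data["delta2"].to_numpy()
    return FlowCounts(
        n_total=len(cohort),
        n_nonterminal=int((d1 == 1).sum()),
        n_no_nonterminal=int((d1 == 0).sum()),
        n_death_given_nonterminal=int(((d1 == 1) & (d2 == 1)).sum()),
        n_death_given_no_nonterminal=int(((d1 == 0) & (d2 == 1)).sum()),
        n_excluded_invalid=cohort.n_excluded_invalid,
    )


def _is_binary(col: np.ndarray) -> bool:
    vals = np.unique(col[np.isfinite(col)])
    return vals.size <= 2 and np.all(np.isin(vals, (0.0, 1.0)))


def baseline_table(cohort: CohortTable, include_death: bool = True) -> BaselineSummary:
    """Baseline characteristics split by non-terminal outcome group.

    Binary covariates are summarised as count and percentage, continuous
    ones as mean and SD.  An empty group is marked explicitly in the
    formatted output rather than producing NaN percentages.
    """
    d1 = cohort.data["delta1"].to_numpy()
    groups = {"0": cohort.data[d1 == 0], "1": cohort.data[d1 == 1]}
    n0, n1 = len(groups["0"]), len(groups["1"])

    variables = list(cohort.covariate_names)
    rows = []
    specs = [(v, cohort.data[v].to_numpy(float)) for v in variables]
    if include_death:
        specs.append(("death", cohort.data["delta2"].to_numpy(float)))
    for name, col in specs:
        kind = "binary" if _is_binary(col) else "continuous"
        row: dict = {"variable": name, "type": kind}
        for g, sub in groups.items():
            vals = (
                sub["delta2"].to_numpy(float)
                if name == "death"
                else sub[name].to_numpy(float)
            )
            if len(vals) == 0:
                row.update({f"n{g}": 0, f"stat{g}": np.nan, f"sd{g}": np.nan})
            elif kind == "binary":
                k = int(vals.sum())
                row.update({f"n{g}": k, f"stat{g}": pct(k, len(vals)), f"sd{g}": np.nan})
            else:
                row.update(
                    {
                        f"n{g}": len(vals),
                        f"stat{g}": float(np.mean(vals)),
                        f"sd{g}": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    }
                )
        rows.append(row)
    return BaselineSummary(table=pd.DataFrame(rows), n_group0=n0, n_group1=n1)
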