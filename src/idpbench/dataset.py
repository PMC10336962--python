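"""Curated IDP radius-of-gyration benchmark tables.

The packaged fixture is a transcription of the 24-protein compilation of
Baul et al. as used for cross-model comparison: for every protein it lists
the chain length, the SAXS-derived experimental Rg (with its reported
uncertainty where available), and the predictions of four models — an
N-only scaling law, the two-bead SOP-IDP model, the one-bead bead-necklace
model, and Martini 2 with the Stark corrections.

Two systems carry a pair of values and the evaluation conventions for them
are recorded explicitly on the table rather than being hidden in the
statistics code: alpha-synuclein has two experimental determinations
(40.0 and 35.5 A; comparisons use 35.5 A), and Prothymosin alpha has
bead-necklace predictions at 0 and 150 mM salt (72.3 and 44.6 A;
comparisons use the 150 mM value 44.6 A).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "MODEL_COLUMNS",
    "ProteinRecord",
    "BenchmarkTable",
    "ConsistencyReport",
    "load_benchmark",
    "load_extension",
    "load_deviation_table",
    "validate_consistency",
]

#: model-prediction columns, in presentation order
MODEL_COLUMNS = ("rg_scaling", "rg_sop_idp", "rg_bead_necklace", "rg_martini")

_REQUIRED = ("name", "n_residues", "rg_exp")

_OPTIONAL_FLOAT = (
    "rg_exp_err",
    "rg_exp_alt",
    "rg_exp_alt_err",
    "rg_scaling",
    "rg_sop_idp",
    "rg_bead_necklace",
    "rg_bead_necklace_alt",
    "rg_martini",
    "salt_mM",
    "temperature_K",
)


class BenchmarkParseError(ValueError):
    """Raised when a benchmark CSV is malformed."""


@dataclass(frozen=True)
class ProteinRecord:
    """One benchmark system: experimental reference plus model predictions.

    All radii are in Angstrom.  ``rg_exp_err`` is ``None`` when the source
    literature did not report an uncertainty; it is never silently zero.
    ``rg_exp_alt`` / ``rg_bead_necklace_alt`` hold the second value of
    dual-valued cells (see module docstring).
    """

    name: str
    n_residues: int
    rg_exp: float
    rg_exp_err: float | None = None
    rg_exp_alt: float | None = None
    rg_exp_alt_err: float | None = None
    rg_scaling: float | None = None
    rg_sop_idp: float | None = None
    rg_bead_necklace: float | None = None
    rg_bead_necklace_alt: float | None = None
    rg_martini: float | None = None
    salt_mM: float | None = None
    temperature_K: float | None = None
    comment: str = ""

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise BenchmarkParseError(
                f"{self.name}: n_residues must be >= 1, got {self.n_residues}"
            )
        for attr in ("rg_exp", "rg_exp_alt") + MODEL_COLUMNS + ("rg_bead_necklace_alt",):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise BenchmarkParseError(f"{self.name}: {attr} must be > 0, got {v}")
        for attr in ("rg_exp_err", "rg_exp_alt_err"):
            v = getattr(self, attr)
            if v is not None and v < 0:
                raise BenchmarkParseError(f"{self.name}: {attr} must be >= 0, got {v}")


@dataclass
class BenchmarkTable:
    """Ordered collection of :class:`ProteinRecord` plus evaluation conventions.

    ``evaluation_conventions`` maps ``(protein_name, field)`` to the string
    ``"alt"`` when the alternate value of a dual-valued cell is the one the
    comparison statistics should use.
    """

    records: list[ProteinRecord]
    evaluation_conventions: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise BenchmarkParseError(f"duplicate protein names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def get(self, name: str) -> ProteinRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(f"no protein named {name!r} in table")

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def experimental_rg(self, name: str) -> float:
        """Experimental Rg honouring the recorded convention (E_i)."""
        r = self.get(name)
        if self.evaluation_conventions.get((name, "rg_exp")) == "alt":
            if r.rg_exp_alt is None:
                raise BenchmarkParseError(f"{name}: convention points at missing alt value")
            return r.rg_exp_alt
        return r.rg_exp

    def model_rg(self, name: str, model_column: str) -> float:
        """Model-predicted Rg honouring the recorded convention (S_i)."""
        if model_column not in MODEL_COLUMNS:
            raise KeyError(f"unknown model column {model_column!r}")
        r = self.get(name)
        if self.evaluation_conventions.get((name, model_column)) == "alt":
            alt = getattr(r, model_column + "_alt", None)
            if alt is None:
                raise BenchmarkParseError(f"{name}: convention points at missing alt value")
            return alt
        v = getattr(r, model_column)
        if v is None:
            raise BenchmarkParseError(f"{name}: missing value in column {model_column}")
        return v

    def subset(self, names: Iterable[str]) -> "BenchmarkTable":
        keep = set(names)
        return BenchmarkTable(
            records=[r for r in self.records if r.name in keep],
            evaluation_conventions=dict(self.evaluation_conventions),
        )

    def without(self, name: str) -> "BenchmarkTable":
        self.get(name)  # raise KeyError if absent
        return BenchmarkTable(
            records=[r for r in self.records if r.name != name],
            evaluation_conventions=dict(self.evaluation_conventions),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


#: conventions for the canonical fixture: which value of a dual cell the
#: comparison statistics use.  They are the only choices consistent with
#: the printed signed-deviation table (alpha-synuclein scored against
#: 35.5 A; Prothymosin alpha bead-necklace scored at 150 mM, 44.6 A).
CANONICAL_CONVENTIONS: dict[tuple[str, str], str] = {
    ("Alpha-synuclein", "rg_exp"): "alt",
    ("Proth. alpha", "rg_bead_necklace"): "alt",
}


def _float_or_none(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _records_from_frame(df: pd.DataFrame) -> list[ProteinRecord]:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise BenchmarkParseError(f"missing required columns: {missing}")
    records = []
    for _, row in df.iterrows():
        kwargs = {
            "name": str(row["name"]),
            "n_residues": int(row["n_residues"]),
            "rg_exp": float(row["rg_exp"]),
            "comment": "" if "comment" not in df.columns or pd.isna(row.get("comment")) else str(row["comment"]),
        }
        for col in _OPTIONAL_FLOAT:
            if col in df.columns:
                kwargs[col] = _float_or_none(row[col])
        records.append(ProteinRecord(**kwargs))
    return records


def _packaged(name: str):
    return resources.files("idpbench.data").joinpath(name)


def load_benchmark(path: str | Path | None = None) -> BenchmarkTable:
    """Load the packaged 24-protein benchmark, or a user CSV of the same schema.

    The user CSV needs at least ``name``, ``n_residues`` and ``rg_exp``
    columns; model columns and conditions are optional.  An empty CSV with
    a header parses to an empty table.
    """
    conventions: dict[tuple[str, str], str] = {}
    if path is None:
        with resources.as_file(_packaged("table1.csv")) as p:
            df = pd.read_csv(p)
        conventions = dict(CANONICAL_CONVENTIONS)
    else:
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise BenchmarkParseError(f"{path}: empty file, no header") from exc
    table = BenchmarkTable(records=_records_from_frame(df), evaluation_conventions=conventions)
    if path is None and len(table) != 24:
        raise BenchmarkParseError(
            f"packaged fixture must contain 24 records, found {len(table)}"
        )
    return table


def load_extension(path: str | Path | None = None) -> BenchmarkTable:
    """Load the two-peptide extension set (KEIF and the Histatin 5 dimer)."""
    if path is None:
        with resources.as_file(_packaged("extension.csv")) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return BenchmarkTable(records=_records_from_frame(df))


def load_deviation_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the transcription of the printed signed-percentage-deviation table."""
    if path is None:
        with resources.as_file(_packaged("table2.csv")) as p:
            return pd.read_csv(p, index_col="name")
    return pd.read_csv(path, index_col="name")


@dataclass
class ConsistencyReport:
    """Cross-check of recomputed deviations against the printed deviation table."""

    deviations: pd.DataFrame  # recomputed, rounded to integer
    printed: pd.DataFrame
    mismatches: list[tuple[str, str, int, int]]  # (protein, model, recomputed, printed)

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)

    def __str__(self) -> str:
        if not self.mismatches:
            return "all deviation cells agree with the printed table within 1 point"
        lines = ["cells deviating by more than 1 percentage point:"]
        lines += [f"  {p} / {m}: recomputed {a:+d}, printed {b:+d}" for p, m, a, b in self.mismatches]
        return "\n".join(lines)


def validate_consistency(
    table: BenchmarkTable, printed: pd.DataFrame | None = None, tolerance: int = 1
) -> ConsistencyReport:
    """Recompute every signed percentage deviation and compare to the printed table.

    Because the printed inputs are rounded to 0.1 A the recomputed integer
    deviation may differ from the printed integer by one unit; anything
    larger is flagged.
    """
    from .evaluation import signed_pct_deviation

    if printed is None:
        printed = load_deviation_table()
    model_to_col = {
        "rg_scaling": "dev_scaling",
        "rg_sop_idp": "dev_sop_idp",
        "rg_bead_necklace": "dev_bead_necklace",
        "rg_martini": "dev_martini",
    }
    recomputed = {}
    mismatches = []
    for r in table:
        row = {}
        for model, col in model_to_col.items():
            dev = signed_pct_deviation(table.model_rg(r.name, model), table.experimental_rg(r.name))
            as_int = int(round(dev))
            row[col] = as_int
            printed_val = int(printed.loc[r.name, col])
            if abs(as_int - printed_val) > tolerance:
                mismatches.append((r.name, model, as_int, printed_val))
        recomputed[r.name] = row
    dev_df = pd.DataFrame.from_dict(recomputed, orient="index")
    dev_df.index.name = "name"
    return ConsistencyReport(deviations=dev_df, printed=printed, mismatches=mismatches)
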