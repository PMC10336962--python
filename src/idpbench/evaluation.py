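"""Model-comparison statistics for the Rg benchmark.

Per system the error is the signed percentage deviation
100*(Rg_sim - Rg_exp)/Rg_exp; across systems a model is scored by the
modified Pearson chi-square, the unnormalized sum over systems of
(E_i - S_i)**2 / E_i with E_i the experimental and S_i the model Rg.
Bias analysis regresses the per-system error on protein properties
(experimental Rg, chain length, FCR, NCPR, hydropathy, proline content,
disorder score).  The trend statistic reported alongside the OLS line is
the *signed correlation coefficient* r: an unsigned coefficient of
determination cannot be negative, so r — which carries the slope's sign
and reduces to R**2 in magnitude-squared — is what figure captions in this
model-benchmark literature usually quote for trendlines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import MODEL_COLUMNS, BenchmarkTable

__all__ = [
    "ModelScore",
    "BiasTrend",
    "ScorecardReport",
    "signed_pct_deviation",
    "chi2",
    "chi2_leave_one_out",
    "bias_trend",
    "scorecard",
]

#: pretty names for report output
MODEL_LABELS = {
    "rg_scaling": "Scaling law",
    "rg_sop_idp": "SOP-IDP",
    "rg_bead_necklace": "Bead-necklace",
    "rg_martini": "Martini Stark",
}


def signed_pct_deviation(rg_sim: float, rg_exp: float) -> float:
    """100 * (Rg_sim - Rg_exp) / Rg_exp; rounding happens only at presentation."""
    if rg_exp <= 0:
        raise ValueError(f"rg_exp must be > 0, got {rg_exp}")
    return 100.0 * (rg_sim - rg_exp) / rg_exp


def _pairs(table: BenchmarkTable, model_column: str) -> tuple[np.ndarray, np.ndarray]:
    e = np.array([table.experimental_rg(n) for n in table.names])
    s = np.array([table.model_rg(n, model_column) for n in table.names])
    return e, s


def chi2(table: BenchmarkTable, model_column: str) -> float:
    """Modified Pearson chi-square: sum of (E_i - S_i)**2 / E_i over the table."""
    e, s = _pairs(table, model_column)
    return float(np.sum((e - s) ** 2 / e))


def chi2_leave_one_out(table: BenchmarkTable, model_column: str, excluded: str) -> float:
    """The chi-square sum with one protein's term removed."""
    return chi2(table.without(excluded), model_column)


@dataclass(frozen=True)
class ModelScore:
    model_name: str
    per_protein_deviation: dict[str, float]  # signed %, unrounded
    chi2: float
    chi2_excluding: dict[str, float]

    def __post_init__(self) -> None:
        assert self.chi2 >= 0
        assert all(v <= self.chi2 + 1e-12 for v in self.chi2_excluding.values())


@dataclass(frozen=True)
class BiasTrend:
    """OLS of signed % error on one protein property."""

    property_name: str
    slope: float
    intercept: float
    r_signed: float  # Pearson r, carries the slope's sign (caption statistic)
    r_squared: float  # plain OLS coefficient of determination

    def __post_init__(self) -> None:
        assert abs(self.r_signed) <= 1.0 + 1e-12
        assert -1e-12 <= self.r_squared <= 1.0 + 1e-12


def bias_trend(errors, property_values, property_name: str = "property") -> BiasTrend:
    """Least-squares trendline of per-protein signed % error versus a property."""
    y = np.asarray(errors, dtype=float)
    x = np.asarray(property_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("errors and property_values must be 1-D of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 paired values, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError(f"property {property_name!r} is constant; trend undefined")
    res = stats.linregress(x, y)
    return BiasTrend(
        property_name=property_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_signed=float(res.rvalue),
        r_squared=float(res.rvalue**2),
    )


@dataclass
class ScorecardReport:
    scores: dict[str, ModelScore]
    trends: dict[tuple[str, str], BiasTrend]  # (model, property) -> trend
    table: BenchmarkTable = field(repr=False)

    def ranking(self) -> list[str]:
        """Model columns ordered best (lowest chi-square) first."""
        return sorted(self.scores, key=lambda m: self.scores[m].chi2)

    def scores_frame(self) -> pd.DataFrame:
        rows = [
            {"model": m, "label": MODEL_LABELS.get(m, m), "chi2": sc.chi2}
            for m, sc in self.scores.items()
        ]
        return pd.DataFrame(rows).sort_values("chi2", ignore_index=True)

    def deviations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {m: sc.per_protein_deviation for m, sc in self.scores.items()}
        ).rename_axis("name")

    def trends_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model": m,
                "property": p,
                "slope": t.slope,
                "intercept": t.intercept,
                "r_signed": t.r_signed,
                "r_squared": t.r_squared,
            }
            for (m, p), t in self.trends.items()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Model benchmark scorecard", "=" * 25, ""]
        lines.append(f"{'model':<16}{'chi2':>8}")
        for m in self.ranking():
            lines.append(f"{MODEL_LABELS.get(m, m):<16}{self.scores[m].chi2:>8.1f}")
        if self.trends:
            lines += ["", "trendlines (signed r of error vs property):"]
            props = sorted({p for _, p in self.trends})
            for p in props:
                vals = ", ".join(
                    f"{MODEL_LABELS.get(m, m)} {self.trends[(m, p)].r_signed:+.2f}"
                    for m in MODEL_COLUMNS
                    if (m, p) in self.trends
                )
                lines.append(f"  {p}: {vals}")
        return "\n".join(lines) + "\n"


def scorecard(
    table: BenchmarkTable,
    properties: pd.DataFrame | None = None,
    models: tuple[str, ...] = MODEL_COLUMNS,
) -> ScorecardReport:
    """Full benchmark report: chi-square scores plus bias trendlines.

    ``properties`` is an optional per-protein frame (indexed by name) of
    extra regressors such as fcr/ncpr/kd_hydrophobicity/proline_fraction/
    disorder_score; experimental Rg and chain length always come from the
    table itself.
    """
    scores: dict[str, ModelScore] = {}
    trends: dict[tuple[str, str], BiasTrend] = {}
    names = table.names
    base = pd.DataFrame(
        {
            "rg_exp": [table.experimental_rg(n) for n in names],
            "n_residues": [table.get(n).n_residues for n in names],
        },
        index=names,
    )
    if properties is not None:
        base = base.join(properties, how="left")

    for model in models:
        devs = {
            n: signed_pct_deviation(table.model_rg(n, model), table.experimental_rg(n))
            for n in names
        }
        scores[model] = ModelScore(
            model_name=model,
            per_protein_deviation=devs,
            chi2=chi2(table, model),
            chi2_excluding={n: chi2_leave_one_out(table, model, n) for n in names},
        )
        err = np.array([devs[n] for n in names])
        for prop in base.columns:
            vals = base[prop].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            if ok.sum() >= 3 and np.ptp(vals[ok]) > 0:
                trends[(model, prop)] = bias_trend(err[ok], vals[ok], prop)
    return ScorecardReport(scores=scores, trends=trends, table=table)
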