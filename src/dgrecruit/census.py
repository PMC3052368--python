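"""Census arithmetic and per-animal count-table summaries.

Links the sampled counts (one animal's ~80,000 upper-blade granule cells
counted over 450 um) to region- and population-level predictions, and
collapses per-animal, per-layer BrdU/Arc count tables into the group
proportions and layer distributions the analysis works with.

Layers are the subgranular zone (SGZ) plus the inner, middle and outer
thirds of the granule cell layer (L1, L2, L3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

LAYERS: tuple[str, ...] = ("SGZ", "L1", "L2", "L3")

#: Study census constants.
GRANULE_CELLS_SAMPLED = 80_000
SAMPLED_EXTENT_UM = 450.0
REGION_EXTENT_UM = 1300.0
WHOLE_DG_GRANULE_CELLS = 1_200_000
ONE_DAY_SURVIVAL_FRACTION = 0.0015   # granule cells born in one day surviving 45 d
EXPLORATION_ARC_FRACTION = 0.015     # granule cells expressing Arc after exploration
CAGE_CONTROL_ARC_FRACTION = 0.0031   # unstimulated Arc fraction

__all__ = [
    "LAYERS",
    "GRANULE_CELLS_SAMPLED",
    "SAMPLED_EXTENT_UM",
    "REGION_EXTENT_UM",
    "WHOLE_DG_GRANULE_CELLS",
    "ONE_DAY_SURVIVAL_FRACTION",
    "EXPLORATION_ARC_FRACTION",
    "CAGE_CONTROL_ARC_FRACTION",
    "LayerDistribution",
    "AnimalCountRecord",
    "StudySummary",
    "scale_to_region",
    "responding_population",
    "survival_decline",
    "group_summaries",
    "compare_groups",
    "records_to_frame",
    "frame_to_records",
    "read_animal_counts",
    "write_animal_counts",
]


@dataclass(frozen=True)
class LayerDistribution:
    """Fractions over the four DG layers; must sum to 1."""

    sgz: float
    l1: float
    l2: float
    l3: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError(f"layer fractions must lie in [0, 1]: {vals}")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"layer fractions must sum to 1, got {vals.sum()!r}")

    @classmethod
    def from_counts(cls, counts: Sequence[float]) -> "LayerDistribution":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("cannot form a distribution from all-zero counts")
        return cls(*(counts / total))

    @classmethod
    def normalized(cls, raw: Sequence[float]) -> "LayerDistribution":
        """Build from possibly non-normalized fractions (e.g. rounded percentages)."""
        return cls.from_counts(raw)

    def as_array(self) -> np.ndarray:
        return np.array([self.sgz, self.l1, self.l2, self.l3], dtype=float)


@dataclass(frozen=True)
class AnimalCountRecord:
    """One animal's per-layer triple-label counts.

    ``layer_counts`` maps each layer to a ``(brdu_positive, arc_positive,
    brdu_arc_double)`` triple; ``arc_positive`` includes the double-labelled
    cells.
    """

    animal_id: str
    pbi_days: int
    condition: str  # "CC" (cage control) or "SE" (spatial exploration)
    layer_counts: dict[str, tuple[int, int, int]]
    total_granule_sampled: int

    def __post_init__(self) -> None:
        if self.condition not in ("CC", "SE"):
            raise ValueError(f"condition must be 'CC' or 'SE', got {self.condition!r}")
        if set(self.layer_counts) != set(LAYERS):
            raise ValueError(f"layer_counts must cover exactly {LAYERS}")
        for layer, (brdu, arc, double) in self.layer_counts.items():
            if min(brdu, arc, double) < 0:
                raise ValueError(f"negative count in layer {layer}")
            if double > min(brdu, arc):
                raise ValueError(
                    f"double-labelled exceeds BrdU or Arc count in layer {layer}"
                )
        if self.brdu_total > self.total_granule_sampled:
            raise ValueError("BrdU-positive cells exceed total granule cells sampled")
        if self.arc_total > self.total_granule_sampled:
            raise ValueError("Arc-positive cells exceed total granule cells sampled")

    @property
    def brdu_total(self) -> int:
        return sum(c[0] for c in self.layer_counts.values())

    @property
    def arc_total(self) -> int:
        return sum(c[1] for c in self.layer_counts.values())

    @property
    def double_total(self) -> int:
        return sum(c[2] for c in self.layer_counts.values())


def scale_to_region(
    per_animal_cells: float,
    sampled_extent_um: float = SAMPLED_EXTENT_UM,
    region_extent_um: float = REGION_EXTENT_UM,
    round_to_thousand: bool = False,
) -> float:
    """Scale a sampled cell count to the full antero-posterior region.

    Linear in the count; with rounding, 80,000 cells over 450 um scale to
    231,000 over the 1300 um region.
    """
    if sampled_extent_um <= 0 or region_extent_um <= 0:
        raise ValueError("extents must be positive")
    scaled = per_animal_cells * region_extent_um / sampled_extent_um
    if round_to_thousand:
        return float(round(scaled / 1000.0) * 1000)
    return scaled


def responding_population(total_cells: float, response_fraction: float) -> int:
    """Cells responding at a given fraction, rounded to the nearest cell."""
    if total_cells < 0:
        raise ValueError("total_cells must be non-negative")
    if not 0.0 <= response_fraction <= 1.0:
        raise ValueError("response_fraction must lie in [0, 1]")
    return int(round(total_cells * response_fraction))


def survival_decline(fraction_day7: float, fraction_day45: float) -> float:
    """Percent of the day-7 BrdU-positive population lost by day 45."""
    if fraction_day7 <= 0:
        raise ValueError("fraction_day7 must be positive")
    return 100.0 * (fraction_day7 - fraction_day45) / fraction_day7


# ---------------------------------------------------------------------------
# Count-table summaries
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "animal_id", "pbi_days", "condition", "layer",
    "brdu_positive", "arc_positive", "brdu_arc_double", "total_granule_sampled",
]


def records_to_frame(records: Iterable[AnimalCountRecord]) -> pd.DataFrame:
    """Long-format frame: one row per animal x layer."""
    rows = []
    for r in records:
        for layer in LAYERS:
            brdu, arc, double = r.layer_counts[layer]
            rows.append(
                (r.animal_id, r.pbi_days, r.condition, layer,
                 brdu, arc, double, r.total_granule_sampled)
            )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[AnimalCountRecord]:
    records = []
    for (animal_id, pbi, cond, total), sub in df.groupby(
        ["animal_id", "pbi_days", "condition", "total_granule_sampled"], sort=False
    ):
        counts = {
            row.layer: (int(row.brdu_positive), int(row.arc_positive),
                        int(row.brdu_arc_double))
            for row in sub.itertuples()
        }
        records.append(
            AnimalCountRecord(str(animal_id), int(pbi), str(cond), counts, int(total))
        )
    return records


def read_animal_counts(path: str | Path) -> list[AnimalCountRecord]:
    df = pd.read_csv(path, comment="#")
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count CSV missing columns: {sorted(missing)}")
    return frame_to_records(df)


def write_animal_counts(
    records: Iterable[AnimalCountRecord], path: str | Path,
    header_lines: list[str] | None = None,
) -> None:
    body = records_to_frame(records).to_csv(index=False)
    head = "".join(f"# {h}\n" for h in (header_lines or []))
    Path(path).write_text(head + body)


@dataclass(frozen=True)
class StudySummary:
    """Group-level summaries with the per-animal table retained."""

    per_animal: pd.DataFrame
    groups: pd.DataFrame


def _per_animal_row(r: AnimalCountRecord) -> dict:
    row = {
        "animal_id": r.animal_id,
        "pbi_days": r.pbi_days,
        "condition": r.condition,
        "granule_total": r.total_granule_sampled,
        "brdu_total": r.brdu_total,
        "arc_total": r.arc_total,
        "double_total": r.double_total,
        "brdu_fraction": r.brdu_total / r.total_granule_sampled,
        "arc_fraction": r.arc_total / r.total_granule_sampled,
    }
    if r.brdu_total > 0:
        row["double_of_brdu"] = r.double_total / r.brdu_total
        for layer in LAYERS:
            row[f"brdu_dist_{layer}"] = r.layer_counts[layer][0] / r.brdu_total
    else:
        row["double_of_brdu"] = np.nan
        for layer in LAYERS:
            row[f"brdu_dist_{layer}"] = np.nan
    for layer in LAYERS:
        brdu_l = r.layer_counts[layer][0]
        row[f"double_of_brdu_{layer}"] = (
            r.layer_counts[layer][2] / brdu_l if brdu_l > 0 else np.nan
        )
        row[f"double_dist_{layer}"] = (
            r.layer_counts[layer][2] / r.double_total if r.double_total > 0 else np.nan
        )
    return row


def group_summaries(
    records: Iterable[AnimalCountRecord], pooled: bool = False
) -> StudySummary:
    """Summarize per-animal counts into per-(PBI day, condition) means.

    Default behaviour averages per-animal fractions (each animal is one
    experimental unit, matching how the group plots are built); with
    ``pooled=True`` fractions are instead computed from counts pooled over
    the group's animals.  Animals with zero BrdU-positive cells have an
    undefined double-labelled fraction and are excluded from those means
    with a warning.
    """
    records = list(records)
    if not records:
        raise ValueError("no records supplied")
    per_animal = pd.DataFrame([_per_animal_row(r) for r in records])

    zero_brdu = per_animal[per_animal["brdu_total"] == 0]
    if len(zero_brdu):
        warnings.warn(
            "excluding animals with zero BrdU-positive cells from "
            f"double-labelled fractions: {sorted(zero_brdu['animal_id'])}",
            stacklevel=2,
        )

    if pooled:
        def agg(sub: pd.DataFrame) -> pd.Series:
            out = {
                "n_animals": len(sub),
                "brdu_fraction": sub["brdu_total"].sum() / sub["granule_total"].sum(),
                "brdu_count_mean": sub["brdu_total"].mean(),
                "arc_fraction": sub["arc_total"].sum() / sub["granule_total"].sum(),
                "double_of_brdu": (
                    sub["double_total"].sum() / sub["brdu_total"].sum()
                    if sub["brdu_total"].sum() > 0 else np.nan
                ),
            }
            return pd.Series(out)
        groups = per_animal.groupby(["pbi_days", "condition"]).apply(
            agg, include_groups=False
        ).reset_index()
    else:
        value_cols = (
            ["brdu_fraction", "arc_fraction", "double_of_brdu"]
            + [f"brdu_dist_{l}" for l in LAYERS]
            + [f"double_of_brdu_{l}" for l in LAYERS]
            + [f"double_dist_{l}" for l in LAYERS]
        )
        grouped = per_animal.groupby(["pbi_days", "condition"])
        groups = grouped[value_cols].mean().reset_index()
        groups.insert(2, "n_animals", grouped.size().values)
        groups.insert(4, "brdu_count_mean", grouped["brdu_total"].mean().values)
    return StudySummary(per_animal=per_animal, groups=groups)


def compare_groups(
    summary: StudySummary | pd.DataFrame,
    response: str = "double_of_brdu",
    factors: Sequence[str] = ("pbi_days", "condition"),
) -> pd.DataFrame:
    """Standard ANOVA plus Bonferroni-corrected pairwise comparisons.

    A reporting convenience delegating to stock routines: one-way ANOVA
    (single factor) or type-II two-way ANOVA with interaction (two factors)
    on the per-animal response column, followed by pairwise Welch t-tests
    between the levels of each factor with Bonferroni correction.

    Returns a tidy frame with columns
    ``term, comparison, statistic, df, p, corrected_p``.
    """
    df = summary.per_animal if isinstance(summary, StudySummary) else summary
    df = df.dropna(subset=[response])
    factors = list(factors)
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels with data")
    cell_sizes = df.groupby(factors).size()
    if (cell_sizes < 2).any():
        raise ValueError(
            "insufficient replication: every factor combination needs >= 2 animals, "
            f"got minimum {int(cell_sizes.min())}"
        )

    rows: list[dict] = []
    if len(factors) == 1:
        f = factors[0]
        groups = [sub[response].to_numpy() for _, sub in df.groupby(f)]
        stat, p = stats.f_oneway(*groups)
        dfn, dfd = len(groups) - 1, len(df) - len(groups)
        rows.append({"term": f, "comparison": "omnibus", "statistic": float(stat),
                     "df": f"{dfn},{dfd}", "p": float(p), "corrected_p": float(p)})
    else:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        data = df.rename(columns={response: "_y"}).copy()
        terms = " * ".join(f"C({f})" for f in factors)
        model = smf.ols(f"_y ~ {terms}", data=data).fit()
        table = sm.stats.anova_lm(model, typ=2)
        resid_df = int(table.loc["Residual", "df"])
        for term, row in table.iterrows():
            if term == "Residual":
                continue
            rows.append({
                "term": term, "comparison": "omnibus",
                "statistic": float(row["F"]), "df": f"{int(row['df'])},{resid_df}",
                "p": float(row["PR(>F)"]), "corrected_p": float(row["PR(>F)"]),
            })

    # pairwise comparisons within each factor, Bonferroni-corrected per factor
    from itertools import combinations

    for f in factors:
        levels = sorted(df[f].unique())
        pairs = list(combinations(levels, 2))
        for a, b in pairs:
            xa = df.loc[df[f] == a, response].to_numpy()
            xb = df.loc[df[f] == b, response].to_numpy()
            stat, p = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append({
                "term": f, "comparison": f"{a} vs {b}",
                "statistic": float(stat), "df": f"{len(xa) + len(xb) - 2}",
                "p": float(p), "corrected_p": float(min(1.0, p * len(pairs))),
            })
    return pd.DataFrame(rows)
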