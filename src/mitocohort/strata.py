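"""Gender x age x immune-level subpopulations and trend statistics.

The cohort is partitioned into 16 strata — 2 genders x 4 age groups
(17-29, 30-44, 45-59, >=60 years) x 2 pre-treatment immune levels
(severe immunodeficiency: CD4 < 200 cells/ul; mild: CD4 >= 200) — after
restricting to a single ethnicity so that mutational patterns are not
confounded by ancestry.  Age-related trends of a metric are summarized
by the least-squares slope over the ordinal age-group codes 1..4, and
distributions between matched strata are compared with the Wilcoxon
rank-sum test; sequencing-platform batches are compared with Welch's
unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import age_group_of

AGE_GROUPS = ("17-29", "30-44", "45-59", ">=60")
GENDERS = ("male", "female")
IMMUNE_LEVELS = ("severe", "mild")

#: CD4 cells/ul threshold separating severe from mild immunodeficiency.
CD4_SEVERE_CUT = 200.0

StratumKey = tuple[str, str, str]  # (gender, age_group, immune_level)


@dataclass
class ParticipantRecord:
    """One subject's metadata and (optionally) called variants."""

    id: str
    gender: str
    age: float
    ethnicity: str
    transmission: str
    cd4_pre: float
    cd4_post: float | None = None
    regimen: str | None = None
    duration_class: str | None = None
    haplogroup: str | None = None
    variants: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(f"{self.id}: gender must be male/female")
        if not 0 <= self.age <= 120:
            raise ValueError(f"{self.id}: implausible age {self.age}")

    @property
    def age_group(self) -> str:
        return age_group_of(self.age)

    @property
    def immune_level(self) -> str:
        return "severe" if self.cd4_pre < CD4_SEVERE_CUT else "mild"

    @property
    def stratum(self) -> StratumKey:
        return (self.gender, self.age_group, self.immune_level)


def load_metadata(path) -> list[ParticipantRecord]:
    """Read a tab-delimited participant table into records.

    Requires columns ``id, gender, age, ethnicity, transmission,
    cd4_pre``; ``cd4_post``, ``regimen``, ``duration_class`` and
    ``haplogroup`` are optional.
    """
    table = pd.read_csv(path, sep="\t")
    required = {"id", "gender", "age", "ethnicity", "transmission", "cd4_pre"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    records = []
    for row in table.to_dict("records"):
        records.append(
            ParticipantRecord(
                id=str(row["id"]),
                gender=row["gender"],
                age=float(row["age"]),
                ethnicity=row["ethnicity"],
                transmission=row["transmission"],
                cd4_pre=float(row["cd4_pre"]),
                cd4_post=(
                    float(row["cd4_post"])
                    if "cd4_post" in row and pd.notna(row["cd4_post"])
                    else None
                ),
                regimen=row.get("regimen"),
                duration_class=row.get("duration_class"),
                haplogroup=row.get("haplogroup"),
            )
        )
    return records


def records_from_frame(meta: pd.DataFrame) -> list[ParticipantRecord]:
    """Build records from a metadata DataFrame (simulator output)."""
    return [
        ParticipantRecord(
            id=str(r["id"]),
            gender=r["gender"],
            age=float(r["age"]),
            ethnicity=r["ethnicity"],
            transmission=r["transmission"],
            cd4_pre=float(r["cd4_pre"]),
            cd4_post=float(r["cd4_post"]) if pd.notna(r.get("cd4_post")) else None,
            regimen=r.get("regimen"),
            duration_class=r.get("duration_class"),
        )
        for r in meta.to_dict("records")
    ]


@dataclass
class Stratification:
    """The 16-cell partition with per-stratum membership."""

    strata: dict[StratumKey, list[str]]
    min_size: int = 5

    @property
    def sizes(self) -> pd.Series:
        idx = pd.MultiIndex.from_tuples(
            self.strata.keys(), names=["gender", "age_group", "immune_level"]
        )
        return pd.Series([len(v) for v in self.strata.values()], index=idx)

    @property
    def undersized(self) -> list[StratumKey]:
        """Strata below the minimum-size rule (flagged, never dropped)."""
        return [k for k, v in self.strata.items() if len(v) < self.min_size]

    def members(self, key: StratumKey) -> list[str]:
        return self.strata[key]


def stratify(
    cohort: list[ParticipantRecord],
    ethnicity_filter: str | None = "Han",
    min_size: int = 5,
) -> Stratification:
    """Partition eligible participants into the 16 strata.

    Participants whose ethnicity differs from ``ethnicity_filter`` are
    excluded (pass None to keep everyone).  Every one of the 2 x 4 x 2
    cells is present, possibly empty; cells under ``min_size`` are
    flagged via :attr:`Stratification.undersized`.
    """
    if not cohort:
        raise ValueError("empty cohort")
    strata: dict[StratumKey, list[str]] = {
        (g, a, i): []
        for g in GENDERS
        for a in AGE_GROUPS
        for i in IMMUNE_LEVELS
    }
    for rec in cohort:
        if ethnicity_filter is not None and rec.ethnicity != ethnicity_filter:
            continue
        strata[rec.stratum].append(rec.id)
    return Stratification(strata=strata, min_size=min_size)


@dataclass(frozen=True)
class TrendResult:
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    n: int


def age_trend(
    metric_by_age_group: dict[str, float] | pd.Series,
    codes: dict[str, int] | None = None,
) -> TrendResult:
    """OLS slope of a metric over ordinal age-group codes (1..4).

    Missing age groups are dropped; at least 3 values are required.
    """
    series = pd.Series(metric_by_age_group).dropna()
    if codes is None:
        codes = {g: i + 1 for i, g in enumerate(AGE_GROUPS)}
    x = np.array([codes[g] for g in series.index], dtype=float)
    y = series.to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("age trend needs at least 3 age groups with values")
    fit = stats.linregress(x, y)
    return TrendResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        r_squared=float(fit.rvalue) ** 2,
        n=len(y),
    )


def compare_bias_density(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two value sets.

    Returns the rank-sum statistic W of the first group and the p-value
    (exact for small tie-free samples, tie-corrected normal
    approximation otherwise).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank sum
    return w, float(res.pvalue)


def platform_comparison(counts_a, counts_b) -> tuple[float, float]:
    """Welch's unequal-variance t-test between per-sample counts."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("degenerate zero-variance groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def stratum_metric_series(
    values_by_stratum: dict[StratumKey, float],
    gender: str,
    immune_level: str,
) -> pd.Series:
    """Extract the 4-point age profile of one (gender, immune) family."""
    return pd.Series(
        {
            a: values_by_stratum[(gender, a, immune_level)]
            for a in AGE_GROUPS
            if (gender, a, immune_level) in values_by_stratum
        }
    )
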