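"""Montane-island-population (MIP) statistics.

A *montane island population* is an individual island population that has
not been recorded below 100 masl; populations whose elevational range
extends below 100 masl are *lowland island populations* (LIPs).  This
module rolls island-population tables up to per-species summaries (MIP and
LIP counts, per-archipelago counts, MIP proportions) and provides the
nonparametric comparisons used on them: Mann-Whitney rank-sum tests
(W statistic of the first-listed group), Yates-corrected 2x2 chi-squared
tests, group medians, and island-assemblage competition flags.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "IslandPopulation",
    "TestResult",
    "MONTANE_FLOOR_MASL",
    "classify_population",
    "summarize_species",
    "mann_whitney_w",
    "chi_square_2x2",
    "group_medians_and_proportions",
    "competition_flags",
    "read_population_table",
]

#: minimum elevation (masl) at or above which an island population counts
#: as montane (no record below 100 m above sea level)
MONTANE_FLOOR_MASL = 100.0

#: exact Mann-Whitney p-values are used when n1*n2 is at most this and the
#: pooled sample is tie-free
EXACT_MW_LIMIT = 400


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class IslandPopulation:
    species: str
    island: str
    archipelago: str  # "Wallacea" | "Bismarcks/Solomons"
    min_masl: float
    max_masl: float
    genus: str = ""
    family: str = ""

    def __post_init__(self):
        if not 0 <= self.min_masl <= self.max_masl:
            raise StatsError(
                f"invalid elevational limits {self.min_masl}-{self.max_masl} "
                f"for {self.species} on {self.island}"
            )


@dataclass
class TestResult:
    statistic: str  # "W" | "X2" | "F"
    value: float
    n: tuple[int, ...]
    p_value: float
    method: str = ""


def classify_population(pop: IslandPopulation) -> str:
    """"MIP" if the population has never been recorded below 100 masl
    (minimum elevation >= 100), else "LIP"."""
    return "MIP" if pop.min_masl >= MONTANE_FLOOR_MASL else "LIP"


def read_population_table(path_or_buf, sep: str = "\t") -> list[IslandPopulation]:
    df = pd.read_csv(path_or_buf, sep=sep)
    required = {"species", "island", "archipelago", "min_masl", "max_masl"}
    missing = required - set(df.columns)
    if missing:
        raise StatsError(f"population table lacks column(s): {sorted(missing)}")
    return [
        IslandPopulation(
            species=str(r.species),
            island=str(r.island),
            archipelago=str(r.archipelago),
            min_masl=float(r.min_masl),
            max_masl=float(r.max_masl),
            genus=str(getattr(r, "genus", "")),
            family=str(getattr(r, "family", "")),
        )
        for r in df.itertuples()
    ]


def summarize_species(
    populations: list[IslandPopulation],
    classifications: pd.DataFrame | None = None,
    ages: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-species roll-up of MIP/LIP counts.

    ``classifications`` (optional) is a frame with columns ``species`` and
    ``origin`` (plus any ancestry-probability columns, carried through);
    species classified but absent from the population table are warned
    about and kept with zero counts.  ``ages`` maps species to divergence
    age in Ma.

    A species with populations in both archipelagos contributes to both
    regional counts.
    """
    rows: dict[str, dict] = {}
    for pop in populations:
        rec = rows.setdefault(
            pop.species,
            {
                "species": pop.species,
                "n_mips": 0,
                "n_lips": 0,
                "n_mips_wallacea": 0,
                "n_mips_bismarcks_solomons": 0,
            },
        )
        if classify_population(pop) == "MIP":
            rec["n_mips"] += 1
            if pop.archipelago == "Wallacea":
                rec["n_mips_wallacea"] += 1
            else:
                rec["n_mips_bismarcks_solomons"] += 1
        else:
            rec["n_lips"] += 1

    if classifications is not None:
        known = set(rows)
        for _, crow in classifications.iterrows():
            sp = crow["species"]
            if sp not in known:
                warnings.warn(
                    f"species {sp!r} classified but absent from the "
                    "population table; kept with zero counts"
                )
                rows[sp] = {
                    "species": sp,
                    "n_mips": 0,
                    "n_lips": 0,
                    "n_mips_wallacea": 0,
                    "n_mips_bismarcks_solomons": 0,
                }

    df = pd.DataFrame(sorted(rows.values(), key=lambda r: r["species"]))
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "species", "n_mips", "n_lips", "n_mips_wallacea",
                "n_mips_bismarcks_solomons",
            ]
        )
    total = df["n_mips"] + df["n_lips"]
    df["p_mip"] = df["n_mips"] / total.replace(0, np.nan)
    if classifications is not None:
        df = df.merge(classifications, on="species", how="left")
    if ages:
        df["divergence_age"] = df["species"].map(ages)
    return df


def regional_rollup(summaries: pd.DataFrame) -> pd.DataFrame:
    """Study-wide roll-up: species and MIP counts, total and per region,
    split by origin group."""
    out = []
    regions = {
        "All archipelagos": "n_mips",
        "Wallacea": "n_mips_wallacea",
        "Bismarcks/Solomons": "n_mips_bismarcks_solomons",
    }
    has_origin = "origin" in summaries.columns
    for label, col in regions.items():
        present = summaries[summaries[col] > 0]
        row = {
            "region": label,
            "n_species": len(present),
            "n_mips": int(summaries[col].sum()),
        }
        if has_origin:
            for grp in ("Eurasian", "Australo-Papuan", "unresolved"):
                sub = present[present["origin"] == grp]
                row[f"n_species_{grp}"] = len(sub)
                row[f"n_mips_{grp}"] = int(sub[col].sum())
        out.append(row)
    return pd.DataFrame(out)


# -- tests -------------------------------------------------------------


def mann_whitney_w(group1, group2) -> TestResult:
    """Mann-Whitney rank-sum test; W is the statistic of the first group.

    ``W = (rank sum of group1, midranks for ties) - n1(n1+1)/2``.  The
    two-sided p-value uses the normal approximation with tie and
    continuity corrections; when ``n1*n2 <= 400`` and the pooled sample is
    tie-free, the exact permutation distribution is used instead.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise StatsError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = not has_ties and len(x) * len(y) <= EXACT_MW_LIMIT

    ranks = scipy.stats.rankdata(pooled)
    w = float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2)
    if exact:
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
        method = "normal approximation, tie and continuity corrected"
    # scipy's U1 must agree with the rank-sum W convention used here
    assert abs(float(res.statistic) - w) <= 1e-9
    return TestResult(
        statistic="W", value=w, n=(len(x), len(y)),
        p_value=float(res.pvalue), method=method,
    )


def chi_square_2x2(table) -> TestResult:
    """Pearson chi-squared on a 2x2 table with the Yates continuity
    correction: sum of (max(|O-E| - 0.5, 0))^2 / E, df = 1."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise StatsError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise StatsError("counts must be non-negative integers")
    n = t.sum()
    if n <= 0:
        raise StatsError("empty table")
    row, col = t.sum(axis=1), t.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise StatsError("zero marginal total")
    expected = np.outer(row, col) / n
    x2 = float(((np.maximum(np.abs(t - expected) - 0.5, 0)) ** 2 / expected).sum())
    p = float(scipy.stats.chi2.sf(x2, df=1))
    return TestResult(
        statistic="X2", value=x2, n=(int(n),), p_value=p,
        method="Pearson with Yates continuity correction, df=1",
    )


def group_medians_and_proportions(
    summaries: pd.DataFrame,
    grouping: str = "origin",
    variables: tuple[str, ...] = ("n_mips", "p_mip"),
) -> pd.DataFrame:
    """Per-group plain medians (midpoint of the two central order
    statistics for even n) of the requested variables."""
    out = []
    for grp, sub in summaries.groupby(grouping):
        if len(sub) == 0:
            raise StatsError(f"empty group {grp!r}")
        row = {grouping: grp, "n": len(sub)}
        for var in variables:
            if var in sub.columns:
                row[f"median_{var}"] = float(sub[var].median())
        out.append(row)
    return pd.DataFrame(out)


def competition_flags(
    mip: IslandPopulation, island_assemblage: list[IslandPopulation]
) -> tuple[bool, bool, int]:
    """Potential lowland competition faced by one MIP on its island.

    ``island_assemblage`` must be the lowland breeders (min elevation
    below 100 masl) on the MIP's island.  Returns whether the MIP shares
    the island with a lowland congener, with a lowland confamilial, and
    the lowland assemblage size (for the diffuse-competition rank test).
    """
    lowland = [
        p for p in island_assemblage
        if p.island == mip.island
        and p.min_masl < MONTANE_FLOOR_MASL
        and p.species != mip.species
    ]
    congener = any(p.genus == mip.genus and p.genus for p in lowland)
    confamilial = any(p.family == mip.family and p.family for p in lowland)
    return congener, confamilial, len(lowland)
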