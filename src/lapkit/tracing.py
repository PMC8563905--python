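"""Monosynaptic rabies-tracing input quantification.

Takes a table of manually annotated neurons — starter (seed) cells
co-infected by helper and G-deleted rabies virus, and input cells
labeled by rabies alone — each assigned an atlas region acronym and a
hemisphere, and produces the standard per-region summary: per-animal
input fractions, pooled mean ± SEM across animals, seeding efficiency
(inputs per starter), and the ipsilateral bias.  Animals are weighted
equally (fractions are computed per animal before pooling); a display
cutoff (default 0.3%) flags minor inputs for exclusion from bar graphs
without ever touching the totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegionInputSummary",
    "validate_annotations",
    "tabulate_regions",
    "pool_fractions",
    "summarize_tracing",
    "seeding_efficiency",
    "laterality_bias",
    "DEFAULT_ATLAS_ACRONYMS",
]

REQUIRED_COLUMNS = ("animal_id", "cell_id", "class", "region_acronym", "hemisphere")
CLASSES = ("starter", "input")
HEMISPHERES = ("ipsi", "contra")
DISPLAY_CUTOFF_PERCENT = 0.3

#: A small working set of Allen-atlas-style acronyms for the hindbrain-centred
#: regions this analysis encounters; callers studying other regions should
#: supply their own acronym list.
DEFAULT_ATLAS_ACRONYMS = (
    "MY", "P", "MB", "CTX", "CB", "CNU", "DCN", "SC", "Mes5",
    "IRN", "GRN", "PARN", "PCRt", "Peri5", "V", "XII", "NTS", "SpV",
)


@dataclass(frozen=True)
class RegionInputSummary:
    """Per-region input percentages with pooled statistics.

    ``per_animal`` — animals × regions table of percentages (rows sum to
    100 before any display filtering).  ``pooled`` — one row per region
    with mean percent, SEM across animals (absent for a single animal)
    and the display-exclusion flag.  Totals and laterality/efficiency
    live alongside.
    """

    per_animal: pd.DataFrame
    pooled: pd.DataFrame
    n_inputs: int
    n_starters: int
    n_animals: int
    min_percent: float
    ipsi_percent_mean: float | None = None
    ipsi_percent_sem: float | None = None
    efficiency_mean: float | None = None
    efficiency_sem: float | None = None


def validate_annotations(
    table: pd.DataFrame,
    atlas_acronyms: tuple[str, ...] | list[str] = DEFAULT_ATLAS_ACRONYMS,
) -> pd.DataFrame:
    """Validate an annotation table against the closed vocabularies.

    Checks required columns, class/hemisphere vocabularies, per-animal
    cell-id uniqueness, and that every region acronym is in the supplied
    atlas list.  Returns the table unchanged on success.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table is missing columns {missing}")
    bad_class = set(table["class"]) - set(CLASSES)
    if bad_class:
        raise ValueError(f"unknown cell classes {sorted(bad_class)}; expected {CLASSES}")
    blank = table["hemisphere"].isna() | (table["hemisphere"].astype(str).str.strip() == "")
    if blank.any():
        idx = table.index[blank][0]
        raise ValueError(
            f"hemisphere missing on record {idx} "
            f"(animal {table.loc[idx, 'animal_id']}, cell {table.loc[idx, 'cell_id']})"
        )
    bad_hemi = set(table["hemisphere"]) - set(HEMISPHERES)
    if bad_hemi:
        raise ValueError(f"unknown hemisphere labels {sorted(bad_hemi)}; expected {HEMISPHERES}")
    unknown = sorted(set(table["region_acronym"]) - set(atlas_acronyms))
    if unknown:
        raise ValueError(f"region acronyms not in the atlas list: {unknown}")
    dup = table.duplicated(subset=["animal_id", "cell_id"])
    if dup.any():
        pair = table.loc[dup.idxmax(), ["animal_id", "cell_id"]].tolist()
        raise ValueError(f"duplicate cell id {pair[1]!r} for animal {pair[0]!r}")
    return table


def tabulate_regions(
    table: pd.DataFrame,
    atlas_acronyms: tuple[str, ...] | list[str] = DEFAULT_ATLAS_ACRONYMS,
) -> pd.DataFrame:
    """Counts of input-class cells per (animal, region); starters excluded.

    Returns an animals × regions DataFrame of integer counts.
    """
    validate_annotations(table, atlas_acronyms)
    inputs = table[table["class"] == "input"]
    counts = (
        inputs.groupby(["animal_id", "region_acronym"]).size().unstack(fill_value=0)
    )
    return counts


def pool_fractions(
    counts: pd.DataFrame,
    min_percent: float = DISPLAY_CUTOFF_PERCENT,
    mode: str = "per_animal",
) -> RegionInputSummary:
    """Normalize per-animal counts to percentages and pool across animals.

    ``per_animal`` mode (default): each animal's counts are converted to
    percentages of that animal's total, then averaged unweighted across
    animals (mean ± SEM).  ``pooled_counts`` mode: percentages of the
    summed counts (no SEM).  Regions whose pooled mean falls below
    ``min_percent`` are flagged for exclusion from display but retained
    in every table and total.  Animals with zero inputs are dropped with
    a warning flag rather than an error.
    """
    if counts.size == 0 or counts.values.sum() == 0:
        raise ValueError("no input cells to pool")
    totals = counts.sum(axis=1)
    empty = totals == 0
    counts = counts.loc[~empty]
    totals = totals.loc[~empty]
    percents = counts.div(totals, axis=0) * 100.0
    n_animals = len(percents)
    if mode == "per_animal":
        mean = percents.mean(axis=0)
        sem = percents.std(axis=0, ddof=1) / np.sqrt(n_animals) if n_animals > 1 else None
    elif mode == "pooled_counts":
        mean = counts.sum(axis=0) / counts.values.sum() * 100.0
        sem = None
    else:
        raise ValueError(f"unknown pooling mode {mode!r}")
    pooled = pd.DataFrame({"mean_percent": mean})
    pooled["sem_percent"] = sem if sem is not None else np.nan
    pooled["display_excluded"] = pooled["mean_percent"] < min_percent
    pooled = pooled.sort_values("mean_percent", ascending=False)
    return RegionInputSummary(
        per_animal=percents,
        pooled=pooled,
        n_inputs=int(counts.values.sum()),
        n_starters=0,  # filled by callers holding the full table
        n_animals=n_animals,
        min_percent=min_percent,
    )


def summarize_tracing(
    table: pd.DataFrame,
    atlas_acronyms: tuple[str, ...] | list[str] = DEFAULT_ATLAS_ACRONYMS,
    min_percent: float = DISPLAY_CUTOFF_PERCENT,
    mode: str = "per_animal",
) -> RegionInputSummary:
    """One-stop summary: region fractions, totals, laterality, efficiency."""
    counts = tabulate_regions(table, atlas_acronyms)
    summary = pool_fractions(counts, min_percent=min_percent, mode=mode)
    _, ipsi_mean, ipsi_sem = laterality_bias(table)
    _, eff_mean, eff_sem = seeding_efficiency(table)
    from dataclasses import replace as _replace

    return _replace(
        summary,
        n_starters=int((table["class"] == "starter").sum()),
        ipsi_percent_mean=ipsi_mean,
        ipsi_percent_sem=ipsi_sem,
        efficiency_mean=eff_mean,
        efficiency_sem=eff_sem,
    )


def seeding_efficiency(table: pd.DataFrame) -> tuple[pd.Series, float, float | None]:
    """Inputs per starter, per animal, and the across-animal mean ± SEM.

    The reported efficiency is the mean of per-animal ratios (each animal
    weighted equally), not the ratio of pooled counts — the two differ
    whenever animals vary in starter number.
    """
    validate_annotations(table, tuple(pd.unique(table["region_acronym"])))
    per_animal = {}
    for animal, grp in table.groupby("animal_id"):
        n_start = int((grp["class"] == "starter").sum())
        n_in = int((grp["class"] == "input").sum())
        if n_start == 0:
            raise ValueError(f"animal {animal!r} has no starter cells; efficiency undefined")
        per_animal[animal] = n_in / n_start
    ratios = pd.Series(per_animal, name="inputs_per_starter")
    mean = float(ratios.mean())
    sem = float(ratios.std(ddof=1) / np.sqrt(len(ratios))) if len(ratios) > 1 else None
    return ratios, mean, sem


def laterality_bias(table: pd.DataFrame) -> tuple[pd.Series, float, float | None]:
    """Percent of input cells ipsilateral to the injection, per animal,
    and the across-animal mean ± SEM."""
    validate_annotations(table, tuple(pd.unique(table["region_acronym"])))
    inputs = table[table["class"] == "input"]
    per_animal = {}
    for animal, grp in inputs.groupby("animal_id"):
        n = len(grp)
        if n == 0:
            continue
        per_animal[animal] = float((grp["hemisphere"] == "ipsi").mean() * 100.0)
    pct = pd.Series(per_animal, name="percent_ipsi")
    mean = float(pct.mean())
    sem = float(pct.std(ddof=1) / np.sqrt(len(pct))) if len(pct) > 1 else None
    return pct, mean, sem
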