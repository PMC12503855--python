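"""Census data model: stage ontology, fate resolution, transition tabulation.

The census design is an annual (July) revisit of permanently tagged
ramets in fixed plots.  A ramet is recorded aboveground in one of six
stages; absence from a census is ambiguous between belowground dormancy
("inactive", IA) and death, and is resolved retrospectively: a tag that
reappears after missing one or two growing seasons was inactive in the
gap years, while a tag missing three consecutive seasons with no
reappearance is assumed dead from the first missing year.  Flowering
ramets are monocarpic — they die after seed set — so the flowering
stages have no survival transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Living stage codes, in canonical matrix order.
#: Sd seedling; SR juvenile single rosette; MR juvenile multiple rosette;
#: SF flowering single rosette; MF flowering multiple rosette; IA inactive.
STAGES = ("Sd", "SR", "MR", "SF", "MF", "IA")
DEAD = "DEAD"

#: Stages that can act as the origin of a survival transition.
#: SF and MF are monocarpic: they always die, so they are never origins.
ORIGIN_STAGES = ("Sd", "SR", "MR", "IA")
FATE_STAGES = ("SR", "MR", "SF", "MF", "IA", DEAD)

#: Recruit classes: entry stage of a tag at its first observation.
RECRUIT_CLASSES = ("Sd_rec", "SR_rec", "MR_rec", "SF_rec", "MF_rec")

#: Distance threshold (cm) beyond which an untagged rosette is
#: conservatively treated as a new ramet rather than a resprout of the
#: nearest existing tag.
NEW_RAMET_DISTANCE_CM = 10.0

CENSUS_COLUMNS = ["site", "plot", "tag_id", "year", "stage", "dist_cm", "cotyledons"]


class CensusError(ValueError):
    """Raised for malformed or inconsistent census records."""


def classify_new_ramet(distance_to_nearest_tag_cm: float | None,
                       has_cotyledons: bool) -> str:
    """Classify a first-time observation of an untagged rosette.

    Cotyledon leaves identify a seedling regardless of distance; beyond
    ``NEW_RAMET_DISTANCE_CM`` from the nearest existing tag the rosette
    is a new vegetative sprout; otherwise it is attributed to the
    nearest existing tag (a resprout of that ramet).

    Returns one of ``"seedling_recruit"``, ``"new_sprout_recruit"``,
    ``"attributed_to_existing_tag"``.
    """
    if has_cotyledons:
        return "seedling_recruit"
    if distance_to_nearest_tag_cm is None or (
            isinstance(distance_to_nearest_tag_cm, float)
            and np.isnan(distance_to_nearest_tag_cm)):
        raise CensusError(
            "first observation without a distance to the nearest tag "
            "cannot be classified")
    if distance_to_nearest_tag_cm < 0:
        raise CensusError("distance must be nonnegative")
    if distance_to_nearest_tag_cm > NEW_RAMET_DISTANCE_CM:
        return "new_sprout_recruit"
    return "attributed_to_existing_tag"


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = {"site", "plot", "tag_id", "year", "stage"} - set(records.columns)
    if missing:
        raise CensusError(f"census table missing columns: {sorted(missing)}")
    bad = set(records["stage"]) - set(STAGES) - {DEAD}
    if bad:
        raise CensusError(f"unknown stage codes: {sorted(bad)}")
    dup = records.duplicated(subset=["site", "plot", "tag_id", "year"])
    if dup.any():
        rows = records.loc[dup, ["site", "plot", "tag_id", "year"]].iloc[0]
        raise CensusError(f"duplicate tag-year observation: {tuple(rows)}")
    return records


def resolve_fates(records: pd.DataFrame) -> pd.DataFrame:
    """Impute inactive (IA) and dead (DEAD) years into a census table.

    For each tag, gaps of 1–2 years between observations become IA
    rows; a tag absent for >= 3 seasons before the site's final census
    year, and never seen again, receives a single DEAD row at its first
    missing year.  Tags still present (or missing < 3 years) at the end
    of the series are right-censored: no DEAD row is emitted, because
    the inactive-vs-dead distinction needs a future reappearance.

    Idempotent: resolving an already-resolved table is a no-op.
    """
    records = _validate_records(records.copy())
    if records.empty:
        return records.reindex(columns=CENSUS_COLUMNS)
    for col in ("dist_cm", "cotyledons"):
        if col not in records.columns:
            records[col] = np.nan

    final_year = records.groupby("site")["year"].max()
    out = [records]
    for (site, plot, tag), grp in records.groupby(["site", "plot", "tag_id"],
                                                  sort=False):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy()
        stages = grp["stage"].to_numpy()
        if DEAD in stages[:-1]:
            raise CensusError(f"tag {tag}: observations after a DEAD record")
        new_rows = []
        for y0, y1 in zip(years[:-1], years[1:]):
            gap = y1 - y0 - 1
            if gap == 0:
                continue
            if gap > 2:
                raise CensusError(
                    f"tag {tag}: reappeared after {gap} missing seasons; "
                    "a gap longer than 2 years cannot be inactive")
            for y in range(y0 + 1, y1):
                new_rows.append((site, plot, tag, y, "IA"))
        last_year, last_stage = years[-1], stages[-1]
        if last_stage != DEAD:
            absent = final_year[site] - last_year
            if last_stage in ("SF", "MF"):
                # monocarpic: flowering ramets die after seed set
                if absent >= 1:
                    new_rows.append((site, plot, tag, last_year + 1, DEAD))
            elif absent >= 3:
                new_rows.append((site, plot, tag, last_year + 1, DEAD))
        if new_rows:
            out.append(pd.DataFrame(new_rows,
                                    columns=["site", "plot", "tag_id",
                                             "year", "stage"]))
    resolved = pd.concat(out, ignore_index=True)
    resolved = resolved.sort_values(["site", "plot", "tag_id", "year"],
                                    kind="stable").reset_index(drop=True)
    return resolved.reindex(columns=CENSUS_COLUMNS)


@dataclass
class TransitionTable:
    """Per-site, per-year tally of stage transitions, recruits, exposures.

    counts
        Wide table indexed by (year, origin) with one column per fate in
        ``FATE_STAGES``; ``counts.loc[(t, o), f]`` is the number of
        tracked ramets in stage *o* at census *t* that were in state *f*
        at census *t+1*.
    recruits
        Long table (year, plot, rec_class, n): tags first observed in
        *year*, classed by their entry stage (``Sd_rec`` ... ``MF_rec``).
    exposures
        Long table (year, plot, stage, n): ramets present per stage at
        each census, the denominators for recruitment rates.
    """

    site: str
    counts: pd.DataFrame
    recruits: pd.DataFrame
    exposures: pd.DataFrame

    def flowering_at(self, year: int) -> int:
        sel = self.exposures.query("year == @year and stage in ('SF', 'MF')")
        return int(sel["n"].sum())

    def sprout_pool_at(self, year: int) -> int:
        """Ramets that could plausibly own an anonymous taproot sprout."""
        sel = self.exposures.query("year == @year and stage in ('SR', 'MR', 'IA')")
        return int(sel["n"].sum())


def tabulate_transitions(records: pd.DataFrame, site: str) -> TransitionTable:
    """Count annual origin→fate moves and recruits for one site.

    Requires fates already resolved.  Every ramet alive at census *t*
    with a record at *t+1* (including an imputed DEAD row) contributes
    exactly one count; tags right-censored at the final census
    contribute exposures but no transition.
    """
    sub = records[records["site"] == site]
    counts: dict[tuple[int, str], dict[str, int]] = {}
    rec_rows: list[tuple[int, str, str, int]] = []
    expo: dict[tuple[int, str, str], int] = {}

    for (plot, tag), grp in sub.groupby(["plot", "tag_id"], sort=False):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy()
        stages = grp["stage"].to_numpy()
        if stages[0] == DEAD:
            raise CensusError(f"tag {tag}: first record is DEAD")
        first_stage = stages[0] if stages[0] in STAGES else None
        if first_stage is not None:
            rec_rows.append((int(years[0]), plot, f"{first_stage}_rec", 1))
        for y, s in zip(years, stages):
            if s in STAGES:
                key = (int(y), plot, s)
                expo[key] = expo.get(key, 0) + 1
        for (y0, s0), (y1, s1) in zip(zip(years[:-1], stages[:-1]),
                                      zip(years[1:], stages[1:])):
            if s0 == DEAD:
                raise CensusError(f"tag {tag}: DEAD used as transition origin")
            if y1 != y0 + 1:
                raise CensusError(
                    f"tag {tag}: unresolved gap {y0}->{y1}; run resolve_fates first")
            if s0 in ("SF", "MF"):
                continue  # monocarpic terminus; enters fecundity, not survival
            row = counts.setdefault((int(y0), s0), dict.fromkeys(FATE_STAGES, 0))
            row[s1] += 1

    if counts:
        cdf = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
        cdf.index = pd.MultiIndex.from_tuples(cdf.index, names=["year", "origin"])
        cdf = cdf.reindex(columns=list(FATE_STAGES), fill_value=0).sort_index()
    else:
        cdf = pd.DataFrame(columns=list(FATE_STAGES),
                           index=pd.MultiIndex.from_tuples([],
                                                           names=["year", "origin"]))
    rdf = pd.DataFrame(rec_rows, columns=["year", "plot", "rec_class", "n"])
    if not rdf.empty:
        rdf = (rdf.groupby(["year", "plot", "rec_class"], as_index=False)["n"]
               .sum().sort_values(["year", "plot", "rec_class"])
               .reset_index(drop=True))
    edf = pd.DataFrame([(y, p, s, n) for (y, p, s), n in sorted(expo.items())],
                       columns=["year", "plot", "stage", "n"])
    return TransitionTable(site=site, counts=cdf, recruits=rdf, exposures=edf)


def read_census_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return _validate_records(df)


def write_census_csv(records: pd.DataFrame, path) -> None:
    records.reindex(columns=CENSUS_COLUMNS).to_csv(path, index=False)
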