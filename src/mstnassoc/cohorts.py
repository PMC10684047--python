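"""Record editing and contemporary-group construction.

Calving and carcass records pass through ordered edit filters (each removal
attributed to the first rule that catches it, with an audit trail), then are
clustered into contemporary groups: herd-year-season groups for calving
(10-day chain clusters, small clusters merged with their nearest neighbour
while the merged span stays under 90 days, groups under 3 records dropped)
and herd-year-sex groups for carcass (60-day chain clusters retained when
they contain at least five genotyped animals).

Numeric bounds are inclusive unless the source wording is strict: parities
"greater than 15" are removed (15 kept), first calvings "younger than 660
days" are removed (660 kept), carcass weights between 100 and 800 kg are
kept inclusive, merged spans must be strictly under 90 days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EditAudit:
    rule: str
    n_in: int
    n_removed: int

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


@dataclass
class ContemporaryGroup:
    group_id: str
    herd: object
    members: list
    first_date: pd.Timestamp
    last_date: pd.Timestamp

    @property
    def span_days(self) -> int:
        return int((self.last_date - self.first_date).days)

    def __len__(self) -> int:
        return len(self.members)


def _require(records: pd.DataFrame, columns: list[str], what: str):
    for c in columns:
        if c not in records.columns:
            raise KeyError(f"{what} records lack required column {c!r}")
        bad = records.index[records[c].isna()] if c not in (
            "sire", "days_since_herd_move") else []
        if len(bad):
            raise ValueError(
                f"{what} record {bad[0]!r} is missing required field {c!r}")


def _apply_rules(records: pd.DataFrame, rules) -> tuple[pd.DataFrame, list[EditAudit]]:
    audits = []
    df = records
    for name, predicate in rules:
        remove = predicate(df)
        remove = remove.fillna(False).astype(bool)
        audits.append(EditAudit(rule=name, n_in=len(df), n_removed=int(remove.sum())))
        df = df.loc[~remove]
    return df.copy(), audits


def parity_age_medians(records: pd.DataFrame) -> dict[int, float]:
    """Median age at calving (days) per parity, from the data themselves."""
    return records.groupby("parity")["age_days"].median().to_dict()


def edit_calving_records(
    records: pd.DataFrame,
    parity_medians: dict[int, float] | None = None,
) -> tuple[pd.DataFrame, list[EditAudit]]:
    """Ordered calving-record edits.

    Expected columns: calf, dam, sire, herd, date, parity, age_days, score,
    twin, embryo_transfer, breed_society, genotyped_pair.
    """
    _require(records, ["dam", "herd", "date", "parity", "age_days", "score"], "calving")
    med = parity_medians or parity_age_medians(records)
    year = pd.to_datetime(records["date"]).dt.year
    herd_year = records["herd"].astype(str) + ":" + year.astype(str)
    records = records.assign(_hy=herd_year)

    def age_dev(df):
        m = df["parity"].map(med)
        return (df["age_days"] - m).abs() > 425

    def hy_no_variability(df):
        nun = df.groupby("_hy")["score"].transform("nunique")
        return nun <= 1

    def hy_few_genotyped(df):
        g = df.groupby("_hy")["genotyped_pair"].transform("sum")
        return g < 5

    rules = [
        ("parity > 15", lambda df: df["parity"] > 15),
        ("age deviates > 425 d from parity median", age_dev),
        ("first parity younger than 660 d", lambda df: (df["parity"] == 1) & (df["age_days"] < 660)),
        ("twin birth or embryo transfer", lambda df: df["twin"] | df["embryo_transfer"]),
        ("herd-year without score variability", hy_no_variability),
        ("herd-year with < 5 genotyped dam-progeny pairs", hy_few_genotyped),
        ("missing sire", lambda df: df["sire"].isna()),
        ("breed-society registered", lambda df: df["breed_society"]),
    ]
    out, audits = _apply_rules(records, rules)
    return out.drop(columns="_hy"), audits


def edit_carcass_records(records: pd.DataFrame) -> tuple[pd.DataFrame, list[EditAudit]]:
    """Ordered carcass-record edits.

    Expected columns: animal, herd, slaughter_date, sex_class (steer /
    heifer / young_bull), age_months, weight, dam_parity, embryo_transfer,
    n_lifetime_herds, days_since_herd_move (NA if the animal never moved),
    breed_society.
    """
    _require(records, ["animal", "herd", "slaughter_date", "sex_class",
                       "age_months", "weight"], "carcass")

    def age_window(df):
        yb = df["sex_class"] == "young_bull"
        ok = np.where(yb,
                      (df["age_months"] >= 12) & (df["age_months"] <= 24),
                      (df["age_months"] >= 14) & (df["age_months"] <= 36))
        return ~pd.Series(ok, index=df.index)

    rules = [
        ("age outside slaughter window for sex class", age_window),
        ("carcass weight outside 100-800 kg", lambda df: (df["weight"] < 100) | (df["weight"] > 800)),
        ("dam parity > 10 or embryo transfer",
         lambda df: (df["dam_parity"] > 10) | df["embryo_transfer"]),
        ("more than two lifetime herds or moved within 100 d of slaughter",
         lambda df: (df["n_lifetime_herds"] > 2)
         | (df["days_since_herd_move"].fillna(np.inf) <= 100)),
        ("breed-society registered", lambda df: df["breed_society"]),
    ]
    return _apply_rules(records, rules)


def _chain_clusters(dates: pd.Series, gap_days: int) -> list[list]:
    """Split date-sorted records into clusters broken where the gap between
    consecutive records exceeds gap_days."""
    order = dates.sort_values(kind="stable").index
    clusters, current, prev = [], [], None
    for idx in order:
        d = dates[idx]
        if prev is not None and (d - prev).days > gap_days:
            clusters.append(current)
            current = []
        current.append(idx)
        prev = d
    if current:
        clusters.append(current)
    return clusters


def assign_calving_contemporary_groups(
    records: pd.DataFrame,
    gap_days: int = 10,
    min_cluster: int = 10,
    max_merged_span: int = 90,
    min_size: int = 3,
) -> tuple[pd.Series, list[ContemporaryGroup]]:
    """Herd-year-season contemporary groups for calving records.

    Within each herd, records are chained into clusters with consecutive
    calvings at most ``gap_days`` apart.  Clusters with fewer than
    ``min_cluster`` records are merged with their nearest-in-time adjacent
    cluster while the merged first-to-last span stays under
    ``max_merged_span`` days, iterating until stable (ties merge with the
    earlier neighbour).  Groups with fewer than ``min_size`` records are
    discarded.  Returns a cg_id series (NA = discarded) and the group list.
    """
    dates = pd.to_datetime(records["date"])
    cg = pd.Series(pd.NA, index=records.index, dtype="object")
    groups: list[ContemporaryGroup] = []
    for herd in sorted(records["herd"].unique(), key=str):
        sub = records.index[records["herd"] == herd]
        clusters = _chain_clusters(dates[sub], gap_days)
        spans = [(dates[c].min(), dates[c].max()) for c in clusters]
        changed = True
        while changed:
            changed = False
            for i in range(len(clusters)):
                if len(clusters[i]) >= min_cluster:
                    continue
                cands = []
                if i > 0:
                    gap = (spans[i][0] - spans[i - 1][1]).days
                    merged_span = (spans[i][1] - spans[i - 1][0]).days
                    if merged_span < max_merged_span:
                        cands.append((gap, 0, i - 1))
                if i < len(clusters) - 1:
                    gap = (spans[i + 1][0] - spans[i][1]).days
                    merged_span = (spans[i + 1][1] - spans[i][0]).days
                    if merged_span < max_merged_span:
                        cands.append((gap, 1, i + 1))
                if not cands:
                    continue
                cands.sort()  # nearest in time; tie -> earlier neighbour
                j = cands[0][2]
                lo, hi = min(i, j), max(i, j)
                clusters[lo] = clusters[lo] + clusters[hi]
                spans[lo] = (min(spans[lo][0], spans[hi][0]),
                             max(spans[lo][1], spans[hi][1]))
                del clusters[hi], spans[hi]
                changed = True
                break
        seq = 0
        for c, (lo, hi) in zip(clusters, spans):
            if len(c) < min_size:
                continue
            gid = f"{herd}:{seq}"
            seq += 1
            cg[c] = gid
            groups.append(ContemporaryGroup(gid, herd, list(c), lo, hi))
    return cg, groups


def assign_carcass_contemporary_groups(
    records: pd.DataFrame,
    genotyped: pd.Series,
    gap_days: int = 60,
    min_genotyped: int = 5,
) -> tuple[pd.Series, list[ContemporaryGroup]]:
    """Herd-year-sex contemporary groups for carcass records: 60-day chain
    clusters within herd and sex class, retained when they contain at least
    ``min_genotyped`` genotyped animals."""
    dates = pd.to_datetime(records["slaughter_date"])
    cg = pd.Series(pd.NA, index=records.index, dtype="object")
    groups: list[ContemporaryGroup] = []
    keys = sorted(
        records.groupby(["herd", "sex_class"]).groups.items(),
        key=lambda kv: (str(kv[0][0]), str(kv[0][1])))
    for (herd, sex), sub in keys:
        seq = 0
        for c in _chain_clusters(dates[sub], gap_days):
            if int(genotyped[c].sum()) < min_genotyped:
                continue
            gid = f"{herd}:{sex}:{seq}"
            seq += 1
            cg[c] = gid
            groups.append(ContemporaryGroup(gid, herd, list(c), dates[c].min(), dates[c].max()))
    return cg, groups
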