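"""Dendrophenotypes: per-tree quantitative traits from ring-width records.

Covers the stress-response (Lloret) indices per reference stress period,
climate-quantile-conditioned mean indices, insect-defoliation reconstruction
from host/non-host comparison, and descriptive growth/needle traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dendrogwas.core import Chronology, ClimateSeries, IndexSeries, RingSeries


@dataclass
class StressPeriod:
    """A 1-3 year reference stress period (inclusive years)."""

    label: str
    start_year: int
    end_year: int
    window: int = 3  # pre/post averaging window, years

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError("start_year must be <= end_year")
        if not 1 <= self.end_year - self.start_year + 1 <= 3:
            raise ValueError("stress period must span 1-3 years")


@dataclass
class LloretIndices:
    """Resistance/recovery/resilience record for one tree and period.

    Rt = Gd/Gprev, Rc = Gpost/Gd, Rs = Gpost/Gprev, RRs = (Gpost-Gd)/Gprev,
    where Gprev/Gd/Gpost are mean ring widths before/during/after the
    stress period.  `missing_reason` is set (and the indices are NaN) when
    the series does not cover the required windows or a denominator is zero.
    """

    tree_id: str
    period: str
    g_prev: float = np.nan
    g_d: float = np.nan
    g_post: float = np.nan
    rt: float = np.nan
    rc: float = np.nan
    rs: float = np.nan
    rrs: float = np.nan
    missing_reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return self.missing_reason is not None


def lloret_indices(series: RingSeries, period: StressPeriod) -> LloretIndices:
    """Lloret stress-response indices for one tree at one stress period.

    Gd averages the whole period; Gprev/Gpost are `period.window`-year
    means immediately before/after the period boundaries.  Records with a
    zero denominator are returned as missing, never +/-inf.
    """
    w = period.window
    a, b = period.start_year, period.end_year
    if series.first_year > a - w or series.last_year < b + w:
        return LloretIndices(
            series.tree_id, period.label,
            missing_reason=f"series does not cover {a - w}-{b + w}",
        )
    g_prev = float(np.mean(series.window(a - w, a - 1)))
    g_d = float(np.mean(series.window(a, b)))
    g_post = float(np.mean(series.window(b + 1, b + w)))
    if g_prev == 0.0 or g_d == 0.0:
        return LloretIndices(
            series.tree_id, period.label, g_prev, g_d, g_post,
            missing_reason="zero denominator",
        )
    rt = g_d / g_prev
    rc = g_post / g_d
    rs = g_post / g_prev
    return LloretIndices(
        series.tree_id, period.label, g_prev, g_d, g_post, rt, rc, rs, rs - rt
    )


def lloret_trait_table(
    series: list[RingSeries], periods: list[StressPeriod]
) -> pd.DataFrame:
    """Tree x trait table of Rt/Rc/Rs/RRs per stress period (NaN if missing)."""
    rows: dict[str, dict[str, float]] = {}
    for s in series:
        rec: dict[str, float] = {}
        for p in periods:
            li = lloret_indices(s, p)
            rec[f"Rt{p.label}"] = li.rt
            rec[f"Rc{p.label}"] = li.rc
            rec[f"Rs{p.label}"] = li.rs
            rec[f"RRs{p.label}"] = li.rrs
        rows[s.tree_id] = rec
    return pd.DataFrame.from_dict(rows, orient="index")


def conditioned_mean_indices(
    series: RingSeries,
    climate: ClimateSeries,
    variable: str,
    month: int,
    lag: str = "current",
    tail: str = "lower",
    q: float = 0.25,
) -> dict:
    """Mean single-year Lloret indices over climate-selected stress years.

    Stress years are those whose monthly climate value falls strictly in the
    stated tail of its empirical distribution (below the q-quantile for
    "lower", above the (1-q)-quantile for "upper").  With lag="previous"
    the ring year responding to a qualifying climate year is the following
    calendar year.  Single-year indices at each qualifying ring year are
    averaged per index; returns a dict with meanRt/meanRc/meanRs/meanRRs,
    the qualifying years, or missing_reason when none qualify.
    """
    if lag not in ("current", "previous"):
        raise ValueError("lag must be 'current' or 'previous'")
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    vals = climate.monthly(variable, month)
    if tail == "lower":
        thr = float(vals.quantile(q))
        qual_clim = vals.index[vals < thr]
    else:
        thr = float(vals.quantile(1.0 - q))
        qual_clim = vals.index[vals > thr]
    ring_years = [int(y) + (1 if lag == "previous" else 0) for y in qual_clim]
    recs = []
    for y in ring_years:
        li = lloret_indices(series, StressPeriod(str(y), y, y))
        if not li.is_missing:
            recs.append(li)
    if not recs:
        return {
            "tree_id": series.tree_id,
            "meanRt": np.nan, "meanRc": np.nan, "meanRs": np.nan, "meanRRs": np.nan,
            "years": [], "missing_reason": "no qualifying stress years",
        }
    return {
        "tree_id": series.tree_id,
        "meanRt": float(np.mean([r.rt for r in recs])),
        "meanRc": float(np.mean([r.rc for r in recs])),
        "meanRs": float(np.mean([r.rs for r in recs])),
        "meanRRs": float(np.mean([r.rrs for r in recs])),
        "years": [int(r.period) for r in recs],
        "missing_reason": None,
    }


@dataclass
class DefoliationEvent:
    """A reconstructed multi-year defoliation episode.

    `event_year` is the year of deepest median growth depression within the
    run; `response` flags, per candidate tree, whether the tree's own
    corrected series showed a qualifying depression overlapping the event.
    """

    event_year: int
    start_year: int
    end_year: int
    duration: int
    affected_tree_ids: list[str]
    response: dict[str, bool]
    prop_affected: float

    def __post_init__(self) -> None:
        assert self.duration == self.end_year - self.start_year + 1


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) index pairs of maximal True runs."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def detect_defoliation(
    host: list[IndexSeries],
    nonhost: Chronology,
    min_duration: int = 5,
    min_fraction: float = 0.25,
    depth_threshold: float = 1.28,
) -> list[DefoliationEvent]:
    """Reconstruct defoliation episodes from host vs non-host growth.

    For each host tree the non-host (climate-only) signal is removed:
    corrected_i = z(host_i) - (sd_host/sd_nonhost) * z(nonhost), then the
    corrected series is re-standardized.  A tree shows a defoliation signal
    where the corrected series stays below zero for >= min_duration
    consecutive years and dips below -depth_threshold at least once in that
    run.  An episode is emitted for every run of years in which at least
    min_fraction of candidate trees show a simultaneous signal.
    """
    nh_vals = np.asarray(nonhost.values, float)
    if np.std(nh_vals) == 0:
        raise ValueError("non-host chronology has zero variance")
    nh = pd.Series(nh_vals, index=nonhost.years)

    all_years = np.arange(
        min(s.first_year for s in host), max(s.last_year for s in host) + 1
    )
    corrected: dict[str, pd.Series] = {}
    signal_years: dict[str, set[int]] = {}
    for s in host:
        common = np.intersect1d(s.years, nonhost.years)
        if len(common) < min_duration + 2:
            continue
        h = pd.Series(s.indices, index=s.years).loc[common].to_numpy()
        n = nh.loc[common].to_numpy()
        # robust (median/MAD) center and scale: the outbreak signal itself
        # would otherwise inflate sd_host and over-subtract the non-host
        sd_h = 1.4826 * np.median(np.abs(h - np.median(h)))
        sd_n = 1.4826 * np.median(np.abs(n - np.median(n)))
        if sd_h == 0:
            continue
        ci = (h - np.median(h)) - (sd_h / sd_n) * (n - np.median(n))
        sd_c = 1.4826 * np.median(np.abs(ci - np.median(ci)))
        zc = (ci - np.median(ci)) / sd_c if sd_c > 0 else ci
        corrected[s.tree_id] = pd.Series(zc, index=common)
        flagged: set[int] = set()
        for i0, i1 in _runs(zc < 0):
            if i1 - i0 + 1 >= min_duration and zc[i0 : i1 + 1].min() < -depth_threshold:
                flagged.update(int(y) for y in common[i0 : i1 + 1])
        signal_years[s.tree_id] = flagged

    if not corrected:
        return []
    tree_ids = list(corrected)
    # per-year fraction of candidate trees showing signal
    frac = np.zeros(len(all_years))
    for k, y in enumerate(all_years):
        cand = [t for t in tree_ids if y in set(corrected[t].index)]
        if not cand:
            continue
        hits = sum(1 for t in cand if y in signal_years[t])
        frac[k] = hits / len(cand)

    events: list[DefoliationEvent] = []
    for i0, i1 in _runs(frac >= min_fraction):
        if i1 - i0 + 1 < min_duration:
            continue
        run_years = all_years[i0 : i1 + 1]
        # deepest median depression across trees showing signal
        medians = []
        for y in run_years:
            vals = [
                corrected[t].loc[y]
                for t in tree_ids
                if y in signal_years[t]
            ]
            medians.append(np.median(vals) if vals else np.inf)
        event_year = int(run_years[int(np.argmin(medians))])
        affected = sorted(
            t for t in tree_ids if signal_years[t] & set(int(y) for y in run_years)
        )
        response = {t: (t in affected) for t in tree_ids}
        events.append(
            DefoliationEvent(
                event_year=event_year,
                start_year=int(run_years[0]),
                end_year=int(run_years[-1]),
                duration=len(run_years),
                affected_tree_ids=affected,
                response=response,
                prop_affected=len(affected) / len(tree_ids),
            )
        )
    return events


def descriptive_traits(
    series: list[RingSeries],
    needles: pd.DataFrame | None = None,
    blocks: list[tuple[int, int]] | None = None,
    recent_window: int = 30,
) -> pd.DataFrame:
    """Descriptive growth (and optional needle) traits per tree.

    meanTRW/varTRW over the whole record, meanTRW30 over the last
    `recent_window` years, per-block meanTRW_/varTRW_ columns for each
    (start, end) block fully covered by the series, and meanL/varL joined
    from the needle table.  Variances are unbiased (ddof=1); uncovered
    blocks are NaN.
    """
    rows: dict[str, dict[str, float]] = {}
    for s in series:
        rec = {
            "meanTRW": float(np.mean(s.widths)),
            "varTRW": float(np.var(s.widths, ddof=1)) if len(s) > 1 else np.nan,
        }
        if len(s) >= recent_window:
            rec["meanTRW30"] = float(np.mean(s.widths[-recent_window:]))
        else:
            rec["meanTRW30"] = np.nan
        for a, b in blocks or []:
            key = f"{a}-{b}"
            if s.first_year <= a and s.last_year >= b:
                w = s.window(a, b)
                rec[f"meanTRW_{key}"] = float(np.mean(w))
                rec[f"varTRW_{key}"] = float(np.var(w, ddof=1)) if len(w) > 1 else np.nan
            else:
                rec[f"meanTRW_{key}"] = np.nan
                rec[f"varTRW_{key}"] = np.nan
        rows[s.tree_id] = rec
    out = pd.DataFrame.from_dict(rows, orient="index")
    if needles is not None:
        out = out.join(needles[["meanL", "varL"]], how="left")
    return out
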