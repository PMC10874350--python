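"""End-to-end analysis pipeline and replicated simulation studies.

``analyze_cohort`` runs the full chain on in-memory inputs: ULS-8 scoring and
group assignment, the complete-weeks inclusion filter, five-bin count/ratio
profiles, per-bin one-way ANOVAs with Tukey-Kramer post-hocs, the quadratic
shape-coefficient ANOVA, and weekday/weekend cosine similarity with pairwise
Welch tests. ``run_analysis`` is the file-based wrapper; ``run_simulation_study``
repeats generate-cohort + analyze to tabulate calibration and effect-direction
recovery for the three headline comparisons.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .features import (
    BIN_LABELS,
    InclusionDecision,
    ParticipantProfile,
    _profile_from_arrays,
    complete_week_set,
    completeness_filter,
    daily_bin_counts,
    participant_profile,
    profiles_frame,
)
from .group_stats import AnovaResult, TukeyResult, WelchResult, one_way_anova, tukey_hsd, welch_t
from .io import StudyCalendar, read_calendar, read_event_log, read_uls8_file
from .shape import BIN_MIDPOINT_HOURS, fit_quadratic, group_curve
from .similarity import UndefinedSimilarityError, weekday_weekend_similarity
from .synth import CohortBundle, SimCohortConfig, generate_cohort
from .uls8 import GROUP_LABELS, ULS8Response, assign_group, score_uls8

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "analyze_cohort",
    "run_analysis",
    "write_report",
    "HeadlineStats",
    "headline_stats",
    "run_simulation_study",
    "summarize_simulation",
]

HEADLINE_PAIR = ("very_severe", "no")


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis choices (defaults reproduce the headline pipeline)."""

    alpha: float = 0.05
    min_complete_weeks: int = 3
    ratio_method: str = "per_day"  # or "pooled"
    fit_abscissa: str = "index"  # or "midpoint_hours"

    @property
    def fit_x(self) -> np.ndarray | None:
        if self.fit_abscissa == "index":
            return None
        if self.fit_abscissa == "midpoint_hours":
            return BIN_MIDPOINT_HOURS
        raise ValueError(f"unknown fit_abscissa {self.fit_abscissa!r}")

    def hash(self, calendar: StudyCalendar) -> str:
        payload = json.dumps(
            {
                **dataclasses.asdict(self),
                "start_date": calendar.start_date.isoformat(),
                "n_weeks": calendar.n_weeks,
                "n_adjustment_weeks": calendar.n_adjustment_weeks,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclasses.dataclass
class AnalysisReport:
    """All pipeline outputs, machine-precision; text rendering rounds to 2 d.p."""

    inclusion: pd.DataFrame
    scores: pd.DataFrame
    group_summary: pd.DataFrame
    profiles: pd.DataFrame
    anova_table: pd.DataFrame
    tukey_table: pd.DataFrame
    similarity: pd.DataFrame
    similarity_group_means: pd.DataFrame
    welch_table: pd.DataFrame
    group_curves: pd.DataFrame
    group_fit_r: pd.DataFrame
    notes: list[str]
    provenance: dict

    @property
    def n_included(self) -> int:
        return int(self.inclusion["included"].sum())

    def to_json(self) -> str:
        def df(d: pd.DataFrame) -> list[dict]:
            return json.loads(d.to_json(orient="records"))

        payload = {
            name: df(getattr(self, name))
            for name in (
                "inclusion",
                "scores",
                "group_summary",
                "profiles",
                "anova_table",
                "tukey_table",
                "similarity",
                "similarity_group_means",
                "welch_table",
                "group_curves",
                "group_fit_r",
            )
        }
        payload["notes"] = self.notes
        payload["provenance"] = self.provenance
        return json.dumps(payload, indent=1, sort_keys=True)

    def to_text(self) -> str:
        lines = ["keyrhythm analysis report", "=" * 26, ""]
        lines.append(f"participants included: {self.n_included} of {len(self.inclusion)}")
        lines.append("")
        lines.append("group summary")
        for row in self.group_summary.itertuples(index=False):
            lines.append(
                f"  {row.group:<12} n={row.n:<3} ULS-8 {row.uls8_mean:.2f} ({row.uls8_sd:.2f})"
                f"  keystrokes {row.keystrokes_mean:,.0f} ({row.keystrokes_sd:,.0f})"
            )
        lines.append("")
        lines.append("one-way ANOVAs (per time section and quadratic coefficient)")
        for row in self.anova_table.itertuples(index=False):
            star = " *" if row.significant else ""
            lines.append(
                f"  {row.analysis:<14} F = {row.F:.2f}  df = ({row.df_between},{row.df_within})"
                f"  p = {row.p:.4f}{star}"
            )
        lines.append("")
        lines.append("weekday/weekend cosine similarity (group means)")
        for row in self.similarity_group_means.itertuples(index=False):
            lines.append(f"  {row.group:<12} n={row.n:<3} cosine {row.cosine_mean:.4f} ({row.cosine_sd:.4f})")
        lines.append("")
        lines.append("pairwise Welch's t on cosine similarity")
        for row in self.welch_table.itertuples(index=False):
            star = " *" if row.significant else ""
            head = "  [headline]" if row.headline else ""
            lines.append(
                f"  {row.group_a} vs {row.group_b}: t = {row.t:.2f}, df = {row.df:.1f},"
                f" p = {row.p:.4f}{star}{head}"
            )
        lines.append("")
        lines.append("group fitted-curve correlation (observed vs fitted mean counts)")
        for row in self.group_fit_r.itertuples(index=False):
            lines.append(f"  {row.group:<12} r = {row.r:.2f}")
        if self.notes:
            lines.append("")
            lines.append("notes")
            lines.extend(f"  - {n}" for n in self.notes)
        lines.append("")
        lines.append(f"provenance: {json.dumps(self.provenance, sort_keys=True)}")
        return "\n".join(lines) + "\n"


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")


def analyze_cohort(
    day_counts: Mapping[str, pd.DataFrame],
    uls8: Mapping[str, ULS8Response],
    calendar: StudyCalendar,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> AnalysisReport:
    """Run every analysis stage on per-participant daily bin counts."""
    config = config or AnalysisConfig()
    notes: list[str] = []
    pids = sorted(day_counts)
    missing_q = [p for p in pids if p not in uls8]
    if missing_q:
        raise ValueError(f"no ULS-8 response for participants {missing_q}")

    # scoring and group assignment
    totals = {p: score_uls8(uls8[p]) for p in pids}
    groups = {p: assign_group(totals[p]).label for p in pids}

    # completeness filter
    decisions: dict[str, InclusionDecision] = {
        p: completeness_filter(day_counts[p], calendar, config.min_complete_weeks) for p in pids
    }
    included = [p for p in pids if decisions[p].included]
    for p in pids:
        if not decisions[p].included:
            logger.info("excluded %s: %s", p, decisions[p].reason)
    inclusion = pd.DataFrame(
        {
            "participant_id": pids,
            "included": [decisions[p].included for p in pids],
            "complete_weeks": [
                ",".join(map(str, sorted(decisions[p].complete_weeks))) for p in pids
            ],
            "reason": [decisions[p].reason for p in pids],
        }
    )
    scores = pd.DataFrame(
        {
            "participant_id": pids,
            "uls8_total": [totals[p] for p in pids],
            "group": [groups[p] for p in pids],
            "included": [decisions[p].included for p in pids],
        }
    )

    # profiles over complete weeks
    profiles: dict[str, ParticipantProfile] = {
        p: participant_profile(day_counts[p], decisions[p], ratio_method=config.ratio_method)
        for p in included
    }
    prof_frame = profiles_frame([profiles[p] for p in included])
    prof_frame.insert(1, "group", [groups[p] for p in included])

    members = {g: [p for p in included if groups[p] == g] for g in GROUP_LABELS}
    testable = [g for g in GROUP_LABELS if len(members[g]) >= 2]
    for g in GROUP_LABELS:
        if len(members[g]) < 2:
            notes.append(
                f"group '{g}' has {len(members[g])} included participant(s); "
                "its group tests are skipped"
            )

    # group summary (keystroke total over the complete weeks actually used)
    summary_rows = []
    for g in GROUP_LABELS:
        if not members[g]:
            continue
        u = np.array([totals[p] for p in members[g]], dtype=float)
        ks = np.array(
            [
                day_counts[p]
                .loc[day_counts[p]["week"].isin(decisions[p].complete_weeks), "total"]
                .sum()
                for p in members[g]
            ],
            dtype=float,
        )
        summary_rows.append(
            {
                "group": g,
                "n": len(members[g]),
                "uls8_mean": u.mean(),
                "uls8_sd": _sd(u),
                "keystrokes_mean": ks.mean(),
                "keystrokes_sd": _sd(ks),
            }
        )
    group_summary = pd.DataFrame(summary_rows)

    # per-bin ANOVAs + Tukey, then the quadratic-coefficient ANOVA
    anova_rows, tukey_rows = [], []

    def add_test(name: str, values: Mapping[str, float]) -> AnovaResult | None:
        if len(testable) < 2:
            notes.append(f"ANOVA '{name}' skipped: fewer than 2 testable groups")
            return None
        samples = [[values[p] for p in members[g]] for g in testable]
        res = one_way_anova(samples)
        anova_rows.append(
            {
                "analysis": name,
                "F": res.F,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "p": res.p,
                "significant": res.p < config.alpha,
            }
        )
        tuk = tukey_hsd(samples)
        for pair in tuk.pairs:
            tukey_rows.append(
                {
                    "analysis": name,
                    "group_a": testable[pair.i],
                    "group_b": testable[pair.j],
                    "mean_diff": pair.mean_diff,
                    "q": pair.q,
                    "p_adjusted": pair.p_adjusted,
                    "significant": pair.p_adjusted < config.alpha,
                }
            )
        return res

    for j, bin_label in enumerate(BIN_LABELS):
        add_test(bin_label, {p: float(profiles[p].mean_counts[j]) for p in included})

    fits = {p: fit_quadratic(profiles[p].mean_counts, x=config.fit_x) for p in included}
    add_test("quadratic_a2", {p: fits[p].a2 for p in included})

    anova_table = pd.DataFrame(
        anova_rows, columns=["analysis", "F", "df_between", "df_within", "p", "significant"]
    )
    tukey_table = pd.DataFrame(
        tukey_rows,
        columns=["analysis", "group_a", "group_b", "mean_diff", "q", "p_adjusted", "significant"],
    )

    # weekday/weekend cosine similarity
    sim_rows = []
    cos: dict[str, float] = {}
    for p in included:
        try:
            cos[p] = weekday_weekend_similarity(profiles[p]).cosine
            sim_rows.append({"participant_id": p, "group": groups[p], "cosine": cos[p]})
        except UndefinedSimilarityError as exc:
            notes.append(str(exc))
    similarity = pd.DataFrame(sim_rows, columns=["participant_id", "group", "cosine"])
    sim_members = {g: [p for p in members[g] if p in cos] for g in GROUP_LABELS}
    sim_mean_rows = [
        {
            "group": g,
            "n": len(sim_members[g]),
            "cosine_mean": float(np.mean([cos[p] for p in sim_members[g]])),
            "cosine_sd": _sd(np.array([cos[p] for p in sim_members[g]])),
        }
        for g in GROUP_LABELS
        if sim_members[g]
    ]
    similarity_group_means = pd.DataFrame(sim_mean_rows)

    welch_rows = []
    order = [g for g in GROUP_LABELS if len(sim_members[g]) >= 2]
    for ai in range(len(order)):
        for bi in range(ai + 1, len(order)):
            ga, gb = order[ai], order[bi]
            if {ga, gb} == set(HEADLINE_PAIR):
                ga, gb = HEADLINE_PAIR  # report the headline contrast as very_severe vs no
            res = welch_t([cos[p] for p in sim_members[ga]], [cos[p] for p in sim_members[gb]])
            welch_rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "significant": res.p < config.alpha,
                    "headline": {ga, gb} == set(HEADLINE_PAIR),
                }
            )
    skipped_pairs = {g for g in GROUP_LABELS if len(sim_members[g]) < 2}
    if skipped_pairs & set(HEADLINE_PAIR):
        notes.append(
            f"headline Welch test ({HEADLINE_PAIR[0]} vs {HEADLINE_PAIR[1]}) skipped: "
            f"group(s) {sorted(skipped_pairs & set(HEADLINE_PAIR))} below 2 participants"
        )
    welch_table = pd.DataFrame(
        welch_rows, columns=["group_a", "group_b", "t", "df", "p", "significant", "headline"]
    )

    # group-level fitted curves
    curve_rows, r_rows = [], []
    for g in GROUP_LABELS:
        if not members[g]:
            continue
        observed, fitted, r = group_curve(
            [profiles[p].mean_counts for p in members[g]], x=config.fit_x
        )
        for j, bin_label in enumerate(BIN_LABELS):
            curve_rows.append(
                {
                    "group": g,
                    "bin": bin_label,
                    "observed_mean": float(observed[j]),
                    "fitted_mean": float(fitted[j]),
                }
            )
        r_rows.append({"group": g, "r": r if r is not None else float("nan")})
    group_curves = pd.DataFrame(curve_rows, columns=["group", "bin", "observed_mean", "fitted_mean"])
    group_fit_r = pd.DataFrame(r_rows, columns=["group", "r"])

    provenance = {
        "software": f"keyrhythm {__version__}",
        "config_hash": config.hash(calendar),
        "alpha": config.alpha,
        "ratio_method": config.ratio_method,
        "fit_abscissa": config.fit_abscissa,
        "seed": seed,
    }
    return AnalysisReport(
        inclusion=inclusion,
        scores=scores,
        group_summary=group_summary,
        profiles=prof_frame,
        anova_table=anova_table,
        tukey_table=tukey_table,
        similarity=similarity,
        similarity_group_means=similarity_group_means,
        welch_table=welch_table,
        group_curves=group_curves,
        group_fit_r=group_fit_r,
        notes=notes,
        provenance=provenance,
    )


def write_report(report: AnalysisReport, output_dir: str | Path) -> Path:
    """Write intermediate CSVs plus report.json / report.txt; returns the dir."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in (
        "inclusion",
        "scores",
        "group_summary",
        "profiles",
        "anova_table",
        "tukey_table",
        "similarity",
        "similarity_group_means",
        "welch_table",
        "group_curves",
        "group_fit_r",
    ):
        getattr(report, name).to_csv(outdir / f"{name}.csv", index=False)
    (outdir / "report.json").write_text(report.to_json(), encoding="utf-8")
    (outdir / "report.txt").write_text(report.to_text(), encoding="utf-8")
    return outdir


def run_analysis(
    events_dir: str | Path,
    uls8_path: str | Path,
    calendar: StudyCalendar | str | Path,
    output_dir: str | Path | None = None,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """File-based pipeline: read logs and questionnaire, analyze, write outputs."""
    if not isinstance(calendar, StudyCalendar):
        calendar = read_calendar(calendar)
    uls8 = read_uls8_file(uls8_path)
    events_dir = Path(events_dir)
    paths = sorted(
        p for p in events_dir.iterdir() if p.suffix in {".csv", ".jsonl", ".ndjson"}
    )
    if not paths:
        raise FileNotFoundError(f"no event logs (*.csv / *.jsonl) found in {events_dir}")
    day_counts: dict[str, pd.DataFrame] = {}
    for path in paths:
        log = read_event_log(path, calendar=calendar)
        day_counts[log.participant_id] = daily_bin_counts(log, calendar)
    report = analyze_cohort(day_counts, uls8, calendar, config=config)
    if output_dir is not None:
        write_report(report, output_dir)
    return report


# ---------------------------------------------------------------------------
# fast replicated simulation studies


@dataclasses.dataclass
class HeadlineStats:
    """The three headline comparisons on one cohort."""

    n_included: int
    group_ns: dict[str, int]
    sleep_group_means: dict[str, float]
    sleep_anova: AnovaResult | None
    very_severe_sleep_highest: bool
    a2_group_means: dict[str, float]
    a2_anova: AnovaResult | None
    cosine_group_means: dict[str, float]
    cosine_welch: WelchResult | None


def headline_stats(bundle: CohortBundle, config: AnalysisConfig | None = None) -> HeadlineStats:
    """Sleep-bin ANOVA, quadratic-coefficient ANOVA and headline Welch test.

    Operates directly on the generator's recorded per-day draws (identical to
    the event path by the ground-truth-fidelity invariant), skipping post-hoc
    tables, so thousands of replicates stay cheap.
    """
    config = config or AnalysisConfig()
    cal = bundle.config.calendar
    dates = cal.analysis_dates()
    is_weekend = np.array([d.weekday() >= 5 for d in dates])
    weeks = np.array([cal.week_of(d) for d in dates])
    skip = 7 * cal.n_adjustment_weeks

    sleep_by_group: dict[str, list[float]] = {g: [] for g in GROUP_LABELS}
    a2_by_group: dict[str, list[float]] = {g: [] for g in GROUP_LABELS}
    cos_by_group: dict[str, list[float]] = {g: [] for g in GROUP_LABELS}
    n_included = 0
    for pid, truth in bundle.truths.items():
        counts = truth.counts[skip:]
        complete = complete_week_set(counts.sum(axis=1), weeks, cal.analysis_weeks)
        if len(complete) < config.min_complete_weeks:
            continue
        n_included += 1
        keep = np.isin(weeks, list(complete))
        mean_counts, _, wk, we, *_ = _profile_from_arrays(counts[keep], is_weekend[keep])
        g = truth.group
        sleep_by_group[g].append(float(mean_counts[0]))
        a2_by_group[g].append(fit_quadratic(mean_counts, x=config.fit_x).a2)
        if wk is not None and we is not None:
            denom = float(np.linalg.norm(wk) * np.linalg.norm(we))
            if denom > 0:
                cos_by_group[g].append(float(wk @ we) / denom)

    group_ns = {g: len(v) for g, v in sleep_by_group.items()}
    testable = [g for g in GROUP_LABELS if group_ns[g] >= 2]

    def means(d: Mapping[str, Sequence[float]]) -> dict[str, float]:
        return {g: float(np.mean(v)) for g, v in d.items() if len(v)}

    sleep_means = means(sleep_by_group)
    sleep_anova = (
        one_way_anova([sleep_by_group[g] for g in testable]) if len(testable) >= 2 else None
    )
    highest = bool(
        "very_severe" in sleep_means
        and sleep_means["very_severe"] == max(sleep_means.values())
    )
    a2_anova = one_way_anova([a2_by_group[g] for g in testable]) if len(testable) >= 2 else None
    ga, gb = HEADLINE_PAIR
    cosine_welch = (
        welch_t(cos_by_group[ga], cos_by_group[gb])
        if len(cos_by_group[ga]) >= 2 and len(cos_by_group[gb]) >= 2
        else None
    )
    return HeadlineStats(
        n_included=n_included,
        group_ns=group_ns,
        sleep_group_means=sleep_means,
        sleep_anova=sleep_anova,
        very_severe_sleep_highest=highest,
        a2_group_means=means(a2_by_group),
        a2_anova=a2_anova,
        cosine_group_means=means(cos_by_group),
        cosine_welch=cosine_welch,
    )


def run_simulation_study(
    config: SimCohortConfig,
    n_replicates: int,
    seed: int = 0,
    analysis_config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Repeat generate-cohort + headline analysis; one row per replicate."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    analysis_config = analysis_config or AnalysisConfig()
    alpha = analysis_config.alpha
    rep_seeds = (
        np.random.SeedSequence(seed).generate_state(n_replicates, dtype=np.uint64) >> 33
    ).astype(int)
    rows = []
    for rep, rep_seed in enumerate(rep_seeds):
        cfg = dataclasses.replace(config, seed=int(rep_seed))
        hs = headline_stats(generate_cohort(cfg, events=False), analysis_config)
        sleep_p = hs.sleep_anova.p if hs.sleep_anova else float("nan")
        a2_p = hs.a2_anova.p if hs.a2_anova else float("nan")
        t = hs.cosine_welch.t if hs.cosine_welch else float("nan")
        welch_p = hs.cosine_welch.p if hs.cosine_welch else float("nan")
        a2 = hs.a2_group_means
        rows.append(
            {
                "replicate": rep,
                "seed": int(rep_seed),
                "n_included": hs.n_included,
                "sleep_F": hs.sleep_anova.F if hs.sleep_anova else float("nan"),
                "sleep_p": sleep_p,
                "sleep_reject": bool(sleep_p < alpha),
                "very_severe_sleep_highest": hs.very_severe_sleep_highest,
                "dir_sleep": bool(sleep_p < alpha and hs.very_severe_sleep_highest),
                "a2_F": hs.a2_anova.F if hs.a2_anova else float("nan"),
                "a2_p": a2_p,
                "a2_mean_no": a2.get("no", float("nan")),
                "a2_mean_moderate": a2.get("moderate", float("nan")),
                "a2_mean_severe": a2.get("severe", float("nan")),
                "a2_mean_very_severe": a2.get("very_severe", float("nan")),
                "dir_a2": bool(
                    a2.get("very_severe", float("nan")) > 0
                    and a2.get("no", float("nan")) < 0
                    and a2.get("moderate", float("nan")) < 0
                ),
                "cosine_t": t,
                "cosine_p": welch_p,
                "dir_cosine": bool(t > 0 and welch_p < alpha),
            }
        )
    return pd.DataFrame(rows)


def summarize_simulation(table: pd.DataFrame) -> dict[str, float]:
    """Rejection and direction-recovery rates over a simulation-study table."""
    return {
        "n_replicates": int(len(table)),
        "sleep_rejection_rate": float(table["sleep_reject"].mean()),
        "dir_sleep_rate": float(table["dir_sleep"].mean()),
        "dir_a2_rate": float(table["dir_a2"].mean()),
        "dir_cosine_rate": float(table["dir_cosine"].mean()),
        "mean_n_included": float(table["n_included"].mean()),
    }
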