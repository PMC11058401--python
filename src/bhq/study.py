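"""The intervention-study model: a 2-group pre/post battery over a CohortFrame.

Organised like a statsmodels model: :class:`InterventionStudy` is constructed
from a tidy long table (participant, group, time, measure, value), and
``fit()`` returns a :class:`StudyResults` carrying the full battery —

* baseline group comparisons (pooled two-sample t per measure, plus a sex
  chi-square when demographics are supplied);
* per-measure Time-by-Group mixed-ANOVA interactions with partial eta squared
  and within-group paired t-tests (Cohen's d = t/sqrt(n)), with
  Benjamini-Hochberg adjustment over the regional brain family;
* per-group change-score correlation matrices (brain change x behavioral
  change) with exact-null t tests;
* Fisher r-to-z comparisons of the two groups' correlations, reporting both
  one- and two-sided tails.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats as bst

__all__ = ["InterventionStudy", "StudyResults", "analyze_study", "validate_cohort_frame"]

FRAME_COLUMNS = ["participant", "group", "time", "measure", "value"]
GROUPS = ("intervention", "control")
TIMES = ("pre", "post")


def round_half_up(x: float, digits: int = 3) -> float:
    """Display rounding matching conventional report tables (half away from 0)."""
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(abs(x))).quantize(q, rounding=ROUND_HALF_UP)) * (1 if x >= 0 else -1)


def validate_cohort_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FRAME_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"CohortFrame lacks columns {missing}")
    frame = frame[FRAME_COLUMNS].copy()
    bad_groups = set(frame["group"]) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"unknown groups {sorted(bad_groups)}")
    bad_times = set(frame["time"]) - set(TIMES)
    if bad_times:
        raise ValueError(f"unknown timepoints {sorted(bad_times)}")
    dup = frame.duplicated(subset=["participant", "time", "measure"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate (participant, time, measure) rows")
    return frame


def _change_table(frame: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Per-participant (group, pre, post, change) for one measure."""
    sub = frame[frame["measure"] == measure]
    wide = sub.pivot_table(
        index=["participant", "group"], columns="time", values="value", aggfunc="first"
    ).reset_index()
    wide = wide.dropna(subset=["pre", "post"])
    wide["change"] = wide["post"] - wide["pre"]
    return wide


class InterventionStudy:
    """Two-group pre/post study over quotient scores and behavioral measures.

    Parameters
    ----------
    frame
        Long CohortFrame with columns participant, group, time, measure, value.
    participants
        Optional demographics table with columns ``participant`` and ``sex``
        (and anything else); enables the baseline sex chi-square.
    regional_measures
        The brain measures forming the multiple-comparison family for the
        interaction tests.  Default: every measure named ``"fa_bhq:<region>"``.
    bh_level
        FDR level for the Benjamini-Hochberg step-up over that family.
    welch
        Use Welch instead of pooled-variance t for baseline comparisons.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        *,
        participants: pd.DataFrame | None = None,
        regional_measures: Sequence[str] | None = None,
        correlation_brain: Sequence[str] | None = None,
        correlation_behavior: Sequence[str] | None = None,
        bh_level: float = 0.05,
        welch: bool = False,
    ) -> None:
        self.frame = validate_cohort_frame(frame)
        self.participants = participants
        measures = list(dict.fromkeys(self.frame["measure"]))
        self.measures = measures
        self.brain_measures = [m for m in measures if m.startswith(("fa_bhq", "gm_bhq"))]
        self.behavioral_measures = [m for m in measures if m not in self.brain_measures]
        if regional_measures is None:
            regional_measures = [m for m in measures if m.startswith("fa_bhq:")]
        self.regional_measures = list(regional_measures)
        if correlation_brain is None:
            correlation_brain = [m for m in measures if m == "fa_bhq" or m.startswith("fa_bhq:")]
        self.correlation_brain = list(correlation_brain)
        self.correlation_behavior = list(
            correlation_behavior if correlation_behavior is not None else self.behavioral_measures
        )
        self.bh_level = bh_level
        self.welch = welch

    @classmethod
    def from_frames(
        cls,
        scores: pd.DataFrame,
        behavior: pd.DataFrame,
        participants: pd.DataFrame | None = None,
        **kwargs,
    ) -> "InterventionStudy":
        """Build from separate score and behavioral long tables.

        ``scores`` may omit the group column, in which case it is joined from
        ``behavior`` or ``participants``.
        """
        scores = scores.copy()
        if "group" not in scores.columns:
            if participants is not None and "group" in participants.columns:
                gmap = participants.set_index("participant")["group"]
            else:
                gmap = behavior.drop_duplicates("participant").set_index("participant")["group"]
            scores["group"] = scores["participant"].map(gmap)
        frame = pd.concat(
            [scores[FRAME_COLUMNS], behavior[FRAME_COLUMNS]], ignore_index=True
        )
        return cls(frame, participants=participants, **kwargs)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "StudyResults":
        notes: list[str] = []
        baseline = self._baseline_table()
        sex = self._sex_table()
        longitudinal = self._longitudinal_table(notes)
        correlations = {g: self._correlation_table(g) for g in GROUPS}
        fisher = self._fisher_table(correlations)
        notes.append(
            "fisher_z p-values are reported both one- and two-sided; printed "
            "study reports of this design quote one-sided tails under a "
            "two-sided significance rule"
        )
        return StudyResults(
            model=self,
            baseline=baseline,
            sex_comparison=sex,
            longitudinal=longitudinal,
            correlations=correlations,
            fisher=fisher,
            notes=notes,
        )

    def _baseline_table(self) -> pd.DataFrame:
        rows = []
        for m in self.measures:
            wide = _change_table(self.frame, m)
            gi = wide.loc[wide["group"] == "intervention", "pre"].to_numpy()
            gc = wide.loc[wide["group"] == "control", "pre"].to_numpy()
            if gi.size < 2 or gc.size < 2:
                continue
            try:
                res = bst.two_sample_t(gi, gc, welch=self.welch)
            except ValueError:
                continue
            rows.append(
                {
                    "measure": m,
                    "kind": "brain" if m in self.brain_measures else "behavioral",
                    "mean_intervention": gi.mean(),
                    "sd_intervention": np.std(gi, ddof=1),
                    "sem_intervention": np.std(gi, ddof=1) / np.sqrt(gi.size),
                    "mean_control": gc.mean(),
                    "sd_control": np.std(gc, ddof=1),
                    "sem_control": np.std(gc, ddof=1) / np.sqrt(gc.size),
                    "t": res.statistic,
                    "df": res.df,
                    "p": res.p_two_sided,
                    "n_intervention": gi.size,
                    "n_control": gc.size,
                }
            )
        return pd.DataFrame(rows)

    def _sex_table(self) -> pd.DataFrame | None:
        if self.participants is None or "sex" not in getattr(self.participants, "columns", []):
            return None
        part = self.participants
        ids = set(self.frame["participant"])
        part = part[part["participant"].isin(ids)]
        counts = {}
        for g in GROUPS:
            sub = part[part["group"] == g]
            counts[g] = {
                "male": int((sub["sex"] == "male").sum()),
                "female": int((sub["sex"] == "female").sum()),
            }
        res = bst.chi_square_2x2(
            counts["intervention"]["male"],
            counts["intervention"]["female"],
            counts["control"]["male"],
            counts["control"]["female"],
        )
        return pd.DataFrame(
            [
                {
                    "male_intervention": counts["intervention"]["male"],
                    "female_intervention": counts["intervention"]["female"],
                    "male_control": counts["control"]["male"],
                    "female_control": counts["control"]["female"],
                    "chi2": res.statistic,
                    "p": res.p_two_sided,
                }
            ]
        )

    def _longitudinal_table(self, notes: list[str]) -> pd.DataFrame:
        rows = []
        for m in self.measures:
            wide = _change_table(self.frame, m)
            try:
                anova = bst.mixed_anova_2x2(self.frame, m)
            except ValueError:
                continue
            if anova.extra.get("n_dropped_incomplete"):
                notes.append(
                    f"{m}: dropped {anova.extra['n_dropped_incomplete']} incomplete pre/post pairs"
                )
            row = {
                "measure": m,
                "kind": "brain" if m in self.brain_measures else "behavioral",
                "F": anova.statistic,
                "df1": anova.df[0],
                "df2": anova.df[1],
                "p_interaction": anova.p_two_sided,
                "partial_eta_sq": anova.effect_size,
            }
            for g in GROUPS:
                sub = wide[wide["group"] == g]
                pre, post = sub["pre"].to_numpy(), sub["post"].to_numpy()
                row[f"mean_pre_{g}"] = pre.mean()
                row[f"sd_pre_{g}"] = np.std(pre, ddof=1)
                row[f"mean_post_{g}"] = post.mean()
                row[f"sd_post_{g}"] = np.std(post, ddof=1)
                try:
                    pt = bst.paired_t(pre, post)
                    row[f"t_paired_{g}"] = pt.statistic
                    row[f"p_paired_{g}"] = pt.p_two_sided
                    row[f"cohens_d_{g}"] = pt.effect_size
                except ValueError:
                    row[f"t_paired_{g}"] = np.nan
                    row[f"p_paired_{g}"] = np.nan
                    row[f"cohens_d_{g}"] = np.nan
                # direction column: positive change means post > pre
                row[f"mean_change_{g}"] = post.mean() - pre.mean()
            rows.append(row)
        table = pd.DataFrame(rows)
        if not table.empty and self.regional_measures:
            fam = table["measure"].isin(self.regional_measures)
            if fam.any():
                adj, rej = bst.benjamini_hochberg(
                    table.loc[fam, "p_interaction"].to_numpy(), self.bh_level
                )
                table.loc[fam, "p_interaction_bh"] = adj
                table.loc[fam, "significant_bh"] = rej
        return table

    def _correlation_table(self, group: str) -> pd.DataFrame:
        changes = {
            m: _change_table(self.frame, m).set_index("participant")
            for m in set(self.correlation_brain) | set(self.correlation_behavior)
        }
        rows = []
        for bm in self.correlation_behavior:
            for br in self.correlation_brain:
                cb = changes[bm]
                cr = changes[br]
                cb = cb[cb["group"] == group]
                cr = cr[cr["group"] == group]
                common = cb.index.intersection(cr.index)
                if len(common) < 4:
                    continue
                try:
                    res = bst.pearson_change_correlation(
                        cr.loc[common, "change"].to_numpy(), cb.loc[common, "change"].to_numpy()
                    )
                except ValueError:
                    continue
                rows.append(
                    {
                        "behavior": bm,
                        "brain": br,
                        "r": res.extra["r"],
                        "t": res.statistic,
                        "p": res.p_two_sided,
                        "n": res.n,
                    }
                )
        return pd.DataFrame(rows)

    def _fisher_table(self, correlations: dict[str, pd.DataFrame]) -> pd.DataFrame:
        ci = correlations["intervention"]
        cc = correlations["control"]
        if ci.empty or cc.empty:
            return pd.DataFrame()
        merged = ci.merge(cc, on=["behavior", "brain"], suffixes=("_intervention", "_control"))
        rows = []
        for _, row in merged.iterrows():
            try:
                cmp_ = bst.fisher_z_compare(
                    row["r_intervention"],
                    int(row["n_intervention"]),
                    row["r_control"],
                    int(row["n_control"]),
                )
            except ValueError:
                continue
            rows.append(
                {
                    "behavior": row["behavior"],
                    "brain": row["brain"],
                    "r_intervention": row["r_intervention"],
                    "r_control": row["r_control"],
                    "z": cmp_.z,
                    "p_one_sided": cmp_.p_one_sided,
                    "p_two_sided": cmp_.p_two_sided,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class StudyResults:
    """Fitted battery: report tables plus machine-readable full precision."""

    model: InterventionStudy
    baseline: pd.DataFrame
    sex_comparison: pd.DataFrame | None
    longitudinal: pd.DataFrame
    correlations: dict[str, pd.DataFrame]
    fisher: pd.DataFrame
    notes: list[str] = field(default_factory=list)

    def summary(self, digits: int = 3) -> str:
        """Human-readable report, rounded half-up to ``digits`` decimals."""

        def fmt(df: pd.DataFrame) -> str:
            if df is None or df.empty:
                return "  (none)"
            shown = df.copy()
            for c in shown.columns:
                if shown[c].dtype.kind == "f":
                    shown[c] = shown[c].map(lambda v: round_half_up(v, digits))
            return shown.to_string(index=False)

        parts = [
            "Intervention study battery",
            "==========================",
            "",
            "Baseline group comparison (pooled two-sample t, control - intervention)",
            fmt(self.baseline),
            "",
            "Sex distribution (Pearson chi-square, df = 1)",
            fmt(self.sex_comparison),
            "",
            "Time x Group interaction and within-group paired tests",
            fmt(self.longitudinal),
            "",
            "Change-score correlations, intervention group",
            fmt(self.correlations.get("intervention", pd.DataFrame())),
            "",
            "Change-score correlations, control group",
            fmt(self.correlations.get("control", pd.DataFrame())),
            "",
            "Between-group comparison of change correlations (Fisher r-to-z)",
            fmt(self.fisher),
            "",
            "Notes",
            *(f"- {n}" for n in self.notes),
        ]
        return "\n".join(parts)

    def to_dict(self) -> dict:
        def df_dict(df):
            return None if df is None else json.loads(df.to_json(orient="records"))

        return {
            "baseline": df_dict(self.baseline),
            "sex_comparison": df_dict(self.sex_comparison),
            "longitudinal": df_dict(self.longitudinal),
            "correlations": {g: df_dict(t) for g, t in self.correlations.items()},
            "fisher": df_dict(self.fisher),
            "notes": self.notes,
        }

    def save(self, out_dir: str | Path) -> dict[str, str]:
        """Write CSV report tables and a JSON bundle; returns the file index."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        index: dict[str, str] = {}

        def put(name: str, df: pd.DataFrame | None):
            if df is None:
                return
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            index[name] = str(path)

        put("baseline", self.baseline)
        put("sex_comparison", self.sex_comparison)
        put("longitudinal", self.longitudinal)
        for g, t in self.correlations.items():
            put(f"correlations_{g}", t)
        put("fisher_comparisons", self.fisher)
        bundle = out / "results.json"
        bundle.write_text(json.dumps(self.to_dict(), indent=1))
        index["results_json"] = str(bundle)
        (out / "summary.txt").write_text(self.summary())
        index["summary"] = str(out / "summary.txt")
        return index


def analyze_study(frame: pd.DataFrame, **kwargs) -> StudyResults:
    """One-call battery: build the model from a CohortFrame and fit it."""
    return InterventionStudy(frame, **kwargs).fit()
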