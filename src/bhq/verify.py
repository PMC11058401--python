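"""Recompute every closed-form published statistic from its printed inputs.

Each check recomputes a statistic (baseline t, chi-square, partial eta
squared, F p-value, paired Cohen's d and p, correlation p, Fisher z and p,
the BH rejection set, the power-analysis sample size, the screening
arithmetic) from the printed summary numbers it is a function of, and
compares at printed precision.  Tolerances reflect only the propagation of
the inputs' 3-decimal rounding.

One check is an internal-consistency flag rather than an identity: the mean
of per-person TMT B-A differences versus the difference of the TMT B and
TMT A means.  The control group is exactly consistent; the intervention
group's printed values are not (31.641 vs 29.227), which is reported as a
known source inconsistency.
"""

from __future__ import annotations

import math

import pandas as pd

from . import printed, stats as bst
from .simulate import Participant, apply_exclusions

__all__ = ["verify_printed_statistics"]

N = printed.N_PER_GROUP

# tolerance per derivation, dominated by 3-dp rounding of the printed inputs
TOL_T_FROM_SUMMARY = 0.010
TOL_P_FROM_SUMMARY = 0.010
TOL_3DP = 0.0015
TOL_P_FROM_F = 0.005
TOL_P_FROM_T = 0.005
TOL_P_FROM_R = 0.0035
TOL_Z = 0.002
TOL_P_FISHER = 0.003


def _row(check, target, expected, computed, tol, note=""):
    passed = bool(abs(computed - expected) <= tol) if expected is not None else None
    return {
        "check": check,
        "target": target,
        "expected": expected,
        "computed": computed,
        "tol": tol,
        "passed": passed,
        "note": note,
    }


def verify_printed_statistics(
    table1: dict | None = None,
    longitudinal: dict | None = None,
    correlations_intervention: dict | None = None,
    correlations_control: dict | None = None,
    fisher: tuple | None = None,
) -> pd.DataFrame:
    """Pass/fail table over every recomputable printed statistic.

    The keyword arguments default to the embedded printed tables; they exist
    so that sensitivity analyses can perturb an input and watch the matching
    check fail.
    """
    t1 = table1 if table1 is not None else printed.TABLE1
    lng = longitudinal if longitudinal is not None else printed.LONGITUDINAL
    corr_i = (
        correlations_intervention
        if correlations_intervention is not None
        else printed.CHANGE_CORRELATIONS_INTERVENTION
    )
    corr_c = (
        correlations_control
        if correlations_control is not None
        else printed.CHANGE_CORRELATIONS_CONTROL
    )
    fz = fisher if fisher is not None else printed.FISHER_COMPARISONS

    rows: list[dict] = []

    # baseline two-sample t from printed means/SDs
    for m, (mi, si, mc, sc, t_pr, p_pr) in t1.items():
        res = bst.two_sample_t_from_stats(mi, si, N, mc, sc, N)
        rows.append(_row("baseline_t", m, t_pr, abs(res.statistic), TOL_T_FROM_SUMMARY))
        rows.append(_row("baseline_p", m, p_pr, res.p_two_sided, TOL_P_FROM_SUMMARY))

    a, b, c, d, chi_pr, chi_p_pr = printed.TABLE1_SEX
    chi = bst.chi_square_2x2(a, b, c, d)
    rows.append(_row("sex_chi_square", "sex", chi_pr, chi.statistic, TOL_3DP))
    rows.append(_row("sex_chi_square_p", "sex", chi_p_pr, chi.p_two_sided, TOL_3DP))

    # interaction effect sizes and p-values from printed F with df (1, 68)
    df1, df2 = 1.0, 2.0 * N - 2.0
    from scipy import stats as sps

    for m, (F, p_pr, eta_pr, g_int, g_ctl) in lng.items():
        if F > 0:
            rows.append(
                _row("partial_eta_sq", m, eta_pr, bst.partial_eta_squared(F, df1, df2), TOL_3DP)
            )
            rows.append(_row("interaction_p", m, p_pr, float(sps.f.sf(F, df1, df2)), TOL_P_FROM_F))
        for group, stats7 in (("intervention", g_int), ("control", g_ctl)):
            _, _, _, _, t_paired, p_paired, d_pr = stats7
            rows.append(
                _row(
                    "cohens_d",
                    f"{m}/{group}",
                    d_pr,
                    t_paired / math.sqrt(N),
                    TOL_3DP,
                    "d = t / sqrt(n)",
                )
            )
            rows.append(
                _row(
                    "paired_p",
                    f"{m}/{group}",
                    p_paired,
                    float(2.0 * sps.t.sf(abs(t_paired), N - 1)),
                    TOL_P_FROM_T,
                )
            )

    # correlation-test p-values from printed r with n = 35
    for group, table in (("intervention", corr_i), ("control", corr_c)):
        for behavior, cells in table.items():
            for brain, (r, p_pr) in zip(printed.CORRELATION_COLUMNS, cells):
                if abs(r) >= 1.0:
                    continue
                dfree = N - 2
                if r == 0.0:
                    p = 1.0
                else:
                    t = r * math.sqrt(dfree) / math.sqrt(1.0 - r * r)
                    p = float(2.0 * sps.t.sf(abs(t), dfree))
                rows.append(
                    _row("correlation_p", f"{behavior}~{brain}/{group}", p_pr, p, TOL_P_FROM_R)
                )

    # Fisher r-to-z between-group comparisons from the two printed r tables
    col_index = {name: i for i, name in enumerate(printed.CORRELATION_COLUMNS)}
    for behavior, brain, z_pr, p_pr in fz:
        r1 = corr_i[behavior][col_index[brain]][0]
        r2 = corr_c[behavior][col_index[brain]][0]
        cmp_ = bst.fisher_z_compare(r1, N, r2, N)
        rows.append(_row("fisher_z", f"{behavior}~{brain}", z_pr, cmp_.z, TOL_Z))
        rows.append(
            _row(
                "fisher_p",
                f"{behavior}~{brain}",
                p_pr,
                cmp_.p_one_sided,
                TOL_P_FISHER,
                "printed p matches the one-sided normal tail",
            )
        )

    # BH step-up over the eight regional interaction p-values
    fam = list(printed.REGIONAL_FAMILY)
    pvals = [lng[m][1] for m in fam]
    _, reject = bst.benjamini_hochberg(pvals, 0.05)
    rejected = {m for m, rj in zip(fam, reject) if rj}
    expected_set = set(printed.REGIONS_SIGNIFICANT_BH)
    rows.append(
        {
            "check": "bh_regional_rejections",
            "target": "regional interaction family (m=8)",
            "expected": float(len(expected_set)),
            "computed": float(len(rejected)),
            "tol": 0.0,
            "passed": rejected == expected_set,
            "note": "BH step-up reproduces the published significant set",
        }
    )

    # a-priori sample size from the noncentral-t power analysis
    rows.append(
        _row(
            "power_sample_size",
            "paired t, d=.5, alpha=.05, power=.80",
            float(printed.DESIGN["power_required_n"]),
            float(
                bst.power_paired_n(
                    printed.DESIGN["power_effect_size_d"],
                    printed.DESIGN["power_alpha"],
                    printed.DESIGN["power_target"],
                )
            ),
            0.0,
        )
    )

    # screening arithmetic via the exclusion operation itself
    pool = (
        [
            Participant(f"R{i:03d}", "intervention", 50, "female", cesd=5)
            for i in range(printed.DESIGN["retained"])
        ]
        + [
            Participant(f"X{i:03d}", "control", 50, "female", cesd=20)
            for i in range(printed.DESIGN["excluded_cesd"])
        ]
        + [Participant("I000", "control", 50, "male", cesd=5, imaging_ok=False)]
    )
    retained, log = apply_exclusions(pool)
    rows.append(
        _row(
            "screening_count",
            f"{printed.DESIGN['recruited']} recruited",
            float(printed.DESIGN["retained"]),
            float(len(retained)),
            0.0,
            f"{len(log)} exclusions logged",
        )
    )

    # TMT B-A internal consistency (not an identity; see module docstring)
    for group, idx in (("intervention", 0), ("control", 2)):
        diff_of_means = t1["tmt_b"][idx] - t1["tmt_a"][idx]
        printed_mean = t1["tmt_b_a"][idx]
        known_bad = group == "intervention"
        rows.append(
            _row(
                "tmt_consistency",
                group,
                printed_mean,
                diff_of_means,
                TOL_3DP,
                "known source inconsistency" if known_bad else "",
            )
        )

    return pd.DataFrame(rows)
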