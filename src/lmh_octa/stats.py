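"""Small-sample statistical battery for two-group OCTA cohorts.

Implements the test selection used for the cohort tables: a Shapiro-Wilk
normality gate chooses between mean/SD + t test and median/IQR +
Mann-Whitney; paired BCVA/IOP changes use the Wilcoxon signed-rank test;
categorical prevalences use Fisher's exact test (chi-square with continuity
correction when all expected cells reach 5); monotone associations use
Spearman's rank correlation; grader agreement uses the two-way random
single-measure absolute-agreement ICC, i.e. ICC(2,1).

At the study's sample size (14 eyes per group) asymptotic p-values are not
trustworthy, so the exact null distributions are enumerated:

* Mann-Whitney U — full permutation distribution of the rank sum for
  ``n_x + n_y <= 20`` (ties handled through average ranks);
* Wilcoxon signed-rank — dynamic program over the signed-rank sum for up to
  25 nonzero pairs (average ranks doubled to keep integer support);
* Spearman — full enumeration of the ``n!`` rank permutations for
  ``n <= 8``, seeded Monte-Carlo permutation p beyond.

Two-sided p-values are ``min(1, 2 * min(P(T <= t), P(T >= t)))``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatReport",
    "normality_gate",
    "descriptives",
    "compare_groups",
    "paired_test",
    "mann_whitney",
    "signed_rank",
    "spearman",
    "icc_two_way",
    "categorical_test",
    "build_results_tables",
    "count_percent",
]

#: seed of the Monte-Carlo permutation fallback (overridable per call)
DEFAULT_PERMUTATION_SEED = 20210919
#: number of Monte-Carlo permutations when exact enumeration is infeasible
N_PERMUTATIONS = 100_000


@dataclass
class StatReport:
    """Outcome of one hypothesis test, plus the gated descriptives."""

    variable: str
    test_name: str
    statistic: float
    p_value: float
    descriptives: dict = field(default_factory=dict)
    paired: bool = False
    degenerate: bool = False
    notes: str = ""


# ---------------------------------------------------------------------------
# normality gate and descriptives
# ---------------------------------------------------------------------------

def normality_gate(x, alpha: float = 0.05) -> str:
    """Shapiro-Wilk gate: ``"non_normal"`` iff its p-value < ``alpha``."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("normality gate needs at least 3 observations")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk is unreliable beyond n=5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: variance undefined for the gate")
    _, p = sps.shapiro(x)
    return "non_normal" if p < alpha else "normal"


def descriptives(x, gate: str) -> tuple[float, float]:
    """(location, spread): median/IQR if non-normal, mean/SD (n-1) if normal.

    Quantiles use linear interpolation (numpy default, type 7).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if gate == "normal":
        return float(np.mean(x)), float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), float(q3 - q1)


def count_percent(k: int, n: int, decimals: int = 2) -> float:
    """Prevalence as a percentage truncated (not rounded) at ``decimals``."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    scale = 10**decimals
    return math.floor(100.0 * k / n * scale) / scale


# ---------------------------------------------------------------------------
# exact two-sample tests
# ---------------------------------------------------------------------------

def _two_sided_from_counts(n_le: float, n_ge: float, total: float) -> float:
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def mann_whitney(x, y) -> StatReport:
    """Two-sided Mann-Whitney U.

    Exact permutation null (all ``C(n, n_x)`` group assignments of the
    pooled average ranks) when ``n_x + n_y <= 20``; normal approximation
    with tie correction otherwise.  All-tied data yield a degenerate p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)

    if np.ptp(pooled) == 0:
        return StatReport(
            variable="", test_name="mann_whitney_exact", statistic=u_obs,
            p_value=1.0, degenerate=True, notes="all observations tied",
        )

    n = nx + ny
    if n <= 20:
        offset = nx * (nx + 1) / 2.0
        us = np.fromiter(
            (ranks[list(c)].sum() - offset for c in itertools.combinations(range(n), nx)),
            dtype=float,
        )
        tol = 1e-9
        p = _two_sided_from_counts(
            np.count_nonzero(us <= u_obs + tol),
            np.count_nonzero(us >= u_obs - tol),
            us.size,
        )
        return StatReport(
            variable="", test_name="mann_whitney_exact", statistic=u_obs, p_value=p
        )

    mu = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return StatReport(
            variable="", test_name="mann_whitney_asymptotic", statistic=u_obs,
            p_value=1.0, degenerate=True, notes="zero variance under ties",
        )
    # continuity-corrected two-sided normal approximation
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return StatReport(
        variable="", test_name="mann_whitney_asymptotic", statistic=u_obs, p_value=p
    )


def signed_rank(before, after) -> StatReport:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon convention).  Exact null via a
    dynamic program over the positive-rank sum for up to 25 nonzero pairs
    (average ranks are doubled so tied ranks keep integer support); normal
    approximation with tie correction beyond.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    if before.size < 2:
        raise ValueError("need at least 2 pairs")
    d = after - before
    d = d[d != 0]
    m = d.size
    if m == 0:
        return StatReport(
            variable="", test_name="wilcoxon_signed_rank", statistic=0.0,
            p_value=1.0, paired=True, degenerate=True,
            notes="all differences zero",
        )
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())

    if m <= 25:
        # distribution of the doubled positive-rank sum over the 2^m signs
        doubled = np.rint(2 * ranks).astype(int)
        support = int(doubled.sum())
        counts = np.zeros(support + 1, dtype=float)
        counts[0] = 1.0
        for r in doubled:
            counts[r:] += counts[: support + 1 - r]
        total = counts.sum()  # == 2**m
        w2 = int(round(2 * w_pos))
        p = _two_sided_from_counts(counts[: w2 + 1].sum(), counts[w2:].sum(), total)
        return StatReport(
            variable="", test_name="wilcoxon_signed_rank_exact",
            statistic=w_pos, p_value=p, paired=True,
        )

    mu = m * (m + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    sigma2 = m * (m + 1) * (2 * m + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    z = (abs(w_pos - mu) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return StatReport(
        variable="", test_name="wilcoxon_signed_rank_asymptotic",
        statistic=w_pos, p_value=p, paired=True,
    )


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def spearman(x, y, seed: int = DEFAULT_PERMUTATION_SEED) -> tuple[float, float]:
    """Spearman rank correlation with a permutation p-value.

    Average ranks for ties.  Exact enumeration of all ``n!`` permutations
    for ``n <= 8``; otherwise ``N_PERMUTATIONS`` Monte-Carlo permutations
    with a fixed seed.  Two-sided p on ``|rho|``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4 or y.size != n:
        raise ValueError("need paired samples with n >= 4")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero variance in ranks")
    rho = _spearman_rho(rx, ry)

    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    norm = math.sqrt((rxc @ rxc) * (ryc @ ryc))
    tol = 1e-12
    if n <= 8:
        perms = np.array(list(itertools.permutations(ryc)))
        rhos = perms @ rxc / norm
        p = float(np.mean(np.abs(rhos) >= abs(rho) - tol))
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(N_PERMUTATIONS):
            rhos = (rng.permutation(ryc) @ rxc) / norm
            hits += abs(rhos) >= abs(rho) - tol
        p = (hits + 1) / (N_PERMUTATIONS + 1)  # add-one Monte-Carlo correction
    return rho, p


def icc_two_way(ratings) -> StatReport:
    """ICC(2,1): two-way random-effects, single measure, absolute agreement.

    From the two-way ANOVA mean squares of an ``n x k`` table (subjects by
    raters):  ``(MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))``.
    Undefined (NaN, flagged) when there is no between-subject variance.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need an n>=2 by k>=2 complete ratings matrix")
    if np.isnan(m).any():
        raise ValueError("missing cells are not supported")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((m - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if ssr <= 1e-12 * max(sst, 1.0) or abs(denom) < 1e-300:
        return StatReport(
            variable="", test_name="icc_2_1", statistic=float("nan"),
            p_value=float("nan"), degenerate=True,
            notes="no between-subject variance: ICC undefined",
        )
    icc = float((msr - mse) / denom)
    return StatReport(variable="", test_name="icc_2_1", statistic=icc, p_value=float("nan"))


def categorical_test(table) -> StatReport:
    """2x2 prevalence comparison.

    Fisher's exact test (two-sided) whenever any expected cell count is
    below 5, chi-square with continuity correction otherwise.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.rint(t)):
        raise ValueError("need a 2x2 table of nonnegative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("empty margin in contingency table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected < 5).any():
        stat, p = sps.fisher_exact(np.rint(t).astype(int), alternative="two-sided")
        return StatReport(variable="", test_name="fisher_exact", statistic=float(stat), p_value=float(p))
    chi2, p, _, _ = sps.chi2_contingency(t, correction=True)
    return StatReport(variable="", test_name="chi2_yates", statistic=float(chi2), p_value=float(p))


# ---------------------------------------------------------------------------
# gated comparisons
# ---------------------------------------------------------------------------

def compare_groups(x, y, gates: tuple[str, str] | None = None, welch: bool = True) -> StatReport:
    """Between-group comparison with the normality gate.

    Both samples normal -> two-tailed independent t test (Welch by
    default); otherwise Mann-Whitney.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if gates is None:
        try:
            gates = (normality_gate(x), normality_gate(y))
        except ValueError:
            gates = ("non_normal", "non_normal")
    if gates[0] == "normal" and gates[1] == "normal":
        stat, p = sps.ttest_ind(x, y, equal_var=not welch)
        rep = StatReport(
            variable="", test_name="welch_t" if welch else "student_t",
            statistic=float(stat), p_value=float(p),
        )
    else:
        rep = mann_whitney(x, y)
    rep.descriptives = {
        "x": dict(zip(("location", "spread"), descriptives(x, gates[0]))) | {"gate": gates[0]},
        "y": dict(zip(("location", "spread"), descriptives(y, gates[1]))) | {"gate": gates[1]},
    }
    return rep


def paired_test(before, after) -> StatReport:
    """Within-group change over time (Wilcoxon signed-rank)."""
    return signed_rank(before, after)


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

#: quantitative rows of the clinical table: column -> printed label
TABLE1_QUANTITATIVE = {
    "age": "Age (years)",
    "bcva_baseline": "BCVA at baseline (decimals)",
    "bcva_followup": "BCVA at last follow up (decimals)",
    "followup_years": "Follow up duration (years)",
    "se_diopters": "SE (D)",
    "iop_baseline": "IOP at baseline (mmHg)",
    "iop_followup": "IOP at last follow up (mmHg)",
}

TABLE1_CATEGORICAL = {
    "sex_male": "Sex (male)",
    "cv_dementia_stroke": "CV or dementia or previous stroke",
    "diabetes": "Diabetes mellitus",
    "sah": "SAH",
    "pseudophakia": "Pseudophakia",
}

TABLE2_CATEGORICAL = {
    "pvd_complete": "PVD complete",
    "pvd_incomplete": "PVD incomplete",
    "ez_disruption": "EZ disruption",
    "lhep": "LHEP",
}

TABLE2_QUANTITATIVE = {
    "scp_cfz_circularity": "SCP CFZ circularity",
    "scp_cfz_area_mm2": "SCP CFZ area (mm2)",
    "scp_cfz_perimeter_mm": "SCP CFZ perimeter (mm)",
    "scp_foveal_vd": "SCP Foveal VD (%)",
    "scp_foveal_pd": "SCP Foveal PD (%)",
    "scp_parafoveal_vd": "SCP Parafoveal VD (%)",
    "scp_parafoveal_pd": "SCP Parafoveal PD (%)",
    "dcp_cfz_circularity": "DCP CFZ circularity",
    "dcp_cfz_area_mm2": "DCP CFZ area (mm2)",
    "dcp_cfz_perimeter_mm": "DCP CFZ perimeter (mm)",
    "dcp_foveal_vd": "DCP Foveal VD (%)",
    "dcp_foveal_pd": "DCP Foveal PD (%)",
    "dcp_parafoveal_vd": "DCP Parafoveal VD (%)",
    "dcp_parafoveal_pd": "DCP Parafoveal PD (%)",
}


class MissingColumnsError(KeyError):
    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"cohort table lacks required columns: {', '.join(self.missing)}")


def _quant_row(label, x, y, welch=True):
    rep = compare_groups(x, y, welch=welch)
    dx, dy = rep.descriptives["x"], rep.descriptives["y"]
    return {
        "variable": label,
        "tl_location": dx["location"], "tl_spread": dx["spread"], "tl_style": dx["gate"],
        "st_location": dy["location"], "st_spread": dy["spread"], "st_style": dy["gate"],
        "test": rep.test_name, "statistic": rep.statistic, "p_value": rep.p_value,
    }


def _cat_row(label, tl: pd.Series, st: pd.Series):
    k_tl, n_tl = int(tl.sum()), int(tl.size)
    k_st, n_st = int(st.sum()), int(st.size)
    try:
        rep = categorical_test([[k_tl, n_tl - k_tl], [k_st, n_st - k_st]])
    except ValueError:
        # an empty margin (nobody / everybody positive) carries no contrast
        rep = StatReport(variable=label, test_name="degenerate",
                         statistic=float("nan"), p_value=float("nan"),
                         degenerate=True)
    return {
        "variable": label,
        "tl_count": f"{k_tl}/{n_tl}", "tl_percent": count_percent(k_tl, n_tl),
        "st_count": f"{k_st}/{n_st}", "st_percent": count_percent(k_st, n_st),
        "test": rep.test_name, "statistic": rep.statistic, "p_value": rep.p_value,
    }


def build_results_tables(cohort: pd.DataFrame, welch: bool = True,
                         spearman_seed: int = DEFAULT_PERMUTATION_SEED) -> dict[str, pd.DataFrame]:
    """Recompute the full cohort analysis on a per-patient table.

    Returns ``table1`` (clinical), ``table2`` (structural + OCTA),
    ``paired`` (within-group BCVA/IOP changes), and ``correlations``
    (TL-group Spearman links plus the ROI-vs-other-quadrants PD contrast).
    """
    work = cohort.copy()
    if "pvd" in work.columns:
        work["pvd_complete"] = work["pvd"] == "complete"
        work["pvd_incomplete"] = work["pvd"] == "incomplete"
    required = (
        {"group", "tl_top3_mm2", "tl_speed_mm2_per_year",
         "scp_roi_pd", "scp_r1_pd", "scp_r2_pd", "scp_r3_pd"}
        | set(TABLE1_QUANTITATIVE) | set(TABLE1_CATEGORICAL)
        | set(TABLE2_CATEGORICAL) | set(TABLE2_QUANTITATIVE)
    )
    missing = required - set(work.columns)
    if missing:
        raise MissingColumnsError(missing)

    tl = work[work["group"] == "TL"]
    st = work[work["group"] == "ST"]
    if len(tl) < 2 or len(st) < 2:
        raise ValueError("both groups need at least 2 patients")

    table1 = pd.DataFrame(
        [_quant_row(lbl, tl[c], st[c], welch) for c, lbl in TABLE1_QUANTITATIVE.items()]
        + [_cat_row(lbl, tl[c], st[c]) for c, lbl in TABLE1_CATEGORICAL.items()]
    )
    table2 = pd.DataFrame(
        [_cat_row(lbl, tl[c].astype(bool), st[c].astype(bool)) for c, lbl in TABLE2_CATEGORICAL.items()]
        + [_quant_row(lbl, tl[c], st[c], welch) for c, lbl in TABLE2_QUANTITATIVE.items()]
    )

    paired_rows = []
    for grp_name, grp in (("TL", tl), ("ST", st)):
        for var, base_c, fu_c in (
            ("BCVA", "bcva_baseline", "bcva_followup"),
            ("IOP", "iop_baseline", "iop_followup"),
        ):
            rep = paired_test(grp[base_c].to_numpy(), grp[fu_c].to_numpy())
            paired_rows.append(
                {"group": grp_name, "variable": var, "test": rep.test_name,
                 "statistic": rep.statistic, "p_value": rep.p_value}
            )
    paired = pd.DataFrame(paired_rows)

    corr_rows = []

    def _corr(label, x, y):
        if len(tl) < 4:  # permutation p needs n >= 4
            corr_rows.append({"variables": label + " [too few patients]",
                              "rho": float("nan"), "p_value": float("nan"),
                              "n": len(tl)})
            return
        rho, p = spearman(x, y, seed=spearman_seed)
        corr_rows.append({"variables": label, "rho": rho, "p_value": p, "n": len(tl)})

    _corr("TL amount vs SCP parafoveal PD (TL group)",
          tl["tl_top3_mm2"], tl["scp_parafoveal_pd"])
    _corr("Speed of TL vs BCVA decline (TL group)",
          tl["tl_speed_mm2_per_year"],
          (tl["bcva_baseline"] - tl["bcva_followup"]).to_numpy())
    other = tl[["scp_r1_pd", "scp_r2_pd", "scp_r3_pd"]].mean(axis=1).to_numpy()
    rep = paired_test(other, tl["scp_roi_pd"].to_numpy())
    corr_rows.append({"variables": "SCP parafoveal PD: ROI vs other quadrants (TL group)",
                      "rho": float("nan"), "p_value": rep.p_value, "n": len(tl)})
    correlations = pd.DataFrame(corr_rows)

    return {"table1": table1, "table2": table2, "paired": paired,
            "correlations": correlations}
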